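# Methods

## The simulated experiment

The simulator (`circprio.synthetic_data`) emulates the statistical
structure of a two-fraction circRNA sequencing study, not any particular
genome. A toy single-chromosome annotation is drawn with uniform random
nucleotides; genes have 2–8 exons of 100–300 nt separated by 50–200 nt
introns, on either strand (exon indices on molecules are always
transcript-order, 5′→3′). Defaults mirror a typical design: two cell
contexts × three groups (control plus two treatments) × four replicates;
most analyses in the tests use one context with control/treatment × 4.

Three molecule species are simulated per gene:

* **linear mRNA** over all exons, polyadenylated; expected copy number
  log-normal(μ=4, σ=1) (median ≈ 55 copies),
* **exonic circle** over a random contiguous exon span in a configurable
  fraction of genes (`circ_rate`, default 0.3), never polyadenylated;
  copy number log-normal(μ=1, σ=1.5) — mostly very low counts with a heavy
  right tail, as circRNA libraries are dominated by lowly expressed
  circles,
* **exon-repetition transcript** (one contiguous exon block duplicated in
  tandem) in a disjoint `exonrep_rate` fraction (default 0.05),
  polyadenylated, with abundance a factor 10 below the circle prior —
  these linear back-spliced species are far rarer and weaker than circles.

Treatment effects multiply expected copy numbers by 2^log2FC in treatment
groups; realized copy numbers are Poisson draws, and the ground truth
records the planted expectations and fold changes per feature.

Fractionation is per-copy binomial thinning: the poly(A) fraction keeps
polyadenylated molecules with probability `polya_capture` (default 1) and
circles with `polya_circle_leak` (default 0); the RNase R fraction keeps
linear copies with `rnaser_linear_survival` (default 0.02) and circles
with `rnaser_circle_survival` (default 0.95). No published RNase R
efficiency was adopted; these are stated configuration values chosen to
give a strong (≈50-fold) but imperfect enrichment.

Reads are 75-nt single-end (constant Phred 30 — qualities are unused
downstream), drawn per sample with molecules weighted by copy number ×
mature length, start positions uniform, and circles treated as periodic
sequences so reads can wrap the back-splice point. Per-base substitution
errors at `error_rate` (default 0). Not modeled: paired ends, indels, PCR
duplicates, GC bias, fragment-size effects, intron-lariat circles. Because
reads are emitted on the mature-transcript strand (stranded protocol) and
molecule weights are exact, passing tests demonstrate correctness of the
counting and inference machinery — not robustness to alignment artifacts,
unannotated boundaries or biased coverage found in real libraries.

## Junction detection

The junction library is annotation-constrained: forward junctions for each
adjacent exon pair and a back-splice candidate for every ordered exon pair
(donor ≥ acceptor, including single-exon circles). Flanks are
`read_len − min_overhang` nt (55 by default), truncated at transcript
ends, so any read satisfying the overhang rule fits inside the junction
sequence. BSJ coordinates are reported BED-style, 0-based half-open,
(chrom, leftmost partner-exon start, rightmost partner-exon end).

Matching is ungapped and exact in semantics: a read counts for a junction
iff some placement leaves ≥ `min_overhang` (20) bases on each side of the
splice point with ≤ `max_mismatch` (2) substitutions over the full read.
A pigeonhole seed index ((m+1)-way read partition; any placement with
≤ m mismatches contains one exact part) accelerates the scan but is
checked against a brute-force all-placements oracle in the tests. Reads
matching several junctions go to the fewest-mismatch one; ties are dropped
as ambiguous (conservative, deterministic). Reads matching no junction but
matching a gene's mature transcript are counted to that gene's linear
body; `gene_linear_counts()` adds forward-junction reads back so that a
gene's linear support is body + colinear junctions. Circles with mature
length below ~read_len/2 cannot present a full-length placement inside a
one-period junction window and are undetectable by design.

Classification compares mean BSJ support between fractions: circular if
the RNase R mean reaches `min_support` (2) and exceeds poly(A) support
`dominance`-fold (5); the mirror pattern gives linear back-spliced;
support in both without dominance is ambiguous (a gene can host both
species); below support in both, no call.

## Differential expression

Median-of-ratios size factors use the geometric-mean reference over
features nonzero in all samples, with an explicit pseudo-reference
fallback (geometric mean over nonzero entries) that must be requested.
Factors are defined up to a common scale, as usual; depth changes move a
sample's factor proportionally and leave between-sample normalized ratios
unchanged. The low-expression filter removes a feature iff more than two
samples have normalized counts < 1 *and* the mean over all samples is
below the cutoff (2); both clauses are required, and the mean cutoffs
(2 and 40) are always applied to means over all samples of a cell context.

The Wald test fits per-group gamma-Poisson means on normalized counts.
Dispersions are pooled within-group method-of-moments estimates
α̂ = (s² − μ)/μ², shrunk 50/50 toward a fitted trend α(μ) = a₀ + a₁/μ
(least squares on the raw estimates, coefficients clipped at 0). The
shrunk value is floored at −0.3/μ rather than 0: moment noise around a
near-zero true dispersion is symmetric, and clipping it at zero inflates
standard errors enough to visibly depress the null rejection rate
(~0.03 instead of 0.05 at 4 vs 4 replicates); allowing a modest
sub-Poisson dip restores calibration while the total variance term
1/μ + α stays positive. SE(log₂FC) comes from the delta method,
Var(log mean_g) ≈ (1/μ_g + α)/n_g; p is two-sided normal; BH adjustment
over tested features. Zero group means get a 0.5 pseudocount on both
means and are flagged. This estimator is deliberately *not* a numerical
clone of DESeq2; its contract is parameter recovery and calibration,
which the acceptance checks measure. Known limitations: no multi-factor
designs, no LFC shrinkage, no outlier handling, and compositional bias
when a dominant feature changes (visible in the README example).

## Ratio analysis

Circles pair to host-gene linear counts by the `<gene>:bsj:<i>-<j>` id
convention (or an explicit map); circles without detected host linear
counts are kept but flagged and excluded from ratio operations. Spearman's
ρ uses log₂(mean + 1) with average ranks and the large-sample t
approximation. Per-sample ratios add a pseudocount of 1 to the denominator
only where the per-sample linear count is 0, preserving exact ratios
elsewhere; rows are z-scored with population (ddof = 0) SD so each
non-constant row has mean 0 and SD 1 to machine precision; constant rows
become zeros with a warning. Normalized counts are used for ratios,
consistent with the count-normalized cutoff semantics.

Hierarchical clustering is average linkage on Euclidean distances with an
explicit agglomeration loop so the tie-break (merge the lowest-index pair
among equal distances) is part of the contract; merge heights agree with
the standard library implementation whenever distances are unique. The
clustering contract here is structural (merge order, determinism), not
figure reproduction.

## Candidate selection

Stages run in a configured order over survivors only, so per-stage counts
are non-increasing, and every circle carries a (status, triggering value)
pair per stage from which each decision can be recomputed. Deduplication
keys on BSJ coordinates when present (id otherwise), keeps the most
abundant row per junction and removes assembly-only (unannotated) rows.
Reference matching uses circBase-style ids; unmatched circles are excluded
and logged; fold-change bounds (> 2, < 0.5) are strict, and a zero
reference with nonzero expression selects with an infinite-ratio flag.
Wet-lab outcomes (Sanger validation, "detected by qPCR") enter only as
externally supplied predicates; the Ct < 30 reliability stage consumes the
qPCR module's filter. The discordance call requires the circle
significantly down (adjusted p < α = 0.05, test group below reference)
with the host mRNA non-significant; mRNA also significantly down is
concordant; anything else is unflagged. The call is agnostic to whether
the per-feature statistics come from qPCR Welch tests or RNA-seq Wald
tests, as long as both sides share the sample design.

The recovery benchmark plants 5 discordant circles (circle log₂FC −2,
host mRNA unchanged, control-group expectation pinned at 60 copies so the
circles are comfortably detectable) among 100 genes, sequences ~200k
reads per fraction over 2 × 4 samples, and runs detection → classification
→ Wald tests → discordance end to end. Problem sizes throughout the tests
(20–100 genes, 80k–200k reads) were chosen as the smallest scales at which
the benchmarked properties are statistically stable.

## qPCR quantification

Amplification efficiency is fixed at 2 (the 2^−ΔΔCt form without
efficiency correction). Technical replicates are averaged on the Ct scale
before ΔCt (standard Livak practice); undetected targets are excluded,
never imputed; no-RT controls never enter quantification. ΔΔCt subtracts
the control-condition mean ΔCt, so the control RQ is exactly 1; the RQ
SEM is delta-method propagated (RQ · ln2 · SEM_ΔCt). Welch t-tests do not
assume equal variances; with both groups at zero variance, equal means
give p = 1 and unequal means p = 0 with a degenerate flag. Holm–Šidák and
BH adjustments are delegated to statsmodels and verified against
brute-force formulas. The priming classifier calls a target circular-like
when its random-hexamer : oligo(dT) detectability ratio reaches 5 — the
observed separation for genuine circles is ~10-fold, so 5 leaves margin on
noisy data — and linear-like at ≤ 2. The two-group Welch comparison
defaults to per-sample means (technical replicates collapsed first);
pooling technical replicates instead is possible by passing them as rows.

## Determinism and numerics

Every stochastic routine takes an integer seed; fixed seeds give
byte-identical FASTQ and truth tables. Derived seeds stay below 2³¹.
Strict inequalities follow the stated rules everywhere (log₂FC bounds,
p thresholds, Ct < 30, FC > 2 / < 0.5); boundary cases are tested.
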