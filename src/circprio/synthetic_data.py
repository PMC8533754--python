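"""Ground-truth simulator for two-fraction circRNA sequencing experiments.

The simulator emulates the data structure of a circRNA discovery study in
which total RNA from replicated treatment/control groups is split into

* a poly(A)-selected fraction capturing linear, polyadenylated mRNAs
  (including rare "exon repetition" transcripts that carry a back-spliced
  junction without being circular), and
* a RiboMinus/RNase R fraction in which linear molecules are degraded by the
  3'->5' exonuclease while covalently closed circles survive.

Single-end reads (default 75 nt) are then drawn from each fraction with full
per-read provenance, so that junction detection, differential expression and
the downstream candidate-selection cascade can be scored against known truth.

Coordinates are 0-based half-open genomic throughout.  Exon indices on
molecules are *transcript-order* indices (5'->3'), so index 0 is the first
exon of the mature transcript regardless of genomic strand.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._common import ValidationError, logger

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LINEAR_MRNA = "linear_mrna"
CIRCLE = "circle"
LINEAR_BACKSPLICED = "linear_backspliced"
TOPOLOGIES = (LINEAR_MRNA, CIRCLE, LINEAR_BACKSPLICED)

POLYA = "polyA"
RNASER = "ribominus_rnaseR"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic coords, sorted by start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def transcript_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class Annotation:
    """A toy gene annotation plus its genome sequence.

    Stands in for a genome-scale reference assembly: genes carry strand and
    non-overlapping, start-sorted exons whose coordinates lie within the
    chromosome sequence.
    """

    genes: list[Gene]
    genome: dict[str, str]

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene.strand not in ("+", "-"):
                raise ValidationError(f"{gene.gene_id}: strand must be + or -")
            if gene.chrom not in self.genome:
                raise ValidationError(f"{gene.gene_id}: unknown chrom {gene.chrom}")
            clen = len(self.genome[gene.chrom])
            prev_end = -1
            for start, end in gene.exons:
                if not (0 <= start < end <= clen):
                    raise ValidationError(
                        f"{gene.gene_id}: exon ({start},{end}) outside chrom"
                    )
                if start < prev_end:
                    raise ValidationError(
                        f"{gene.gene_id}: exons overlap or are unsorted"
                    )
                prev_end = end

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def exon_sequence(self, gene: Gene, transcript_index: int) -> str:
        """Sequence of one exon, transcript orientation."""
        start, end = gene.transcript_exons()[transcript_index]
        seq = self.genome[gene.chrom][start:end]
        return seq if gene.strand == "+" else reverse_complement(seq)

    def mature_sequence(self, gene: Gene, exon_indices: Sequence[int]) -> str:
        """Spliced sequence for the given transcript-order exon index list."""
        return "".join(self.exon_sequence(gene, i) for i in exon_indices)

    # ---- I/O -------------------------------------------------------------

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.genome.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for gene in self.genes:
                gstart = min(s for s, _ in gene.exons) + 1
                gend = max(e for _, e in gene.exons)
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
                fh.write(
                    f"{gene.chrom}\tcircprio\tgene\t{gstart}\t{gend}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{gene.chrom}\tcircprio\ttranscript\t{gstart}\t{gend}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for start, end in gene.exons:
                    fh.write(
                        f"{gene.chrom}\tcircprio\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )

    @classmethod
    def from_files(cls, gtf_path, fasta_path) -> "Annotation":
        genome = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        exons: dict[str, dict] = {}
        with open(gtf_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, _, feat, start, end, _, strand, _, attrs = line.rstrip(
                    "\n"
                ).split("\t")
                if feat != "exon":
                    continue
                gene_id = None
                for token in attrs.split(";"):
                    token = token.strip()
                    if token.startswith("gene_id"):
                        gene_id = token.split(" ", 1)[1].strip().strip('"')
                if gene_id is None:
                    raise ValidationError("GTF exon line lacks gene_id")
                rec = exons.setdefault(
                    gene_id, {"chrom": chrom, "strand": strand, "exons": []}
                )
                rec["exons"].append((int(start) - 1, int(end)))
        genes = [
            Gene(gid, rec["chrom"], rec["strand"], tuple(sorted(rec["exons"])))
            for gid, rec in exons.items()
        ]
        return cls(genes=genes, genome=genome)


def generate_annotation(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (2, 8),
    exon_len: tuple[int, int] = (100, 300),
    intron_len: tuple[int, int] = (50, 200),
    intergenic_len: tuple[int, int] = (200, 500),
    seed: int = 0,
    chrom: str = "chr1",
) -> Annotation:
    """Generate a single-chromosome toy annotation with uniform random sequence.

    Deterministic for a fixed seed.  All range lower bounds must be positive.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    for name, (lo, hi) in (
        ("exons_per_gene", exons_per_gene),
        ("exon_len", exon_len),
        ("intron_len", intron_len),
        ("intergenic_len", intergenic_len),
    ):
        if lo < 1 or hi < lo:
            raise ValidationError(f"{name} range must have positive lower bound <= upper")

    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    cursor = int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for e in range(n_ex):
            if e > 0:
                cursor += int(rng.integers(intron_len[0], intron_len[1] + 1))
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length
        genes.append(Gene(f"G{g:04d}", chrom, strand, tuple(exons)))
        cursor += int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))
    sequence = "".join(rng.choice(_BASES, size=cursor))
    return Annotation(genes=genes, genome={chrom: sequence})


# ---------------------------------------------------------------------------
# Sample design, molecules, ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    cell_context: str
    group: str
    replicate: int


def make_design(
    contexts: Sequence[str] = ("ctxA", "ctxB"),
    groups: Sequence[str] = ("control", "treatment_A", "treatment_B"),
    n_replicates: int = 4,
) -> dict[str, SampleInfo]:
    """Default experimental design: 2 contexts x 3 groups x 4 replicates."""
    if len(groups) < 2:
        raise ValidationError("design needs >= 2 groups")
    design = {}
    for ctx in contexts:
        for grp in groups:
            for rep in range(1, n_replicates + 1):
                design[f"{ctx}_{grp}_r{rep}"] = SampleInfo(ctx, grp, rep)
    return design


@dataclass
class Molecule:
    molecule_id: str
    gene_id: str
    topology: str
    exon_indices: tuple[int, ...]
    polyadenylated: bool
    copy_number: dict[str, int]

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology}")
        if self.topology == CIRCLE and self.polyadenylated:
            raise ValidationError("circles are never polyadenylated")
        if self.topology in (LINEAR_MRNA, LINEAR_BACKSPLICED) and not self.polyadenylated:
            raise ValidationError(f"{self.topology} must be polyadenylated")
        if self.topology == LINEAR_BACKSPLICED:
            if len(set(self.exon_indices)) == len(self.exon_indices):
                raise ValidationError(
                    "linear_backspliced molecules must repeat at least one exon"
                )
        if any(c < 0 for c in self.copy_number.values()):
            raise ValidationError("copy numbers must be >= 0")


@dataclass
class MoleculePool:
    molecules: list[Molecule]
    sample_design: dict[str, SampleInfo]
    fraction: str | None = None  # None (total RNA), POLYA or RNASER

    def validate(self) -> None:
        for mol in self.molecules:
            mol.validate()
            extra = set(mol.copy_number) - set(self.sample_design)
            if extra:
                raise ValidationError(f"{mol.molecule_id}: unknown samples {extra}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_design)


@dataclass
class GroundTruth:
    """Planted truth for every simulated feature.

    ``features``: one row per feature with gene, topology, BSJ id and genomic
    coordinates (NA for plain linear mRNAs) and the planted treatment
    log2 fold change.  ``abundance``: expected (pre-Poisson) copy numbers,
    features x samples.
    """

    features: pd.DataFrame
    abundance: pd.DataFrame

    def validate(self) -> None:
        bsj = self.features.dropna(subset=["bsj_id"])
        if bsj["bsj_id"].duplicated().any():
            raise ValidationError("duplicate BSJ in ground truth")
        if not np.isfinite(self.features["log2fc"]).all():
            raise ValidationError("non-finite planted fold change")


def bsj_id_for(gene_id: str, acceptor: int, donor: int) -> str:
    """Canonical id of the back-splice joining donor exon's 3' end to
    acceptor exon's 5' end (transcript-order indices, donor >= acceptor)."""
    return f"{gene_id}:bsj:{acceptor}-{donor}"


def bsj_genomic_coords(gene: Gene, acceptor: int, donor: int) -> tuple[str, int, int]:
    """BED-style (chrom, start, end) of a BSJ: leftmost start / rightmost end
    of the two partner exons, 0-based half-open."""
    t_exons = gene.transcript_exons()
    ex_a, ex_d = t_exons[acceptor], t_exons[donor]
    return gene.chrom, min(ex_a[0], ex_d[0]), max(ex_a[1], ex_d[1])


@dataclass(frozen=True)
class AbundanceModel:
    """Log-normal abundance priors (natural-log scale).

    Linear mRNAs are drawn around ~50 copies; circles are mostly low-count
    with a heavy right tail (median ~3, sigma 1.5), matching the observation
    that circRNA-seq libraries are dominated by very lowly expressed circles.
    """

    linear_mu: float = 4.0
    linear_sigma: float = 1.0
    circ_mu: float = 1.0
    circ_sigma: float = 1.5


@dataclass(frozen=True)
class Effect:
    """A planted treatment effect on one feature.

    ``groups`` restricts the effect to particular treatment groups; None
    applies it to every non-control group.
    """

    gene_id: str
    topology: str
    log2fc: float
    groups: tuple[str, ...] | None = None


def simulate_transcriptome(
    annotation: Annotation,
    design: Mapping[str, SampleInfo],
    circ_rate: float = 0.3,
    exonrep_rate: float = 0.05,
    abundance_model: AbundanceModel | None = None,
    effect_model: Iterable[Effect] = (),
    exonrep_abundance_factor: float = 10.0,
    control_group: str = "control",
    abundance_override: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> tuple[MoleculePool, GroundTruth]:
    """Simulate the molecule pool of a treatment/control experiment.

    Every gene expresses a linear mRNA over all its exons.  A ``circ_rate``
    fraction of genes additionally hosts one exonic circle over a random
    contiguous exon span; a disjoint ``exonrep_rate`` fraction hosts a
    polyadenylated exon-repetition transcript (one contiguous exon block
    duplicated in tandem) whose abundance is ``exonrep_abundance_factor``
    below what a circle at that locus would have.  Treatment effects from
    ``effect_model`` multiply the expected copy number of the targeted
    feature in treatment-group samples by 2**log2fc.  ``abundance_override``
    pins the control-group expected copy number of specific
    (gene_id, topology) features instead of drawing it from the prior.
    """
    if not (0 <= circ_rate <= 1 and 0 <= exonrep_rate <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    groups = {info.group for info in design.values()}
    if len(groups) < 2:
        raise ValidationError("design needs >= 2 groups")
    model = abundance_model or AbundanceModel()
    rng = np.random.default_rng(seed)
    samples = list(design)

    n = len(annotation.genes)
    order = rng.permutation(n)
    n_circ = int(round(circ_rate * n))
    n_rep = int(round(exonrep_rate * n))
    circ_genes = {annotation.genes[i].gene_id for i in order[:n_circ]}
    exonrep_genes = {annotation.genes[i].gene_id for i in order[n_circ : n_circ + n_rep]}

    effects: dict[tuple[str, str], Effect] = {}
    for eff in effect_model:
        if eff.gene_id not in {g.gene_id for g in annotation.genes}:
            raise ValidationError(f"effect on unknown gene {eff.gene_id}")
        effects[(eff.gene_id, eff.topology)] = eff
    # effects on circles of genes not selected to host one would be silent
    for (gid, topo), _ in effects.items():
        if topo == CIRCLE:
            circ_genes.add(gid)
            exonrep_genes.discard(gid)
        elif topo == LINEAR_BACKSPLICED:
            exonrep_genes.add(gid)
            circ_genes.discard(gid)

    molecules: list[Molecule] = []
    feat_rows: list[dict] = []
    abundance_rows: dict[str, np.ndarray] = {}

    def expected_counts(base: float, eff: Effect | None) -> np.ndarray:
        mult = np.ones(len(samples))
        if eff is not None:
            for k, sid in enumerate(samples):
                grp = design[sid].group
                hit = (
                    grp != control_group
                    if eff.groups is None
                    else grp in eff.groups
                )
                if hit:
                    mult[k] = 2.0 ** eff.log2fc
        return base * mult

    def add_feature(
        mol_id: str,
        gene: Gene,
        topology: str,
        exon_indices: tuple[int, ...],
        base: float,
        bsj: tuple[int, int] | None,
    ) -> None:
        if abundance_override is not None:
            base = abundance_override.get((gene.gene_id, topology), base)
        eff = effects.get((gene.gene_id, topology))
        means = expected_counts(base, eff)
        copies = {
            sid: int(rng.poisson(mu)) for sid, mu in zip(samples, means)
        }
        molecules.append(
            Molecule(
                molecule_id=mol_id,
                gene_id=gene.gene_id,
                topology=topology,
                exon_indices=exon_indices,
                polyadenylated=topology != CIRCLE,
                copy_number=copies,
            )
        )
        if bsj is None:
            bid, coords = None, (None, None, None)
        else:
            bid = bsj_id_for(gene.gene_id, bsj[0], bsj[1])
            coords = bsj_genomic_coords(gene, bsj[0], bsj[1])
        feat_rows.append(
            {
                "feature_id": mol_id,
                "gene_id": gene.gene_id,
                "topology": topology,
                "bsj_id": bid,
                "chrom": coords[0],
                "bsj_start": coords[1],
                "bsj_end": coords[2],
                "log2fc": 0.0 if eff is None else eff.log2fc,
            }
        )
        abundance_rows[mol_id] = means

    for gene in annotation.genes:
        lam_lin = float(rng.lognormal(model.linear_mu, model.linear_sigma))
        add_feature(
            f"{gene.gene_id}|lin",
            gene,
            LINEAR_MRNA,
            tuple(range(gene.n_exons)),
            lam_lin,
            bsj=None,
        )
        if gene.gene_id in circ_genes:
            i = int(rng.integers(0, gene.n_exons))
            j = int(rng.integers(i, gene.n_exons))
            lam_circ = float(rng.lognormal(model.circ_mu, model.circ_sigma))
            add_feature(
                f"{gene.gene_id}|circ",
                gene,
                CIRCLE,
                tuple(range(i, j + 1)),
                lam_circ,
                bsj=(i, j),
            )
        if gene.gene_id in exonrep_genes:
            b = int(rng.integers(0, gene.n_exons))
            c = int(rng.integers(b, gene.n_exons))
            lam_circ_scale = float(rng.lognormal(model.circ_mu, model.circ_sigma))
            lam_rep = lam_circ_scale / exonrep_abundance_factor
            idx = tuple(range(0, c + 1)) + tuple(range(b, gene.n_exons))
            add_feature(
                f"{gene.gene_id}|rep",
                gene,
                LINEAR_BACKSPLICED,
                idx,
                lam_rep,
                bsj=(b, c),
            )

    pool = MoleculePool(molecules=molecules, sample_design=dict(design))
    pool.validate()
    features = pd.DataFrame(feat_rows)
    abundance = pd.DataFrame(abundance_rows, index=samples).T
    abundance.index.name = "feature_id"
    truth = GroundTruth(features=features, abundance=abundance)
    truth.validate()
    return pool, truth


# ---------------------------------------------------------------------------
# Library fractions
# ---------------------------------------------------------------------------

def prepare_fractions(
    pool: MoleculePool,
    rnaser_linear_survival: float = 0.02,
    rnaser_circle_survival: float = 0.95,
    polya_capture: float = 1.0,
    polya_circle_leak: float = 0.0,
    seed: int = 0,
) -> tuple[MoleculePool, MoleculePool]:
    """Split a total-RNA pool into poly(A) and RiboMinus/RNase R fractions.

    Each molecule copy is retained independently: in the poly(A) fraction
    polyadenylated molecules with probability ``polya_capture`` and circles
    with ``polya_circle_leak`` (default 0 — oligo(dT) selection captures only
    poly(A) RNAs); in the RNase R fraction linear molecules survive digestion
    with ``rnaser_linear_survival`` and circles with
    ``rnaser_circle_survival``.
    """
    for name, p in (
        ("rnaser_linear_survival", rnaser_linear_survival),
        ("rnaser_circle_survival", rnaser_circle_survival),
        ("polya_capture", polya_capture),
        ("polya_circle_leak", polya_circle_leak),
    ):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]")
    if not rnaser_linear_survival < rnaser_circle_survival:
        raise ValidationError(
            "RNase R must favor circles: linear survival < circle survival"
        )
    rng = np.random.default_rng(seed)

    def thin(mol: Molecule, p: float) -> dict[str, int]:
        return {
            sid: int(rng.binomial(c, p)) if c > 0 else 0
            for sid, c in mol.copy_number.items()
        }

    polya_mols, rnaser_mols = [], []
    for mol in pool.molecules:
        p_polya = polya_circle_leak if mol.topology == CIRCLE else polya_capture
        p_rnaser = (
            rnaser_circle_survival
            if mol.topology == CIRCLE
            else rnaser_linear_survival
        )
        polya_mols.append(dataclasses.replace(mol, copy_number=thin(mol, p_polya)))
        rnaser_mols.append(dataclasses.replace(mol, copy_number=thin(mol, p_rnaser)))

    polya = MoleculePool(polya_mols, dict(pool.sample_design), fraction=POLYA)
    rnaser = MoleculePool(rnaser_mols, dict(pool.sample_design), fraction=RNASER)
    return polya, rnaser


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated single-end reads plus their per-read provenance table.

    ``truth`` columns: read_id, sample_id, molecule_id, gene_id, topology,
    bsj_id, bsj_overhang (largest min(left, right) flank over all BSJ
    crossings inside the read; -1 when the read does not cross a BSJ),
    start (offset on the possibly-periodic mature sequence).
    """

    reads: pd.DataFrame  # read_id, sample_id, sequence, molecule_id, start
    truth: pd.DataFrame
    fraction: str | None
    read_len: int

    def __len__(self) -> int:
        return len(self.reads)


def _molecule_bsj_position(mol: Molecule, exon_lengths: Sequence[int]) -> int | None:
    """Mature-coordinate position of the back-splice point, if any.

    For circles the BSJ sits at position 0 == L (the sequence is periodic);
    for exon-repetition molecules it is the internal boundary where the
    exon-index list jumps backwards.
    """
    if mol.topology == CIRCLE:
        return 0
    if mol.topology == LINEAR_BACKSPLICED:
        pos = 0
        for k in range(len(mol.exon_indices) - 1):
            pos += exon_lengths[k]
            if mol.exon_indices[k + 1] <= mol.exon_indices[k]:
                return pos
        raise ValidationError(f"{mol.molecule_id}: no backwards exon jump found")
    return None


def sample_reads(
    pool: MoleculePool,
    annotation: Annotation,
    n_reads: int,
    read_len: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw ``n_reads`` single-end reads per sample from a fraction pool.

    Molecules are sampled proportionally to copy_number x mature length; read
    start positions are uniform over the molecule, with circular molecules
    treated as periodic sequences (reads may wrap the back-splice point).
    Linear molecules shorter than ``read_len`` cannot yield a full-length
    read and receive weight 0.  Substitution errors are applied per base at
    ``error_rate``; base qualities are a constant Phred 30 downstream.
    """
    if n_reads < 0:
        raise ValidationError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    samples = pool.sample_ids

    genes = {g.gene_id: g for g in annotation.genes}
    mol_info = []
    for mol in pool.molecules:
        gene = genes[mol.gene_id]
        exon_lens = [
            gene.transcript_exons()[i][1] - gene.transcript_exons()[i][0]
            for i in mol.exon_indices
        ]
        seq = annotation.mature_sequence(gene, mol.exon_indices)
        L = len(seq)
        usable = L if mol.topology == CIRCLE else (L if L >= read_len else 0)
        mol_info.append(
            {
                "mol": mol,
                "seq": seq,
                "L": L,
                "usable": usable,
                "bsj_pos": _molecule_bsj_position(mol, exon_lens),
                "bsj_id": (
                    None
                    if mol.topology == LINEAR_MRNA
                    else _bsj_id_of_molecule(mol)
                ),
            }
        )

    read_rows = []
    truth_rows = []
    for sid in samples:
        weights = np.array(
            [info["mol"].copy_number.get(sid, 0) * info["usable"] for info in mol_info],
            dtype=float,
        )
        total = weights.sum()
        if total == 0:
            if n_reads > 0:
                raise ValidationError(
                    f"sample {sid}: empty pool cannot yield {n_reads} reads"
                )
            continue
        counts = rng.multinomial(n_reads, weights / total)
        ridx = 0
        for info, k in zip(mol_info, counts):
            if k == 0:
                continue
            mol, seq, L = info["mol"], info["seq"], info["L"]
            circular = mol.topology == CIRCLE
            if circular:
                starts = rng.integers(0, L, size=k)
                # tile enough copies to cover any wrap
                reps = math.ceil((L + read_len) / L)
                tiled = seq * reps
            else:
                starts = rng.integers(0, L - read_len + 1, size=k)
                tiled = seq
            for s in starts:
                s = int(s)
                raw = tiled[s : s + read_len]
                if error_rate > 0:
                    arr = np.frombuffer(raw.encode(), dtype="S1").astype("U1")
                    hits = np.nonzero(rng.random(read_len) < error_rate)[0]
                    for h in hits:
                        choices = [b for b in "ACGT" if b != arr[h]]
                        arr[h] = choices[int(rng.integers(0, 3))]
                    raw = "".join(arr)
                read_id = f"{sid}:{mol.molecule_id}:{ridx}"
                ridx += 1
                overhang = -1
                if circular:
                    k_lo = s // L + 1
                    k_hi = (s + read_len - 1) // L
                    for kk in range(k_lo, k_hi + 1):
                        pos = kk * L
                        if s < pos < s + read_len:
                            overhang = max(
                                overhang, min(pos - s, s + read_len - pos)
                            )
                elif info["bsj_pos"] is not None:
                    pos = info["bsj_pos"]
                    if s < pos < s + read_len:
                        overhang = min(pos - s, s + read_len - pos)
                read_rows.append(
                    {
                        "read_id": read_id,
                        "sample_id": sid,
                        "sequence": raw,
                        "molecule_id": mol.molecule_id,
                        "start": s,
                    }
                )
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample_id": sid,
                        "molecule_id": mol.molecule_id,
                        "gene_id": mol.gene_id,
                        "topology": mol.topology,
                        "bsj_id": info["bsj_id"],
                        "bsj_overhang": overhang,
                        "start": s,
                    }
                )

    cols_r = ["read_id", "sample_id", "sequence", "molecule_id", "start"]
    cols_t = [
        "read_id",
        "sample_id",
        "molecule_id",
        "gene_id",
        "topology",
        "bsj_id",
        "bsj_overhang",
        "start",
    ]
    reads = pd.DataFrame(read_rows, columns=cols_r)
    truth = pd.DataFrame(truth_rows, columns=cols_t)
    return ReadSet(reads=reads, truth=truth, fraction=pool.fraction, read_len=read_len)


def _bsj_id_of_molecule(mol: Molecule) -> str | None:
    if mol.topology == CIRCLE:
        return bsj_id_for(mol.gene_id, min(mol.exon_indices), max(mol.exon_indices))
    if mol.topology == LINEAR_BACKSPLICED:
        for k in range(len(mol.exon_indices) - 1):
            if mol.exon_indices[k + 1] <= mol.exon_indices[k]:
                return bsj_id_for(
                    mol.gene_id, mol.exon_indices[k + 1], mol.exon_indices[k]
                )
    return None


def write_fastq(readset: ReadSet, path, quality: int = 30) -> None:
    """Write the reads as FASTQ with a constant quality string."""
    records = []
    for row in readset.reads.itertuples(index=False):
        rec = SeqRecord(Seq(row.sequence), id=row.read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(row.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path, sample_from_id: bool = True) -> pd.DataFrame:
    """Load a FASTQ into the reads-table layout used by the detector.

    Read ids produced by :func:`write_fastq` encode the sample as the first
    colon-separated field; with ``sample_from_id=False`` all reads are
    assigned to a single sample ``"S1"``.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        sid = rec.id.split(":", 1)[0] if sample_from_id else "S1"
        rows.append({"read_id": rec.id, "sample_id": sid, "sequence": str(rec.seq)})
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "sequence"])


def write_truth(readset: ReadSet, path) -> None:
    readset.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR Ct-table simulation
# ---------------------------------------------------------------------------

def simulate_ct_table(
    targets: pd.DataFrame,
    group_sizes: Mapping[str, int] = None,
    control_group: str = "cerebellum",
    housekeeping: str = "TBP",
    hk_ct: float = 20.0,
    biological_sd: float = 0.25,
    technical_sd: float = 0.1,
    n_technical: int = 3,
    priming: str = "NA",
    oligo_dt_fold: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted between-group fold changes.

    ``targets`` needs columns ``target``, ``base_dct`` (ΔCt vs the
    housekeeping gene in the control group) and ``log2fc`` (planted log2 fold
    change in every non-control group; under perfect doubling a log2fc of
    -2 raises the treated ΔCt by 2 cycles).  One housekeeping target is
    emitted per sample.  ``oligo_dt_fold`` maps targets to the factor by
    which oligo(dT) priming under-detects them (circles ~10, linear ~1);
    when given, ``priming`` labels this table's cDNA preparation.
    """
    if group_sizes is None:
        group_sizes = {"cerebellum": 3, "medulloblastoma": 3}
    if control_group not in group_sizes:
        raise ValidationError(f"control group {control_group!r} not in design")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n_samp in group_sizes.items():
        for rep in range(1, n_samp + 1):
            sid = f"{group}_{rep}"
            hk_level = hk_ct + rng.normal(0, biological_sd)
            for t in range(n_technical):
                rows.append(
                    {
                        "target": housekeeping,
                        "sample": sid,
                        "group": group,
                        "replicate": t + 1,
                        "priming": priming,
                        "ct": hk_level + rng.normal(0, technical_sd),
                        "is_housekeeping": True,
                        "no_rt": False,
                    }
                )
            for row in targets.itertuples(index=False):
                dct = row.base_dct
                if group != control_group:
                    dct -= row.log2fc  # fewer molecules -> more cycles
                if oligo_dt_fold is not None:
                    dct += math.log2(oligo_dt_fold.get(row.target, 1.0))
                level = hk_level + dct + rng.normal(0, biological_sd)
                for t in range(n_technical):
                    rows.append(
                        {
                            "target": row.target,
                            "sample": sid,
                            "group": group,
                            "replicate": t + 1,
                            "priming": priming,
                            "ct": level + rng.normal(0, technical_sd),
                            "is_housekeeping": False,
                            "no_rt": False,
                        }
                    )
    return pd.DataFrame(rows)
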