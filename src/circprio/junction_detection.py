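"""Annotation-constrained splice-junction detection for circRNA discovery.

A junction *library* is enumerated directly from the annotation: forward
junctions for every adjacent exon pair of a transcript, and back-splice
candidates for every ordered exon pair (donor >= acceptor, including
single-exon circles).  Reads are matched to junction sequences by exhaustive
ungapped placement: a read supports a junction iff some placement leaves at
least ``min_overhang`` bases on each side of the splice point with at most
``max_mismatch`` substitutions over the full read — the classic
back-spliced-junction criterion (20 bases each side, 2 mismatches).  Reads
that match no junction but match a gene's exonic (mature transcript)
sequence are counted to that gene's linear body.

Matching is exact-equivalent to a brute-force all-placements scan; a
pigeonhole seed index (any placement with <= m mismatches contains an exact
(m+1)-way read partition) is used for speed only.

Finally, back-splice calls are classified as *circular* versus
*linear back-spliced* (exon repetition) by comparing read support between
the RNase R and poly(A) library fractions: a genuine circle survives RNase R
and is invisible to poly(A) selection, while an exon-repetition transcript
shows the mirror-image pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import ConfigurationError, ValidationError, logger
from .synthetic_data import (
    Annotation,
    ReadSet,
    bsj_genomic_coords,
    bsj_id_for,
)

FORWARD = "forward"
BACKSPLICE = "backsplice"

CIRCULAR = "circular"
LINEAR_BS = "linear_backspliced"
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# Junction library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionEntry:
    junction_id: str
    gene_id: str
    jtype: str  # forward | backsplice
    donor: int  # transcript-order exon index providing the 3' side
    acceptor: int  # transcript-order exon index providing the 5' side
    left_flank: str  # sequence immediately 5' of the splice point
    right_flank: str  # sequence immediately 3' of it
    chrom: str
    start: int  # BSJ genomic coords (BED convention); forward junctions too
    end: int

    @property
    def sequence(self) -> str:
        return self.left_flank + self.right_flank

    @property
    def splice_pos(self) -> int:
        return len(self.left_flank)


@dataclass
class JunctionLibrary:
    entries: list[JunctionEntry]
    transcripts: dict[str, str]  # gene_id -> mature mRNA sequence
    read_len: int
    min_overhang: int

    @property
    def flank_len(self) -> int:
        return self.read_len - self.min_overhang

    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "junction_id": e.junction_id,
                    "gene_id": e.gene_id,
                    "type": e.jtype,
                    "donor": e.donor,
                    "acceptor": e.acceptor,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                }
                for e in self.entries
            ]
        )

    def write_bed(self, path, scores: pd.Series | None = None) -> None:
        """BED6 export of backsplice entries; score = total read count."""
        with open(path, "w") as fh:
            for e in self.entries:
                if e.jtype != BACKSPLICE:
                    continue
                score = 0 if scores is None else int(scores.get(e.junction_id, 0))
                fh.write(
                    f"{e.chrom}\t{e.start}\t{e.end}\t{e.junction_id}\t{score}\t+\n"
                )


def build_junction_library(
    annotation: Annotation,
    read_len: int = 75,
    min_overhang: int = 20,
) -> JunctionLibrary:
    """Enumerate forward and back-splice junction sequences from an annotation.

    Flank length is ``read_len - min_overhang`` (55 for the 75/20 defaults)
    so that any read satisfying the overhang rule fits entirely within the
    junction sequence; flanks are truncated at transcript (or circle) ends.
    """
    flank = read_len - min_overhang
    if flank < min_overhang:
        raise ConfigurationError(
            f"flank length {flank} < min_overhang {min_overhang}; "
            "increase read_len or decrease min_overhang"
        )
    entries: list[JunctionEntry] = []
    transcripts: dict[str, str] = {}
    for gene in annotation.genes:
        n = gene.n_exons
        exon_seqs = [annotation.exon_sequence(gene, i) for i in range(n)]
        mature = "".join(exon_seqs)
        transcripts[gene.gene_id] = mature
        t_exons = gene.transcript_exons()
        # forward junctions between adjacent transcript exons
        cum = np.cumsum([len(s) for s in exon_seqs])
        for i in range(n - 1):
            left = mature[max(0, cum[i] - flank) : cum[i]]
            right = mature[cum[i] : cum[i] + flank]
            ex_d, ex_a = t_exons[i], t_exons[i + 1]
            entries.append(
                JunctionEntry(
                    junction_id=f"{gene.gene_id}:fwd:{i}-{i + 1}",
                    gene_id=gene.gene_id,
                    jtype=FORWARD,
                    donor=i,
                    acceptor=i + 1,
                    left_flank=left,
                    right_flank=right,
                    chrom=gene.chrom,
                    start=min(ex_d[0], ex_a[0]),
                    end=max(ex_d[1], ex_a[1]),
                )
            )
        # back-splice candidates: donor j joined back to acceptor i, j >= i
        for i in range(n):
            for j in range(i, n):
                span = "".join(exon_seqs[i : j + 1])
                chrom, start, end = bsj_genomic_coords(gene, i, j)
                entries.append(
                    JunctionEntry(
                        junction_id=bsj_id_for(gene.gene_id, i, j),
                        gene_id=gene.gene_id,
                        jtype=BACKSPLICE,
                        donor=j,
                        acceptor=i,
                        left_flank=span[-flank:],
                        right_flank=span[:flank],
                        chrom=chrom,
                        start=start,
                        end=end,
                    )
                )
    return JunctionLibrary(
        entries=entries,
        transcripts=transcripts,
        read_len=read_len,
        min_overhang=min_overhang,
    )


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

@dataclass
class JunctionCounts:
    """Read support per junction and per-gene linear body counts."""

    junctions: pd.DataFrame  # junction_id x sample integer counts
    gene_body: pd.DataFrame  # gene_id x sample integer counts
    junction_meta: pd.DataFrame
    fraction: str | None = None

    def backsplice_counts(self) -> pd.DataFrame:
        ids = self.junction_meta.loc[
            self.junction_meta["type"] == BACKSPLICE, "junction_id"
        ]
        return self.junctions.loc[ids]

    def gene_linear_counts(self) -> pd.DataFrame:
        """Total linear support per gene: exon-body reads plus reads spanning
        forward (colinear) splice junctions of that gene."""
        fwd = self.junction_meta[self.junction_meta["type"] == FORWARD]
        fwd_counts = self.junctions.loc[fwd["junction_id"]]
        fwd_by_gene = fwd_counts.groupby(fwd.set_index("junction_id")["gene_id"]).sum()
        out = self.gene_body.add(
            fwd_by_gene.reindex(self.gene_body.index, fill_value=0), fill_value=0
        )
        return out.astype(int)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, ReadSet):
        return reads.reads
    return reads


def detect_junction_reads(
    reads,
    library: JunctionLibrary,
    min_overhang: int = 20,
    max_mismatch: int = 2,
) -> JunctionCounts:
    """Count reads supporting each junction and each gene's linear body.

    ``reads`` is a :class:`~circprio.synthetic_data.ReadSet` or a DataFrame
    with columns read_id, sample_id, sequence (all sequences equal length).
    A read is assigned to the junction it matches with fewest mismatches;
    ties between distinct junctions are dropped as ambiguous.  Reads that
    match no junction are tried against every gene's mature transcript and
    counted to the best-matching gene (ties dropped).
    """
    frame = _reads_frame(reads)
    if not library.entries:
        raise ValidationError("empty junction library")
    if len(frame) == 0:
        samples: list[str] = []
    else:
        lens = frame["sequence"].str.len()
        if lens.nunique() > 1:
            raise ValidationError("mixed read lengths are not supported")
        read_len = int(lens.iloc[0])
        if read_len != library.read_len:
            raise ValidationError(
                f"read length {read_len} != library read_len {library.read_len}"
            )
        samples = list(pd.unique(frame["sample_id"]))

    # targets: junctions first, then gene transcripts
    jseqs = [_encode(e.sequence) for e in library.entries]
    jsplice = [e.splice_pos for e in library.entries]
    gene_ids = list(library.transcripts)
    gseqs = [_encode(library.transcripts[g]) for g in gene_ids]
    n_j = len(jseqs)
    targets = jseqs + gseqs

    parts = max_mismatch + 1
    k = library.read_len // parts
    index: dict[bytes, list[tuple[int, int]]] = {}
    for t_idx, arr in enumerate(targets):
        b = arr.tobytes()
        for pos in range(0, len(b) - k + 1):
            index.setdefault(b[pos : pos + k], []).append((t_idx, pos))

    jcounts = {e.junction_id: {} for e in library.entries}
    gcounts = {g: {} for g in gene_ids}

    for row in frame.itertuples(index=False):
        seq = _encode(row.sequence)
        b = seq.tobytes()
        R = len(seq)
        candidates: set[tuple[int, int]] = set()
        for p in range(parts):
            seed = b[p * k : (p + 1) * k]
            for t_idx, pos in index.get(seed, ()):
                candidates.add((t_idx, pos - p * k))
        best_j: dict[int, int] = {}  # junction target -> min mismatches
        best_g: dict[int, int] = {}
        for t_idx, off in candidates:
            arr = targets[t_idx]
            if off < 0 or off + R > len(arr):
                continue
            if t_idx < n_j:
                S = jsplice[t_idx]
                if S - off < min_overhang or off + R - S < min_overhang:
                    continue
            mm = int(np.count_nonzero(arr[off : off + R] != seq))
            if mm > max_mismatch:
                continue
            pool = best_j if t_idx < n_j else best_g
            if mm < pool.get(t_idx, max_mismatch + 1):
                pool[t_idx] = mm
        if best_j:
            mmin = min(best_j.values())
            winners = [t for t, mm in best_j.items() if mm == mmin]
            if len(winners) == 1:
                jid = library.entries[winners[0]].junction_id
                d = jcounts[jid]
                d[row.sample_id] = d.get(row.sample_id, 0) + 1
            # else: ambiguous, dropped
        elif best_g:
            mmin = min(best_g.values())
            winners = [t for t, mm in best_g.items() if mm == mmin]
            if len(winners) == 1:
                gid = gene_ids[winners[0] - n_j]
                d = gcounts[gid]
                d[row.sample_id] = d.get(row.sample_id, 0) + 1

    junctions = pd.DataFrame(
        [
            [jcounts[e.junction_id].get(s, 0) for s in samples]
            for e in library.entries
        ],
        index=pd.Index([e.junction_id for e in library.entries], name="junction_id"),
        columns=samples,
        dtype=int,
    )
    gene_body = pd.DataFrame(
        [[gcounts[g].get(s, 0) for s in samples] for g in gene_ids],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
        dtype=int,
    )
    fraction = reads.fraction if isinstance(reads, ReadSet) else None
    return JunctionCounts(
        junctions=junctions,
        gene_body=gene_body,
        junction_meta=library.meta(),
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Circular vs linear back-spliced classification
# ---------------------------------------------------------------------------

def classify_backspliced(
    polya_counts: JunctionCounts,
    rnaser_counts: JunctionCounts,
    min_support: float = 2.0,
    dominance: float = 5.0,
) -> pd.DataFrame:
    """Label each supported BSJ as circular, linear_backspliced or ambiguous.

    A BSJ whose mean RNase R-fraction support reaches ``min_support`` and
    exceeds its poly(A) support ``dominance``-fold is *circular*; the mirror
    pattern is *linear_backspliced* (exon repetition); support in both
    fractions without dominance is *ambiguous* (a gene may genuinely host
    both species).  BSJs below ``min_support`` in both fractions are not
    called.
    """
    if not polya_counts.junctions.index.equals(rnaser_counts.junctions.index):
        raise ValidationError("count matrices derive from different junction libraries")
    meta = rnaser_counts.junction_meta.set_index("junction_id")
    bs_ids = meta.index[meta["type"] == BACKSPLICE]
    p_mean = polya_counts.junctions.loc[bs_ids].mean(axis=1)
    r_mean = rnaser_counts.junctions.loc[bs_ids].mean(axis=1)

    rows = []
    for jid in bs_ids:
        p, r = float(p_mean[jid]), float(r_mean[jid])
        if max(p, r) < min_support:
            continue
        r_over_p = np.inf if p == 0 else r / p
        p_over_r = np.inf if r == 0 else p / r
        if r >= min_support and r_over_p >= dominance:
            label = CIRCULAR
        elif p >= min_support and p_over_r >= dominance:
            label = LINEAR_BS
        else:
            label = AMBIGUOUS
        m = meta.loc[jid]
        rows.append(
            {
                "junction_id": jid,
                "gene_id": m["gene_id"],
                "chrom": m["chrom"],
                "start": m["start"],
                "end": m["end"],
                "label": label,
                "polya_mean": p,
                "rnaser_mean": r,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "label",
            "polya_mean",
            "rnaser_mean",
        ],
    )
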