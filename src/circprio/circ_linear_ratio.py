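"""Circular-to-linear ratio analysis.

Circles rarely track their host gene's linear output: the correlation of
BSJ-supporting counts with host-gene linear counts is typically near zero.
This module pairs each detected circle with its host gene's linear counts,
quantifies the (lack of) correlation with Spearman's rho on log2(x + 1)
mean counts, computes per-sample circular/linear ratios above an abundance
cutoff, row-z-scores them (each row then has mean 0 and variance 1),
clusters rows and samples hierarchically and reports cutoff-based set
overlaps (Venn counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import squareform

from ._common import ValidationError, logger


@dataclass
class PairedCircLin:
    """Per-BSJ circular counts joined to host-gene linear counts.

    ``summary`` has one row per BSJ: gene_id, mean_circ, mean_lin,
    log2_ratio (NaN and ``zero_linear=True`` when the mean linear count is
    zero, in which case the row is excluded from ratio operations).
    """

    circ: pd.DataFrame  # bsj_id x samples
    lin: pd.DataFrame  # bsj_id x samples (host-gene counts, repeated per BSJ)
    summary: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.circ.columns)


def _gene_of_bsj(bsj_id: str) -> str:
    if ":bsj:" not in bsj_id:
        raise ValidationError(f"cannot infer host gene from id {bsj_id!r}")
    return bsj_id.split(":bsj:")[0]


def join_circ_linear(
    circ: pd.DataFrame,
    lin: pd.DataFrame,
    bsj_gene: Mapping[str, str] | None = None,
) -> PairedCircLin:
    """Join circular BSJ counts (bsj_id x samples) to host-gene linear counts.

    ``bsj_gene`` maps BSJ ids to host genes; by default the gene is parsed
    from the ``<gene>:bsj:<i>-<j>`` id convention.  Circles whose host gene
    is absent from ``lin`` keep zero linear counts and are flagged.  Both
    matrices must share the same sample universe.
    """
    if set(circ.columns) != set(lin.columns):
        raise ValidationError("circular and linear matrices have different samples")
    lin = lin[circ.columns]
    genes = pd.Series(
        {b: (bsj_gene[b] if bsj_gene is not None else _gene_of_bsj(b)) for b in circ.index},
        name="gene_id",
    )
    lin_rows = []
    for b in circ.index:
        g = genes[b]
        if g in lin.index:
            lin_rows.append(lin.loc[g].astype(float))
        else:
            logger.info("join_circ_linear: no linear counts for host gene %s", g)
            lin_rows.append(pd.Series(0.0, index=circ.columns))
    lin_matched = pd.DataFrame(lin_rows, index=circ.index)
    mean_circ = circ.mean(axis=1)
    mean_lin = lin_matched.mean(axis=1)
    zero_linear = mean_lin == 0
    with np.errstate(divide="ignore"):
        log2_ratio = np.where(zero_linear, np.nan, np.log2(mean_circ / mean_lin))
    summary = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_circ": mean_circ,
            "mean_lin": mean_lin,
            "log2_ratio": log2_ratio,
            "zero_linear": zero_linear,
        },
        index=circ.index,
    )
    return PairedCircLin(circ=circ.astype(float), lin=lin_matched, summary=summary)


def spearman_circ_lin(paired: PairedCircLin) -> tuple[float, float]:
    """Spearman rank correlation of log2(mean + 1) circular vs linear counts.

    Average ranks for ties; p from the large-sample t approximation."""
    s = paired.summary
    if len(s) < 3:
        raise ValidationError("Spearman correlation needs >= 3 paired rows")
    x = np.log2(s["mean_circ"].values + 1.0)
    y = np.log2(s["mean_lin"].values + 1.0)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ratio_zscores(paired: PairedCircLin, cutoff: float = 40.0) -> pd.DataFrame:
    """Row-z-scored per-sample circular/linear ratios above the cutoff.

    Rows are BSJs with mean circular count >= ``cutoff`` and a nonzero mean
    linear count.  Per-sample ratio x = circ / lin, with a pseudocount of 1
    added to the denominator only where the per-sample linear count is 0.
    Each row is transformed to z = (x - mean) / std; constant rows become
    all-zero (with a warning), everything else has mean 0 and SD 1.
    """
    keep = (paired.summary["mean_circ"] >= cutoff) & (~paired.summary["zero_linear"])
    circ = paired.circ.loc[keep]
    lin = paired.lin.loc[keep]
    denom = lin.where(lin > 0, lin + 1.0)
    if (lin.values == 0).any():
        logger.info("ratio_zscores: pseudocount 1 applied to zero linear counts")
    x = circ / denom
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    z = x.sub(mean, axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant-ratio rows set to zero z-scores")
    z = z.div(sd.where(~const, 1.0), axis=0)
    z.loc[const] = 0.0
    return z


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def _average_linkage(X: np.ndarray) -> np.ndarray:
    """Agglomerative average-linkage clustering on Euclidean distances.

    Returns a scipy-format linkage matrix.  Deterministic: on equal merge
    distances the pair with the lowest cluster indices is merged first.
    Written out explicitly so that the tie-breaking rule is part of the
    contract rather than an implementation detail of a library routine.
    """
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (i, j), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = active[i], active[j]
        Z[step] = (i, j, d, ni + nj)
        del active[i], active[j]
        for k in list(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dk = (ni * dist[a] + nj * dist[b]) / (ni + nj)
            del dist[a], dist[b]
            dist[(k, next_id)] = dk
        del dist[(i, j)]
        active[next_id] = ni + nj
        next_id += 1
    return Z


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[int]
    col_order: list[int]


def hierarchical_cluster(z: pd.DataFrame) -> ClusterResult:
    """Cluster rows and columns of a z-matrix (Euclidean, average linkage)."""
    if np.isnan(z.values).any():
        raise ValidationError("z-matrix contains NaN")
    if z.shape[0] < 2:
        raise ValidationError("clustering needs >= 2 rows")
    row_Z = _average_linkage(z.values)
    col_Z = (
        _average_linkage(z.values.T) if z.shape[1] >= 2 else np.zeros((0, 4))
    )
    row_order = list(leaves_list(row_Z))
    col_order = list(leaves_list(col_Z)) if len(col_Z) else list(range(z.shape[1]))
    return ClusterResult(row_Z, col_Z, row_order, col_order)


def overlap_sets(ids_a: Iterable, ids_b: Iterable) -> tuple[int, int, int]:
    """Venn counts (|A only|, |B only|, |A and B|) after deduplication."""
    a, b = set(ids_a), set(ids_b)
    return len(a - b), len(b - a), len(a & b)
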