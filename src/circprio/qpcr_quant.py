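"""qPCR relative quantification and group testing.

Implements the Livak workflow with a fixed amplification efficiency of 2
(perfect doubling): technical replicates are averaged on the Ct scale,
ΔCt = Ct_target - Ct_housekeeping per sample (default housekeeping gene
TBP), ΔΔCt = mean ΔCt(condition) - mean ΔCt(control) with RQ = 2^-ΔΔCt
(so the control condition's RQ is exactly 1), multiple Welch t-tests with
Holm–Šidák (FWER) or Benjamini–Hochberg (FDR) adjustment, a circular vs
linear classification from random-hexamer versus oligo(dT) priming
detectability (circles are primed by random hexamers but, lacking a poly(A)
tail, are nearly invisible to oligo(dT)), and the Ct < 30 reliability
filter used to exclude targets too lowly expressed for trustworthy
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._common import ValidationError, logger

CT_COLUMNS = [
    "target",
    "sample",
    "group",
    "replicate",
    "priming",
    "ct",
    "is_housekeeping",
    "no_rt",
]

CIRCULAR_LIKE = "circular_like"
LINEAR_LIKE = "linear_like"
INDETERMINATE = "indeterminate"


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    bad = table["ct"].dropna() <= 0
    if bad.any():
        raise ValidationError("Ct values must be positive (or missing = undetected)")
    return table


def delta_ct(
    table: pd.DataFrame,
    housekeeping: str = "TBP",
) -> pd.DataFrame:
    """Per-(target, sample) ΔCt and 2^-ΔCt.

    Technical replicates are averaged on the Ct scale first.  no-RT control
    rows never enter quantification.  Samples lacking a housekeeping
    measurement are excluded with a warning; undetected targets (missing
    Ct) are dropped, not imputed.
    """
    t = validate_ct_table(table)
    t = t[~t["no_rt"].astype(bool)].dropna(subset=["ct"])
    mean_ct = (
        t.groupby(["target", "sample"], sort=False)
        .agg(
            ct=("ct", "mean"),
            group=("group", "first"),
            priming=("priming", "first"),
            n_technical=("ct", "size"),
        )
        .reset_index()
    )
    hk = mean_ct[mean_ct["target"] == housekeeping].set_index("sample")["ct"]
    if hk.empty:
        raise ValidationError(f"housekeeping target {housekeeping!r} not found")
    out = mean_ct[mean_ct["target"] != housekeeping].copy()
    no_hk = ~out["sample"].isin(hk.index)
    if no_hk.any():
        logger.warning(
            "delta_ct: excluding samples without housekeeping Ct: %s",
            sorted(out.loc[no_hk, "sample"].unique()),
        )
        out = out[~no_hk]
    out["delta_ct"] = out["ct"] - hk.loc[out["sample"]].values
    out["rq_dct"] = 2.0 ** (-out["delta_ct"])
    return out.reset_index(drop=True)


def delta_delta_ct(
    dct: pd.DataFrame,
    control_condition: str,
) -> pd.DataFrame:
    """Per-(target, condition) ΔΔCt versus the control condition.

    ΔΔCt = mean ΔCt(condition) - mean ΔCt(control); RQ = 2^-ΔΔCt, with the
    SEM propagated from the replicate ΔCt spread by the delta method
    (SEM_RQ = RQ * ln2 * SEM_ΔCt).  The control condition's RQ is 1.
    """
    rows = []
    for target, sub in dct.groupby("target", sort=False):
        ctrl = sub[sub["group"] == control_condition]["delta_ct"]
        if ctrl.empty:
            raise ValidationError(f"control condition missing for target {target!r}")
        for group, g in sub.groupby("group", sort=False):
            ddct = g["delta_ct"].mean() - ctrl.mean()
            rq = 2.0 ** (-ddct)
            n = len(g)
            sem_dct = g["delta_ct"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append(
                {
                    "target": target,
                    "group": group,
                    "n": n,
                    "delta_delta_ct": ddct,
                    "rq": rq,
                    "rq_sem": rq * np.log(2.0) * sem_dct,
                }
            )
    return pd.DataFrame(rows)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: ``"bh"`` (Benjamini–Hochberg step-up FDR) or
    ``"holm_sidak"`` (step-down Holm–Šidák FWER,
    adj_i = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1), clipped at 1)."""
    if method not in ("bh", "holm_sidak"):
        raise ValidationError("method must be 'bh' or 'holm_sidak'")
    sm_method = "fdr_bh" if method == "bh" else "holm-sidak"
    return multipletests(np.asarray(p, dtype=float), method=sm_method)[1]


def multiple_welch_tests(
    values: pd.DataFrame,
    group_test: str,
    group_ref: str,
    adjust: str = "bh",
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-target Welch t-tests between two groups with multiplicity control.

    ``values`` has columns target, group and ``value_col`` (one row per
    biological replicate).  Unequal variances are not assumed (Welch t with
    Welch–Satterthwaite degrees of freedom).  ``adjust`` is ``"bh"``
    (Benjamini–Hochberg step-up) or ``"holm_sidak"`` (step-down
    Holm–Šidák).  ``direction`` is 'down' when the test group's mean is
    below the reference group's.  Targets with zero variance in both
    groups get p = 1 on equal means, or p = 0 flagged degenerate otherwise.
    """
    if adjust not in ("bh", "holm_sidak"):
        raise ValidationError("adjust must be 'bh' or 'holm_sidak'")
    rows = []
    for target, sub in values.groupby("target", sort=False):
        a = sub.loc[sub["group"] == group_test, value_col].astype(float).values
        b = sub.loc[sub["group"] == group_ref, value_col].astype(float).values
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"target {target!r}: >= 2 replicates per group required")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        degenerate = False
        if va == 0 and vb == 0:
            degenerate = a.mean() != b.mean()
            t_stat, df, p = (np.inf if degenerate else 0.0), float(
                len(a) + len(b) - 2
            ), (0.0 if degenerate else 1.0)
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            sa, sb = va / len(a), vb / len(b)
            df = (sa + sb) ** 2 / (
                sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
            )
        rows.append(
            {
                "target": target,
                "t": float(t_stat),
                "df": float(df),
                "p": float(p),
                "direction": "down" if a.mean() < b.mean() else "up",
                "mean_test": a.mean(),
                "mean_ref": b.mean(),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].values, method=adjust)
    return out.set_index("target")


def priming_ratio_classifier(
    rq_hexamer: pd.Series,
    rq_oligodt: pd.Series,
    fold_threshold: float = 5.0,
    linear_threshold: float = 2.0,
) -> pd.DataFrame:
    """Classify targets as circular-like or linear-like from priming bias.

    ``rq_hexamer`` / ``rq_oligodt`` map targets to relative quantities from
    random-hexamer and oligo(dT)-primed cDNA on the same samples.  The
    detectability ratio r = RQ_hex / RQ_dT classifies: r >= fold_threshold
    -> circular_like (circles lack a poly(A) tail); r <= linear_threshold
    -> linear_like; otherwise indeterminate.  RQ_dT = 0 is circular_like
    with an infinite-ratio flag.
    """
    common = rq_hexamer.index.intersection(rq_oligodt.index)
    if len(common) < len(rq_hexamer.index) or len(common) < len(rq_oligodt.index):
        raise ValidationError("both preparations must cover the same targets")
    rows = []
    for t in common:
        hx, dt = float(rq_hexamer[t]), float(rq_oligodt[t])
        infinite = dt == 0
        r = np.inf if infinite else hx / dt
        if r >= fold_threshold:
            label = CIRCULAR_LIKE
        elif r <= linear_threshold:
            label = LINEAR_LIKE
        else:
            label = INDETERMINATE
        rows.append({"target": t, "ratio": r, "label": label, "infinite_ratio": infinite})
    return pd.DataFrame(rows).set_index("target")


def ct_reliability_filter(
    table: pd.DataFrame,
    max_ct: float = 30.0,
    reference_samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Flag targets whose mean Ct in the reference sample set is < ``max_ct``.

    High cycle thresholds indicate abundance too low for reliable
    quantification; the comparison is strict (mean Ct of exactly
    ``max_ct`` is unreliable).  ``reference_samples`` defaults to all
    samples.
    """
    t = validate_ct_table(table)
    t = t[~t["no_rt"].astype(bool) & ~t["is_housekeeping"].astype(bool)]
    t = t.dropna(subset=["ct"])
    if reference_samples is not None:
        t = t[t["sample"].isin(set(reference_samples))]
    mean_ct = t.groupby("target")["ct"].mean()
    return pd.DataFrame(
        {"mean_ct": mean_ct, "reliable": mean_ct < max_ct}
    )


def reliable_targets(filtered: pd.DataFrame) -> set[str]:
    return set(filtered.index[filtered["reliable"]])
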