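"""Multi-criterion circRNA candidate prioritization cascade.

Detected circles are funneled through a configurable sequence of stages —
deduplication of entries sharing a back-spliced junction, differential-
expression selection, cross-context abundance checks (the top-5 of one cell
context that also rank in the other context's top-50), pathway-gene
membership, top-20-in-both selection, fold change against a reference
tissue expression table (> 2 or < 0.5), qPCR reliability (mean Ct < 30) and
finally the discordance call: a circle significantly *down* in tumor versus
normal whose host mRNA shows no significant change.  Every circle carries a
complete per-stage audit trail (pass / fail / not_evaluated plus the
triggering value) so each decision can be recomputed from the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._common import ValidationError, logger

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"

STAGES = (
    "dedupe",
    "de_selected",
    "top_crosscheck",
    "pathway_selected",
    "top20_both",
    "reference_fc",
    "qpcr_reliable",
    "discordant",
)


def _ranked(table: pd.DataFrame) -> pd.DataFrame:
    if "abundance" not in table.columns:
        raise ValidationError("table needs an 'abundance' column")
    return table.sort_values("abundance", ascending=False, kind="mergesort")


def _keys(table: pd.DataFrame) -> pd.Series:
    if {"chrom", "start", "end"}.issubset(table.columns):
        if table[["chrom", "start", "end"]].isna().any().any():
            raise ValidationError("missing BSJ coordinates")
        return (
            table["chrom"].astype(str)
            + ":"
            + table["start"].astype(int).astype(str)
            + "-"
            + table["end"].astype(int).astype(str)
        )
    if "bsj_id" in table.columns:
        return table["bsj_id"].astype(str)
    raise ValidationError("table needs BSJ coordinates or a bsj_id column")


def dedupe_circles(table: pd.DataFrame) -> pd.DataFrame:
    """One row per unique BSJ, keeping the most abundant; unannotated
    (assembly-only) rows are removed first."""
    t = table.copy()
    if "annotated" in t.columns:
        t = t[t["annotated"].astype(bool)]
    t = t.assign(_key=_keys(t))
    t = _ranked(t).drop_duplicates("_key", keep="first")
    return t.drop(columns="_key")


def top_abundance_crosscheck(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k_top: int = 5,
    k_ref: int = 50,
) -> set[str]:
    """Top-``k_top`` circles of either table that also rank in the other
    table's top-``k_ref`` (union of both directions)."""
    if k_top > k_ref:
        raise ValidationError("k_top must not exceed k_ref")
    ka, kb = _keys(_ranked(table_a)), _keys(_ranked(table_b))
    a_top, a_ref = list(ka[:k_top]), set(ka[:k_ref])
    b_top, b_ref = list(kb[:k_top]), set(kb[:k_ref])
    return {k for k in a_top if k in b_ref} | {k for k in b_top if k in a_ref}


def pathway_gene_filter(
    table: pd.DataFrame,
    gene_list: Iterable[str],
    k_ref: int = 50,
) -> set[str]:
    """Circles within the top-``k_ref`` whose host gene is in ``gene_list``."""
    genes = set(gene_list)
    if not genes:
        logger.warning("pathway_gene_filter: empty gene list")
        return set()
    top = _ranked(table).head(k_ref)
    hit = top["gene_id"].isin(genes)
    return set(_keys(top)[hit.values])


def top_shared_filter(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k: int = 20,
) -> set[str]:
    """Circles ranking in the top-``k`` of both tables."""
    ka = set(_keys(_ranked(table_a))[:k])
    kb = set(_keys(_ranked(table_b))[:k])
    return ka & kb


def reference_fold_change_filter(
    table: pd.DataFrame,
    reference: pd.DataFrame,
    up: float = 2.0,
    down: float = 0.5,
) -> pd.DataFrame:
    """Select circles whose expression differs from a reference tissue.

    ``table`` needs columns circ_id (circBase-style) and expression;
    ``reference`` circ_id and expression.  FC = sample / reference; a circle
    is selected iff FC > ``up`` or FC < ``down`` (strict).  Unmatched
    circles are excluded (logged); zero reference with nonzero sample
    expression gives FC = +inf and is selected.  Returns the matched table
    with fold_change and selected columns.
    """
    for df, name in ((table, "table"), (reference, "reference")):
        if (df["expression"] < 0).any():
            raise ValidationError(f"negative expression in {name}")
    ref = reference.set_index("circ_id")["expression"]
    matched = table[table["circ_id"].isin(ref.index)].copy()
    n_lost = len(table) - len(matched)
    if n_lost:
        logger.info("reference_fold_change_filter: %d circles without a reference id", n_lost)
    rexp = ref.loc[matched["circ_id"]].values.astype(float)
    sexp = matched["expression"].values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(rexp > 0, sexp / rexp, np.where(sexp > 0, np.inf, 1.0))
    matched["fold_change"] = fc
    matched["selected"] = (fc > up) | (fc < down)
    return matched


def discordance_call(
    circ_stats: pd.DataFrame,
    mrna_stats: pd.DataFrame,
    circ_gene: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag circles down-regulated in tumor whose host mRNA is unchanged.

    ``circ_stats`` is indexed by circle id with columns direction
    ('up'/'down') and p_adj; ``mrna_stats`` likewise indexed by gene id.
    A circle is *discordant* iff it is significantly down (p_adj < alpha)
    while its host mRNA is not significant (p_adj >= alpha); a circle whose
    mRNA is also significantly down is *concordant*; anything else is
    *not_flagged*.
    """
    rows = []
    for cid in circ_stats.index:
        gene = circ_gene.get(cid)
        if gene is None or gene not in mrna_stats.index:
            raise ValidationError(f"missing mRNA stats for circle {cid}")
        c = circ_stats.loc[cid]
        m = mrna_stats.loc[gene]
        circ_down = c["p_adj"] < alpha and c["direction"] == "down"
        if not circ_down:
            flag = "not_flagged"
        elif m["p_adj"] >= alpha:
            flag = "discordant"
        elif m["direction"] == "down":
            flag = "concordant"
        else:
            flag = "not_flagged"
        rows.append(
            {
                "circ_id": cid,
                "gene_id": gene,
                "circ_p_adj": float(c["p_adj"]),
                "circ_direction": c["direction"],
                "mrna_p_adj": float(m["p_adj"]),
                "mrna_direction": m["direction"],
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("circ_id")


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    """Audit trail (one row per circle, per-stage status and value columns),
    per-stage survivor counts, and the final candidate key set."""

    records: pd.DataFrame
    summary: dict[str, int]
    final: set[str]


def run_cascade(config: Mapping, inputs: Mapping) -> CascadeResult:
    """Run the configured prioritization stages in order.

    ``config``: ``{"stages": [...], <stage parameters>}`` — unknown stage
    names raise.  ``inputs`` supplies, as needed per stage: ``table`` (the
    primary context's ranked circle table with bsj keys, gene_id, abundance,
    annotated, optionally circ_id/expression), ``table_b`` (the second
    context), ``de_flags`` (set of keys flagged DE), ``gene_list``,
    ``reference`` (circ_id/expression table), ``reliable_targets`` (set of
    keys passing the Ct filter), ``circ_stats``/``mrna_stats``/``circ_gene``
    for the discordance stage.  Every circle of the input table gets a
    complete audit trail; stages are evaluated only for circles that passed
    all previous configured stages, so survivor counts are non-increasing.
    """
    stages = list(config.get("stages", []))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown cascade stage(s): {sorted(unknown)}")

    table = inputs["table"]
    keys = _keys(table)
    records = pd.DataFrame(index=pd.Index(keys.values, name="bsj_key"))
    records["gene_id"] = table["gene_id"].values
    for st in STAGES:
        records[st] = NOT_EVALUATED
        records[f"{st}_value"] = np.nan if st != "dedupe" else np.nan

    alive = set(keys.values)
    summary: dict[str, int] = {"input": len(records)}

    for st in stages:
        if st == "dedupe":
            kept = set(_keys(dedupe_circles(table)))
            values = {k: float(k in kept) for k in alive}
            passed = alive & kept
        elif st == "de_selected":
            flags = set(inputs["de_flags"])
            values = {k: float(k in flags) for k in alive}
            passed = alive & flags
        elif st == "top_crosscheck":
            sel = top_abundance_crosscheck(
                table,
                inputs["table_b"],
                k_top=config.get("k_top", 5),
                k_ref=config.get("k_ref", 50),
            )
            values = {k: float(k in sel) for k in alive}
            passed = alive & sel
        elif st == "pathway_selected":
            sel = pathway_gene_filter(
                table, inputs.get("gene_list", ()), k_ref=config.get("k_ref", 50)
            )
            values = {k: float(k in sel) for k in alive}
            passed = alive & sel
        elif st == "top20_both":
            sel = top_shared_filter(table, inputs["table_b"], k=config.get("k", 20))
            values = {k: float(k in sel) for k in alive}
            passed = alive & sel
        elif st == "reference_fc":
            fc = reference_fold_change_filter(
                table,
                inputs["reference"],
                up=config.get("up", 2.0),
                down=config.get("down", 0.5),
            )
            fc_keys = _keys(fc)
            fc_map = dict(zip(fc_keys, fc["fold_change"]))
            sel = set(fc_keys[fc["selected"].values])
            values = {k: fc_map.get(k, np.nan) for k in alive}
            passed = alive & sel
        elif st == "qpcr_reliable":
            rel = set(inputs["reliable_targets"])
            values = {k: float(k in rel) for k in alive}
            passed = alive & rel
        elif st == "discordant":
            calls = discordance_call(
                inputs["circ_stats"],
                inputs["mrna_stats"],
                inputs["circ_gene"],
                alpha=config.get("alpha", 0.05),
            )
            disc = set(calls.index[calls["flag"] == "discordant"])
            pmap = calls["circ_p_adj"].to_dict()
            values = {k: pmap.get(k, np.nan) for k in alive}
            passed = alive & disc
        for k in alive:
            records.loc[k, st] = PASS if k in passed else FAIL
            records.loc[k, f"{st}_value"] = values.get(k, np.nan)
        alive = passed
        summary[st] = len(alive)

    return CascadeResult(records=records, summary=summary, final=alive)


# ---------------------------------------------------------------------------
# End-to-end parameter-recovery benchmark
# ---------------------------------------------------------------------------

def benchmark_discordant_recovery(
    n_genes: int = 100,
    n_discordant: int = 5,
    circle_log2fc: float = -2.0,
    reads_per_fraction: int = 200_000,
    n_replicates: int = 4,
    planted_circle_abundance: float = 60.0,
    seed: int = 0,
) -> dict:
    """Simulate, detect and call discordant circles; score against truth.

    The default benchmark plants ``n_discordant`` circles (log2FC
    ``circle_log2fc`` in treatment, host mRNA unchanged) among ``n_genes``
    genes, sequences ~``reads_per_fraction`` reads per library fraction
    split over 2 groups x ``n_replicates`` samples, runs junction detection
    on both fractions, NB Wald tests on circular and linear counts and the
    discordance call, and reports precision/recall of the recovered set.
    """
    from . import differential_expression as de
    from . import junction_detection as jd
    from . import synthetic_data as sd

    rng = np.random.default_rng(seed)
    ann = sd.generate_annotation(n_genes, seed=int(rng.integers(2**31)))
    design = sd.make_design(
        contexts=("ctx",), groups=("control", "treatment"), n_replicates=n_replicates
    )
    target_genes = [g.gene_id for g in ann.genes[:n_discordant]]
    effects = [sd.Effect(g, sd.CIRCLE, circle_log2fc) for g in target_genes]
    pool, truth = sd.simulate_transcriptome(
        ann,
        design,
        circ_rate=0.3,
        exonrep_rate=0.05,
        effect_model=effects,
        abundance_override={(g, sd.CIRCLE): planted_circle_abundance for g in target_genes},
        seed=int(rng.integers(2**31)),
    )
    polya, rnaser = sd.prepare_fractions(pool, seed=int(rng.integers(2**31)))
    n_per_sample = reads_per_fraction // len(design)
    reads_p = sd.sample_reads(
        polya, ann, n_per_sample, seed=int(rng.integers(2**31))
    )
    reads_r = sd.sample_reads(
        rnaser, ann, n_per_sample, seed=int(rng.integers(2**31))
    )
    lib = jd.build_junction_library(ann)
    counts_p = jd.detect_junction_reads(reads_p, lib)
    counts_r = jd.detect_junction_reads(reads_r, lib)
    calls = jd.classify_backspliced(counts_p, counts_r)
    circ_ids = list(calls.loc[calls["label"] == jd.CIRCULAR, "junction_id"])

    groups = {s: info.group for s, info in design.items()}
    circ_counts = counts_r.junctions.loc[circ_ids]
    lin_counts = counts_p.gene_linear_counts()
    circ_de = de.wald_de_test(circ_counts, ("treatment", "control"), groups=groups)
    lin_de = de.wald_de_test(lin_counts, ("treatment", "control"), groups=groups)

    def stats_frame(res: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction": np.where(res["log2FoldChange"] < 0, "down", "up"),
                "p_adj": res["padj"],
            },
            index=res.index,
        )

    circ_gene = {cid: cid.split(":bsj:")[0] for cid in circ_ids}
    calls_df = discordance_call(
        stats_frame(circ_de), stats_frame(lin_de), circ_gene, alpha=0.05
    )
    found = {
        circ_gene[c] for c in calls_df.index[calls_df["flag"] == "discordant"]
    }
    planted = set(target_genes)
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "found": found,
        "planted": planted,
        "n_circles_called": len(circ_ids),
        "calls": calls_df,
    }
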