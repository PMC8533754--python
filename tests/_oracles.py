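"""Independent brute-force oracles used across the test suite.

These re-derive expected results by exhaustive enumeration or textbook
formulas, deliberately sharing no code with the implementation they check.
"""

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def brute_force_counts(reads_df, library, min_overhang=20, max_mismatch=2):
    """All-placements scan of every read against every junction and every
    gene transcript, applying the overhang/mismatch/tie rules literally."""
    j_arrays = [(_enc(e.sequence), e.splice_pos, e.junction_id) for e in library.entries]
    g_arrays = [(_enc(seq), gid) for gid, seq in library.transcripts.items()]
    jcounts, gcounts = {}, {}
    for row in reads_df.itertuples(index=False):
        r = _enc(row.sequence)
        R = len(r)
        best_mm, best_ids = max_mismatch + 1, []
        for arr, S, jid in j_arrays:
            if len(arr) < R:
                continue
            wins = sliding_window_view(arr, R)
            mm = (wins != r).sum(axis=1)
            offs = np.arange(len(mm))
            ok = (S - offs >= min_overhang) & (offs + R - S >= min_overhang)
            mm = np.where(ok, mm, max_mismatch + 1)
            m = int(mm.min()) if len(mm) else max_mismatch + 1
            if m <= max_mismatch:
                if m < best_mm:
                    best_mm, best_ids = m, [jid]
                elif m == best_mm:
                    best_ids.append(jid)
        if best_ids:
            if len(best_ids) == 1:
                key = (best_ids[0], row.sample_id)
                jcounts[key] = jcounts.get(key, 0) + 1
            continue
        best_mm, best_g = max_mismatch + 1, []
        for arr, gid in g_arrays:
            if len(arr) < R:
                continue
            mm = (sliding_window_view(arr, R) != r).sum(axis=1)
            m = int(mm.min())
            if m <= max_mismatch:
                if m < best_mm:
                    best_mm, best_g = m, [gid]
                elif m == best_mm:
                    best_g.append(gid)
        if len(best_g) == 1:
            key = (best_g[0], row.sample_id)
            gcounts[key] = gcounts.get(key, 0) + 1
    return jcounts, gcounts


def counts_to_dict(counts_frame) -> dict:
    out = {}
    for fid, row in counts_frame.iterrows():
        for sid, v in row.items():
            if v:
                out[(fid, sid)] = int(v)
    return out


def rank_then_pearson(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    rx = pd.Series(x).rank(method="average").values
    ry = pd.Series(y).rank(method="average").values
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def bh_adjust(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def holm_sidak_adjust(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, 1.0 - (1.0 - p[i]) ** (m - rank + 1))
        adj[i] = min(running, 1.0)
    return adj


def welch_t(a, b):
    """Textbook Welch t, Welch–Satterthwaite df and two-sided p."""
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p
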