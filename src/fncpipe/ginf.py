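"""Group inference on FNC edges.

Within each group, every edge's Fisher-z values are tested against zero
(one-sample t, BH-FDR across the group's edges), keeping the sign of the
mean — the positive/negative (red/blue) connection semantics.  Across the
three groups, each edge gets a one-way ANOVA with BH-FDR over edges and
Tukey-Kramer post hoc pairwise comparisons (valid for the unequal group
sizes 21/20/21), with mean differences reported in the fixed orders
AS-HC, MS-HC, AS-MS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GROUP_LABELS
from .vstat import CONTRAST_PAIRS, bh_fdr

__all__ = [
    "within_group_test",
    "anova_tukey",
    "tukey_kramer_p",
    "summarize_connections",
]


def _edge_frame(edges) -> list[tuple[str, str]]:
    return [tuple(e) for e in edges]


def within_group_test(
    z_values: np.ndarray,
    edges: list[tuple[str, str]],
    group: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t of each edge's z against 0 within one group.

    ``z_values`` is (n_subjects, n_edges).  Returns per edge: mean z, t,
    p, BH-FDR q over the group's edges, significance at ``alpha`` and the
    sign of the mean (positive/negative connection).
    """
    z = np.asarray(z_values, dtype=np.float64)
    if z.ndim != 2 or z.shape[1] != len(edges):
        raise ValueError(f"z_values shape {z.shape} does not match {len(edges)} edges")
    n = z.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    t = np.zeros(z.shape[1])
    p = np.ones(z.shape[1])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    q = bh_fdr(p)
    ef = _edge_frame(edges)
    return pd.DataFrame({
        "rsn_i": [e[0] for e in ef], "rsn_j": [e[1] for e in ef],
        "group": group, "mean_z": mean, "t": t, "p": p, "q": q,
        "significant": q < alpha,
        "sign": np.where(mean >= 0, "positive", "negative"),
    })


def tukey_kramer_p(
    mean_diff: float,
    mse: float,
    n_i: int,
    n_j: int,
    k_groups: int,
    df_error: int,
) -> float:
    """Tukey-Kramer p-value for one pairwise comparison.

    q = |mean_i - mean_j| / sqrt( MSE/2 * (1/n_i + 1/n_j) ), referred to
    the studentized range distribution with (k_groups, df_error).
    """
    if mse <= 0:
        return 1.0
    q = abs(mean_diff) / np.sqrt(mse / 2.0 * (1.0 / n_i + 1.0 / n_j))
    return float(stats.studentized_range.sf(q, k_groups, df_error))


def anova_tukey(
    z_values: np.ndarray,
    groups: list[str] | np.ndarray,
    edges: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-edge one-way ANOVA with Tukey-Kramer post hoc comparisons.

    ``z_values`` is (n_subjects, n_edges) and ``groups`` labels each row
    HC/MS/AS.  ANOVA p-values are BH-FDR corrected across edges; post hoc
    p-values rely on the studentized range's built-in familywise control
    and are reported unadjusted beyond it.  MSE is pooled across all
    three groups.
    """
    z = np.asarray(z_values, dtype=np.float64)
    groups = np.asarray(groups)
    if z.shape[0] != len(groups):
        raise ValueError("one group label per subject row required")
    if z.shape[1] != len(edges):
        raise ValueError(f"z_values shape {z.shape} does not match {len(edges)} edges")
    by_group = {}
    for g in GROUP_LABELS:
        sel = groups == g
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} missing or has < 2 subjects")
        by_group[g] = z[sel]
    ns = {g: by_group[g].shape[0] for g in GROUP_LABELS}
    n_total = sum(ns.values())
    k = len(GROUP_LABELS)
    df_err = n_total - k

    means = {g: by_group[g].mean(axis=0) for g in GROUP_LABELS}
    grand = z.mean(axis=0)
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in GROUP_LABELS)
    ss_within = sum(((by_group[g] - means[g]) ** 2).sum(axis=0) for g in GROUP_LABELS)
    # edges with (numerically) no variation at all carry no evidence:
    # F = 0, p = 1, post hoc p = 1 by convention
    scale = n_total * np.maximum(np.abs(grand), 1.0) ** 2
    degenerate = (ss_between + ss_within) <= scale * 1e-24
    mse = np.where(degenerate, 0.0, ss_within / df_err)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / (k - 1)) / mse
    F = np.where(np.isfinite(F), F, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(mse > 0, stats.f.sf(F, k - 1, df_err), 1.0)
    q = bh_fdr(p)

    ef = _edge_frame(edges)
    out = {
        "rsn_i": [e[0] for e in ef], "rsn_j": [e[1] for e in ef],
        "F": F, "p": p, "q": q, "significant": q < alpha,
    }
    for a, b in CONTRAST_PAIRS:
        diff = means[a] - means[b]
        with np.errstate(invalid="ignore", divide="ignore"):
            q_stat = np.abs(diff) / np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        pvals = np.ones_like(diff)
        ok = mse > 0
        if ok.any():
            pvals[ok] = stats.studentized_range.sf(q_stat[ok], k, df_err)
        out[f"md_{a}_{b}"] = diff
        out[f"p_{a}_{b}"] = pvals
    return pd.DataFrame(out)


def summarize_connections(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Report layout: significant edges sorted by ANOVA p, plus per-contrast
    increase/decrease edge lists (by the sign of the mean difference)."""
    sig = table[table["q"] < alpha].sort_values("p", kind="stable").reset_index(drop=True)
    contrasts = {}
    for a, b in CONTRAST_PAIRS:
        name = f"{a}-{b}"
        rows = sig[sig[f"p_{a}_{b}"] < alpha]
        contrasts[name] = pd.DataFrame({
            "rsn_i": rows["rsn_i"], "rsn_j": rows["rsn_j"],
            "mean_diff": rows[f"md_{a}_{b}"],
            "p": rows[f"p_{a}_{b}"],
            "direction": np.where(rows[f"md_{a}_{b}"] >= 0, "increase", "decrease"),
        }).reset_index(drop=True)
    return {"table": sig, "contrasts": contrasts, "n_significant": len(sig)}
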