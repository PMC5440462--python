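"""Voxelwise within-network group statistics.

RSN masks come from a one-sample t-test over subjects' network maps with
Bonferroni family-wise-error control; three-group comparisons are a
voxelwise one-way ANOVA plus pairwise Welch-t contrasts, each
Benjamini-Hochberg FDR-corrected within the RSN mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GROUP_LABELS

__all__ = [
    "VoxelStatMap",
    "CONTRAST_PAIRS",
    "rsn_mask",
    "voxelwise_anova",
    "pairwise_contrasts",
    "bh_fdr",
]

#: Fixed contrast order for the three-group design.
CONTRAST_PAIRS: tuple[tuple[str, str], ...] = (("AS", "HC"), ("MS", "HC"), ("AS", "MS"))


@dataclass
class VoxelStatMap:
    """Per-voxel statistic/p/q arrays; q is defined only inside the mask."""

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    name: str = ""

    def suprathreshold(self, alpha: float = 0.05) -> np.ndarray:
        out = np.zeros_like(self.mask, dtype=bool)
        out[self.mask] = self.q[self.mask] < alpha
        return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1 — the exact step-up
    definition (p_(i) <= i*alpha/m significant iff q_(i) <= alpha).
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="mergesort")
    ranked = flat[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    return q.reshape(p.shape)


def rsn_mask(
    subject_maps: np.ndarray,
    alpha: float = 0.05,
    correction: str = "fwe",
) -> np.ndarray:
    """Network-presence mask from a voxelwise one-sample t-test.

    ``subject_maps`` is (n_subjects, ...grid).  Family-wise error is
    controlled by Bonferroni over all voxels; a voxel enters the mask when
    its corrected two-sided p falls below ``alpha`` with positive t.
    Zero-variance voxels are non-significant by convention.
    """
    maps = np.asarray(subject_maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    grid = maps.shape[1:]
    flat = maps.reshape(n, -1)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    t = np.zeros(flat.shape[1])
    p = np.ones(flat.shape[1])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    if correction == "fwe":
        p_corr = np.minimum(p * p.size, 1.0)
    elif correction == "fdr":
        p_corr = bh_fdr(p)
    elif correction == "none":
        p_corr = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return ((p_corr < alpha) & (t > 0)).reshape(grid)


def _group_arrays(subject_maps: dict[str, np.ndarray], design: dict[str, str], mask: np.ndarray):
    """Split subjects' in-mask map values by group -> {group: (n_g, Vm)}."""
    mask = np.asarray(mask, dtype=bool)
    groups: dict[str, list[np.ndarray]] = {}
    for sid, m in subject_maps.items():
        g = design[sid]
        groups.setdefault(g, []).append(np.asarray(m, dtype=np.float64)[mask])
    return {g: np.stack(v) for g, v in groups.items()}, mask


def voxelwise_anova(
    subject_maps: dict[str, np.ndarray],
    design: dict[str, str],
    mask: np.ndarray,
) -> VoxelStatMap:
    """One-way ANOVA (three groups) at every in-mask voxel, BH-FDR within
    the mask; q < 0.05 defines the suprathreshold set."""
    by_group, mask = _group_arrays(subject_maps, design, mask)
    for g in GROUP_LABELS:
        if g not in by_group or by_group[g].shape[0] < 2:
            raise ValueError(f"group {g!r} missing or has < 2 subjects")
    arrays = [by_group[g] for g in GROUP_LABELS]
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*arrays, axis=0)
    F = np.nan_to_num(F, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    stat = np.full(mask.shape, np.nan)
    pmap = np.full(mask.shape, np.nan)
    qmap = np.full(mask.shape, np.nan)
    stat[mask] = F
    pmap[mask] = p
    qmap[mask] = bh_fdr(p)
    return VoxelStatMap(statistic=stat, p=pmap, q=qmap, mask=mask, name="anova")


def pairwise_contrasts(
    subject_maps: dict[str, np.ndarray],
    design: dict[str, str],
    mask: np.ndarray,
) -> dict[str, VoxelStatMap]:
    """Signed Welch-t maps for AS-HC, MS-HC and AS-MS, each FDR-corrected
    within the mask (unequal group variances are not assumed)."""
    by_group, mask = _group_arrays(subject_maps, design, mask)
    out = {}
    for a, b in CONTRAST_PAIRS:
        if a not in by_group or b not in by_group:
            raise ValueError(f"missing group for contrast {a}-{b}")
        if min(by_group[a].shape[0], by_group[b].shape[0]) < 2:
            raise ValueError(f"contrast {a}-{b} needs >= 2 subjects per group")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(by_group[a], by_group[b], equal_var=False, axis=0)
        t = np.nan_to_num(t, nan=0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        stat = np.full(mask.shape, np.nan)
        pmap = np.full(mask.shape, np.nan)
        qmap = np.full(mask.shape, np.nan)
        stat[mask] = t
        pmap[mask] = p
        qmap[mask] = bh_fdr(p)
        out[f"{a}-{b}"] = VoxelStatMap(statistic=stat, p=pmap, q=qmap, mask=mask, name=f"{a}-{b}")
    return out
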