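"""Resting-state network selection by spatial template matching.

The study design calls for twelve named networks chosen among the group
components; here the choice is automated as an optimal one-to-one
assignment maximizing total absolute spatial correlation against a
template atlas (for simulated cohorts, the planted ground-truth maps; for
real data, any user-supplied template set on the analysis grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["Assignment", "score_matrix", "match_templates", "greedy_vs_optimal_audit"]


@dataclass(frozen=True)
class Assignment:
    label: str
    component: int
    score: float          # |spatial Pearson correlation|
    matched: bool         # score >= threshold


def _flat_maps(maps: np.ndarray) -> np.ndarray:
    m = np.asarray(maps, dtype=np.float64)
    return m.reshape(m.shape[0], -1)


def score_matrix(components: np.ndarray, atlas: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """|Pearson correlation| between every component and every template."""
    comp = _flat_maps(components)
    labels = list(atlas)
    temps = _flat_maps(np.stack([np.asarray(atlas[l], dtype=np.float64).ravel() for l in labels]))
    for l, t in zip(labels, temps):
        if t.std() == 0:
            raise ValueError(f"template {l!r} has zero variance")
    cz = (comp - comp.mean(axis=1, keepdims=True))
    cs = cz.std(axis=1)
    cs[cs == 0] = np.inf            # flat components correlate with nothing
    tz = temps - temps.mean(axis=1, keepdims=True)
    ts = temps.std(axis=1)
    corr = (cz @ tz.T) / comp.shape[1] / np.outer(cs, ts)
    return np.abs(corr), labels


def match_templates(
    components: np.ndarray,
    atlas: dict[str, np.ndarray],
    threshold: float = 0.2,
) -> dict[str, Assignment]:
    """Optimal bipartite assignment of components to template labels.

    Invariant to component sign and common affine rescaling (scores are
    absolute correlations).  Labels whose best assigned score falls below
    ``threshold`` are flagged unmatched.  Ties break toward the lower
    component index.
    """
    scores, labels = score_matrix(components, atlas)
    n_comp, n_temp = scores.shape
    if n_comp < n_temp:
        raise ValueError(f"{n_comp} components cannot cover {n_temp} templates")
    # tiny index-decreasing perturbation => deterministic lower-index tie-break
    tie = 1e-12 * np.arange(n_comp)[::-1, None]
    rows, cols = linear_sum_assignment(scores + tie, maximize=True)
    out = {}
    for r, c in zip(rows, cols):
        lab = labels[c]
        out[lab] = Assignment(
            label=lab, component=int(r), score=float(scores[r, c]),
            matched=bool(scores[r, c] >= threshold),
        )
    return {lab: out[lab] for lab in labels}


def _greedy(scores: np.ndarray) -> dict[int, int]:
    s = scores.copy()
    taken_r, taken_c, pairs = set(), set(), {}
    n = min(s.shape)
    for _ in range(n):
        s_masked = s.copy()
        if taken_r:
            s_masked[list(taken_r), :] = -np.inf
        if taken_c:
            s_masked[:, list(taken_c)] = -np.inf
        r, c = np.unravel_index(np.argmax(s_masked), s.shape)
        pairs[int(c)] = int(r)
        taken_r.add(int(r))
        taken_c.add(int(c))
    return pairs


def greedy_vs_optimal_audit(
    components: np.ndarray,
    atlas: dict[str, np.ndarray],
) -> dict:
    """Compare greedy and optimal assignments; flag disagreements.

    A divergence signals an ambiguous decomposition where the best joint
    assignment sacrifices some label's individually best component.
    """
    if not atlas:
        return {"agrees": True, "differences": []}
    scores, labels = score_matrix(components, atlas)
    optimal = match_templates(components, atlas)
    greedy = _greedy(scores)
    diffs = []
    for c_idx, lab in enumerate(labels):
        g = greedy.get(c_idx)
        o = optimal[lab].component
        if g != o:
            diffs.append({
                "label": lab,
                "greedy_component": g,
                "optimal_component": o,
                "greedy_score": float(scores[g, c_idx]) if g is not None else None,
                "optimal_score": optimal[lab].score,
            })
    return {"agrees": not diffs, "differences": diffs}
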