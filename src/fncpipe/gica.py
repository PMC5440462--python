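"""Group spatial ICA: temporal concatenation, MDL order selection, PCA
whitening, Infomax unmixing, and dual regression back to subjects.

Spatial ICA convention: the concatenated data matrix is (total time x
voxels); independent components are spatial maps (rows over voxels) with
associated concatenated time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.utils.extmath import randomized_svd

from .core import Volume4D, check_rng_seed

__all__ = [
    "ConcatMatrix",
    "OrderEstimate",
    "PcaReduction",
    "IcaDecomposition",
    "SubjectNetworkSet",
    "concat_temporal",
    "estimate_order_mdl",
    "pca_reduce",
    "infomax_ica",
    "group_ica",
    "dual_regression",
]


@dataclass
class ConcatMatrix:
    """Temporally concatenated group data, (sum of subject T) x (voxels).

    Each subject's block is mean-centered per voxel before stacking.
    """

    data: np.ndarray
    subject_offsets: dict[str, tuple[int, int]]   # subject id -> (start, stop) rows
    mask: np.ndarray                              # (X, Y, Z) bool


@dataclass
class OrderEstimate:
    k: int
    criterion_curve: np.ndarray    # MDL value per candidate order 1..len(curve)


@dataclass
class PcaReduction:
    """Top-k spatial whitening of the concatenated data.

    ``whitened`` is (k, V) with identity sample covariance;
    ``back_projection`` (rows x k) satisfies
    back_projection @ whitened = rank-k approximation of the input.
    """

    whitened: np.ndarray
    back_projection: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: float


@dataclass
class IcaDecomposition:
    """Group components: spatial maps (unit variance, skew-positive sign,
    ordered by explained variance) and concatenated time courses."""

    unmixing: np.ndarray              # (k, k) on whitened space
    mixing: np.ndarray                # (k, k) whitened-space loadings
    component_maps: np.ndarray        # (k, V)
    component_timecourses: np.ndarray  # (rows, k)
    explained_variance: np.ndarray    # (k,)
    n_iter: int = 0
    converged: bool = True
    mask: np.ndarray | None = None


@dataclass
class SubjectNetworkSet:
    """Per-subject dual-regression outputs for the selected components."""

    subject_id: str
    maps: np.ndarray          # (k, V)
    timecourses: np.ndarray   # (T, k)


def concat_temporal(
    subjects: dict[str, Volume4D] | list[Volume4D],
    brain_mask: np.ndarray | None = None,
) -> ConcatMatrix:
    """Stack per-subject (T, V) blocks after per-voxel mean removal."""
    if isinstance(subjects, dict):
        items = list(subjects.items())
    else:
        items = [(v.subject_id or str(i), v) for i, v in enumerate(subjects)]
    if not items:
        raise ValueError("no subjects to concatenate")
    grid = items[0][1].grid_dims
    mask = items[0][1].get_mask() if brain_mask is None else np.asarray(brain_mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != grid {grid}")
    blocks, offsets, row = [], {}, 0
    for sid, vol in items:
        if vol.grid_dims != grid:
            raise ValueError(f"subject {sid!r} grid {vol.grid_dims} != {grid}")
        block = vol.to_matrix(mask).astype(np.float64)
        block -= block.mean(axis=0, keepdims=True)
        blocks.append(block)
        offsets[sid] = (row, row + block.shape[0])
        row += block.shape[0]
    return ConcatMatrix(data=np.vstack(blocks), subject_offsets=offsets, mask=mask)


def estimate_order_mdl(data: ConcatMatrix | np.ndarray) -> OrderEstimate:
    """Model order by the minimum-description-length criterion.

    With covariance eigenvalues l_1 >= ... >= l_p (p = min dimension,
    n = number of rows treated as samples),

        MDL(k) = -(p - k) n ln(gm_k / am_k) + k (2p - k + 1) ln(n) / 2

    where gm_k / am_k is the geometric/arithmetic mean ratio of the
    trailing eigenvalues l_{k+1}..l_p; the estimated order minimizes the
    curve over k = 1..p-1.
    """
    X = data.data if isinstance(data, ConcatMatrix) else np.asarray(data, dtype=np.float64)
    n, cols = X.shape
    p = min(n, cols)
    # eigenvalues of the p x p covariance via the smaller Gram matrix
    if cols <= n:
        G = (X.T @ X) / n
    else:
        G = (X @ X.T) / n
    lam = np.sort(np.linalg.eigvalsh(G))[::-1][:p]
    lam = np.clip(lam, 0.0, None)
    if np.sum(lam > max(lam[0], 1e-300) * 1e-12) < 3:
        raise ValueError("degenerate input: fewer than 3 nonzero eigenvalues")
    eps = lam[0] * 1e-15 + 1e-300
    curve = np.empty(p - 1)
    for k in range(1, p):
        tail = lam[k:] + eps
        log_gm = np.mean(np.log(tail))
        am = np.mean(tail)
        curve[k - 1] = -(p - k) * n * (log_gm - np.log(am)) + 0.5 * k * (2 * p - k + 1) * np.log(n)
    k_hat = int(np.argmin(curve)) + 1
    return OrderEstimate(k=k_hat, criterion_curve=curve)


def pca_reduce(data: ConcatMatrix | np.ndarray, k: int, seed: int = 0) -> PcaReduction:
    """Retain the top-k spatial principal components and whiten them.

    Randomized SVD is used for large matrices, exact SVD otherwise.  The
    whitened rows have identity sample covariance; back-projection times
    whitened reproduces the rank-k approximation exactly.
    """
    X = data.data if isinstance(data, ConcatMatrix) else np.asarray(data, dtype=np.float64)
    n, V = X.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    total_var = float(np.sum(X**2))
    if min(n, V) <= 1500 or k > min(n, V) // 4:
        U, s, Vt = sla.svd(X, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    else:
        U, s, Vt = randomized_svd(
            X, n_components=k, n_oversamples=20, n_iter=7,
            random_state=check_rng_seed(seed),
        )
    rank_tol = max(n, V) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if s.size < k or s[k - 1] <= rank_tol:
        raise ValueError(f"k={k} exceeds the numerical rank of the data")
    whitened = Vt * np.sqrt(V)                    # rows: unit variance, uncorrelated
    back = U * (s / np.sqrt(V))
    evr = float(np.sum(s**2) / total_var) if total_var > 0 else 1.0
    return PcaReduction(
        whitened=whitened, back_projection=back,
        singular_values=s, explained_variance_ratio=evr,
    )


def _canonicalize(W: np.ndarray, pca: PcaReduction) -> IcaDecomposition:
    """Fix sign (positive map skewness) and order (explained variance)."""
    S = W @ pca.whitened                       # (k, V) raw sources
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S = S / sd
    A = pca.back_projection @ np.linalg.inv(W) * sd.T   # (rows, k)
    mean = S.mean(axis=1, keepdims=True)
    skew = np.mean((S - mean) ** 3, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    S *= flip[:, None]
    A = A * flip[None, :]
    W = W * (flip / sd[:, 0])[:, None]
    ev = np.sum(A**2, axis=0)                  # variance contribution per component
    order = np.argsort(ev)[::-1]
    return IcaDecomposition(
        unmixing=W[order],
        mixing=np.linalg.inv(W)[:, order],
        component_maps=S[order],
        component_timecourses=A[:, order],
        explained_variance=ev[order],
    )


def infomax_ica(
    pca: PcaReduction,
    seed: int = 0,
    *,
    learning_rate: float | None = None,
    max_iter: int = 512,
    tol: float = 1e-6,
    block_size: int | None = None,
    anneal: float = 0.9,
    anneal_step: float = 0.98,
    anneal_deg: float = 60.0,
) -> IcaDecomposition:
    """Infomax ICA by natural-gradient ascent with a logistic nonlinearity.

    Block updates ``W += lr (B I + (1 - 2 g(u)) u^T) W`` with
    g(u) = 1 / (1 + exp(-u)).  On divergence the learning rate shrinks by
    ``anneal`` and the pass restarts; when successive pass updates turn by
    more than ``anneal_deg`` degrees (oscillation near the optimum) the
    rate shrinks by ``anneal_step``, so the stochastic passes settle below
    ``tol``.  Components are canonicalized afterwards: unit-variance maps,
    skewness-positive sign, descending explained variance.
    """
    Y = pca.whitened
    k, m = Y.shape
    if k < 2:
        raise ValueError(f"need k >= 2 components, got {k}")
    rng = np.random.default_rng(check_rng_seed(seed))
    lr = learning_rate if learning_rate is not None else 0.01 / np.log(max(np.e, k))
    B = block_size or int(min(m, max(64, np.floor(np.sqrt(m / 3.0)) * 8)))
    W = np.eye(k)
    I = np.eye(k)
    n_restarts = 0
    it = 0
    change = np.inf
    prev_delta = None
    cos_thresh = float(np.cos(np.deg2rad(anneal_deg)))
    while it < max_iter:
        it += 1
        W_prev = W.copy()
        perm = rng.permutation(m)
        diverged = False
        for start in range(0, m, B):
            idx = perm[start:start + B]
            u = W @ Y[:, idx]
            g = 1.0 / (1.0 + np.exp(-u))
            dW = lr * ((len(idx) * I + (1.0 - 2.0 * g) @ u.T) @ W) / len(idx)
            W = W + dW
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                diverged = True
                break
        if diverged:
            lr *= anneal
            n_restarts += 1
            W = np.eye(k)
            prev_delta = None
            if n_restarts > 200:
                raise RuntimeError(
                    f"Infomax diverged after {n_restarts} annealing restarts "
                    f"(iteration {it}, learning rate {lr:.3g})"
                )
            continue
        delta = W - W_prev
        change = float(np.max(np.abs(delta)))
        if change < tol:
            break
        if prev_delta is not None:
            norm = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if norm > 0 and float(np.sum(delta * prev_delta)) / norm < cos_thresh:
                lr *= anneal_step
        prev_delta = delta
    dec = _canonicalize(W, pca)
    dec.n_iter = it
    dec.converged = bool(change < tol)
    return dec


def group_ica(
    concat: ConcatMatrix,
    k: int | str = 12,
    seed: int = 0,
    **infomax_kwargs,
) -> tuple[IcaDecomposition, OrderEstimate | None]:
    """PCA reduction + Infomax; ``k='mdl'`` selects the order by MDL."""
    order = None
    if isinstance(k, str):
        if k != "mdl":
            raise ValueError(f"k must be an integer or 'mdl', got {k!r}")
        order = estimate_order_mdl(concat)
        k = max(2, order.k)
    pca = pca_reduce(concat, int(k), seed=seed)
    dec = infomax_ica(pca, seed=seed, **infomax_kwargs)
    dec.mask = concat.mask
    return dec, order


def dual_regression(
    group_maps: np.ndarray,
    subject_vol: Volume4D,
    mask: np.ndarray | None = None,
    *,
    subject_id: str | None = None,
) -> SubjectNetworkSet:
    """Two-stage least squares from group maps to one subject.

    Stage 1 regresses every volume's voxel vector on all group maps
    jointly (plus an intercept), giving k subject time courses.  Stage 2
    z-scores those time courses and regresses every voxel's series on
    them jointly, giving k subject spatial maps (the coefficients).
    """
    G = np.asarray(group_maps, dtype=np.float64)
    if G.ndim != 2:
        raise ValueError("group_maps must be (k, V)")
    k = G.shape[0]
    data = subject_vol.to_matrix(mask).astype(np.float64)   # (T, V)
    T, V = data.shape
    if G.shape[1] != V:
        raise ValueError(f"group maps have {G.shape[1]} voxels, subject has {V}")
    if k >= T:
        raise ValueError(f"k={k} must be < T={T}")
    cond = np.linalg.cond(G @ G.T)
    if cond > 1e8:
        raise ValueError(f"group maps are collinear (condition number {cond:.3g})")
    data = data - data.mean(axis=0, keepdims=True)

    X1 = np.column_stack([G.T, np.ones(V)])                 # (V, k+1)
    beta1, *_ = np.linalg.lstsq(X1, data.T, rcond=None)     # (k+1, T)
    tcs = beta1[:k].T                                       # (T, k)

    tz = tcs - tcs.mean(axis=0, keepdims=True)
    sd = tz.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    tz = tz / sd
    X2 = np.column_stack([tz, np.ones(T)])                  # (T, k+1)
    beta2, *_ = np.linalg.lstsq(X2, data, rcond=None)       # (k+1, V)
    maps = beta2[:k]
    return SubjectNetworkSet(
        subject_id=subject_id or subject_vol.subject_id,
        maps=maps,
        timecourses=tcs,
    )
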