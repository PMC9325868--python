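"""Sparse canonical correlation on the adjusted cross-matrix W.

The core estimator is the L1-penalized rank-one matrix approximation: find a
unit-L2 variant-loading vector u and gene-loading vector v maximizing
``v.T @ W @ u`` subject to ``||u||_1 <= c_u`` and ``||v||_1 <= c_v``.  It is
solved by alternating soft-thresholding (the standard penalized matrix
decomposition scheme), with the per-update L1 threshold found by bisection and
the iteration initialized from the leading singular vectors of W.  Further
components come from rank-one deflation and are therefore only approximately
orthogonal.

Each component's strength is summarized by the cc-value::

    q2 = (v.T W u)**2 / sqrt((u.T W.T W u) * (v.T W W.T v))

which lies in [0, 1] by Cauchy-Schwarz and is invariant to rescaling W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_correlation import AdjustedMatrix

__all__ = [
    "SparsityConfig",
    "ArchieComponent",
    "ComponentSet",
    "soft_threshold",
    "cc_value",
    "fit_component",
    "fit_components",
    "tune_sparsity",
    "default_budget",
]

_BISECT_STEPS = 40


def default_budget(dim: int) -> float:
    """Default L1 budget for a loading vector of length ``dim``: 1 + 0.3*(sqrt(dim) - 1)."""
    return 1.0 + 0.3 * (np.sqrt(dim) - 1.0)


@dataclass
class SparsityConfig:
    """L1 budgets and solver controls for one sCCA fit.

    ``c_u`` / ``c_v`` must lie in [1, sqrt(p)] / [1, sqrt(g)] (the feasible
    range for a unit-L2 vector); ``None`` selects the default budget for the
    matrix the config is used on.
    """

    c_u: float | None = None
    c_v: float | None = None
    max_iter: int = 200
    tol: float = 1e-8

    def resolved(self, p: int, g: int) -> "SparsityConfig":
        c_u = default_budget(p) if self.c_u is None else float(self.c_u)
        c_v = default_budget(g) if self.c_v is None else float(self.c_v)
        if not 1.0 <= c_u <= np.sqrt(p) + 1e-12:
            raise ValueError(f"c_u={c_u:.4g} outside feasible range [1, sqrt({p})]")
        if not 1.0 <= c_v <= np.sqrt(g) + 1e-12:
            raise ValueError(f"c_v={c_v:.4g} outside feasible range [1, sqrt({g})]")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")
        return SparsityConfig(c_u, c_v, self.max_iter, self.tol)


@dataclass
class ArchieComponent:
    """One paired sparse (variant, gene) component with its cc-value."""

    u: np.ndarray
    v: np.ndarray
    q2: float
    rank: int = 1
    objective: float = 0.0
    iterations: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def selected_variants(self) -> np.ndarray:
        return np.flatnonzero(self.u)

    @property
    def selected_genes(self) -> np.ndarray:
        return np.flatnonzero(self.v)


@dataclass
class ComponentSet:
    components: list[ArchieComponent] = field(default_factory=list)
    deflation_residuals: list[float] = field(default_factory=list)

    @property
    def q2(self) -> np.ndarray:
        return np.array([c.q2 for c in self.components])

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, k: int) -> ArchieComponent:
        return self.components[k]


def soft_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise ``sign(x) * max(|x| - delta, 0)``."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _l1_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 soft-thresholded direction of ``a`` with ``||.||_1 <= c`` (bisection)."""
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    u = a / norm
    if np.abs(u).sum() <= c + 1e-12:
        return u
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(_BISECT_STEPS):
        mid = 0.5 * (lo + hi)
        s = soft_threshold(a, mid)
        sn = np.linalg.norm(s)
        if sn > 0 and np.abs(s).sum() / sn <= c:
            hi = mid
        else:
            lo = mid
    s = soft_threshold(a, hi)
    sn = np.linalg.norm(s)
    if sn == 0:  # bisection collapsed onto the max entry
        s = np.zeros_like(a)
        s[int(np.argmax(np.abs(a)))] = np.sign(a[int(np.argmax(np.abs(a)))])
        sn = 1.0
    return s / sn


def cc_value(W: AdjustedMatrix | np.ndarray, u: np.ndarray, v: np.ndarray, return_flag: bool = False):
    """The cc-value q2 of the pair (u, v) on W; 0 for degenerate directions."""
    Wv = W.values if isinstance(W, AdjustedMatrix) else np.asarray(W, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not u.any() or not v.any():
        raise ValueError("u and v must be non-zero")
    Wu = Wv @ u
    Wtv = Wv.T @ v
    nu, nv = np.linalg.norm(Wu), np.linalg.norm(Wtv)
    if nu == 0 or nv == 0:
        return (0.0, True) if return_flag else 0.0
    q2 = float((v @ Wu) ** 2 / (nu * nv))
    q2 = min(q2, 1.0)  # guard roundoff at the Cauchy-Schwarz boundary
    return (q2, False) if return_flag else q2


def _fix_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # largest-|loading| entry of u positive; np.argmax breaks ties at the lowest index
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        return -u, -v
    return u, v


def fit_component(
    W: AdjustedMatrix | np.ndarray,
    cfg: SparsityConfig | None = None,
    seed: int = 0,
    q2_against: np.ndarray | None = None,
) -> ArchieComponent:
    """Extract one sparse component from W by alternating soft-thresholding.

    ``q2_against`` lets deflated fits report their cc-value against the
    original (undeflated) matrix.  ``seed`` is accepted for interface
    stability; the fit itself is deterministic (SVD initialization).
    """
    Wm = W.values if isinstance(W, AdjustedMatrix) else np.asarray(W, dtype=float)
    if Wm.ndim != 2 or not Wm.any():
        raise ValueError("W must be a non-zero 2-D matrix")
    g, p = Wm.shape
    cfg = (cfg or SparsityConfig()).resolved(p, g)

    U, _, Vh = np.linalg.svd(Wm, full_matrices=False)
    v = U[:, 0]
    u = Vh[0]
    obj = float(v @ Wm @ u)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        u = _l1_unit(Wm.T @ v, cfg.c_u)
        if not u.any():
            raise ValueError("all-zero variant loading after thresholding; c_u too small")
        v = _l1_unit(Wm @ u, cfg.c_v)
        if not v.any():
            raise ValueError("all-zero gene loading after thresholding; c_v too small")
        new_obj = float(v @ Wm @ u)
        if abs(new_obj - obj) < cfg.tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    u, v = _fix_sign(u, v)
    target = Wm if q2_against is None else q2_against
    q2, degenerate = cc_value(target, u, v, return_flag=True)
    return ArchieComponent(
        u=u, v=v, q2=q2, objective=obj, iterations=it, converged=converged, degenerate=degenerate
    )


def fit_components(
    W: AdjustedMatrix | np.ndarray,
    K: int,
    cfg: SparsityConfig | None = None,
    seed: int = 0,
    q2_reference: str = "deflated",
) -> ComponentSet:
    """Extract K components by successive rank-one deflation.

    After each extraction ``W <- W - (v.T W u) v u.T``.  Each component's q2
    is computed against the matrix it was extracted from (its deflated
    residual), so the rank-k cc-value measures the correlation captured at
    rank k net of earlier components; ``q2_reference="original"`` evaluates
    all ranks against the undeflated matrix instead.
    """
    Wm = (W.values if isinstance(W, AdjustedMatrix) else np.asarray(W, dtype=float)).copy()
    g, p = Wm.shape
    if not 1 <= K <= min(p, g):
        raise ValueError(f"K={K} outside [1, min(p, g)={min(p, g)}]")
    if q2_reference not in ("deflated", "original"):
        raise ValueError(f"unknown q2_reference {q2_reference!r}")
    original = Wm.copy()
    out = ComponentSet()
    for k in range(1, K + 1):
        if not Wm.any():
            break  # fully deflated; remaining ranks carry no signal
        comp = fit_component(
            Wm, cfg, seed=seed, q2_against=original if q2_reference == "original" else None
        )
        comp.rank = k
        d = float(comp.v @ Wm @ comp.u)
        Wm -= d * np.outer(comp.v, comp.u)
        out.components.append(comp)
        out.deflation_residuals.append(float(np.linalg.norm(Wm)))
    return out


# ---------------------------------------------------------------------------
# batched solver: same alternating scheme vectorized over a stack of matrices.
# Used by the resampling machinery, where thousands of equally-shaped null
# matrices must be decomposed.

def _batched_l1_unit(a: np.ndarray, c: float) -> np.ndarray:
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    u = a / safe
    need = np.abs(u).sum(axis=1) > c + 1e-12
    if need.any():
        sub = a[need]
        lo = np.zeros(sub.shape[0])
        hi = np.abs(sub).max(axis=1)
        for _ in range(_BISECT_STEPS):
            mid = 0.5 * (lo + hi)
            s = np.sign(sub) * np.maximum(np.abs(sub) - mid[:, None], 0.0)
            sn = np.linalg.norm(s, axis=1)
            l1 = np.abs(s).sum(axis=1)
            ok = (sn > 0) & (l1 <= c * sn)
            hi = np.where(ok, mid, hi)
            lo = np.where(ok, lo, mid)
        s = np.sign(sub) * np.maximum(np.abs(sub) - hi[:, None], 0.0)
        sn = np.linalg.norm(s, axis=1, keepdims=True)
        bad = sn[:, 0] == 0
        if bad.any():
            idx = np.argmax(np.abs(sub[bad]), axis=1)
            s[bad] = 0.0
            s[np.flatnonzero(bad), idx] = np.sign(sub[bad, idx])
            sn = np.linalg.norm(s, axis=1, keepdims=True)
        u[need] = s / sn
    u[(norms[:, 0] == 0)] = 0.0
    return u


def _batched_top_pair(
    Wb: np.ndarray, c_u: float, c_v: float, max_iter: int = 100, tol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Top sparse pair (u, v) for each matrix in a (B, g, p) stack.

    Matrices are dropped from the active set once their objective stabilizes,
    so a few support-oscillating members do not stall the whole batch.
    """
    U, _, Vh = np.linalg.svd(Wb, full_matrices=False)
    v = U[:, :, 0]
    u = Vh[:, 0, :]
    obj = np.einsum("bg,bgp,bp->b", v, Wb, u)
    active = np.arange(Wb.shape[0])
    for _ in range(max_iter):
        Wa = Wb[active]
        ua = _batched_l1_unit(np.einsum("bgp,bg->bp", Wa, v[active]), c_u)
        va = _batched_l1_unit(np.einsum("bgp,bp->bg", Wa, ua), c_v)
        new_obj = np.einsum("bg,bgp,bp->b", va, Wa, ua)
        u[active] = ua
        v[active] = va
        moved = np.abs(new_obj - obj[active]) >= tol
        obj[active] = new_obj
        active = active[moved]
        if active.size == 0:
            break
    return u, v


def _batched_q2(Wb: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    Wu = np.einsum("bgp,bp->bg", Wb, u)
    Wtv = np.einsum("bgp,bg->bp", Wb, v)
    nu = np.linalg.norm(Wu, axis=1)
    nv = np.linalg.norm(Wtv, axis=1)
    num = np.einsum("bg,bg->b", v, Wu) ** 2
    denom = nu * nv
    q2 = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.minimum(q2, 1.0)


def batched_component_q2(
    Wb: np.ndarray, K: int, cfg: SparsityConfig | None = None
) -> np.ndarray:
    """cc-values of the first K deflation components for each matrix in a stack.

    Returns a ``(B, K)`` array; as in :func:`fit_components`, the rank-k q2 is
    evaluated on the rank-k deflated residual.
    """
    Wb = np.asarray(Wb, dtype=float)
    B, g, p = Wb.shape
    cfg = (cfg or SparsityConfig()).resolved(p, g)
    Wb = Wb.copy()
    out = np.zeros((B, K))
    for k in range(K):
        u, v = _batched_top_pair(Wb, cfg.c_u, cfg.c_v, max_iter=cfg.max_iter, tol=cfg.tol)
        out[:, k] = _batched_q2(Wb, u, v)
        d = np.einsum("bg,bgp,bp->b", v, Wb, u)
        Wb -= d[:, None, None] * np.einsum("bg,bp->bgp", v, u)
    return out


def tune_sparsity(
    W: AdjustedMatrix | np.ndarray,
    grid_u: np.ndarray | None = None,
    grid_v: np.ndarray | None = None,
    T: int = 20,
    seed: int = 0,
) -> SparsityConfig:
    """Permutation tuning of (c_u, c_v).

    For each grid point, compares the observed top cc-value with its mean over
    ``T`` replicas of W whose columns are independently permuted within each
    row (destroying the variant-gene pairing while preserving margins), and
    returns the budgets maximizing the gap.
    """
    Wm = W.values if isinstance(W, AdjustedMatrix) else np.asarray(W, dtype=float)
    g, p = Wm.shape
    rng = np.random.default_rng(seed)
    if grid_u is None:
        grid_u = 1.0 + np.array([0.1, 0.3, 0.5, 0.7]) * (np.sqrt(p) - 1.0)
    if grid_v is None:
        grid_v = 1.0 + np.array([0.1, 0.3, 0.5, 0.7]) * (np.sqrt(g) - 1.0)
    perms = np.stack(
        [np.take_along_axis(Wm, np.argsort(rng.random(Wm.shape), axis=1), axis=1) for _ in range(T)]
    )
    best, best_gap = None, -np.inf
    for cu in np.atleast_1d(grid_u):
        for cv in np.atleast_1d(grid_v):
            cfg = SparsityConfig(float(cu), float(cv))
            obs = fit_component(Wm, cfg).q2
            null_mean = batched_component_q2(perms, 1, cfg)[:, 0].mean()
            gap = obs - null_mean
            if gap > best_gap:
                best, best_gap = cfg, gap
    return best
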