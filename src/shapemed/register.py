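"""Elastic registration of SRVF curves: rotation, warping, Karcher mean.

Alignment of a curve q to a reference q_ref solves

    argmin_{O in SO(2), tau in Gamma}  || q_ref - O (q o tau) sqrt(tau') ||_{L2},

where Gamma is the set of boundary-preserving monotone reparameterizations
of [0, 1].  The rotation is a closed-form Procrustes step (SVD of the 2x2
cross-covariance); the warping is found by dynamic programming over a
lattice of piecewise-linear warps with local slopes k/l, 1 <= k, l <= 3.
Curves are treated as open with a consistently ordered seed landmark.

The cohort atlas is the Karcher mean under this metric, computed by the
usual align-average-renormalize iteration initialized at the medoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .curves import CoordinateFunctions, LandmarkCurve, SRVFCurve, normalize_landmarks, srvf_transform

__all__ = [
    "WarpingFunction",
    "RotationMatrix",
    "AtlasShape",
    "optimal_rotation",
    "optimal_warping",
    "warp_apply",
    "align_pair",
    "elastic_distance",
    "karcher_mean",
    "align_cohort",
    "DP_STEPS",
]

#: coprime DP lattice steps (di, dj): local slopes k/l with 1 <= k, l <= 3
DP_STEPS = np.array(
    [(1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)], dtype=np.int64
)


@dataclass
class WarpingFunction:
    """Monotone reparameterization tau of [0, 1] with tau(0)=0, tau(1)=1."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("warping values must match the grid in length")
        if abs(self.values[0]) > 1e-12 or abs(self.values[-1] - 1.0) > 1e-12:
            raise ValueError("warping must preserve the boundaries tau(0)=0, tau(1)=1")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("warping must be non-decreasing")

    def inverse(self) -> "WarpingFunction":
        """Numerical inverse on the same grid (piecewise-linear)."""
        vals = np.interp(self.grid, self.values, self.grid)
        vals[0], vals[-1] = 0.0, 1.0
        return WarpingFunction(grid=self.grid.copy(), values=vals)


@dataclass
class RotationMatrix:
    """Element of SO(2); ``degenerate`` flags a numerically zero Procrustes problem."""

    entries: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (2, 2):
            raise ValueError("rotation must be 2x2")

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.entries[1, 0], self.entries[0, 0]))


@dataclass
class AtlasShape:
    """Karcher-mean atlas with convergence diagnostics."""

    srvf: SRVFCurve
    n_iterations: int
    converged: bool
    objective_trace: np.ndarray | None = None


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def _l2(q1: np.ndarray, q2: np.ndarray, grid: np.ndarray) -> float:
    d = q1 - q2
    return float(np.sqrt(np.trapezoid((d * d).sum(axis=1), grid)))


def optimal_rotation(q_ref: SRVFCurve, q: SRVFCurve) -> RotationMatrix:
    """Procrustes rotation minimizing ||q_ref - O q||_{L2} over SO(2).

    Computed from the SVD of A = int q_ref(s) q(s)^T ds with the
    determinant-sign correction enforcing det(O) = +1.  A numerically zero
    cross-covariance returns the identity flagged degenerate.
    """
    if q_ref.grid.shape != q.grid.shape or not np.allclose(q_ref.grid, q.grid):
        raise ValueError("curves must share a common grid")
    w = _trapz_weights(q_ref.grid)
    A = (q_ref.values * w[:, None]).T @ q.values
    scale = np.abs(A).max()
    if scale < 1e-14:
        return RotationMatrix(entries=np.eye(2), degenerate=True)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    O = U @ np.diag([1.0, d]) @ Vt
    return RotationMatrix(entries=O)


@njit(cache=True)
def _edge_cost(q1, q2, grid, a, b, i, j):  # pragma: no cover - numba
    """Integral of |q1(s) - sqrt(m) q2(gamma(s))|^2 over [s_a, s_i],
    gamma linear from s_b to s_j with slope m, trapezoid on the fine grid."""
    m = (grid[j] - grid[b]) / (grid[i] - grid[a])
    sqm = np.sqrt(m)
    T = grid.shape[0]
    total = 0.0
    prev = 0.0
    for t in range(a, i + 1):
        g = grid[b] + m * (grid[t] - grid[a])
        # linear interpolation of q2 at g (uniform grid)
        pos = g * (T - 1)
        k = int(pos)
        if k >= T - 1:
            k = T - 2
        frac = pos - k
        v = 0.0
        for d in range(2):
            q2g = q2[k, d] + frac * (q2[k + 1, d] - q2[k, d])
            diff = q1[t, d] - sqm * q2g
            v += diff * diff
        if t > a:
            total += 0.5 * (prev + v) * (grid[t] - grid[t - 1])
        prev = v
    return total


@njit(cache=True)
def _dp_tables(q1, q2, grid, steps):  # pragma: no cover - numba
    T = grid.shape[0]
    n_steps = steps.shape[0]
    INF = 1e300
    E = np.full((T, T), INF)
    Pi = np.full((T, T), -1, dtype=np.int64)
    Pj = np.full((T, T), -1, dtype=np.int64)
    E[0, 0] = 0.0
    for i in range(1, T):
        for j in range(1, T):
            best = INF
            bi = -1
            bj = -1
            for s in range(n_steps):
                di = steps[s, 0]
                dj = steps[s, 1]
                a = i - di
                b = j - dj
                if a < 0 or b < 0:
                    continue
                if E[a, b] >= INF:
                    continue
                c = E[a, b] + _edge_cost(q1, q2, grid, a, b, i, j)
                if c < best:
                    best = c
                    bi = a
                    bj = b
            E[i, j] = best
            Pi[i, j] = bi
            Pj[i, j] = bj
    return E, Pi, Pj


def _dp_solve(q1: np.ndarray, q2: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, float]:
    """Run the DP and return (tau values on grid, optimal lattice objective)."""
    E, Pi, Pj = _dp_tables(q1, q2, grid, DP_STEPS)
    T = grid.size
    # trace back the optimal monotone lattice path from (T-1, T-1)
    path_i, path_j = [T - 1], [T - 1]
    while path_i[-1] != 0:
        i, j = path_i[-1], path_j[-1]
        path_i.append(int(Pi[i, j]))
        path_j.append(int(Pj[i, j]))
    path_i.reverse()
    path_j.reverse()
    tau = np.interp(grid, grid[np.array(path_i)], grid[np.array(path_j)])
    tau[0], tau[-1] = 0.0, 1.0
    return tau, float(E[T - 1, T - 1])


def optimal_warping(q_ref: SRVFCurve, q: SRVFCurve) -> WarpingFunction:
    """DP search for the warping minimizing ||q_ref - (q o tau) sqrt(tau')||.

    The search space is the lattice of piecewise-linear boundary-preserving
    warps through grid nodes with local slopes ``k/l``, ``1 <= k, l <= 3``;
    within that lattice the returned warp is a global minimizer.
    """
    if q_ref.grid.size < 5:
        raise ValueError("optimal_warping needs a grid of at least 5 points")
    if q_ref.grid.shape != q.grid.shape or not np.allclose(q_ref.grid, q.grid):
        raise ValueError("curves must share a common grid")
    tau, _ = _dp_solve(
        np.ascontiguousarray(q_ref.values), np.ascontiguousarray(q.values), q_ref.grid
    )
    return WarpingFunction(grid=q_ref.grid.copy(), values=tau)


def warp_apply(q: SRVFCurve, tau: WarpingFunction) -> SRVFCurve:
    """Group action of a warp on an SRVF: (q, tau) -> (q o tau) sqrt(tau').

    The action is an L2 isometry up to grid error.
    """
    taud = np.gradient(tau.values, tau.grid)
    taud = np.maximum(taud, 0.0)
    vals = np.column_stack(
        [np.interp(tau.values, q.grid, q.values[:, 0]), np.interp(tau.values, q.grid, q.values[:, 1])]
    ) * np.sqrt(taud)[:, None]
    return SRVFCurve(grid=q.grid.copy(), values=vals, subject_id=q.subject_id)


def align_pair(
    q_ref: SRVFCurve, q: SRVFCurve, n_sweeps: int = 2
) -> tuple[SRVFCurve, RotationMatrix, WarpingFunction]:
    """Align q to q_ref by alternating Procrustes rotation and DP warping.

    Returns the aligned curve O* (q o tau*) sqrt(tau*') together with the
    accumulated rotation and warp.
    """
    cur = q
    O_total = np.eye(2)
    tau_total = np.linspace(0.0, 1.0, q.grid.size)
    for _ in range(n_sweeps):
        rot = optimal_rotation(q_ref, cur)
        cur = SRVFCurve(grid=cur.grid, values=cur.values @ rot.entries.T, subject_id=q.subject_id)
        O_total = rot.entries @ O_total
        tau = optimal_warping(q_ref, cur)
        cur = warp_apply(cur, tau)
        tau_total = np.interp(tau.values, cur.grid, tau_total)
    tau_total[0], tau_total[-1] = 0.0, 1.0
    return cur, RotationMatrix(entries=O_total), WarpingFunction(grid=q.grid.copy(), values=tau_total)


def elastic_distance(q1: SRVFCurve, q2: SRVFCurve, n_sweeps: int = 2) -> float:
    """L2 distance between q1 and q2 after rotation/warping alignment of q2."""
    aligned, _, _ = align_pair(q1, q2, n_sweeps=n_sweeps)
    return _l2(q1.values, aligned.values, q1.grid)


def karcher_mean(
    curves: list[SRVFCurve], max_iter: int = 20, tol: float = 1e-5
) -> AtlasShape:
    """Karcher mean of a sample of SRVFs under the elastic metric.

    Initialized at the medoid (minimal total elastic distance to the rest),
    then iterates: align every curve to the current mean, replace the mean
    by the cross-sectional average, rescale to unit L2 norm.  Stops when
    the mean moves less than ``tol`` in L2 or after ``max_iter`` passes.
    """
    if len(curves) == 0:
        raise ValueError("karcher_mean requires at least one curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("all curves must share one grid")
    if len(curves) == 1:
        return AtlasShape(srvf=curves[0], n_iterations=1, converged=True,
                          objective_trace=np.zeros(1))
    # medoid initialization
    n = len(curves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = elastic_distance(curves[i], curves[j])
    mean = curves[int(np.argmin(D.sum(axis=1)))]
    mean = SRVFCurve(grid=grid, values=mean.values / mean.norm())
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [align_pair(mean, c)[0].values for c in curves]
        trace.append(sum(_l2(mean.values, a, grid) ** 2 for a in aligned))
        new_vals = np.mean(aligned, axis=0)
        new = SRVFCurve(grid=grid, values=new_vals)
        nrm = new.norm()
        if nrm > 0:
            new.values = new.values / nrm
        delta = _l2(mean.values, new.values, grid)
        mean = new
        if delta < tol:
            converged = True
            break
    return AtlasShape(srvf=mean, n_iterations=it, converged=converged,
                      objective_trace=np.asarray(trace))


def align_cohort(
    curves: list[LandmarkCurve], n_grid: int = 100, max_iter: int = 20, tol: float = 1e-5
) -> tuple[AtlasShape, list[SRVFCurve]]:
    """Full shape pipeline: normalize, SRVF, Karcher atlas, align each subject.

    Returns the atlas and the per-subject aligned SRVFs m_i(s) on the
    shared grid — the mediator representation consumed by the functional
    mediation models.
    """
    if len(curves) < 2:
        raise ValueError("align_cohort requires at least two curves")
    srvfs = []
    for c in curves:
        try:
            f = normalize_landmarks(c, n_grid)
            srvfs.append(srvf_transform(f, unit_norm=True))
        except ValueError as e:
            raise ValueError(f"subject {c.subject_id!r}: {e}") from e
    atlas = karcher_mean(srvfs, max_iter=max_iter, tol=tol)
    aligned = [align_pair(atlas.srvf, q)[0] for q in srvfs]
    return atlas, aligned
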