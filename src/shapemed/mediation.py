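"""Functional mediation models linking exposure, shape mediator, and outcome.

Two regressions are fit per candidate SNP g, with m_i(s) the subject's
aligned two-dimensional SRVF mediator on a shared grid over [0, 1]:

shape-on-scalar (mediator model), fit pointwise by OLS at every grid
point and coordinate dimension j:

    m_{i,j}(s) = x_i alpha_j(s) + c_i' xi_j(s) + eta_{i,j}(s) + eps_{i,j}(s)

scalar-on-shape (outcome model), fit by expanding the centered mediator
functions in a K-dimensional FPCA basis and regressing the outcome on the
exposure, the mediator scores, and the covariates:

    y_i = x_i gamma + sum_j int_0^1 m_{i,j}(s) beta_j(s) ds + c_i' kappa + delta_i

The two coordinate dimensions are concatenated into a single function for
the FPCA so cross-dimension covariance is respected; beta_j(s) is
reconstructed from the basis coefficients.  All quadrature is trapezoidal
on the uniform grid so model fitting and downstream causal-effect
integration are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq as _scipy_lstsq


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, _, _ = _scipy_lstsq(X, y, lapack_driver="gelsy", check_finite=False)
    return coef

__all__ = [
    "BasisConfig",
    "ShapeOnScalarFit",
    "ScalarOnShapeFit",
    "fit_shape_on_scalar",
    "fit_scalar_on_shape",
    "functional_inner_product",
    "trapezoid_weights",
]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w with sum_t w_t f(s_t) = int f ds (trapezoid)."""
    grid = np.asarray(grid, dtype=float)
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def functional_inner_product(f: np.ndarray, g: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal approximation of int_0^1 f(s) g(s) ds on a shared grid."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.shape[-1] != np.asarray(grid).size:
        raise ValueError("functions must live on the same grid")
    return float(np.trapezoid(f * g, grid))


@dataclass
class BasisConfig:
    """Mediator basis for the scalar-on-shape model.

    Exactly one of ``pve_threshold`` (keep the smallest K functional
    principal components explaining that fraction of variance) or
    ``n_components`` (fixed K) is active.
    """

    method: str = "fpca"
    pve_threshold: float | None = 0.95
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("fpca",):
            raise ValueError(f"unknown basis method {self.method!r}")
        if (self.pve_threshold is None) == (self.n_components is None):
            raise ValueError("exactly one of pve_threshold / n_components must be set")
        if self.pve_threshold is not None and not 0 < self.pve_threshold <= 1:
            raise ValueError("pve_threshold must lie in (0, 1]")


@dataclass
class ShapeOnScalarFit:
    """Pointwise-OLS fit of the mediator model."""

    grid: np.ndarray
    alpha: np.ndarray  # T x 2, genetic effect function per dimension
    xi: np.ndarray  # p x T x 2, covariate effect functions
    fitted: np.ndarray  # n x T x 2
    residual: np.ndarray  # n x T x 2, estimates of eta + eps


@dataclass
class ScalarOnShapeFit:
    """FPCA-truncated OLS fit of the outcome model."""

    grid: np.ndarray
    gamma: float  # direct genetic effect
    beta: np.ndarray  # T x 2, mediator effect function per dimension
    kappa: np.ndarray  # p, covariate effects
    basis_coefs: np.ndarray  # K
    basis: np.ndarray  # K x T x 2 orthonormal eigenfunctions
    scores: np.ndarray  # n x K
    pve: np.ndarray  # cumulative proportion of variance explained
    fitted: np.ndarray  # n
    residuals: np.ndarray  # n, delta-hat

    @property
    def n_components(self) -> int:
        return self.basis_coefs.size


def _flatten(M: np.ndarray) -> np.ndarray:
    """n x T x 2 -> n x 2T with the two dimensions concatenated."""
    return np.concatenate([M[:, :, 0], M[:, :, 1]], axis=1)


def _unflatten(v: np.ndarray, T: int) -> np.ndarray:
    """... x 2T -> ... x T x 2."""
    return np.stack([v[..., :T], v[..., T:]], axis=-1)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j] if j < len(names) else f"col{j}")
            r = rj
        raise ValueError(f"collinear design; offending columns: {bad}")


def fit_shape_on_scalar(M: np.ndarray, x: np.ndarray, C: np.ndarray) -> ShapeOnScalarFit:
    """Fit the mediator model by OLS at every grid point and dimension.

    Parameters
    ----------
    M
        ``n x T x 2`` aligned SRVF mediators on a shared uniform grid.
    x
        Length-n exposure vector (SNP dosage).
    C
        ``n x p`` covariates including the intercept column.
    """
    M = np.asarray(M, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n, T, d = M.shape
    if d != 2:
        raise ValueError("mediators must be two-dimensional functions (n x T x 2)")
    if x.size != n or C.shape[0] != n:
        raise ValueError("subject-count mismatch across M, x, C")
    X = np.column_stack([x, C])
    if n <= X.shape[1]:
        raise ValueError("need n > p + 1 subjects")
    _check_design(X, ["x"] + [f"C{j}" for j in range(C.shape[1])])
    Mf = _flatten(M)  # n x 2T
    B, *_ = np.linalg.lstsq(X, Mf, rcond=None)  # (1+p) x 2T
    fitted = _unflatten(X @ B, T)
    grid = np.linspace(0.0, 1.0, T)
    return ShapeOnScalarFit(
        grid=grid,
        alpha=_unflatten(B[0], T),
        xi=_unflatten(B[1:], T),
        fitted=fitted,
        residual=M - fitted,
    )


def _fpca(Mc_flat: np.ndarray, w2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature-weighted FPCA of centered concatenated functions.

    Returns (eigenfunctions Phi as columns of a 2T x K matrix, orthonormal
    in the concatenated L2 inner product, K = full numerical rank) and the
    eigenvalues of the covariance operator.
    """
    n, d = Mc_flat.shape
    sw = np.sqrt(w2)
    Mw = Mc_flat * sw[None, :]
    if d <= n:
        # eigendecomposition of the d x d Gram matrix (faster than the SVD
        # of the tall matrix, same right singular vectors)
        G = Mw.T @ Mw
        evals, V = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        lam = np.clip(evals[order], 0.0, None) / n
        Vt = V[:, order].T
    else:
        _, S, Vt = np.linalg.svd(Mw, full_matrices=False)
        lam = S**2 / n
    keep = lam > max(1e-12 * lam[0] if lam.size and lam[0] > 0 else 0.0, 1e-30)
    Phi = (Vt[keep] / sw[None, :]).T  # 2T x K, int sum_j phi_kj^2 ds = 1
    return Phi, lam[keep]


def fit_scalar_on_shape(
    y: np.ndarray,
    M: np.ndarray,
    x: np.ndarray,
    C: np.ndarray,
    basis: BasisConfig | None = None,
    validate: bool = True,
) -> ScalarOnShapeFit:
    """Fit the outcome model with functional mediator predictors.

    The mediators, centered at their cross-sectional mean function, are
    expanded in the FPCA basis of the pooled two-dimensional functions;
    scores z_{ik} = sum_j int m_{i,j}(s) phi_{k,j}(s) ds enter an OLS of y
    on [x, z, C], and beta_j(s) is reconstructed from the score
    coefficients.  Mediators with numerically zero variance drop to K = 0
    and the model reduces to OLS of y on (x, C).
    """
    if basis is None:
        basis = BasisConfig()
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n, T, d = M.shape
    if d != 2:
        raise ValueError("mediators must be n x T x 2")
    if y.size != n or x.size != n or C.shape[0] != n:
        raise ValueError("subject-count mismatch across y, M, x, C")
    grid = np.linspace(0.0, 1.0, T)
    w = trapezoid_weights(grid)
    w2 = np.concatenate([w, w])
    Mf = _flatten(M)
    Mc = Mf - Mf.mean(axis=0)
    total_var = float((Mc**2).mean())
    p = C.shape[1]
    if total_var < 1e-24:
        K = 0
        Phi = np.zeros((2 * T, 0))
        pve = np.zeros(0)
    else:
        Phi_full, lam = _fpca(Mc, w2)
        cum = np.cumsum(lam) / lam.sum()
        if basis.n_components is not None:
            K = min(basis.n_components, Phi_full.shape[1])
        else:
            K = int(np.searchsorted(cum, basis.pve_threshold - 1e-12) + 1)
        if K >= n - p - 1:
            raise ValueError(
                f"K={K} basis functions saturate the design (n={n}, p={p}); "
                "reduce pve_threshold or fix a smaller K"
            )
        Phi = Phi_full[:, :K]
        pve = cum[:K]
    Z = (Mc * w2[None, :]) @ Phi  # n x K scores
    X = np.column_stack([x, Z, C])
    if n <= X.shape[1]:
        raise ValueError("saturated design: n <= 1 + K + p")
    if validate:
        _check_design(X, ["x"] + [f"z{k}" for k in range(K)] + [f"C{j}" for j in range(p)])
    coef = _lstsq(X, y)
    fitted = X @ coef
    b = coef[1 : 1 + K]
    beta_flat = Phi @ b if K > 0 else np.zeros(2 * T)
    return ScalarOnShapeFit(
        grid=grid,
        gamma=float(coef[0]),
        beta=_unflatten(beta_flat, T),
        kappa=coef[1 + K :],
        basis_coefs=b,
        basis=_unflatten(Phi.T, T) if K > 0 else np.zeros((0, T, 2)),
        scores=Z,
        pve=pve,
        fitted=fitted,
        residuals=y - fitted,
    )
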