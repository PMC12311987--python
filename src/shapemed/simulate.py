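"""Synthetic cohorts with the exact generative structure of the mediation models.

The generator draws, for each subject i,

* a biallelic exposure x_i ~ Bernoulli(maf) (carrier coding; additive
  Binomial(2, maf) optional),
* confounders c_i = (1, standard normal, Bernoulli(0.5)),
* a two-dimensional functional mediator assembled from the
  shape-on-scalar model, with the subject effect eta_{i,j} drawn from a
  zero-mean Gaussian process on the grid and white measurement error,
* a scalar outcome assembled from the scalar-on-shape model with
  trapezoidal integration of int m_{i,j}(s) beta_j(s) ds.

The true ADE/AIE/SAIE implied by the chosen coefficient functions are
returned in closed form (quadrature on the grid), so recovery, coverage,
and band-validity experiments all have an exact truth to compare with.
An optional hidden confounder entering both equations — but withheld from
the returned covariates — operationalizes violation of the
no-unmeasured-mediator-outcome-confounding assumption for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .curves import LandmarkCurve
from .effects import CausalEffectSet
from .mediation import trapezoid_weights
from .screen import GenotypeTable

__all__ = [
    "SimulationScenario",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_hidden_confounder",
    "simulate_genotypes",
    "simulate_shape_cohort_from_template",
    "cc_like_template",
    "miae",
    "mise",
    "mae",
    "mse",
]

FunctionPair = tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]


def _default_alpha() -> FunctionPair:
    return (lambda s: np.sin(2 * np.pi * s), lambda s: np.cos(2 * np.pi * s))


def _default_beta() -> FunctionPair:
    return (lambda s: np.sin(2 * np.pi * s), lambda s: np.cos(2 * np.pi * s))


def _default_xi():
    # effect functions for the two non-intercept confounders plus intercept
    return (
        (lambda s: 0.5 * np.ones_like(s), lambda s: 0.5 * s),  # intercept
        (lambda s: 0.3 * s, lambda s: 0.3 * (1 - s)),  # normal confounder
        (lambda s: 0.2 * np.sin(np.pi * s), lambda s: 0.2 * np.cos(np.pi * s)),  # binary
    )


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic cohort.

    Defaults give a moderate-signal regime: unit true AIE
    (alpha_j = beta_j = (sin, cos)(2 pi s) so int sum_j alpha_j beta_j = 1),
    direct effect gamma = 1, squared-exponential GP subject effects
    (length_scale 0.2, variance 0.5), and noise SDs 0.5.
    """

    n: int = 200
    T: int = 50
    maf: float = 0.3
    coding: str = "binary"
    true_alpha: FunctionPair = field(default_factory=_default_alpha)
    true_beta: FunctionPair = field(default_factory=_default_beta)
    true_gamma: float = 1.0
    true_xi: tuple = field(default_factory=_default_xi)
    true_kappa: tuple[float, ...] = (0.5, -0.5, 0.3)
    gp_kernel: dict = field(
        default_factory=lambda: {"name": "squared_exponential", "length_scale": 0.2, "variance": 0.5}
    )
    sigma_eps: float = 0.5
    sigma_delta: float = 0.5
    hidden_confounder_strength: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("invalid scenario field n: must be >= 1")
        if self.T < 3:
            raise ValueError("invalid scenario field T: must be >= 3")
        if not 0 < self.maf <= 0.5:
            raise ValueError("invalid scenario field maf: must lie in (0, 0.5]")
        if self.coding not in ("binary", "additive"):
            raise ValueError("invalid scenario field coding")
        for name in ("sigma_eps", "sigma_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid scenario field {name}: must be >= 0")
        if self.gp_kernel.get("variance", 0.0) < 0:
            raise ValueError("invalid scenario field gp_kernel.variance: must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.T)

    def truth(self) -> CausalEffectSet:
        """Closed-form causal estimands implied by the coefficient functions."""
        s = self.grid
        saie = self.true_alpha[0](s) * self.true_beta[0](s) + self.true_alpha[1](s) * self.true_beta[1](s)
        aie = float(np.trapezoid(saie, s))
        ade = float(self.true_gamma)
        ate = ade + aie
        mp = float("nan") if ate == 0 else abs(aie / ate) * 100.0
        return CausalEffectSet(ade=ade, aie=aie, ate=ate, mp=mp, saie=saie, grid=s)


@dataclass
class SimulatedCohort:
    """One draw from a :class:`SimulationScenario`."""

    x: np.ndarray  # n exposures
    C: np.ndarray  # n x 3 confounders (intercept, normal, Bernoulli)
    M: np.ndarray  # n x T x 2 mediators
    y: np.ndarray  # n outcomes
    truth: CausalEffectSet
    grid: np.ndarray
    hidden_u: np.ndarray | None = None  # the withheld confounder, for diagnostics


def _gp_covariance(grid: np.ndarray, kernel: dict) -> np.ndarray:
    name = kernel.get("name", "squared_exponential")
    ell = kernel.get("length_scale", 0.2)
    var = kernel.get("variance", 0.5)
    d = grid[:, None] - grid[None, :]
    if name == "squared_exponential":
        K = var * np.exp(-0.5 * (d / ell) ** 2)
    elif name == "matern32":
        a = np.sqrt(3.0) * np.abs(d) / ell
        K = var * (1.0 + a) * np.exp(-a)
    else:
        raise ValueError(f"invalid scenario field gp_kernel.name: {name!r}")
    return K


def gp_covariance(scenario: SimulationScenario) -> np.ndarray:
    """Configured covariance matrix of the subject-effect GP on the grid."""
    return _gp_covariance(scenario.grid, scenario.gp_kernel)


def _draw_cohort(scenario: SimulationScenario, hidden: bool) -> SimulatedCohort:
    rng = np.random.default_rng(scenario.seed)
    n, T = scenario.n, scenario.T
    s = scenario.grid
    if scenario.coding == "binary":
        x = rng.binomial(1, scenario.maf, size=n).astype(float)
    else:
        x = rng.binomial(2, scenario.maf, size=n).astype(float)
    C = np.column_stack(
        [np.ones(n), rng.standard_normal(n), rng.binomial(1, 0.5, size=n).astype(float)]
    )
    K = _gp_covariance(s, scenario.gp_kernel)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(T)) if scenario.gp_kernel["variance"] > 0 else np.zeros((T, T))
    eta = rng.standard_normal((n, 2, T)) @ L.T  # independent GP per dimension
    eps = scenario.sigma_eps * rng.standard_normal((n, T, 2))
    u = rng.standard_normal(n)
    su_m, su_y = scenario.hidden_confounder_strength if hidden else (0.0, 0.0)
    alpha = np.column_stack([scenario.true_alpha[0](s), scenario.true_alpha[1](s)])  # T x 2
    xi = np.stack(
        [np.column_stack([fj[0](s), fj[1](s)]) for fj in scenario.true_xi]
    )  # p x T x 2
    M = (
        x[:, None, None] * alpha[None, :, :]
        + np.einsum("ip,ptj->itj", C, xi)
        + eta.transpose(0, 2, 1)
        + eps
    )
    if su_m != 0.0:
        M = M + su_m * u[:, None, None]
    beta = np.column_stack([scenario.true_beta[0](s), scenario.true_beta[1](s)])
    w = trapezoid_weights(s)
    integral = np.einsum("itj,tj,t->i", M, beta, w)
    delta = scenario.sigma_delta * rng.standard_normal(n)
    y = scenario.true_gamma * x + integral + C @ np.asarray(scenario.true_kappa) + delta
    if su_y != 0.0:
        y = y + su_y * u
    return SimulatedCohort(
        x=x, C=C, M=M, y=y, truth=scenario.truth(), grid=s, hidden_u=u if hidden else None
    )


def simulate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw a fully observed cohort (no hidden confounding).

    Reproducible: the same scenario (including seed) yields byte-identical
    output.
    """
    return _draw_cohort(scenario, hidden=False)


def simulate_hidden_confounder(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw a cohort with an unmeasured confounder U ~ N(0, 1).

    U shifts the mediator by ``strength[0] * U`` (both dimensions,
    constant in s) and the outcome by ``strength[1] * U``, but is withheld
    from the returned covariates; with strength (0, 0) the draw is
    identical to :func:`simulate_cohort` at the same seed.
    """
    return _draw_cohort(scenario, hidden=True)


def simulate_genotypes(
    n: int,
    n_snps: int,
    maf: float | np.ndarray = 0.3,
    coding: str = "binary",
    seed: int = 0,
) -> GenotypeTable:
    """A panel of independent SNPs at the given minor-allele frequencies."""
    rng = np.random.default_rng(seed)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
    k = 1 if coding == "binary" else 2
    dos = rng.binomial(k, maf[None, :], size=(n, n_snps)).astype(float)
    return GenotypeTable(
        dosages=dos,
        snp_ids=np.array([f"rs{j:06d}" for j in range(n_snps)]),
        subject_ids=np.array([f"S{i:05d}" for i in range(n)]),
        coding=coding,
    )


def cc_like_template(m: int = 100) -> LandmarkCurve:
    """A smooth closed bean-like outline resembling a mid-sagittal corpus
    callosum contour, from a low-order Fourier series; synthetic stand-in
    for segmented imaging data."""
    t = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    r = 1.0 + 0.35 * np.cos(t) + 0.18 * np.sin(2 * t) + 0.07 * np.cos(3 * t)
    x = 1.8 * r * np.cos(t)
    y = 0.7 * r * np.sin(t)
    pts = np.column_stack([x, y])
    pts = np.vstack([pts, pts[:1]])  # close the outline; treated as open from the seed landmark
    return LandmarkCurve(points=pts, subject_id="template")


def _random_warp(m: int, warp_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random boundary-preserving warp of [0, 1] sampled at m points."""
    u = np.linspace(0.0, 1.0, m)
    if warp_sd == 0.0:
        return u
    a = rng.normal(0.0, warp_sd, size=2)
    g = u + a[0] * np.sin(2 * np.pi * u) * u * (1 - u) + a[1] * np.sin(np.pi * u) * u * (1 - u)
    g = np.maximum.accumulate(g)
    g = (g - g[0]) / (g[-1] - g[0])
    return g


def simulate_shape_cohort_from_template(
    template: LandmarkCurve,
    n: int,
    rotation_sd: float = 0.3,
    warp_sd: float = 0.2,
    translation_sd: float = 1.0,
    scale_sd: float = 0.3,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> list[LandmarkCurve]:
    """Perturb a template contour with shape-preserving nuisance variation.

    Each copy receives a random rotation (angle ~ N(0, rotation_sd)),
    translation, log-normal scaling, a smooth random reparameterization of
    the landmarks, and optional landmark jitter.  Since all variation is
    nuisance, :func:`shapemed.register.align_cohort` should collapse the
    cohort back onto (nearly) a single shape.
    """
    rng = np.random.default_rng(seed)
    m = template.points.shape[0]
    u, _ = _cum_param(template.points)
    uu = np.linspace(0.0, 1.0, m)
    out = []
    for i in range(n):
        # evaluate the random warp at the template's own parameter values so
        # that warp_sd = 0 reproduces the template landmarks exactly
        g = np.interp(u, uu, _random_warp(m, warp_sd, rng))
        pts = np.column_stack(
            [np.interp(g, u, template.points[:, 0]), np.interp(g, u, template.points[:, 1])]
        )
        th = rng.normal(0.0, rotation_sd)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = pts @ R.T
        pts = pts * np.exp(rng.normal(0.0, scale_sd))
        pts = pts + rng.normal(0.0, translation_sd, size=2)
        if jitter_sd > 0:
            pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
        out.append(LandmarkCurve(points=pts, subject_id=f"S{i:05d}"))
    return out


def _cum_param(points: np.ndarray) -> tuple[np.ndarray, float]:
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    cum = np.concatenate([[0.0], np.cumsum(seglen)]) / total
    return cum, total


# ---------------------------------------------------------------------------
# Error metrics for simulation studies

def miae(est: np.ndarray, truth: np.ndarray, grid: np.ndarray) -> float:
    """Integrated absolute error int |est - truth| ds, summed over function
    dimensions; grid runs along axis 0."""
    return float(np.sum(np.trapezoid(np.abs(est - truth), grid, axis=0)))


def mise(est: np.ndarray, truth: np.ndarray, grid: np.ndarray) -> float:
    """Integrated squared error int (est - truth)^2 ds, summed over function
    dimensions; grid runs along axis 0."""
    return float(np.sum(np.trapezoid((est - truth) ** 2, grid, axis=0)))


def mae(est: float, truth: float) -> float:
    return abs(est - truth)


def mse(est: float, truth: float) -> float:
    return (est - truth) ** 2
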