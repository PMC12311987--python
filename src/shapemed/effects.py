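"""Causal estimands and wild-bootstrap inference for shape mediation.

For a binary exposure contrast (x = 0 vs 1) the fitted mediation models
give plug-in estimators of

    ADE      = gamma                         (average direct effect)
    SAIE(s)  = sum_j alpha_j(s) beta_j(s)    (spatial average indirect effect)
    AIE      = int_0^1 SAIE(s) ds            (average indirect effect)
    ATE      = ADE + AIE                     (average total effect)
    MP       = |AIE / ATE| * 100%            (mediation proportion)

Uncertainty is quantified by a wild bootstrap: each subject's whole
mediator-model residual function and, independently, its outcome-model
residual are multiplied by random weights (Rademacher by default), the
starred data are refit, and symmetric intervals point +/- C(theta) are
built from the (1 - theta) quantile of absolute deviations.  The SAIE
gets a constant-width simultaneous confidence band from the sup-norm
deviation quantile, from which significant subregions are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mediation import (
    BasisConfig,
    ScalarOnShapeFit,
    ShapeOnScalarFit,
    fit_scalar_on_shape,
    fit_shape_on_scalar,
)

__all__ = [
    "CausalEffectSet",
    "BootstrapConfig",
    "BootstrapReplicates",
    "compute_effects",
    "compute_mp",
    "wild_bootstrap",
    "interval_from_bootstrap",
    "band_from_bootstrap",
    "detect_subregions",
    "call_significance",
    "mediate",
]


@dataclass
class CausalEffectSet:
    """Point estimates and (optionally) bootstrap inference for one SNP."""

    ade: float
    aie: float
    ate: float
    mp: float  # |AIE/ATE| in percent; NaN when ATE = 0
    saie: np.ndarray  # T
    grid: np.ndarray
    snp_id: str = ""
    outcome_name: str = ""
    ade_interval: tuple[float, float] | None = None
    aie_interval: tuple[float, float] | None = None
    saie_band: tuple[np.ndarray, np.ndarray] | None = None
    significant_mask: np.ndarray | None = None
    subregions: list[tuple[float, float]] | None = None
    significance: dict | None = None


@dataclass
class BootstrapConfig:
    """Wild-bootstrap settings: replicate count, multiplier law, level, seed."""

    n_boot: int = 1000
    multiplier: str = "rademacher"
    level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.multiplier not in ("rademacher", "mammen", "gaussian"):
            raise ValueError(f"unknown multiplier {self.multiplier!r}")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")


@dataclass
class BootstrapReplicates:
    """Per-replicate point estimates from the wild bootstrap."""

    ade: np.ndarray  # B
    aie: np.ndarray  # B
    saie: np.ndarray  # B x T
    grid: np.ndarray

    @property
    def ate(self) -> np.ndarray:
        return self.ade + self.aie


def compute_mp(aie: float, ate: float) -> float:
    """Mediation proportion |AIE/ATE| as a percentage; NaN for ATE = 0."""
    if ate == 0.0:
        return float("nan")
    return abs(aie / ate) * 100.0


def compute_effects(
    fit4: ShapeOnScalarFit,
    fit5: ScalarOnShapeFit,
    snp_id: str = "",
    outcome_name: str = "",
) -> CausalEffectSet:
    """Plug-in causal estimands from the two fitted mediation models."""
    if fit4.grid.size != fit5.grid.size or not np.allclose(fit4.grid, fit5.grid):
        raise ValueError("mediator and outcome fits must share one grid")
    saie = (fit4.alpha * fit5.beta).sum(axis=1)  # sum over the 2 dims
    aie = float(np.trapezoid(saie, fit4.grid))
    ade = float(fit5.gamma)
    ate = ade + aie
    return CausalEffectSet(
        ade=ade,
        aie=aie,
        ate=ate,
        mp=compute_mp(aie, ate),
        saie=saie,
        grid=fit4.grid.copy(),
        snp_id=snp_id,
        outcome_name=outcome_name,
    )


def _multipliers(rng: np.random.Generator, kind: str, size: int) -> np.ndarray:
    if kind == "rademacher":
        return rng.integers(0, 2, size=size) * 2.0 - 1.0
    if kind == "gaussian":
        return rng.standard_normal(size)
    # Mammen two-point law: mean 0, variance 1, third moment 1
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    p = (golden) / np.sqrt(5.0)  # P(v = (1-golden))
    u = rng.random(size)
    return np.where(u < p, 1.0 - golden, golden)


def wild_bootstrap(
    y: np.ndarray,
    M: np.ndarray,
    x: np.ndarray,
    C: np.ndarray,
    fit4: ShapeOnScalarFit,
    fit5: ScalarOnShapeFit,
    config: BootstrapConfig,
    basis: BasisConfig | None = None,
) -> BootstrapReplicates:
    """Wild-bootstrap replicates of (ADE, AIE, SAIE).

    Per replicate b, independent per-subject multipliers v_i and w_i are
    drawn; starred data are rebuilt as

        m*_i(s) = fitted4_i(s) + v_i * residual4_i(s)
        y*_i    = fitted5_i   + w_i * deltahat_i

    (one multiplier per subject scales the whole residual function,
    preserving within-curve correlation of eta + eps; the outcome's
    mediator-dependent part is rebuilt from the starred mediators so that
    y* stays coupled to m*).  Both models are then refit on the starred
    data — the mediator model on (m*, x, C), the outcome model on
    (y*, m*, x, C) with the FPCA basis recomputed — and the plug-in
    estimands recorded.  Residuals are leverage-scaled (HC2): raw OLS
    residuals have variance (1 - h_ii) sigma^2, a material understatement
    for the wide outcome design (1 + K + p parameters).  Deterministic
    given ``config.seed``.
    """
    from .mediation import trapezoid_weights

    rng = np.random.default_rng(config.seed)
    n = y.size
    B = config.n_boot
    T = M.shape[1]
    X4 = np.column_stack([x, C])
    pinv4 = np.linalg.pinv(X4)
    h4 = np.einsum("ij,ji->i", X4, pinv4)
    resid4 = fit4.residual / np.sqrt(np.clip(1.0 - h4, 1e-8, None))[:, None, None]
    X5 = np.column_stack([x, fit5.scores, C])
    pinv5 = np.linalg.pinv(X5)
    h5 = np.einsum("ij,ji->i", X5, pinv5)
    resid5 = fit5.residuals / np.sqrt(np.clip(1.0 - h5, 1e-8, None))
    w = trapezoid_weights(fit4.grid)
    # outcome fitted values with the <m_i, beta-hat> part split out, so it
    # can be rebuilt from each replicate's starred mediators
    mbeta_hat = np.einsum("itj,tj,t->i", M, fit5.beta, w)
    base5 = fit5.fitted - mbeta_hat
    ade = np.empty(B)
    aie = np.empty(B)
    saie = np.empty((B, T))
    for b in range(B):
        v = _multipliers(rng, config.multiplier, n)
        wmult = _multipliers(rng, config.multiplier, n)
        Mstar = fit4.fitted + v[:, None, None] * resid4
        ystar = base5 + np.einsum("itj,tj,t->i", Mstar, fit5.beta, w) + wmult * resid5
        # mediator-model refit: design unchanged, only the response is starred
        Mstar_flat = np.concatenate([Mstar[:, :, 0], Mstar[:, :, 1]], axis=1)
        row = pinv4[0] @ Mstar_flat
        alpha_star = np.stack([row[:T], row[T:]], axis=-1)
        f5s = fit_scalar_on_shape(ystar, Mstar, x, C, basis=basis, validate=False)
        s = (alpha_star * f5s.beta).sum(axis=1)
        ade[b] = f5s.gamma
        saie[b] = s
        aie[b] = np.trapezoid(s, fit4.grid)
    return BootstrapReplicates(ade=ade, aie=aie, saie=saie, grid=fit4.grid.copy())


def interval_from_bootstrap(
    point: float, replicates: np.ndarray, level: float = 0.05
) -> tuple[float, float]:
    """Symmetric interval point +/- C, C the (1-level) quantile of |theta*_b - point|."""
    c = float(np.quantile(np.abs(np.asarray(replicates) - point), 1.0 - level))
    return (point - c, point + c)


def band_from_bootstrap(
    saie_hat: np.ndarray, saie_replicates: np.ndarray, level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-width simultaneous band from the sup-norm deviation quantile."""
    saie_hat = np.asarray(saie_hat, dtype=float)
    dev = np.abs(np.asarray(saie_replicates) - saie_hat[None, :]).max(axis=1)
    c = float(np.quantile(dev, 1.0 - level))
    return (saie_hat - c, saie_hat + c)


def detect_subregions(
    band: tuple[np.ndarray, np.ndarray], grid: np.ndarray
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Grid points where the band excludes zero, and their contiguous runs in s."""
    lower, upper = band
    mask = (lower > 0) | (upper < 0)
    regions: list[tuple[float, float]] = []
    start = None
    for t, m in enumerate(mask):
        if m and start is None:
            start = t
        elif not m and start is not None:
            regions.append((float(grid[start]), float(grid[t - 1])))
            start = None
    if start is not None:
        regions.append((float(grid[start]), float(grid[len(mask) - 1])))
    return mask, regions


def call_significance(effects: CausalEffectSet) -> dict:
    """Strict-exclusion significance calls from the computed intervals."""
    out = {}
    for name, iv in (("ade", effects.ade_interval), ("aie", effects.aie_interval)):
        if iv is None:
            out[name] = None
        else:
            lo, hi = iv
            out[name] = bool(lo > 0 or hi < 0)
    return out


def mediate(
    y: np.ndarray,
    M: np.ndarray,
    x: np.ndarray,
    C: np.ndarray,
    basis: BasisConfig | None = None,
    bootstrap: BootstrapConfig | None = None,
    snp_id: str = "",
    outcome_name: str = "",
) -> CausalEffectSet:
    """Full mediation analysis for one SNP: fit both models, compute the
    causal estimands, and (if a bootstrap config is given) attach
    intervals, the SAIE simultaneous band, subregions, and significance
    calls."""
    fit4 = fit_shape_on_scalar(M, x, C)
    fit5 = fit_scalar_on_shape(y, M, x, C, basis=basis)
    eff = compute_effects(fit4, fit5, snp_id=snp_id, outcome_name=outcome_name)
    if bootstrap is not None:
        if bootstrap.n_boot < 100:
            import warnings

            warnings.warn("n_boot < 100 is unreliable for inference", stacklevel=2)
        reps = wild_bootstrap(y, M, x, C, fit4, fit5, bootstrap, basis=basis)
        eff.ade_interval = interval_from_bootstrap(eff.ade, reps.ade, bootstrap.level)
        eff.aie_interval = interval_from_bootstrap(eff.aie, reps.aie, bootstrap.level)
        eff.saie_band = band_from_bootstrap(eff.saie, reps.saie, bootstrap.level)
        eff.significant_mask, eff.subregions = detect_subregions(eff.saie_band, eff.grid)
        eff.significance = call_significance(eff)
    return eff
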