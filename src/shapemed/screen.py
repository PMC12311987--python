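"""Per-SNP association screen of a scalar outcome with FDR selection.

For each locus g the model

    y_i = x_ig * nu_g + c_i' u_g + eps_i

is fit by ordinary least squares, with a two-sided t-test on the genetic
effect nu_g.  Benjamini-Hochberg adjustment across loci yields the
candidate set G0 of SNPs passed on to mediation analysis.  Genotypes may
be coded {0,1} (carrier) or {0,1,2} (additive dosage); the screen is
identical either way.

The genome-wide fit is vectorized by Frisch-Waugh-Lovell residualization
against the shared covariates, which is algebraically the per-SNP OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeTable",
    "ScreenResult",
    "fit_snp_model",
    "bh_adjust",
    "genome_screen",
    "read_genotypes",
]


@dataclass
class GenotypeTable:
    """Subjects x SNPs dosage matrix with locus metadata."""

    dosages: np.ndarray  # n x N_G
    snp_ids: np.ndarray
    subject_ids: np.ndarray
    chromosomes: np.ndarray | None = None
    positions: np.ndarray | None = None
    coding: str = "binary"  # "binary" {0,1} or "additive" {0,1,2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.shape != (self.subject_ids.size, self.snp_ids.size):
            raise ValueError("dosage matrix must be n_subjects x n_snps")
        allowed = {0.0, 1.0} if self.coding == "binary" else {0.0, 1.0, 2.0}
        vals = set(np.unique(self.dosages[np.isfinite(self.dosages)]))
        if not vals.issubset(allowed):
            raise ValueError(f"dosages outside {self.coding} coding {sorted(allowed)}: {sorted(vals - allowed)}")
        if self.chromosomes is None:
            self.chromosomes = np.zeros(self.snp_ids.size, dtype=int)
        if self.positions is None:
            self.positions = np.arange(self.snp_ids.size)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP."""
        denom = 1.0 if self.coding == "binary" else 2.0
        return self.dosages.mean(axis=0) / denom


@dataclass
class ScreenResult:
    """Per-SNP screen statistics and the FDR-selected flag."""

    table: pd.DataFrame  # snp, chr, pos, freq, effect, se, p, p_adj, selected
    q_threshold: float

    @property
    def selected_snps(self) -> np.ndarray:
        return self.table.loc[self.table["selected"], "snp"].to_numpy()

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def fit_snp_model(y: np.ndarray, x_g: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of one SNP: returns (effect, standard error, two-sided p).

    ``C`` must include the intercept column.  A monomorphic SNP (constant
    dosage) yields NaN effect/se/p.
    """
    y = np.asarray(y, dtype=float)
    x_g = np.asarray(x_g, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = y.size
    if np.ptp(x_g) == 0.0:
        return (np.nan, np.nan, np.nan)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    X = np.column_stack([x_g, C])
    if n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix [x_g, C] is rank deficient")
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df if df > 0 else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    eff = float(beta[0])
    if se == 0.0:
        p = 0.0 if eff != 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(eff) / se, df))
    return (eff, se, p)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaNs (monomorphic SNPs) are passed through and excluded from the
    adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def genome_screen(
    y: np.ndarray,
    genotypes: GenotypeTable,
    C: np.ndarray,
    q_threshold: float = 0.05,
) -> ScreenResult:
    """Screen every SNP against the outcome and select at FDR ``q_threshold``.

    Vectorized per-SNP OLS: y and each dosage column are residualized
    against C (which includes the intercept); the slope of the residual
    regression equals the OLS genetic effect, with the t-test on
    n - p - 1 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = y.size
    if genotypes.n_subjects != n or C.shape[0] != n:
        raise ValueError(
            f"subject-count mismatch: y has {n}, genotypes {genotypes.n_subjects}, C {C.shape[0]}"
        )
    X = genotypes.dosages
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    Sxx = (Xr**2).sum(axis=0)
    mono = np.ptp(X, axis=0) == 0.0
    Sxx_safe = np.where(Sxx > 0, Sxx, 1.0)
    eff = (Xr * yr[:, None]).sum(axis=0) / Sxx_safe
    df = n - C.shape[1] - 1
    rss = (yr @ yr) - eff**2 * Sxx
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / Sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, eff / se, np.where(eff != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    eff[mono] = se[mono] = p[mono] = np.nan
    p_adj = bh_adjust(p)
    selected = np.where(np.isfinite(p_adj), p_adj <= q_threshold, False)
    table = pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chr": genotypes.chromosomes,
            "pos": genotypes.positions,
            "freq": genotypes.allele_frequencies(),
            "effect": eff,
            "se": se,
            "p": p,
            "p_adj": p_adj,
            "selected": selected,
        }
    )
    return ScreenResult(table=table, q_threshold=q_threshold)


def read_genotypes(path, coding: str = "binary") -> GenotypeTable:
    """Read a genotype dosage table.

    Supports PLINK ``.raw`` (whitespace-delimited, columns FID IID PAT MAT
    SEX PHENOTYPE then one column per SNP) and plain CSV with a
    ``subject_id`` column and one column per SNP.  Missing dosages are
    imputed with the per-SNP modal value.
    """
    path = str(path)
    if path.endswith(".raw"):
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        snp_cols = [c for c in df.columns if c not in meta]
        subject_ids = df["IID"].astype(str).to_numpy()
    else:
        df = pd.read_csv(path)
        if "subject_id" not in df.columns:
            raise ValueError("CSV genotype table requires a subject_id column")
        snp_cols = [c for c in df.columns if c != "subject_id"]
        subject_ids = df["subject_id"].astype(str).to_numpy()
    dos = df[snp_cols].to_numpy(dtype=float)
    # modal-value imputation per SNP
    for j in range(dos.shape[1]):
        col = dos[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            vals, counts = np.unique(col[~miss], return_counts=True)
            col[miss] = vals[np.argmax(counts)] if vals.size else 0.0
    return GenotypeTable(
        dosages=dos,
        snp_ids=np.asarray(snp_cols),
        subject_ids=subject_ids,
        coding=coding,
    )
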