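"""End-to-end orchestration: screen -> align -> per-SNP mediation with inference.

The three-stage workflow mirrors how a practitioner would analyze a
cohort: (i) a genome-wide linear screen of each outcome selects candidate
SNPs at a chosen FDR level; (ii) the landmark contours are normalized,
transformed to SRVFs, and aligned once to a Karcher-mean atlas (the
mediator does not depend on the SNP, so alignment is shared across loci);
(iii) for every selected SNP the two mediation models are fit, the causal
estimands computed, and wild-bootstrap intervals/bands attached.  Each
outcome is processed independently.

Reports: a per-outcome screen table (SNP, effect, SE, p, adjusted p,
selected), a causal table (ATE, ADE, AIE, AIE CI, MP, significance), and
per-SNP SAIE band files, plus JSON run metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import LandmarkCurve, read_landmarks, write_aligned_srvfs
from .effects import BootstrapConfig, CausalEffectSet, mediate
from .mediation import BasisConfig
from .register import align_cohort
from .screen import GenotypeTable, ScreenResult, genome_screen, read_genotypes

logger = logging.getLogger("shapemed")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    Data can be given as paths (CSV files, see the reader functions) or as
    in-memory objects; paths are validated eagerly.
    """

    genotypes: GenotypeTable | str
    landmarks: list[LandmarkCurve] | str
    phenotypes: pd.DataFrame | str  # subject_id, outcome column(s), covariate columns
    outcomes: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    n_grid: int = 100
    fdr_level: float = 0.05
    basis: BasisConfig = field(default_factory=BasisConfig)
    n_boot: int = 1000
    ci_level: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    genotype_coding: str = "binary"

    def __post_init__(self) -> None:
        for attr in ("genotypes", "landmarks", "phenotypes"):
            v = getattr(self, attr)
            if isinstance(v, str) and not Path(v).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {v}")


@dataclass
class PipelineResult:
    """Report bundle for one run."""

    screen_results: dict[str, ScreenResult]
    causal_tables: dict[str, pd.DataFrame]
    effects: dict[str, list[CausalEffectSet]]
    counts: pd.DataFrame  # outcome, n_selected (N_G0), n_significant (N_Gc)
    metadata: dict


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    basis_raw = raw.pop("basis", None)
    basis = BasisConfig(**basis_raw) if basis_raw else BasisConfig()
    return PipelineConfig(basis=basis, **raw)


def _resolve_inputs(config: PipelineConfig):
    geno = (
        read_genotypes(config.genotypes, coding=config.genotype_coding)
        if isinstance(config.genotypes, str)
        else config.genotypes
    )
    curves = (
        read_landmarks(config.landmarks) if isinstance(config.landmarks, str) else config.landmarks
    )
    pheno = (
        pd.read_csv(config.phenotypes) if isinstance(config.phenotypes, str) else config.phenotypes
    )
    return geno, curves, pheno


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screen -> align -> mediate workflow.

    An empty candidate set for an outcome is a valid run producing an
    empty causal report.  Any stage failure aborts with the stage name and
    the offending subject/SNP attached.
    """
    geno, curves, pheno = _resolve_inputs(config)
    outcomes = config.outcomes or [
        c for c in pheno.columns if c not in ("subject_id", *config.covariates)
    ]
    # covariate matrix with intercept
    if config.covariates:
        C = np.column_stack([np.ones(len(pheno)), pheno[config.covariates].to_numpy(dtype=float)])
    else:
        C = np.ones((len(pheno), 1))
    n = len(pheno)
    if geno.n_subjects != n or len(curves) != n:
        raise ValueError(
            f"stage screen: subject-count mismatch (phenotypes {n}, "
            f"genotypes {geno.n_subjects}, landmarks {len(curves)})"
        )

    logger.info("stage align: %d subjects, grid %d", n, config.n_grid)
    try:
        atlas, aligned = align_cohort(curves, n_grid=config.n_grid)
    except ValueError as e:
        raise RuntimeError(f"stage align failed: {e}") from e
    M = np.stack([a.values for a in aligned])  # n x T x 2

    screen_results: dict[str, ScreenResult] = {}
    causal_tables: dict[str, pd.DataFrame] = {}
    effects: dict[str, list[CausalEffectSet]] = {}
    counts = []
    rng = np.random.default_rng(config.seed)
    for outcome in outcomes:
        y = pheno[outcome].to_numpy(dtype=float)
        logger.info("stage screen: outcome %s, %d SNPs, FDR %.3g", outcome, geno.n_snps, config.fdr_level)
        sr = genome_screen(y, geno, C, q_threshold=config.fdr_level)
        screen_results[outcome] = sr
        sel = sr.table.index[sr.table["selected"]].tolist()
        logger.info("stage mediate: outcome %s, %d candidate SNPs", outcome, len(sel))
        rows = []
        eff_list = []
        for idx in sel:
            snp = str(sr.table.at[idx, "snp"])
            boot = BootstrapConfig(
                n_boot=config.n_boot,
                level=config.ci_level,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                eff = mediate(
                    y, M, geno.dosages[:, idx], C,
                    basis=config.basis, bootstrap=boot,
                    snp_id=snp, outcome_name=outcome,
                )
            except ValueError as e:
                raise RuntimeError(f"stage mediate failed at SNP {snp}, outcome {outcome}: {e}") from e
            eff_list.append(eff)
            lo, hi = eff.aie_interval
            rows.append(
                {
                    "snp": snp,
                    "outcome": outcome,
                    "ate": eff.ate,
                    "ade": eff.ade,
                    "aie": eff.aie,
                    "aie_ci_lower": lo,
                    "aie_ci_upper": hi,
                    "mp_percent": eff.mp,
                    "aie_significant": eff.significance["aie"],
                }
            )
        tab = pd.DataFrame(
            rows,
            columns=[
                "snp", "outcome", "ate", "ade", "aie",
                "aie_ci_lower", "aie_ci_upper", "mp_percent", "aie_significant",
            ],
        )
        causal_tables[outcome] = tab
        effects[outcome] = eff_list
        counts.append(
            {
                "outcome": outcome,
                "n_selected": sr.n_selected,
                "n_significant": int(tab["aie_significant"].sum()) if len(tab) else 0,
            }
        )
    counts_df = pd.DataFrame(counts, columns=["outcome", "n_selected", "n_significant"])
    metadata = {
        "seed": config.seed,
        "n_subjects": n,
        "n_snps": geno.n_snps,
        "n_grid": config.n_grid,
        "fdr_level": config.fdr_level,
        "n_boot": config.n_boot,
        "ci_level": config.ci_level,
        "atlas_converged": bool(atlas.converged),
        "atlas_iterations": int(atlas.n_iterations),
    }
    result = PipelineResult(
        screen_results=screen_results,
        causal_tables=causal_tables,
        effects=effects,
        counts=counts_df,
        metadata=metadata,
    )
    if config.out_dir is not None:
        _write_reports(result, aligned, config)
    return result


def _write_reports(result: PipelineResult, aligned, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_aligned_srvfs(out / "aligned_srvfs.csv", aligned)
    for outcome, sr in result.screen_results.items():
        sr.write(out / f"screen_{outcome}.csv")
    for outcome, tab in result.causal_tables.items():
        tab.to_csv(out / f"causal_{outcome}.csv", index=False)
        for eff in result.effects[outcome]:
            lo, hi = eff.saie_band
            pd.DataFrame(
                {
                    "s": eff.grid,
                    "saie": eff.saie,
                    "band_lower": lo,
                    "band_upper": hi,
                    "significant": eff.significant_mask,
                }
            ).to_csv(out / f"saie_{outcome}_{eff.snp_id}.csv", index=False)
    result.counts.to_csv(out / "counts.csv", index=False)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2)
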