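"""End-to-end pipeline: simulate, standardize, fit, compare, render tables.

Outputs mirror the published study's reporting: a cohort-averaged PGS
correlation matrix, a multivariate results table (21 PGS rows plus sex and
age), seven single-score univariate tables, and a univariate-versus-
multivariate comparison table that makes the attenuation of correlated-score
associations visible.  Every artifact embeds the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CohortDataset,
    PGS_COLUMNS,
    PGS_LABELS,
    standardize_for_analysis,
    write_cohort_table,
)
from .fit import (
    FitOptions,
    FitResult,
    bonferroni_alpha,
    fit_multivariate,
    fit_univariate,
    wald_results,
)
from .synthetic import (
    GeneratorTruth,
    StudyConfig,
    load_config,
    simulate_study,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class CorrelationReport:
    """Per-cohort PGS correlation matrices and their equal-weight average."""

    average: pd.DataFrame
    per_cohort: dict[str, pd.DataFrame] = field(default_factory=dict)

    def entry(self, a: str, b: str) -> float:
        return float(self.average.loc[a, b])


def pgs_correlation_table(
    study: Sequence[CohortDataset],
) -> CorrelationReport:
    """Pearson PGS correlations within each cohort, averaged with equal
    cohort weights (complete PGS rows only; cohorts with fewer than 3
    children are excluded with a warning)."""
    mats: dict[str, pd.DataFrame] = {}
    for ds in study:
        if ds.n_children < 3:
            logger.warning(
                "cohort %s has %d children; excluded from the correlation "
                "average", ds.spec.name, ds.n_children,
            )
            continue
        g = ds.pgs()
        g = g[~np.isnan(g).any(axis=1)]
        r = np.corrcoef(g, rowvar=False)
        mats[ds.spec.name] = pd.DataFrame(
            r, index=PGS_LABELS, columns=PGS_LABELS
        )
    if not mats:
        raise ValueError("no cohort large enough for a correlation matrix")
    avg = sum(mats.values()) / len(mats)
    return CorrelationReport(average=avg, per_cohort=mats)


# ---------------------------------------------------------------------------
# pipeline

def _config_hash(cfg: StudyConfig, truth: GeneratorTruth) -> str:
    payload = json.dumps(
        {"study": cfg.to_dict(), "truth": truth.to_dict()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(
    df: pd.DataFrame, path: Path, *, cfg_hash: str, seed: int,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def comparison_table(
    multi: pd.DataFrame, unis: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Side-by-side univariate and multivariate betas per (outcome, PGS)."""
    rows = []
    for pred, uni in unis.items():
        for _, r in uni.iterrows():
            m = multi[
                (multi["outcome"] == r["outcome"])
                & (multi["predictor"] == pred)
            ].iloc[0]
            rows.append(
                {
                    "outcome": r["outcome"],
                    "predictor": pred,
                    "beta_univariate": r["beta"],
                    "se_univariate": r["se"],
                    "beta_multivariate": m["beta"],
                    "se_multivariate": m["se"],
                    "attenuation": m["beta"] - r["beta"],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: str | Path | tuple[StudyConfig, GeneratorTruth],
    outdir: str | Path,
    *,
    seed: int | None = None,
    scale: float = 1.0,
    opts: FitOptions | None = None,
    univariate: bool = True,
) -> Path:
    """Simulate a study, fit every model, and write the artifact directory.

    ``seed`` overrides the config seed; ``scale`` multiplies every cohort
    size (for fast runs).  Artifacts: per-cohort data TSVs, Table-2-style
    correlation TSV, Table-3-style multivariate results TSV, per-score
    univariate TSVs, the comparison table, and a JSON-lines run log.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kw) -> None:
        rec = {"stage": stage, "elapsed_s": round(time.time() - t0, 2), **kw}
        log_fh.write(json.dumps(rec) + "\n")
        log_fh.flush()
        logger.info("%s (%.1fs) %s", stage, rec["elapsed_s"], kw or "")

    try:
        if isinstance(config, (str, Path)):
            cfg, truth = load_config(config)
        else:
            cfg, truth = config
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        if scale != 1.0:
            cfg = StudyConfig(
                cohorts=[
                    (spec, max(4, int(n * scale))) for spec, n in cfg.cohorts
                ],
                seed=cfg.seed,
            )
        cfg_hash = _config_hash(cfg, truth)
        log("config", config_hash=cfg_hash, seed=cfg.seed,
            n_total=cfg.total_children)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("config", str(exc)) from exc

    try:
        study = simulate_study(cfg, truth)
        for ds in study:
            write_cohort_table(ds, outdir / f"data_{ds.spec.name}.tsv")
        log("simulate", cohorts={ds.spec.name: ds.n_children for ds in study})
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        std_study = [standardize_for_analysis(ds) for ds in study]
        log("standardize")
    except Exception as exc:
        raise PipelineError("standardize", str(exc)) from exc

    try:
        corr = pgs_correlation_table(std_study)
        _write_tsv(
            corr.average.round(4), outdir / "pgs_correlations.tsv",
            cfg_hash=cfg_hash, seed=cfg.seed, index=True,
        )
        log("correlations", mdd_neu=round(corr.entry("MDD", "NEU"), 4))
    except Exception as exc:
        raise PipelineError("correlations", str(exc)) from exc

    try:
        fit = fit_multivariate(std_study, opts)
        alpha = bonferroni_alpha(3, 7, 0.05)
        multi = wald_results(fit, alpha)
        _write_tsv(
            multi, outdir / "results_multivariate.tsv",
            cfg_hash=cfg_hash, seed=cfg.seed,
        )
        log("fit_multivariate", loglik=round(fit.loglik, 2),
            converged=fit.converged, n_iter=fit.n_iter,
            grad_norm=fit.grad_norm)
    except Exception as exc:
        raise PipelineError("fit_multivariate", str(exc)) from exc

    if univariate:
        try:
            unis = {}
            for pred in PGS_LABELS:
                unis[pred] = fit_univariate(std_study, pred, opts, alpha)
                log("fit_univariate", predictor=pred)
            for pred, tab in unis.items():
                _write_tsv(
                    tab, outdir / f"results_univariate_{pred}.tsv",
                    cfg_hash=cfg_hash, seed=cfg.seed,
                )
            comp = comparison_table(multi, unis)
            _write_tsv(
                comp, outdir / "comparison_univariate_multivariate.tsv",
                cfg_hash=cfg_hash, seed=cfg.seed,
            )
        except Exception as exc:
            raise PipelineError("fit_univariate", str(exc)) from exc

    log("done")
    log_fh.close()
    return outdir
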