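"""Parameter-recovery simulations at the published study scale.

The real cohort data cannot be redistributed, so the package's claim to
correctness rests on recovery studies: generate a four-cohort study whose
generating coefficients are the published multivariate estimates and whose
PGS correlations are the published cross-cohort averages, run the full
multi-group FIML analysis, and check that the estimates concentrate on the
generating values.  Nuisance dimensionality (number of PCs, chip/batch
factors) is reduced by default here: PCs and factors carry zero true effect,
so they only add flat likelihood directions, and two PCs per cohort are
enough to exercise the per-cohort covariate machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import standardize_for_analysis
from .fit import FitOptions, fit_multivariate, standard_errors, wald_results
from .report import CorrelationReport, pgs_correlation_table
from .synthetic import (
    GeneratorTruth,
    default_study_config,
    simulate_study,
)


def _derive_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 1009 + i) % (2**31 - 1))


def recovery_simulation(
    base_seed: int = 0,
    n_seeds: int = 5,
    *,
    scale: float = 1.0,
    n_pcs: int = 2,
    include_factors: bool = False,
    truth: GeneratorTruth | None = None,
    opts: FitOptions | None = None,
    compute_se: bool = True,
) -> pd.DataFrame:
    """Repeat the full simulate-standardize-fit cycle over several seeds.

    Returns a long table with one row per (seed, outcome, predictor) holding
    the shared coefficient estimate and (optionally) its observed-information
    SE.  Per-replicate seeds are derived deterministically from
    ``base_seed``.
    """
    truth = truth or GeneratorTruth()
    rows = []
    for i in range(n_seeds):
        seed = _derive_seed(base_seed, i)
        cfg = default_study_config(
            seed=seed, scale=scale, n_pcs=n_pcs,
            include_factors=include_factors,
        )
        study = simulate_study(cfg, truth)
        std = [standardize_for_analysis(ds) for ds in study]
        fit = fit_multivariate(std, opts)
        if compute_se:
            standard_errors(fit)
            tab = wald_results(fit)
        else:
            tab = pd.DataFrame(
                [
                    {
                        "outcome": out,
                        "predictor": pred,
                        "beta": fit.coefficient(out, pred),
                        "se": np.nan,
                    }
                    for (out, pred) in fit.space._shared_slots
                ]
            )
        tab = tab.assign(seed=seed, replicate=i,
                         converged=fit.converged)
        rows.append(tab[["replicate", "seed", "outcome", "predictor",
                         "beta", "se", "converged"]])
    return pd.concat(rows, ignore_index=True)


def summarize_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Mean estimate and Monte-Carlo SE of the mean per (outcome, predictor).

    The MC SE of the mean uses the average model-based SE divided by
    sqrt(n_seeds); with a handful of replicates this estimates the sampling
    variability of the mean far more stably than the across-seed spread.
    """
    g = results.groupby(["outcome", "predictor"], sort=False)
    out = g.agg(
        mean_beta=("beta", "mean"),
        sd_beta=("beta", "std"),
        mean_se=("se", "mean"),
        n_seeds=("beta", "size"),
    ).reset_index()
    out["mc_se"] = out["mean_se"] / np.sqrt(out["n_seeds"])
    return out


def correlation_recovery(
    seed: int = 0, *, scale: float = 1.0
) -> tuple[CorrelationReport, int]:
    """Simulate the default study and average the per-cohort PGS
    correlations; returns the report and the smallest cohort size (which
    sets the Monte-Carlo error of the averaged entries)."""
    cfg = default_study_config(seed=seed, scale=scale, n_pcs=0,
                               include_factors=False)
    study = simulate_study(cfg, GeneratorTruth())
    std = [standardize_for_analysis(ds) for ds in study]
    report = pgs_correlation_table(std)
    n_smallest = min(ds.n_children for ds in study)
    return report, n_smallest
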