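"""Maximum-likelihood fitting, inference, and fit indices.

``fit_multivariate`` maximizes the multi-group FIML likelihood with a
quasi-Newton optimizer (L-BFGS-B, analytic gradient) from a data-informed
start: per-outcome complete-case OLS for the coefficients, OLS residual
moments for ``Sigma_W``, and cross-twin residual products for ``Sigma_X``.
Standard errors come from the observed information matrix (finite
differences of the analytic gradient at the optimum); Wald z tests with a
Bonferroni-adjusted significance threshold give the published-style results
table.  ``fit_univariate`` refits the same model with the PGS block
restricted to a single score, which is what makes the univariate-versus-
multivariate attenuation comparison possible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .data_model import (
    CohortDataset,
    OUTCOME_COLUMNS,
    OUTCOME_LABELS,
    PGS_COLUMNS,
    PGS_LABELS,
)
from .likelihood import (
    LikelihoodError,
    ParameterSpace,
    StudyEvaluator,
    build_design,
    cov_to_chol,
    cov_to_sym,
)

logger = logging.getLogger(__name__)

_PGS_BY_LABEL = dict(zip(PGS_LABELS, PGS_COLUMNS))


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """A maximized multi-group FIML model.

    ``theta_hat`` is the flat MLE vector in the layout of ``space``;
    ``information`` (observed information, i.e. the negative Hessian of the
    log-likelihood at the optimum) is filled in lazily by
    :func:`standard_errors`.
    """

    space: ParameterSpace
    evaluator: StudyEvaluator
    theta_hat: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    n_iter: int
    message: str
    n_children: int
    n_families: int
    pattern_counts: list[dict[str, int]]
    information: np.ndarray | None = None
    se: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.space.n_params

    def structured(self) -> dict[str, float]:
        return self.space.unpack(self.theta_hat)

    def coefficient(self, outcome: str, predictor: str) -> float:
        """Shared (outcome, predictor) coefficient estimate."""
        return float(
            self.theta_hat[self.space.shared_slot(outcome, predictor)]
        )

    def to_dict(self) -> dict:
        d = {
            "names": self.space.names,
            "theta_hat": self.theta_hat.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "message": self.message,
            "n_children": self.n_children,
            "n_families": self.n_families,
        }
        if self.information is not None:
            d["information"] = self.information.tolist()
        return d


# ---------------------------------------------------------------------------
# initialization

def _ols_start(space: ParameterSpace, study: Sequence[CohortDataset]) -> np.ndarray:
    """Data-informed starting vector.

    Per cohort and outcome: complete-case OLS of the outcome on the cohort's
    design; shared slots average the per-cohort OLS estimates (weighted by
    the number of complete cases).  ``Sigma_W`` starts at the OLS residual
    covariance (log-Cholesky scale) and ``Sigma_X`` at the cross-twin
    residual product moment, shrunk toward zero for stability.
    """
    theta = np.zeros(space.n_params)
    contrib = np.zeros(space.n_params)
    for c, ds in enumerate(study):
        lay = space.cohorts[c]
        X = build_design(ds, lay.design_columns)
        ocols = [OUTCOME_COLUMNS[o] for o in lay.oidx]
        Y = ds.table[ocols].to_numpy(dtype=float)
        d = lay.d
        resid = np.full_like(Y, np.nan)
        for j in range(d):
            ok = ~np.isnan(Y[:, j])
            if ok.sum() <= X.shape[1]:
                continue
            b, *_ = np.linalg.lstsq(X[ok], Y[ok, j], rcond=None)
            idx = lay.coef_idx[:, j]
            w = float(ok.sum())
            theta[idx] += w * b
            contrib[idx] += w
            resid[ok, j] = Y[ok, j] - X[ok] @ b
        # residual covariance from pairwise-complete residuals
        sw = np.eye(d)
        for i in range(d):
            for j in range(i + 1):
                ok = ~np.isnan(resid[:, i]) & ~np.isnan(resid[:, j])
                if ok.sum() > 2:
                    sw[i, j] = sw[j, i] = float(
                        np.mean(resid[ok, i] * resid[ok, j])
                    )
        # ensure SPD before taking the log-Cholesky
        lo = np.linalg.eigvalsh(sw).min()
        if lo < 1e-6:
            sw += (1e-6 - lo) * np.eye(d)
        if space.diagonal_residual:
            theta[lay.sw_slice] = 0.5 * np.log(np.diag(sw))
            contrib[lay.sw_slice] = 1.0
        else:
            theta[lay.sw_slice] = cov_to_chol(sw)
            contrib[lay.sw_slice] = 1.0
        if lay.sx_slice is not None:
            sx = _cross_twin_moment(ds, resid, d)
            # keep the start strictly inside the PD region of the twin block
            theta[lay.sx_slice] = cov_to_sym(0.5 * sx)
            contrib[lay.sx_slice] = 1.0
    shared = contrib > 0
    theta[shared] /= np.where(shared, contrib, 1.0)[shared]
    return theta


def _cross_twin_moment(
    ds: CohortDataset, resid: np.ndarray, d: int
) -> np.ndarray:
    tab = ds.table
    order = np.lexsort(
        (tab["member_index"].to_numpy(), tab["family_id"].to_numpy())
    )
    fam = tab["family_id"].to_numpy()[order]
    boundary = np.flatnonzero(np.r_[True, fam[1:] != fam[:-1]])
    sizes = np.diff(np.r_[boundary, len(fam)])
    starts = boundary[sizes == 2]
    sx = np.zeros((d, d))
    if not len(starts):
        return sx
    r1 = resid[order[starts]]
    r2 = resid[order[starts + 1]]
    for i in range(d):
        for j in range(d):
            ok = ~np.isnan(r1[:, i]) & ~np.isnan(r2[:, j])
            if ok.sum() > 2:
                sx[i, j] = float(np.mean(r1[ok, i] * r2[ok, j]))
    return 0.5 * (sx + sx.T)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitOptions:
    """Optimizer settings: gradient tolerance on the flat scale, iteration
    budget, and whether to use the analytic gradient."""

    gtol: float = 1e-5
    maxiter: int = 2000
    analytic_gradient: bool = True


def fit_model(
    study: Sequence[CohortDataset],
    space: ParameterSpace,
    opts: FitOptions | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Maximize the FIML likelihood over an arbitrary parameter space."""
    opts = opts or FitOptions()
    ev = StudyEvaluator(space, study)
    if ev.n_families == 0:
        raise FitError("study contains no families")
    if theta0 is None:
        theta0 = _ols_start(space, study)

    # Sigma_X is parameterized without a PD constraint; a trial step that
    # leaves the PD region of the twin block is treated as +inf so the line
    # search backtracks into the feasible region.
    _BIG = 1e12

    if opts.analytic_gradient:
        def objective(t):
            try:
                ll, g = ev.loglik_grad(t)
            except (LikelihoodError, np.linalg.LinAlgError):
                return _BIG, np.zeros_like(t)
            return -ll, -g
        jac = True
    else:
        def objective(t):
            try:
                return -ev.loglik(t)
            except (LikelihoodError, np.linalg.LinAlgError):
                return _BIG
        jac = None

    res = optimize.minimize(
        objective,
        theta0,
        jac=jac,
        method="L-BFGS-B",
        options={
            "maxiter": opts.maxiter,
            "gtol": opts.gtol,
            "ftol": 1e-14,
            "maxcor": 25,
        },
    )
    ll, g = ev.loglik_grad(res.x)
    gnorm = float(np.max(np.abs(g)))
    converged = bool(res.success) or gnorm < 10 * opts.gtol
    if not converged:
        logger.warning(
            "optimizer did not converge (%s); grad max-norm %.3g",
            res.message, gnorm,
        )
    ll0 = ev.loglik(theta0)
    if ll < ll0 - 1e-6:
        raise FitError(
            f"optimum log-likelihood {ll:.6f} below start {ll0:.6f}"
        )
    return FitResult(
        space=space,
        evaluator=ev,
        theta_hat=res.x,
        loglik=float(ll),
        converged=converged,
        grad_norm=gnorm,
        n_iter=int(res.nit),
        message=str(res.message),
        n_children=sum(ds.n_children for ds in study),
        n_families=ev.n_families,
        pattern_counts=ev.pattern_counts(),
    )


def fit_multivariate(
    study: Sequence[CohortDataset],
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit the full multi-group model: all seven PGS jointly, coefficients
    shared across cohorts, per-cohort residual and cross-twin covariances."""
    space = ParameterSpace(study, predictors=PGS_LABELS)
    return fit_model(study, space, opts)


def fit_univariate(
    study: Sequence[CohortDataset],
    predictor: str,
    opts: FitOptions | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Refit with the PGS block restricted to one score (covariates kept).

    Returns the 3-row results table (one row per outcome) for the named
    predictor, mirroring how single-score association analyses are usually
    run.
    """
    if predictor not in PGS_LABELS:
        raise KeyError(
            f"unknown predictor {predictor!r}; expected one of {PGS_LABELS}"
        )
    space = ParameterSpace(study, predictors=(predictor,))
    fit = fit_model(study, space, opts)
    if alpha is None:
        alpha = bonferroni_alpha(3, 7, 0.05)
    table = wald_results(fit, alpha)
    return table[table["predictor"] == predictor].reset_index(drop=True)


# ---------------------------------------------------------------------------
# inference

def observed_information(
    fit: FitResult, step: float = 1e-5
) -> np.ndarray:
    """Observed information: central finite differences of the analytic
    gradient of the negative log-likelihood at the optimum, symmetrized."""
    ev = fit.evaluator
    theta = fit.theta_hat
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        # shrink the step when a perturbation crosses the PD boundary of
        # the twin-block covariance (possible when the MLE sits near it)
        for h in (step, step / 10, step / 100):
            h *= max(1.0, abs(theta[i]))
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            try:
                _, gp = ev.loglik_grad(tp)
                _, gm = ev.loglik_grad(tm)
            except (LikelihoodError, np.linalg.LinAlgError):
                continue
            H[i] = (gp - gm) / (2 * h)
            break
        else:
            raise FitError(
                f"cannot differentiate the gradient along "
                f"{fit.space.names[i]!r}: parameter at a covariance boundary"
            )
    return -0.5 * (H + H.T)


def standard_errors(fit: FitResult) -> np.ndarray:
    """SEs from the inverse observed information (cached on the fit)."""
    if fit.se is not None:
        return fit.se
    if fit.information is None:
        fit.information = observed_information(fit)
    info = fit.information
    eigval, eigvec = np.linalg.eigh(info)
    bad = eigval <= 1e-10 * max(1.0, float(eigval.max()))
    if bad.any():
        directions = []
        for k in np.flatnonzero(bad):
            top = np.argsort(-np.abs(eigvec[:, k]))[:3]
            directions.append(
                [fit.space.names[t] for t in top]
            )
        raise FitError(
            "observed information is singular along directions involving "
            f"{directions}"
        )
    cov = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    fit.se = np.sqrt(np.diag(cov))
    return fit.se


def bonferroni_alpha(
    n_outcomes: int, n_predictors: int, fw_alpha: float = 0.05
) -> float:
    """Family-wise alpha divided by the number of (outcome, predictor) tests."""
    if n_outcomes <= 0 or n_predictors <= 0:
        raise ValueError("counts must be positive")
    if not (0.0 < fw_alpha < 1.0):
        raise ValueError("fw_alpha must be in (0, 1)")
    return fw_alpha / (n_outcomes * n_predictors)


def wald_results(
    fit: FitResult, alpha: float | None = None
) -> pd.DataFrame:
    """Published-style results table for the shared coefficients.

    One row per (outcome, predictor) with the standardized beta, its SE,
    Wald z, two-sided normal p, the symmetric 95% CI (beta +/- 1.96 SE) and
    the Bonferroni significance flag.
    """
    if alpha is None:
        alpha = bonferroni_alpha(3, 7, 0.05)
    se = standard_errors(fit)
    rows = []
    predictors = list(fit.space.predictors) + ["sex", "age"]
    for pred in predictors:
        for out in OUTCOME_LABELS:
            try:
                slot = fit.space.shared_slot(out, pred)
            except KeyError:
                continue
            beta = float(fit.theta_hat[slot])
            s = float(se[slot])
            if s == 0.0:
                raise FitError(
                    f"zero SE for ({out}, {pred}): z undefined"
                )
            z = beta / s
            p = 2.0 * float(norm.sf(abs(z)))
            rows.append(
                {
                    "outcome": out,
                    "predictor": pred,
                    "beta": beta,
                    "se": s,
                    "z": z,
                    "p": p,
                    "ci_low": beta - 1.96 * s,
                    "ci_high": beta + 1.96 * s,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fit indices

@dataclass
class FitIndices:
    """Chi-square-based structural fit indices.

    The comparison ("saturated") model releases every cross-cohort equality
    constraint; the baseline model drops the PGS block, forces a diagonal
    residual covariance and no cross-twin covariance.  CFI can legitimately
    fall below zero when the baseline fits better per degree of freedom.
    """

    chi2: float
    df: int
    rmsea: float
    cfi: float
    tli: float
    chi2_baseline: float
    df_baseline: int
    loglik_fitted: float
    loglik_saturated: float
    loglik_baseline: float
    n_total: int


def compute_fit_indices(
    ll_fit: float,
    n_fit: int,
    ll_sat: float,
    n_sat: int,
    ll_base: float,
    n_base: int,
    n_total: int,
) -> FitIndices:
    """Index arithmetic from log-likelihoods and parameter counts."""
    chi2 = 2.0 * (ll_sat - ll_fit)
    df = n_sat - n_fit
    if df <= 0:
        raise ValueError("df of the fitted model must be positive")
    chi2_b = 2.0 * (ll_sat - ll_base)
    df_b = n_sat - n_base
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_total)))
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    ratio_b = chi2_b / df_b if df_b > 0 else np.nan
    ratio_f = chi2 / df
    tli = (
        (ratio_b - ratio_f) / (ratio_b - 1.0)
        if df_b > 0 and ratio_b != 1.0
        else np.nan
    )
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        rmsea=rmsea,
        cfi=float(cfi),
        tli=float(tli),
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_b),
        loglik_fitted=float(ll_fit),
        loglik_saturated=float(ll_sat),
        loglik_baseline=float(ll_base),
        n_total=n_total,
    )


def fit_indices(
    fit: FitResult,
    study: Sequence[CohortDataset],
    opts: FitOptions | None = None,
) -> FitIndices:
    """RMSEA / CFI / TLI for a fitted multi-group model.

    Fits the constraint-free comparison model (per-cohort coefficients and
    covariances) and the covariates-only baseline (no PGS, diagonal
    ``Sigma_W``, no cross-twin covariance), then applies the standard index
    formulas.
    """
    sat_space = ParameterSpace(
        study, predictors=fit.space.predictors, share_coefficients=False
    )
    sat = fit_model(study, sat_space, opts)
    base_space = ParameterSpace(
        study, predictors=(), diagonal_residual=True, cross_twin=False
    )
    base = fit_model(study, base_space, opts)
    return compute_fit_indices(
        fit.loglik,
        fit.n_params,
        sat.loglik,
        sat.n_params,
        base.loglik,
        base.n_params,
        fit.n_children,
    )
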