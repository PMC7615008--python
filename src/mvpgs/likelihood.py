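"""Multi-group FIML likelihood for twin-clustered multivariate regression.

The model: within each cohort, a child's vector of (up to three) standardized
outcomes is multivariate normal with mean ``X beta`` — PGS, sex and age
coefficients constrained equal across cohorts, intercepts / PC / chip / batch
coefficients free per cohort — and residual covariance ``Sigma_W`` estimated
per cohort.  In twin cohorts the two children of a family are modelled
jointly with the stacked covariance::

    [[Sigma_W, Sigma_X],
     [Sigma_X, Sigma_W]]

where the symmetric ``Sigma_X`` holds cross-twin (same-trait and cross-trait)
residual covariances.  Missing outcome cells are handled by full-information
maximum likelihood: each family contributes the density of its *observed*
sub-vector, i.e. missing entries are marginalized out, never imputed.

``fiml_loglik`` groups families by missingness pattern so each pattern is one
vectorized multivariate-normal evaluation; ``loglik_naive`` is the
unvectorized per-family reference implementation used as a correctness
oracle.  The analytic gradient propagates through the log-Cholesky
parameterization of ``Sigma_W`` (which keeps it positive definite for any
real parameter values) and the symmetric parameterization of ``Sigma_X``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import multivariate_normal

from .data_model import (
    CohortDataset,
    CohortSpec,
    OUTCOME_COLUMNS,
    OUTCOME_LABELS,
    PGS_COLUMNS,
    PGS_LABELS,
)

_LOG2PI = math.log(2.0 * math.pi)

_PGS_BY_LABEL = dict(zip(PGS_LABELS, PGS_COLUMNS))


class ParameterSpaceError(ValueError):
    pass


class LikelihoodError(FloatingPointError):
    """Non-finite or numerically degenerate likelihood evaluation."""


# ---------------------------------------------------------------------------
# covariance parameterizations

def _tri_len(d: int) -> int:
    return d * (d + 1) // 2


def _tri_indices(d: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(d)


def chol_to_cov(v: np.ndarray, d: int) -> np.ndarray:
    """Log-Cholesky vector (lower triangle row-major, log diagonal) -> SPD."""
    L = np.zeros((d, d))
    r, c = _tri_indices(d)
    L[r, c] = v
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    return L @ L.T


def cov_to_chol(S: np.ndarray) -> np.ndarray:
    """Inverse of :func:`chol_to_cov` for an SPD matrix."""
    L = np.linalg.cholesky(S)
    L = L.copy()
    L[np.diag_indices(len(S))] = np.log(np.diag(L))
    r, c = _tri_indices(len(S))
    return L[r, c]


def _chol_grad(v: np.ndarray, W: np.ndarray, d: int) -> np.ndarray:
    """Chain an unstructured d(ll)/dSigma through the log-Cholesky map."""
    L = np.zeros((d, d))
    r, c = _tri_indices(d)
    L[r, c] = v
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    dL = (W + W.T) @ L
    dL[np.diag_indices(d)] *= np.diag(L)  # chain through exp
    return dL[r, c]


def sym_to_cov(v: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangle vector -> symmetric matrix (no PD constraint)."""
    S = np.zeros((d, d))
    r, c = _tri_indices(d)
    S[r, c] = v
    S[c, r] = v
    return S


def cov_to_sym(S: np.ndarray) -> np.ndarray:
    r, c = _tri_indices(len(S))
    return S[r, c]


def _sym_grad(G: np.ndarray, d: int) -> np.ndarray:
    """Unstructured gradient -> gradient w.r.t. the lower-triangle params."""
    M = G + G.T
    M[np.diag_indices(d)] = np.diag(G)
    r, c = _tri_indices(d)
    return M[r, c]


# ---------------------------------------------------------------------------
# parameter space

@dataclass
class CohortLayout:
    """Flat-vector bookkeeping for one cohort's slice of the model."""

    spec: CohortSpec
    oidx: np.ndarray              # indices into OUTCOME_LABELS present here
    design_columns: list[str]     # design-matrix columns, fixed order
    coef_idx: np.ndarray          # (p, d) int indices into the flat vector
    sw_slice: slice               # Sigma_W parameters (log-Cholesky or log-SD)
    sx_slice: slice | None        # Sigma_X parameters (twin cohorts)
    diagonal_residual: bool

    @property
    def d(self) -> int:
        return len(self.oidx)


class ParameterSpace:
    """Bijection between the flat parameter vector and structured parameters.

    The flat layout is: shared coefficient block first (one slot per
    (outcome, predictor/sex/age) pair, if coefficients are shared), then per
    cohort the free coefficients, the ``Sigma_W`` log-Cholesky block and —
    for twin cohorts — the ``Sigma_X`` symmetric block.  A shared parameter
    occupies exactly one flat slot referenced from every cohort's coefficient
    index map.
    """

    def __init__(
        self,
        study: Sequence[CohortDataset],
        predictors: Sequence[str] = PGS_LABELS,
        *,
        share_coefficients: bool = True,
        diagonal_residual: bool = False,
        cross_twin: bool = True,
    ):
        unknown = set(predictors) - set(PGS_LABELS)
        if unknown:
            raise ParameterSpaceError(f"unknown predictors {sorted(unknown)}")
        self.predictors = tuple(predictors)
        self.share_coefficients = share_coefficients
        self.diagonal_residual = diagonal_residual
        self.cross_twin = cross_twin
        self.names: list[str] = []
        self.cohorts: list[CohortLayout] = []
        self._shared_slots: dict[tuple[str, str], int] = {}

        for ds in study:
            self.cohorts.append(self._layout_cohort(ds))
        self.n_params = len(self.names)

    # -- construction helpers ------------------------------------------------

    def _layout_cohort(self, ds: CohortDataset) -> CohortLayout:
        spec = ds.spec
        oidx = np.array(
            [OUTCOME_LABELS.index(lab) for lab in spec.outcomes_present]
        )
        d = len(oidx)
        cols = design_columns(ds, self.predictors)
        p = len(cols)
        coef_idx = np.empty((p, d), dtype=int)
        for i, col in enumerate(cols):
            lab = _coef_label(col)
            shared = self.share_coefficients and (
                col in [_PGS_BY_LABEL[q] for q in self.predictors]
                or col in ("sex", "age")
            )
            for j, o in enumerate(oidx):
                out = OUTCOME_LABELS[o]
                if shared:
                    # shared slots are created lazily, by the first cohort
                    # that observes the (outcome, predictor) pair, so no
                    # slot exists without data behind it
                    if (out, lab) not in self._shared_slots:
                        self._shared_slots[(out, lab)] = len(self.names)
                        self.names.append(f"beta[{out},{lab}]")
                    coef_idx[i, j] = self._shared_slots[(out, lab)]
                else:
                    coef_idx[i, j] = len(self.names)
                    self.names.append(f"{spec.name}:beta[{out},{lab}]")
        n_sw = d if self.diagonal_residual else _tri_len(d)
        sw = slice(len(self.names), len(self.names) + n_sw)
        self.names += [f"{spec.name}:sigma_w[{k}]" for k in range(n_sw)]
        sx = None
        if spec.is_twin_cohort and self.cross_twin:
            sx = slice(len(self.names), len(self.names) + _tri_len(d))
            self.names += [
                f"{spec.name}:sigma_x[{k}]" for k in range(_tri_len(d))
            ]
        return CohortLayout(
            spec=spec,
            oidx=oidx,
            design_columns=cols,
            coef_idx=coef_idx,
            sw_slice=sw,
            sx_slice=sx,
            diagonal_residual=self.diagonal_residual,
        )

    # -- structured accessors ------------------------------------------------

    def shared_slot(self, outcome: str, predictor: str) -> int:
        """Flat index of a shared (outcome, predictor) coefficient."""
        return self._shared_slots[(outcome, predictor)]

    def coef(self, theta: np.ndarray, c: int) -> np.ndarray:
        """(p, d) coefficient matrix of cohort ``c`` (a view through indices)."""
        return np.asarray(theta)[self.cohorts[c].coef_idx]

    def sigma_w(self, theta: np.ndarray, c: int) -> np.ndarray:
        lay = self.cohorts[c]
        v = np.asarray(theta)[lay.sw_slice]
        if lay.diagonal_residual:
            return np.diag(np.exp(2.0 * v))
        return chol_to_cov(v, lay.d)

    def sigma_x(self, theta: np.ndarray, c: int) -> np.ndarray:
        lay = self.cohorts[c]
        if lay.sx_slice is None:
            return np.zeros((lay.d, lay.d))
        return sym_to_cov(np.asarray(theta)[lay.sx_slice], lay.d)

    def pair_cov(self, theta: np.ndarray, c: int) -> np.ndarray:
        """2d x 2d joint residual covariance of a twin pair in cohort c."""
        sw = self.sigma_w(theta, c)
        sx = self.sigma_x(theta, c)
        return np.block([[sw, sx], [sx, sw]])

    # -- pack / unpack -------------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        """Flat vector -> ``{slot name: value}`` (exact, bijective)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ParameterSpaceError(
                f"expected flat vector of length {self.n_params}, "
                f"got shape {theta.shape}"
            )
        return dict(zip(self.names, theta))

    def pack(self, structured: dict[str, float]) -> np.ndarray:
        """``{slot name: value}`` -> flat vector (inverse of :meth:`unpack`)."""
        if set(structured) != set(self.names):
            extra = set(structured) - set(self.names)
            missing = set(self.names) - set(structured)
            raise ParameterSpaceError(
                f"slot mismatch: extra={sorted(extra)[:3]}, "
                f"missing={sorted(missing)[:3]}"
            )
        return np.array([structured[n] for n in self.names])


def _coef_label(col: str) -> str:
    """Design-column name -> predictor label used in slot names."""
    inv = {v: k for k, v in _PGS_BY_LABEL.items()}
    return inv.get(col, col)


def design_columns(
    ds: CohortDataset, predictors: Sequence[str]
) -> list[str]:
    """Ordered design columns for one cohort.

    Intercept, then the selected PGS, sex, age (where available), PCs and
    drop-first dummies for each factor covariate.  Columns that are constant
    in the data (other than the intercept) carry no information and are
    dropped.
    """
    spec = ds.spec
    cols = ["intercept"]
    cols += [_PGS_BY_LABEL[p] for p in predictors]
    cols += ["sex"]
    if spec.has_age_covariate:
        cols.append("age")
    cols += list(spec.pc_columns)
    for fac in spec.factor_covariates:
        levels = sorted(ds.table[fac].dropna().unique().tolist())
        cols += [f"{fac}={lev}" for lev in levels[1:]]
    # drop constant columns (absent factor levels, degenerate covariates)
    out = []
    for col in cols:
        if col == "intercept":
            out.append(col)
            continue
        x = _design_column_values(ds, col)
        if np.nanstd(x) > 0:
            out.append(col)
    return out


def _design_column_values(ds: CohortDataset, col: str) -> np.ndarray:
    if col == "intercept":
        return np.ones(ds.n_children)
    if "=" in col:
        fac, lev = col.split("=", 1)
        return (ds.table[fac].astype(str) == lev).to_numpy(dtype=float)
    return ds.table[col].to_numpy(dtype=float)


def build_design(ds: CohortDataset, columns: Sequence[str]) -> np.ndarray:
    """(n, p) design matrix with the given columns."""
    return np.column_stack(
        [_design_column_values(ds, c) for c in columns]
    )


# ---------------------------------------------------------------------------
# family designs (naive path) and prepared study (vectorized path)

@dataclass
class FamilyDesign:
    """One family's contribution to the likelihood.

    ``X`` has one row per member (1 or 2 rows); ``y`` is the (size, d) outcome
    slice on the cohort's measured outcomes with NaN for missing cells;
    ``observed`` indexes the observed entries of the stacked
    (size*d,) outcome vector.
    """

    cohort_index: int
    family_id: str
    X: np.ndarray
    y: np.ndarray
    observed: np.ndarray

    @property
    def size(self) -> int:
        return self.X.shape[0]


def iter_family_designs(
    space: ParameterSpace, study: Sequence[CohortDataset]
) -> Iterator[FamilyDesign]:
    for c, ds in enumerate(study):
        lay = space.cohorts[c]
        X = build_design(ds, lay.design_columns)
        ocols = [OUTCOME_COLUMNS[o] for o in lay.oidx]
        Y = ds.table[ocols].to_numpy(dtype=float)
        tab = ds.table
        order = np.lexsort(
            (tab["member_index"].to_numpy(), tab["family_id"].to_numpy())
        )
        fam = tab["family_id"].to_numpy()[order]
        start = 0
        while start < len(order):
            end = start + 1
            while end < len(order) and fam[end] == fam[start]:
                end += 1
            rows = order[start:end]
            yv = Y[rows]
            obs = np.flatnonzero(~np.isnan(yv.reshape(-1)))
            yield FamilyDesign(
                cohort_index=c,
                family_id=str(fam[start]),
                X=X[rows],
                y=yv,
                observed=obs,
            )
            start = end


def family_mean_cov(
    space: ParameterSpace,
    theta: np.ndarray,
    fd: FamilyDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Full (pre-marginalization) mean vector and covariance of a family.

    A singleton yields a d-vector and ``Sigma_W``; a twin pair yields the
    stacked 2d-vector and ``[[Sigma_W, Sigma_X], [Sigma_X, Sigma_W]]``.
    """
    C = space.coef(theta, fd.cohort_index)
    mean = (fd.X @ C).reshape(-1)
    if fd.size == 1:
        cov = space.sigma_w(theta, fd.cohort_index)
    else:
        cov = space.pair_cov(theta, fd.cohort_index)
    return mean, cov


def loglik_naive(
    theta: np.ndarray,
    study: Sequence[CohortDataset],
    space: ParameterSpace,
) -> float:
    """Reference FIML log-likelihood: per-family marginalized MVN densities.

    Deliberately unvectorized and routed through ``scipy.stats`` so it is an
    independent check on :func:`fiml_loglik`.
    """
    total = 0.0
    for fd in iter_family_designs(space, study):
        if fd.observed.size == 0:
            continue
        mean, cov = family_mean_cov(space, theta, fd)
        obs = fd.observed
        y = fd.y.reshape(-1)[obs]
        total += multivariate_normal.logpdf(
            y, mean=mean[obs], cov=cov[np.ix_(obs, obs)]
        )
    return float(total)


@dataclass
class _PatternGroup:
    observed: np.ndarray      # observed entry indices within the stacked vec
    rows: np.ndarray          # (m,) member rows for singles, (m, 2) for pairs
    y: np.ndarray             # (m, k) observed outcome values


@dataclass
class _CohortEval:
    X: np.ndarray
    singles: list[_PatternGroup]
    pairs: list[_PatternGroup]
    n_families: int
    n_contributing: int


class StudyEvaluator:
    """Pattern-grouped FIML evaluator for a fixed study and parameter space.

    Groups families by (family size, missingness pattern) once; every
    log-likelihood / gradient call is then a handful of vectorized
    multivariate-normal evaluations per cohort.  Contractually equivalent to
    :func:`loglik_naive`.
    """

    def __init__(
        self, space: ParameterSpace, study: Sequence[CohortDataset]
    ):
        self.space = space
        self.study = list(study)
        self._cohorts: list[_CohortEval] = []
        for c, ds in enumerate(self.study):
            self._cohorts.append(self._prepare(c, ds))
        self.n_families = sum(ce.n_families for ce in self._cohorts)

    def _prepare(self, c: int, ds: CohortDataset) -> _CohortEval:
        lay = self.space.cohorts[c]
        X = build_design(ds, lay.design_columns)
        ocols = [OUTCOME_COLUMNS[o] for o in lay.oidx]
        Y = ds.table[ocols].to_numpy(dtype=float)
        tab = ds.table
        order = np.lexsort(
            (tab["member_index"].to_numpy(), tab["family_id"].to_numpy())
        )
        fam = tab["family_id"].to_numpy()[order]
        # family boundaries
        boundary = np.flatnonzero(
            np.r_[True, fam[1:] != fam[:-1]]
        )
        sizes = np.diff(np.r_[boundary, len(fam)])
        if (sizes > 2).any():
            raise ValueError("families with more than two members")
        single_rows = order[boundary[sizes == 1]]
        pair_starts = boundary[sizes == 2]
        pair_rows = np.column_stack(
            [order[pair_starts], order[pair_starts + 1]]
        ) if len(pair_starts) else np.empty((0, 2), dtype=int)

        singles = self._group(Y[single_rows], single_rows[:, None])
        if len(pair_rows):
            ypairs = np.hstack([Y[pair_rows[:, 0]], Y[pair_rows[:, 1]]])
            pairs = self._group(ypairs, pair_rows)
        else:
            pairs = []
        n_contrib = sum(len(g.rows) for g in singles + pairs)
        return _CohortEval(
            X=X,
            singles=singles,
            pairs=pairs,
            n_families=len(single_rows) + len(pair_rows),
            n_contributing=n_contrib,
        )

    @staticmethod
    def _group(
        yfull: np.ndarray, rows: np.ndarray
    ) -> list[_PatternGroup]:
        if not len(yfull):
            return []
        obs_mask = ~np.isnan(yfull)
        # encode each row's pattern as an integer key
        key = obs_mask @ (1 << np.arange(obs_mask.shape[1]))
        groups = []
        for k in np.unique(key):
            sel = key == k
            obs = np.flatnonzero(obs_mask[np.argmax(sel)])
            if obs.size == 0:
                continue  # fully missing families contribute exactly 0
            groups.append(
                _PatternGroup(
                    observed=obs,
                    rows=rows[sel],
                    y=yfull[np.ix_(sel, obs)],
                )
            )
        return groups

    def pattern_counts(self) -> list[dict[str, int]]:
        """Per cohort: number of families per missingness pattern."""
        out = []
        for ce in self._cohorts:
            d = {}
            for g in ce.singles:
                d[f"single:{tuple(g.observed)}"] = len(g.rows)
            for g in ce.pairs:
                d[f"pair:{tuple(g.observed)}"] = len(g.rows)
            out.append(d)
        return out

    # -- evaluation ----------------------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        return self._eval(np.asarray(theta, dtype=float), want_grad=False)[0]

    def loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        return self._eval(np.asarray(theta, dtype=float), want_grad=True)

    def _eval(
        self, theta: np.ndarray, want_grad: bool
    ) -> tuple[float, np.ndarray]:
        space = self.space
        total = 0.0
        grad = np.zeros(space.n_params) if want_grad else None
        for c, ce in enumerate(self._cohorts):
            lay = space.cohorts[c]
            d = lay.d
            C = theta[lay.coef_idx]
            M = ce.X @ C
            ocols = [OUTCOME_COLUMNS[o] for o in lay.oidx]
            sw = space.sigma_w(theta, c)
            if not np.all(np.isfinite(sw)):
                raise LikelihoodError(
                    "non-finite Sigma_W (covariance parameters out of range)"
                )
            has_pairs = bool(ce.pairs)
            omega = space.pair_cov(theta, c) if has_pairs else None

            gmean = np.zeros_like(M) if want_grad else None
            W3 = np.zeros((d, d)) if want_grad else None
            W6 = np.zeros((2 * d, 2 * d)) if want_grad else None

            for g in ce.singles:
                total += self._group_eval(
                    g, M[g.rows[:, 0]], sw, W3, gmean, g.rows[:, 0], d,
                    want_grad,
                )
            for g in ce.pairs:
                mu = np.hstack([M[g.rows[:, 0]], M[g.rows[:, 1]]])
                total += self._group_eval(
                    g, mu, omega, W6, gmean, g.rows, d, want_grad,
                )

            if want_grad:
                np.add.at(grad, lay.coef_idx, ce.X.T @ gmean)
                Wsw = W3.copy()
                if has_pairs:
                    Wsw += W6[:d, :d] + W6[d:, d:]
                    if lay.sx_slice is not None:
                        Gx = W6[:d, d:] + W6[d:, :d].T
                        grad[lay.sx_slice] += _sym_grad(Gx, d)
                v = theta[lay.sw_slice]
                if lay.diagonal_residual:
                    grad[lay.sw_slice] += (
                        np.diag(Wsw) * 2.0 * np.exp(2.0 * v)
                    )
                else:
                    grad[lay.sw_slice] += _chol_grad(v, Wsw, d)
        if not np.isfinite(total):
            self._raise_nonfinite(theta)
        return total, grad

    def _group_eval(
        self,
        g: _PatternGroup,
        mu_full: np.ndarray,
        cov_full: np.ndarray,
        Wacc: np.ndarray | None,
        gmean: np.ndarray | None,
        rows,
        d: int,
        want_grad: bool,
    ) -> float:
        obs = g.observed
        k = obs.size
        m = len(g.y)
        S = cov_full[np.ix_(obs, obs)]
        if np.linalg.cond(S) > 1e12:
            raise LikelihoodError(
                "residual covariance sub-block is numerically singular "
                f"(condition number > 1e12) for pattern {tuple(obs)}"
            )
        try:
            cho = cho_factor(S, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise LikelihoodError(str(exc)) from exc
        R = g.y - mu_full[:, obs]
        A = cho_solve(cho, R.T)  # (k, m) = S^{-1} R'
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        quad = float(np.sum(R.T * A))
        ll = -0.5 * (m * (k * _LOG2PI + logdet) + quad)
        if want_grad:
            # d ll / d mu_i = S^{-1} r_i; scatter into member means
            if rows.ndim == 1:  # singles: obs indexes the d outcomes
                np.add.at(gmean, (rows[:, None], obs[None, :]), A.T)
            else:  # pairs: split stacked 2d indices into the two members
                first = obs < d
                if first.any():
                    np.add.at(
                        gmean,
                        (rows[:, 0][:, None], obs[first][None, :]),
                        A.T[:, first],
                    )
                if (~first).any():
                    np.add.at(
                        gmean,
                        (rows[:, 1][:, None], (obs[~first] - d)[None, :]),
                        A.T[:, ~first],
                    )
            # d ll / d S (unstructured): 0.5 (S^-1 R'R S^-1 - m S^-1)
            Sinv = cho_solve(cho, np.eye(k))
            W = 0.5 * (A @ A.T - m * Sinv)
            Wacc[np.ix_(obs, obs)] += W
        return ll

    def _raise_nonfinite(self, theta: np.ndarray) -> None:
        for fd in iter_family_designs(self.space, self.study):
            if fd.observed.size == 0:
                continue
            mean, cov = family_mean_cov(self.space, theta, fd)
            obs = fd.observed
            y = fd.y.reshape(-1)[obs]
            try:
                val = multivariate_normal.logpdf(
                    y, mean=mean[obs], cov=cov[np.ix_(obs, obs)],
                    allow_singular=True,
                )
            except Exception:
                val = np.nan
            if not np.isfinite(val):
                raise LikelihoodError(
                    f"non-finite log-likelihood at family {fd.family_id}"
                )
        raise LikelihoodError("non-finite log-likelihood")


def fiml_loglik(
    theta: np.ndarray,
    study: Sequence[CohortDataset],
    space: ParameterSpace | None = None,
) -> float:
    """Multi-group FIML log-likelihood (pattern-grouped, vectorized).

    Convenience wrapper constructing a :class:`StudyEvaluator`; repeated
    evaluations should build the evaluator once.
    """
    if space is None:
        space = ParameterSpace(study)
    return StudyEvaluator(space, study).loglik(theta)
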