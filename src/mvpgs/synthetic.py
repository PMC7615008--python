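"""Synthetic multi-cohort study generator.

Emulates the four-cohort layout of the published study — one birth cohort of
singletons (ALSPAC-shaped) and three twin cohorts (CATSS-, NTR-, TEDS-shaped),
with the CATSS-shaped cohort lacking a social-problems measure and the age
covariate — so the full multi-group FIML analysis can be exercised without
any real cohort data.  Children's polygenic scores are drawn from a
multivariate normal with a configurable correlation matrix (default: the
published cross-cohort average PGS correlations); outcomes follow the linear
model

    y = B @ pgs + b_sex * sex + b_age * age_z + b_pcs @ pcs + e

with family residuals drawn jointly from the 6x6 twin block covariance
``[[Sigma_W, Sigma_X], [Sigma_X, Sigma_W]]`` for pairs and from ``Sigma_W``
for singletons.  Structural missingness (outcomes a cohort never measured)
and random MCAR masking are both applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    CohortDataset,
    CohortSpec,
    OUTCOME_COLUMNS,
    OUTCOME_LABELS,
    PGS_COLUMNS,
    PGS_LABELS,
)

# ---------------------------------------------------------------------------
# Published-study default values (cross-cohort average PGS correlations and
# multivariate standardized coefficients) used as generator truth.

#: Default 7x7 PGS correlation matrix, order MDD, BIP, SWB, NEU, INS, EA, BMI.
DEFAULT_R_PGS = np.array(
    [
        [1.000, 0.184, -0.215, 0.306, 0.191, -0.125, 0.050],
        [0.184, 1.000, -0.030, 0.068, 0.014, 0.068, -0.009],
        [-0.215, -0.030, 1.000, -0.305, -0.118, 0.047, 0.011],
        [0.306, 0.068, -0.305, 1.000, 0.244, -0.152, -0.082],
        [0.191, 0.014, -0.118, 0.244, 1.000, -0.152, 0.040],
        [-0.125, 0.068, 0.047, -0.152, -0.152, 1.000, -0.201],
        [0.050, -0.009, 0.011, -0.082, 0.040, -0.201, 1.000],
    ]
)

#: Default 3x7 standardized coefficient matrix, rows ADHD, INT, SOC; columns
#: MDD, BIP, SWB, NEU, INS, EA, BMI.
DEFAULT_B = np.array(
    [
        [0.035, -0.002, 0.004, 0.004, 0.008, -0.087, 0.024],
        [0.027, -0.004, -0.002, 0.041, -0.004, -0.025, 0.011],
        [0.034, 0.009, -0.006, 0.029, 0.002, -0.015, 0.057],
    ]
)

DEFAULT_B_SEX = np.array([0.210, -0.081, 0.074])
DEFAULT_B_AGE = np.array([-0.010, 0.005, -0.003])

#: Age range in years; ages are drawn uniformly over this interval and twins
#: share the family draw.
AGE_RANGE = (8.5, 10.5)
_AGE_MEAN = (AGE_RANGE[0] + AGE_RANGE[1]) / 2.0
_AGE_SD = (AGE_RANGE[1] - AGE_RANGE[0]) / np.sqrt(12.0)


def _default_sigma_w() -> np.ndarray:
    # unit residual variances, modest 0.3 intercorrelation among the three
    # childhood traits; magnitudes are a convention, not an estimated value
    s = np.full((3, 3), 0.3)
    np.fill_diagonal(s, 1.0)
    return s


@dataclass
class GeneratorTruth:
    """True generating parameters for the synthetic study.

    Attributes
    ----------
    B
        3x7 standardized coefficients (outcomes x PGS).
    b_sex, b_age
        Shared covariate effects per outcome; sex is coded 0 female / 1 male
        and the age effect applies to population-standardized age.
    b_pcs
        3 x 10 PC effects, zero by default (PCs act as pure nuisance
        covariates).
    R_pgs
        7x7 PGS correlation matrix (symmetric, unit diagonal, SPD).
    Sigma_W
        3x3 within-person residual covariance (SPD).
    Sigma_X
        3x3 cross-twin residual covariance (symmetric); the stacked twin
        block [[Sigma_W, Sigma_X], [Sigma_X, Sigma_W]] must be PD.
    miss_rate
        MCAR per-cell missingness probability for measured outcomes.
    twin_pgs_corr
        Within-pair correlation of each PGS.  0 draws twins' scores
        independently (the default; residual clustering alone carries the
        family structure), 0.5 mimics dizygotic relatedness.
    """

    B: np.ndarray = field(default_factory=lambda: DEFAULT_B.copy())
    b_sex: np.ndarray = field(default_factory=lambda: DEFAULT_B_SEX.copy())
    b_age: np.ndarray = field(default_factory=lambda: DEFAULT_B_AGE.copy())
    b_pcs: np.ndarray = field(default_factory=lambda: np.zeros((3, 10)))
    R_pgs: np.ndarray = field(default_factory=lambda: DEFAULT_R_PGS.copy())
    Sigma_W: np.ndarray = field(default_factory=_default_sigma_w)
    Sigma_X: np.ndarray = field(
        default_factory=lambda: 0.3 * _default_sigma_w()
    )
    miss_rate: float = 0.10
    twin_pgs_corr: float = 0.0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.b_sex = np.asarray(self.b_sex, dtype=float)
        self.b_age = np.asarray(self.b_age, dtype=float)
        self.b_pcs = np.asarray(self.b_pcs, dtype=float)
        self.R_pgs = np.asarray(self.R_pgs, dtype=float)
        self.Sigma_W = np.asarray(self.Sigma_W, dtype=float)
        self.Sigma_X = np.asarray(self.Sigma_X, dtype=float)

    def validate(self) -> None:
        if self.B.shape != (3, 7):
            raise ValueError("B must be 3x7")
        _check_correlation(self.R_pgs, "R_pgs")
        if not np.allclose(self.Sigma_W, self.Sigma_W.T):
            raise ValueError("Sigma_W must be symmetric")
        if np.linalg.eigvalsh(self.Sigma_W).min() <= 0:
            raise ValueError("Sigma_W must be positive definite")
        if not np.allclose(self.Sigma_X, self.Sigma_X.T):
            raise ValueError("Sigma_X must be symmetric")
        if np.linalg.eigvalsh(self.twin_block()).min() <= 0:
            raise ValueError(
                "twin block [[Sigma_W, Sigma_X], [Sigma_X, Sigma_W]] must be "
                "positive definite"
            )
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must be in [0, 1)")
        if not (-1.0 < self.twin_pgs_corr < 1.0):
            raise ValueError("twin_pgs_corr must be in (-1, 1)")

    def twin_block(self) -> np.ndarray:
        """6x6 joint residual covariance of a twin pair."""
        return np.block(
            [[self.Sigma_W, self.Sigma_X], [self.Sigma_X, self.Sigma_W]]
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorTruth":
        return cls(**d)


def _check_correlation(R: np.ndarray, name: str) -> None:
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError(f"{name} must have unit diagonal")
    lo = float(np.linalg.eigvalsh(R).min())
    if lo <= 0:
        raise np.linalg.LinAlgError(
            f"{name} is not positive definite (smallest eigenvalue {lo:.3g})"
        )


# ---------------------------------------------------------------------------
# Study configuration

def default_cohort_specs(
    *, n_pcs: int = 10, include_factors: bool = True
) -> dict[str, CohortSpec]:
    """Cohort layouts mirroring the published four-cohort design.

    ``n_pcs`` and ``include_factors`` scale the nuisance-covariate load; the
    defaults reproduce the published covariate sets.
    """
    chip = ("chip",) if include_factors else ()
    chip_batch = ("chip", "batch") if include_factors else ()
    return {
        "ALSPAC": CohortSpec(
            name="ALSPAC",
            outcomes_present=("ADHD", "INT", "SOC"),
            has_age_covariate=True,
            n_pcs=n_pcs,
            is_twin_cohort=False,
        ),
        "CATSS": CohortSpec(
            name="CATSS",
            outcomes_present=("ADHD", "INT"),
            has_age_covariate=False,
            n_pcs=n_pcs,
            is_twin_cohort=True,
        ),
        "NTR": CohortSpec(
            name="NTR",
            outcomes_present=("ADHD", "INT", "SOC"),
            has_age_covariate=True,
            n_pcs=n_pcs,
            factor_covariates=chip,
            is_twin_cohort=True,
        ),
        "TEDS": CohortSpec(
            name="TEDS",
            outcomes_present=("ADHD", "INT", "SOC"),
            has_age_covariate=True,
            n_pcs=n_pcs,
            factor_covariates=chip_batch,
            is_twin_cohort=True,
        ),
    }


#: Published per-cohort child counts.
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "ALSPAC": 5025,
    "CATSS": 7284,
    "NTR": 3652,
    "TEDS": 4578,
}

#: Number of levels for the categorical nuisance covariates.
FACTOR_LEVELS: dict[str, int] = {"chip": 2, "batch": 3}


@dataclass
class StudyConfig:
    """Which cohorts to simulate, how large, and from which seed."""

    cohorts: list[tuple[CohortSpec, int]]
    seed: int = 0

    def __post_init__(self) -> None:
        for spec, n in self.cohorts:
            if n <= 0:
                raise ValueError(f"cohort {spec.name}: n_children must be > 0")

    @property
    def total_children(self) -> int:
        return sum(n for _, n in self.cohorts)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohorts": [
                {**dataclasses.asdict(spec), "n_children": n}
                for spec, n in self.cohorts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cohorts = []
        for c in d["cohorts"]:
            c = dict(c)
            n = c.pop("n_children")
            c["outcomes_present"] = tuple(c["outcomes_present"])
            c["factor_covariates"] = tuple(c.get("factor_covariates", ()))
            cohorts.append((CohortSpec(**c), n))
        return cls(cohorts=cohorts, seed=d.get("seed", 0))


def default_study_config(
    seed: int = 0,
    *,
    scale: float = 1.0,
    n_pcs: int = 10,
    include_factors: bool = True,
) -> StudyConfig:
    """Four-cohort study at the published sample sizes.

    ``scale`` multiplies every cohort size (floor, minimum 4) for fast test
    runs; ``n_pcs``/``include_factors`` thin the nuisance covariates.
    """
    specs = default_cohort_specs(n_pcs=n_pcs, include_factors=include_factors)
    cohorts = [
        (specs[name], max(4, int(DEFAULT_COHORT_SIZES[name] * scale)))
        for name in ("ALSPAC", "CATSS", "NTR", "TEDS")
    ]
    return StudyConfig(cohorts=cohorts, seed=seed)


# ---------------------------------------------------------------------------
# Simulation

def simulate_pgs(
    n: int,
    R_pgs: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` rows of correlated standard-normal PGS via Cholesky.

    Raises ``numpy.linalg.LinAlgError`` naming the smallest eigenvalue when
    ``R_pgs`` is not positive definite.
    """
    R_pgs = np.asarray(R_pgs, dtype=float)
    _check_correlation(R_pgs, "R_pgs")
    L = np.linalg.cholesky(R_pgs)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, R_pgs.shape[0]))
    return z @ L.T


def _simulate_family_pgs(
    n_pairs: int,
    n_singles: int,
    R: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """PGS draws for twin pairs (2*n_pairs rows) and singletons.

    With within-pair correlation ``rho`` each pair's 14-vector is MVN with
    covariance [[R, rho*R], [rho*R, R]].
    """
    k = R.shape[0]
    L = np.linalg.cholesky(R)
    if n_pairs:
        if rho == 0.0:
            z = rng.standard_normal((n_pairs, 2, k))
            pairs = z @ L.T
        else:
            # (a, b) with Cov = [[R, rho R],[rho R, R]]: a = L z1,
            # b = L (rho z1 + sqrt(1-rho^2) z2)
            z1 = rng.standard_normal((n_pairs, k))
            z2 = rng.standard_normal((n_pairs, k))
            a = z1 @ L.T
            b = (rho * z1 + np.sqrt(1 - rho**2) * z2) @ L.T
            pairs = np.stack([a, b], axis=1)
        pair_rows = pairs.reshape(2 * n_pairs, k)
    else:
        pair_rows = np.empty((0, k))
    singles = (
        rng.standard_normal((n_singles, k)) @ L.T
        if n_singles
        else np.empty((0, k))
    )
    return pair_rows, singles


def simulate_cohort(
    spec: CohortSpec,
    n: int,
    truth: GeneratorTruth,
    seed: int | np.random.Generator,
) -> CohortDataset:
    """Simulate one cohort of ``n`` children under ``truth``.

    Twin cohorts are laid out as ``n // 2`` pairs plus one singleton when
    ``n`` is odd; non-twin cohorts are all singletons.  Outcomes are raw
    (unstandardized) model draws; downstream analysis standardizes them
    within cohort.
    """
    truth.validate()
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)

    if spec.is_twin_cohort:
        n_pairs, n_singles = divmod(n, 2)
    else:
        n_pairs, n_singles = 0, n
    n_families = n_pairs + n_singles

    pair_pgs, single_pgs = _simulate_family_pgs(
        n_pairs, n_singles, truth.R_pgs, truth.twin_pgs_corr, rng
    )
    pgs = np.vstack([pair_pgs, single_pgs])

    fam_of_child = np.concatenate(
        [np.repeat(np.arange(n_pairs), 2), n_pairs + np.arange(n_singles)]
    ).astype(int)
    member_index = np.concatenate(
        [np.tile([0, 1], n_pairs), np.zeros(n_singles, dtype=int)]
    )

    sex = rng.integers(0, 2, size=n)
    fam_age = rng.uniform(*AGE_RANGE, size=n_families)  # twins share age
    age = fam_age[fam_of_child]
    age_z = (age - _AGE_MEAN) / _AGE_SD
    pcs = rng.standard_normal((n, truth.b_pcs.shape[1]))

    mean = (
        pgs @ truth.B.T
        + sex[:, None] * truth.b_sex
        + age_z[:, None] * truth.b_age
        + pcs @ truth.b_pcs.T
    )

    # residuals: joint 6-dim draw per pair, 3-dim per singleton
    resid = np.empty((n, 3))
    if n_pairs:
        L6 = np.linalg.cholesky(truth.twin_block())
        e = rng.standard_normal((n_pairs, 6)) @ L6.T
        resid[: 2 * n_pairs] = e.reshape(2 * n_pairs, 3)
    if n_singles:
        L3 = np.linalg.cholesky(truth.Sigma_W)
        resid[2 * n_pairs:] = rng.standard_normal((n_singles, 3)) @ L3.T
    y = mean + resid

    # structural missingness, then MCAR masking of measured cells
    y[:, ~spec.outcome_mask] = np.nan
    if truth.miss_rate > 0:
        mask = rng.random((n, 3)) < truth.miss_rate
        y[mask & spec.outcome_mask[None, :]] = np.nan

    tab = pd.DataFrame(
        {
            "family_id": [f"{spec.name}_F{f:06d}" for f in fam_of_child],
            "member_index": member_index,
            "sex": sex,
        }
    )
    if spec.has_age_covariate:
        tab["age"] = age
    for i, col in enumerate(spec.pc_columns):
        tab[col] = pcs[:, i]
    for fac in spec.factor_covariates:
        levels = FACTOR_LEVELS.get(fac, 2)
        fam_level = rng.integers(0, levels, size=n_families)
        tab[fac] = np.array(
            [f"{fac}{k}" for k in fam_level[fam_of_child]]
        )
    for j, col in enumerate(OUTCOME_COLUMNS):
        tab[col] = y[:, j]
    for j, col in enumerate(PGS_COLUMNS):
        tab[col] = pgs[:, j]
    return CohortDataset(spec=spec, table=tab)


def simulate_study(
    cfg: StudyConfig, truth: GeneratorTruth
) -> list[CohortDataset]:
    """Simulate every cohort of a study; deterministic given ``cfg.seed``.

    Per-cohort generators are spawned from a single ``SeedSequence`` so each
    cohort's draws are independent and reproducible.
    """
    truth.validate()
    children = [np.random.default_rng(s)
                for s in np.random.SeedSequence(cfg.seed).spawn(
                    len(cfg.cohorts))]
    return [
        simulate_cohort(spec, n, truth, rng)
        for (spec, n), rng in zip(cfg.cohorts, children)
    ]


# ---------------------------------------------------------------------------
# Config I/O

def save_config(
    path: str | Path, cfg: StudyConfig, truth: GeneratorTruth
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"study": cfg.to_dict(), "truth": truth.to_dict()}, fh, indent=1
        )


def load_config(path: str | Path) -> tuple[StudyConfig, GeneratorTruth]:
    with open(path) as fh:
        d = json.load(fh)
    return StudyConfig.from_dict(d["study"]), GeneratorTruth.from_dict(
        d["truth"]
    )
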