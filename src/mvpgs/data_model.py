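"""Cohort data structures, table I/O, validation, and within-cohort scaling.

The study design is a multi-cohort (multi-group) one: each cohort contributes
one tidy table with one row per child, rows grouped into families of one or
two members (twin pairs in twin cohorts, singletons otherwise).  Three
childhood outcomes (ADHD symptoms, internalizing problems, social problems)
may be partially missing; seven adult-trait polygenic scores (PGS) and the
covariates are always observed.  Outcomes and PGS are analyzed as
within-cohort z-scores, so a :class:`CohortDataset` carries both the raw
table and the machinery to standardize it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Outcome column names, fixed order: ADHD symptoms, internalizing problems,
#: social problems.
OUTCOME_COLUMNS: tuple[str, ...] = ("adhd", "int", "soc")

#: PGS column names, fixed order: major depression, bipolar disorder,
#: subjective well-being, neuroticism, insomnia, educational attainment, BMI.
PGS_COLUMNS: tuple[str, ...] = (
    "pgs_mdd",
    "pgs_bip",
    "pgs_swb",
    "pgs_neu",
    "pgs_ins",
    "pgs_ea",
    "pgs_bmi",
)

#: Short predictor labels matching :data:`PGS_COLUMNS`.
PGS_LABELS: tuple[str, ...] = ("MDD", "BIP", "SWB", "NEU", "INS", "EA", "BMI")

OUTCOME_LABELS: tuple[str, ...] = ("ADHD", "INT", "SOC")

ID_COLUMNS: tuple[str, ...] = ("family_id", "member_index")


class DataFormatError(ValueError):
    """Malformed input table (missing/unknown header columns)."""


class DataStructureError(ValueError):
    """Table violates the family structure (e.g. more than two members)."""


class DataValidationError(ValueError):
    """Values violate dataset invariants (e.g. a missing PGS entry)."""


@dataclass(frozen=True)
class CohortSpec:
    """Structural description of one cohort.

    Parameters
    ----------
    name
        Cohort label (e.g. ``"ALSPAC"``).
    outcomes_present
        Subset of :data:`OUTCOME_LABELS` measured in this cohort.  A cohort
        that never measured an outcome contributes no information on it; the
        column is structurally missing for every member.
    has_age_covariate
        Whether child age is available and used as a covariate.
    n_pcs
        Number of genetic principal components used as covariates.
    factor_covariates
        Names of categorical covariates (genotyping chip / batch), modelled
        per cohort via dummy coding.
    is_twin_cohort
        Twin cohorts contribute families of up to two children whose residuals
        are correlated; non-twin cohorts contribute singletons only.
    """

    name: str
    outcomes_present: tuple[str, ...] = OUTCOME_LABELS
    has_age_covariate: bool = True
    n_pcs: int = 10
    factor_covariates: tuple[str, ...] = ()
    is_twin_cohort: bool = False

    def __post_init__(self) -> None:
        outcomes = tuple(self.outcomes_present)
        unknown = set(outcomes) - set(OUTCOME_LABELS)
        if unknown:
            raise ValueError(f"unknown outcomes {sorted(unknown)}")
        if not outcomes:
            raise ValueError("outcomes_present must be non-empty")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        object.__setattr__(self, "outcomes_present", outcomes)
        object.__setattr__(
            self, "factor_covariates", tuple(self.factor_covariates)
        )

    @property
    def outcome_mask(self) -> np.ndarray:
        """Boolean mask over :data:`OUTCOME_LABELS` for measured outcomes."""
        return np.array(
            [lab in self.outcomes_present for lab in OUTCOME_LABELS]
        )

    @property
    def pc_columns(self) -> tuple[str, ...]:
        return tuple(f"pc{i + 1}" for i in range(self.n_pcs))

    def required_columns(self) -> tuple[str, ...]:
        cols = list(ID_COLUMNS) + ["sex"]
        if self.has_age_covariate:
            cols.append("age")
        cols += list(self.pc_columns)
        cols += list(self.factor_covariates)
        cols += [
            OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
            for lab in self.outcomes_present
        ]
        cols += list(PGS_COLUMNS)
        return tuple(cols)


@dataclass
class CohortDataset:
    """One cohort's data: a :class:`CohortSpec` plus a per-child table.

    ``table`` has one row per child with columns ``family_id``,
    ``member_index`` (0 or 1 within family), ``sex`` (0 female / 1 male),
    optionally ``age``, ``pc1..pcK``, factor columns, the three outcome
    columns (NaN where missing, including structurally absent outcomes) and
    the seven PGS columns.
    """

    spec: CohortSpec
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in OUTCOME_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        self.table = self.table.reset_index(drop=True)

    @property
    def n_children(self) -> int:
        return len(self.table)

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def outcomes(self) -> np.ndarray:
        """(n, 3) float array of outcomes with NaN for missing cells."""
        return self.table[list(OUTCOME_COLUMNS)].to_numpy(dtype=float)

    def pgs(self) -> np.ndarray:
        """(n, 7) float array of polygenic scores."""
        return self.table[list(PGS_COLUMNS)].to_numpy(dtype=float)

    def family_sizes(self) -> pd.Series:
        return self.table.groupby("family_id", sort=False).size()

    def copy(self) -> "CohortDataset":
        return CohortDataset(spec=self.spec, table=self.table.copy())


@dataclass
class StandardizationReport:
    """Per-column scaling bookkeeping: pre-scaling moments and flags."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self, column: str, mean: float, sd: float, n_nonmissing: int,
        zero_variance: bool,
    ) -> None:
        self.rows.append(
            {
                "column": column,
                "pre_mean": mean,
                "pre_sd": sd,
                "n_nonmissing": n_nonmissing,
                "zero_variance": zero_variance,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["column", "pre_mean", "pre_sd", "n_nonmissing",
                     "zero_variance"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ValidationReport:
    """List of dataset-invariant violations; empty iff the dataset is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cohort_table(path: str | Path, spec: CohortSpec) -> CohortDataset:
    """Read a per-cohort TSV/CSV into a :class:`CohortDataset`.

    Missing outcome values may be encoded as empty fields or ``NA``.
    Outcome columns the cohort never measured may be absent from the file;
    they are materialized as all-missing.  PGS values must never be missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip float parsing: the default fast parser can be off by 1 ulp,
    # which breaks bit-exact write->read round trips
    tab = pd.read_csv(
        path, sep=_sep_for(path), na_values=["NA"],
        float_precision="round_trip",
    )

    required = set(spec.required_columns())
    # Structurally absent outcome columns are allowed to be absent on disk.
    structural_absent = {
        OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
        for lab in OUTCOME_LABELS
        if lab not in spec.outcomes_present
    }
    missing_cols = required - set(tab.columns)
    if missing_cols:
        raise DataFormatError(
            f"{path}: missing required columns {sorted(missing_cols)}"
        )
    unknown = set(tab.columns) - required - structural_absent - set(
        OUTCOME_COLUMNS
    )
    if unknown:
        raise DataFormatError(
            f"{path}: unrecognized columns {sorted(unknown)}"
        )

    ds = CohortDataset(spec=spec, table=tab)
    if len(tab):
        sizes = ds.family_sizes()
        if (sizes > 2).any():
            bad = sizes.index[sizes > 2].tolist()
            raise DataStructureError(
                f"{path}: families with more than 2 members: {bad[:5]}"
            )
        if np.isnan(ds.pgs()).any():
            raise DataValidationError(f"{path}: missing PGS values")
        # structurally absent outcomes must be entirely missing
        for lab in OUTCOME_LABELS:
            col = OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
            if lab not in spec.outcomes_present and tab[col].notna().any():
                raise DataValidationError(
                    f"{path}: cohort {spec.name} has values in structurally "
                    f"absent outcome column {col!r}"
                )
    return ds


def write_cohort_table(ds: CohortDataset, path: str | Path) -> None:
    """Write a cohort table as TSV/CSV (extension decides the separator)."""
    cols = [c for c in ds.table.columns]
    # keep structurally absent outcome columns out of the file: read_cohort_table
    # re-materializes them, and their absence mirrors the real cohort files
    absent = [
        OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
        for lab in OUTCOME_LABELS
        if lab not in ds.spec.outcomes_present
    ]
    cols = [c for c in cols if c not in absent]
    ds.table[cols].to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def standardize_columns(
    ds: CohortDataset, columns: Sequence[str]
) -> tuple[CohortDataset, StandardizationReport]:
    """Within-cohort z-scoring of the given columns.

    Each column is centred on the mean and divided by the sample SD
    (``n - 1`` denominator) of its non-missing values; missing cells stay
    missing.  A zero-variance column raises :class:`DataValidationError`
    naming the column.
    """
    out = ds.copy()
    report = StandardizationReport()
    for col in columns:
        if col not in out.table.columns:
            raise KeyError(f"no column {col!r} in cohort {ds.spec.name}")
        vals = out.table[col].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise DataValidationError(
                f"column {col!r}: fewer than 2 non-missing values"
            )
        mean = float(obs.mean())
        sd = float(obs.std(ddof=1))
        zero = sd == 0.0 or not np.isfinite(sd)
        report.add(col, mean, sd, obs.size, zero)
        if zero:
            raise DataValidationError(f"column {col!r} has zero variance")
        out.table[col] = (vals - mean) / sd
    return out, report


def standardize_for_analysis(ds: CohortDataset) -> CohortDataset:
    """Standardize the analysis columns of one cohort.

    Outcomes (their measured subset) and all seven PGS are z-scored within
    cohort, as is age where present.  Sex stays on its 0/1 coding and PCs and
    factor covariates are left untouched.
    """
    cols = [
        OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
        for lab in ds.spec.outcomes_present
    ]
    cols += list(PGS_COLUMNS)
    if ds.spec.has_age_covariate:
        cols.append("age")
    out, _ = standardize_columns(ds, cols)
    return out


def validate_dataset(ds: CohortDataset) -> ValidationReport:
    """Scan a dataset for invariant violations (reporting, never raising)."""
    rep = ValidationReport()
    tab = ds.table
    if not len(tab):
        return rep
    sizes = ds.family_sizes()
    if (sizes > 2).any():
        rep.violations.append(
            f"families with >2 members: {sizes.index[sizes > 2].tolist()[:5]}"
        )
    if not ds.spec.is_twin_cohort and (sizes == 2).any():
        rep.violations.append(
            "non-twin cohort contains multi-member families"
        )
    if np.isnan(ds.pgs()).any():
        rep.violations.append("missing PGS values")
    for lab in OUTCOME_LABELS:
        col = OUTCOME_COLUMNS[OUTCOME_LABELS.index(lab)]
        if lab not in ds.spec.outcomes_present and tab[col].notna().any():
            rep.violations.append(
                f"values present in structurally absent outcome {col!r}"
            )
    if not tab["sex"].isin([0, 1]).all():
        rep.violations.append("sex values outside {0, 1}")
    if ds.spec.has_age_covariate and "age" not in tab.columns:
        rep.violations.append("age covariate declared but column absent")
    return rep
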