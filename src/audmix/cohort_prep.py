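"""Inclusion/exclusion filtering, PEF coding, and design-matrix construction.

The analysis unit is the PEF (patient-ear-frequency): one ear of one patient
at one stimulus frequency. Records enter modelling only if they come from a
bone-conduction test at one of the four frequencies of interest (500, 1000,
2000, 4000 Hz), have a non-zero threshold, fall in the pediatric 0-21 year
age range, and belong to a PEF with at least four surviving tests (which also
guarantees every 4-bin imputation fold is non-empty).

The regression design per record is [1, ln(age), gender==F, ln(diagnoses+1)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import DESIGN_COLUMNS, FREQUENCY_GRID, RECORD_COLUMNS

VALID_EARS = frozenset({"left", "right", "soundfield"})

#: one-week floor on age: ln(age) must be finite, and a recorded age of 0
#: is clinically a newborn screen rather than a usable behavioural test
DEFAULT_AGE_FLOOR = 7.0 / 365.0

#: criterion keys in report order
CRITERIA = ("ear", "conduction", "frequency", "zero_threshold", "min_tests", "age_range")


@dataclass
class FilterReport:
    """Removal counts per inclusion criterion, in the order they are reported:
    (1) ear validity, (2) bone conduction, (3) frequency grid, (4) zero
    threshold, (5) <4 tests per PEF, (6) age range."""

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_output": self.n_output, "removed": dict(self.counts)}


def _require_fields(records: pd.DataFrame) -> None:
    missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"record table is missing columns: {missing_cols}")
    required = records[list(RECORD_COLUMNS)]
    bad = required.isna().any(axis=1)
    if bad.any():
        rownum = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"malformed record at row {rownum}: missing field(s)")


def apply_filters(
    records: pd.DataFrame,
    age_floor: float = DEFAULT_AGE_FLOOR,
    min_tests: int = 4,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the six inclusion/exclusion criteria, returning survivors and a
    per-criterion removal report.

    Row-level criteria (ear label, bone conduction, frequency grid, non-zero
    threshold, age range) run first; the per-PEF minimum-test-count rule then
    removes whole PEFs counting only surviving tests, so the output satisfies
    the >= ``min_tests`` invariant regardless of which rows the other criteria
    dropped. Filtering is idempotent and order-stable.
    """
    _require_fields(records)
    df = records.reset_index(drop=True)
    counts = {c: 0 for c in CRITERIA}
    n_input = len(df)

    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, criterion: str) -> None:
        hit = mask & keep
        counts[criterion] += int(hit.sum())
        keep[hit] = False

    drop(~df["ear"].isin(VALID_EARS), "ear")
    drop(df["conduction"] != "bone", "conduction")
    drop(~df["frequency_hz"].isin(FREQUENCY_GRID), "frequency")
    drop(df["threshold_db"] == 0.0, "zero_threshold")
    drop((df["age_years"] < age_floor) | (df["age_years"] > 21.0), "age_range")

    survivors = df[keep]
    pef = survivors["patient_id"].astype(str) + "|" + survivors["ear"].astype(str) + "|" + survivors["frequency_hz"].astype(int).astype(str)
    sizes = pef.map(pef.value_counts())
    small = sizes < min_tests
    counts["min_tests"] = int(small.sum())
    out = survivors[~small].reset_index(drop=True)

    report = FilterReport(counts=counts, n_input=n_input, n_output=len(out))
    return out, report


@dataclass
class PEFDataset:
    """Filtered records grouped by PEF, with an optional design-matrix view.

    ``df`` is sorted by (pef_key, age) with stable tie-breaking; ``pef_codes``
    assigns each row the integer code of its PEF, contiguous in row order.
    After :func:`build_design`, ``X`` holds the n x 4 design
    [1, ln(age), gender_F, ln(diag+1)] and ``y`` the thresholds in dB.
    """

    df: pd.DataFrame
    pef_codes: np.ndarray
    pef_keys: list[str]
    X: np.ndarray | None = None
    y: np.ndarray | None = None

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_pefs(self) -> int:
        return len(self.pef_keys)

    @property
    def group_starts(self) -> np.ndarray:
        """Start row of each PEF's contiguous block (for segmented reductions)."""
        return np.searchsorted(self.pef_codes, np.arange(self.n_pefs))

    def rows_of(self, pef_key: str) -> np.ndarray:
        """Positional row indices of one PEF."""
        code = self.pef_keys.index(pef_key)
        return np.flatnonzero(self.pef_codes == code)

    def subset(self, row_mask: np.ndarray) -> "PEFDataset":
        """New dataset from a boolean row mask (PEF grouping recomputed)."""
        sub = self.df.loc[np.asarray(row_mask)].reset_index(drop=True)
        ds = _from_sorted_frame(sub)
        if self.X is not None:
            ds.X = self.X[row_mask]
            ds.y = self.y[row_mask]
        return ds

    def require_design(self) -> None:
        if self.X is None:
            raise ValueError("design matrix not built; call build_design first")


def _pef_key_series(df: pd.DataFrame) -> pd.Series:
    return (
        df["patient_id"].astype(str)
        + "|"
        + df["ear"].astype(str)
        + "|"
        + df["frequency_hz"].astype(int).astype(str)
    )


def _from_sorted_frame(df: pd.DataFrame) -> PEFDataset:
    keys = df["pef_key"]
    codes, uniques = pd.factorize(keys, sort=False)
    return PEFDataset(df=df, pef_codes=codes, pef_keys=list(uniques))


def code_pefs(records: pd.DataFrame) -> PEFDataset:
    """Group filtered records into PEFs, sorted by age within each PEF.

    Age ties keep input order (stable sort) so downstream fold construction
    is deterministic.
    """
    df = records.reset_index(drop=True).copy()
    df["pef_key"] = _pef_key_series(df)
    df = df.sort_values(["pef_key", "age_years"], kind="mergesort").reset_index(drop=True)
    return _from_sorted_frame(df)


def build_design(dataset: PEFDataset) -> PEFDataset:
    """Populate the design columns and matrix view; idempotent.

    Raises if any age is non-positive (ln undefined): such records should have
    been removed by the filter stage's age floor; lower the floor only with an
    explicit epsilon if truly desired.
    """
    df = dataset.df.copy()
    ages = df["age_years"].to_numpy(dtype=float)
    if np.any(ages <= 0):
        raise ValueError(
            "age_years <= 0 encountered: ln(age) is undefined; apply_filters with a "
            "positive age_floor (default one week) before building the design"
        )
    df["log_age"] = np.log(ages)
    df["gender_f"] = (df["gender"] == "F").astype(float)
    df["log_diag"] = np.log(df["diag_count"].to_numpy(dtype=float) + 1.0)
    X = np.column_stack(
        [np.ones(len(df)), df["log_age"], df["gender_f"], df["log_diag"]]
    )
    y = df["threshold_db"].to_numpy(dtype=float)
    return PEFDataset(
        df=df, pef_codes=dataset.pef_codes.copy(), pef_keys=list(dataset.pef_keys), X=X, y=y
    )


def prepare(records: pd.DataFrame, **filter_kwargs) -> tuple[PEFDataset, FilterReport]:
    """Filter, group, and build the design in one step."""
    filtered, report = apply_filters(records, **filter_kwargs)
    return build_design(code_pefs(filtered)), report
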