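"""Synthetic audiogram cohort generator with known latent-cluster ground truth.

Real bone-conduction audiogram extracts (a few thousand patient-ear-frequency
series, 4-21 tests each) cannot be redistributed, so every downstream stage is
exercised on cohorts drawn from the generating model itself: each PEF belongs
to one of ``k_true`` latent clusters, and its thresholds follow that cluster's
linear regression on [1, log(age), gender, log(diagnoses + 1)] with Gaussian
noise. Optional per-PEF random-effect deviations emulate between-individual
drift; an optional horizon-proportional shift on the final test emulates
within-individual drift; optional contaminant records violate the inclusion
criteria so the filter stage can be tested record-by-record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FREQUENCY_GRID = (500, 1000, 2000, 4000)
EARS = ("left", "right")

#: column order of the regression design; shared with cohort_prep
DESIGN_COLUMNS = ("intercept", "log_age", "gender_f", "log_diag")

RECORD_COLUMNS = [
    "patient_id",
    "ear",
    "conduction",
    "frequency_hz",
    "age_years",
    "gender",
    "diag_count",
    "threshold_db",
]

# Defaults describe a three-cluster cohort whose coefficient spread mirrors
# the kind of structure latent-class audiogram analyses report: a severe
# progressive-loss cluster, a moderate stable cluster, and a mild
# "improving" cluster (likely data artifacts in real extracts), with
# intercepts >= 20 dB apart and 5 dB residual noise. The gender offset is
# common to all clusters: gender is constant within a PEF, so strongly
# cluster-specific gender effects would make cluster identity ambiguous
# across gender strata (members could be swapped between clusters and
# refitted almost equally well).
_DEFAULT_BETAS = (
    (60.0, 3.0, 2.0, 0.6),
    (40.0, 0.5, 2.0, 0.3),
    (15.0, -1.5, 2.0, 0.1),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic cohort is drawn.

    Parameters
    ----------
    n_pefs:
        Number of patient-ear-frequency series.
    tests_per_pef:
        Inclusive (min, max) bounds on tests per PEF; counts are drawn as
        ``min + Poisson(2)`` truncated at ``max``, giving a mean near 6.
    age_range:
        Age bounds in years (lower bound must be positive); test ages are
        sorted log-uniform draws within it.
    k_true:
        Number of generating clusters.
    cluster_betas:
        ``k_true`` rows of (intercept, log-age slope, gender-F offset,
        log-diagnosis slope), in dB per unit of each design column.
    cluster_sigmas:
        Per-cluster residual SD in dB.
    mixing:
        Prior cluster probabilities; must sum to 1.
    random_effect_sd:
        Per-coefficient SD of optional PEF-level coefficient deviations
        (scalar or length-4); 0 disables.
    drift_rate:
        dB per year of forecast horizon added to the *final* test's noiseless
        mean (within-individual concept drift); 0 disables.
    contamination_rate:
        Fraction (of the clean record count) of injected records violating
        inclusion criteria.
    seed:
        RNG seed; identical (config, seed) gives byte-identical output.
    """

    n_pefs: int = 1000
    tests_per_pef: tuple[int, int] = (4, 21)
    age_range: tuple[float, float] = (0.5, 21.0)
    k_true: int = 3
    cluster_betas: tuple[tuple[float, float, float, float], ...] = _DEFAULT_BETAS
    cluster_sigmas: tuple[float, ...] = (5.0, 5.0, 5.0)
    mixing: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    random_effect_sd: float | tuple[float, float, float, float] = 0.0
    drift_rate: float = 0.0
    contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true != len(self.cluster_betas):
            raise ValueError(
                f"k_true={self.k_true} but {len(self.cluster_betas)} cluster_betas given"
            )
        if len(self.cluster_sigmas) != self.k_true or len(self.mixing) != self.k_true:
            raise ValueError("cluster_sigmas and mixing must have length k_true")
        if abs(sum(self.mixing) - 1.0) > 1e-12:
            raise ValueError(f"mixing must sum to 1, got {sum(self.mixing)!r}")
        if any(s < 0 for s in self.cluster_sigmas):
            raise ValueError("cluster_sigmas must be non-negative")
        lo, hi = self.tests_per_pef
        if lo < 4 or hi > 21 or lo > hi:
            raise ValueError("tests_per_pef must satisfy 4 <= min <= max <= 21")
        if not (0.0 < self.age_range[0] < self.age_range[1] <= 21.0):
            raise ValueError("age_range must lie within (0, 21]")
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be non-negative")

    @property
    def random_effect_sds(self) -> np.ndarray:
        sd = np.asarray(self.random_effect_sd, dtype=float)
        return np.broadcast_to(sd, (4,)).copy()


@dataclass
class GroundTruth:
    """Generating parameters and per-PEF latent state of a synthetic cohort."""

    pef_cluster: dict[str, int]
    pef_random_effects: dict[str, np.ndarray]
    cluster_betas: np.ndarray
    cluster_sigmas: np.ndarray
    mixing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pef_key": list(self.pef_cluster), "true_cluster": list(self.pef_cluster.values())}
        )


def pef_key(patient_id: str, ear: str, frequency_hz: int | float) -> str:
    """Canonical key of a patient-ear-frequency series."""
    return f"{patient_id}|{ear}|{int(frequency_hz)}"


def design_vector(age_years: float, gender: str, diag_count: int) -> np.ndarray:
    """Design row [1, ln(age), gender==F, ln(diag_count + 1)]."""
    return np.array([1.0, np.log(age_years), 1.0 if gender == "F" else 0.0, np.log(diag_count + 1)])


def _draw_ages(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    # uniform on the log scale: pediatric follow-up concentrates tests at
    # young ages, and it keeps ln(age) well spread around 0 so the regression
    # intercept is actually estimable
    ages = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    # continuous draws tie with probability zero, but the strict-increase
    # invariant is a hard contract
    while np.any(np.diff(ages) <= 0):
        ages = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    return ages


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort from the latent-cluster generating model.

    Every record of a PEF comes from that PEF's single cluster (plus its
    random-effect deviation if enabled); ages increase strictly within a PEF,
    gender is constant within a patient, and the cumulative diagnosis count is
    non-decreasing within a PEF. When ``config.drift_rate > 0`` the final
    record of each PEF has ``drift_rate * (age gap since previous test)``
    added to its noiseless mean.

    Returns the record table (one row per audiogram test) and the
    :class:`GroundTruth` used to generate it.
    """
    rng = np.random.default_rng(config.seed)
    betas = np.asarray(config.cluster_betas, dtype=float)
    sigmas = np.asarray(config.cluster_sigmas, dtype=float)
    mixing = np.asarray(config.mixing, dtype=float)
    re_sds = config.random_effect_sds

    # patients own up to four (ear, frequency) combinations; gender is a
    # patient-level attribute shared across that patient's PEFs
    combos = [(e, f) for e in EARS for f in FREQUENCY_GRID]
    rows: list[dict] = []
    pef_cluster: dict[str, int] = {}
    pef_re: dict[str, np.ndarray] = {}

    pefs_made = 0
    patient_no = 0
    while pefs_made < config.n_pefs:
        patient_no += 1
        pid = f"P{patient_no:05d}"
        gender = "F" if rng.random() < 0.5 else "M"
        n_here = min(int(rng.integers(1, 5)), config.n_pefs - pefs_made)
        picked = rng.choice(len(combos), size=n_here, replace=False)
        for ci in picked:
            ear, freq = combos[ci]
            key = pef_key(pid, ear, freq)
            k = int(rng.choice(config.k_true, p=mixing))
            b_dev = rng.normal(0.0, re_sds) if np.any(re_sds > 0) else np.zeros(4)
            lo, hi = config.tests_per_pef
            n_tests = min(lo + int(rng.poisson(2.0)), hi)
            ages = _draw_ages(rng, n_tests, *config.age_range)
            diag = np.cumsum(rng.poisson(0.7, size=n_tests)).astype(int)
            beta_eff = betas[k] + b_dev
            X = np.column_stack(
                [
                    np.ones(n_tests),
                    np.log(ages),
                    np.full(n_tests, 1.0 if gender == "F" else 0.0),
                    np.log(diag + 1),
                ]
            )
            mean = X @ beta_eff
            if config.drift_rate > 0 and n_tests >= 2:
                mean[-1] += config.drift_rate * (ages[-1] - ages[-2])
            thr = mean + rng.normal(0.0, sigmas[k], size=n_tests)
            for j in range(n_tests):
                rows.append(
                    {
                        "patient_id": pid,
                        "ear": ear,
                        "conduction": "bone",
                        "frequency_hz": int(freq),
                        "age_years": float(ages[j]),
                        "gender": gender,
                        "diag_count": int(diag[j]),
                        "threshold_db": float(thr[j]),
                    }
                )
            pef_cluster[key] = k
            pef_re[key] = b_dev
            pefs_made += 1

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    truth = GroundTruth(
        pef_cluster=pef_cluster,
        pef_random_effects=pef_re,
        cluster_betas=betas,
        cluster_sigmas=sigmas,
        mixing=mixing,
    )
    if config.contamination_rate > 0:
        records = inject_contamination(records, config)
    return records, truth


def generate_drift_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort whose final-per-PEF observations drift with the forecast horizon.

    Requires ``drift_rate > 0``; otherwise identical in contract to
    :func:`generate_cohort`.
    """
    if config.drift_rate <= 0:
        raise ValueError("generate_drift_cohort requires drift_rate > 0")
    return generate_cohort(config)


# violation tag -> inclusion criterion it breaks (cohort_prep criterion keys)
CONTAMINANT_TAGS = ("ear", "conduction", "frequency", "zero_threshold", "min_tests", "age_range")


def inject_contamination(records: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Append records that each violate exactly one inclusion criterion.

    Roughly ``contamination_rate`` * len(records) rows are added, cycling
    through the violation types: unknown ear label, air conduction, off-grid
    frequency, zero threshold, a new PEF with only 3 tests, and age above 21.
    Each injected row carries its violation in a ``contaminant`` column
    (empty string for clean rows) so filter tests can count removals
    criterion by criterion.
    """
    out = records.copy()
    if "contaminant" not in out.columns:
        out["contaminant"] = ""
    if config.contamination_rate == 0:
        return out

    rng = np.random.default_rng(config.seed + 1)
    n_inject = int(round(config.contamination_rate * len(records)))
    bad_rows: list[dict] = []
    tag_cycle = 0
    short_pef_no = 0
    while len(bad_rows) < n_inject:
        tag = CONTAMINANT_TAGS[tag_cycle % len(CONTAMINANT_TAGS)]
        tag_cycle += 1
        base = records.iloc[int(rng.integers(len(records)))].to_dict()
        base["contaminant"] = tag
        if tag == "ear":
            base["ear"] = "unspecified"
        elif tag == "conduction":
            base["conduction"] = "air"
        elif tag == "frequency":
            base["frequency_hz"] = 3000
        elif tag == "zero_threshold":
            base["threshold_db"] = 0.0
        elif tag == "age_range":
            base["age_years"] = float(rng.uniform(21.5, 40.0))
        elif tag == "min_tests":
            # a whole new PEF with only three (otherwise valid) tests
            short_pef_no += 1
            pid = f"C{short_pef_no:05d}"
            gender = "F" if rng.random() < 0.5 else "M"
            ages = _draw_ages(rng, 3, *config.age_range)
            diag = np.cumsum(rng.poisson(0.7, size=3)).astype(int)
            for j in range(3):
                bad_rows.append(
                    {
                        "patient_id": pid,
                        "ear": "left",
                        "conduction": "bone",
                        "frequency_hz": 1000,
                        "age_years": float(ages[j]),
                        "gender": gender,
                        "diag_count": int(diag[j]),
                        "threshold_db": float(rng.uniform(10, 60)),
                        "contaminant": tag,
                    }
                )
            continue
        bad_rows.append(base)

    bad = pd.DataFrame(bad_rows, columns=RECORD_COLUMNS + ["contaminant"])
    return pd.concat([out, bad], ignore_index=True)


def write_cohort(records: pd.DataFrame, path, truth: GroundTruth | None = None, truth_path=None) -> None:
    """Write the record table (and optionally ground truth) as CSV."""
    records.to_csv(path, index=False)
    if truth is not None and truth_path is not None:
        truth.to_frame().to_csv(truth_path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"patient_id": str, "ear": str, "conduction": str, "gender": str},
    )
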