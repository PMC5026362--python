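"""The three simulated prediction tasks and their scoring.

Task 1 (imputation): each PEF's rows are randomly split into 4 near-equal
bins; bins rotate through the "missing" role, models retrain per rotation,
and accuracy is the 4-fold average mean squared error.

Task 2 (forecasting): each PEF's final (maximal-age) test is withheld; models
train on the earlier rows and predict the future observation. The per-PEF gap
between the last training test and the withheld one (the forecast horizon)
supports a follow-up regression of the mixed-vs-mixture absolute-error
difference on horizon, controlling for the observed threshold — positive
horizon coefficient means the mixed model degrades faster with distance into
the future (within-individual concept drift).

Task 3 (new-patient generalization): whole PEFs are withheld; trained models
must predict them without retraining — the mixed model falls back to fixed
effects, the mixture infers membership by Bayes rule.

MSE per fold is the mean squared prediction error over that fold's test rows;
the task score averages fold MSEs (a single fold for tasks 2-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .baseline_models import fit_mixed, fit_ols, predict_baseline_rows
from .cohort_prep import PEFDataset
from .mixture_model import Responsibilities, fit_mixture
from .prediction import predict_for_task

TASKS = ("imputation", "forecast", "new_patient")


@dataclass
class FoldSpec:
    """Row-level assignment of a dataset to folds for one task.

    imputation: ``bins`` holds each row's bin index 0..3.
    forecast / new_patient: ``test_mask`` marks test rows; forecast also
    records each PEF's horizon (years from last training test to the withheld
    one); new_patient records the withheld PEF keys.
    """

    task: str
    seed: int | None = None
    bins: np.ndarray | None = None
    test_mask: np.ndarray | None = None
    horizons: dict[str, float] = field(default_factory=dict)
    test_pefs: list[str] = field(default_factory=list)


@dataclass
class TaskResult:
    """Per-fold and averaged MSE for one model on one task."""

    model: str
    per_fold_mse: list[float]
    predictions: pd.DataFrame

    @property
    def mse(self) -> float:
        return float(np.mean(self.per_fold_mse))

    @property
    def rmse(self) -> float:
        """Root-MSE: the average margin of error in dB."""
        return float(np.sqrt(self.mse))


def make_imputation_folds(dataset: PEFDataset, seed: int) -> FoldSpec:
    """Randomly split each PEF's rows into 4 bins of near-equal size.

    Bin sizes differ by at most one (larger bins first); every bin is
    non-empty because filtering guarantees >= 4 rows per PEF.
    """
    rng = np.random.default_rng(seed)
    bins = np.empty(dataset.n_records, dtype=int)
    for code in range(dataset.n_pefs):
        rows = np.flatnonzero(dataset.pef_codes == code)
        n = len(rows)
        if n < 4:
            raise ValueError(f"PEF {dataset.pef_keys[code]} has {n} < 4 rows")
        perm = rng.permutation(rows)
        base, rem = divmod(n, 4)
        sizes = [base + 1] * rem + [base] * (4 - rem)
        start = 0
        for b, s in enumerate(sizes):
            bins[perm[start : start + s]] = b
            start += s
    return FoldSpec(task="imputation", seed=seed, bins=bins)


def make_forecast_split(dataset: PEFDataset) -> FoldSpec:
    """Withhold each PEF's final (maximal-age) test; record horizons."""
    test_mask = np.zeros(dataset.n_records, dtype=bool)
    horizons: dict[str, float] = {}
    ages = dataset.df["age_years"].to_numpy()
    for code, key in enumerate(dataset.pef_keys):
        rows = np.flatnonzero(dataset.pef_codes == code)
        # rows are age-sorted with stable ties, so the last row is the
        # maximal-age test (last in input order on a tie)
        test_mask[rows[-1]] = True
        horizons[key] = float(ages[rows[-1]] - ages[rows[-2]]) if len(rows) >= 2 else 0.0
    return FoldSpec(task="forecast", test_mask=test_mask, horizons=horizons)


def make_newpatient_split(
    dataset: PEFDataset, test_fraction: float = 0.22, seed: int = 0
) -> FoldSpec:
    """Withhold whole PEFs, sampled without replacement, until their rows
    reach ``test_fraction`` of all rows. The split is at PEF level: no PEF
    ever straddles train and test."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.n_pefs)
    target = test_fraction * dataset.n_records
    test_mask = np.zeros(dataset.n_records, dtype=bool)
    test_pefs: list[str] = []
    got = 0
    for code in order:
        if got >= target:
            break
        rows = np.flatnonzero(dataset.pef_codes == code)
        test_mask[rows] = True
        test_pefs.append(dataset.pef_keys[code])
        got += len(rows)
    if got < target or len(test_pefs) >= dataset.n_pefs:
        raise ValueError("test_fraction unreachable while keeping a non-empty training set")
    return FoldSpec(task="new_patient", seed=seed, test_mask=test_mask, test_pefs=test_pefs)


def score_mse(predictions: pd.DataFrame, model_name: str = "") -> TaskResult:
    """Eq-style MSE scoring: per-fold mean squared error, averaged over folds.

    ``predictions`` needs columns observed_db, predicted_db and (optionally) a
    ``fold`` column; without one the table is a single fold.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    df = predictions if "fold" in predictions.columns else predictions.assign(fold=0)
    per_fold = []
    for _, grp in df.groupby("fold", sort=True):
        if len(grp) == 0:
            raise ValueError("empty fold")
        err = grp["predicted_db"].to_numpy() - grp["observed_db"].to_numpy()
        per_fold.append(float(np.mean(err**2)))
    return TaskResult(model=model_name, per_fold_mse=per_fold, predictions=df)


def error_gap_regression(table: pd.DataFrame) -> pd.DataFrame:
    """Regress (|mixed error| - |mixture error|) on forecast horizon,
    controlling for the observed threshold.

    A positive horizon coefficient says the mixed model's error grows faster
    than the mixture's as the withheld observation lies further in the
    future. Input columns: abs_err_mixed, abs_err_mixture, horizon_years,
    observed_db; one row per PEF. Returns coefficient, SE and two-sided
    p-value per term.
    """
    if len(table) < 3:
        raise ValueError("error-gap regression needs at least 3 PEFs")
    yv = (table["abs_err_mixed"] - table["abs_err_mixture"]).to_numpy(dtype=float)
    Xv = sm.add_constant(table[["horizon_years", "observed_db"]].to_numpy(dtype=float))
    res = sm.OLS(yv, Xv).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "horizon_years", "observed_db"],
            "coef": res.params,
            "se": res.bse,
            "pvalue": res.pvalues,
        }
    )


def _fit_and_predict_fold(
    train: PEFDataset,
    test: PEFDataset,
    models: tuple[str, ...],
    k_values: list[int],
    seed: int,
    mixture_mode: str,
    condition: str,
    n_starts: int,
) -> dict[str, pd.DataFrame]:
    """Train every requested model on one fold and predict its test rows."""
    preds: dict[str, pd.DataFrame] = {}
    base_cols = test.df[["pef_key", "age_years"]].reset_index(drop=True)

    def baseline_frame(model) -> pd.DataFrame:
        vals, fb = predict_baseline_rows(model, test, np.arange(test.n_records))
        return base_cols.assign(observed_db=test.y, predicted_db=vals, fallback=fb)

    if "ols" in models:
        preds["ols"] = baseline_frame(fit_ols(train))
    if "mixed" in models:
        preds["mixed"] = baseline_frame(fit_mixed(train))
    if "mixture" in models:
        for k in k_values:
            model, resp, _ = fit_mixture(train, k, n_starts=n_starts, seed=seed + 1000 * k)
            preds[f"mixture_k{k}"] = predict_for_task(
                model, resp, test, mode=mixture_mode, condition=condition
            )
    return preds


def run_task(
    task: str,
    dataset: PEFDataset,
    models: tuple[str, ...] = ("ols", "mixed", "mixture"),
    k_max: int = 6,
    seed: int = 0,
    test_fraction: float = 0.22,
    condition: str = "loo",
    n_starts: int = 3,
) -> dict:
    """Run one full prediction task: split, train, predict, score.

    Returns a dict with ``results`` (model name -> :class:`TaskResult`, the
    mixture at each k as ``mixture_k<k>``), ``comparison`` (tidy table of MSE
    and RMSE per model, the mixture reported at its best k), ``mse_vs_k``
    (the accuracy-vs-cluster-count curve), ``k_star``, the fold spec(s), and
    for the forecasting task the per-PEF ``error_gap`` input table.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    dataset.require_design()
    k_values = list(range(1, k_max + 1)) if "mixture" in models else []

    fold_preds: dict[str, list[pd.DataFrame]] = {}
    folds: list[FoldSpec] = []

    if task == "imputation":
        spec = make_imputation_folds(dataset, seed)
        folds.append(spec)
        for b in range(4):
            mask = spec.bins == b
            train, test = dataset.subset(~mask), dataset.subset(mask)
            fp = _fit_and_predict_fold(
                train, test, models, k_values, seed + b, "known_pef", condition, n_starts
            )
            for name, df in fp.items():
                fold_preds.setdefault(name, []).append(df.assign(fold=b))
    else:
        if task == "forecast":
            spec = make_forecast_split(dataset)
            mode = "known_pef"
        else:
            spec = make_newpatient_split(dataset, test_fraction=test_fraction, seed=seed)
            mode = "new_pef"
        folds.append(spec)
        train, test = dataset.subset(~spec.test_mask), dataset.subset(spec.test_mask)
        fp = _fit_and_predict_fold(train, test, models, k_values, seed, mode, condition, n_starts)
        for name, df in fp.items():
            fold_preds.setdefault(name, []).append(df.assign(fold=0))

    results = {
        name: score_mse(pd.concat(parts, ignore_index=True), name)
        for name, parts in fold_preds.items()
    }

    mse_vs_k = pd.DataFrame(
        [{"k": k, "mse": results[f"mixture_k{k}"].mse} for k in k_values]
    )
    k_star = int(mse_vs_k.loc[mse_vs_k["mse"].idxmin(), "k"]) if k_values else None

    comp_rows = []
    for name in ("ols", "mixed"):
        if name in results:
            comp_rows.append({"model": name, "mse": results[name].mse, "rmse": results[name].rmse})
    if k_star is not None:
        r = results[f"mixture_k{k_star}"]
        comp_rows.append({"model": f"mixture(k={k_star})", "mse": r.mse, "rmse": r.rmse})
    comparison = pd.DataFrame(comp_rows)

    out = {
        "task": task,
        "results": results,
        "comparison": comparison,
        "mse_vs_k": mse_vs_k,
        "k_star": k_star,
        "folds": folds,
        "seed": seed,
    }

    if task == "forecast" and {"mixed"}.issubset(set(results)) and k_star is not None:
        mixed_p = results["mixed"].predictions.set_index("pef_key")
        mix_p = results[f"mixture_k{k_star}"].predictions.set_index("pef_key")
        gap = pd.DataFrame(
            {
                "abs_err_mixed": (mixed_p["predicted_db"] - mixed_p["observed_db"]).abs(),
                "abs_err_mixture": (mix_p["predicted_db"] - mix_p["observed_db"]).abs(),
                "observed_db": mixed_p["observed_db"],
            }
        )
        gap["horizon_years"] = [folds[0].horizons[k] for k in gap.index]
        out["error_gap"] = gap.reset_index()
    return out
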