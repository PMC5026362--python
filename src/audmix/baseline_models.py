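"""Comparison predictors: pooled OLS and a PEF-grouped linear mixed model.

The OLS baseline assumes a single population-level relationship between
threshold and [1, ln(age), gender, ln(diagnoses+1)]. The mixed-effects
baseline adds a per-PEF random intercept and random slopes for all predictors
(B_pef ~ N(0, Sigma), unstructured Sigma, REML estimation via statsmodels
MixedLM); its prediction for a PEF seen in training adds that PEF's BLUP to
the fixed effects, and for an unseen PEF falls back to the fixed effects
alone — the property that makes it behave like OLS on new patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._linear import weighted_least_squares
from .cohort_prep import PEFDataset
from .synthetic_data import DESIGN_COLUMNS


@dataclass
class OLSModel:
    beta: np.ndarray  # (4,)
    sigma2: float
    se: np.ndarray  # (4,)
    column_names: tuple[str, ...] = DESIGN_COLUMNS


@dataclass
class MixedModel:
    """Fixed effects plus per-PEF random-effect BLUPs.

    ``structure`` records whether the full random intercept+slopes covariance
    was estimated or the intercept-only fallback was used; BLUP vectors are
    always length 4 (slope entries zero under the fallback).
    """

    beta_fixed: np.ndarray  # (4,)
    random_cov: np.ndarray  # (4, 4), symmetric PSD
    blups: dict[str, np.ndarray]  # pef_key -> (4,)
    sigma2: float
    structure: str = "full"
    converged: bool = True
    se_fixed: np.ndarray | None = None  # (4,)
    column_names: tuple[str, ...] = DESIGN_COLUMNS


def fit_ols(dataset: PEFDataset) -> OLSModel:
    """Pooled least squares over all rows; deterministic."""
    dataset.require_design()
    try:
        beta, sigma2, se = weighted_least_squares(dataset.X, dataset.y)
    except np.linalg.LinAlgError:
        # identify which column is collinear with the others for the message
        X = dataset.X
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                raise np.linalg.LinAlgError(
                    f"design is rank deficient: column '{DESIGN_COLUMNS[j]}' is "
                    "collinear with the remaining columns"
                ) from None
        raise
    return OLSModel(beta=beta, sigma2=sigma2, se=se)


def _psd_ok(cov: np.ndarray) -> bool:
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    return bool(eig.min() > 1e-10 * max(eig.max(), 1.0))


def fit_mixed(dataset: PEFDataset) -> MixedModel:
    """REML fit of the random intercept + slopes model grouped by PEF.

    Falls back to an intercept-only random effect (with a log-worthy
    ``structure`` flag) when the unstructured 4x4 covariance estimate fails to
    converge or is singular.
    """
    dataset.require_design()
    if dataset.n_pefs < 2:
        raise ValueError("mixed model needs at least 2 PEFs")
    groups = dataset.df["pef_key"].to_numpy()

    def _fit(exog_re: np.ndarray):
        # try optimizers in turn ourselves: statsmodels' method list does not
        # shield against LinAlgError raised mid-optimization (e.g. a singular
        # profiled covariance when the true random effects are zero)
        last_err: Exception | None = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(dataset.y, dataset.X, groups=groups, exog_re=exog_re)
            for meth in ("lbfgs", "cg", "powell"):
                try:
                    return md.fit(reml=True, method=meth, maxiter=200)
                except (np.linalg.LinAlgError, ValueError) as err:
                    last_err = err
        raise np.linalg.LinAlgError(f"mixed-model fit failed: {last_err}")

    structure = "full"
    try:
        res = _fit(dataset.X)
        cov = np.asarray(res.cov_re)
        if not (res.converged and _psd_ok(cov)):
            raise np.linalg.LinAlgError("singular or non-converged covariance")
    except (np.linalg.LinAlgError, ValueError):
        structure = "intercept_only"
        res = _fit(dataset.X[:, :1])
        cov1 = float(np.asarray(res.cov_re).ravel()[0])
        cov = np.zeros((4, 4))
        cov[0, 0] = cov1

    blups: dict[str, np.ndarray] = {}
    for key, re_vec in res.random_effects.items():
        v = np.zeros(4)
        arr = np.asarray(re_vec, dtype=float).ravel()
        v[: arr.size] = arr
        blups[str(key)] = v

    return MixedModel(
        beta_fixed=np.asarray(res.fe_params, dtype=float),
        random_cov=cov,
        blups=blups,
        sigma2=float(res.scale),
        structure=structure,
        converged=bool(res.converged),
        se_fixed=np.asarray(res.bse_fe, dtype=float),
    )


def predict_baseline(model, pef_key: str | None, x: np.ndarray) -> tuple[float, bool]:
    """Predict one row's threshold; returns (prediction, fallback_used).

    OLS always uses the population coefficients (fallback flag False). The
    mixed model adds the PEF's BLUP when the PEF was seen in training and
    otherwise falls back to the fixed effects alone (flag True).
    """
    x = np.asarray(x, dtype=float)
    if isinstance(model, OLSModel):
        return float(model.beta @ x), False
    if isinstance(model, MixedModel):
        b = model.blups.get(pef_key)
        if b is None:
            return float(model.beta_fixed @ x), True
        return float((model.beta_fixed + b) @ x), False
    raise TypeError(f"unknown baseline model type {type(model)!r}")


def predict_baseline_rows(model, dataset: PEFDataset, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized predict_baseline over positional row indices of a dataset."""
    dataset.require_design()
    keys = dataset.df["pef_key"].to_numpy()
    preds = np.empty(len(rows))
    fallback = np.zeros(len(rows), dtype=bool)
    for i, r in enumerate(rows):
        preds[i], fallback[i] = predict_baseline(model, keys[r], dataset.X[r])
    return preds, fallback
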