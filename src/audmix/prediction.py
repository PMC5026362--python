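"""Mixture-model prediction: posterior-weighted regression and Bayes-rule
membership inference for unseen PEFs.

For a PEF seen in training, its membership posterior is retrieved from the
training responsibilities and the predicted threshold is the posterior-
weighted average of the per-cluster regression predictions. For a new PEF the
posterior is inferred from whatever observations are supplied —
p(cluster=k | rows) proportional to pi_k * L(rows | k) — without touching any
model parameter, so generalization to new patients requires no retraining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort_prep import PEFDataset
from .mixture_model import MixtureModel, Responsibilities, _row_log_density


@dataclass
class MembershipPosterior:
    """Posterior cluster membership of one PEF given its observed rows.

    With zero observations the posterior is exactly the mixing prior.
    """

    pef_key: str
    probs: np.ndarray
    n_obs_used: int


def infer_membership(
    model: MixtureModel,
    X_obs: np.ndarray | None,
    y_obs: np.ndarray | None,
    pef_key: str = "<new>",
) -> MembershipPosterior:
    """Bayes-rule membership inference for a (possibly unseen) PEF.

    probs_k proportional to pi_k * exp(joint log-likelihood of the observed
    rows under cluster k), normalized in log space; empty observations return
    the prior. Model parameters are never modified.
    """
    if X_obs is None or y_obs is None or len(np.atleast_1d(y_obs)) == 0:
        return MembershipPosterior(pef_key, model.mixing.copy(), 0)
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    y_obs = np.atleast_1d(np.asarray(y_obs, dtype=float))
    ll = _row_log_density(model, X_obs, y_obs).sum(axis=0)  # (k,)
    joint = ll + np.log(model.mixing)
    probs = np.exp(joint - logsumexp(joint))
    return MembershipPosterior(pef_key, probs, len(y_obs))


def predict_threshold(model: MixtureModel, posterior: np.ndarray | MembershipPosterior, x: np.ndarray) -> float:
    """Posterior-weighted prediction sum_k p_k * (beta_k . x) — a convex
    combination of the per-cluster regression predictions."""
    probs = posterior.probs if isinstance(posterior, MembershipPosterior) else np.asarray(posterior)
    if len(probs) != model.k:
        raise ValueError(f"posterior length {len(probs)} != k={model.k}")
    return float(probs @ (model.betas @ np.asarray(x, dtype=float)))


def _conditioning_rows(rows: np.ndarray, j_local: int, ages: np.ndarray, condition: str) -> np.ndarray:
    if condition == "all":
        return rows
    if condition == "loo":
        return np.delete(rows, j_local)
    if condition == "prefix":
        return rows[ages < ages[j_local]]
    raise ValueError(f"unknown conditioning mode {condition!r}")


def predict_for_task(
    model: MixtureModel,
    train_responsibilities: Responsibilities | None,
    test_dataset: PEFDataset,
    mode: str,
    condition: str = "loo",
) -> pd.DataFrame:
    """Predict every row of ``test_dataset`` under the mixture model.

    mode='known_pef': each test PEF's posterior is looked up from the training
    responsibilities (a PEF absent from training falls through to the new-PEF
    path and is flagged). mode='new_pef': the posterior is inferred by Bayes
    rule from the PEF's *other* test rows — all of them, leave-one-out, or the
    strictly-earlier prefix, per ``condition`` — and the model is never
    updated. A prediction made from the bare prior (no conditioning rows) is
    flagged.

    Returns one row per test observation: pef_key, age_years, observed_db,
    predicted_db, mode_used, fallback (known-PEF lookup missed),
    prior_only, n_conditioning, and the posterior used (p_1..p_k).
    """
    if mode not in {"known_pef", "new_pef"}:
        raise ValueError(f"unknown mode {mode!r}")
    test_dataset.require_design()
    train_post = train_responsibilities.as_dict() if train_responsibilities is not None else {}

    out_rows = []
    X, y = test_dataset.X, test_dataset.y
    ages_all = test_dataset.df["age_years"].to_numpy()
    for code, key in enumerate(test_dataset.pef_keys):
        rows = np.flatnonzero(test_dataset.pef_codes == code)
        ages = ages_all[rows]
        known = mode == "known_pef" and key in train_post
        for j_local, r in enumerate(rows):
            fallback = False
            prior_only = False
            if known:
                probs = train_post[key]
                n_cond = -1  # posterior from training, not from test rows
            else:
                fallback = mode == "known_pef"
                cond = _conditioning_rows(rows, j_local, ages, condition)
                post = infer_membership(model, X[cond], y[cond], key)
                probs = post.probs
                n_cond = post.n_obs_used
                prior_only = n_cond == 0
            pred = predict_threshold(model, probs, X[r])
            rec = {
                "pef_key": key,
                "age_years": float(ages_all[r]),
                "observed_db": float(y[r]),
                "predicted_db": pred,
                "mode_used": "known_pef" if known else "new_pef",
                "fallback": fallback,
                "prior_only": prior_only,
                "n_conditioning": n_cond,
            }
            for kk in range(model.k):
                rec[f"p_{kk + 1}"] = float(probs[kk])
            out_rows.append(rec)
    return pd.DataFrame(out_rows)
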