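import numpy as np
import pandas as pd
import pytest

from audmix.cohort_prep import prepare
from audmix.synthetic_data import GeneratorConfig, generate_cohort


def make_records(rows):
    """Build a record table from (pid, ear, cond, freq, age, gender, diag, thr) tuples."""
    cols = [
        "patient_id",
        "ear",
        "conduction",
        "frequency_hz",
        "age_years",
        "gender",
        "diag_count",
        "threshold_db",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def cluster_cohort():
    """Default three-cluster cohort (no random effects), 300 PEFs."""
    cfg = GeneratorConfig(n_pefs=300, seed=11)
    records, truth = generate_cohort(cfg)
    dataset, _ = prepare(records)
    return cfg, records, truth, dataset


@pytest.fixture(scope="session")
def random_effects_cohort():
    """Single-population cohort with strong per-PEF random intercept/slope."""
    cfg = GeneratorConfig(
        n_pefs=150,
        k_true=1,
        cluster_betas=((30.0, 1.0, 2.0, 0.3),),
        cluster_sigmas=(4.0,),
        mixing=(1.0,),
        random_effect_sd=(10.0, 2.0, 0.0, 0.0),
        seed=12,
    )
    records, truth = generate_cohort(cfg)
    dataset, _ = prepare(records)
    return cfg, records, truth, dataset


@pytest.fixture(scope="session")
def fitted_mixture(cluster_cohort):
    from audmix.mixture_model import fit_mixture

    _, _, truth, dataset = cluster_cohort
    model, resp, trace = fit_mixture(dataset, 3, seed=21)
    return dataset, truth, model, resp, trace
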