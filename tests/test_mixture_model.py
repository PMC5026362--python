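import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from audmix.baseline_models import fit_ols
from audmix.cohort_prep import prepare
from audmix.mixture_model import (
    MixtureModel,
    Responsibilities,
    e_step,
    fit_mixture,
    log_likelihood,
    m_step,
    pef_log_likelihood,
    select_k,
)
from audmix.prediction import predict_for_task
from audmix.evaluation import make_newpatient_split
from audmix.synthetic_data import GeneratorConfig, generate_cohort


def toy_model(betas, sigma2s, mixing):
    return MixtureModel(
        k=len(sigma2s), betas=np.array(betas, float),
        sigma2s=np.array(sigma2s, float), mixing=np.array(mixing, float),
    )


class TestPefLogLikelihood:
    def test_zero_residual_special_variance_gives_zero(self):
        # N(0; 0, 1/(2*pi)) has density exactly 1
        m = toy_model([[5, 0, 0, 0]], [1 / (2 * np.pi)], [1.0])
        x = np.array([[1.0, 0, 0, 0]])
        assert pef_log_likelihood(m, x, [5.0], 0) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_rows(self):
        m = toy_model([[5, 1, 0, 0], [10, -1, 0, 0]], [2.0, 3.0], [0.4, 0.6])
        X = np.array([[1, 0.5, 0, 0.1], [1, 1.5, 1, 0.2]])
        y = np.array([6.0, 5.0])
        total = pef_log_likelihood(m, X, y, 1)
        parts = sum(pef_log_likelihood(m, X[i : i + 1], y[i : i + 1], 1) for i in range(2))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_matches_scipy_density_product(self):
        rng = np.random.default_rng(0)
        m = toy_model([[20, 2, 1, 0.5], [40, -1, 0, 0.2]], [4.0, 9.0], [0.5, 0.5])
        X = np.column_stack([np.ones(3), rng.normal(size=3), rng.integers(0, 2, 3), rng.normal(size=3)])
        y = rng.normal(30, 10, size=3)
        for k in range(2):
            expected = stats.norm.logpdf(y, X @ m.betas[k], np.sqrt(m.sigma2s[k])).sum()
            assert pef_log_likelihood(m, X, y, k) == pytest.approx(expected, abs=1e-12)

    def test_empty_rows_rejected(self):
        m = toy_model([[0, 0, 0, 0]], [1.0], [1.0])
        with pytest.raises(ValueError):
            pef_log_likelihood(m, np.empty((0, 4)), [], 0)


class TestEStep:
    def test_identical_clusters_give_uniform_posterior(self, cluster_cohort):
        _, _, _, ds = cluster_cohort
        beta = np.array([30.0, 1.0, 2.0, 0.3])
        m = toy_model([beta, beta], [25.0, 25.0], [0.5, 0.5])
        resp = e_step(m, ds)
        np.testing.assert_allclose(resp.probs, 0.5, atol=1e-12)

    def test_on_line_pef_gets_decisive_posterior(self):
        m = toy_model([[10, 5, 0, 0], [60, -5, 0, 0]], [1.0, 1.0], [0.5, 0.5])
        cfg = GeneratorConfig(
            n_pefs=5, k_true=1, cluster_betas=((10.0, 5.0, 0.0, 0.0),),
            cluster_sigmas=(0.0,), mixing=(1.0,), seed=2,
        )
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        resp = e_step(m, ds)
        assert (resp.probs[:, 0] > 0.99).all()

    def test_matches_enumeration_oracle_small_instance(self):
        # 5 PEFs x 3 clusters against direct normalized product-density computation
        rng = np.random.default_rng(3)
        m = toy_model(rng.normal(20, 10, (3, 4)), [4.0, 6.0, 9.0], [0.2, 0.3, 0.5])
        cfg = GeneratorConfig(n_pefs=5, seed=4)
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        resp = e_step(m, ds)
        for code, key in enumerate(ds.pef_keys):
            rows = ds.rows_of(key)
            dens = np.array(
                [
                    m.mixing[k]
                    * np.prod(
                        stats.norm.pdf(ds.y[rows], ds.X[rows] @ m.betas[k], np.sqrt(m.sigma2s[k]))
                    )
                    for k in range(3)
                ]
            )
            np.testing.assert_allclose(resp.probs[code], dens / dens.sum(), atol=1e-10)

    def test_rows_sum_to_one(self, fitted_mixture):
        ds, _, model, resp, _ = fitted_mixture
        np.testing.assert_allclose(resp.probs.sum(axis=1), 1.0, atol=1e-10)
        assert (resp.probs >= 0).all()


class TestMStep:
    def test_hard_truth_responsibilities_recover_betas_exactly(self):
        cfg = GeneratorConfig(
            n_pefs=60, k_true=2,
            cluster_betas=((10.0, 5.0, 1.0, 0.5), (50.0, -2.0, 0.0, 0.1)),
            cluster_sigmas=(0.0, 0.0), mixing=(0.5, 0.5), seed=5,
        )
        records, truth = generate_cohort(cfg)
        ds, _ = prepare(records)
        R = np.zeros((ds.n_pefs, 2))
        for i, key in enumerate(ds.pef_keys):
            R[i, truth.pef_cluster[key]] = 1.0
        m = m_step(ds, Responsibilities(list(ds.pef_keys), R))
        np.testing.assert_allclose(m.betas, truth.cluster_betas, atol=1e-8)

    def test_uniform_responsibilities_give_pooled_ols_everywhere(self, cluster_cohort):
        _, _, _, ds = cluster_cohort
        R = np.full((ds.n_pefs, 2), 0.5)
        m = m_step(ds, Responsibilities(list(ds.pef_keys), R))
        pooled = fit_ols(ds)
        np.testing.assert_allclose(m.betas[0], pooled.beta, atol=1e-8)
        np.testing.assert_allclose(m.betas[1], pooled.beta, atol=1e-8)

    def test_empty_cluster_raises_naming_it(self, cluster_cohort):
        _, _, _, ds = cluster_cohort
        R = np.zeros((ds.n_pefs, 2))
        R[:, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="cluster 1"):
            m_step(ds, Responsibilities(list(ds.pef_keys), R))


class TestFitMixture:
    def test_k1_reduces_to_ols_exactly(self, cluster_cohort):
        _, _, _, ds = cluster_cohort
        model, resp, trace = fit_mixture(ds, 1, seed=0)
        pooled = fit_ols(ds)
        np.testing.assert_allclose(model.betas[0], pooled.beta, atol=1e-10)
        assert trace.converged
        np.testing.assert_array_equal(resp.probs, 1.0)

    def test_recovers_well_separated_clusters(self, fitted_mixture):
        ds, truth, model, resp, trace = fitted_mixture
        labels_true = [truth.pef_cluster[k] for k in resp.pef_keys]
        assert adjusted_rand_score(labels_true, resp.modal()) >= 0.95
        assert trace.converged

    def test_monotone_loglik(self, fitted_mixture):
        _, _, _, _, trace = fitted_mixture
        assert (np.diff(trace.loglik) >= -1e-8).all()

    def test_label_permutation_leaves_likelihood_and_predictions_unchanged(
        self, fitted_mixture
    ):
        ds, _, model, _, _ = fitted_mixture
        perm = np.array([2, 0, 1])
        permuted = MixtureModel(
            k=3, betas=model.betas[perm], sigma2s=model.sigma2s[perm],
            mixing=model.mixing[perm],
        )
        assert log_likelihood(permuted, ds) == pytest.approx(
            log_likelihood(model, ds), abs=1e-8
        )
        resp_a = e_step(model, ds)
        resp_b = e_step(permuted, ds)
        # posterior-weighted predictions are label-invariant
        pred_a = (resp_a.probs[ds.pef_codes] * model.cluster_means(ds.X)).sum(axis=1)
        pred_b = (resp_b.probs[ds.pef_codes] * permuted.cluster_means(ds.X)).sum(axis=1)
        np.testing.assert_allclose(pred_a, pred_b, atol=1e-8)

    def test_clusters_sorted_by_descending_age_slope(self, fitted_mixture):
        _, _, model, _, _ = fitted_mixture
        assert (np.diff(model.betas[:, 1]) <= 1e-12).all()

    def test_pruning_drops_tiny_cluster(self):
        # one generating cluster holds ~8% of PEFs; with the prune threshold
        # raised above that, the fit must drop it and renormalize
        cfg = GeneratorConfig(
            n_pefs=200, k_true=3,
            cluster_betas=((60.0, 3.0, 2.0, 0.5), (40.0, 0.5, 2.0, 0.3), (15.0, -1.5, 2.0, 0.1)),
            cluster_sigmas=(4.0, 4.0, 4.0), mixing=(0.46, 0.46, 0.08), seed=6,
        )
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        model, resp, trace = fit_mixture(ds, 3, n_starts=5, seed=1, prune_fraction=0.2)
        assert trace.pruned
        assert model.k < 3
        assert model.mixing.sum() == pytest.approx(1.0, abs=1e-10)
        assert resp.probs.shape[1] == model.k

    def test_overfit_cluster_pruned_at_default_threshold(self):
        # 8 components on a 6-cluster cohort small enough that a surplus
        # component ends below the 1%-of-PEFs heuristic
        b6 = tuple((10.0 + 15 * i, 2.5 - i, 2.0, 0.3) for i in range(6))
        cfg = GeneratorConfig(
            n_pefs=150, k_true=6, cluster_betas=b6, cluster_sigmas=(4.0,) * 6,
            mixing=(1 / 6,) * 6, seed=23,
        )
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        model, _, trace = fit_mixture(ds, 8, n_starts=5, seed=3)
        assert trace.pruned
        assert model.k < 8

    def test_json_round_trip(self, fitted_mixture):
        _, _, model, _, _ = fitted_mixture
        back = MixtureModel.from_json(model.to_json())
        np.testing.assert_allclose(back.betas, model.betas)
        np.testing.assert_allclose(back.mixing, model.mixing)
        assert back.k == model.k


class TestSelectK:
    @staticmethod
    def _heldout_scorer(test):
        def score(model, resp):
            p = predict_for_task(model, resp, test, mode="new_pef")
            return float(np.mean((p.predicted_db - p.observed_db) ** 2))

        return score

    def test_single_cluster_generator_chooses_one(self):
        cfg = GeneratorConfig(
            n_pefs=150, k_true=1, cluster_betas=((30.0, 1.0, 2.0, 0.3),),
            cluster_sigmas=(5.0,), mixing=(1.0,), seed=9,
        )
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        split = make_newpatient_split(ds, 0.25, seed=1)
        train, test = ds.subset(~split.test_mask), ds.subset(split.test_mask)
        k, _ = select_k(train, self._heldout_scorer(test), k_max=4, seed=3, n_starts=5)
        assert k == 1

    def test_three_cluster_generator_chooses_three(self):
        cfg = GeneratorConfig(n_pefs=300, seed=8)
        records, _ = generate_cohort(cfg)
        ds, _ = prepare(records)
        split = make_newpatient_split(ds, 0.25, seed=1)
        train, test = ds.subset(~split.test_mask), ds.subset(split.test_mask)
        k, table = select_k(train, self._heldout_scorer(test), k_max=6, seed=3, n_starts=5)
        assert k == 3
        # MSE improves (or plateaus) with k up to the chosen k
        mse = table["heldout_mse"].to_numpy()
        assert (np.diff(mse[:k]) < 0).all()
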