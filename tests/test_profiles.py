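"""EM mixture fitting, fit statistics, BLRT, model selection, description."""

import numpy as np
import pytest

from actiprofile import (
    MixtureConfig,
    ProfileSolution,
    blrt,
    describe_profiles,
    fit_mixture,
    fit_statistics,
    match_classes,
    select_profiles,
)
from actiprofile.profiles import _n_parameters


@pytest.fixture(scope="module")
def two_clusters():
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.3, size=(60, 3))
    b = rng.normal(4.0, 0.3, size=(40, 3))
    X = np.vstack([a, b])
    labels = np.array([0] * 60 + [1] * 40)
    return X, labels


class TestFitMixture:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(size=(50, 3))
        sol = fit_mixture(X, 1, MixtureConfig(seed=0))
        np.testing.assert_allclose(sol.means[0], X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sol.variances[0], X.var(axis=0), atol=1e-12)
        assert sol.weights[0] == 1.0 and sol.n_parameters == 6

    def test_separated_clusters_fully_recovered(self, two_clusters):
        X, labels = two_clusters
        sol = fit_mixture(X, 2, MixtureConfig(seed=0))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, sol.assignments) == 1.0

    def test_log_likelihood_nondecreasing(self, table_cohort_ilr):
        for K in (2, 3, 4):
            sol = fit_mixture(table_cohort_ilr, K, MixtureConfig(seed=K))
            assert np.all(np.diff(sol.ll_trace) >= -1e-7 * np.abs(sol.ll_trace[:-1]))

    def test_posteriors_and_weights_normalized(self, table_cohort_ilr):
        sol = fit_mixture(table_cohort_ilr, 4, MixtureConfig(seed=1))
        np.testing.assert_allclose(sol.posteriors.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(sol.weights.sum(), 1.0, atol=1e-9)
        assert np.all(sol.weights > 0)

    def test_free_diagonal_matches_sklearn_likelihood(self, two_clusters):
        # independent implementation cross-check on the same model class
        from sklearn.mixture import GaussianMixture

        X, _ = two_clusters
        ours = fit_mixture(X, 2, MixtureConfig(seed=0, variance_structure="free"))
        gm = GaussianMixture(2, covariance_type="diag", n_init=5, random_state=0,
                             reg_covar=1e-10, tol=1e-8, max_iter=1000).fit(X)
        sk_ll = gm.score(X) * len(X)
        assert abs(ours.log_likelihood - sk_ll) < 1e-3 * abs(sk_ll)

    def test_equal_structure_shares_variances(self, table_cohort_ilr):
        sol = fit_mixture(table_cohort_ilr, 3, MixtureConfig(seed=2))
        assert np.allclose(sol.variances, sol.variances[0])

    def test_needs_more_observations_than_classes(self):
        with pytest.raises(ValueError):
            fit_mixture(np.zeros((3, 3)), 3)

    def test_missing_values_rejected(self):
        X = np.full((10, 3), np.nan)
        with pytest.raises(ValueError):
            fit_mixture(X, 2)


class TestFitStatistics:
    def test_bic_formula_single_component(self, rng):
        X = rng.normal(size=(10, 3))
        sol = fit_mixture(X, 1, MixtureConfig(seed=0))
        st = fit_statistics(sol, X)
        assert st.bic == pytest.approx(-2 * sol.log_likelihood + 6 * np.log(10))
        assert st.aic == pytest.approx(-2 * sol.log_likelihood + 12)
        assert st.entropy == 1.0

    def test_entropy_endpoints(self):
        one_hot = np.zeros((8, 2))
        one_hot[:4, 0] = 1
        one_hot[4:, 1] = 1
        sol = ProfileSolution(
            K=2, means=np.zeros((2, 3)), variances=np.ones((2, 3)),
            weights=np.array([0.5, 0.5]), log_likelihood=-1.0,
            posteriors=one_hot, assignments=one_hot.argmax(axis=1),
            n_parameters=_n_parameters(2, 3, "equal"), converged=True,
        )
        assert fit_statistics(sol, np.zeros((8, 3))).entropy == pytest.approx(1.0)
        sol.posteriors = np.full((8, 2), 0.5)
        assert fit_statistics(sol, np.zeros((8, 3))).entropy == pytest.approx(0.0, abs=1e-12)

    def test_min_class_from_modal_assignments(self, two_clusters):
        X, _ = two_clusters
        sol = fit_mixture(X, 2, MixtureConfig(seed=0))
        st = fit_statistics(sol, X)
        assert st.min_class_n == 40
        assert st.min_class_frac == pytest.approx(0.4)

    def test_parameter_counts_by_structure(self):
        assert _n_parameters(4, 3, "equal") == 12 + 3 + 3
        assert _n_parameters(4, 3, "free") == 12 + 12 + 3


class TestBlrt:
    def test_p_value_in_unit_interval(self, rng):
        X = rng.normal(size=(60, 3))
        p = blrt(X, 2, MixtureConfig(seed=0, n_restarts=2), B=9, inner_restarts=1)
        assert 0 < p <= 1

    def test_strong_two_cluster_structure_minimal_p(self, two_clusters):
        X, _ = two_clusters
        B = 19
        p = blrt(X, 2, MixtureConfig(seed=0), B=B)
        assert p == pytest.approx(1 / (B + 1))

    def test_requires_k_at_least_two(self, rng):
        with pytest.raises(ValueError):
            blrt(rng.normal(size=(30, 3)), 1)


class TestSelectProfiles:
    def test_single_cluster_data_selects_one(self, rng):
        X = rng.normal(size=(120, 3))
        sol, table, note = select_profiles(
            X, K_range=range(1, 4), config=MixtureConfig(seed=0, n_restarts=3), B=19
        )
        assert sol.K == 1 and note == ""
        assert len(table) == 3

    def test_two_cluster_data_selects_two(self, two_clusters):
        X, _ = two_clusters
        # B must give a minimum attainable p below alpha: 1/(39+1) < 0.05
        sol, table, _ = select_profiles(
            X, K_range=range(1, 4), config=MixtureConfig(seed=0, n_restarts=3),
            B=39, min_class_n=10,
        )
        assert sol.K == 2

    def test_fit_table_bookkeeping(self, two_clusters):
        X, _ = two_clusters
        _, table, _ = select_profiles(
            X, K_range=range(1, 4), config=MixtureConfig(seed=1, n_restarts=2), B=9,
            min_class_n=10,
        )
        assert list(table["K"]) == [1, 2, 3]
        assert table["BLRT_p"].iloc[0] is None or np.isnan(table["BLRT_p"].iloc[0])
        assert table.loc[table.K > 1, "BLRT_p"].between(0, 1).all()

    def test_no_eligible_model_flagged(self, two_clusters):
        X, _ = two_clusters
        sol, _, note = select_profiles(
            X, K_range=[2], config=MixtureConfig(seed=0, n_restarts=2), B=9,
            min_class_n=90,  # impossible: forces the fallback
        )
        assert note == "no model met criteria"


class TestDescribeProfiles:
    def test_labels_relative_to_grand_mean(self, two_clusters):
        X, _ = two_clusters
        sol = fit_mixture(X, 2, MixtureConfig(seed=0))
        rep = describe_profiles(sol, kappa=100.0)
        assert set(rep.columns) >= {"sleep", "sb", "lpa", "mvpa", "sleep_label"}
        np.testing.assert_allclose(
            rep[["sleep", "sb", "lpa", "mvpa"]].sum(axis=1), 100.0, atol=1e-9
        )
        # the two classes sit on opposite sides of the overall mean
        assert {rep["mvpa_label"][0], rep["mvpa_label"][1]} == {"above", "below"}

    def test_class_at_reference_labeled_average(self, two_clusters):
        X, _ = two_clusters
        sol = fit_mixture(X, 2, MixtureConfig(seed=0))
        rep = describe_profiles(sol, kappa=100.0, reference_ilr=sol.means[0])
        assert all(rep.iloc[0][f"{p}_label"] == "average" for p in ("sleep", "sb", "lpa", "mvpa"))

    def test_labels_invariant_to_kappa(self, two_clusters):
        X, _ = two_clusters
        sol = fit_mixture(X, 2, MixtureConfig(seed=0))
        a = describe_profiles(sol, kappa=100.0)
        b = describe_profiles(sol, kappa=1440.0)
        for p in ("sleep", "sb", "lpa", "mvpa"):
            assert list(a[f"{p}_label"]) == list(b[f"{p}_label"])


class TestMatchClasses:
    def test_permutation_recovered(self):
        true = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([2, 2, 0, 0, 1, 1])
        np.testing.assert_array_equal(match_classes(true, pred), true)

    def test_identity_untouched(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        np.testing.assert_array_equal(match_classes(labels, labels), labels)
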