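import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from brainstates.io import RegionProfile
from brainstates.multistate import (
    GmmPrior,
    MultiStateTable,
    StateModel,
    binarize,
    classify_dataset,
    determine_prior,
    fit_vb_gmm,
    merge_overlapping_states,
    select_state_model,
    tune_alpha0,
    up_regions,
)
from brainstates.synthetic import SyntheticSpec, generate_dataset
from brainstates.io import collapse_replicates


def _profile(region_means, medvar=0.04):
    regions = list(region_means.columns)
    ev = pd.DataFrame(medvar, index=region_means.index, columns=regions)
    return RegionProfile(region_means, ev, ev.median(axis=1))


class TestDeterminePrior:
    def test_constant_error_variance_gives_reciprocal_mean_precision(self):
        rm = pd.DataFrame(np.full((10, 4), 7.0), columns=list("abcd"))
        prior = determine_prior(_profile(rm, 0.04))
        assert prior.a0 / prior.b0 == pytest.approx(25.0)

    def test_moment_matching_arithmetic(self):
        # precisions {10, 20, 30}: mean 20, population variance 200/3
        rm = pd.DataFrame(np.full((3, 4), 7.0), index=list("xyz"), columns=list("abcd"))
        ev = pd.DataFrame(
            np.array([[0.1], [0.05], [1 / 30.0]]) * np.ones((1, 4)),
            index=list("xyz"),
            columns=list("abcd"),
        )
        prof = RegionProfile(rm, ev, ev.median(axis=1))
        prior = determine_prior(prof)
        assert prior.a0 == pytest.approx(6.0)
        assert prior.b0 == pytest.approx(0.3)

    def test_m0_is_grand_mean(self):
        rng = np.random.default_rng(0)
        rm = pd.DataFrame(rng.normal(7.5, 1, (20, 6)))
        rm -= rm.to_numpy().mean() - 7.5
        prior = determine_prior(_profile(rm))
        assert prior.m0 == pytest.approx(7.5)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GmmPrior(alpha0=0.0)

    def test_all_zero_variances_advise_explicit_prior(self):
        rm = pd.DataFrame(np.full((5, 4), 7.0), columns=list("abcd"))
        with pytest.raises(ValueError, match="explicit"):
            determine_prior(_profile(rm, 0.0))


def _k1_elbo_oracle(x, prior, fit):
    """Numerically integrate the K=1 variational bound over q(mu, lambda)."""
    beta, m, a, b = fit.beta[0], fit.m[0], fit.a[0], fit.b[0]

    def integrand(mu, lam):
        q = stats.norm.pdf(mu, m, 1 / np.sqrt(beta * lam)) * stats.gamma.pdf(
            lam, a, scale=1 / b
        )
        log_lik = stats.norm.logpdf(x, mu, 1 / np.sqrt(lam)).sum()
        log_prior = stats.norm.logpdf(
            mu, prior.m0, 1 / np.sqrt(prior.beta0 * lam)
        ) + stats.gamma.logpdf(lam, prior.a0, scale=1 / prior.b0)
        log_q = stats.norm.logpdf(mu, m, 1 / np.sqrt(beta * lam)) + stats.gamma.logpdf(
            lam, a, scale=1 / b
        )
        return q * (log_lik + log_prior - log_q)

    lam_lo = stats.gamma.ppf(1e-12, a, scale=1 / b)
    lam_hi = stats.gamma.ppf(1 - 1e-12, a, scale=1 / b)
    val, err = integrate.dblquad(
        integrand,
        lam_lo,
        lam_hi,
        lambda lam: m - 12 / np.sqrt(beta * lam),
        lambda lam: m + 12 / np.sqrt(beta * lam),
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return val


class TestFitVbGmm:
    def test_constant_profile_collapses_to_one_state(self, default_prior):
        fit = fit_vb_gmm(np.full(48, 6.0), default_prior, K=6)
        assert len(np.unique(fit.assignments())) == 1

    def test_two_cluster_recovery_matches_em_oracle(self, default_prior):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(4, 0.2, 24), rng.normal(8, 0.2, 24)])
        fit = fit_vb_gmm(x, default_prior, K=2)
        means = np.sort(fit.means)
        assert means == pytest.approx([4, 8], abs=0.1)
        assert np.sort(fit.weights) == pytest.approx([0.5, 0.5], abs=0.05)
        from sklearn.mixture import GaussianMixture

        em = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(
            means, np.sort(em.means_.ravel()), atol=0.1
        )

    def test_responsibilities_and_weights_normalize(self, default_prior):
        rng = np.random.default_rng(11)
        for K in (1, 3, 6):
            x = rng.normal(8, 2, 48)
            fit = fit_vb_gmm(x, default_prior, K=K, seed=K)
            np.testing.assert_allclose(fit.resp.sum(axis=1), 1.0, atol=1e-10)
            assert fit.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_elbo_monotone_on_random_profiles(self, default_prior):
        rng = np.random.default_rng(12)
        for _ in range(25):
            x = rng.normal(rng.uniform(4, 10), rng.uniform(0.1, 2.0), 48)
            K = int(rng.integers(1, 7))
            fit = fit_vb_gmm(x, default_prior, K=K, seed=3)
            assert (np.diff(fit.elbo_trace) >= -1e-8).all()

    def test_k1_elbo_matches_numerical_integration(self, default_prior):
        rng = np.random.default_rng(13)
        x = rng.normal(7, 0.5, 10)
        fit = fit_vb_gmm(x, default_prior, K=1)
        assert fit.converged
        oracle = _k1_elbo_oracle(x, default_prior, fit)
        assert fit.elbo == pytest.approx(oracle, abs=1e-6)

    def test_init_order_permutation_does_not_change_state_model(self, default_prior):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(4, 0.3, 20), rng.normal(9, 0.3, 28)])
        inits = np.array([4.0, 9.0])
        regions = [f"r{i}" for i in range(48)]
        models = []
        for perm in (inits, inits[::-1]):
            fit = fit_vb_gmm(x, default_prior, K=2, init_means=perm)
            from brainstates.multistate import _build_state_model

            models.append(
                _build_state_model(regions, fit.means, fit.sigmas,
                                   fit.assignments(), c_merge=2.0)
            )
        assert models[0].state_means == pytest.approx(models[1].state_means)
        np.testing.assert_array_equal(models[0].assignment, models[1].assignment)

    def test_bad_inputs_rejected(self, default_prior):
        with pytest.raises(ValueError):
            fit_vb_gmm(np.ones(10), default_prior, K=0)
        with pytest.raises(ValueError):
            fit_vb_gmm(np.array([1.0, np.nan]), default_prior, K=1)


class TestStateModelSelection:
    def test_planted_three_states_recovered(self, default_prior):
        rng = np.random.default_rng(20)
        x = np.concatenate(
            [rng.normal(4, 0.2, 16), rng.normal(7, 0.2, 16), rng.normal(10, 0.2, 16)]
        )
        model = select_state_model(x, default_prior, seed=5)
        assert model.n_states == 3
        assert model.state_means == pytest.approx([4, 7, 10], abs=0.15)

    def test_one_state_profile_stays_one_state(self, default_prior):
        rng = np.random.default_rng(21)
        model = select_state_model(rng.normal(8, 0.4, 48), default_prior, seed=5)
        assert model.n_states == 1

    def test_selection_agrees_with_em_bic_oracle(self, default_prior):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(22)
        for true_k in (2, 3):
            means = 4 + 3.0 * np.arange(true_k)
            sizes = np.full(true_k, 48 // true_k)
            sizes[-1] += 48 - sizes.sum()
            x = np.concatenate(
                [rng.normal(m, 0.2, s) for m, s in zip(means, sizes)]
            )
            model = select_state_model(x, default_prior, seed=6)
            bics = [
                GaussianMixture(k, n_init=3, random_state=0)
                .fit(x[:, None])
                .bic(x[:, None])
                for k in range(1, 5)
            ]
            assert model.n_states == int(np.argmin(bics)) + 1 == true_k

    def test_nested_components_merge_into_one_state(self):
        groups = merge_overlapping_states([5.0, 5.2], [1.0, 0.1], c=2.0)
        assert groups == [[0, 1]]

    def test_merge_is_transitive(self):
        # a-b overlap and b-c overlap: all three merge although a-c are far
        groups = merge_overlapping_states([0.0, 1.5, 3.0], [1.0, 1.0, 1.0], c=2.0)
        assert groups == [[0, 1, 2]]

    def test_separated_components_stay_apart(self):
        groups = merge_overlapping_states([4.0, 9.0], [0.3, 0.3], c=2.0)
        assert groups == [[0], [1]]


class TestBinarize:
    def _model(self, assignment, means):
        return StateModel(
            region_ids=tuple(f"r{i}" for i in range(len(assignment))),
            state_means=tuple(means),
            assignment=np.array(assignment),
        )

    def test_three_state_rule(self):
        model = self._model([0, 0, 1, 1, 2], [3.0, 6.0, 9.0])
        labels = binarize(model)
        assert {r for r, l in labels.items() if l == "up"} == {"r2", "r3", "r4"}
        assert {r for r, l in labels.items() if l == "down"} == {"r0", "r1"}

    def test_two_state_up_is_high(self):
        model = self._model([0, 1, 0], [3.0, 9.0])
        assert up_regions(model) == {"r1"}

    def test_one_state_raises(self):
        with pytest.raises(ValueError):
            binarize(self._model([0, 0], [5.0]))

    def test_up_region_count_contributes_to_totals(self):
        # a probe with 14 of 48 regions in non-lowest states adds 14 to U
        assignment = [1] * 10 + [2] * 4 + [0] * 34
        model = self._model(assignment, [3.0, 6.0, 9.0])
        assert len(up_regions(model)) == 14


class TestClassifyDataset:
    def test_one_state_only_dataset_has_zero_totals(self, default_prior):
        rng = np.random.default_rng(30)
        rm = pd.DataFrame(
            rng.normal(8, 0.3, (30, 48)),
            index=[f"P{i}" for i in range(30)],
            columns=[f"r{i}" for i in range(48)],
        )
        table = classify_dataset(_profile(rm), default_prior, seed=1)
        assert table.G == 0 and table.U == 0

    def test_toy_up_region_totals(self):
        # two single-probe genes with 3 and 11 up regions: U = 14, G = 2
        regions = tuple(f"r{i}" for i in range(48))
        models = {}
        recs = []
        for pid, n_up in (("P1", 3), ("P2", 11)):
            assignment = np.array([1] * n_up + [0] * (48 - n_up))
            models[pid] = StateModel(regions, (3.0, 9.0), assignment)
            recs.append((pid, pid.replace("P", "G"), 2, up_regions(models[pid])))
        probes = pd.DataFrame(
            recs, columns=["probe_id", "gene", "n_states", "up_regions"]
        ).set_index("probe_id")
        table = MultiStateTable(probes=probes, models=models, region_ids=regions)
        assert table.U == 14
        assert table.G == 2

    def test_gene_aggregation_unions_probe_up_regions(self, default_prior):
        rng = np.random.default_rng(31)
        # two probes of one gene, up in disjoint region sets
        x1 = np.where(np.arange(48) < 5, 11.0, 5.0) + rng.normal(0, 0.2, 48)
        x2 = np.where((np.arange(48) >= 5) & (np.arange(48) < 9), 11.0, 5.0) + rng.normal(0, 0.2, 48)
        rm = pd.DataFrame(
            [x1, x2], index=["Pa", "Pb"], columns=[f"r{i}" for i in range(48)]
        )
        from brainstates.io import ProbeAnnotation

        ann = ProbeAnnotation.from_probe_ids(["Pa", "Pb"], {"Pa": "G1", "Pb": "G1"})
        table = classify_dataset(_profile(rm), default_prior, annotation=ann, seed=2)
        assert table.G == 1
        assert len(table.gene_up_regions("G1")) == 9
        assert table.U == 9


class TestTuneAlpha0:
    def _small(self):
        spec = SyntheticSpec(
            class_counts={"one_state_stable": 15, "one_state_variable": 5,
                          "k2": 15, "k3": 5, "k4": 0, "k5": 0, "k6": 0},
            n_pathways=1, n_controls=0, seed=40,
        )
        ds = generate_dataset(spec)
        profile = collapse_replicates(ds.expression.drop_controls())
        truth_multi = set(ds.truth.probes.index[ds.truth.probes["true_k"] >= 2])
        return profile, truth_multi

    def test_single_value_grid_returns_it(self, default_prior):
        profile, truth = self._small()
        best, curve = tune_alpha0(profile, truth, [0.7], default_prior, n_restarts=2)
        assert best == 0.7
        assert len(curve) == 1

    def test_returns_grid_argmin_of_error_sum(self, default_prior):
        profile, truth = self._small()
        grid = [0.01, 1.0, 10.0]
        best, curve = tune_alpha0(profile, truth, grid, default_prior, n_restarts=2)
        assert best == curve.loc[curve["sum"].idxmin(), "alpha0"]
        assert set(curve["alpha0"]) == set(grid)

    def test_degenerate_all_true_reference_selects_most_sensitive(self, default_prior):
        profile, _ = self._small()
        all_probes = set(profile.probe_ids)
        best, curve = tune_alpha0(
            profile, all_probes, [0.5, 2.0], default_prior, n_restarts=2
        )
        assert (curve["fpr"] == 0).all()  # no negatives exist
        assert best == curve.loc[curve["fnr"].idxmin(), "alpha0"]

    def test_empty_inputs_error(self, default_prior):
        profile, truth = self._small()
        with pytest.raises(ValueError):
            tune_alpha0(profile, truth, [], default_prior)
        with pytest.raises(ValueError):
            tune_alpha0(profile, set(), [1.0], default_prior)
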