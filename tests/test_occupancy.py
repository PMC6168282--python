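"""MVB occupancy model: cells, likelihood oracle, MCMC recovery, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from urbanwild import occupancy, simulate
from urbanwild.occupancy import OccupancyModelSpec

from conftest import make_sites


def brute_force_site_likelihood(y, cell_probs, p, effort=None):
    """Independent oracle: explicit sum over all 2^S latent states."""
    y = np.atleast_2d(np.asarray(y, float))
    S, K = y.shape
    p = np.asarray(p, float)
    if p.ndim == 1:
        p = np.repeat(p[:, None], K, axis=1)
    eff = np.ones((S, K)) if effort is None else np.broadcast_to(np.asarray(effort, float), (S, K))
    total = 0.0
    for m, z in enumerate(itertools.product([1, 0], repeat=S)):
        term = cell_probs[m]
        for s in range(S):
            for k in range(K):
                if not eff[s, k]:
                    continue
                if z[s] == 1:
                    term *= p[s, k] if y[s, k] else (1 - p[s, k])
                elif y[s, k]:
                    term = 0.0
        total += term
    return total


class TestNaturalToCell:
    def test_zero_parameters_uniform(self):
        np.testing.assert_allclose(occupancy.natural_to_cell(0, 0, 0), 0.25)

    def test_independence_factorization(self, rng):
        for _ in range(20):
            f1, f2 = rng.normal(size=2)
            c = occupancy.natural_to_cell(f1, f2, 0.0)
            psi11, psi10, psi01, psi00 = c
            assert psi11 == pytest.approx((psi11 + psi10) * (psi11 + psi01), abs=1e-12)
            # marginals are the single-species logits
            assert psi11 + psi10 == pytest.approx(expit(f1), abs=1e-12)

    def test_hand_softmax(self):
        e = np.array([1 - 1 + 0.5, 1.0, -1.0, 0.0])
        expected = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(occupancy.natural_to_cell(1.0, -1.0, 0.5), expected, atol=1e-12)

    def test_overflow_safe(self):
        c = occupancy.natural_to_cell(800.0, -800.0, 0.0)
        assert np.all(np.isfinite(c))
        assert c.sum() == pytest.approx(1.0)

    def test_cells_sum_to_one(self, rng):
        for _ in range(50):
            c = occupancy.natural_to_cell(*rng.normal(scale=3, size=3))
            assert c.sum() == pytest.approx(1.0, abs=1e-12)


class TestSiteLikelihood:
    def test_single_species_detected(self):
        assert occupancy.site_likelihood([[1, 0]], [0.5, 0.5], [0.5]) == pytest.approx(0.125)

    def test_single_species_all_zero(self):
        # psi * (1-p)^2 + (1 - psi)
        assert occupancy.site_likelihood([[0, 0]], [0.5, 0.5], [0.5]) == pytest.approx(0.625)

    def test_two_species_enumeration_example(self):
        val = occupancy.site_likelihood(
            [[1, 0], [0, 0]], [0.2, 0.3, 0.1, 0.4], [0.6, 0.5]
        )
        assert val == pytest.approx(0.2 * (0.6 * 0.4) * (0.5 * 0.5) + 0.3 * (0.6 * 0.4))

    def test_matches_brute_force_on_random_instances(self, rng):
        # optimized implementation vs independent 2^S enumeration, S <= 3
        for _ in range(200):
            S = int(rng.integers(1, 4))
            K = int(rng.integers(1, 6))
            y = (rng.random((S, K)) < 0.4).astype(float)
            cells, _ = occupancy.joint_state_probs(
                rng.normal(size=(1, S)), rng.normal(size=(S, S))
            )
            p = rng.uniform(0.05, 0.95, size=(S, K))
            a = occupancy.site_likelihood(y, cells[0], p)
            b = brute_force_site_likelihood(y, cells[0], p)
            assert a == pytest.approx(b, abs=1e-12)

    def test_independence_reduces_to_product(self, rng):
        # f12 = 0: joint likelihood equals the product of single-species ones
        for _ in range(50):
            K = 4
            y = (rng.random((2, K)) < 0.4).astype(float)
            f1, f2 = rng.normal(size=2)
            cells = occupancy.natural_to_cell(f1, f2, 0.0)
            p = rng.uniform(0.1, 0.9, 2)
            joint = occupancy.site_likelihood(y, cells, p)
            prod = 1.0
            for s, f in enumerate((f1, f2)):
                psi = expit(f)
                prod *= occupancy.site_likelihood(y[s : s + 1], [psi, 1 - psi], [p[s]])
            assert joint == pytest.approx(prod, abs=1e-12)

    def test_per_occasion_p_and_effort_mask(self, rng):
        y = np.array([[1.0, 0.0, 0.0]])
        p = np.array([[0.3, 0.6, 0.9]])
        eff = np.array([1.0, 1.0, 0.0])
        val = occupancy.site_likelihood(y, [0.7, 0.3], p, effort=eff)
        assert val == pytest.approx(0.7 * 0.3 * 0.4)


def _single_species_survey(psi, p, n, K, seed, sd_re=0.0):
    logit = lambda q: float(np.log(q / (1 - q)))
    cfg = simulate.ScenarioConfig(
        species=[
            simulate.SpeciesParams(
                name="x", occ_intercept=logit(psi), det_intercept=logit(p),
                detection_random_sd=sd_re,
            )
        ],
        n_sites_per_cell=2, n_days=K, seed=seed,
    )
    sites = make_sites(n, n_days=K)
    history, truth = simulate.simulate_occupancy_survey(cfg, sites)
    return sites, history, truth


class TestFitMCMC:
    def test_intercept_only_recovery(self):
        psi, p = 0.6, 0.4
        sites, history, _ = _single_species_survey(psi, p, 400, 21, seed=21)
        spec = OccupancyModelSpec(species=["x"])
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=300, iters=300, seed=1)
        assert float(draws.rhat().max()) <= 1.1
        for name, truth in [("occ[x]:intercept", np.log(psi / (1 - psi))),
                            ("det[x]:intercept", np.log(p / (1 - p)))]:
            d = draws.param(name)
            assert abs(d.mean() - truth) < 3 * d.std()

    def test_flat_data_pulls_psi_below_prior_mean(self):
        sites = make_sites(150, n_days=21)
        import urbanwild.data as data

        hist = data.build_detection_history(
            pd.DataFrame(columns=["site_id", "timestamp", "species", "animal_count"]),
            sites, species=["x"],
        )
        spec = OccupancyModelSpec(species=["x"])
        draws = occupancy.fit_mcmc(spec, hist, sites, warmup=200, iters=200, seed=2)
        # prior mean of the occupancy intercept is 0 (psi = 0.5)
        assert draws.param("occ[x]:intercept").mean() < -1.0

    def test_posterior_stable_under_more_iterations(self):
        sites, history, _ = _single_species_survey(0.5, 0.45, 250, 14, seed=31)
        spec = OccupancyModelSpec(species=["x"])
        a = occupancy.fit_mcmc(spec, history, sites, warmup=250, iters=250, seed=3)
        b = occupancy.fit_mcmc(spec, history, sites, warmup=250, iters=500, seed=4)
        for name in a.names:
            mc_se = a.param(name).std() / 8  # generous Monte-Carlo allowance
            assert abs(a.param(name).mean() - b.param(name).mean()) < max(6 * mc_se, 0.05)

    def test_random_effect_species_adds_parameter(self):
        sites, history, _ = _single_species_survey(0.6, 0.4, 80, 10, seed=5, sd_re=0.5)
        spec = OccupancyModelSpec(species=["x"], random_effect_species=["x"])
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=150, iters=150, seed=5)
        assert "log_sd_det[x]" in draws.names
        assert np.all(np.isfinite(draws.draws))

    def test_duplicated_design_column_rejected(self, small_survey):
        sites, history, _ = small_survey
        sites = sites.assign(dup=sites["core_forest_5km"])
        spec = OccupancyModelSpec(species=["coyote"], occ_covariates=["core_forest_5km", "dup"])
        with pytest.raises(ValueError, match="rank-deficient"):
            occupancy.fit_mcmc(spec, history, sites, warmup=10, iters=10, seed=0)


class TestDesign:
    def test_columns_mean_centered(self, small_survey):
        sites, _, _ = small_survey
        X, names, _ = occupancy.build_design(sites, ["core_forest_5km", "housing_density"])
        assert np.all(np.abs(X[:, 1:].mean(axis=0)) < 1e-10)

    def test_restrictive_prior_flag_follows_correlation_rule(self):
        cfg = simulate.ScenarioConfig(
            species=[simulate.SpeciesParams(name="x")],
            n_sites_per_cell=40,
            correlated_pair=("core_forest_5km", "forest_100m", 0.87),
            seed=8,
        )
        sites = simulate.simulate_sites(cfg)
        _, names, restr = occupancy.build_design(
            sites, ["core_forest_5km", "forest_100m", "detection_distance"]
        )
        assert restr[names.index("core_forest_5km")]
        assert restr[names.index("forest_100m")]
        assert not restr[names.index("detection_distance")]


class TestMarginalOccupancy:
    def test_cells_sum_to_one_per_draw_and_site(self, small_survey):
        sites, history, _ = small_survey
        spec = OccupancyModelSpec(species=["coyote", "red_fox"], estimate_interactions=True)
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=100, iters=100, seed=6)
        post = occupancy._OccupancyPosterior(spec, history, sites)
        for t in range(0, draws.draws.shape[0], 200):
            B, _, f12, _ = post.unpack(draws.draws[t])
            probs, _ = occupancy.joint_state_probs(post.X_occ @ B.T, f12)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_independence_marginal_equals_logit_inverse(self, small_survey):
        sites, history, _ = small_survey
        spec = OccupancyModelSpec(species=["coyote", "red_fox"])
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=100, iters=100, seed=7)
        post = occupancy._OccupancyPosterior(spec, history, sites)
        B, _, f12, _ = post.unpack(draws.draws[0])
        probs, states = occupancy.joint_state_probs(post.X_occ @ B.T, f12)
        psi1_marg = probs[:, states[:, 0] == 1].sum(axis=1)
        np.testing.assert_allclose(psi1_marg, expit(post.X_occ @ B[0]), atol=1e-12)

    def test_unsampled_stratum_absent(self, small_survey):
        sites, history, _ = small_survey
        spec = OccupancyModelSpec(species=["coyote"])
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=100, iters=100, seed=8)
        marg = occupancy.marginal_occupancy(spec, draws, history, sites)
        combos = set(zip(marg["development_level"], marg["plot_type"]))
        assert ("wild", "yard") not in combos
        assert ("urban", "yard") not in combos

    def test_stratum_recovery_within_credible_intervals(self):
        # stratum-specific psi reproduced at n = 800 sites
        n, K = 800, 21
        rng = np.random.default_rng(77)
        sites = make_sites(n, n_days=K)
        half = n // 2
        sites.loc[half:, "development_level"] = "rural"
        sites.loc[half:, "housing_density"] = 5.0
        sites["is_rural"] = (sites["development_level"] == "rural").astype(float)
        psi = np.where(sites["is_rural"] == 1, 0.7, 0.4)
        p = 0.35
        z = rng.random(n) < psi
        Y = ((rng.random((1, n, K)) < p) & z[None, :, None]).astype(np.uint8)
        import urbanwild.data as data

        history = data.DetectionHistory(
            species=["x"], sites=sites["site_id"].tolist(), Y=Y, effort=np.ones((n, K), bool)
        )
        spec = OccupancyModelSpec(species=["x"], occ_covariates=["is_rural"])
        draws = occupancy.fit_mcmc(spec, history, sites, warmup=300, iters=300, seed=9)
        marg = occupancy.marginal_occupancy(
            spec, draws, history, sites, strata=["development_level"]
        )
        for level, true_psi in [("wild", 0.4), ("rural", 0.7)]:
            row = marg[(marg["development_level"] == level)].iloc[0]
            assert row["psi_lo"] - 0.03 <= true_psi <= row["psi_hi"] + 0.03


class TestSignificanceReport:
    def _draws(self, values):
        arr = np.asarray(values)[None, :, None]
        arr = np.concatenate([arr, arr], axis=0)
        return occupancy.PosteriorDraws(names=["beta"], chains=arr)

    def test_all_positive_significant(self, rng):
        rep = occupancy.significance_report(self._draws(rng.uniform(0.5, 1.5, 200)))
        assert bool(rep.loc[0, "significant"])
        assert rep.loc[0, "mean"] > 0

    def test_symmetric_not_significant(self, rng):
        rep = occupancy.significance_report(self._draws(rng.normal(0, 1, 500)))
        assert not bool(rep.loc[0, "significant"])

    def test_non_converged_flagged_not_significant(self):
        chains = np.stack([np.full((200, 1), -5.0), np.full((200, 1), 5.0)])
        chains = chains + np.random.default_rng(0).normal(0, 0.1, chains.shape)
        rep = occupancy.significance_report(
            occupancy.PosteriorDraws(names=["beta"], chains=chains)
        )
        assert not bool(rep.loc[0, "converged"])
        assert not bool(rep.loc[0, "significant"])

    def test_strong_effect_power(self):
        # |beta| = 1.5 on a binary covariate, n = 800: detected in >= 90% of
        # seeded replicates (scaled to 10 here; the acceptance suite carries
        # the heavier experiments)
        n_detected = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n, K = 800, 14
            sites = make_sites(n, n_days=K)
            sites["x1"] = rng.integers(0, 2, n).astype(float)
            eta = -0.5 + 1.5 * sites["x1"].to_numpy()
            z = rng.random(n) < expit(eta)
            Y = ((rng.random((1, n, K)) < 0.35) & z[None, :, None]).astype(np.uint8)
            import urbanwild.data as data

            history = data.DetectionHistory(
                species=["x"], sites=sites["site_id"].tolist(), Y=Y,
                effort=np.ones((n, K), bool),
            )
            spec = OccupancyModelSpec(species=["x"], occ_covariates=["x1"])
            draws = occupancy.fit_mcmc(spec, history, sites, warmup=250, iters=250, seed=r)
            rep = occupancy.significance_report(draws).set_index("parameter")
            row = rep.loc["occ[x]:x1"]
            n_detected += bool(row["significant"]) and row["mean"] > 0
        assert n_detected >= 9
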