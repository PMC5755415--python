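"""BYM smoothing model: posterior correctness, diagnostics, classification."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cariesmap as cm
from cariesmap.mapping import connectivity_report, validate_graph


def make_counts(ids, observed, expected):
    return pd.DataFrame(
        {"parish_id": ids, "observed": observed, "expected": expected}
    )


def quadrature_poisson_lognormal(O, E, alpha, sigma_v, n_grid=4001):
    """Independent oracle: posterior of theta = exp(alpha + v) for a single
    Poisson count with a fixed N(0, sigma_v^2) prior on v, by dense grid
    integration; returns (posterior median of theta, Pr(theta > 1))."""
    grid = np.linspace(-5, 5, n_grid)
    logpost = -0.5 * (grid / sigma_v) ** 2 + O * (alpha + grid) - E * np.exp(alpha + grid)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    median_theta = float(np.exp(alpha + np.interp(0.5, cdf, grid)))
    pr = float(w[np.exp(alpha + grid) > 1.0].sum())
    return median_theta, pr


class TestGraph:
    def test_edge_list_round_trip(self, tmp_path, small_region):
        path = tmp_path / "edges.csv"
        cm.mapping.write_edge_list(small_region.graph, path)
        back = cm.mapping.load_edge_list(path)
        assert set(back.edges()) == set(small_region.graph.edges())

    def test_missing_parish_rejected(self, small_region):
        with pytest.raises(ValueError, match="ZZZ"):
            validate_graph(small_region.graph, ["P01", "ZZZ"])

    def test_connectivity_report_flags_islands(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        rep = connectivity_report(g)
        assert rep["n_components"] == 2
        assert rep["islands"] == ["C"]
        assert not rep["connected"]


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self, rng):
        chain = rng.standard_normal(500)
        assert cm.gelman_rubin(np.stack([chain, chain])) == 1.0

    def test_disjoint_chains_diverge(self, rng):
        a = rng.standard_normal(500)
        assert cm.gelman_rubin(np.stack([a, a + 10.0])) > 1.5

    def test_iid_normal_chains_converge(self):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((4, 5000))
        assert cm.gelman_rubin(chains) < 1.01

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="unequal"):
            cm.check_convergence({"x": [rng.standard_normal(100), rng.standard_normal(99)]})


class TestExceedance:
    def test_all_above_one(self):
        assert cm.exceedance(np.full(200, 1.5)) == 1.0

    def test_symmetric_about_one(self, rng):
        draws = np.concatenate([1 + rng.random(500), 1 - rng.random(500) * 0.5])
        assert cm.exceedance(draws) == pytest.approx(0.5, abs=0.05)

    def test_matches_lognormal_tail(self):
        # theta ~ LogNormal(mu, s): Pr(theta > 1) = Phi(mu/s)
        rng = np.random.default_rng(3)
        mu, s = 0.2, 0.5
        draws = np.exp(mu + s * rng.standard_normal(1000))
        expected = stats.norm.cdf(mu / s)
        mc_err = 3 * np.sqrt(expected * (1 - expected) / 1000)
        assert cm.exceedance(draws) == pytest.approx(expected, abs=mc_err)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            cm.exceedance(np.ones(99))


class TestClassifyCertainty:
    @pytest.mark.parametrize(
        "pr, expected",
        [
            (0.96, "elevated"),   # red
            (0.03, "lowered"),    # green
            (0.95, "uncertain"),  # boundary is strict
            (0.05, "uncertain"),
            (0.50, "uncertain"),
        ],
    )
    def test_three_color_rule(self, pr, expected):
        assert cm.classify_certainty(pr) == expected

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            cm.classify_certainty(0.9, threshold=0.4)


class TestFitBym:
    def test_null_data_shrinks_to_one(self, fast_mcmc):
        g = cm.make_lattice(3, 3)
        counts = make_counts(sorted(g.nodes()), [20] * 9, [20.0] * 9)
        post = cm.fit_bym(counts, g, cm.MCMCConfig(**fast_mcmc))
        assert post.table["smrr"].between(0.8, 1.2).all()
        assert post.table["pr_exceed"].between(0.2, 0.8).all()

    def test_matches_quadrature_oracle_without_spatial_effect(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        counts = make_counts(["A", "B"], [8, 25], [15.0, 18.0])
        post = cm.fit_bym(
            counts,
            g,
            cm.MCMCConfig(
                n_chains=4,
                n_iterations=20_000,
                n_burnin=5_000,
                seed=7,
                sigma_u_fixed=0.0,
                sigma_v_fixed=0.7,
                alpha_fixed=0.0,
            ),
        )
        for _, row in post.table.iterrows():
            med, pr = quadrature_poisson_lognormal(
                row["observed"], row["expected"], 0.0, 0.7
            )
            assert row["smrr"] == pytest.approx(med, abs=5e-3)
            assert row["pr_exceed"] == pytest.approx(pr, abs=0.02)

    def test_recovers_true_risk_surface(self, small_region, fitted_small):
        _, mapper = fitted_small
        corr = np.corrcoef(small_region.true_rr, mapper.summary_["smrr"])[0, 1]
        assert corr >= 0.8

    def test_smoothing_shrinks_spread(self, fitted_small):
        _, mapper = fitted_small
        t = mapper.summary_
        assert t["smrr"].std() <= t["smr"].std()

    def test_credible_intervals_nested(self, fitted_small):
        _, mapper = fitted_small
        t = mapper.summary_
        assert (t["ci95_low"] <= t["ci90_low"]).all()
        assert (t["ci90_high"] <= t["ci95_high"]).all()
        assert (t["smrr"] > 0).all()
        assert t["pr_exceed"].between(0, 1).all()

    def test_deterministic_given_seed(self, small_region, small_cohort, fast_mcmc):
        counts = cm.expected_counts(cm.filter_cohort(small_cohort, birth_class="domestic"))
        a = cm.BYMMapper(**fast_mcmc).fit(counts, small_region.graph).summary_
        b = cm.BYMMapper(**fast_mcmc).fit(counts, small_region.graph).summary_
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_more_cases_never_lower_smrr(self, fast_mcmc):
        # 5-parish path; double one parish's cases with E fixed and refit
        g = cm.make_lattice(1, 5)
        ids = sorted(g.nodes())
        O = [10, 12, 9, 11, 10]
        counts = make_counts(ids, O, [10.0] * 5)
        before = cm.fit_bym(counts, g, cm.MCMCConfig(**fast_mcmc))
        O2 = list(O)
        O2[2] = 25
        counts2 = make_counts(ids, O2, [10.0] * 5)
        after = cm.fit_bym(counts2, g, cm.MCMCConfig(**fast_mcmc))
        i = ids.index(ids[2])
        assert after.table.loc[i, "smrr"] > before.table.loc[i, "smrr"]

    def test_nonpositive_expected_rejected(self, fast_mcmc):
        g = cm.make_lattice(1, 2)
        counts = make_counts(sorted(g.nodes()), [1, 1], [0.0, 2.0])
        with pytest.raises(ValueError, match="expected"):
            cm.fit_bym(counts, g, cm.MCMCConfig(**fast_mcmc))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cm.MCMCConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            cm.MCMCConfig(n_chains=1)
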