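"""Multiplicative-null epistasis: expectations, errors, tests, decompositions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiland import epistasis as ep
from epiland.landscape import LocusSet, parse_genotype
from epiland.synthetic import LandscapeSpec, simulate_fitness_table, true_landscape

from conftest import make_landscape

# Published single-mutant fitness factors in the chelator (EGTA) environment,
# used as realistic inputs for the product expectation.
EGTA_SINGLES = {"r": 1.00, "t": 1.22, "s": 1.06, "g": 1.04, "p": 1.12}
GUAN_SINGLES = {"r": 1.005, "t": 1.13, "s": 0.92, "g": 1.01, "p": 0.99}


class TestExpectedFitness:
    def test_neutral_singles_give_unit_expectation(self):
        singles = {l: (1.0, 0.0) for l in "rtsgp"}
        assert ep.expected_fitness(singles) == (1.0, 0.0)

    def test_product_of_published_singles(self):
        singles = {l: (w, 0.0) for l, w in EGTA_SINGLES.items()}
        w_exp, _ = ep.expected_fitness(singles)
        assert w_exp == pytest.approx(float(np.prod(list(EGTA_SINGLES.values()))))
        assert w_exp == pytest.approx(1.5063, abs=1e-4)

    def test_quadrature_combines_relative_errors(self):
        singles = {"a": (1.0, 0.03), "b": (1.0, 0.04)}
        _, sd_exp = ep.expected_fitness(singles)
        assert sd_exp == pytest.approx(0.05)

    def test_linear_option_sums_relative_errors(self):
        singles = {"a": (1.0, 0.03), "b": (1.0, 0.04)}
        _, sd_exp = ep.expected_fitness(singles, method="linear")
        assert sd_exp == pytest.approx(0.07)

    def test_sd_invariant_under_permutation_and_scales_linearly(self):
        rng = np.random.default_rng(5)
        items = [(f"l{i}", (rng.uniform(0.8, 1.3), rng.uniform(0.01, 0.1))) for i in range(4)]
        _, sd1 = ep.expected_fitness(dict(items))
        _, sd2 = ep.expected_fitness(dict(reversed(items)))
        assert sd1 == pytest.approx(sd2)
        scaled = {k: (2 * m, 2 * s) for k, (m, s) in items}
        w_exp, sd_scaled = ep.expected_fitness(scaled)
        # scaling every fitness and SD by c multiplies w_exp by c^L but keeps
        # relative errors, so sd_exp scales with w_exp
        assert sd_scaled / w_exp == pytest.approx(sd1 / ep.expected_fitness(dict(items))[0])

    def test_nonpositive_single_rejected(self):
        with pytest.raises(ValueError):
            ep.expected_fitness({"a": (0.0, 0.1)})


class TestAbsoluteEpistasis:
    def test_zero_when_observation_matches_product(self):
        singles = {l: (w, 0.0) for l, w in EGTA_SINGLES.items()}
        w_exp = float(np.prod(list(EGTA_SINGLES.values())))
        assert ep.absolute_epistasis(w_exp, singles) == pytest.approx(0.0)

    def test_sign_positive_in_inhibitor_environment(self):
        # full mutant fitter than the product of its singles -> positive eps
        singles = {l: (w, 0.0) for l, w in GUAN_SINGLES.items()}
        eps = ep.absolute_epistasis(1.116, singles)
        assert eps == pytest.approx(1.116 - float(np.prod(list(GUAN_SINGLES.values()))))
        assert eps > 0.05

    def test_sign_near_zero_negative_in_chelator_environment(self):
        singles = {l: (w, 0.0) for l, w in EGTA_SINGLES.items()}
        eps = ep.absolute_epistasis(1.497, singles)
        assert -0.05 < eps < 0.0


class TestEpistasisSdAndTest:
    @pytest.mark.parametrize(
        "sd_obs, sd_exp, expected",
        [(0.0, 0.0, 0.0), (0.12, 0.05, 0.13), (0.07, 0.0, 0.07)],
    )
    def test_quadrature_examples(self, sd_obs, sd_exp, expected):
        assert ep.epistasis_sd(sd_obs, sd_exp) == pytest.approx(expected)

    def test_zero_epistasis_is_insignificant(self):
        t, df, p = ep.epistasis_test(0.0, 0.1, 5)
        assert (t, df, p) == (0.0, 4, pytest.approx(1.0))

    def test_t_statistic_and_p_from_t_distribution(self):
        t, df, p = ep.epistasis_test(0.10, 0.05, 5)
        assert t == pytest.approx(2.0)
        assert df == 4
        assert p == pytest.approx(0.1161, abs=5e-4)  # frozen from the t_4 CDF

    def test_sign_symmetry(self):
        t_pos, _, p_pos = ep.epistasis_test(0.10, 0.05, 5)
        t_neg, _, p_neg = ep.epistasis_test(-0.10, 0.05, 5)
        assert t_neg == -t_pos
        assert p_neg == pytest.approx(p_pos)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            ep.epistasis_test(0.1, 0.0, 5)
        with pytest.raises(ValueError):
            ep.epistasis_test(0.1, 0.05, 1)


class TestNetHigherOrder:
    def _toy(self, three_loci, pair_eps, triple_obs):
        """3-locus landscape: singles 1.1/1.2/1.3, planted pair terms, given triple."""
        singles = {"a": 1.1, "b": 1.2, "c": 1.3}
        data = {"anc": (1.0, 0.0, 3)}
        data.update({l: (w, 0.0, 3) for l, w in singles.items()})
        for pair in ("ab", "ac", "bc"):
            w_exp = singles[pair[0]] * singles[pair[1]]
            data[pair] = (w_exp + pair_eps.get(pair, 0.0), 0.0, 3)
        data["abc"] = (triple_obs, 0.0, 3)
        return make_landscape(three_loci, {"env": data})

    def test_recursion_base_no_pairwise_terms(self, three_loci):
        land = self._toy(three_loci, {}, triple_obs=1.8)
        g = parse_genotype("abc", three_loci)
        eps_abs = 1.8 - 1.1 * 1.2 * 1.3
        assert ep.net_higher_order(land, "env", g) == pytest.approx(eps_abs)

    def test_triple_at_product_with_pairwise_terms(self, three_loci):
        # observed triple equals the product of singles, but the pairs interact:
        # the higher-order term must cancel the summed pairwise terms
        pair_eps = {"ab": 0.05, "ac": -0.02, "bc": 0.04}
        land = self._toy(three_loci, pair_eps, triple_obs=1.1 * 1.2 * 1.3)
        g = parse_genotype("abc", three_loci)
        assert ep.net_higher_order(land, "env", g) == pytest.approx(-sum(pair_eps.values()))

    def test_pair_equals_absolute_epistasis(self, three_loci):
        land = self._toy(three_loci, {"ab": 0.07}, triple_obs=1.7)
        g = parse_genotype("ab", three_loci)
        assert ep.net_higher_order(land, "env", g) == pytest.approx(0.07)

    def test_multiplicative_landscape_has_no_interactions(self, loci):
        spec = LandscapeSpec(
            loci=loci,
            environments=("e",),
            singles={"e": {"r": 1.02, "t": 1.13, "s": 1.09, "g": 1.05, "p": 0.99}},
            interactions={},
            noise_sd=0.0,
        )
        land = true_landscape(spec)
        for g in loci.all_genotypes():
            if g.size >= 2:
                assert abs(ep.net_higher_order(land, "e", g)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_identity_on_random_landscapes(self, loci, seed):
        """w_obs = prod(singles) + sum of net terms over all subsets, exactly."""
        rng = np.random.default_rng(seed)
        singles = {l: float(rng.uniform(0.9, 1.25)) for l in loci.loci}
        interactions = {}
        for g in loci.all_genotypes():
            if g.size >= 2 and rng.random() < 0.6:
                interactions[g.label] = float(rng.normal(0.0, 0.05))
        spec = LandscapeSpec(
            loci=loci, environments=("e",), singles={"e": singles},
            interactions={"e": interactions}, noise_sd=0.0,
        )
        land = true_landscape(spec)
        for g in loci.all_genotypes():
            if g.size < 2:
                continue
            # planted net coefficients are recovered exactly...
            got = ep.net_higher_order(land, "e", g)
            assert got == pytest.approx(interactions.get(g.label, 0.0), abs=1e-10)
            # ...and summing them over subsets reconstructs the observation
            w_exp = float(np.prod([singles[l] for l in g.present]))
            from epiland.landscape import subsets

            total = sum(
                ep.net_higher_order(land, "e", b) for b in subsets(g, 2)
            ) + ep.net_higher_order(land, "e", g)
            assert land.w_mean("e", g) == pytest.approx(w_exp + total, abs=1e-10)


class TestEpistasisTable:
    def test_record_count_and_base_identities(self, loci):
        spec = LandscapeSpec(
            loci=loci,
            environments=("e",),
            singles={"e": {l: 1.0 + 0.05 * i for i, l in enumerate(loci.loci)}},
            interactions={"e": {"rt": -0.04}},
            n_reps=5,
            noise_sd=0.02,
        )
        land = ep.LandscapeSummary.from_observations(simulate_fitness_table(spec, 9))
        table = ep.epistasis_table(land, "e")
        assert len(table) == 26  # 32 - 5 singles - ancestor
        pairs = table[table.n_mut == 2]
        # recursion base: for pairs the net higher-order term IS the epistasis
        assert np.allclose(pairs["eps_higher"], pairs["eps"])
        assert (table["eps"] == table["w_obs"] - table["w_exp"]).all()

    def test_bonferroni_correction_is_more_conservative(self, loci):
        spec = LandscapeSpec(
            loci=loci,
            environments=("e",),
            singles={"e": {l: 1.1 for l in loci.loci}},
            interactions={"e": {"rt": -0.1}},
            n_reps=5,
            noise_sd=0.02,
        )
        land = ep.LandscapeSummary.from_observations(simulate_fitness_table(spec, 2))
        plain = ep.epistasis_table(land, "e", correction="none")
        bonf = ep.epistasis_table(land, "e", correction="bonferroni")
        assert (bonf["p_adj"] >= plain["p_adj"] - 1e-15).all()
        assert bonf["significant"].sum() <= plain["significant"].sum()


class TestMeanEpistasis:
    def test_all_zero_is_null(self):
        m = ep.mean_epistasis([0.0] * 26)
        assert m.mean == 0.0 and m.p == 1.0

    def test_recovers_simulated_mean_within_ci(self):
        rng = np.random.default_rng(12)
        values = 0.057 + rng.normal(0.0, 0.055, size=26)
        m = ep.mean_epistasis(values)
        assert m.ci_low < 0.057 < m.ci_high
        assert m.df == 25

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ep.mean_epistasis([0.01])


class TestDiminishingReturns:
    def _records(self, x, y):
        return pd.DataFrame({"environment": "e", "w_exp": x, "eps": y})

    def test_exact_positive_line(self):
        x = np.array([1.0, 1.1, 1.2, 1.35])
        fit = ep.diminishing_returns_fit(self._records(x, 2 * x))
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.sma_slope == pytest.approx(2.0)
        assert fit.sma_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_negative_line(self):
        x = np.array([1.0, 1.1, 1.2, 1.35])
        fit = ep.diminishing_returns_fit(self._records(x, -x + 0.5))
        assert fit.pearson_r == pytest.approx(-1.0)
        assert fit.sma_slope == pytest.approx(-1.0)

    def test_sma_closed_form_on_random_data(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 1.5, 26)
        y = -0.5 * x + rng.normal(0, 0.05, 26)
        fit = ep.diminishing_returns_fit(self._records(x, y))
        r = float(np.corrcoef(x, y)[0, 1])
        assert fit.pearson_r == pytest.approx(r)
        assert fit.sma_slope == pytest.approx(math.copysign(y.std(ddof=1) / x.std(ddof=1), r))
        assert math.copysign(1, fit.sma_slope) == math.copysign(1, fit.pearson_r)

    def test_relative_scale_divides_by_expected_fitness(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1.0, 1.5, 10)
        y = rng.normal(0, 0.05, 10)
        fit = ep.diminishing_returns_fit(self._records(x, y), scale="relative")
        r_manual = float(np.corrcoef(x, y / x)[0, 1])
        assert fit.pearson_r == pytest.approx(r_manual)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ep.diminishing_returns_fit(self._records([1.0, 1.1], [0.0, 0.1]))
        with pytest.raises(ValueError):
            ep.diminishing_returns_fit(self._records([1.0, 1.0, 1.0], [0.0, 0.1, 0.2]))


class TestFocalMutation:
    def _records(self, labels, w_exp, eps):
        return pd.DataFrame({"genotype": labels, "w_exp": w_exp, "eps": eps})

    def test_identical_strata_show_no_effect(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1.0, 1.5, 13)
        y = -0.3 * x + rng.normal(0, 0.02, 13)
        labels = [f"r{'tsgp'[i % 4]}" for i in range(13)] + ["ts"] * 13
        rec = self._records(labels, np.concatenate([x, x]), np.concatenate([y, y]))
        rep = ep.focal_mutation_analysis(rec, "r")
        assert rep.t_group == pytest.approx(0.0, abs=1e-12)
        assert rep.p_interaction > 0.9
        assert rep.p_mutation > 0.9

    def test_planted_slope_difference_flags_interaction(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(1.0, 1.5, 13)
        with_locus = -1.0 * (x - 1.25) + rng.normal(0, 0.02, 13)
        without = 0.0 * x + rng.normal(0, 0.02, 13)
        labels = ["rt"] * 13 + ["ts"] * 13
        rec = self._records(labels, np.concatenate([x, x]), np.concatenate([with_locus, without]))
        rep = ep.focal_mutation_analysis(rec, "r")
        assert rep.p_interaction < 0.01
        assert rep.r_with < -0.9 and abs(rep.r_without) < 0.5

    def test_intercept_shift_flags_main_effect_not_interaction(self):
        rng = np.random.default_rng(22)
        x = rng.uniform(1.0, 1.5, 13)
        slope = -0.5
        with_locus = slope * x + 0.2 + rng.normal(0, 0.02, 13)
        without = slope * x + rng.normal(0, 0.02, 13)
        labels = ["rt"] * 13 + ["ts"] * 13
        rec = self._records(labels, np.concatenate([x, x]), np.concatenate([with_locus, without]))
        rep = ep.focal_mutation_analysis(rec, "r")
        assert rep.p_mutation < 0.01
        assert rep.p_interaction > 0.05
        # pooled-variance group t uses df = n1 + n2 - 2 (24 for 26 genotypes)
        assert rep.df_group == 24

    def test_small_stratum_rejected(self):
        rec = self._records(["rt", "ts", "ts", "ts"], [1.0, 1.1, 1.2, 1.3], [0, 0, 0, 0])
        with pytest.raises(ValueError):
            ep.focal_mutation_analysis(rec, "r")
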