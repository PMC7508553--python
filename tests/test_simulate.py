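import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoselect import (
    brood_rate,
    copy_number,
    develop_within_host,
    make_stock_population,
    maturation_probability,
    neutral_preset,
    simulate_competition,
    simulate_lineages,
    stock_frequencies,
    transmit_bottleneck,
)
from mitoselect.exceptions import ParameterError
from mitoselect.simulate import STOCK_ALPHA, L4_GAIN_FRACTION, stock_mean


class TestStock:
    def test_mean_matches_closed_form_at_large_n(self):
        # oracle: the scaled symmetric Beta has mean exactly mean_f; the
        # sample mean at n=1e5 must sit within 4 standard errors of it
        n, mean_f, spread = 100_000, 0.60, 0.15
        var_beta = STOCK_ALPHA**2 / ((2 * STOCK_ALPHA) ** 2 * (2 * STOCK_ALPHA + 1))
        se = 2 * spread * np.sqrt(var_beta / n)
        freqs = stock_frequencies(n, mean_f, spread, seed=1)
        assert abs(freqs.mean() - stock_mean(mean_f, spread)) < 4 * se

    def test_support_is_respected(self):
        freqs = stock_frequencies(10_000, 0.60, 0.15, seed=2)
        assert freqs.min() >= 0.45 and freqs.max() <= 0.75

    def test_zero_spread_is_point_mass(self):
        assert np.all(stock_frequencies(5, 0.60, 0.0) == 0.60)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=0), dict(mean_f=0.0), dict(mean_f=1.0), dict(spread=-0.1),
         dict(mean_f=0.9, spread=0.2)],
    )
    def test_invalid_parameters_raise(self, kwargs):
        full = dict(n=10, mean_f=0.6, spread=0.15)
        full.update(kwargs)
        with pytest.raises(ParameterError):
            stock_frequencies(**full)

    def test_population_copy_numbers_follow_hitchhiking(self):
        pop = make_stock_population(50, seed=3, wt_setpoint=1000)
        for ind in pop:
            assert ind.n_wt == 1000
            assert ind.n_mut == round(1000 * ind.f / (1 - ind.f))


class TestBottleneck:
    def test_fixed_points(self):
        assert transmit_bottleneck(0.0, B=50, seed=0) == 0.0
        assert transmit_bottleneck(1.0, B=50, seed=0) == 1.0

    def test_mean_matches_binomial_oracle(self):
        # oracle: draws are Binomial(B, f + delta)/B
        f, B, delta, n = 0.6, 200, -0.03, 20_000
        draws = transmit_bottleneck(np.full(n, f), B=B, delta_embryo=delta, seed=4)
        se = np.sqrt((f + delta) * (1 - f - delta) / B / n)
        assert abs(draws.mean() - (f + delta)) < 4 * se

    def test_array_in_array_out(self):
        out = transmit_bottleneck(np.array([0.2, 0.8]), B=10, seed=0)
        assert out.shape == (2,)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParameterError):
            transmit_bottleneck(0.5, B=0)
        with pytest.raises(ParameterError):
            transmit_bottleneck(1.5)


class TestDevelop:
    def test_zero_stays_zero(self, wt):
        # the deletion cannot arise de novo
        assert develop_within_host(0.0, wt, seed=0) == 0.0

    def test_deterministic_affine_oracle(self, wt):
        # oracle: with sd=0 the map is exactly f + g*(a + b f), clamped
        p = wt.with_overrides(shift_sd=0.0)
        f = np.array([0.2, 0.5, 0.7])
        for g in (0.5, 1.0):
            expected = np.clip(f + g * (p.shift_a + p.shift_b * f), 0, p.f_max)
            assert np.allclose(develop_within_host(f, p, seed=0, gain_fraction=g), expected)

    def test_ceiling_clamp(self, wt):
        p = wt.with_overrides(shift_sd=0.0, shift_a=0.5, shift_b=0.0)
        assert develop_within_host(0.89, p) == p.f_max

    def test_invalid_frequency_raises(self, wt):
        with pytest.raises(ParameterError):
            develop_within_host(-0.1, wt)


class TestHostCosts:
    def test_brood_rate_flat_below_threshold(self, wt):
        f = np.linspace(0, wt.fecundity_theta, 7)
        assert np.allclose(brood_rate(f, wt), wt.fecundity_base)

    def test_brood_rate_zero_at_ceiling(self, wt):
        assert brood_rate(wt.f_max, wt) == 0.0
        assert brood_rate(0.95, wt) == 0.0

    def test_brood_rate_monotone_nonincreasing(self, wt):
        f = np.linspace(0, 1, 101)
        rates = brood_rate(f, wt)
        assert np.all(np.diff(rates) <= 1e-12)

    def test_maturation_linear_oracle(self, wt):
        f = np.linspace(0, 1, 11)
        assert np.allclose(
            maturation_probability(f, wt), np.clip(1 - wt.delay_slope * f, 0, 1)
        )


class TestCopyNumber:
    def test_zero_frequency(self):
        assert copy_number(0.0, 1000) == (1000, 0)

    def test_total_strictly_increasing_in_f(self):
        totals = [sum(copy_number(f, 200_000)) for f in np.linspace(0, 0.95, 40)]
        assert np.all(np.diff(totals) > 0)

    def test_homoplasmy_raises(self):
        with pytest.raises(ParameterError):
            copy_number(1.0, 100)
        with pytest.raises(ParameterError):
            copy_number(0.5, 0)

    @given(st.floats(0.0, 0.99), st.integers(1, 10**6))
    def test_hitchhiking_formula(self, f, W):
        n_wt, n_mut = copy_number(f, W)
        assert n_wt == W
        assert n_mut == round(W * f / (1 - f))


class TestLineages:
    def test_shape_and_columns(self, lineage_table):
        assert list(lineage_table.columns) == [
            "lineage_id", "parent_f", "embryo_f", "l4_f", "adult_f"]
        assert len(lineage_table) == 30
        for col in ("parent_f", "embryo_f", "l4_f", "adult_f"):
            vals = lineage_table[col].to_numpy()
            assert np.all((vals >= 0) & (vals <= 1))

    def test_reproducible_and_seed_sensitive(self, wt):
        a = simulate_lineages(8, wt, seed=5)
        b = simulate_lineages(8, wt, seed=5)
        c = simulate_lineages(8, wt, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_spawn_stability_under_extension(self, wt):
        # adding lineages must not perturb the ones already simulated
        small = simulate_lineages(5, wt, seed=7)
        large = simulate_lineages(12, wt, seed=7)
        pd.testing.assert_frame_equal(small, large.iloc[:5])

    def test_deterministic_forward_propagation_oracle(self, wt):
        # oracle: with sd=0 and a huge bottleneck the stage values are the
        # deterministic affine propagation of the parent frequency
        p = wt.with_overrides(shift_sd=0.0, bottleneck_b=1_000_000)
        t = simulate_lineages(10, p, seed=8)
        fp = t["parent_f"].to_numpy()
        emb = fp + p.delta_embryo
        assert np.allclose(t["embryo_f"], emb, atol=2e-3)
        assert np.allclose(
            t["l4_f"], emb + L4_GAIN_FRACTION * (p.shift_a + p.shift_b * emb), atol=2e-3)
        assert np.allclose(
            t["adult_f"], emb + (p.shift_a + p.shift_b * emb), atol=2e-3)

    def test_validation(self, wt):
        with pytest.raises(ParameterError):
            simulate_lineages(0, wt)
        with pytest.raises(ParameterError):
            simulate_lineages(3, wt, pool_size=0)


class TestCompetition:
    def test_shape_and_census(self, wt):
        t = simulate_competition(n_lines=3, generations=4, carry_n=50,
                                 preset=wt, seed=9)
        assert list(t.columns) == ["line_id", "generation", "competed",
                                   "pooled_f", "het_fraction", "n_genotyped",
                                   "terminated"]
        # generations 0..4 inclusive for every surviving line
        assert set(t["generation"]) == {0, 1, 2, 3, 4}
        assert t["pooled_f"].between(0, 1).all()

    def test_noncompeted_lines_stay_fully_heteroplasmic(self, wt):
        t = simulate_competition(n_lines=2, generations=3, carry_n=100,
                                 preset=wt, competed=False, seed=10)
        assert (t["het_fraction"] == 1.0).all()

    def test_competed_founding_mix(self, wt):
        t = simulate_competition(n_lines=4, generations=1, carry_n=200,
                                 init_het_fraction=0.5, preset=wt, seed=11)
        gen0 = t[t["generation"] == 0]
        assert abs(gen0["het_fraction"].mean() - 0.5) < 0.15

    def test_sterile_line_terminates_with_flag(self):
        p = neutral_preset(fecundity_base=0.0)
        t = simulate_competition(n_lines=2, generations=5, carry_n=20,
                                 preset=p, competed=False, seed=12)
        assert (t.groupby("line_id").size() == 1).all()
        assert t["terminated"].all()

    def test_reproducible(self, wt):
        a = simulate_competition(n_lines=2, generations=2, carry_n=30, preset=wt, seed=13)
        b = simulate_competition(n_lines=2, generations=2, carry_n=30, preset=wt, seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_validation(self, wt):
        with pytest.raises(ParameterError):
            simulate_competition(carry_n=5, preset=wt)
        with pytest.raises(ParameterError):
            simulate_competition(generations=0, preset=wt)
        with pytest.raises(ParameterError):
            simulate_competition(init_het_fraction=1.5, preset=wt)
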