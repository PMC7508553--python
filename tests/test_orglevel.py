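import numpy as np
import pandas as pd
import pytest

from mitoselect import (
    endpoint_contrast,
    estimate_s_org,
    fit_org_decline,
    fraction_trajectory,
    neutral_preset,
    normalize_to_noncompeted,
    simulate_competition,
)
from mitoselect.exceptions import (
    EstimationError,
    NormalizationError,
    ParameterError,
)


def _comp_table(values, competed=True, het=None, n_genotyped=48):
    """values: dict line_id -> list of pooled_f by generation."""
    rows = []
    for line_id, series in values.items():
        for t, f in enumerate(series):
            rows.append(dict(
                line_id=line_id, generation=t, competed=competed,
                pooled_f=f,
                het_fraction=f if het is None else het[line_id][t],
                n_genotyped=n_genotyped, terminated=False))
    return pd.DataFrame(rows)


class TestNormalize:
    def test_self_normalization_is_exactly_one(self):
        non = _comp_table({0: [0.6, 0.62, 0.61], 1: [0.58, 0.6, 0.63]},
                          competed=False)
        norm = normalize_to_noncompeted(non, non)
        per_gen = norm.groupby("generation")["value"].mean()
        assert np.allclose(per_gen, 1.0, rtol=0, atol=1e-12)

    def test_competed_equal_to_reference_mean_is_flat_at_one(self):
        non = _comp_table({0: [0.5, 0.6], 1: [0.7, 0.8]}, competed=False)
        comp = _comp_table({0: [0.6, 0.7]})  # equals the per-gen ref mean
        norm = normalize_to_noncompeted(comp, non)
        assert np.allclose(norm["value"], 1.0)

    def test_difference_mode(self):
        non = _comp_table({0: [0.5, 0.5]}, competed=False)
        comp = _comp_table({0: [0.4, 0.3]})
        norm = normalize_to_noncompeted(comp, non, mode="difference")
        assert np.allclose(norm["value"], [-0.1, -0.2])

    def test_missing_reference_generation_raises(self):
        non = _comp_table({0: [0.5, 0.5]}, competed=False)
        comp = _comp_table({0: [0.4, 0.3, 0.2]})
        with pytest.raises(NormalizationError):
            normalize_to_noncompeted(comp, non)

    def test_zero_reference_raises(self):
        non = _comp_table({0: [0.0, 0.0]}, competed=False)
        comp = _comp_table({0: [0.4, 0.3]})
        with pytest.raises(NormalizationError):
            normalize_to_noncompeted(comp, non)

    def test_bad_mode_raises(self):
        t = _comp_table({0: [0.5]})
        with pytest.raises(ParameterError):
            normalize_to_noncompeted(t, t, mode="log")


class TestFitOrgDecline:
    def test_constant_trajectory_is_neutral(self):
        traj = pd.DataFrame({"line_id": [0] * 4 + [1] * 4,
                             "generation": list(range(4)) * 2,
                             "value": [1.0] * 8})
        fit = fit_org_decline(traj, n_boot=200, seed=0)
        assert fit.slope_hat == pytest.approx(0.0, abs=1e-12)
        assert fit.s_org == pytest.approx(0.0, abs=1e-12)

    def test_exact_geometric_decline_oracle(self):
        # oracle: value r^t gives log-slope ln r, so s_org = 1 - r exactly
        r = 0.8
        gens = np.arange(6)
        traj = pd.DataFrame({"line_id": np.zeros(6, int) ,
                             "generation": gens,
                             "value": r ** gens})
        fit = fit_org_decline(traj, n_boot=200, seed=0)
        assert fit.s_org == pytest.approx(1 - r, abs=1e-10)
        # and the linear slope matches an independent least-squares fit
        ref_slope = np.polyfit(gens.astype(float), r ** gens, 1)[0]
        assert fit.slope_hat == pytest.approx(ref_slope, abs=1e-10)

    def test_single_generation_raises(self):
        traj = pd.DataFrame({"line_id": [0, 1], "generation": [0, 0],
                             "value": [1.0, 0.9]})
        with pytest.raises(EstimationError):
            fit_org_decline(traj)

    def test_ci_covers_slope_on_simulated_decline(self, rng):
        gens = np.tile(np.arange(8), 6)
        lines = np.repeat(np.arange(6), 8)
        vals = 1.0 - 0.05 * gens + rng.normal(0, 0.02, gens.size)
        traj = pd.DataFrame({"line_id": lines, "generation": gens, "value": vals})
        fit = fit_org_decline(traj, n_boot=2000, seed=2)
        assert fit.ci_slope[0] < -0.05 < fit.ci_slope[1]


class TestFractionTrajectory:
    def test_pivots_to_generation_by_line(self):
        t = _comp_table({0: [0.5, 0.4], 1: [0.5, 0.3]},
                        het={0: [1.0, 0.8], 1: [0.9, 0.6]})
        fx = fraction_trajectory(t)
        assert fx.shape == (2, 2)
        assert fx.loc[1, 0] == 0.8

    def test_rejects_noncompeted_tables(self):
        t = _comp_table({0: [0.5, 0.4]}, competed=False)
        with pytest.raises(ParameterError):
            fraction_trajectory(t)

    def test_zero_genotyped_becomes_missing(self, caplog):
        t = _comp_table({0: [0.5, 0.4]}, n_genotyped=0)
        with caplog.at_level("WARNING"):
            fx = fraction_trajectory(t)
        assert fx.isna().all().all()


class TestEndpointContrast:
    def test_identical_conditions_give_one(self):
        t = _comp_table({0: [0.5, 0.4], 1: [0.5, 0.4]},
                        het={0: [1.0, 1.0], 1: [1.0, 1.0]})
        fx = fraction_trajectory(t)
        assert endpoint_contrast(fx, fx) == pytest.approx(1.0)

    def test_uses_last_common_generation(self):
        a = fraction_trajectory(_comp_table({0: [0.5, 0.5, 0.5]},
                                            het={0: [1.0, 0.6, 0.3]}))
        b = fraction_trajectory(_comp_table({0: [0.5, 0.5]},
                                            het={0: [1.0, 0.9]}))
        assert endpoint_contrast(a, b) == pytest.approx(0.6 / 0.9)

    def test_zero_reference_raises(self):
        a = fraction_trajectory(_comp_table({0: [0.5, 0.5]}, het={0: [1.0, 0.5]}))
        b = fraction_trajectory(_comp_table({0: [0.5, 0.5]}, het={0: [1.0, 0.0]}))
        with pytest.raises(NormalizationError):
            endpoint_contrast(a, b)


class TestEstimateSOrg:
    def test_constant_fraction_is_neutral(self):
        fx = pd.DataFrame({0: [0.5, 0.5, 0.5], 1: [0.7, 0.7, 0.7]})
        est = estimate_s_org(fx, n_boot=200, seed=0)
        assert est.s_org == pytest.approx(0.0, abs=1e-12)
        assert est.n_steps == 4

    def test_exact_odds_decline_oracle(self):
        # oracle: odds multiplied by w each step gives s_org = 1 - w exactly
        w = 0.7
        odds0 = 1.0
        odds = odds0 * w ** np.arange(5)
        p = odds / (1 + odds)
        est = estimate_s_org(pd.DataFrame({0: p}), n_boot=200, seed=0)
        assert est.s_org == pytest.approx(1 - w, abs=1e-12)

    def test_boundary_steps_skipped(self, caplog):
        fx = pd.DataFrame({0: [1.0, 0.5, 0.25]})
        with caplog.at_level("WARNING"):
            est = estimate_s_org(fx, n_boot=100, seed=0)
        assert est.n_steps == 1
        assert "skipped" in caplog.text

    def test_all_boundary_raises(self):
        fx = pd.DataFrame({0: [1.0, 1.0, 0.0]})
        with pytest.raises(EstimationError):
            estimate_s_org(fx, n_boot=100)

    def test_recovers_simulated_cost(self):
        # simulation-based recovery oracle (reduced replication; the full
        # 50-replicate benchmark lives in the acceptance suite): neutral
        # within-host dynamics with a pure fecundity step cost c makes the
        # heteroplasmic relative fitness exactly 1 - c
        c = 0.3
        p = neutral_preset(fecundity_cost=c, fecundity_theta=0.0,
                           fecundity_ramp=1e-9, fecundity_base=4.0)
        ests = []
        for s in range(6):
            t = simulate_competition(n_lines=6, generations=10, carry_n=500,
                                     preset=p, competed=True, seed=(50, s))
            ests.append(estimate_s_org(fraction_trajectory(t),
                                       n_boot=100, seed=s).s_org)
        assert abs(np.mean(ests) - c) / c < 0.2
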