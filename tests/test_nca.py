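"""Non-compartmental estimation: AUC, terminal fit, derived parameters."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from fishpk import (
    ConcentrationTimeProfile,
    NCAError,
    SimulationConfig,
    TerminalPhaseSpec,
    analyze_profile,
    auc_trapezoid,
    extrapolate_auc_tail,
    fit_terminal_phase,
    halflife_family,
    run_nca,
    simulate_study,
    tissue_plasma_ratio,
)
from fishpk.nca import FLAG_NEGATIVE_KEL, FLAG_NO_TERMINAL

from conftest import exponential_profile


def profile_from(times, concs, **kw):
    return ConcentrationTimeProfile(tissue=kw.pop("tissue", "plasma"),
                                    analyte=kw.pop("analyte", "FF"),
                                    times=times, concentrations=concs, **kw)


class TestTrapezoid:
    def test_rectangle(self):
        assert auc_trapezoid(profile_from([0, 10], [10, 10])) == pytest.approx(100.0)

    def test_hand_sum(self):
        # 0.5*4*2 + 0.5*6*2 = 10
        assert auc_trapezoid(profile_from([0, 2, 4], [0, 4, 2])) == pytest.approx(10.0)

    def test_matches_dense_integration_of_interpolant(self):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0, 128, size=14))
        times[0] = 0.0
        concs = rng.uniform(0, 500, size=14)
        profile = profile_from(times, concs)
        dense_t = np.union1d(times, np.linspace(0, times[-1], 200_001))
        dense_c = np.interp(dense_t, times, concs)
        oracle = np.trapezoid(dense_c, dense_t)
        assert auc_trapezoid(profile) == pytest.approx(oracle, rel=1e-9)

    def test_insufficient_points_raise(self):
        with pytest.raises(NCAError):
            auc_trapezoid(profile_from([0, 2], [0, 5], bloq_mask=[False, True]))

    @given(st.lists(st.floats(0.1, 1e4), min_size=4, max_size=12),
           st.integers(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additivity_over_partitions(self, concs, cut):
        # area over [t0, tn] equals the sum over sub-ranges sharing a boundary
        n = len(concs)
        times = np.arange(n, dtype=float) * 2.0
        cut = min(cut, n - 3) + 1  # interior boundary, >= 2 points per side
        whole = auc_trapezoid(profile_from(times, concs))
        left = auc_trapezoid(profile_from(times[:cut + 1], concs[:cut + 1]))
        right = auc_trapezoid(profile_from(times[cut:], concs[cut:]))
        assert whole == pytest.approx(left + right, rel=1e-12, abs=1e-9)

    def test_bloq_policy_zero_before_tmax_drop_after(self):
        profile = profile_from([0, 2, 4, 8, 16], [0.2, 5, 10, 4, 0.2],
                               loq=0.5,
                               bloq_mask=[True, False, False, False, True])
        # pre-peak BLOQ counts as 0; the post-peak BLOQ point is dropped,
        # so the last interval ends at t=8
        expected = 0.5 * (0 + 5) * 2 + 0.5 * (5 + 10) * 2 + 0.5 * (10 + 4) * 4
        assert auc_trapezoid(profile) == pytest.approx(expected)
        # LOQ/2 substitution keeps all points
        expected_loq2 = (0.5 * (0.25 + 5) * 2 + 0.5 * (5 + 10) * 2
                         + 0.5 * (10 + 4) * 4 + 0.5 * (4 + 0.25) * 8)
        assert auc_trapezoid(profile, bloq_policy="loq2") == pytest.approx(expected_loq2)


class TestTerminalFit:
    def test_exact_exponential(self):
        profile = exponential_profile(a=100.0, k=0.05,
                                      times=[2, 24, 32, 48, 64, 96, 128])
        fit = fit_terminal_phase(profile)
        assert fit.k_el == pytest.approx(0.05, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_ols_on_logs(self):
        rng = np.random.default_rng(5)
        times = np.array([24.0, 32, 48, 64, 96, 128])
        concs = 100.0 * np.exp(-0.05 * times) * np.exp(rng.normal(0, 0.1, 6))
        profile = profile_from(np.concatenate([[8.0], times]),
                               np.concatenate([[200.0], concs]))
        fit = fit_terminal_phase(profile, TerminalPhaseSpec("fixed-last-n", 6))
        X = sm.add_constant(times)
        oracle = sm.OLS(np.log(concs), X).fit()
        assert fit.slope == pytest.approx(oracle.params[1], abs=1e-12)
        assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-12)
        assert fit.r_squared == pytest.approx(oracle.rsquared, abs=1e-12)

    def test_monotonically_increasing_profile_flagged(self):
        profile = profile_from([0, 2, 4, 8, 16], [0, 1, 2, 4, 8])
        res = analyze_profile(profile)
        assert FLAG_NO_TERMINAL in res.flags or FLAG_NEGATIVE_KEL in res.flags

    def test_negative_slope_reported_not_dropped(self):
        # rising tail after an early peak: k_el comes out negative but is
        # still reported, with a flag
        profile = profile_from([0, 2, 4, 8, 16, 32], [0, 50, 10, 12, 15, 20])
        res = analyze_profile(profile)
        assert FLAG_NEGATIVE_KEL in res.flags
        assert res.k_el is not None and res.k_el < 0
        assert res.auc_tail is None and res.auc_0_inf is None

    def test_best_r2_prefers_straightest_window(self):
        # bi-exponential: early points curve, late points are straight
        times = np.array([4.0, 8, 16, 24, 32, 48, 64, 96, 128])
        concs = 400 * np.exp(-0.2 * times) + 100 * np.exp(-0.03 * times)
        profile = profile_from(np.concatenate([[0.0], times]),
                               np.concatenate([[0.0], concs]))
        fit = fit_terminal_phase(profile, TerminalPhaseSpec("best-r2-search", 3))
        assert fit.t_start >= 32.0
        assert fit.k_el == pytest.approx(0.03, rel=0.02)

    def test_too_few_post_tmax_points(self):
        profile = profile_from([0, 2, 4, 8], [0, 10, 5, 3])
        with pytest.raises(NCAError, match="after Tmax"):
            fit_terminal_phase(profile)


class TestDerivedParameters:
    @pytest.mark.parametrize(
        "c_last, k_el, expected",
        [(1.14, 0.03489, 32.6713), (83.8, 0.022512, 3722.423)],
        ids=["plasma", "intestine"],
    )
    def test_tail_extrapolation_reproduces_reported(self, c_last, k_el, expected):
        assert extrapolate_auc_tail(c_last, k_el) == pytest.approx(expected, rel=1e-3)

    def test_tail_zero_and_invalid(self):
        assert extrapolate_auc_tail(0.0, 0.05) == 0.0
        with pytest.raises(NCAError, match="negative k_el"):
            extrapolate_auc_tail(1.0, -0.01)

    def test_halflife_family_reported_values(self):
        mean_lifetime, lam, ka = halflife_family(23.34)
        assert mean_lifetime == pytest.approx(33.67, abs=0.01)
        assert ka == pytest.approx(0.030, abs=0.001)
        assert halflife_family(86.95)[0] == pytest.approx(125.44, abs=0.01)

    def test_halflife_family_identities(self):
        mean_lifetime, lam, ka = halflife_family(math.log(2))
        assert mean_lifetime == pytest.approx(1.0, abs=1e-15)
        assert lam == pytest.approx(1.0, abs=1e-15)
        assert ka == lam
        with pytest.raises(NCAError):
            halflife_family(0.0)

    def test_tissue_plasma_ratio(self):
        assert tissue_plasma_ratio(107_043.1, 7_735.43) == pytest.approx(13.84, abs=0.005)
        assert tissue_plasma_ratio(43_779.0, 7_735.43) == pytest.approx(5.66, abs=0.005)
        assert tissue_plasma_ratio(5.0, 5.0) == 1.0
        with pytest.raises(NCAError):
            tissue_plasma_ratio(1.0, 0.0)


class TestRunNCA:
    def test_parameter_recovery_noise_free(self, noise_free_study, noise_free_config):
        results = [r for r in run_nca(noise_free_study) if r.analyte == "FF"]
        assert len(results) == 7
        for res in results:
            assert res.k_el == pytest.approx(noise_free_config.ke, rel=0.02)

    def test_intra_result_invariants(self, noise_free_study):
        for res in run_nca(noise_free_study):
            if res.k_el is None or res.k_el <= 0:
                continue
            assert res.auc_0_inf == res.auc_0_last + res.auc_tail  # exact
            assert res.mean_lifetime == pytest.approx(res.t_half / math.log(2), rel=1e-15)
            assert res.decay_constant == pytest.approx(1 / res.mean_lifetime, rel=1e-15)
            assert res.ka == pytest.approx(res.decay_constant, rel=1e-12)

    def test_single_tissue_no_ratio(self):
        cfg = SimulationConfig(noise_cv=0.0, tissue_partition={"kidney": 8.2})
        results = run_nca(simulate_study(cfg))
        assert all(r.auc_ratio is None for r in results)

    def test_ratios_filled_against_plasma(self, noise_free_study, noise_free_config):
        results = {(r.tissue, r.analyte): r for r in run_nca(noise_free_study)}
        plasma = results[("plasma", "FF")]
        for tissue, kp in noise_free_config.tissue_partition.items():
            if tissue == "plasma":
                assert results[(tissue, "FF")].auc_ratio is None
            else:
                # linear kinetics: AUC ratio equals the Kp ratio exactly
                assert results[(tissue, "FF")].auc_ratio == pytest.approx(kp, rel=1e-12)
        assert plasma.auc_0_last > 0

    def test_fault_isolation_ascending_tail(self, noise_free_study):
        profiles = dict(noise_free_study.profiles)
        bad = ConcentrationTimeProfile(
            tissue="skin", analyte="FFA", times=[0, 8, 16, 32, 64, 128],
            concentrations=[0, 50, 10, 12, 15, 20])
        profiles[("skin", "FFA")] = bad
        noise_free_study.profiles = profiles
        results = {(r.tissue, r.analyte): r for r in run_nca(noise_free_study)}
        assert FLAG_NEGATIVE_KEL in results[("skin", "FFA")].flags
        # the corruption stays contained: no other profile turns negative
        others = [r for k, r in results.items() if k != ("skin", "FFA")]
        assert all(FLAG_NEGATIVE_KEL not in r.flags for r in others)
        assert not results[("skin", "FF")].flags

    def test_dense_late_sampling_converges_to_closed_form(self):
        # AUC(0-inf) -> A/k as late sampling densifies
        a, k = 100.0, 0.05
        previous_error = None
        for n_late in (8, 16, 32):
            times = np.concatenate([np.linspace(0.0, 20, 10),
                                    np.linspace(21, 200, n_late)])
            profile = exponential_profile(a=a, k=k, times=times)
            res = analyze_profile(profile)
            error = abs(res.auc_0_inf - a / k) / (a / k)
            if previous_error is not None:
                assert error <= previous_error * 1.05
            previous_error = error
        assert previous_error < 0.005
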