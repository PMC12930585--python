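import numpy as np
import pytest

from avdflux.compounds import get_compound
from avdflux.physiology import (
    CultureTimeCourse,
    compute_molar_yield,
    compute_selectivity,
    compute_specific_rates,
    fit_growth_rate,
    space_time_yield,
    specific_enzyme_activity,
)
from avdflux.synthetic import SyntheticScenario, avd11_scenario, gen_timecourse


def exponential_course(mu=0.12, od0=0.2, times=None, cdw_factor=0.3):
    times = np.arange(0, 12, 2.0) if times is None else times
    od = od0 * np.exp(mu * times)
    return CultureTimeCourse(times=times, od660=od, cdw_factor=cdw_factor)


class TestGrowthRate:
    def test_exact_on_noiseless_exponential(self):
        tc = exponential_course(mu=0.12)
        mu, se = fit_growth_rate(tc)
        assert mu == pytest.approx(0.12, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_constant_od_gives_zero(self):
        tc = CultureTimeCourse(times=np.arange(5.0), od660=np.full(5, 2.0))
        mu, _ = fit_growth_rate(tc)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generator_mu_with_noise(self):
        sc = avd11_scenario()
        sc.mu, sc.q_substrate, sc.s0_gL = 0.28, 3.45, 80.0
        tc = gen_timecourse(sc, noise_rel=0.02, seed=1, times=np.arange(0, 13, 1.0))
        mu, _ = fit_growth_rate(tc)
        assert mu == pytest.approx(0.28, abs=0.01)

    def test_unbiased_over_replicates(self):
        sc = avd11_scenario()
        sc.mu = 0.28
        sc.s0_gL = 80.0
        estimates = []
        for seed in range(200):
            tc = gen_timecourse(sc, noise_rel=0.02, seed=seed, times=np.arange(0, 13, 1.0))
            estimates.append(fit_growth_rate(tc)[0])
        mean = np.mean(estimates)
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(mean - 0.28) < 3 * se + 1e-4

    def test_requires_three_positive_points(self):
        tc = exponential_course()
        with pytest.raises(ValueError):
            fit_growth_rate(tc, window=(0.0, 2.0))


class TestSpecificRates:
    def test_noiseless_recovery_exact(self):
        sc = avd11_scenario()
        tc = gen_timecourse(sc, noise_rel=0.0)
        res = compute_specific_rates(tc, substrate="glucose", window=(tc.times[0], tc.times[-1]))
        assert res.mu == pytest.approx(sc.mu, abs=1e-9)
        assert res.q_substrate == pytest.approx(sc.q_substrate, rel=1e-6)
        assert res.q_products["5-AVD"] == pytest.approx(1.09, rel=1e-6)
        # yield equals regression of product formed vs substrate consumed
        glc = tc.concentrations["glucose"] / get_compound("glucose").molar_mass
        avd = tc.concentrations["5-AVD"] / get_compound("5-AVD").molar_mass
        slope = np.polyfit(glc[0] - glc, avd, 1)[0] * 1000.0
        assert res.yields_molar["5-AVD"] == pytest.approx(slope, rel=1e-6)

    def test_constant_product_gives_zero_rate(self):
        tc = exponential_course()
        tc.concentrations["glucose"] = 10.0 - 0.5 * tc.cdw
        tc.concentrations["5-AVD"] = np.full(len(tc.times), 1.0)
        res = compute_specific_rates(tc, window=(tc.times[0], tc.times[-1]))
        assert res.q_products["5-AVD"] == pytest.approx(0.0, abs=1e-12)

    def test_avd11_like_noisy_recovery_within_5_percent(self):
        sc = avd11_scenario()
        tc = gen_timecourse(sc, noise_rel=0.02, seed=7)
        res = compute_specific_rates(tc, window=(tc.times[0], tc.times[-1]))
        assert res.mu == pytest.approx(0.12, rel=0.05)
        assert res.q_substrate == pytest.approx(3.45, rel=0.05)
        assert res.q_products["5-AVD"] == pytest.approx(1.09, rel=0.05)


class TestMolarYield:
    def test_avd11_yield_matches_table(self):
        assert compute_molar_yield(1.09, 3.45) == pytest.approx(316.0, abs=0.5)

    def test_avd2a_yield_matches_table(self):
        assert compute_molar_yield(0.72, 3.09) == pytest.approx(233.1, abs=0.5)

    def test_zero_product(self):
        assert compute_molar_yield(0.0, 3.0) == 0.0

    def test_zero_substrate_rejected(self):
        with pytest.raises(ValueError):
            compute_molar_yield(1.0, 0.0)


class TestSelectivity:
    def test_single_product_is_100(self):
        sel = compute_selectivity({"5-AVD": 10.0, "lysine": 0.0}, "5-AVD")
        assert sel == pytest.approx(100.0, abs=1e-9)

    def test_equimolar_mixture_is_50(self):
        m_avd = get_compound("5-AVD").molar_mass
        m_lys = get_compound("lysine").molar_mass
        sel = compute_selectivity({"5-AVD": m_avd, "lysine": m_lys}, "5-AVD")
        assert sel == pytest.approx(50.0, abs=1e-9)

    def test_fed_batch_titers_exceed_97_percent(self):
        # final titers 36.3 g/L 5-AVD, 1.6 g/L lysine of which 0.3 was medium
        sel = compute_selectivity(
            {"5-AVD": 36.3, "lysine": 1.6}, "5-AVD", baseline_correction={"lysine": 0.3}
        )
        assert sel > 97.0

    def test_dilution_invariance(self):
        titers = {"5-AVD": 10.0, "lysine": 2.0}
        sel1 = compute_selectivity(titers, "5-AVD")
        sel2 = compute_selectivity({k: v / 7 for k, v in titers.items()}, "5-AVD")
        assert sel1 == pytest.approx(sel2, rel=1e-12)

    def test_all_zero_signalled(self):
        with pytest.raises(ValueError):
            compute_selectivity({"5-AVD": 0.0}, "5-AVD")


class TestSpaceTimeYield:
    def test_linear_rise(self):
        tc = CultureTimeCourse(
            times=np.linspace(0, 36, 10),
            od660=np.ones(10),
            concentrations={"5-AVD": np.linspace(0, 36, 10)},
        )
        overall, maximum = space_time_yield(tc, "5-AVD")
        assert overall == pytest.approx(1.0)
        assert maximum == pytest.approx(1.0)

    def test_piecewise_max_slope(self):
        times = np.array([0.0, 12.0, 24.0, 36.0])
        conc = np.array([0.0, 6.0, 20.4, 28.0])  # middle interval slope 1.2
        tc = CultureTimeCourse(
            times=times, od660=np.ones(4), concentrations={"5-AVD": conc},
            phase_labels=["batch", "feed", "feed", "feed"],
        )
        overall, maximum = space_time_yield(tc, "5-AVD", phase="feed")
        assert maximum == pytest.approx(1.2, abs=1e-12)
        assert overall == pytest.approx((28.0 - 6.0) / 24.0)

    def test_constant_titer(self):
        tc = CultureTimeCourse(
            times=np.arange(4.0), od660=np.ones(4),
            concentrations={"5-AVD": np.full(4, 3.0)},
        )
        assert space_time_yield(tc, "5-AVD") == (0.0, 0.0)

    def test_empty_phase_rejected(self):
        tc = CultureTimeCourse(
            times=np.arange(4.0), od660=np.ones(4),
            concentrations={"5-AVD": np.arange(4.0)}, phase_labels=["batch"] * 4,
        )
        with pytest.raises(ValueError):
            space_time_yield(tc, "5-AVD", phase="feed")


class TestEnzymeActivity:
    def test_lysine_depletion_assay(self):
        # 20 -> 18 mM over 10 min, 10 mL, 3 mg protein total (0.3 mg/mL)
        act, flat = specific_enzyme_activity(
            np.array([0.0, 5.0, 10.0]), np.array([20.0, 19.0, 18.0]),
            protein_mg_per_ml=0.3,
        )
        assert act == pytest.approx(666.7, abs=0.5)
        assert not flat

    def test_flat_substrate_is_zero_and_flagged(self):
        act, flat = specific_enzyme_activity(
            np.array([0.0, 5.0, 10.0]), np.full(3, 20.0), protein_mg_per_ml=0.3
        )
        assert act == 0.0
        assert flat

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            specific_enzyme_activity(np.arange(3.0), np.arange(3.0), 0.0)
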