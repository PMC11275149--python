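import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fdgquant as fq
from fdgquant.errors import ConfigError, ParameterError
from fdgquant.synthetic_data import (
    WEEKLY_MEAN_VOLUME_DAYS,
    WEEKLY_MEAN_VOLUMES_MM3,
    _fine_grid_min,
    feng_plasma_input,
    frame_average,
    two_tissue_concentration,
)

# the classic human-derived Feng parameterization, used as a worked example
FENG_EXAMPLE = fq.InputModelParams(
    a1=851.1, a2=21.9, a3=20.8, lambda1=4.13, lambda2=0.12, lambda3=0.01
)


class TestFengInput:
    def test_zero_at_injection(self):
        assert feng_plasma_input(FENG_EXAMPLE, np.array([0.0, 1.0]))[0] == 0.0

    def test_peaks_early_then_decays_monotonically(self):
        t = np.linspace(0, 60, 36001)
        cp = feng_plasma_input(FENG_EXAMPLE, t)
        peak = int(np.argmax(cp))
        assert t[peak] < 2.0
        assert np.all(np.diff(cp[peak:]) <= 0)
        assert np.all(cp >= 0)

    def test_linear_in_amplitudes(self):
        t = np.linspace(0, 60, 601)
        doubled = fq.InputModelParams(
            a1=2 * 851.1, a2=2 * 21.9, a3=2 * 20.8,
            lambda1=4.13, lambda2=0.12, lambda3=0.01,
        )
        np.testing.assert_allclose(
            feng_plasma_input(doubled, t), 2 * feng_plasma_input(FENG_EXAMPLE, t)
        )

    def test_decay_rate_ordering_is_enforced(self):
        with pytest.raises(ParameterError):
            fq.InputModelParams(lambda1=0.1, lambda2=0.12, lambda3=0.01)


class TestTwoTissueModel:
    def test_zero_influx_gives_zero_tissue(self, input_params):
        tac = fq.simulate_tissue_tac(
            fq.KineticGroundTruth(0.0, 0.2, 0.05, 0.0), input_params
        )
        np.testing.assert_array_equal(tac, 0.0)

    def test_matches_independent_ode_solver(self, input_params):
        """Exponential-update solver agrees with a stiff adaptive integrator."""
        gt = fq.KineticGroundTruth(0.1, 0.2, 0.05, vb=0.1)
        fine = _fine_grid_min(fq.mouse_dynamic_schedule(), 0.1)
        plasma = feng_plasma_input(input_params, fine)
        blood = fq.blood_from_plasma(plasma, fine, input_params)
        ours = two_tissue_concentration(gt, fine, plasma, blood)

        def rhs(t, y):
            cp = feng_plasma_input(input_params, np.array([0.0, max(t, 1e-12)]))[-1]
            return [gt.k1 * cp - (gt.k2 + gt.k3) * y[0], gt.k3 * y[0]]

        check_t = np.array([1.0, 5.0, 15.0, 30.0, 60.0])
        sol = solve_ivp(rhs, (0.0, 60.0), [0.0, 0.0], t_eval=check_t,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        oracle = (1 - gt.vb) * sol.y.sum(axis=0) + gt.vb * fq.blood_from_plasma(
            feng_plasma_input(input_params, check_t), check_t, input_params
        )
        np.testing.assert_allclose(np.interp(check_t, fine, ours), oracle, rtol=1e-4)

    def test_reversible_tracer_approaches_k1_over_k2_equilibrium(self):
        # with k3 = 0 and a slowly varying input, tissue/plasma -> K1/k2
        gt = fq.KineticGroundTruth(0.1, 0.5, 0.0, 0.0)
        slow = fq.InputModelParams(a1=0.0, a2=0.0, a3=100.0)
        t = np.linspace(0, 300, 18001)
        plasma = feng_plasma_input(slow, t)
        tissue = two_tissue_concentration(gt, t, plasma)
        assert gt.ki == 0.0
        # for an input decaying at rate l3 the exact quasi-steady ratio is
        # K1/(k2 - l3), which tends to K1/k2 as the input flattens
        ratio = tissue[-1] / plasma[-1]
        np.testing.assert_allclose(ratio, gt.k1 / (gt.k2 - slow.lambda3), rtol=1e-3)
        np.testing.assert_allclose(ratio, gt.k1 / gt.k2, rtol=0.05)

    def test_negative_rate_constants_rejected(self):
        with pytest.raises(ParameterError):
            fq.KineticGroundTruth(0.1, -0.2, 0.05)
        with pytest.raises(ParameterError):
            fq.KineticGroundTruth(0.1, 0.2, 0.05, vb=1.0)


class TestBloodPlasmaRelation:
    def test_identity_ratio_makes_blood_equal_plasma(self, schedule, input_params):
        t = schedule.mid_times_min
        plasma = feng_plasma_input(input_params, t)
        flat = fq.PlasmaBloodRatio(r0=1.0, r_eq=1.0)
        np.testing.assert_array_equal(fq.blood_from_plasma(plasma, t, flat), plasma)

    def test_late_time_ratio_approaches_equilibrium(self):
        ratio = fq.PlasmaBloodRatio(r0=1.0, r_eq=1.2, tau_r_min=5.0)
        assert ratio(60.0) == pytest.approx(1.2, abs=1e-5)

    def test_plasma_blood_conversion_is_an_exact_inverse_pair(self, schedule, input_params):
        t = schedule.mid_times_min
        plasma = feng_plasma_input(input_params, t)
        blood = fq.blood_from_plasma(plasma, t, input_params)
        from conftest import make_tac

        recovered = fq.plasma_input_from_blood(
            make_tac(schedule, blood, organ="vena_cava"), input_params.ratio
        )
        np.testing.assert_allclose(recovered.plasma_values, plasma, rtol=1e-14)


class TestPhantom:
    def test_noise_free_voi_tacs_equal_analytic_curves(self, clean_phantom):
        session = clean_phantom.session
        for organ, expected in clean_phantom.organ_curves.items():
            tac = fq.extract_tac(session.image, session.mask, organ)
            np.testing.assert_allclose(tac.values, expected, rtol=1e-12)

    def test_vena_cava_region_holds_the_whole_blood_curve(self, clean_phantom):
        session = clean_phantom.session
        vc = fq.extract_tac(session.image, session.mask, "vena_cava")
        np.testing.assert_allclose(vc.values, clean_phantom.blood_curve, rtol=1e-12)

    def test_liver_last_frame_matches_blood_last_frame(self, clean_phantom):
        liver = clean_phantom.organ_curves["liver"]
        assert liver[-1] == pytest.approx(clean_phantom.blood_curve[-1], rel=1e-12)

    def test_same_seed_reproduces_the_session_exactly(self):
        config = fq.PhantomConfig(noise_level=1.0)
        a = fq.build_phantom_session(config, seed=5)
        b = fq.build_phantom_session(config, seed=5)
        np.testing.assert_array_equal(a.session.image.values, b.session.image.values)
        np.testing.assert_array_equal(a.session.mask.labels, b.session.mask.labels)

    def test_overlapping_organs_are_a_config_error(self):
        organs = fq.synthetic_data.default_organs()
        organs["tumor"] = fq.synthetic_data.OrganSpec(
            1, organs["liver"].center_frac, (2.0, 2.0, 2.0),
            fq.KineticGroundTruth(0.1, 0.2, 0.05),
        )
        with pytest.raises(ConfigError):
            fq.build_phantom_session(fq.PhantomConfig(organs=organs), seed=0)

    def test_activities_are_nonnegative(self):
        phantom = fq.build_phantom_session(fq.PhantomConfig(noise_level=2.0), seed=3)
        assert np.all(phantom.session.image.values >= 0)


class TestGrowthCohorts:
    def test_one_noise_free_doubling(self):
        params = fq.GrowthModelParams(
            v0_mm3=10.0, doubling_time_days=7.0, sigma_animal=0.0, sigma_meas=0.0,
            measurement_days=(0.0, 7.0),
        )
        cohort = fq.generate_growth_cohort(params, 3, seed=0)
        day7 = cohort.loc[cohort["day"] == 7.0, "volume_mm3"]
        np.testing.assert_allclose(day7, 20.0)

    def test_same_seed_gives_identical_cohort(self):
        params = fq.growth_preset()
        a = fq.generate_growth_cohort(params, 50, seed=9)
        b = fq.generate_growth_cohort(params, 50, seed=9)
        assert a.equals(b)

    def test_large_cohort_mean_matches_closed_form_model_mean(self):
        params = fq.growth_preset()
        cohort = fq.generate_growth_cohort(params, 10_000, seed=2)
        day29 = cohort.loc[cohort["day"] == 29.0, "volume_mm3"].to_numpy()
        model_mean = params.mean_volume(29.0)
        # mean-one lognormal noise: SE of the sample mean ~ sd/sqrt(n)
        se = day29.std(ddof=1) / np.sqrt(day29.size)
        assert abs(day29.mean() - model_mean) < 4 * se

    def test_preset_anchors_are_the_published_weekly_means(self):
        np.testing.assert_array_equal(WEEKLY_MEAN_VOLUME_DAYS, [7.7, 15.0, 22.0, 29.0])
        np.testing.assert_array_equal(WEEKLY_MEAN_VOLUMES_MM3, [18.0, 44.0, 127.0, 332.0])
        preset = fq.growth_preset("weekly-means")
        assert 4.5 < preset.doubling_time_days < 5.5  # log-linear fit of the means
        alt = fq.growth_preset("reported-doubling")
        assert alt.doubling_time_days == 6.4
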