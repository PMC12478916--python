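"""Cohort simulation: sampling, programming rules, censoring, Kaplan-Meier."""

import math

import numpy as np
import pytest
from pydantic import ValidationError

import pcipace as p


def km_counting_oracle(events, grid):
    """Empirical survival by direct counting (valid without censoring)."""
    times = np.array([e.time for e in events])
    return np.array([(times > t).sum() / len(times) for t in grid])


class TestSampling:
    def test_reproducible_bit_for_bit(self, degenerate_config):
        cfg = p.example_cohort_config(n=100, seed=5)
        assert p.sample_cohort(cfg) == p.sample_cohort(cfg)

    def test_prefix_stability_when_growing_cohort(self):
        small = p.sample_cohort(p.example_cohort_config(n=20, seed=9))
        large = p.sample_cohort(p.example_cohort_config(n=40, seed=9))
        assert large[:20] == small

    def test_degenerate_distributions_give_identical_patients(
        self, degenerate_config
    ):
        patients = p.sample_cohort(degenerate_config)
        assert all(pt == patients[0] for pt in patients)

    def test_indication_frequencies_match_mix(self):
        cfg = p.example_cohort_config(n=20_000, seed=13)
        patients = p.sample_cohort(cfg)
        freq = {
            ind: sum(pt.indication is ind for pt in patients) / len(patients)
            for ind in p.Indication
        }
        for ind, target in cfg.indication_mix.items():
            assert freq[ind] == pytest.approx(target, abs=0.01)

    def test_zero_patients_rejected(self):
        with pytest.raises(ValidationError):
            p.example_cohort_config(n=0, seed=1)

    def test_mix_must_sum_to_one(self, degenerate_config):
        with pytest.raises(ValidationError):
            p.CohortConfig(
                **{
                    **degenerate_config.model_dump(),
                    "indication_mix": {
                        p.Indication.SND: 0.5,
                        p.Indication.COMPLETE_AVB: 0.6,
                    },
                }
            )


class TestLifeTable:
    def test_expected_remaining_decreases_with_age(self):
        lt = p.LifeTable(kind="gompertz")
        values = [lt.expected_remaining(a) for a in (55, 65, 75, 85, 95)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_tabulated_interpolates(self):
        lt = p.LifeTable(
            kind="tabulated", ages=(60.0, 80.0), remaining_years=(24.0, 9.0)
        )
        assert lt.expected_remaining(70.0) == pytest.approx(16.5)

    def test_immortal_never_censors(self):
        lt = p.LifeTable(kind="immortal")
        rng = np.random.default_rng(0)
        assert math.isinf(lt.sample_remaining(80.0, rng))


class TestDeriveProfile:
    def test_snd_on_aai_ddd_dr_device_paces_ventricle_29pct(
        self, degenerate_config, registry
    ):
        cfg = degenerate_config.model_copy(
            update={
                "indication_mix": {
                    p.Indication.SND: 1.0,
                    p.Indication.INTERMITTENT_AVB: 0.0,
                    p.Indication.COMPLETE_AVB: 0.0,
                }
            }
        )
        patient = p.sample_cohort(cfg)[0]
        azure = p.get_device("Azure XT DR", registry)  # AAI/DDD-capable
        prof = p.derive_profile(patient, azure, cfg)
        assert prof.channels[p.Chamber.RV].pacing_fraction == pytest.approx(0.29)
        assert prof.channels[p.Chamber.A].pacing_fraction == pytest.approx(0.70)
        assert prof.rvpa_mode is p.RvpaMode.AAI_DDD
        # without AAI/DDD mode switching the ventricular burden is higher
        accolade = p.get_device("Accolade DR", registry)
        prof2 = p.derive_profile(patient, accolade, cfg)
        assert prof2.channels[p.Chamber.RV].pacing_fraction == pytest.approx(0.47)

    def test_complete_avb_on_sr_device_paces_90pct(
        self, degenerate_config, registry
    ):
        patient = p.sample_cohort(degenerate_config)[0]
        device = p.get_device("Accolade VR", registry)
        prof = p.derive_profile(patient, device, degenerate_config)
        assert prof.channels[p.Chamber.RV].pacing_fraction == pytest.approx(0.90)

    def test_previous_generation_never_remote(self, degenerate_config, registry):
        cfg = degenerate_config.model_copy(update={"remote_adoption": 1.0})
        patient = p.sample_cohort(cfg)[0]
        old = p.get_device("Adapta SR", registry)
        assert (
            p.derive_profile(patient, old, cfg).remote_mode is p.RemoteMode.OFF
        )
        new = p.get_device("Azure XT SR", registry)
        assert (
            p.derive_profile(patient, new, cfg).remote_mode
            is p.RemoteMode.BLUETOOTH
        )

    def test_amplitude_follows_threshold_with_safety_margin(
        self, degenerate_config, registry
    ):
        patient = p.sample_cohort(degenerate_config)[0]  # threshold 1.25 V
        device = p.get_device("Accolade VR", registry)
        prof = p.derive_profile(patient, device, degenerate_config)
        assert prof.channels[p.Chamber.RV].amplitude == pytest.approx(2.5)


class TestPatientLongevity:
    def test_no_progression_matches_closed_form(self, sr_device):
        from conftest import sr_profile

        prof = sr_profile(2.5, fraction=0.47)
        closed = p.project_longevity(sr_device, prof).longevity_years
        assert p.patient_longevity(sr_device, prof, progression=0.0) == closed

    def test_progression_strictly_shortens(self, sr_device):
        from conftest import sr_profile

        prof = sr_profile(2.5, fraction=0.47)
        base = p.patient_longevity(sr_device, prof, progression=0.0)
        prog = p.patient_longevity(sr_device, prof, progression=0.015)
        assert prog < base
        faster = p.patient_longevity(sr_device, prof, progression=0.05)
        assert faster < prog

    def test_saturated_fraction_is_progression_invariant(self, sr_device):
        from conftest import sr_profile

        prof = sr_profile(2.5, fraction=1.0)
        assert p.patient_longevity(
            sr_device, prof, progression=0.1
        ) == p.patient_longevity(sr_device, prof, progression=0.0)

    def test_integration_error_is_small(self, sr_device):
        # closed-form check: with linear drift the analytic depletion time can
        # be solved from the quadratic charge integral
        from conftest import sr_profile

        f0, rate = 0.47, 0.015
        prof = sr_profile(2.5, fraction=f0)
        i0 = p.total_current(sr_device, prof).total
        slope = 2.0  # µA per unit fraction at these settings
        budget = 1e6 * sr_device.battery.capacity_to_eri / 8760.0
        # solve i0*t + slope*rate*t^2/2 = budget (saturation not reached)
        a, b, c = slope * rate / 2.0, i0, -budget
        exact = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        numeric = p.patient_longevity(sr_device, prof, progression=rate)
        assert numeric == pytest.approx(exact, abs=1 / 12 / 10)

    def test_non_positive_step_rejected(self, sr_device):
        from conftest import sr_profile

        with pytest.raises(p.DomainError):
            p.patient_longevity(sr_device, sr_profile(2.5), step=0.0)


class TestCensoring:
    def test_definition(self):
        events = p.censor_events([10.0, 10.0], [8.0, 12.0])
        assert (events[0].time, events[0].observed) == (8.0, False)
        assert (events[1].time, events[1].observed) == (10.0, True)

    def test_infinite_life_observes_everything(self):
        events = p.censor_events([3.0, 7.0], [math.inf, math.inf])
        assert all(e.observed for e in events)

    def test_length_mismatch_rejected(self):
        with pytest.raises(p.DomainError):
            p.censor_events([1.0], [1.0, 2.0])

    def test_shorter_life_expectancy_never_increases_observed_events(self):
        rng = np.random.default_rng(21)
        longevities = rng.uniform(5, 15, size=500)
        observed_counts = []
        for life in (20.0, 12.0, 8.0, 4.0):
            events = p.censor_events(longevities, [life] * 500)
            observed_counts.append(sum(e.observed for e in events))
        assert observed_counts == sorted(observed_counts, reverse=True)


class TestSurvivalCurve:
    def test_degenerate_unit_step(self):
        events = p.censor_events([10.0] * 30, [math.inf] * 30)
        curve = p.survival_curve(events, grid=[0, 5, 9.99, 10.0, 12])
        s = dict(zip(curve.times, curve.survival))
        assert s[0.0] == 1.0 and s[9.99] == 1.0 and s[10.0] == 0.0

    def test_matches_counting_oracle_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(2, 12, size=17)
        events = p.censor_events(times, [math.inf] * 17)
        grid = np.linspace(0, 13, 40)
        curve = p.survival_curve(events, grid=grid)
        oracle = km_counting_oracle(events, curve.times)
        assert np.allclose(curve.survival, oracle, atol=1e-12)

    def test_monotone_with_unit_start(self, degenerate_config, registry):
        device = p.get_device("Micra", registry)
        curve = p.simulate_device(device, degenerate_config)
        assert curve.survival[0] == 1.0
        assert all(
            b <= a + 1e-12 for a, b in zip(curve.survival, curve.survival[1:])
        )

    def test_degenerate_cohort_steps_at_nominal_longevity(
        self, degenerate_config, registry
    ):
        device = p.get_device("Micra", registry)
        patients = p.sample_cohort(degenerate_config)
        profile = p.derive_profile(patients[0], device, degenerate_config)
        nominal = p.project_longevity(device, profile).longevity_years
        curve = p.simulate_device(device, degenerate_config)
        # a single mass point: survival 1 just before, 0 at the nominal time
        assert curve.survival[curve.times.index(nominal)] == 0.0
        before = [s for t, s in zip(curve.times, curve.survival) if t < nominal]
        assert all(s == 1.0 for s in before)

    def test_empty_events_rejected(self):
        with pytest.raises(p.DomainError):
            p.survival_curve([])

    def test_ci_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(17)

        def half_width(n):
            times = rng.lognormal(math.log(10.0), 0.04, size=n)
            events = p.censor_events(times, [math.inf] * n)
            grid = np.quantile(times, [0.25, 0.5, 0.75])
            curve = p.survival_curve(events, grid=grid)
            widths = [
                (hi - lo) / 2
                for t, lo, hi in zip(curve.times, curve.ci_low, curve.ci_high)
                if t > 0
            ]
            return np.median(widths)

        w1, w2 = half_width(1_000), half_width(10_000)
        assert w1 / w2 == pytest.approx(math.sqrt(10), rel=0.25)


class TestSensitivity:
    def test_zero_perturbation_zero_spread(self, sr_device):
        from conftest import sr_profile

        out = p.current_sensitivity(sr_device, sr_profile(2.5), 0.0, 100, 1)
        assert out["sd_years"] == 0.0
        assert out["mean_years"] == pytest.approx(out["nominal_years"])

    def test_seeded_runs_are_identical(self, sr_device):
        from conftest import sr_profile

        a = p.current_sensitivity(sr_device, sr_profile(2.5), 0.05, 200, 7)
        b = p.current_sensitivity(sr_device, sr_profile(2.5), 0.05, 200, 7)
        assert a == b

    def test_output_spread_matches_delta_method(self, sr_device):
        from conftest import sr_profile

        sd_in = 0.04
        prof = sr_profile(2.5, fraction=0.9)
        bd = p.total_current(sr_device, prof)
        comps = np.array(
            [bd.background]
            + list(bd.pacing_per_channel.values())
            + list(bd.options.values())
        )
        # independent multiplicative noise: relative sd of the total is the
        # component-weighted input sd; longevity inherits it to first order
        expected = sd_in * math.sqrt((comps**2).sum()) / comps.sum()
        out = p.current_sensitivity(sr_device, prof, sd_in, 20_000, 23)
        assert out["sd_over_nominal"] == pytest.approx(expected, rel=0.1)


class TestSharedPool:
    def test_two_devices_share_the_patient_pool(self, registry):
        cfg = p.example_cohort_config(n=150, seed=31)
        devices = [
            p.get_device("Azure XT SR", registry),
            p.get_device("Accolade VR", registry),
        ]
        curves = p.simulate_devices(devices, cfg)
        assert set(curves) == {d.name for d in devices}
        # same seed, rerun: bit-identical curves (common random numbers)
        again = p.simulate_devices(devices, cfg)
        assert curves == again
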