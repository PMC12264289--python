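"""Cohort generator: Windkessel physics, sampling calibration, transfer."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pulseco.exceptions import ConfigurationError, DomainError
from pulseco.population import (
    ALL_SITES,
    HYPERDYNAMIC,
    NORMODYNAMIC,
    SITE_AORTA,
    SITE_CAROTID,
    SITE_RADIAL,
    ArterialSiteSpec,
    CardiacParameters,
    GroupSampling,
    PopulationConfig,
    PressureWaveform,
    _simulate_windkessel_cohort,
    generate_population,
    parameters_frame,
    propagate_to_site,
    sample_parameters,
    simulate_aortic_pressure,
    summarize_population,
)


def _params(hr=75.0, sv=70.0, map_=100.0, pv=5.0, zc_frac=0.05, c=1.6, pwv=8.0):
    co = hr * sv / 1000.0
    q_mean = co * 1000.0 / 60.0
    r_tot = (map_ - pv) / q_mean
    zc = zc_frac * r_tot
    return CardiacParameters(
        group=NORMODYNAMIC,
        heart_rate=hr,
        stroke_volume=sv,
        cardiac_output=co,
        target_map=map_,
        peripheral_resistance=r_tot - zc,
        total_compliance=c,
        characteristic_impedance=zc,
        ejection_fraction_of_cycle=0.36,
        venous_pressure=pv,
        pulse_wave_velocity=pwv,
    )


class TestWindkessel:
    def test_dc_balance_matches_closed_form(self):
        """Cycle-mean pressure minus venous pressure equals Q̄ × total
        input resistance (peripheral R + Zc), the Windkessel DC balance."""
        p = _params()
        wave = simulate_aortic_pressure(p)
        q_mean = p.cardiac_output * 1000.0 / 60.0
        expected = p.venous_pressure + q_mean * (
            p.peripheral_resistance + p.characteristic_impedance
        )
        assert wave.mean == pytest.approx(expected, rel=0.01)

    def test_fine_step_integration_agrees(self):
        """Halving the step changes the cycle beyond tolerance nowhere."""
        p = _params()
        coarse = simulate_aortic_pressure(p, dt=p.period / 512)
        fine = simulate_aortic_pressure(p, dt=p.period / 2048)
        assert coarse.mean == pytest.approx(fine.mean, rel=1e-4)
        assert coarse.pulse_pressure == pytest.approx(fine.pulse_pressure, rel=1e-3)

    def test_no_forcing_stays_at_venous_pressure(self):
        """With (numerically) zero inflow and P(0) = P_ven the solution
        is the constant P_ven."""
        arrays = {
            "heart_rate": np.array([75.0]),
            "stroke_volume": np.array([1e-12]),
            "ejection_fraction_of_cycle": np.array([0.36]),
            "peripheral_resistance": np.array([1.0]),
            "total_compliance": np.array([1.5]),
            "characteristic_impedance": np.array([0.05]),
            "venous_pressure": np.array([5.0]),
            "target_map": np.array([5.0]),  # initial condition = P_ven
        }
        p_ao, converged = _simulate_windkessel_cohort(arrays, 512)
        assert converged.all()
        assert np.allclose(p_ao, 5.0, atol=1e-9)

    def test_doubling_compliance_reduces_pulse_pressure(self):
        p = _params(c=1.6)
        p2 = dataclasses.replace(p, total_compliance=3.2)
        assert (
            simulate_aortic_pressure(p2).pulse_pressure
            < simulate_aortic_pressure(p).pulse_pressure
        )

    def test_coarse_step_rejected(self):
        p = _params()
        with pytest.raises(DomainError):
            simulate_aortic_pressure(p, dt=p.period / 100)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(DomainError):
            _params(sv=-10.0)


class TestTubeLoad:
    def _sine_wave(self, period=1.0, n=512, freq_harmonic=1, mean=100.0, amp=10.0):
        t = np.arange(n) * period / n
        p = mean + amp * np.sin(2 * np.pi * freq_harmonic * t / period)
        return PressureWaveform(SITE_AORTA, period, t, p)

    def test_identity_transfer_is_circular_delay(self):
        """Γ=0, α=0, no drop: the output is the input circularly
        delayed by L/c."""
        # L=25 cm, c=8 m/s, T=1 s → delay = 16 of 512 samples exactly
        site = ArterialSiteSpec("x", 25.0, 0, 0.0, 0.0, 0.0)
        p = _params(hr=60.0, pwv=8.0)
        rng = np.random.default_rng(3)
        base = 100 + np.cumsum(rng.normal(size=512))
        base = base - np.linspace(0, base[-1] - base[0], 512)  # periodic-ish
        t = np.arange(512) / 512
        wave = PressureWaveform(SITE_AORTA, 1.0, t, base)
        out = propagate_to_site(wave, site, p)
        shifted = np.roll(wave.pressure - wave.pressure.mean(), 16) + wave.pressure.mean()
        assert np.allclose(out.pressure, shifted, atol=1e-8)

    @pytest.mark.parametrize("harmonic", [1, 3])
    def test_sinusoid_gain_matches_transfer_magnitude(self, harmonic):
        site = ArterialSiteSpec("x", 60.0, 0, 0.4, 0.003, 0.0)
        p = _params(hr=60.0, pwv=7.0)
        wave = self._sine_wave(freq_harmonic=harmonic)
        out = propagate_to_site(wave, site, p)
        # closed-form |H| at the driven harmonic
        omega = 2 * np.pi * harmonic / wave.period
        prop = (1j * omega / (p.pulse_wave_velocity * 100) + site.attenuation_per_cm) * site.path_length
        g = site.reflection_coefficient
        h = (1 + g) * np.exp(-prop) / (1 + g * np.exp(-2 * prop))
        spec_in = np.fft.rfft(wave.pressure - wave.pressure.mean())
        spec_out = np.fft.rfft(out.pressure - out.pressure.mean())
        measured_gain = abs(spec_out[harmonic]) / abs(spec_in[harmonic])
        assert measured_gain == pytest.approx(abs(h), rel=1e-9)

    def test_unstable_reflection_rejected(self):
        with pytest.raises(DomainError):
            ArterialSiteSpec("x", 10.0, 0, 1.0, 0.0, 0.0)

    def test_aorta_not_a_propagation_target(self, small_cohort):
        s = small_cohort[0]
        site = ArterialSiteSpec(SITE_AORTA, 0.0, 0, 0.0, 0.0, 0.0)
        with pytest.raises(DomainError):
            propagate_to_site(s.waveforms[SITE_AORTA], site, s.params)


class TestSampling:
    def test_group_means_near_targets(self):
        cfg = PopulationConfig(n_normodynamic=2000, n_hyperdynamic=1000, seed=5)
        params = sample_parameters(cfg, np.random.default_rng(5))
        for group, co_t, hr_t, map_t in (
            (NORMODYNAMIC, 5.5, 81.9, 108.1),
            (HYPERDYNAMIC, 6.9, 83.9, 85.8),
        ):
            sub = [p for p in params if p.group == group]
            n = len(sub)
            assert np.mean([p.cardiac_output for p in sub]) == pytest.approx(
                co_t, abs=3 * 1.0 / np.sqrt(n)
            )
            assert np.mean([p.heart_rate for p in sub]) == pytest.approx(hr_t, abs=1.0)
            assert np.mean([p.target_map for p in sub]) == pytest.approx(
                map_t, abs=3 * 21 / np.sqrt(n)
            )

    def test_heart_rate_respects_truncation_bounds(self):
        cfg = PopulationConfig(n_normodynamic=500, n_hyperdynamic=500, seed=6)
        params = sample_parameters(cfg, np.random.default_rng(6))
        for p in params:
            lo, hi = cfg.groups[p.group].hr_bounds
            assert lo <= p.heart_rate <= hi

    def test_co_identity_exact(self):
        cfg = PopulationConfig(n_normodynamic=50, n_hyperdynamic=50, seed=1)
        for p in sample_parameters(cfg, np.random.default_rng(1)):
            assert p.cardiac_output == pytest.approx(
                p.heart_rate * p.stroke_volume / 1000.0, abs=1e-12
            )

    def test_degenerate_zero_variance_sampler(self):
        groups = {
            g: dataclasses.replace(
                gs, co_sd=1e-9, map_sd=1e-9, hr_sd=1e-9, compliance_jitter=0.0
            )
            for g, gs in PopulationConfig().groups.items()
        }
        cfg = PopulationConfig(n_normodynamic=5, n_hyperdynamic=5, groups=groups)
        params = sample_parameters(cfg, np.random.default_rng(0))
        normo = [p for p in params if p.group == NORMODYNAMIC]
        assert all(
            p.cardiac_output == pytest.approx(normo[0].cardiac_output, abs=1e-6)
            for p in normo
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(n_normodynamic=0).validate()
        bad_groups = dict(PopulationConfig().groups)
        bad_groups[NORMODYNAMIC] = dataclasses.replace(
            bad_groups[NORMODYNAMIC], co_sd=-1.0
        )
        with pytest.raises(ConfigurationError):
            PopulationConfig(groups=bad_groups).validate()
        bad_groups[NORMODYNAMIC] = dataclasses.replace(
            PopulationConfig().groups[NORMODYNAMIC], hr_bounds=(120.0, 140.0)
        )
        with pytest.raises(ConfigurationError):
            PopulationConfig(groups=bad_groups).validate()


class TestCohort:
    def test_exact_counts_and_sites(self, small_cohort):
        assert len(small_cohort) == 240
        for s in small_cohort:
            assert set(s.waveforms) == set(ALL_SITES)
            periods = {w.period for w in s.waveforms.values()}
            assert len(periods) == 1

    def test_same_seed_reproducible(self):
        cfg = PopulationConfig(n_normodynamic=30, n_hyperdynamic=15, seed=21)
        a = parameters_frame(generate_population(cfg))
        b = parameters_frame(generate_population(cfg))
        assert a.equals(b)

    def test_dc_balance_for_every_subject(self, small_cohort):
        for s in small_cohort:
            p = s.params
            q_mean = p.cardiac_output * 1000.0 / 60.0
            expected = p.venous_pressure + q_mean * (
                p.peripheral_resistance + p.characteristic_impedance
            )
            assert s.waveforms[SITE_AORTA].mean == pytest.approx(expected, rel=0.01)

    def test_group_co_separation(self, small_cohort, small_cohort_groups):
        co = np.array([s.params.cardiac_output for s in small_cohort])
        g0 = co[small_cohort_groups == NORMODYNAMIC]
        g1 = co[small_cohort_groups == HYPERDYNAMIC]
        assert mannwhitneyu(g0, g1).pvalue < 1e-3

    def test_peripheral_amplification_ordering(self, small_cohort, small_cohort_groups):
        """Mean pulse pressure: radial > carotid > ascending aorta."""
        for group in (NORMODYNAMIC, HYPERDYNAMIC):
            pps = {
                site: np.mean(
                    [
                        s.waveforms[site].pulse_pressure
                        for s, g in zip(small_cohort, small_cohort_groups)
                        if g == group
                    ]
                )
                for site in (SITE_AORTA, SITE_CAROTID, SITE_RADIAL)
            }
            assert pps[SITE_RADIAL] > pps[SITE_CAROTID] > pps[SITE_AORTA]

    def test_two_subject_population(self):
        cfg = PopulationConfig(n_normodynamic=1, n_hyperdynamic=1, seed=2)
        pop = generate_population(cfg)
        assert [s.params.group for s in pop] == [NORMODYNAMIC, HYPERDYNAMIC]

    def test_summary_single_subject_degenerate(self):
        cfg = PopulationConfig(n_normodynamic=1, n_hyperdynamic=1, seed=2)
        table = summarize_population(generate_population(cfg))
        sd_cols = table.loc[:, (slice(None), "sd")]
        assert (sd_cols.to_numpy() == 0).all()
        mins = table.loc[:, (slice(None), "min")].to_numpy()
        maxs = table.loc[:, (slice(None), "max")].to_numpy()
        assert np.allclose(mins, maxs)

    def test_waveform_invariants(self, small_cohort):
        for s in small_cohort[::17]:
            for w in s.waveforms.values():
                assert w.diastolic <= w.mean <= w.systolic
                assert w.pulse_pressure == pytest.approx(w.systolic - w.diastolic)
                assert (w.pressure > 0).all()
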