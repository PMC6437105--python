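"""Adsorption-rate, latent-period/burst and stability-profile estimators."""

import numpy as np
import pytest

from phagechar import (
    PHAGE_PRESETS,
    KineticSeries,
    NoiseModel,
    estimate_latent_burst,
    fit_adsorption,
    make_adsorption_series,
    make_onestep_series,
    make_stability_series,
    stability_profile,
)
from phagechar.errors import EstimationError, InvalidParameterError, InvalidReferenceError

HOST_DENSITY = 1e8  # one-step inoculum; convention for mL/min recovery


class TestFitAdsorption:
    @pytest.mark.parametrize("key", sorted(PHAGE_PRESETS))
    def test_noiseless_recovery_within_1_percent(self, key):
        preset = PHAGE_PRESETS[key]
        s = make_adsorption_series(preset, host_density=HOST_DENSITY)
        fit = fit_adsorption(s, host_density=HOST_DENSITY)
        assert fit.k_ads == pytest.approx(preset.k_ads, rel=0.01)
        assert fit.diagnostics["r_squared"] > 0.999

    def test_constant_series_reports_zero_with_warning(self):
        s = KineticSeries("adsorption", np.arange(0, 41, 4.0), np.full(11, 1e5))
        fit = fit_adsorption(s, host_density=HOST_DENSITY)
        assert fit.k_ads == 0.0
        assert fit.warnings

    def test_scale_invariance(self, klebsiella):
        s = make_adsorption_series(klebsiella, host_density=HOST_DENSITY)
        scaled = KineticSeries("adsorption", s.times, s.values * 37.0, dict(s.metadata))
        a = fit_adsorption(s, host_density=HOST_DENSITY)
        b = fit_adsorption(scaled, host_density=HOST_DENSITY)
        assert a.k_ads == pytest.approx(b.k_ads, rel=1e-12)

    def test_too_few_points_raises(self, escherichia):
        s = make_adsorption_series(escherichia, host_density=HOST_DENSITY, times=[0, 4])
        with pytest.raises(EstimationError):
            fit_adsorption(s, host_density=HOST_DENSITY)

    def test_noisy_triplicate_recovery_within_25_percent(self):
        # for each preset, >=95% of 200 seeded triplicates within +/-25%
        for key, preset in PHAGE_PRESETS.items():
            means = []
            for rep in range(200):
                ks = []
                for i in range(3):
                    noise = NoiseModel(count_noise=True, seed=20_000 + rep * 3 + i)
                    s = make_adsorption_series(preset, host_density=HOST_DENSITY, noise=noise)
                    ks.append(fit_adsorption(s, host_density=HOST_DENSITY).k_ads)
                means.append(np.mean(ks))
            frac = np.mean(np.abs(np.array(means) / preset.k_ads - 1) <= 0.25)
            assert frac >= 0.95, key


class TestEstimateLatentBurst:
    @pytest.mark.parametrize(
        "key, latent_band",
        [
            ("escherichia_myPSH2311", (22.5, 27.5)),
            ("klebsiella_myPSH1235", (37.5, 42.5)),
            ("enterobacter_myPSH1140", (7.5, 15.0)),
        ],
    )
    def test_noiseless_recovery(self, key, latent_band):
        preset = PHAGE_PRESETS[key]
        est = estimate_latent_burst(make_onestep_series(preset))
        assert latent_band[0] <= est.latent_min <= latent_band[1]
        # within half a sampling interval of the preset value
        assert abs(est.latent_min - preset.latent_min) <= 2.5
        assert est.burst == pytest.approx(preset.burst, rel=0.02)
        assert not est.burst_is_lower_bound

    def test_flat_series_raises_no_burst(self):
        s = KineticSeries("onestep", np.arange(0, 81, 5.0), np.full(17, 1e5))
        with pytest.raises(EstimationError, match="no burst"):
            estimate_latent_burst(s)

    def test_scale_invariance(self, enterobacter):
        s = make_onestep_series(enterobacter)
        scaled = KineticSeries("onestep", s.times, s.values * 1e3, dict(s.metadata))
        a, b = estimate_latent_burst(s), estimate_latent_burst(scaled)
        assert a.latent_min == b.latent_min
        assert a.burst == pytest.approx(b.burst, rel=1e-12)

    def test_latent_unchanged_by_postplateau_points(self, escherichia):
        short = make_onestep_series(escherichia, times=np.arange(0.0, 81.0, 5.0))
        long = make_onestep_series(escherichia, times=np.arange(0.0, 121.0, 5.0))
        assert estimate_latent_burst(short).latent_min == estimate_latent_burst(long).latent_min

    def test_still_rising_curve_flags_lower_bound(self, klebsiella):
        s = make_onestep_series(klebsiella, times=np.arange(0.0, 46.0, 5.0))
        est = estimate_latent_burst(s)
        assert est.burst_is_lower_bound

    def test_noisy_triplicate_recovery(self):
        # latent within +/-5 min and burst within +/-15% in >=95% of 200 repeats
        for key, preset in PHAGE_PRESETS.items():
            lat_means, burst_means = [], []
            for rep in range(200):
                lats, bursts = [], []
                for i in range(3):
                    noise = NoiseModel(count_noise=True, seed=30_000 + rep * 3 + i)
                    est = estimate_latent_burst(make_onestep_series(preset, noise=noise))
                    lats.append(est.latent_min)
                    bursts.append(est.burst)
                lat_means.append(np.mean(lats))
                burst_means.append(np.mean(bursts))
            lat_ok = np.mean(np.abs(np.array(lat_means) - preset.latent_min) <= 5.0)
            burst_ok = np.mean(np.abs(np.array(burst_means) / preset.burst - 1) <= 0.15)
            assert lat_ok >= 0.95, key
            assert burst_ok >= 0.95, key


class TestStabilityProfile:
    def test_viability_arithmetic(self):
        rep = stability_profile("pH", [7.0, 8.0], [1e8, 5e7], reference=1e8)
        assert rep.series.viability[0] == pytest.approx(100.0)
        assert rep.series.viability[1] == pytest.approx(50.0)

    def test_ph_stable_window_and_inactivation(self):
        s = make_stability_series("pH")
        rep = stability_profile("pH", s.conditions, s.viability / 100 * 1e8, reference=1e8)
        assert rep.stable_window == (4.0, 11.0)
        assert set(rep.inactivated_conditions) == {1.0, 2.0, 3.0, 12.0, 13.0, 14.0}

    def test_temperature_stable_to_55(self):
        s = make_stability_series("temperature")
        rep = stability_profile("temperature", s.conditions, s.viability / 100 * 1e8, 1e8)
        assert rep.stable_window == (4.0, 55.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidReferenceError):
            stability_profile("pH", [7.0], [1e8], reference=0.0)

    def test_viability_capped_at_100(self):
        rep = stability_profile("pH", [7.0], [2e8], reference=1e8)
        assert rep.series.viability[0] == 100.0
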