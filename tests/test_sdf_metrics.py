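import numpy as np
import pytest

from delaycode.io_core import AnalysisWindow
from delaycode.sdf_metrics import (
    FlatSDFError,
    SpikeDensityFunction,
    half_duration,
    normalize_sdf,
    peak_order,
    sdf_for_unit,
    spike_density,
)
from delaycode.synthetic import (
    NeuronSpec,
    SimConfig,
    generate_session,
    rate_function,
    rate_max,
    sample_spikes,
)

DELAY = AnalysisWindow("delay_on", 0.0, 4.0)
FWHM_HALF = np.sqrt(2 * np.log(2))  # one-sided half-width of a unit Gaussian


def gaussian_sdf(center, std, window=(0.0, 4.0), dt=0.01):
    grid = np.arange(window[0], window[1] + dt / 2, dt)
    rate = np.exp(-((grid - center) ** 2) / (2 * std**2))
    return SpikeDensityFunction(grid, rate, sigma=0.1, n_trials=1, normalized=True)


class TestSpikeDensity:
    def test_single_spike_peak_value(self):
        sdf = spike_density([np.array([2.0])], AnalysisWindow("delay_on", 0.0, 4.0))
        idx = np.argmin(np.abs(sdf.time_grid - 2.0))
        assert sdf.rate[idx] == pytest.approx(1.0 / (0.1 * np.sqrt(2 * np.pi)), rel=1e-6)

    def test_no_spikes_all_zero(self):
        sdf = spike_density([np.empty(0), np.empty(0)], DELAY)
        assert np.all(sdf.rate == 0.0)

    def test_kernel_mass_conservation(self):
        """Integral of the SDF equals spike count / n_trials."""
        rng = np.random.default_rng(5)
        trains = [np.sort(rng.uniform(1.0, 3.0, 12)) for _ in range(4)]
        window = AnalysisWindow("delay_on", 0.0, 4.0)
        sdf = spike_density(trains, window, sigma=0.1, dt=0.002)
        integral = np.trapezoid(sdf.rate, sdf.time_grid)
        assert abs(integral - 12.0) < 1e-3

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            spike_density([], DELAY)


class TestNormalize:
    def test_minmax_mapping(self):
        grid = np.arange(0, 0.03, 0.01)
        sdf = SpikeDensityFunction(grid, np.array([1.0, 3.0, 5.0]), 0.1, 1)
        out = normalize_sdf(sdf)
        np.testing.assert_allclose(out.rate, [0.0, 0.5, 1.0])
        assert out.normalized

    def test_flat_sdf_rejected(self):
        grid = np.arange(0, 0.03, 0.01)
        sdf = SpikeDensityFunction(grid, np.full(3, 2.0), 0.1, 1)
        with pytest.raises(FlatSDFError):
            normalize_sdf(sdf)

    def test_bounds_invariant(self, rng):
        grid = np.arange(0, 1.0, 0.01)
        sdf = SpikeDensityFunction(grid, rng.uniform(0.5, 9, grid.size), 0.1, 1)
        out = normalize_sdf(sdf)
        assert out.rate.min() == 0.0 and out.rate.max() == 1.0


class TestHalfDuration:
    def test_gaussian_fwhm_identity(self):
        """One-sided half-duration of a Gaussian bump is std*sqrt(2 ln 2)."""
        for std in (0.2, 0.4, 0.6):
            hd = half_duration(gaussian_sdf(2.0, std))
            assert hd.value == pytest.approx(FWHM_HALF * std, abs=0.011)
            assert not hd.censored

    def test_longer_side_is_reported(self):
        # peak near the left edge: left side censors, right side crosses;
        # a crossing side wins over a censored one
        hd = half_duration(gaussian_sdf(0.2, 0.15))
        assert hd.side == "right" and not hd.censored

    def test_plateau_censored_at_window_edge(self):
        # idealized persistent-activity limit: flat at the maximum across
        # the whole window; neither side ever crosses 0.5
        grid = np.arange(0.0, 4.0 + 0.005, 0.01)
        sdf = SpikeDensityFunction(grid, np.ones_like(grid), 0.1, 1, normalized=True)
        hd = half_duration(sdf)
        assert hd.censored and hd.value == pytest.approx(4.0, abs=0.02)

    def test_unnormalized_rejected(self):
        sdf = gaussian_sdf(2.0, 0.3)
        sdf.normalized = False
        with pytest.raises(ValueError):
            half_duration(sdf)

    def test_scale_invariance(self, rng):
        """Half-duration unchanged when all rates are multiplied by 7.3."""
        grid = np.arange(0, 4.0, 0.01)
        raw = np.exp(-((grid - 1.7) ** 2) / (2 * 0.5**2)) + 0.05 * rng.uniform(size=grid.size)
        a = half_duration(normalize_sdf(SpikeDensityFunction(grid, raw, 0.1, 1)))
        b = half_duration(normalize_sdf(SpikeDensityFunction(grid, raw * 7.3, 0.1, 1)))
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_monte_carlo_recovery_of_tuning_width(self):
        """Half-duration of a simulated bump neuron recovers the
        Gaussian-convolution prediction 1.1774*sqrt(w^2 + sigma^2)."""
        w, sigma = 0.3, 0.1
        spec = NeuronSpec(
            unit_id="s", code_type="sequential", baseline_rate=0.5, peak_gain=60.0,
            tuning_center=2.0, tuning_width=w,
        )
        trial = {"condition": "fixed", "sample": "L", "t_delay_on": 2.0, "t_delay_off": 6.0}
        fn = rate_function(spec, trial)
        rng = np.random.default_rng(42)
        trains = [
            sample_spikes(fn, 4.0, rng, rate_max(spec), t_start=2.0) - 2.0
            for _ in range(400)
        ]
        sdf = normalize_sdf(spike_density(trains, DELAY, sigma=sigma))
        hd = half_duration(sdf)
        assert hd.value == pytest.approx(FWHM_HALF * np.sqrt(w**2 + sigma**2), abs=0.04)


class TestPeakOrder:
    def test_ascending_with_tiebreak(self):
        sdfs = {
            "unit1": gaussian_sdf(3.0, 0.3),
            "unit2": gaussian_sdf(1.0, 0.3),
            "unit3": gaussian_sdf(2.0, 0.3),
        }
        assert peak_order(sdfs) == ["unit2", "unit3", "unit1"]
        tied = {"b": gaussian_sdf(1.0, 0.3), "a": gaussian_sdf(1.0, 0.3)}
        assert peak_order(tied) == ["a", "b"]

    def test_recovers_ground_truth_tuning_order(self):
        """Peak order on simulated sequential units matches tuning centers."""
        from scipy.stats import spearmanr

        centers = np.linspace(0.3, 3.7, 12)
        specs = [
            NeuronSpec(unit_id=f"u{i:02d}", code_type="sequential", baseline_rate=1.0,
                       peak_gain=8.0, tuning_center=c, tuning_width=0.25)
            for i, c in enumerate(centers)
        ]
        cfg = SimConfig(n_trials_per_condition=80, p_correct=1.0, seed=9)
        units, trials, _ = generate_session(cfg, specs=specs)
        fixed = trials[trials["condition"] == "fixed"]
        sdfs = {
            s.unit_id: normalize_sdf(sdf_for_unit(units[s.unit_id], fixed, DELAY))
            for s in specs
        }
        order = peak_order(sdfs)
        recovered_rank = [order.index(s.unit_id) for s in specs]
        rho, _ = spearmanr(recovered_rank, np.arange(len(specs)))
        assert rho > 0.9


class TestPopulationContrasts:
    def test_sequential_shorter_than_persistent(self):
        """Mean half-duration: sequential bumps < persistent elevation."""
        seq = [
            NeuronSpec(unit_id=f"s{i}", code_type="sequential", baseline_rate=1.0,
                       peak_gain=6.0, tuning_center=c, tuning_width=0.3)
            for i, c in enumerate((0.8, 1.6, 2.4, 3.2))
        ]
        per = [
            NeuronSpec(unit_id=f"p{i}", code_type="persistent", baseline_rate=1.0,
                       peak_gain=1.0)
            for i in range(4)
        ]
        cfg = SimConfig(n_trials_per_condition=60, p_correct=1.0, seed=17)
        units, trials, _ = generate_session(cfg, specs=seq + per)
        fixed = trials[trials["condition"] == "fixed"]

        def mean_hd(specs):
            vals = []
            for s in specs:
                sdf = normalize_sdf(sdf_for_unit(units[s.unit_id], fixed, DELAY))
                vals.append(half_duration(sdf).value)
            return np.mean(vals)

        assert mean_hd(seq) < mean_hd(per)

    def test_half_duration_monotone_in_tuning_width(self):
        """Narrower ground-truth bumps give shorter mean half-durations."""
        means = []
        for width in (0.15, 0.35, 0.6):
            specs = [
                NeuronSpec(unit_id=f"w{i}", code_type="sequential", baseline_rate=1.0,
                           peak_gain=8.0, tuning_center=c, tuning_width=width)
                for i, c in enumerate((1.2, 2.0, 2.8))
            ]
            cfg = SimConfig(n_trials_per_condition=60, p_correct=1.0, seed=23)
            units, trials, _ = generate_session(cfg, specs=specs)
            fixed = trials[trials["condition"] == "fixed"]
            vals = [
                half_duration(normalize_sdf(sdf_for_unit(units[s.unit_id], fixed, DELAY))).value
                for s in specs
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
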