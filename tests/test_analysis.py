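"""LFP construction and spectral statistics on signals with known truth."""

import numpy as np
import pytest

from ca3gamma.analysis import (
    LfpTrace,
    PowerSpectrum,
    band_power,
    compute_lfp,
    delta_gamma,
    mean_rate,
    peak_frequency,
    pooled_rate_signal,
    raster_gamma,
    welch_power,
)
from ca3gamma.engine import SimulationResult
from ca3gamma.fixtures import SurrogateSpec, make_surrogate_lfp


def _fake_result(v_adend3, v_bdend, rec_dt=1.0, discard=0.0, spikes=None,
                 n_pyr=None):
    """Minimal SimulationResult for analysis tests."""
    n_rec, n = v_adend3.shape
    n_pyr = n_pyr or n
    t, g = spikes if spikes is not None else (np.empty(0), np.empty(0, int))
    return SimulationResult(
        spike_times=t, spike_gids=g,
        n_pyr=n_pyr, n_bas=10, n_olm=10,
        rec_times=np.arange(n_rec) * rec_dt,
        v_soma=v_adend3.astype(np.float32),
        v_bdend=v_bdend.astype(np.float32),
        v_adend3=v_adend3.astype(np.float32),
        config=None, duration=n_rec * rec_dt, discard=discard,
        seed=0, dt=0.025,
    )


class TestComputeLfp:
    def test_identical_traces_zero_lfp(self):
        v = np.random.default_rng(0).normal(size=(1000, 5))
        res = _fake_result(v, v)
        assert np.allclose(compute_lfp(res).values, 0.0)

    def test_single_cell_passthrough(self):
        d = np.sin(np.linspace(0, 10, 500))[:, None]
        res = _fake_result(d, np.zeros_like(d))
        np.testing.assert_allclose(compute_lfp(res).values, d[:, 0],
                                   atol=1e-6)

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(800, 4))
        b = rng.normal(size=(800, 4))
        common = rng.normal(size=(800, 1)) * 7.0
        lfp0 = compute_lfp(_fake_result(a, b)).values
        lfp1 = compute_lfp(_fake_result(a + common, b + common)).values
        np.testing.assert_allclose(lfp0, lfp1, atol=1e-4)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a1, b1 = rng.normal(size=(300, 3)), rng.normal(size=(300, 3))
        a2, b2 = rng.normal(size=(300, 3)), rng.normal(size=(300, 3))
        lfp_sum = compute_lfp(_fake_result(a1 + a2, b1 + b2)).values
        lfp1 = compute_lfp(_fake_result(a1, b1)).values
        lfp2 = compute_lfp(_fake_result(a2, b2)).values
        np.testing.assert_allclose(lfp_sum, lfp1 + lfp2, atol=1e-4)

    def test_window_excludes_equilibration(self):
        v = np.ones((1000, 2))
        res = _fake_result(v, np.zeros_like(v), discard=300.0)
        lfp = compute_lfp(res)
        assert lfp.window == (300.0, 1000.0)
        assert lfp.values.size == 700


class TestWelchAndBandPower:
    def test_pure_sine_parseval(self):
        """A 40 Hz sine of amplitude A carries total power A²/2."""
        a = 2.0
        tr = make_surrogate_lfp(
            SurrogateSpec(duration=4.0, components=[(40.0, a, 0.0)])
        )
        spec = welch_power(tr)
        assert band_power(spec, 30, 100) == pytest.approx(a * a / 2,
                                                          rel=0.02)
        assert band_power(spec, 101, 200) == pytest.approx(0.0, abs=1e-6)
        assert peak_frequency(spec) == pytest.approx(40.0, abs=1.0)

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 8000)
        spec = welch_power(x, fs=1000.0)
        sel = spec.frequencies > 2
        logp = np.log(spec.power[sel])
        slope = np.polyfit(spec.frequencies[sel], logp, 1)[0]
        assert abs(slope) < 1e-3

    def test_constant_signal_power_at_dc_only(self):
        spec = welch_power(np.full(4000, 3.0), fs=1000.0)
        assert np.all(spec.power[spec.frequencies > 0] < 1e-12)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            welch_power(np.zeros(100), fs=1000.0, segment_len=1.0)

    def test_band_partition_recovers_total(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 4000)
        spec = welch_power(x, fs=1000.0)
        total = float(spec.power.sum())
        split = band_power(spec, 0.0, 99.5) + band_power(spec, 100.0, 500.0)
        assert split == pytest.approx(total, rel=1e-10)

    def test_two_sines_gamma_captures_half(self):
        tr = make_surrogate_lfp(
            SurrogateSpec(duration=4.0,
                          components=[(10.0, 1.0, 0.0), (60.0, 1.0, 0.3)])
        )
        spec = welch_power(tr)
        total = band_power(spec, 0, 500)
        assert band_power(spec, 30, 100) == pytest.approx(total / 2,
                                                          rel=0.05)

    def test_empty_band_raises(self):
        spec = welch_power(np.random.default_rng(0).normal(size=2000),
                           fs=1000.0)
        with pytest.raises(ValueError):
            band_power(spec, 501, 600)

    def test_spectrum_invariants(self):
        with pytest.raises(ValueError):
            PowerSpectrum(frequencies=np.array([3.0, 1.0]),
                          power=np.array([1.0, 1.0]))


class TestDeltaGamma:
    @pytest.mark.parametrize(
        "cond,ctrl,expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0),
                               (0.5, 1.0, -0.5)]
    )
    def test_ratio_minus_one(self, cond, ctrl, expected):
        assert delta_gamma(cond, ctrl) == pytest.approx(expected)

    def test_zero_control_raises(self):
        with pytest.raises(ValueError):
            delta_gamma(1.0, 0.0)


class TestRasterGamma:
    def test_empty_raster_zero(self):
        assert raster_gamma(np.array([]), (0.0, 4000.0)) == 0.0

    def test_periodic_volleys_peak_in_band(self):
        # 100 cells firing synchronized volleys at 40 Hz
        volleys = np.arange(0.0, 4000.0, 25.0)
        t = np.repeat(volleys, 100)
        sig, fs = pooled_rate_signal(t, (0.0, 4000.0))
        spec = welch_power(sig, fs=fs)
        pk = peak_frequency(spec, lo=5.0)
        assert pk == pytest.approx(40.0, abs=1.0)
        assert raster_gamma(t, (0.0, 4000.0)) > 0

    def test_poisson_scales_with_rate_without_peak(self):
        rng = np.random.default_rng(5)
        g_by_rate = []
        for total_rate in (2000.0, 8000.0):
            n = rng.poisson(total_rate * 4.0)
            t = np.sort(rng.uniform(0, 4000.0, n))
            g_by_rate.append(raster_gamma(t, (0.0, 4000.0)))
            sig, fs = pooled_rate_signal(t, (0.0, 4000.0))
            spec = welch_power(sig, fs=fs)
            in_band = (spec.frequencies >= 30) & (spec.frequencies <= 100)
            peak = spec.power[in_band].max()
            med = np.median(spec.power[in_band])
            assert peak < 6 * med  # no discrete spectral line
        assert g_by_rate[1] > g_by_rate[0]

    def test_invariant_to_cell_relabeling(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 2000.0, 500))
        assert raster_gamma(t, (0, 2000.0)) == raster_gamma(
            t[rng.permutation(t.size)], (0, 2000.0)
        )


class TestMeanRate:
    def test_no_spikes(self):
        res = _fake_result(np.zeros((100, 2)), np.zeros((100, 2)))
        assert mean_rate(res, "pyr", (0, 100.0)) == 0.0

    def test_800_cells_one_spike_each_in_4s(self):
        gids = np.arange(800)
        t = np.linspace(0, 3999.0, 800)
        res = _fake_result(np.zeros((4000, 2)), np.zeros((4000, 2)),
                           spikes=(t, gids), n_pyr=800)
        assert mean_rate(res, "pyr", (0, 4000.0)) == pytest.approx(0.25)

    def test_exact_rate(self):
        # 10 cells at exactly 3 Hz for 2 s
        t = np.tile(np.arange(0, 2000.0, 1000.0 / 3.0), 10)
        gids = np.repeat(np.arange(10), 6)
        res = _fake_result(np.zeros((2000, 2)), np.zeros((2000, 2)),
                           spikes=(np.sort(t), gids), n_pyr=10)
        assert mean_rate(res, "pyr", (0, 2000.0)) == pytest.approx(3.0)

    def test_unknown_population_raises(self):
        res = _fake_result(np.zeros((100, 2)), np.zeros((100, 2)))
        with pytest.raises(ValueError):
            mean_rate(res, "granule", (0, 100.0))
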