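import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvphantom.flow import (
    NormalizedVolumeSeries,
    compare_modalities,
    ejection_fraction,
    integrate_volume,
    normalize_volume,
    resample_spline,
)
from lvphantom.waveform import FlowSeries, VolumeSeries, derive_flows, make_volume_waveform


class TestIntegrateVolume:
    def test_constant_inflow_arithmetic(self):
        # 6 L/min = 100 mL/s for 0.3 s from an ESV of 31 mL -> 61 mL
        t = np.linspace(0, 0.3, 31)
        f = FlowSeries(t, np.full(31, 6.0), np.zeros(31), period=0.3)
        v = integrate_volume(f, esv_constant=31.0, t_reference=0.0)
        assert v.volumes[-1] == pytest.approx(61.0, rel=1e-6)

    def test_round_trip_recovers_the_waveform(self):
        v = make_volume_waveform(n_samples=214)
        rec = integrate_volume(derive_flows(v), esv_constant=v.esv)
        assert np.max(np.abs(rec.volumes - v.volumes)) < 0.005 * v.edv

    def test_zero_flows_stay_at_esv(self):
        t = np.linspace(0, 0.8, 50, endpoint=False)
        f = FlowSeries(t, np.zeros(50), np.zeros(50), period=0.8)
        v = integrate_volume(f, esv_constant=31.0)
        assert np.allclose(v.volumes, 31.0)

    def test_negative_volume_detected(self):
        t = np.linspace(0, 0.5, 50)
        f = FlowSeries(t, np.zeros(50), np.full(50, 20.0), period=0.5)
        with pytest.raises(ValueError, match="non-positive"):
            integrate_volume(f, esv_constant=31.0, t_reference=0.0)

    def test_cycle_closure_for_periodic_flows(self):
        v = make_volume_waveform(n_samples=214)
        f = derive_flows(v)
        t = np.append(f.times, v.period)
        net = np.trapezoid(np.append(f.net_mlps(), f.net_mlps()[0]), t)
        assert abs(net) < 0.005 * v.edv

    def test_filling_raises_volume(self):
        # Eq-sign check: while q_mv > 0 and q_av = 0, V must increase
        v = make_volume_waveform(n_samples=214)
        rec = integrate_volume(derive_flows(v), esv_constant=v.esv)
        f = derive_flows(v)
        filling = (f.q_mv > 0.5) & (f.q_av == 0)
        idx = np.where(filling[:-1] & filling[1:])[0]
        assert np.all(np.diff(rec.volumes)[idx] > 0)


class TestResample:
    def test_identity_on_same_grid(self):
        t = np.linspace(0, 1, 20, endpoint=False)
        y = np.sin(2 * np.pi * t) + 2
        out = resample_spline(t, y, t, period=1.0)
        assert np.allclose(out, y, atol=1e-12)

    def test_sine_20_to_214_oracle(self):
        t20 = np.linspace(0, 1, 20, endpoint=False)
        t214 = np.linspace(0, 1, 214, endpoint=False)
        y = np.sin(2 * np.pi * t20)
        out = resample_spline(t20, y, t214, period=1.0)
        assert np.max(np.abs(out - np.sin(2 * np.pi * t214))) < 1e-3

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            resample_spline([0, 0.3, 0.6], [1, 2, 3], [0.1], period=1.0)

    def test_non_monotone_times(self):
        with pytest.raises(ValueError, match="increasing"):
            resample_spline([0, 0.5, 0.3, 0.8], [1, 2, 3, 4], [0.1], period=1.0)


class TestNormalize:
    def test_division_by_cycle_maximum(self):
        v = VolumeSeries(np.array([0.0, 0.3, 0.6]), np.array([50.0, 65.0, 31.0]), 0.9)
        n = normalize_volume(v)
        assert np.allclose(n.values, [50 / 65, 1.0, 31 / 65])
        assert n.values[1] == 1.0

    def test_constant_series_is_all_ones(self):
        v = VolumeSeries(np.array([0.0, 0.1, 0.2]), np.full(3, 40.0), 0.3)
        assert np.allclose(normalize_volume(v).values, 1.0)

    def test_exactly_one_sample_is_unity(self):
        v = make_volume_waveform(n_samples=128)
        n = normalize_volume(v)
        assert np.sum(n.values == 1.0) >= 1
        assert n.values.max() == 1.0

    def test_idempotent(self):
        v = make_volume_waveform(n_samples=64)
        n1 = normalize_volume(v)
        v2 = VolumeSeries(n1.fractions, n1.values, 1.0)
        n2 = normalize_volume(v2)
        assert np.array_equal(n1.values, n2.values)


class TestEjectionFraction:
    def test_cine_cmr_printed_value(self):
        assert ejection_fraction([65.0, 31.0]) == pytest.approx(52.3, abs=0.05)

    def test_stereo_printed_value(self):
        assert ejection_fraction([62.0, 33.0]) == pytest.approx(46.8, abs=0.05)

    def test_flat_series_is_zero(self):
        assert ejection_fraction([40.0, 40.0]) == 0.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ejection_fraction([10.0, -1.0])


class TestCompareModalities:
    @staticmethod
    def _series(values, label=""):
        f = np.linspace(0, 1, len(values), endpoint=False)
        return NormalizedVolumeSeries(f, np.asarray(values, float), label)

    def test_identical_series_zero_stats(self):
        v = make_volume_waveform(n_samples=64)
        a = normalize_volume(v, "a")
        b = normalize_volume(v, "b")
        rep = compare_modalities(a, b)
        assert rep.mean_percent == pytest.approx(0.0, abs=1e-9)
        assert rep.sd_percent == pytest.approx(0.0, abs=1e-9)
        assert rep.max_percent == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_oracle(self):
        n = 1000
        a = self._series(np.ones(n), "a")
        vals = np.full(n, 0.95)
        vals[0] = 1.0
        b = self._series(vals, "b")
        rep = compare_modalities(a, b)
        assert rep.mean_percent == pytest.approx(5.0 * (n - 1) / n, abs=1e-6)

    def test_order_invariance(self):
        v1 = make_volume_waveform(n_samples=128)
        v2 = make_volume_waveform(edv=62, esv=33, n_samples=20)
        a = normalize_volume(v1, "a")
        b = normalize_volume(v2, "b")
        r1 = compare_modalities(a, b)
        r2 = compare_modalities(b, a)
        assert r1.mean_percent == r2.mean_percent
        assert r1.sd_percent == r2.sd_percent
        assert r1.max_percent == r2.max_percent

    def test_population_sd_convention(self):
        a = self._series([1.0, 0.9, 0.8, 0.7], "a")
        b = self._series([1.0, 0.8, 0.8, 0.8], "b")
        rep = compare_modalities(a, b)
        d = 100 * np.abs(a.values - b.values)
        assert rep.sd_percent == pytest.approx(np.std(d))  # ddof=0

    def test_empty_series_rejected(self):
        a = self._series([1.0, 0.9], "a")
        with pytest.raises(ValueError):
            compare_modalities(
                a, NormalizedVolumeSeries(np.array([]), np.array([]), "b")
            )

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=5, max_value=60))
    def test_self_comparison_is_always_zero(self, n):
        rng = np.random.default_rng(n)
        vals = 0.5 + 0.5 * rng.uniform(0.0, 1.0, n)
        vals[rng.integers(n)] = 1.0
        a = self._series(vals, "x")
        assert compare_modalities(a, a).max_percent == 0.0
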