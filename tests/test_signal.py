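"""Signal-to-concentration conversion, resampling and AIF averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscperf.signal import (
    Aif,
    CtcVolume,
    DscSeries,
    aif_from_voxels,
    moving_average,
    resample_temporal,
    signal_to_ctc,
    synthesize_signal,
)

TE = 0.03


def _series(intens, **kw):
    return DscSeries(intensities=intens, te_seconds=TE, dt_seconds=1.5, **kw)


class TestSignalToCtc:
    def test_constant_signal_gives_zero_concentration(self):
        vol = np.full((3, 3, 2, 10), 55.0)
        ctc, excluded = signal_to_ctc(_series(vol))
        np.testing.assert_array_equal(ctc.curves, 0.0)
        assert not excluded.any()

    def test_exact_inverse_of_log_ratio(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 30, size=(4, 4, 2, 20))
        c[..., 0] = 0.0
        vol = synthesize_signal(c, TE, baseline_intensity=120.0)
        ctc, _ = signal_to_ctc(_series(vol))
        np.testing.assert_allclose(ctc.curves, c, atol=1e-10)

    def test_matches_scalar_reference_loop(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(10.0, 200.0, size=(4, 4, 2, 20))
        ctc, _ = signal_to_ctc(_series(vol))
        # independent element-wise evaluation of the log-ratio relation
        for x in range(4):
            for y in range(4):
                for z in range(2):
                    for t in range(20):
                        expected = np.log(vol[x, y, z, 0] / vol[x, y, z, t]) / TE
                        assert abs(ctc.curves[x, y, z, t] - expected) < 1e-10

    def test_invariant_to_global_intensity_rescaling(self):
        rng = np.random.default_rng(2)
        vol = rng.uniform(50.0, 150.0, size=(3, 3, 1, 12))
        a, _ = signal_to_ctc(_series(vol))
        b, _ = signal_to_ctc(_series(7.3 * vol))
        np.testing.assert_allclose(a.curves, b.curves, atol=1e-12)

    def test_baseline_frame_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(50.0, 150.0, size=(3, 3, 1, 12))
        ctc, _ = signal_to_ctc(_series(vol))
        np.testing.assert_array_equal(ctc.curves[..., 0], 0.0)

    def test_nonpositive_baseline_voxel_excluded(self):
        vol = np.full((2, 2, 1, 6), 80.0)
        vol[0, 0, 0, :] = 0.0
        ctc, excluded = signal_to_ctc(_series(vol))
        assert excluded[0, 0, 0]
        assert excluded.sum() == 1
        np.testing.assert_array_equal(ctc.curves[0, 0, 0], 0.0)

    def test_nonpositive_intensity_clamped_not_fatal(self):
        vol = np.full((1, 1, 1, 6), 80.0)
        vol[0, 0, 0, 3] = -5.0
        ctc, excluded = signal_to_ctc(_series(vol))
        assert not excluded.any()
        assert np.isfinite(ctc.curves).all()
        assert ctc.curves[0, 0, 0, 3] > 0  # clamped to a tiny intensity, large CTC

    def test_out_of_mask_voxels_zeroed(self):
        rng = np.random.default_rng(4)
        vol = rng.uniform(50.0, 150.0, size=(2, 2, 1, 8))
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        ctc, _ = signal_to_ctc(_series(vol, brain_mask=mask))
        np.testing.assert_array_equal(ctc.curves[~mask], 0.0)
        assert np.any(ctc.curves[0, 0, 0] != 0)

    def test_baseline_averaging_window(self):
        vol = np.full((1, 1, 1, 8), 100.0)
        vol[..., 0], vol[..., 1] = 90.0, 110.0
        s = _series(vol, baseline_frames=2)
        assert s.baseline()[0, 0, 0] == 100.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"te_seconds": 0.0},
            {"dt_seconds": -1.0},
            {"baseline_index": 99},
        ],
    )
    def test_invalid_metadata_rejected(self, kw):
        base = dict(intensities=np.ones((2, 2, 1, 5)), te_seconds=TE, dt_seconds=1.5)
        base.update(kw)
        with pytest.raises(ValueError):
            DscSeries(**base)


class TestResampleTemporal:
    def test_linear_ramp_stays_linear(self):
        y = np.linspace(0.0, 19.0, 20)
        out, dt_out = resample_temporal(y, 1.0, 40)
        t_out = np.arange(40) * dt_out
        np.testing.assert_allclose(out, t_out, atol=1e-10)

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(12) * 2.0
        y = 0.3 * t**3 - t**2 + 4 * t - 7
        out, dt_out = resample_temporal(y, 2.0, 31)
        tt = np.arange(31) * dt_out
        np.testing.assert_allclose(out, 0.3 * tt**3 - tt**2 + 4 * tt - 7, atol=1e-8)

    def test_identity_when_resampling_to_same_grid(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(25)
        out, dt_out = resample_temporal(y, 1.5, 25)
        np.testing.assert_allclose(out, y, atol=1e-12)
        assert dt_out == 1.5

    def test_sine_resampled_close_to_analytic(self):
        t = np.arange(30)
        y = np.sin(t * 2 * np.pi / 29)
        out, dt_out = resample_temporal(y, 1.0, 40)
        t40 = np.arange(40) * dt_out
        # frozen oracle: max error vs the closed-form sine is ~7.2e-6
        assert np.abs(out - np.sin(t40 * 2 * np.pi / 29)).max() < 1e-2

    def test_preserves_endpoints_and_window(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        out, dt_out = resample_temporal(y, 2.0, 11)
        assert out[0] == y[0] and out[-1] == y[-1]
        assert dt_out * 10 == pytest.approx(2.0 * 5)

    def test_integral_conserved_for_smooth_curves(self):
        t = np.arange(25)
        y = np.exp(-(((t - 10) / 4.0) ** 2))
        out, dt_out = resample_temporal(y, 2.0, 40)
        before = np.trapezoid(y, dx=2.0)
        after = np.trapezoid(out, dx=dt_out)
        assert abs(after - before) / before < 0.02

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            resample_temporal(np.array([1.0, 2.0, 3.0]), 1.0, 10)


class TestAifFromVoxels:
    def _ctc(self, curves):
        return CtcVolume(curves=curves, dt_seconds=1.5)

    def test_single_voxel_passthrough(self):
        rng = np.random.default_rng(0)
        curves = rng.uniform(0, 5, size=(2, 2, 1, 10))
        aif = aif_from_voxels(self._ctc(curves), [(1, 0, 0)])
        np.testing.assert_array_equal(aif.values, curves[1, 0, 0])

    def test_opposite_curves_average_to_zero(self):
        curves = np.zeros((2, 1, 1, 8))
        c = np.sin(np.arange(8.0))
        curves[0, 0, 0], curves[1, 0, 0] = c, -c
        with pytest.warns(UserWarning):
            aif = aif_from_voxels(self._ctc(curves), [(0, 0, 0), (1, 0, 0)])
        np.testing.assert_allclose(aif.values, 0.0, atol=1e-15)

    def test_mean_of_five_known_curves(self):
        rng = np.random.default_rng(7)
        curves = rng.uniform(0, 3, size=(5, 1, 1, 6))
        coords = [(i, 0, 0) for i in range(5)]
        aif = aif_from_voxels(self._ctc(curves), coords)
        # scalar oracle: per-time-point arithmetic mean
        for t in range(6):
            expected = sum(curves[i, 0, 0, t] for i in range(5)) / 5.0
            assert aif.values[t] == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_coordinate_named_in_error(self):
        curves = np.ones((2, 2, 1, 6))
        with pytest.raises(ValueError, match=r"\(5, 0, 0\)"):
            aif_from_voxels(self._ctc(curves), [(5, 0, 0)])

    def test_lowpass_filter_applied(self):
        curves = np.zeros((1, 1, 1, 9))
        curves[0, 0, 0, 4] = 3.0
        aif = aif_from_voxels(self._ctc(curves), [(0, 0, 0)], lowpass_window=3)
        assert aif.values[4] == pytest.approx(1.0)
        assert aif.values[3] == pytest.approx(1.0)

    def test_moving_average_window_one_is_identity(self):
        y = np.arange(6.0)
        np.testing.assert_array_equal(moving_average(y, 1), y)


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(min_value=0.1, max_value=10.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_roundtrip_synthesis_then_decode_recovers_ctc(scale, seed):
    """Signal synthesis and decoding are exact inverses for any curve."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(0, 20, size=(2, 2, 1, 12)) * scale
    c[..., 0] = 0.0
    vol = synthesize_signal(c, TE, baseline_intensity=90.0)
    ctc, _ = signal_to_ctc(
        DscSeries(intensities=vol, te_seconds=TE, dt_seconds=1.0)
    )
    np.testing.assert_allclose(ctc.curves, c, atol=1e-10)
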