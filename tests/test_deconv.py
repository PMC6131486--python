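"""Block-circulant deconvolution and perfusion parameter readout."""

import numpy as np
import pytest

from dscperf.deconv import (
    DeconvConfig,
    build_circulant,
    compute_cbv,
    compute_scalar_params,
    deconvolve_voxel,
    maps_from_case,
    oscillation_index,
)
from dscperf.phantom import SimulationConfig, gamma_variate, simulate_case
from dscperf.signal import Aif, CtcVolume

DT = 1.5
N_TIME = 40


def _gamma_aif(dt=DT, n=N_TIME):
    return Aif(values=gamma_variate(np.arange(n) * dt), dt_seconds=dt, source="test")


def _impulse_aif(n=8):
    v = np.zeros(n)
    v[0] = 1.0
    return Aif(values=v, dt_seconds=1.0, source="impulse")


def _simulate_voxel(cbf, mtt, delay=0.0, **kw):
    cfg = SimulationConfig(
        shape=(1, 1, 1),
        cbf_range=(cbf, cbf),
        mtt_range=(mtt, mtt),
        delay_range=(delay, delay),
        smoothness=0.0,
        seed=0,
        **kw,
    )
    _, aif, truth, ctc = simulate_case(cfg)
    return ctc.curves[0, 0, 0], aif, truth


class TestBuildCirculant:
    def test_unit_impulse_gives_identity(self):
        A = build_circulant(_impulse_aif(), 16)
        np.testing.assert_array_equal(A, np.eye(16))

    def test_columns_are_cyclic_shifts(self):
        rng = np.random.default_rng(0)
        aif = Aif(values=rng.uniform(0.1, 1, 8), dt_seconds=1.0, source="t")
        A = build_circulant(aif, 16)
        for k in range(16):
            np.testing.assert_array_equal(A[:, k], np.roll(A[:, 0], k))

    def test_matches_double_loop_circular_convolution(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 8)
        r = rng.standard_normal(8)
        dt = 0.7
        aif = Aif(values=a, dt_seconds=dt, source="t")
        A = build_circulant(aif, 8)
        # brute-force double loop oracle for the circular convolution
        expected = np.zeros(8)
        for j in range(8):
            for k in range(8):
                expected[j] += a[(j - k) % 8] * r[k]
        np.testing.assert_allclose(A @ r, expected * dt, atol=1e-12)

    def test_pad_shorter_than_aif_rejected(self):
        with pytest.raises(ValueError):
            build_circulant(_impulse_aif(8), 4)


class TestDeconvolveVoxel:
    def test_impulse_aif_recovers_curve_exactly(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(0, 5, 8)
        res = deconvolve_voxel(c, _impulse_aif(), DeconvConfig(method="tsvd", truncation_fraction=0.001))
        np.testing.assert_allclose(res.values[:8], c, atol=1e-10)
        np.testing.assert_allclose(res.values[8:], 0.0, atol=1e-10)

    def test_all_zero_ctc_gives_zero_residue(self):
        res = deconvolve_voxel(np.zeros(8), _impulse_aif(), DeconvConfig())
        np.testing.assert_array_equal(res.values, 0.0)

    def test_all_zero_aif_rejected(self):
        with pytest.warns(UserWarning):
            aif = Aif(values=np.zeros(8), dt_seconds=1.0, source="z")
        with pytest.raises(ValueError):
            deconvolve_voxel(np.ones(8), aif, DeconvConfig())

    @pytest.mark.parametrize("mtt", [4.0, 8.0, 12.0])
    def test_cbf_recovered_from_forward_simulation(self, mtt):
        """Adaptive-threshold deconvolution of a noiseless simulated voxel
        recovers the residue peak (CBF) to well under 10%."""
        ctc, aif, truth = _simulate_voxel(cbf=1.3, mtt=mtt)
        res = deconvolve_voxel(ctc, aif, DeconvConfig(method="osvd"))
        cbf = res.values[:N_TIME].max()
        assert abs(cbf - 1.3) / 1.3 < 0.1

    def test_delay_insensitivity_of_circulant_inversion(self):
        ctc, aif, _ = _simulate_voxel(cbf=1.0, mtt=6.0)
        cfg = DeconvConfig(method="tsvd", truncation_fraction=0.10)
        r0 = deconvolve_voxel(ctc, aif, cfg)
        cbf0, am0 = r0.values[:N_TIME].max(), np.argmax(r0.values[:N_TIME])
        for d in (1, 2, 3):
            rd = deconvolve_voxel(np.roll(ctc, d), aif, cfg)
            cbfd = rd.values[:N_TIME].max()
            assert abs(cbfd - cbf0) / cbf0 < 0.05
            assert np.argmax(rd.values[:N_TIME]) == am0 + d

    def test_osvd_residue_satisfies_oscillation_limit(self):
        rng = np.random.default_rng(3)
        ctc, aif, _ = _simulate_voxel(cbf=1.0, mtt=6.0)
        noisy = ctc + rng.normal(0, 0.05 * ctc.max(), ctc.size)
        cfg = DeconvConfig(method="osvd", oscillation_threshold=0.095)
        res = deconvolve_voxel(noisy, aif, cfg)
        assert oscillation_index(res.values) <= 0.095


class TestScalarParams:
    def test_cbv_ratio_identity(self):
        aif = _gamma_aif()
        assert compute_cbv(aif.values, aif) == pytest.approx(1.0)

    def test_cbv_zero_curve(self):
        assert compute_cbv(np.zeros(N_TIME), _gamma_aif()) == 0.0

    def test_cbv_scaled_and_delayed_curve(self):
        aif = _gamma_aif()
        shifted = 2.0 * np.roll(aif.values, 3)
        # circular shift conserves the sum; trapezoid ends are ~0 for this bolus
        assert compute_cbv(shifted, aif) == pytest.approx(2.0, abs=1e-6)

    def test_zero_integral_aif_rejected(self):
        with pytest.warns(UserWarning):
            aif = Aif(values=np.zeros(8), dt_seconds=1.0, source="z")
        with pytest.raises(ValueError):
            compute_cbv(np.ones(8), aif)

    def test_argmax_readout(self):
        from dscperf.deconv import ResidueCurve

        residue = ResidueCurve(np.array([0.0, 5.0, 3.0, 1.0, 0, 0, 0, 0]), dt_seconds=1.5)
        ctc = np.array([0.0, 1.0, 2.0, 0.5])
        aif = Aif(values=np.array([1.0, 1, 1, 1]), dt_seconds=1.5, source="t")
        cbf, cbv, mtt, ttp, tmax = compute_scalar_params(residue, ctc, aif)
        assert cbf == 5.0
        assert tmax == 1.5
        assert ttp == 2 * 1.5

    def test_ttp_at_sample_twelve(self):
        ctc = np.zeros(N_TIME)
        ctc[12] = 1.0
        from dscperf.deconv import ResidueCurve

        residue = ResidueCurve(np.ones(2 * N_TIME), dt_seconds=DT)
        *_, ttp, _ = compute_scalar_params(residue, ctc, _gamma_aif())
        assert ttp == pytest.approx(18.0)

    @pytest.mark.parametrize("mtt", [4.0, 6.0, 12.0])
    def test_central_volume_ratio_matches_rectangle_sum_oracle(self, mtt):
        """On the discrete forward model, cbv/cbf equals the rectangle sum
        of the sampled residue (closed form), within quadrature edge terms.

        The sum exceeds the continuous MTT by ~(dt/M)/(1-exp(-dt/M)) — a
        +20% sampling bias at MTT=4 s that is a property of sampling a
        discontinuous exponential, not of the inversion.
        """
        ctc, aif, _ = _simulate_voxel(cbf=1.0, mtt=mtt)
        res = deconvolve_voxel(ctc, aif, DeconvConfig(method="osvd"))
        cbf, cbv, mtt_est, *_ = compute_scalar_params(res, ctc, aif)
        oracle = DT * np.sum(np.exp(-np.arange(N_TIME) * DT / mtt))
        assert cbv / cbf == pytest.approx(oracle, rel=0.025)

    def test_mtt_masked_when_cbf_at_floor(self):
        from dscperf.deconv import ResidueCurve

        residue = ResidueCurve(np.zeros(16), dt_seconds=1.0)
        aif = _impulse_aif()
        cbf, cbv, mtt, *_ = compute_scalar_params(residue, np.zeros(8), aif)
        assert cbf == 0.0
        assert np.isnan(mtt)


class TestMapsFromCase:
    def test_identical_voxels_give_constant_maps(self):
        ctc_1, aif, _ = _simulate_voxel(cbf=1.0, mtt=6.0)
        curves = np.broadcast_to(ctc_1, (4, 4, 1, N_TIME)).copy()
        maps = maps_from_case(CtcVolume(curves=curves, dt_seconds=DT), aif)
        for name in ("cbf", "cbv", "mtt", "ttp", "tmax"):
            assert np.ptp(maps[name]) == 0.0

    def test_recovers_known_cbf_grid_noiseless(self):
        cfg = SimulationConfig(shape=(10, 10, 1), delay_range=(0.0, 0.0), seed=9)
        _, aif, truth, ctc = simulate_case(cfg)
        maps = maps_from_case(ctc, aif, DeconvConfig(method="osvd"))
        rel = np.abs(maps.cbf - truth.cbf) / truth.cbf
        assert rel.max() < 0.10

    def test_empty_mask_warns_and_returns_zeros(self):
        ctc_1, aif, _ = _simulate_voxel(cbf=1.0, mtt=6.0)
        vol = CtcVolume(
            curves=ctc_1[None, None, None, :].copy(),
            dt_seconds=DT,
            mask=np.zeros((1, 1, 1), dtype=bool),
        )
        with pytest.warns(UserWarning, match="empty mask"):
            maps = maps_from_case(vol, aif)
        np.testing.assert_array_equal(maps.cbf, 0.0)

    def test_linearity_in_ctc_scale(self):
        """Scaling the CTC scales cbf and cbv and leaves times unchanged."""
        cfg = SimulationConfig(shape=(4, 4, 1), seed=3)
        _, aif, _, ctc = simulate_case(cfg)
        maps1 = maps_from_case(ctc, aif)
        scaled = CtcVolume(curves=3.0 * ctc.curves, dt_seconds=DT)
        maps3 = maps_from_case(scaled, aif)
        np.testing.assert_allclose(maps3.cbf, 3.0 * maps1.cbf, rtol=1e-8)
        np.testing.assert_allclose(maps3.cbv, 3.0 * maps1.cbv, rtol=1e-8)
        np.testing.assert_allclose(maps3.mtt, maps1.mtt, rtol=1e-8)
        np.testing.assert_array_equal(maps3.ttp, maps1.ttp)
        np.testing.assert_array_equal(maps3.tmax, maps1.tmax)

    def test_mtt_equals_cbv_over_cbf_by_construction(self):
        cfg = SimulationConfig(shape=(5, 5, 1), seed=4, noise_snr_db=40.0)
        series, aif, _, _ = simulate_case(cfg)
        from dscperf.signal import signal_to_ctc

        ctc, _ = signal_to_ctc(series)
        maps = maps_from_case(ctc, aif)
        ok = np.isfinite(maps.mtt)
        np.testing.assert_allclose(maps.mtt[ok], maps.cbv[ok] / maps.cbf[ok], rtol=1e-12)


def test_oscillation_index_of_smooth_vs_rough():
    smooth = np.exp(-np.arange(40) / 6.0)
    rough = smooth * (-1.0) ** np.arange(40)
    assert oscillation_index(smooth) < 0.01
    assert oscillation_index(rough) > oscillation_index(smooth) * 10
    assert oscillation_index(np.zeros(10)) == 0.0
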