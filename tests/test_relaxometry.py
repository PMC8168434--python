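"""SPGR signal model, VFA T1 mapping and concentration conversion."""
import numpy as np
import pytest

from perfutex import (
    AcquisitionParams,
    DynamicSeries,
    FlipAngleSeries,
    InvalidInputError,
    T1Map,
    signal_to_concentration_exact,
    signal_to_concentration_linear,
    spgr_signal,
    vfa_t1_fit,
)


def _uniform_t1map(shape, t1, m0=1000.0):
    return T1Map(
        t1=np.full(shape, float(t1)),
        m0=np.full(shape, float(m0)),
        valid=np.ones(shape, dtype=bool),
    )


def _vfa_series(params, t1, m0=1000.0, shape=(4, 4, 2)):
    vols = [
        spgr_signal(np.full(shape, m0), np.full(shape, t1), params, flip_angle=a)
        for a in params.flip_angles_t1
    ]
    return FlipAngleSeries(volumes=vols, flip_angles=list(params.flip_angles_t1))


class TestSpgrSignal:
    def test_matches_closed_form(self, params):
        # direct evaluation of m0 sin(a) (1-E)/(1-E cos a)
        m0, t1 = 1000.0, 1.0
        e = np.exp(-params.repetition_time / t1)
        a = np.deg2rad(params.flip_angle_dynamic)
        expected = m0 * np.sin(a) * (1 - e) / (1 - e * np.cos(a))
        assert spgr_signal(m0, t1, params) == pytest.approx(expected, rel=1e-15)

    def test_full_relaxation_limit(self):
        # TR >> T1 drives E -> 0 so the signal saturates at m0 sin(a)
        p = AcquisitionParams(repetition_time=10.0)
        s = spgr_signal(500.0, 0.01, p, flip_angle=30.0)
        assert s == pytest.approx(500.0 * np.sin(np.deg2rad(30.0)), rel=1e-9)

    def test_rejects_nonpositive_t1(self, params):
        with pytest.raises(InvalidInputError):
            spgr_signal(1000.0, 0.0, params)


class TestVfaT1Fit:
    def test_noiseless_recovery(self, params):
        fa = _vfa_series(params, t1=1.0)
        fit = vfa_t1_fit(fa, params)
        assert fit.valid.all()
        assert np.allclose(fit.t1, 1.0, rtol=1e-3)  # 0.1%
        assert np.allclose(fit.m0, 1000.0, rtol=1e-3)

    def test_all_zero_voxel_flagged_not_crash(self, params):
        fa = _vfa_series(params, t1=1.0)
        for v in fa.volumes:
            v[0, 0, 0] = 0.0
        fit = vfa_t1_fit(fa, params)
        assert not fit.valid[0, 0, 0]
        assert np.isnan(fit.t1[0, 0, 0])
        assert fit.valid[1:, :, :].all()

    def test_scale_invariance(self, params):
        fa = _vfa_series(params, t1=0.8)
        scaled = FlipAngleSeries(
            volumes=[3.7 * v for v in fa.volumes], flip_angles=fa.flip_angles
        )
        a, b = vfa_t1_fit(fa, params), vfa_t1_fit(scaled, params)
        np.testing.assert_allclose(b.t1, a.t1, rtol=1e-10)
        np.testing.assert_allclose(b.m0, 3.7 * a.m0, rtol=1e-10)

    def test_noisy_median_recovery(self, params, rng):
        shape = (10, 10, 10)  # 1000 voxels
        vols = [
            spgr_signal(np.full(shape, 1000.0), np.full(shape, 1.0), params, a)
            for a in params.flip_angles_t1
        ]
        noisy = [v + rng.standard_normal(shape) * 0.01 * v.mean() for v in vols]
        fit = vfa_t1_fit(
            FlipAngleSeries(volumes=noisy, flip_angles=list(params.flip_angles_t1)),
            params,
        )
        med = np.nanmedian(fit.t1)
        assert abs(med - 1.0) < 0.05

    def test_requires_two_angles(self, params):
        with pytest.raises(InvalidInputError):
            FlipAngleSeries(volumes=[np.ones((2, 2, 2))], flip_angles=[12.0])


def _dyn_from_ratio(params, ratio, shape=(2, 2, 2)):
    """Dynamic series whose post-baseline signal is `ratio` times baseline."""
    s0 = 500.0
    nt = params.n_timepoints
    sig = np.full(shape + (nt,), s0)
    sig[..., params.n_baseline:] = s0 * ratio
    return DynamicSeries(signal=sig, times=params.times, params=params)


class TestLinearConversion:
    def test_flat_signal_gives_zero(self, params):
        dyn = _dyn_from_ratio(params, 1.0)
        conc = signal_to_concentration_linear(dyn, _uniform_t1map((2, 2, 2), 1.0), params)
        np.testing.assert_allclose(conc.conc, 0.0, atol=1e-12)

    def test_hand_value(self, params):
        # 20% enhancement, r1=4.3, T10=1 s -> C = 0.2/4.3
        dyn = _dyn_from_ratio(params, 1.2)
        conc = signal_to_concentration_linear(dyn, _uniform_t1map((2, 2, 2), 1.0), params)
        assert conc.conc[0, 0, 0, -1] == pytest.approx(0.2 / 4.3, rel=1e-12)

    def test_doubling_t10_halves_concentration(self, params):
        dyn = _dyn_from_ratio(params, 1.3)
        c1 = signal_to_concentration_linear(dyn, _uniform_t1map((2, 2, 2), 1.0), params)
        c2 = signal_to_concentration_linear(dyn, _uniform_t1map((2, 2, 2), 2.0), params)
        np.testing.assert_allclose(c2.conc[..., -1], c1.conc[..., -1] / 2.0, rtol=1e-12)

    def test_zero_baseline_voxel_flagged(self, params):
        dyn = _dyn_from_ratio(params, 1.2)
        dyn.signal[0, 0, 0, :] = 0.0
        conc = signal_to_concentration_linear(dyn, _uniform_t1map((2, 2, 2), 1.0), params)
        assert not conc.valid[0, 0, 0]
        assert np.isnan(conc.conc[0, 0, 0]).all()


class TestExactConversion:
    @staticmethod
    def _forward_dyn(params, t10, c_true, shape=(2, 2, 1)):
        """Noiseless SPGR signal at concentration c_true on post-bolus frames."""
        nt = params.n_timepoints
        conc = np.zeros(shape + (nt,))
        conc[..., params.n_baseline:] = c_true
        r1t = 1.0 / t10 + params.relaxivity_r1 * conc
        sig = spgr_signal(1000.0, 1.0 / r1t, params)
        return DynamicSeries(signal=sig, times=params.times, params=params)

    def test_exact_inverse_of_forward_model(self, params):
        t10 = 1.0
        dyn = self._forward_dyn(params, t10, c_true=0.8)
        conc = signal_to_concentration_exact(dyn, _uniform_t1map((2, 2, 1), t10), params)
        assert conc.conc[0, 0, 0, -1] == pytest.approx(0.8, rel=1e-10)

    @staticmethod
    def _linear_sensitivity(params, t10):
        # first-order SPGR sensitivity: the low-C ratio C_linear / C_exact
        # is TR E (1-cos a) / [(1-E)(1-E cos a) T10], not 1, at short TR
        e = np.exp(-params.repetition_time / t10)
        cos_a = np.cos(np.deg2rad(params.flip_angle_dynamic))
        return (
            params.repetition_time * e * (1 - cos_a)
            / ((1 - e) * (1 - e * cos_a) * t10)
        )

    def test_linear_low_limit_matches_sensitivity_factor(self, params):
        # in the low-concentration limit the linear reduction converges to
        # the exact inversion times a constant protocol-dependent factor
        t10 = 1.0
        factor = self._linear_sensitivity(params, t10)
        t1m = _uniform_t1map((2, 2, 1), t10)
        for c_true in (0.002, 0.008):
            dyn = self._forward_dyn(params, t10, c_true=c_true)
            ce = signal_to_concentration_exact(dyn, t1m, params)
            cl = signal_to_concentration_linear(dyn, t1m, params)
            ratio = cl.conc[0, 0, 0, -1] / ce.conc[0, 0, 0, -1]
            assert ratio == pytest.approx(factor, rel=0.01)

    def test_linear_saturates_further_at_large_enhancement(self, params):
        # at C = 2 mmol/L and blood T10 the linear reduction falls well
        # below even its low-concentration sensitivity factor
        t10 = 1.6
        factor = self._linear_sensitivity(params, t10)
        dyn = self._forward_dyn(params, t10, c_true=2.0)
        t1m = _uniform_t1map((2, 2, 1), t10)
        ce = signal_to_concentration_exact(dyn, t1m, params)
        cl = signal_to_concentration_linear(dyn, t1m, params)
        ratio = cl.conc[0, 0, 0, -1] / ce.conc[0, 0, 0, -1]
        assert ratio < factor * 0.95  # > 5% additional saturation

    def test_baseline_frames_zero(self, params):
        dyn = self._forward_dyn(params, 1.0, c_true=0.5)
        conc = signal_to_concentration_exact(dyn, _uniform_t1map((2, 2, 1), 1.0), params)
        nb = params.n_baseline
        np.testing.assert_allclose(conc.conc[..., :nb], 0.0, atol=1e-10)


class TestDynamicSeriesContracts:
    def test_rejects_nonincreasing_times(self, params):
        sig = np.ones((2, 2, 2, 3))
        with pytest.raises(InvalidInputError):
            DynamicSeries(signal=sig, times=np.array([0.0, 6.0, 6.0]), params=params)

    def test_rejects_time_axis_mismatch(self, params):
        sig = np.ones((2, 2, 2, 3))
        from perfutex.errors import DimensionError

        with pytest.raises(DimensionError):
            DynamicSeries(signal=sig, times=np.arange(4.0), params=params)
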