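"""Dual-energy calibration fitting and voxelwise decomposition."""

import numpy as np
import pytest

from cacsim.material_decomposition import (
    CalibrationModel,
    CalibrationSample,
    decompose,
    fit_calibration,
    mass_from_density_map,
)

VOXVOL = 1.25e-4

P_STAR = np.array([3.0, 0.5, 0.1, 1e-4, 5e-5, 8e-5, 2e-4, 1e-4])


def rational(sl, sh, p=P_STAR):
    num = p[0] + p[1] * sl + p[2] * sh + p[3] * sl**2 + p[4] * sl * sh + p[5] * sh**2
    return num / (1.0 + p[6] * sl + p[7] * sh)


def spread_samples(n=12, seed=7):
    rng = np.random.default_rng(seed)
    sl = rng.uniform(0.0, 1500.0, n)
    sh = rng.uniform(0.0, 1200.0, n)
    return [CalibrationSample(a, b, float(rational(a, b))) for a, b in zip(sl, sh)]


class TestCalibrationFit:
    def test_generate_and_refit_heldout_error(self):
        # noiseless samples from a known coefficient vector: the refit model
        # must reproduce f on held-out signal pairs to < 1e-6 relative
        model = fit_calibration(spread_samples())
        rng = np.random.default_rng(21)
        sl = rng.uniform(0.0, 1500.0, 100)
        sh = rng.uniform(0.0, 1200.0, 100)
        rel = np.abs(model.predict(sl, sh) - rational(sl, sh)) / np.abs(rational(sl, sh))
        assert rel.max() < 1e-6

    def test_constant_density_samples(self):
        rng = np.random.default_rng(3)
        sl = rng.uniform(0.0, 1000.0, 10)
        sh = rng.uniform(0.0, 800.0, 10)
        samples = [CalibrationSample(a, b, 42.0) for a, b in zip(sl, sh)]
        model = fit_calibration(samples, fit_denominator=False)
        assert model.predict(sl, sh) == pytest.approx(np.full(10, 42.0), abs=1e-6)

    def test_sample_order_invariance(self):
        samples = spread_samples()
        a = fit_calibration(samples)
        b = fit_calibration(samples[::-1])
        assert a.p == pytest.approx(b.p, rel=1e-9, abs=1e-12)

    def test_identical_samples_rejected(self):
        samples = [CalibrationSample(100.0, 80.0, 50.0)] * 8
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_calibration(samples)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            fit_calibration(spread_samples()[:5])

    def test_collinear_rod_design_stays_stable(self):
        # rod-like samples are nearly collinear in the signal plane; the
        # minimal-norm stage must keep predictions bounded near background
        rho = np.array([0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        sl = 2.8 * rho
        sh = 2.1 * rho
        samples = [CalibrationSample(a, b, f) for a, b, f in zip(sl, sh, rho)]
        model = fit_calibration(samples)
        assert model.residual_rms < 1.0
        assert abs(model.predict(0.0, 0.0)) < 5.0
        assert abs(model.predict(-30.0, -20.0)) < 60.0

    def test_deterministic(self):
        a = fit_calibration(spread_samples()).p
        b = fit_calibration(spread_samples()).p
        assert np.array_equal(a, b)

    def test_serialization_roundtrip(self):
        model = fit_calibration(spread_samples())
        back = CalibrationModel.from_dict(model.to_dict())
        assert back.p == pytest.approx(model.p)
        assert back.protocol_tag == model.protocol_tag


class TestDecomposition:
    def test_constant_numerator_model(self):
        model = CalibrationModel(
            p=np.array([7.0, 0, 0, 0, 0, 0, 0, 0]), residual_rms=0.0,
            signal_range=((0, 1), (0, 1)),
        )
        low = np.random.default_rng(0).normal(100, 30, (8, 8))
        high = np.random.default_rng(1).normal(80, 20, (8, 8))
        res = decompose(low, high, np.ones((8, 8), bool), model, VOXVOL)
        assert res.f_values == pytest.approx(np.full(64, 7.0))

    def test_training_set_consistency(self):
        samples = spread_samples()
        model = fit_calibration(samples)
        for s in samples:
            pred = model.predict(s.s_low, s.s_high)
            assert abs(pred - s.f_true) <= max(5 * model.residual_rms, 1e-6)

    def test_uniform_density_mass_example(self):
        # f = 100 mgHA/cm^3 over 80 voxels of 1.25e-4 cm^3 -> 1.0 mg
        assert mass_from_density_map(np.full(80, 100.0), VOXVOL) == pytest.approx(1.0)

    def test_empty_roi_rejected_and_zero_mass(self):
        model = CalibrationModel(np.zeros(8), 0.0, ((0, 1), (0, 1)))
        with pytest.raises(ValueError, match="empty"):
            decompose(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4), bool), model, VOXVOL)
        assert mass_from_density_map(np.array([]), VOXVOL) == 0.0

    def test_mass_additive_over_roi_partition(self):
        model = fit_calibration(spread_samples())
        rng = np.random.default_rng(5)
        low = rng.uniform(0, 1200, (10, 10))
        high = rng.uniform(0, 1000, (10, 10))
        full = np.ones((10, 10), bool)
        half_a = full.copy(); half_a[:, 5:] = False
        half_b = full & ~half_a
        m_full = decompose(low, high, full, model, VOXVOL).mass_mg
        m_a = decompose(low, high, half_a, model, VOXVOL).mass_mg
        m_b = decompose(low, high, half_b, model, VOXVOL).mass_mg
        assert m_a + m_b == pytest.approx(m_full, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        model = CalibrationModel(np.zeros(8), 0.0, ((0, 1), (0, 1)))
        with pytest.raises(ValueError, match="grid"):
            decompose(np.zeros((4, 4)), np.zeros((5, 5)), np.ones((4, 4), bool), model, VOXVOL)

    def test_nonpositive_denominator_is_error(self):
        model = CalibrationModel(
            p=np.array([0.0, 1.0, 0, 0, 0, 0, -0.01, 0.0]), residual_rms=0.0,
            signal_range=((0, 50), (0, 50)),
        )
        with pytest.raises(ValueError, match="denominator"):
            model.predict(200.0, 0.0)

    def test_background_mass_centred_over_noise(self):
        # Monte-Carlo: an all-background ROI decomposes to ~zero mean mass
        rho = np.array([0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        rng = np.random.default_rng(17)
        sl = np.repeat(2.8 * rho, 30) + rng.normal(0, 20, 240)
        sh = np.repeat(2.1 * rho, 30) + rng.normal(0, 15, 240)
        samples = [CalibrationSample(a, b, f) for a, b, f in zip(sl, sh, np.repeat(rho, 30))]
        model = fit_calibration(samples)
        reps = 500
        masses = np.empty(reps)
        mask = np.ones((6, 6), bool)
        for i in range(reps):
            low = rng.normal(0.0, 20.0, (6, 6))
            high = rng.normal(0.0, 15.0, (6, 6))
            masses[i] = decompose(low, high, mask, model, VOXVOL).mass_mg
        sem = masses.std(ddof=1) / np.sqrt(reps)
        assert abs(masses.mean()) < max(3 * sem, 36 * VOXVOL * 2.0)
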