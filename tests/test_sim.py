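"""Forward projection, noise, FBP reconstruction and the scan pipeline."""

import numpy as np
import pytest

from cacsim.phantom import GRID, PhantomDefinition, Primitive, rasterize
from cacsim.sim import (
    AcquisitionProtocol,
    add_poisson_noise,
    forward_project,
    material_sinograms,
    primitive_sinograms,
    reconstruct_fbp,
    rng_for,
    scan,
)
from cacsim.spectra import Spectrum, generate_spectrum

GRID.setdefault("tiny", {"shape": (192, 192), "body_mm": (80.0, 80.0)})

WATER_60 = 0.2059


def water_disc(radius_mm=30.0) -> PhantomDefinition:
    return PhantomDefinition(
        "disc",
        "tiny",
        [Primitive("circle", (0.0, 0.0), (radius_mm,), {"water": 1.0}, z_extent_mm=1e3, name="body")],
    )


def mono60() -> Spectrum:
    return Spectrum(60.0, np.array([60.0]), np.array([1.0]))


class TestForwardProjection:
    def test_air_phantom_counts_equal_fluence(self):
        # air attenuation is sub-0.5% over the field of view
        ph = PhantomDefinition("nothing", "tiny", [])
        counts = forward_project(rasterize(ph, supersample=1), mono60(), 1000.0, 45)
        assert np.allclose(counts, 1000.0, rtol=5e-3)

    def test_monoenergetic_center_ray_matches_beer_lambert(self):
        # oracle: hand-computed bin-averaged chord of a 30 mm-radius disc
        # (the detector integrates over its 0.5 mm pitch), cross-checked
        # against the plain diameter integral
        r, p = 30.0, 0.5
        F = lambda s: s * np.sqrt(r * r - s * s) + r * r * np.arcsin(s / r)
        center_path_cm = (F(p / 2) - F(-p / 2)) / p / 10.0
        sinos = primitive_sinograms(water_disc(r), 90)
        counts = 1e6 * np.exp(-WATER_60 * sinos["water"])
        assert -np.log(counts.min() / 1e6) == pytest.approx(WATER_60 * center_path_cm, rel=1e-6)
        assert -np.log(counts.min() / 1e6) == pytest.approx(WATER_60 * 6.0, rel=1e-3)

    def test_analytic_and_radon_projectors_agree(self):
        ph = water_disc(30.0)
        a = primitive_sinograms(ph, 30)["water"]
        r = material_sinograms(rasterize(ph, supersample=4), 30)["water"]
        assert np.abs(a - r).max() / r.max() < 0.02

    def test_counts_never_exceed_unattenuated(self):
        sinos = primitive_sinograms(water_disc(25.0), 45)
        counts = forward_project(None, generate_spectrum(120), 5e4, 45, sinograms=sinos)
        assert counts.max() <= 5e4 * (1 + 1e-12)

    def test_beam_hardening_cupping(self):
        # effective mu from the log-transform falls with path length for a
        # polyenergetic beam
        sinos = primitive_sinograms(water_disc(35.0), 45)
        path = sinos["water"]  # g/cm^2 == cm of water
        counts = forward_project(None, generate_spectrum(120).rebinned(2), 1.0, 45, sinograms=sinos)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu_eff = -np.log(counts) / path
        col = np.argmax(path[:, 0] > 0.1)
        sel = path[:, 0] > 0.5
        assert np.corrcoef(path[sel, 0], mu_eff[sel, 0])[0, 1] < -0.9


class TestPoissonNoise:
    def test_zero_expectation_stays_zero(self, rng):
        assert np.all(add_poisson_noise(np.zeros(100), rng) == 0)

    def test_moments(self):
        rng = np.random.default_rng(11)
        draws = add_poisson_noise(np.full(100_000, 1000.0), rng)
        assert draws.mean() == pytest.approx(1000.0, abs=3 * np.sqrt(1000 / 100_000) * 10)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_reproducible_and_integer(self):
        a = add_poisson_noise(np.full(50, 7.3), np.random.default_rng(5))
        b = add_poisson_noise(np.full(50, 7.3), np.random.default_rng(5))
        assert np.array_equal(a, b)
        assert np.array_equal(a, np.round(a))

    def test_negative_expectation_rejected(self, rng):
        with pytest.raises(ValueError):
            add_poisson_noise(np.array([-1.0]), rng)


class TestReconstruction:
    def test_monoenergetic_roundtrip_rmse_below_3pct(self):
        # project -> FBP on a uniform water disc recovers mu away from edges
        ph = water_disc(30.0)
        sinos = primitive_sinograms(ph, 180)
        counts = np.exp(-WATER_60 * sinos["water"])
        theta = np.linspace(0, 180, 180, endpoint=False)
        mu = reconstruct_fbp(counts, 1.0, theta, 0.5, (192, 192), starvation_floor=0)
        yy, xx = np.mgrid[0:192, 0:192]
        r = np.hypot((xx + 0.5 - 96) * 0.5, (yy + 0.5 - 96) * 0.5)
        inside = r < 25.0  # 5 mm margin from the edge
        rel_rmse = np.sqrt(np.mean((mu[inside] - WATER_60) ** 2)) / WATER_60
        assert rel_rmse < 0.03

    def test_all_air_reconstructs_to_zero(self):
        theta = np.linspace(0, 180, 90, endpoint=False)
        counts = np.full((272, 90), 1e5)
        mu = reconstruct_fbp(counts, 1e5, theta, 0.5, (192, 192))
        assert np.abs(mu).max() < 1e-10

    def test_starvation_clamp_and_strict_mode(self):
        theta = np.linspace(0, 180, 45, endpoint=False)
        counts = np.zeros((272, 45))
        mu = reconstruct_fbp(counts, 1e5, theta, 0.5, (192, 192))
        assert np.all(np.isfinite(mu))
        with pytest.raises(ValueError, match="non-positive"):
            reconstruct_fbp(counts, 1e5, theta, 0.5, (192, 192), starvation_floor=0)

    def test_doubling_fluence_reduces_noise_sqrt2(self):
        ph = water_disc(35.0)
        sinos = primitive_sinograms(ph, 180)
        spec = generate_spectrum(120).rebinned(4)
        theta = np.linspace(0, 180, 180, endpoint=False)
        sds = []
        for scale, seed in ((2e4, 1), (4e4, 1)):
            expected = forward_project(None, spec, scale, 180, sinograms=sinos)
            noisy = add_poisson_noise(expected, np.random.default_rng(seed))
            mu = reconstruct_fbp(noisy, scale, theta, 0.5, (192, 192))
            yy, xx = np.mgrid[0:192, 0:192]
            r = np.hypot((xx + 0.5 - 96) * 0.5, (yy + 0.5 - 96) * 0.5)
            sds.append(mu[r < 20].std())
        assert sds[0] / sds[1] == pytest.approx(np.sqrt(2.0), rel=0.15)


class TestScanPipeline:
    def test_fixed_seed_is_bit_identical(self, tiny_bundle):
        ph = tiny_bundle["phantoms"]["measurement"]
        prot = tiny_bundle["protocols"][120.0]
        a = scan(ph, prot, seed=9, n_slices=2)
        b = scan(ph, prot, seed=9, n_slices=2)
        assert np.array_equal(a.hu, b.hu)
        c = scan(ph, prot, seed=10, n_slices=1)
        assert not np.array_equal(a.hu[0], c.hu[0])

    def test_water_background_near_zero_hu(self, tiny_bundle):
        img = tiny_bundle["noiseless"][120.0]
        ny, nx = img.hu.shape[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = np.hypot((xx + 0.5 - nx / 2) * 0.5, (yy + 0.5 - ny / 2) * 0.5)
        bkg = (r > 8) & (r < 14)  # insert-free, away from the body edge cupping
        assert abs(float(img.hu[0][bkg].mean())) < 15.0

    def test_insert_hu_monotone_in_density_and_energy(self, tiny_bundle):
        rois = tiny_bundle["insert_rois"]
        means = {}
        for kv in (80.0, 135.0):
            img = tiny_bundle["noiseless"][kv]
            for roi in rois:
                if roi.diameter_class_mm == 5.0:
                    means[(kv, roi.density_mgha)] = float(img.hu[0][roi.mask].mean())
        assert means[(80.0, 200.0)] > means[(80.0, 50.0)]
        assert means[(135.0, 200.0)] > means[(135.0, 50.0)]
        # calcium contrast falls with tube voltage
        assert means[(80.0, 200.0)] > means[(135.0, 200.0)]

    def test_seed_derivation_is_stable_and_bounded(self):
        a = rng_for(3, "phantom", 120.0, 0).integers(0, 2**31)
        b = rng_for(3, "phantom", 120.0, 0).integers(0, 2**31)
        c = rng_for(3, "phantom", 120.0, 1).integers(0, 2**31)
        assert a == b != c


class TestProtocol:
    def test_exposures_by_size(self):
        assert AcquisitionProtocol.for_size("small", 120).exposure_mr == 0.9
        assert AcquisitionProtocol.for_size("medium", 120).exposure_mr == 2.0
        assert AcquisitionProtocol.for_size("large", 120).exposure_mr == 5.4

    def test_dose_invariant_to_angle_count(self):
        a = AcquisitionProtocol(kv=120, exposure_mr=2.0, n_angles=360)
        b = AcquisitionProtocol(kv=120, exposure_mr=2.0, n_angles=720)
        assert a.fluence_per_view == pytest.approx(2 * b.fluence_per_view)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(kv=120, exposure_mr=0.0)
        with pytest.raises(ValueError):
            AcquisitionProtocol(kv=120, n_angles=4)
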