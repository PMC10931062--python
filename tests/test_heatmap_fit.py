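import math

import numpy as np
import pytest

from octscan import (
    Biomarker,
    DiseasePreset,
    PopulationHeatmap,
    SyntheticCohortConfig,
    ValidationError,
    aggregate,
    fit_gaussian,
    gaussian,
)
from octscan.enface import EnFaceMap, enface_map
from octscan.synthetic import sample_eye

from conftest import SMALL_GEOMETRY, make_volume


def _presence_map(pixels, geometry=SMALL_GEOMETRY, eye_id="e"):
    presence = np.zeros((geometry.n_bscans, geometry.n_ascans), dtype=bool)
    for y, x in pixels:
        presence[y, x] = True
    return EnFaceMap(presence=presence, biomarker=Biomarker.SRF, eye_id=eye_id,
                     geometry=geometry)


def _gaussian_heatmap(A=0.9, mu=(3000.0, 3000.0), sigma=800.0, geometry=SMALL_GEOMETRY):
    X, Y = np.meshgrid(geometry.ascan_positions_um, geometry.bscan_positions_um)
    fraction = gaussian(X, Y, A, mu[0], mu[1], sigma)
    return PopulationHeatmap(fraction=fraction, n_eyes=100,
                             biomarker=Biomarker.SRF, geometry=geometry)


class TestAggregate:
    def test_single_eye_equals_presence(self):
        m = _presence_map([(2, 3), (5, 9)])
        h = aggregate([m])
        assert np.array_equal(h.fraction, m.presence.astype(float))
        assert h.n_eyes == 1

    def test_disjoint_lesions_give_half_fraction(self):
        h = aggregate([_presence_map([(2, 3)]), _presence_map([(7, 40)], eye_id="f")])
        assert h.fraction[2, 3] == 0.5 and h.fraction[7, 40] == 0.5
        assert h.fraction.sum() == 1.0

    def test_all_positive_pixel_reaches_one(self):
        maps = [_presence_map([(6, 48)], eye_id=str(i)) for i in range(80)]
        assert aggregate(maps).fraction[6, 48] == 1.0

    def test_mixed_biomarkers_rejected(self):
        a = _presence_map([(0, 0)])
        b = _presence_map([(0, 0)])
        b.biomarker = Biomarker.IRF
        with pytest.raises(ValidationError, match="biomarker"):
            aggregate([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([])


class TestGaussianModel:
    def test_peak_value_is_amplitude(self):
        assert gaussian(100.0, 200.0, 0.7, 100.0, 200.0, 500.0) == 0.7

    def test_one_sigma_radius_closed_form(self):
        # (x-mux)^2 + (y-muy)^2 = 2 sigma^2  ->  A * e^-1
        sigma = 640.0
        r = math.sqrt(2.0) * sigma
        val = gaussian(3000.0 + r, 3000.0, 0.9, 3000.0, 3000.0, sigma)
        assert val == pytest.approx(0.9 * math.exp(-1.0), rel=1e-12)

    def test_zero_amplitude_is_zero_everywhere(self):
        X = np.linspace(0, 6000, 13)
        assert np.all(gaussian(X, X, 0.0, 3000, 3000, 800) == 0.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            gaussian(0.0, 0.0, 1.0, 0.0, 0.0, 0.0)


class TestFit:
    def test_exact_model_recovered(self):
        h = _gaussian_heatmap(A=0.9, mu=(3000.0, 3000.0), sigma=800.0)
        fit = fit_gaussian(h)
        assert fit.converged
        assert fit.A == pytest.approx(0.9, rel=1e-6)
        assert fit.mu_x_um == pytest.approx(3000.0, rel=1e-6)
        assert fit.mu_y_um == pytest.approx(3000.0, rel=1e-6)
        assert fit.sigma_um == pytest.approx(800.0, rel=1e-6)
        assert fit.r_squared >= 0.999999

    def test_constant_heatmap_flagged_degenerate(self):
        h = PopulationHeatmap(
            fraction=np.full((SMALL_GEOMETRY.n_bscans, SMALL_GEOMETRY.n_ascans), 0.4),
            n_eyes=10, biomarker=Biomarker.SRF, geometry=SMALL_GEOMETRY,
        )
        fit = fit_gaussian(h)
        assert not fit.converged
        assert math.isnan(fit.r_squared)

    def test_all_zero_heatmap_rejected(self):
        h = PopulationHeatmap(
            fraction=np.zeros((SMALL_GEOMETRY.n_bscans, SMALL_GEOMETRY.n_ascans)),
            n_eyes=10, biomarker=Biomarker.SRF, geometry=SMALL_GEOMETRY,
        )
        with pytest.raises(ValidationError):
            fit_gaussian(h)

    def test_translation_equivariance(self):
        # shifting the generating center by one pixel in each axis moves the
        # fitted center by exactly the physical pitch; A and sigma unchanged
        dx, dy = SMALL_GEOMETRY.pitch_x_um, SMALL_GEOMETRY.isd_um
        f0 = fit_gaussian(_gaussian_heatmap(mu=(2500.0, 2500.0)))
        f1 = fit_gaussian(_gaussian_heatmap(mu=(2500.0 + dx, 2500.0 + dy)))
        assert f1.mu_x_um - f0.mu_x_um == pytest.approx(dx, rel=1e-6)
        assert f1.mu_y_um - f0.mu_y_um == pytest.approx(dy, rel=1e-6)
        assert f1.A == pytest.approx(f0.A, rel=1e-6)
        assert f1.sigma_um == pytest.approx(f0.sigma_um, rel=1e-6)

    def test_r_squared_decreases_with_pixel_noise(self):
        h = _gaussian_heatmap()
        rng = np.random.default_rng(17)
        noise = rng.standard_normal(h.fraction.shape)
        fits = []
        for level in (0.0, 0.02, 0.1):
            noisy = np.clip(h.fraction + level * noise, 0.0, 1.0)
            hn = PopulationHeatmap(fraction=noisy, n_eyes=100,
                                   biomarker=Biomarker.SRF, geometry=SMALL_GEOMETRY)
            fits.append(fit_gaussian(hn).r_squared)
        assert fits[0] > fits[1] > fits[2]


def _moment_sigma(h: PopulationHeatmap) -> float:
    """Independent moment oracle: weighted RMS radius of the heatmap / sqrt(2)."""
    X, Y = np.meshgrid(h.geometry.ascan_positions_um, h.geometry.bscan_positions_um)
    w = h.fraction
    tot = w.sum()
    mx = (X * w).sum() / tot
    my = (Y * w).sum() / tot
    msr = (((X - mx) ** 2 + (Y - my) ** 2) * w).sum() / tot
    return math.sqrt(msr / 2.0)


def test_fitted_sigma_matches_moment_oracle_on_synthetic_cohort():
    """200 eyes, one small lesion each: fitted sigma tracks the moment estimate."""
    preset = DiseasePreset(
        name="AMD",
        prevalence={Biomarker.IRF: 0.0, Biomarker.SRF: 1.0, Biomarker.PED: 0.0},
        lesion_count_mean=0.0,
        lesion_radius_range_um=(100.0, 150.0),
        lesion_height_range_um=(50.0, 80.0),
    )
    cfg = SyntheticCohortConfig(n_eyes=200, preset=preset, geometry=SMALL_GEOMETRY, seed=11)
    maps = [enface_map(sample_eye(cfg, i), Biomarker.SRF) for i in range(cfg.n_eyes)]
    h = aggregate(maps)
    fit = fit_gaussian(h)
    oracle = _moment_sigma(h)
    assert fit.converged
    assert abs(fit.sigma_um - oracle) <= 0.20 * oracle
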