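import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octscan import (
    Biomarker,
    ScanGeometry,
    SyntheticCohortConfig,
    ValidationError,
    amd_preset,
    decimate,
    estimate_volume,
    isd_analysis,
    mape,
    sensitivity_by_isd,
    total_retina_volume,
)
from octscan.isd import bscan_weights, make_level
from octscan.synthetic import iter_cohort

from conftest import SMALL_GEOMETRY, make_volume

# 49 B-scans at 125 µm like the reference protocol, but a tiny in-plane grid
THIN_GEOM = ScanGeometry(
    fov_x_um=6000, fov_y_um=6000, isd_um=125, n_bscans=49,
    n_ascans=16, n_depth=10, depth_scale_um=347.2,
)


class TestDecimate:
    def test_factor_two_halves_scan_count(self):
        v = make_volume(THIN_GEOM, [(2, 0, 0, 2)])
        d = decimate(v, 2)
        assert d.geometry.n_bscans == 25
        assert d.geometry.isd_um == 250.0
        assert np.array_equal(d.labels, v.labels[::2])

    def test_factor_one_is_identity(self):
        v = make_volume(THIN_GEOM, [(2, 0, 0, 2)])
        assert decimate(v, 1) is v

    def test_factor_eight_keeps_borders(self):
        level = make_level(THIN_GEOM, 8)
        assert level.kept_indices[0] == 0
        assert level.kept_indices[-1] == 48
        assert len(level.kept_indices) == 7
        assert level.effective_isd_um == 1000.0

    @pytest.mark.parametrize("factor", [3, 5, 32, 0])
    def test_invalid_factors_rejected(self, factor):
        v = make_volume(THIN_GEOM)
        with pytest.raises(ValidationError):
            decimate(v, factor)


class TestWeights:
    @pytest.mark.parametrize("factor,n_expected", [(1, 49), (2, 25), (4, 13), (8, 7)])
    def test_weight_sum_equals_fov_exactly(self, factor, n_expected):
        g = dataclasses.replace(
            THIN_GEOM, isd_um=125.0 * factor, n_bscans=(49 - 1) // factor + 1
        )
        w = bscan_weights(g)
        assert len(w) == n_expected
        assert w.sum() == 6000.0  # exact identity, no tolerance
        assert w[0] == w[-1] == g.isd_um / 2


class TestVolumeEstimate:
    def test_all_background_is_zero(self):
        assert estimate_volume(make_volume(THIN_GEOM), Biomarker.IRF).volume_um3 == 0.0

    def test_constant_cross_section_invariant_across_factors(self):
        # same SRF cross-section in every B-scan -> volume == a * fov_y exactly
        voxels = [(b, 3, a, 3) for b in range(49) for a in range(4)]
        v = make_volume(THIN_GEOM, voxels)
        g = THIN_GEOM
        a_um2 = 4 * g.pitch_x_um * g.depth_scale_um
        vols = [estimate_volume(decimate(v, f), Biomarker.SRF).volume_um3 for f in (1, 2, 4, 8)]
        assert vols == [a_um2 * 6000.0] * 4  # exact equality

    def test_uniform_slab_matches_closed_form(self):
        # 300 µm slab over the full FOV; depth scale chosen so 300 µm is 40 samples
        g = ScanGeometry(fov_x_um=6000, fov_y_um=6000, isd_um=125, n_bscans=49,
                         n_ascans=480, n_depth=64, depth_scale_um=7.5)
        labels = np.zeros(g.shape, dtype=np.uint8)
        labels[:, 10:50, :] = 1
        v = make_volume(g)
        v.labels = labels
        expected = 6000.0 * 6000.0 * 300.0
        tol = 6000.0 * 6000.0 * g.depth_scale_um  # one voxel-quantization layer
        for f in (1, 2, 4, 8):
            vol = total_retina_volume(decimate(v, f)).volume_um3
            assert abs(vol - expected) <= tol
            assert vol == pytest.approx(expected, rel=1e-12)  # exact multiple here

    def test_retina_compartment_includes_fluid_voxels(self):
        voxels = [(0, 3, 0, 1), (0, 4, 0, 2), (0, 5, 0, 3), (0, 6, 0, 4)]
        v = make_volume(THIN_GEOM, voxels)
        g = THIN_GEOM
        per_voxel = g.pitch_x_um * g.depth_scale_um * g.isd_um / 2  # border scan
        assert total_retina_volume(v).volume_um3 == pytest.approx(3 * per_voxel)


class TestSensitivity:
    def test_factor_one_is_unity(self):
        v = make_volume(THIN_GEOM, [(1, 0, 0, 2)])
        assert sensitivity_by_isd([v], Biomarker.IRF, [1])[1] == 1.0

    def test_odd_index_lesion_lost_at_factor_two(self):
        v = make_volume(THIN_GEOM, [(1, 0, 0, 2)])
        sens = sensitivity_by_isd([v], Biomarker.IRF, [1, 2])
        assert sens[1] == 1.0 and sens[2] == 0.0

    def test_no_positive_eyes_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_by_isd([make_volume(THIN_GEOM)], Biomarker.IRF, [1])


class TestMape:
    def test_hand_computed_cases(self):
        assert mape([100.0], [90.0]).percent == pytest.approx(10.0)
        assert mape([100.0, 200.0], [100.0, 200.0]).percent == 0.0
        assert mape([100.0, 200.0], [110.0, 150.0]).percent == pytest.approx(17.5)

    def test_zero_reference_pairs_excluded_and_counted(self):
        r = mape([100.0, 0.0, 200.0], [90.0, 50.0, 200.0])
        assert r.n_used == 2 and r.n_excluded == 1
        assert r.percent == pytest.approx(5.0)

    def test_all_zero_references_rejected(self):
        with pytest.raises(ValidationError):
            mape([0.0, 0.0], [1.0, 2.0])

    @given(
        ref=st.lists(st.floats(1.0, 1e6), min_size=1, max_size=8),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, ref, scale):
        red = [r * 0.9 for r in ref]
        a = mape(ref, red).percent
        b = mape([r * scale for r in ref], [r * scale for r in red]).percent
        assert a == pytest.approx(b, rel=1e-9)


class TestOracleEquivalence:
    def test_analysis_matches_per_eye_decimation(self):
        """Streaming counts equal decimate-then-measure, volume and detection."""
        cfg = SyntheticCohortConfig(
            n_eyes=20, preset=amd_preset(), geometry=SMALL_GEOMETRY, seed=5
        )
        factors = (1, 2, 4)
        bms = (Biomarker.IRF_SRF, Biomarker.PED, Biomarker.RETINA)
        result = isd_analysis(iter_cohort(cfg), biomarkers=bms, factors=factors)
        vols = result.volumes.set_index(["eye_id", "biomarker", "factor"])["volume_um3"]
        for b in bms:
            detected = {f: 0 for f in factors}
            n_pos = 0
            for v in iter_cohort(cfg):
                ref_positive = np.isin(v.labels, [2, 3] if b is Biomarker.IRF_SRF
                                       else [4] if b is Biomarker.PED
                                       else [1, 2, 3]).any()
                n_pos += ref_positive
                for f in factors:
                    d = decimate(v, f)
                    expected = estimate_volume(d, b).volume_um3
                    assert vols.loc[(v.eye_id, b.value, f)] == expected  # exact
                    if ref_positive and np.isin(d.labels, list(
                            {Biomarker.IRF_SRF: [2, 3], Biomarker.PED: [4],
                             Biomarker.RETINA: [1, 2, 3]}[b])).any():
                        detected[f] += 1
            assert result.n_positive[b] == n_pos
            for f in factors:
                assert result.sensitivity[b][f] == detected[f] / n_pos

    def test_sensitivity_monotone_in_factor(self):
        cfg = SyntheticCohortConfig(
            n_eyes=30, preset=amd_preset(), geometry=SMALL_GEOMETRY, seed=8
        )
        for b in (Biomarker.IRF_SRF, Biomarker.PED):
            sens = sensitivity_by_isd(iter_cohort(cfg), b, (1, 2, 4))
            assert sens[1] >= sens[2] >= sens[4]
            assert sens[1] == 1.0
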