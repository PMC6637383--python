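"""Synthetic histology generation and cell morphing on label rasters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myowalk.raster import (LabelRaster, RasterError, _BIG,
                            _neighbour_label_range, _BOX, ecv_area,
                            load_raster, morph_to_ecv, save_raster,
                            shrink_cells, synthesize_histology,
                            thicken_cells, thicken_to_fixed_point)


def simple_raster(labels, shear=None):
    labels = np.asarray(labels, dtype=np.int32)
    ids = np.unique(labels)
    return LabelRaster(labels=labels,
                       sheetlet_of={int(i): 0 for i in ids if i > 0},
                       pixel_size=0.5,
                       shear_mask=(np.zeros_like(labels, dtype=bool)
                                   if shear is None else shear))


def no_cells_8_adjacent(raster):
    """Exhaustive scan: no pixel of one cell has an 8-neighbour of another."""
    lab = raster.labels
    nz = lab > 0
    mn, mx = _neighbour_label_range(lab, _BOX)
    mn = np.where(mn == _BIG, lab, mn)
    mx = np.where(mx == 0, lab, mx)
    return not np.any(nz & ((mn != lab) | (mx != lab)))


class TestEcvArea:
    def test_all_ecs(self):
        assert ecv_area(simple_raster(np.zeros((4, 4)))) == 1.0

    def test_checkerboard_half(self):
        """Half the pixels carry cells, half are ECS -> fraction 0.5."""
        lab = np.zeros((4, 8), dtype=np.int32)
        lab[:, ::2] = np.arange(1, 5)[:, None]  # stripe cells
        assert ecv_area(simple_raster(lab)) == 0.5

    def test_empty_raster_rejected(self):
        with pytest.raises(RasterError):
            LabelRaster(labels=np.zeros((0, 0)), sheetlet_of={},
                        pixel_size=0.5, shear_mask=np.zeros((0, 0), bool))


class TestThicken:
    def test_one_pixel_gap_preserved(self):
        lab = np.zeros((5, 7), dtype=np.int32)
        lab[1:4, 1:3] = 1
        lab[1:4, 4:6] = 2
        out = thicken_cells(simple_raster(lab), 1)
        assert np.array_equal(out.labels[:, 3], np.zeros(5))
        assert no_cells_8_adjacent(out)

    def test_single_cell_ring_growth(self):
        """2x2 cell gains its 4-adjacent ring: 4 -> 12 pixels."""
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[3:5, 3:5] = 1
        out = thicken_cells(simple_raster(lab), 1)
        assert int(np.sum(out.labels == 1)) == 12

    def test_shear_layers_never_invaded(self):
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[3:5, 3:5] = 1
        shear = np.zeros((8, 8), dtype=bool)
        shear[2, :] = True
        out = thicken_cells(LabelRaster(lab, {1: 0}, 0.5, shear), 5)
        assert not np.any((out.labels > 0) & shear)

    def test_fixed_point_is_stable(self, small_histology):
        fixed, n_iter = thicken_to_fixed_point(small_histology)
        assert n_iter >= 1
        again = thicken_cells(fixed, 3)
        assert np.array_equal(again.labels, fixed.labels)
        assert no_cells_8_adjacent(fixed)

    def test_ecv_monotone_non_increasing(self, small_histology):
        r = small_histology
        values = [ecv_area(r)]
        for _ in range(4):
            r = thicken_cells(r, 1)
            values.append(ecv_area(r))
        assert all(b <= a for a, b in zip(values, values[1:]))


class TestShrink:
    def test_three_by_three_erodes_to_centre(self):
        lab = np.zeros((9, 9), dtype=np.int32)
        lab[3:6, 3:6] = 1
        out = shrink_cells(simple_raster(lab), 1)
        assert int(np.sum(out.labels == 1)) == 1
        assert out.labels[4, 4] == 1

    def test_annihilation_guard(self):
        lab = np.zeros((5, 5), dtype=np.int32)
        lab[2, 2] = 1
        out = shrink_cells(simple_raster(lab), 3)
        assert int(np.sum(out.labels == 1)) == 1

    def test_ecv_monotone_non_decreasing(self, small_histology):
        r = small_histology
        values = [ecv_area(r)]
        for _ in range(3):
            r = shrink_cells(r, 1)
            values.append(ecv_area(r))
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestMorphInvariants:
    def test_cell_count_and_sheetlets_preserved(self, small_histology):
        r = small_histology
        thick = thicken_cells(r, 2)
        shrunk = shrink_cells(r, 1)
        for out in (thick, shrunk):
            assert np.array_equal(out.cell_ids, r.cell_ids)
            assert out.sheetlet_of == r.sheetlet_of
            out.validate()

    def test_thicken_shrink_iteration_asymmetry(self, small_histology):
        """Thickening stalls in narrow gaps; shrinking opens all gaps at
        once, so recovering the starting ECS needs far fewer passes."""
        start_ecv = ecv_area(small_histology)
        fixed, n_thick = thicken_to_fixed_point(small_histology)
        assert ecv_area(fixed) < start_ecv
        r = fixed
        n_shrink = 0
        while ecv_area(r) < start_ecv:
            r = shrink_cells(r, 1)
            n_shrink += 1
        assert n_shrink < n_thick

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_blob_morphing_respects_gap_rule(self, seed):
        from hypothesis import assume

        rng = np.random.default_rng(seed)
        lab = np.zeros((24, 24), dtype=np.int32)
        for cid in (1, 2, 3):
            r0, c0 = rng.integers(2, 18, size=2)
            lab[r0:r0 + rng.integers(2, 5), c0:c0 + rng.integers(2, 5)] = cid
        raster = simple_raster(lab)
        # precondition: the random rectangles start separated and intact
        assume(no_cells_8_adjacent(raster))
        assume(np.array_equal(np.unique(lab), [0, 1, 2, 3]))
        out = thicken_cells(raster, 3)
        assert no_cells_8_adjacent(out)
        assert ecv_area(out) <= ecv_area(raster)


class TestGenerator:
    def test_target_fraction_and_structure(self, small_histology):
        r = small_histology
        assert 0.36 <= ecv_area(r) <= 0.40
        r.validate()
        assert len(set(r.sheetlet_of.values())) == 3
        assert no_cells_8_adjacent(r)

    def test_full_size_matches_study_conditions(self):
        """Default 500 x 400 um ROI: ~1e3 cells in 12 sheetlets at 38 %
        extra-cellular area fraction, mean cross-section ~110 um^2."""
        r = synthesize_histology(seed=3)
        assert 0.36 <= ecv_area(r) <= 0.40
        assert 900 <= r.cell_ids.size <= 1400
        assert len(set(r.sheetlet_of.values())) == 12
        areas = np.array(list(r.cell_areas_um2().values()))
        assert 90.0 <= areas.mean() <= 130.0

    def test_deterministic_under_seed(self):
        a = synthesize_histology(roi_um=(100, 80), n_sheetlets=2, seed=9)
        b = synthesize_histology(roi_um=(100, 80), n_sheetlets=2, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_target_rejected(self):
        with pytest.raises(RasterError):
            synthesize_histology(target_ecs=0.0, roi_um=(100, 80),
                                 n_sheetlets=2)


class TestMorphToEcv:
    def test_reaches_target_both_directions(self, small_histology):
        up = morph_to_ecv(small_histology, 0.45, seed=1)
        assert ecv_area(up) == pytest.approx(0.45, abs=0.01)
        down = morph_to_ecv(small_histology, 0.30, seed=1)
        assert ecv_area(down) == pytest.approx(0.30, abs=0.01)
        up.validate()
        down.validate()
        assert no_cells_8_adjacent(down)


class TestIO:
    def test_tiff_sidecar_roundtrip(self, small_histology, tmp_path):
        p = tmp_path / "raster.tiff"
        save_raster(small_histology, p)
        back = load_raster(p)
        assert np.array_equal(back.labels, small_histology.labels)
        assert np.array_equal(back.shear_mask, small_histology.shear_mask)
        assert back.sheetlet_of == small_histology.sheetlet_of
        assert back.pixel_size == small_histology.pixel_size
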