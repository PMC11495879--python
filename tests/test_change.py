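"""Growth/loss mapping, transition encoding and succession/reduction shares."""

import numpy as np
import pytest
from PIL import Image

from scrubshift import (
    GROUND,
    SCRUB,
    TREES,
    ClassCodeMap,
    HeightBandScheme,
    change_map,
    classify_heights,
    class_presence_mask,
    compute_chm,
    encode_transitions,
    isolate_class,
    render_change,
    transition_summary,
)
from scrubshift.change import CHANGE_COLORS, GROWTH, LOSS, NO_CHANGE

from conftest import make_height_raster, make_mask

BAND_HEIGHT = {GROUND: 0.3, SCRUB: 2.0, TREES: 7.0}


def class_raster_from_bands(band_grid):
    """Build a ClassRaster by classifying heights chosen inside each band."""
    heights = np.vectorize(BAND_HEIGHT.get)(np.asarray(band_grid, dtype=object))
    return classify_heights(make_height_raster(heights.astype(np.float64)))


class TestChangeMap:
    def test_subtraction_table(self):
        older = make_mask([[1, 0, 1, 0]])
        newer = make_mask([[0, 1, 1, 0]])
        change = change_map(older, newer)
        assert change.values.tolist() == [[LOSS, GROWTH, NO_CHANGE, NO_CHANGE]]

    def test_identical_epochs_no_change(self):
        m = make_mask((np.random.default_rng(2).random((8, 8)) < 0.4).astype(int))
        change = change_map(m, m)
        assert change.growth_area_m2 == 0 and change.loss_area_m2 == 0

    def test_code_partition_counts(self):
        rng = np.random.default_rng(9)
        older = make_mask((rng.random((12, 12)) < 0.5).astype(int))
        newer = make_mask((rng.random((12, 12)) < 0.5).astype(int))
        change = change_map(older, newer)
        assert (change.growth_cells + change.loss_cells + change.unchanged_cells
                == change.raster.n_data == 144)

    def test_nodata_in_either_epoch_is_nodata(self):
        older = make_mask([[1, 255, 1]], nodata=255)
        newer = make_mask([[255, 1, 0]], nodata=255)
        change = change_map(older, newer)
        assert change.raster.data_mask.tolist() == [[False, False, True]]

    def test_antisymmetry_under_epoch_swap(self):
        rng = np.random.default_rng(13)
        older = make_mask((rng.random((10, 10)) < 0.5).astype(int))
        newer = make_mask((rng.random((10, 10)) < 0.5).astype(int))
        fwd = change_map(older, newer)
        rev = change_map(newer, older)
        np.testing.assert_array_equal(fwd.values, -rev.values)
        assert fwd.growth_area_m2 == rev.loss_area_m2
        assert fwd.loss_area_m2 == rev.growth_area_m2

    def test_scripted_clearance_and_growth_counts(self, demo_sites):
        spec, surveys, truth = demo_sites["B"]
        cls = {s.epoch_label: classify_heights(compute_chm(s)) for s in surveys}
        change = change_map(class_presence_mask(cls["2019"], SCRUB),
                            class_presence_mask(cls["2021"], SCRUB),
                            ("2019", "2021"))
        assert change.loss_cells == truth.loss_cells(("2019", "2021"))
        assert change.growth_cells == truth.growth_cells(("2019", "2021"))

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="not a 0/1"):
            change_map(make_mask([[2]]), make_mask([[0]]))


class TestEncodeTransitions:
    def test_full_code_table(self):
        older = class_raster_from_bands([[GROUND, GROUND, TREES, SCRUB, TREES, SCRUB, SCRUB]])
        newer = class_raster_from_bands([[SCRUB, TREES, SCRUB, TREES, GROUND, GROUND, SCRUB]])
        tr = encode_transitions(older, newer)
        assert tr.raster.values[0, :6].tolist() == [90, 50, 40, -40, -50, -90]
        assert not tr.raster.data_mask[0, 6]  # unchanged cell removed

    def test_round_trip_decode_recovers_class_pairs(self):
        rng = np.random.default_rng(21)
        bands = np.array([GROUND, SCRUB, TREES])
        older = class_raster_from_bands(bands[rng.integers(0, 3, (9, 9))])
        newer = class_raster_from_bands(bands[rng.integers(0, 3, (9, 9))])
        tr = encode_transitions(older, newer)
        decode = tr.decode_table
        for r, c in zip(*np.nonzero(tr.raster.data_mask)):
            a, b = decode[int(tr.raster.values[r, c])]
            assert older.codes.code_of(a) == older.values[r, c]
            assert newer.codes.code_of(b) == newer.values[r, c]

    def test_antisymmetry_under_epoch_swap(self):
        rng = np.random.default_rng(22)
        bands = np.array([GROUND, SCRUB, TREES])
        older = class_raster_from_bands(bands[rng.integers(0, 3, (8, 8))])
        newer = class_raster_from_bands(bands[rng.integers(0, 3, (8, 8))])
        fwd = encode_transitions(older, newer)
        rev = encode_transitions(newer, older)
        np.testing.assert_array_equal(fwd.raster.data_mask, rev.raster.data_mask)
        d = fwd.raster.data_mask
        np.testing.assert_array_equal(fwd.raster.values[d], -rev.raster.values[d])

    def test_mismatched_code_maps_rejected(self):
        older = class_raster_from_bands([[GROUND]])
        newer = classify_heights(make_height_raster([[2.0]]),
                                 codes=ClassCodeMap(ground=200, scrub=10, trees=50))
        with pytest.raises(ValueError, match="code map"):
            encode_transitions(older, newer)


class TestTransitionSummary:
    def test_single_transition_gives_full_reduction_share(self):
        older = class_raster_from_bands([[SCRUB, SCRUB]])
        newer = class_raster_from_bands([[GROUND, GROUND]])
        summary = transition_summary(encode_transitions(older, newer), None, 100.0)
        assert summary.reduction_share_percent == 100.0
        assert summary.succession_share_percent == 0.0

    def test_balanced_growth_and_loss_split_shares_evenly(self):
        older = class_raster_from_bands([[GROUND, SCRUB]])
        newer = class_raster_from_bands([[SCRUB, GROUND]])
        summary = transition_summary(encode_transitions(older, newer), None, 100.0)
        assert summary.succession_share_percent == 50.0
        assert summary.reduction_share_percent == 50.0

    def test_ledger_arithmetic_percent_of_growth_and_loss(self):
        # areas: g→s 30, t→s 10, s→g 45, s→t 15 m² on 1×... grid of 5 m² cells
        bands_old = [GROUND] * 6 + [TREES] * 2 + [SCRUB] * 9 + [SCRUB] * 3
        bands_new = [SCRUB] * 6 + [SCRUB] * 2 + [GROUND] * 9 + [TREES] * 3
        from scrubshift import GridTransform

        t = GridTransform(0, 1, 1.0, 5.0)
        older = classify_heights(make_height_raster(
            [[BAND_HEIGHT[b] for b in bands_old]], t))
        newer = classify_heights(make_height_raster(
            [[BAND_HEIGHT[b] for b in bands_new]], t))
        summary = transition_summary(encode_transitions(older, newer), None, 1000.0)
        assert summary.stats[(GROUND, SCRUB)].area_m2 == 30.0
        assert summary.stats[(GROUND, SCRUB)].percent_of_growth == 75.0
        assert summary.stats[(SCRUB, GROUND)].percent_of_loss == 75.0
        assert summary.growth_area_m2 == 40.0
        assert summary.loss_area_m2 == 60.0

    def test_cross_check_against_change_raster(self, demo_sites):
        spec, surveys, truth = demo_sites["A"]
        cls = {s.epoch_label: classify_heights(compute_chm(s)) for s in surveys}
        for a, b in truth.epoch_pairs():
            change = change_map(class_presence_mask(cls[a], SCRUB),
                                class_presence_mask(cls[b], SCRUB), (a, b))
            tr = encode_transitions(cls[a], cls[b], (a, b))
            summary = transition_summary(tr, change, truth.site_area_m2)
            assert summary.growth_area_m2 == change.growth_area_m2
            assert summary.loss_area_m2 == change.loss_area_m2
            for pair, n in truth.transitions[(a, b)].items():
                assert summary.stats[pair].area_m2 == n * truth.cell_area_m2

    def test_epoch_pair_mismatch_rejected(self):
        older = class_raster_from_bands([[SCRUB]])
        newer = class_raster_from_bands([[GROUND]])
        tr = encode_transitions(older, newer, ("2015", "2021"))
        change = change_map(class_presence_mask(older, SCRUB),
                            class_presence_mask(newer, SCRUB), ("2019", "2021"))
        with pytest.raises(ValueError, match="epoch"):
            transition_summary(tr, change, 100.0)

    def test_ground_tree_flag_changes_share_basis(self):
        # g→t only: excluded by default, succession when included
        older = class_raster_from_bands([[GROUND, SCRUB]])
        newer = class_raster_from_bands([[TREES, GROUND]])
        tr = encode_transitions(older, newer)
        default = transition_summary(tr, None, 100.0)
        assert default.reduction_share_percent == 100.0
        flagged = transition_summary(tr, None, 100.0, include_ground_tree_shares=True)
        assert flagged.succession_share_percent == 50.0


class TestRenderChange:
    def _count_colors(self, path):
        img = np.asarray(Image.open(path).convert("RGB"))
        return {
            code: int((img == np.array(color)).all(axis=-1).sum())
            for code, color in CHANGE_COLORS.items()
        }

    def test_uniform_grey_when_unchanged(self, tmp_path):
        m = make_mask(np.ones((5, 5), dtype=int))
        change = change_map(m, m)
        out = tmp_path / "c.png"
        render_change(change, out)
        counts = self._count_colors(out)
        assert counts[NO_CHANGE] == 25
        assert counts[GROWTH] == 0 and counts[LOSS] == 0

    def test_pixel_counts_match_change_cells(self, tmp_path):
        rng = np.random.default_rng(5)
        older = make_mask((rng.random((16, 16)) < 0.5).astype(int))
        newer = make_mask((rng.random((16, 16)) < 0.5).astype(int))
        change = change_map(older, newer)
        out = tmp_path / "c.png"
        render_change(change, out)
        counts = self._count_colors(out)
        assert counts[GROWTH] == change.growth_cells
        assert counts[LOSS] == change.loss_cells
        assert counts[NO_CHANGE] == change.unchanged_cells

    def test_transition_map_renders(self, tmp_path):
        older = class_raster_from_bands([[GROUND, TREES], [SCRUB, SCRUB]])
        newer = class_raster_from_bands([[SCRUB, SCRUB], [GROUND, TREES]])
        tr = encode_transitions(older, newer)
        out = tmp_path / "t.png"
        render_change(tr, out)
        assert out.exists() and out.stat().st_size > 0
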