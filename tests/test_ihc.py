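"""Quantification pipeline: unmixing, registration, segmentation, qi/Pr, QC."""

import numpy as np
import pytest

from mzlprog import ihc
from mzlprog import synthetic as syn
from mzlprog.synthetic import DAB_OD, HEMATOXYLIN_OD

from _oracles import brute_youden  # noqa: F401  (module path sanity)


def forward_pixel(od_amounts, vectors):
    """Beer-Lambert forward model for a single pixel (no noise)."""
    od = sum(a * np.asarray(v) for a, v in zip(od_amounts, vectors))
    return np.clip(np.round(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)


class TestDeconvolve:
    def test_white_pixel_has_zero_od(self):
        tile = np.full((2, 2, 3), 255, dtype=np.uint8)
        conc = ihc.deconvolve(tile)
        assert np.allclose(conc, 0.0, atol=0.01)

    def test_round_trip_recovers_chromogen_od(self):
        px = forward_pixel([0.0, 1.0], (HEMATOXYLIN_OD, DAB_OD))
        tile = np.tile(px, (3, 3, 1))
        conc = ihc.deconvolve(tile)
        assert conc[0, 0, 1] == pytest.approx(1.0, abs=1e-2)
        assert conc[0, 0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_swapping_vectors_swaps_channels(self, rng):
        tile = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        a = ihc.deconvolve(tile, (HEMATOXYLIN_OD, DAB_OD))
        b = ihc.deconvolve(tile, (DAB_OD, HEMATOXYLIN_OD))
        assert np.allclose(a[:, :, 0], b[:, :, 1], atol=1e-12)
        assert np.allclose(a[:, :, 1], b[:, :, 0], atol=1e-12)

    def test_rank_deficient_matrix_rejected(self):
        v = HEMATOXYLIN_OD
        with pytest.raises(ValueError, match="rank"):
            ihc.deconvolve(np.zeros((2, 2, 3), dtype=np.uint8), (v, v))


class TestRegister:
    def test_identical_tiles_zero_shift(self):
        pair = syn.generate_tile_pair(syn.TileSpec(n_cells=40, seed=1))
        assert ihc.register(pair.he_rgb, pair.he_rgb) == (0, 0)

    @pytest.mark.parametrize("shift", [(5, -3), (-7, 2), (0, 9)])
    def test_recovers_planted_shift_exactly(self, shift):
        pair = syn.generate_tile_pair(
            syn.TileSpec(n_cells=60, shift=shift, noise_sd=0.0, seed=4)
        )
        assert ihc.register(pair.he_rgb, pair.ihc_rgb) == shift

    def test_noisy_shift_within_one_pixel(self):
        hits = 0
        for seed in range(5):
            pair = syn.generate_tile_pair(
                syn.TileSpec(n_cells=60, shift=(5, -3), noise_sd=5.0, seed=seed)
            )
            dy, dx = ihc.register(pair.he_rgb, pair.ihc_rgb)
            hits += abs(dy - 5) <= 1 and abs(dx + 3) <= 1
        assert hits == 5

    def test_constant_tile_rejected(self):
        flat = np.full((32, 32, 3), 200, dtype=np.uint8)
        with pytest.raises(ValueError, match="featureless"):
            ihc.register(flat, flat)


class TestSegmentCells:
    def test_blank_tile_zero_cells(self):
        labels = ihc.segment_cells(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_counts_all_synthetic_disks(self):
        spec = syn.TileSpec(n_cells=50, positive_fraction=0.0, seed=6, noise_sd=1.0)
        pair = syn.generate_tile_pair(spec)
        conc = ihc.deconvolve(pair.ihc_rgb, spec.stain_vectors)
        labels = ihc.segment_cells(conc[:, :, 0])
        assert labels.max() == 50

    def test_two_overlapping_disks_split(self):
        # two disks of radius 6 whose centres are 9 px apart (< one radius overlap)
        od = np.zeros((40, 40))
        rows, cols = np.mgrid[0:40, 0:40]
        for cy, cx in ((20, 15), (20, 24)):
            od[(rows - cy) ** 2 + (cols - cx) ** 2 <= 36] = 0.9
        labels = ihc.segment_cells(od)
        assert labels.max() == 2


class TestAutoThreshold:
    def test_separates_bimodal_groups_perfectly(self):
        qi = np.array([0.02] * 25 + [0.95] * 25)
        alpha = ihc.auto_threshold(qi)
        assert 0.02 < alpha < 0.95
        assert ((qi >= alpha) == (qi > 0.5)).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_between_class_variance_scan(self, seed):
        rng = np.random.default_rng(seed)
        qi = np.round(rng.beta(0.5, 0.5, size=40), 3)
        alpha = ihc.auto_threshold(qi)
        # independent oracle: evaluate the criterion at every midpoint
        uniq = np.unique(qi)
        mids = (uniq[:-1] + uniq[1:]) / 2
        best, best_var = None, -np.inf
        for t in mids:
            lo, hi = qi[qi < t], qi[qi >= t]
            var = (len(lo) / len(qi)) * (len(hi) / len(qi)) * (lo.mean() - hi.mean()) ** 2
            if var > best_var + 1e-15:
                best, best_var = t, var
        assert alpha == pytest.approx(best)
        assert 0.0 < alpha < 1.0

    def test_constant_input_demands_manual_alpha(self):
        with pytest.raises(ValueError, match="manual"):
            ihc.auto_threshold([0.3, 0.3, 0.3])


class TestScoreCells:
    def make_masks(self):
        labels = np.zeros((10, 12), dtype=int)
        labels[0:6, 0:10] = 1  # 60 px cell
        positive = np.zeros((10, 12), dtype=bool)
        positive[0:3, 0:10] = True  # 30 positive px inside cell 1
        return labels, positive

    def test_qi_is_exact_area_ratio(self):
        labels, positive = self.make_masks()
        (cell,) = ihc.score_cells(labels, positive, alpha=0.4)
        assert (cell.area_px, cell.positive_area_px) == (60, 30)
        assert cell.qi == 0.5
        assert cell.is_positive

    def test_boundary_is_inclusive(self):
        labels, positive = self.make_masks()
        (cell,) = ihc.score_cells(labels, positive, alpha=0.5)
        assert cell.qi == 0.5 and cell.is_positive

    def test_zero_positive_area_is_negative(self):
        labels, _ = self.make_masks()
        (cell,) = ihc.score_cells(labels, np.zeros_like(labels, dtype=bool), alpha=0.01)
        assert cell.qi == 0.0 and not cell.is_positive

    def test_alpha_out_of_range_rejected(self):
        labels, positive = self.make_masks()
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="alpha"):
                ihc.score_cells(labels, positive, alpha=bad)


class TestQuantifyRoi:
    def _cells(self, n_pos, n_total):
        mk = lambda i, pos: ihc.CellRecord(i, (0.0, 0.0), 10, 10 if pos else 0,
                                           1.0 if pos else 0.0, pos)
        return [mk(i, i < n_pos) for i in range(n_total)]

    def test_rate_formula(self):
        roi = ihc.quantify_roi(self._cells(45, 100), "r", alpha=0.5)
        assert roi.positivity_rate_pct == 45.0
        assert (roi.n_positive, roi.n_total) == (45, 100)

    def test_all_positive_is_100(self):
        assert ihc.quantify_roi(self._cells(7, 7), "r", 0.5).positivity_rate_pct == 100.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            ihc.quantify_roi([], "r", 0.5)


class TestQc:
    def test_clean_tile_passes(self):
        pair = syn.generate_tile_pair(syn.TileSpec(n_cells=80, seed=8))
        report = ihc.qc_tile(pair)
        assert report.pass_flag
        assert report.signal_to_noise > 2

    def test_black_artifact_fails(self):
        pair = syn.generate_tile_pair(syn.TileSpec(n_cells=80, seed=8))
        ihc_img = pair.ihc_rgb.copy()
        h, w, _ = ihc_img.shape
        ihc_img[: int(0.55 * h), : int(0.55 * w)] = 0  # ~30% painted black
        bad = syn.StainTilePair(he_rgb=pair.he_rgb, ihc_rgb=ihc_img)
        report = ihc.qc_tile(bad)
        assert report.artifact_fraction > 0.2
        assert not report.pass_flag

    def test_blank_tile_fails_with_zero_snr(self):
        blank = np.full((64, 64, 3), 250, dtype=np.uint8)
        report = ihc.qc_tile(syn.StainTilePair(he_rgb=blank, ihc_rgb=blank))
        assert report.signal_to_noise == 0.0
        assert not report.pass_flag


class TestEndToEnd:
    def test_round_trip_recovers_positive_fraction(self):
        errs = []
        for seed in range(5):
            pair = syn.generate_tile_pair(
                syn.TileSpec(n_cells=120, positive_fraction=0.4, seed=100 + seed)
            )
            roi, cells = ihc.quantify_tile_pair(pair)
            errs.append(abs(roi.positivity_rate_pct - 40.0))
            assert all(0.0 <= c.qi <= 1.0 for c in cells)
            assert sum(c.area_px for c in cells) <= pair.ihc_rgb.shape[0] * pair.ihc_rgb.shape[1]
        assert np.mean(errs) < 2.0

    def test_rate_invariant_to_90_degree_rotation(self):
        pair = syn.generate_tile_pair(syn.TileSpec(n_cells=100, positive_fraction=0.3, seed=42))
        roi, _ = ihc.quantify_tile_pair(pair)
        rotated = syn.StainTilePair(
            he_rgb=np.rot90(pair.he_rgb).copy(), ihc_rgb=np.rot90(pair.ihc_rgb).copy()
        )
        roi_rot, _ = ihc.quantify_tile_pair(rotated)
        assert roi_rot.n_total == roi.n_total
        assert roi_rot.positivity_rate_pct == roi.positivity_rate_pct

    def test_quantification_with_shifted_ihc_tile(self):
        pair = syn.generate_tile_pair(
            syn.TileSpec(n_cells=120, positive_fraction=0.4, shift=(6, -4), seed=9)
        )
        roi, _ = ihc.quantify_tile_pair(pair)
        assert abs(roi.positivity_rate_pct - 40.0) < 5.0
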