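"""Co-occurrence contrast, normalizations, gradient profile and ratio metrics."""

import numpy as np
import pandas as pd
import pytest
from skimage.feature import graycomatrix

from conftest import brute_force_contrast, brute_force_cooc
from woundtrack import internalization as itl
from woundtrack.errors import DataError, NormalizationError, ParameterError


class TestCoocMatrix:
    def test_constant_region_all_mass_at_origin(self):
        img = np.full((10, 10), 10.0)
        m = itl.cooc_matrix(img, np.ones((10, 10), bool))
        assert m.p[0, 0] == 1.0
        assert m.p.sum() == pytest.approx(1.0)
        assert itl.contrast(m) == 0.0

    def test_two_level_alternating_columns(self):
        # [[0,1],[0,1]]: the two horizontal pairs are both (0, 1)
        img = np.array([[0, 1], [0, 1]], dtype=float)
        m = itl.cooc_matrix(img, np.ones((2, 2), bool), n_levels=2)
        assert m.p[0, 1] == 1.0
        assert itl.contrast(m) == 1.0

    def test_diagonal_mass_gives_zero_contrast(self):
        p = np.zeros((4, 4))
        p[np.arange(4), np.arange(4)] = 0.25
        m = itl.CoocMatrix(p, 4, (0, 1), False, (0.0, 1.0))
        assert itl.contrast(m) == 0.0

    @pytest.mark.parametrize("offset,symmetric", [
        ((0, 1), False), ((1, 0), False), ((0, 1), True), ((1, 1), False),
    ])
    def test_matches_brute_force_oracle(self, rng, offset, symmetric):
        for _ in range(10):
            img = rng.integers(0, 200, (16, 16)).astype(float)
            mask = rng.uniform(size=(16, 16)) > 0.3
            mask[0, :2] = True  # guarantee at least one pair somewhere
            try:
                m = itl.cooc_matrix(img, mask, n_levels=8, offset=offset,
                                    symmetric=symmetric)
            except DataError:
                continue
            counts = brute_force_cooc(img, mask, 8, offset, symmetric)
            np.testing.assert_allclose(m.p, counts / counts.sum(), atol=1e-9)
            assert itl.contrast(m) == pytest.approx(
                brute_force_contrast(counts), abs=1e-9)

    def test_matches_skimage_on_full_rectangle(self, rng):
        # independent library cross-check where masking plays no role
        img = rng.integers(0, 256, (20, 20))
        levels, _ = itl.quantize(img, np.ones_like(img, bool), 8)
        ref = graycomatrix(levels.astype(np.uint8), [1], [0], levels=8,
                           symmetric=False, normed=True)[:, :, 0, 0]
        m = itl.cooc_matrix(img, np.ones_like(img, bool), n_levels=8)
        np.testing.assert_allclose(m.p, ref, atol=1e-12)

    def test_affine_intensity_invariance(self, rng):
        img = rng.uniform(0, 1000, (16, 16))
        mask = np.ones((16, 16), bool)
        c0 = itl.cell_contrast(img, mask)
        c1 = itl.cell_contrast(2.5 * img + 77.0, mask)
        assert c1 == pytest.approx(c0, abs=1e-9)

    def test_no_valid_pairs_raises(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[2, 2] = True  # no horizontally adjacent pair
        with pytest.raises(DataError):
            itl.cooc_matrix(np.ones((5, 5)), mask)

    def test_contrast_bounded_by_level_range(self, rng):
        img = rng.uniform(0, 1, (12, 12))
        c = itl.cell_contrast(img, np.ones((12, 12), bool), n_levels=8)
        assert 0.0 <= c <= 49.0


class TestNormalization:
    def _results(self, raws):
        return [itl.ContrastResult(i, r) for i, r in enumerate(raws)]

    def test_cht_mean(self):
        out = itl.normalize_contrast(self._results([2.0, 4.0]), "cht_mean",
                                     self._results([1.0, 3.0]))
        assert [r.normalized_contrast for r in out] == [1.0, 2.0]
        assert all(r.reference_value == 2.0 for r in out)

    def test_movie_max_maps_into_unit_interval(self):
        out = itl.normalize_contrast(self._results([0.2, 0.5, 1.0]), "movie_max")
        assert [r.normalized_contrast for r in out] == [0.2, 0.5, 1.0]

    def test_raws_equal_reference_all_one(self):
        out = itl.normalize_contrast(self._results([3.0, 3.0]), "cht_mean",
                                     self._results([3.0]))
        assert all(r.normalized_contrast == 1.0 for r in out)

    def test_zero_divisor_raises(self):
        with pytest.raises(NormalizationError):
            itl.normalize_contrast(self._results([1.0]), "cht_mean",
                                   self._results([0.0]))
        with pytest.raises(NormalizationError):
            itl.normalize_contrast(self._results([0.0]), "movie_max")

    def test_missing_reference_raises(self):
        with pytest.raises(NormalizationError):
            itl.normalize_contrast(self._results([1.0]), "cht_mean", None)


class TestGradientProfile:
    MARGIN = np.array([[0.0, 0.0], [0.0, 100.0]])

    def test_cell_on_margin_lands_in_first_bin(self):
        prof = itl.gradient_profile([(0.0, 50.0)], [1.0], self.MARGIN,
                                    bin_width_um=25.0)
        assert prof.iloc[0]["bin_lo"] == 0.0
        assert prof.iloc[0]["n"] == 1

    def test_binning_at_width_25(self):
        prof = itl.gradient_profile([(10.0, 50.0), (30.0, 50.0)], [1.0, 0.5],
                                    self.MARGIN, bin_width_um=25.0)
        assert list(prof["n"]) == [1, 1]
        assert list(prof["bin_lo"]) == [0.0, 25.0]
        assert np.isnan(prof["sem"]).all()  # SEM undefined for n < 2

    def test_sem_across_cells(self):
        cells = [(10.0, y) for y in (10, 20, 30)]
        prof = itl.gradient_profile(cells, [1.0, 2.0, 3.0], self.MARGIN,
                                    bin_width_um=25.0)
        vals = np.array([1.0, 2.0, 3.0])
        assert prof.iloc[0]["mean"] == pytest.approx(2.0)
        assert prof.iloc[0]["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(3))

    def test_decay_fit_recovers_planted_length(self, rng):
        d = rng.uniform(0, 300, 80)
        vals = 2.0 * np.exp(-d / 150.0)
        L, A = itl.fit_decay_length(d, vals)
        assert L == pytest.approx(150.0, rel=1e-6)
        assert A == pytest.approx(2.0, rel=1e-6)


class TestRatioMetrics:
    def _contour(self):
        m = np.zeros((20, 20), bool)
        m[5:8, 5:15] = True
        return m

    def test_identical_channels_give_unity(self):
        img = np.random.default_rng(0).uniform(1, 2, (20, 20))
        assert itl.membrane_ratio(img, img, self._contour()) == pytest.approx(1.0)

    def test_uniform_scale_cancels(self):
        rng = np.random.default_rng(1)
        cfp = rng.uniform(1, 2, (20, 20))
        assert itl.membrane_ratio(2.0 * cfp, cfp, self._contour()) == \
            pytest.approx(1.0)

    def test_contour_depleted_gfp_scores_below_one(self):
        cfp = np.ones((20, 20))
        gfp = np.ones((20, 20))
        contour = self._contour()
        gfp[contour] = 0.5
        assert itl.membrane_ratio(gfp, cfp, contour) < 1.0

    @pytest.mark.parametrize("cell_level,expected", [(2.0, 2.0), (0.0, 0.0)])
    def test_uptake_score_against_roi(self, cell_level, expected):
        img = np.ones((200, 200))
        mask = np.zeros((200, 200), bool)
        mask[10:20, 10:20] = True
        img[mask] = cell_level
        score = itl.uptake_score(mask, img, (40, 40, 150, 150))
        assert score == pytest.approx(expected)

    def test_uptake_uniform_field_is_one(self):
        img = np.full((200, 200), 7.0)
        mask = np.zeros((200, 200), bool)
        mask[0:5, 0:5] = True
        assert itl.uptake_score(mask, img, (40, 40, 150, 150)) == \
            pytest.approx(1.0)

    def test_zero_roi_raises(self):
        img = np.zeros((200, 200))
        mask = np.zeros((200, 200), bool)
        mask[0:5, 0:5] = True
        with pytest.raises(NormalizationError):
            itl.uptake_score(mask, img, (40, 40, 150, 150))


class TestQualityGate:
    def test_saturated_cell_rejected(self):
        img = np.full((10, 10), 65535, dtype=np.uint16)
        ok, reason = itl.quality_gate(img, np.ones((10, 10), bool))
        assert not ok and "saturated" in reason

    def test_dim_cell_rejected(self):
        img = np.full((10, 10), 5, dtype=np.uint16)
        img[0, 0] = 6  # two distinct levels only
        ok, reason = itl.quality_gate(img, np.ones((10, 10), bool))
        assert not ok and "dynamic range" in reason

    def test_textured_cell_passes(self, rng):
        img = rng.integers(0, 1000, (10, 10)).astype(np.uint16)
        ok, reason = itl.quality_gate(img, np.ones((10, 10), bool))
        assert ok and reason is None
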