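import numpy as np
import pytest

from apbnrr.blockmatch import (block_relevance, flag_zero_correspondence,
                               match_blocks, select_blocks)
from apbnrr.core import ImageVolume


def _textured(shape=(24, 24, 24), seed=0, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    return ImageVolume(rng.normal(100.0, 15.0, size=shape), spacing)


class TestBlockRelevance:
    def test_constant_image_has_zero_relevance(self):
        img = ImageVolume(np.full((12, 12, 12), 5.0))
        rel = block_relevance(img, np.ones((12, 12, 12), dtype=bool))
        assert np.nanmax(rel) == 0.0

    def test_single_bright_voxel_maximizes_containing_blocks(self):
        data = np.zeros((12, 12, 12))
        data[6, 6, 6] = 100.0
        rel = block_relevance(ImageVolume(data), np.ones((12, 12, 12), dtype=bool))
        peak = np.unravel_index(np.nanargmax(rel), rel.shape)
        assert max(abs(peak[a] - 6) for a in range(3)) <= 1

    def test_relevance_matches_direct_variance(self):
        img = _textured()
        rel = block_relevance(img, np.ones(img.shape, dtype=bool), (3, 3, 3))
        c = (7, 9, 11)
        block = img.data[c[0] - 1: c[0] + 2, c[1] - 1: c[1] + 2, c[2] - 1: c[2] + 2]
        assert np.isclose(rel[c], block.var(), rtol=1e-10)

    def test_blocks_must_fit_inside_mask_and_image(self):
        img = _textured()
        mask = np.zeros(img.shape, dtype=bool)
        mask[5:10, 5:10, 5:10] = True
        rel = block_relevance(img, mask, (3, 3, 3))
        finite = np.argwhere(np.isfinite(rel))
        assert finite.min() >= 6 and finite.max() <= 8

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            block_relevance(_textured(), np.ones((24, 24, 24), dtype=bool), (2, 3, 3))


def _contact_codim(a, b, B):
    g = np.abs(np.asarray(a) - np.asarray(b)) - np.asarray(B)
    if np.any(g > 0):
        return None  # disjoint
    return int((g == 0).sum())


class TestSelectBlocks:
    def test_uniform_relevance_tie_breaks_lexicographically(self):
        rel = np.full((9, 9, 9), np.nan)
        rel[2:7, 2:7, 2:7] = 1.0
        sel = select_blocks(rel, F_s=1e-9, pattern="face", B_s=(3, 3, 3))
        assert len(sel) == 1
        assert tuple(sel.centers[0]) == (2, 2, 2)

    def test_unconstrained_count_is_ceil_of_fraction(self):
        rng = np.random.default_rng(1)
        rel = np.full((40, 9, 9), np.nan)
        rel[::5, 4, 4] = rng.uniform(1, 2, size=8)  # all far apart
        sel = select_blocks(rel, F_s=0.5, pattern="vertex")
        assert len(sel) == int(np.ceil(0.5 * 8))

    @pytest.mark.parametrize("pattern,allowed_codims", [
        ("vertex", set()), ("edge", {3}), ("face", {2, 3})])
    def test_pattern_constraints_audited_exhaustively(self, pattern, allowed_codims):
        rng = np.random.default_rng(2)
        rel = rng.uniform(size=(9, 9, 9))
        sel = select_blocks(rel, F_s=1.0, pattern=pattern, B_s=(3, 3, 3))
        assert len(sel) >= 2
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                codim = _contact_codim(sel.centers[i], sel.centers[j], (3, 3, 3))
                assert codim is None or codim in allowed_codims

    def test_selection_invariant_to_monotone_relevance_rescaling(self):
        rng = np.random.default_rng(3)
        rel = rng.uniform(size=(9, 9, 9))
        a = select_blocks(rel, 0.3, "face")
        b = select_blocks(np.exp(5 * rel), 0.3, "face")
        assert np.array_equal(a.centers, b.centers)

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="no candidate"):
            select_blocks(np.full((5, 5, 5), np.nan), 0.5, "face")


class TestMatchBlocks:
    def _selected(self, img, mask=None):
        if mask is None:
            mask = np.ones(img.shape, dtype=bool)
        rel = block_relevance(img, mask)
        return select_blocks(rel, 0.2, "face")

    def test_identity_match_is_zero_displacement_full_score(self):
        img = _textured()
        blocks = self._selected(img)
        field = match_blocks(img, img, blocks, (7, 7, 3))
        assert np.allclose(field.displacements_mm, 0.0)
        assert np.allclose(field.scores, 1.0, atol=1e-12)

    def test_integer_shift_recovered_exactly_in_mm(self):
        img = _textured(spacing=(2.0, 2.0, 2.0))
        shifted = np.zeros_like(img.data)
        shifted[2:, :, :] = img.data[:-2, :, :]
        moving = img.with_data(shifted)
        mask = np.zeros(img.shape, dtype=bool)
        mask[6:18, 4:20, 4:20] = True  # interior, so shifted content exists
        blocks = self._selected(img, mask)
        field = match_blocks(img, moving, blocks, (7, 7, 3))
        assert np.allclose(field.displacements_mm, [4.0, 0.0, 0.0])

    def test_translation_equivariance_of_recovered_offsets(self):
        img = _textured(seed=5)
        shifted = np.roll(img.data, (1, 2, 0), axis=(0, 1, 2))
        mask = np.zeros(img.shape, dtype=bool)
        mask[6:18, 6:18, 4:20] = True
        blocks = self._selected(img, mask)
        field = match_blocks(img, img.with_data(shifted), blocks, (7, 7, 3))
        assert np.allclose(field.displacements_mm, [1.0, 2.0, 0.0])

    def test_constant_dark_window_flags_zero_correspondence(self):
        img = _textured(seed=6)
        dark = img.with_data(np.zeros_like(img.data))
        blocks = self._selected(img)
        field = match_blocks(img, dark, blocks, (7, 7, 3))
        assert (~field.defined).all()
        assert field.zero_correspondence.all()

    def test_scores_bounded_and_affine_intensity_invariance(self):
        img = _textured(seed=7)
        affine = img.with_data(3.0 * img.data + 17.0)
        blocks = self._selected(img)
        field = match_blocks(img, affine, blocks, (7, 7, 3))
        defined = field.defined
        assert np.all(field.scores[defined] <= 1 + 1e-12)
        assert np.all(field.scores[defined] >= -1 - 1e-12)
        assert np.allclose(field.scores[defined], 1.0, atol=1e-9)
        assert np.allclose(field.displacements_mm[defined], 0.0)

    def test_displacements_bounded_by_window_half_extent(self):
        fixed = _textured(seed=8)
        moving = _textured(seed=9)  # unrelated content
        blocks = self._selected(fixed)
        field = match_blocks(fixed, moving, blocks, (9, 9, 3))
        assert np.all(np.abs(field.displacements_mm[:, 0]) <= 3.0 + 1e-9)
        assert np.all(np.abs(field.displacements_mm[:, 2]) <= 1e-9)

    def test_window_below_block_size_rejected(self):
        img = _textured()
        blocks = self._selected(img)
        with pytest.raises(ValueError, match="W_s"):
            match_blocks(img, img, blocks, (1, 1, 1))

    def test_subvoxel_refinement_keeps_exact_integer_peaks(self):
        img = _textured(seed=10)
        shifted = np.roll(img.data, 2, axis=0)
        mask = np.zeros(img.shape, dtype=bool)
        mask[6:18, 4:20, 4:20] = True
        blocks = self._selected(img, mask)
        field = match_blocks(img, img.with_data(shifted), blocks, (7, 7, 3),
                             subvoxel=True)
        assert np.allclose(field.displacements_mm, [2.0, 0.0, 0.0])


class TestFlagZeroCorrespondence:
    def test_threshold_counts(self):
        img = _textured()
        rel = block_relevance(img, np.ones(img.shape, dtype=bool))
        blocks = select_blocks(rel, 0.05, "face")
        field = match_blocks(img, img, blocks, (7, 7, 3))
        field.scores[:3] = [0.9, 0.4, np.nan]
        out, n = flag_zero_correspondence(field, c_min=0.5)
        assert n == 2
        assert list(out.zero_correspondence[:3]) == [False, True, True]

    def test_perfect_scores_flag_nothing(self):
        img = _textured()
        rel = block_relevance(img, np.ones(img.shape, dtype=bool))
        blocks = select_blocks(rel, 0.05, "face")
        field = match_blocks(img, img, blocks, (7, 7, 3))
        _, n = flag_zero_correspondence(field, c_min=0.5)
        assert n == 0
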