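import numpy as np
import pandas as pd
import pytest

from brstnet.core_io import CountMatrix, ValidationError
from brstnet.preprocessing import (
    augment_patch,
    extract_patches,
    filter_genes,
    filter_spots,
    log_transform,
    patch_box,
    preprocess_dataset,
    select_genes,
    standardize_patch,
)
from brstnet.synthetic import SynthConfig, generate_sections

from conftest import make_section


def cm(values, genes=None, spots=None):
    values = np.asarray(values)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    spots = spots or [f"s{i}" for i in range(values.shape[0])]
    return CountMatrix(pd.DataFrame(values, index=spots, columns=genes))


class TestFilterGenes:
    def test_all_zero_gene_removed_others_kept(self):
        m = cm([[0, 1, 0, 2, 0], [0, 0, 0, 1, 0], [0, 5, 0, 0, 0], [0, 0, 0, 3, 0]])
        out = filter_genes(m)
        assert list(out.values.columns) == ["g1", "g3"]
        assert out.values.shape == (4, 2)

    def test_single_count_kept(self):
        vals = np.zeros((100, 2), dtype=int)
        vals[17, 0] = 1
        vals[:, 1] = 5
        out = filter_genes(cm(vals))
        assert list(out.values.columns) == ["g0", "g1"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            filter_genes(cm(np.empty((0, 0))))

    def test_idempotent(self):
        m = cm([[0, 1, 0], [0, 2, 0]])
        once = filter_genes(m)
        twice = filter_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestFilterSpots:
    def test_at_least_threshold_is_inclusive(self):
        m = cm([[999], [1000], [1500], [0]])
        out = filter_spots(m, min_total=1000)
        assert list(out.values.index) == ["s1", "s2"]

    def test_zero_threshold_keeps_all(self):
        m = cm([[1], [0], [7]])
        assert len(filter_spots(m, min_total=0)) == 3

    def test_all_empty_spots(self, caplog):
        m = cm(np.zeros((3, 2), dtype=int))
        with caplog.at_level("WARNING"):
            out = filter_spots(m, min_total=1000)
        assert len(out) == 0

    def test_idempotent(self):
        m = cm([[1200, 0], [500, 100], [800, 800]])
        once = filter_spots(m)
        twice = filter_spots(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestLogTransform:
    def test_zero_maps_to_zero_and_closed_form(self):
        m = cm([[0, int(np.e**2)]])
        out = log_transform(m)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(np.log1p(int(np.e**2)), abs=1e-12)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 500, size=(6, 9))
        out = log_transform(cm(vals))
        assert np.allclose(out.to_numpy(), np.log(1.0 + vals), atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(pd.DataFrame([[-1.0]]))


class TestSelectGenes:
    def test_top_k_by_mean(self):
        m = cm([[3, 1, 4, 1, 5]])
        sel = select_genes(m, k=2)
        assert sel.main_genes == ["g4", "g2"]
        assert sel.aux_genes == ["g0", "g1", "g3"]

    def test_k_equals_all_genes(self):
        m = cm([[1, 2, 3]])
        sel = select_genes(m, k=3)
        assert sel.aux_genes == []

    def test_tie_breaks_lexicographically(self):
        m = cm([[2, 2, 1]], genes=["gb", "ga", "gc"])
        sel = select_genes(m, k=1)
        assert sel.main_genes == ["ga"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_genes(cm([[1, 2]]), k=3)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 50, size=(10, 6))
        m = cm(vals)
        shuffled = CountMatrix(m.values[list(np.array(m.values.columns)[::-1])])
        assert select_genes(m, 3).main_genes == select_genes(shuffled, 3).main_genes


class TestExtractPatches:
    def test_box_arithmetic(self):
        assert patch_box(500, 600, 224) == (488, 712, 388, 612)

    def test_all_white_patch_excluded(self):
        image = np.full((100, 100, 3), 255, dtype=np.uint8)
        sec = make_section(image, [("a", 50, 50)], np.array([[5]]))
        ps = extract_patches(sec, ["a"], patch_size=32)
        assert len(ps) == 0 and ps.n_excluded_white == 1

    def test_exactly_half_white_retained(self):
        image = np.zeros((64, 64, 3), dtype=np.uint8)
        image[:, 32:] = 255  # right half white -> exactly 50%
        sec = make_section(image, [("a", 32, 32)], np.array([[5]]))
        ps = extract_patches(sec, ["a"], patch_size=64)
        assert len(ps) == 1

    def test_just_over_half_white_excluded(self):
        image = np.zeros((64, 64, 3), dtype=np.uint8)
        image[:, 32:] = 255
        image[0, 31] = 255  # one extra white pixel -> > 50%
        sec = make_section(image, [("a", 32, 32)], np.array([[5]]))
        ps = extract_patches(sec, ["a"], patch_size=64)
        assert len(ps) == 0

    def test_border_spot_skipped_not_padded(self):
        image = np.zeros((100, 100, 3), dtype=np.uint8)
        sec = make_section(
            image, [("edge", 5, 5), ("mid", 50, 50)], np.array([[1], [2]])
        )
        ps = extract_patches(sec, ["edge", "mid"], patch_size=32)
        assert len(ps) == 1 and ps.n_skipped_bounds == 1
        assert ps.spot_refs["spot_id"].tolist() == ["mid"]

    def test_patch_larger_than_image_rejected(self):
        image = np.zeros((32, 32, 3), dtype=np.uint8)
        sec = make_section(image, [("a", 16, 16)], np.array([[1]]))
        with pytest.raises(ValidationError):
            extract_patches(sec, ["a"], patch_size=64)


class TestAugmentPatch:
    def test_preserves_pixel_multiset_and_determinism(self):
        rng = np.random.default_rng(3)
        patch = rng.integers(0, 255, size=(3, 16, 16)).astype(np.uint8)
        out1 = augment_patch(patch, np.random.default_rng(7))
        out2 = augment_patch(patch, np.random.default_rng(7))
        assert np.array_equal(out1, out2)
        assert np.array_equal(np.sort(out1.ravel()), np.sort(patch.ravel()))

    def test_flip_and_rotation_group_closure(self):
        rng = np.random.default_rng(4)
        patch = rng.integers(0, 255, size=(3, 8, 8)).astype(np.uint8)
        assert np.array_equal(np.rot90(patch, 4, axes=(-2, -1)), patch)
        assert np.array_equal(patch[..., :, ::-1][..., :, ::-1], patch)

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            augment_patch(np.zeros((3, 8, 10)), np.random.default_rng(0))


class TestStandardizePatch:
    def test_per_patch_stats_zero_mean_unit_std(self):
        rng = np.random.default_rng(5)
        patch = rng.integers(0, 255, size=(3, 32, 32)).astype(np.uint8)
        out = standardize_patch(patch)
        assert np.abs(out.mean(axis=(-2, -1))).max() < 1e-4
        assert np.abs(out.std(axis=(-2, -1)) - 1).max() < 1e-4

    def test_hand_formula(self):
        patch = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        out = standardize_patch(patch, np.array([4.0]), np.array([2.0]))
        assert np.allclose(out, [[[-1.5, -0.5], [0.5, 1.5]]])

    def test_constant_patch_with_dataset_stats(self):
        patch = np.full((3, 4, 4), 100.0)
        out = standardize_patch(patch, np.array([50.0] * 3), np.array([25.0] * 3))
        assert np.allclose(out, 2.0)

    def test_zero_std_rejected(self):
        with pytest.raises(ValidationError):
            standardize_patch(np.zeros((3, 4, 4)), np.zeros(3), np.zeros(3))


@pytest.fixture(scope="module")
def pre(small_dataset):
    return preprocess_dataset(small_dataset.sections, patch_size=32, n_main_genes=5)


class TestPipeline:
    def test_patch_count_bounded_by_retained_spots(self, pre):
        assert len(pre.patches) == len(pre.bundle)
        assert len(pre.patches) <= sum(
            [40, 40]
        )  # two sections x 40 spots

    def test_every_retained_spot_passes_spot_filter(self, pre):
        assert (pre.bundle.count.sum(axis=1) >= 1000).all()

    def test_main_and_aux_partition_gene_set(self, pre):
        assert set(pre.selection.main_genes) | set(pre.selection.aux_genes) == set(
            pre.bundle.gene_ids
        )
        assert not set(pre.selection.main_genes) & set(pre.selection.aux_genes)

    def test_log_counts_parallel_to_bundle(self, pre):
        assert len(pre.log_counts) == len(pre.bundle)
        assert np.allclose(
            pre.log_counts.to_numpy(),
            np.log1p(pre.bundle.count.astype(float)),
        )
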