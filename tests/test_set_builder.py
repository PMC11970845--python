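"""Set construction: one-positive composition, group hygiene, augmentation,
fold splitting and crop preprocessing."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from picaso import (InstanceRecord, augment_instance, build_binary_sets,
                    build_one_positive_sets, group_kfold_split, materialize,
                    preprocess_crop)


def vector_pool(n_groups=6, neg_per_group=10, pos_per_group=2, d=4, seed=0):
    rng = np.random.default_rng(seed)
    pool = []
    for g in range(n_groups):
        for i in range(neg_per_group):
            pool.append(InstanceRecord(f"g{g}n{i}", f"grp{g}", 0,
                                       vector=rng.standard_normal(d)))
        for i in range(pos_per_group):
            pool.append(InstanceRecord(f"g{g}p{i}", f"grp{g}", 1,
                                       vector=rng.standard_normal(d)))
    return pool


class TestOnePositiveSets:
    def test_exactly_one_positive_and_size_in_range(self):
        sets = build_one_positive_sets(vector_pool(), 200, seed=0)
        for b in sets:
            assert b.target.sum() == 1.0
            assert 4 <= b.size <= 8
            assert len(b.target) == b.size

    def test_seeded_determinism(self):
        a = build_one_positive_sets(vector_pool(), 50, seed=3)
        b = build_one_positive_sets(vector_pool(), 50, seed=3)
        assert [[m.instance_id for m in s.members] for s in a] == \
               [[m.instance_id for m in s.members] for s in b]

    def test_augmented_copies_fill_short_groups(self):
        # 3 negatives in the group; any draw of m > 3 must augment
        rng = np.random.default_rng(1)
        pool = [InstanceRecord(f"n{i}", "g", 0, image=rng.random((8, 8)))
                for i in range(3)]
        pool.append(InstanceRecord("p", "g", 1, image=rng.random((8, 8))))
        sets = build_one_positive_sets(pool, 40, seed=1)
        big = [s for s in sets if s.size > 4]
        assert big, "some draws should exceed the distinct-negative count"
        for s in big:
            n_aug = sum(m.augmented for m in s.members)
            assert n_aug == s.size - 4
        # augmented members are flagged and resolvable
        data, target = materialize(big[0], {r.instance_id: r for r in pool})
        assert len(data) == big[0].size

    def test_same_group_negatives_by_default(self):
        pool = vector_pool()
        by_id = {r.instance_id: r for r in pool}
        for b in build_one_positive_sets(pool, 100, seed=2):
            assert {by_id[m.instance_id].group_id for m in b.members} == \
                   {b.group_id}

    def test_set_size_histogram_is_uniform(self):
        """Total sizes 4..8 occur ~uniformly over many draws (chi^2)."""
        sets = build_one_positive_sets(vector_pool(), 10_000, seed=4)
        counts = np.bincount([s.size for s in sets], minlength=9)[4:9]
        assert chisquare(counts).pvalue > 1e-3

    def test_no_positives_rejected(self):
        pool = [r for r in vector_pool() if r.label == 0]
        with pytest.raises(ValueError):
            build_one_positive_sets(pool, 5, seed=0)


class TestBinarySets:
    def pool(self):
        rng = np.random.default_rng(5)
        pool = []
        for g in range(8):
            label = g % 2
            for i in range(rng.integers(5, 12)):
                pool.append(InstanceRecord(f"g{g}i{i}", f"case{g}", label,
                                           vector=rng.standard_normal(4)))
        return pool

    def test_size_range_and_single_group(self):
        sets = build_binary_sets(self.pool(), 100, seed=0)
        by_id = {r.instance_id: r for r in self.pool()}
        for b in sets:
            assert 4 <= b.size <= 8
            gids = {by_id[m.instance_id].group_id for m in b.members}
            assert gids == {b.group_id}
            assert b.target in (0.0, 1.0)

    def test_label_inherited_from_case(self):
        by_id = {r.instance_id: r for r in self.pool()}
        for b in build_binary_sets(self.pool(), 50, seed=1):
            assert b.target == by_id[b.members[0].instance_id].label

    def test_seeded_determinism(self):
        a = build_binary_sets(self.pool(), 30, seed=9)
        b = build_binary_sets(self.pool(), 30, seed=9)
        assert [[m.instance_id for m in s.members] for s in a] == \
               [[m.instance_id for m in s.members] for s in b]


class TestAugmentation:
    def test_output_dims_equal_input_dims(self):
        img = np.random.default_rng(0).random((40, 30, 3)).astype(np.float32)
        out = augment_instance(img, seed=1)
        assert out.shape == img.shape

    def test_seeded_determinism(self):
        img = np.random.default_rng(1).random((32, 32)).astype(np.float32)
        np.testing.assert_array_equal(augment_instance(img, seed=5),
                                      augment_instance(img, seed=5))

    def test_nondegenerate_draw_changes_pixels(self):
        img = np.zeros((32, 32), dtype=np.float32)
        img[8:24, 8:24] = 1.0
        out = augment_instance(img, seed=2)
        assert np.any(out != img)


class TestGroupKFold:
    def records(self, n_groups=10, per_group=4):
        return [InstanceRecord(f"g{g}i{i}", f"grp{g}", 0, vector=np.zeros(2))
                for g in range(n_groups) for i in range(per_group)]

    def test_no_group_straddles_a_fold(self):
        recs = self.records()
        for tr, va in group_kfold_split(recs, k=5, seed=0):
            tr_groups = {recs[i].group_id for i in tr}
            va_groups = {recs[i].group_id for i in va}
            assert tr_groups & va_groups == set()

    def test_every_group_validated_exactly_once(self):
        recs = self.records()
        seen = []
        for _, va in group_kfold_split(recs, k=5, seed=0):
            seen.extend({recs[i].group_id for i in va})
        assert sorted(seen) == sorted({r.group_id for r in recs})

    def test_ten_equal_groups_give_two_per_validation_fold(self):
        recs = self.records(n_groups=10, per_group=3)
        for _, va in group_kfold_split(recs, k=5, seed=1):
            assert len({recs[i].group_id for i in va}) == 2
            assert len(va) == 6

    def test_fewer_groups_than_k_rejected(self):
        with pytest.raises(ValueError):
            group_kfold_split(self.records(n_groups=3), k=5)

    def test_fraction_roughly_80_20(self):
        recs = self.records(n_groups=10, per_group=5)
        for tr, va in group_kfold_split(recs, k=5, seed=2):
            assert len(tr) / len(recs) == pytest.approx(0.8)


class TestPreprocessCrop:
    def test_rectangular_input_padded_then_resized_no_stretch(self):
        """A 100x60 foreground keeps its 5:3 aspect ratio inside 256x256."""
        img = np.ones((100, 60), dtype=np.float32)
        out = preprocess_crop(img, np.ones_like(img))
        assert out.shape == (256, 256)
        rows = np.where(out.max(axis=1) > 0.5)[0]
        cols = np.where(out.max(axis=0) > 0.5)[0]
        h = rows[-1] - rows[0] + 1
        w = cols[-1] - cols[0] + 1
        assert h / w == pytest.approx(100 / 60, rel=0.05)

    def test_all_ones_mask_is_pad_and_resize_only(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64)).astype(np.float32)
        out = preprocess_crop(img, np.ones_like(img))
        assert out.shape == (256, 256)
        # nothing got masked away
        assert out.mean() == pytest.approx(img.mean(), rel=0.05)

    def test_all_zeros_mask_blanks_everything(self):
        img = np.random.default_rng(1).random((50, 70)).astype(np.float32)
        out = preprocess_crop(img, np.zeros_like(img))
        assert np.all(out == 0)

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preprocess_crop(np.zeros((10, 10)), np.zeros((9, 10)))

    def test_color_images_supported(self):
        img = np.random.default_rng(2).random((30, 40, 3)).astype(np.float32)
        out = preprocess_crop(img, np.ones((30, 40)))
        assert out.shape == (256, 256, 3)
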