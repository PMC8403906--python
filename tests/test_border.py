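"""Border voxel detection, pair similarities, ROC/AUC and permutation test."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import hippoparc as hp
from hippoparc.border import (
    BorderError,
    BorderRoc,
    BorderSet,
    find_border,
    pair_similarities,
    rank_auc,
)


def slab_labels(nx=4, ny=8, nz=4, split=4):
    """Two parcels abutting on a plane at j == split."""
    ijk = np.array([(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)])
    labels = np.where(ijk[:, 1] < split, 1, 2)
    return ijk, labels


class TestFindBorder:
    def test_abutting_slabs_radius_2(self):
        ijk, labels = slab_labels()
        border = find_border(labels, ijk, radius=2)
        # hand rule: the two voxel layers either side of the plane qualify
        j = ijk[border.indices, 1]
        assert set(j.tolist()) == {2, 3, 4, 5}
        assert border.n_voxels == 4 * 4 * 4  # 4 layers of 4x4

    def test_radius_zero_raises_empty_border(self):
        ijk, labels = slab_labels()
        with pytest.raises(BorderError, match="no border voxels"):
            find_border(labels, ijk, radius=0)

    def test_matches_brute_force_chebyshev_scan(self, rng):
        ijk = np.array([(i, j, k) for i in range(6) for j in range(6) for k in range(6)])
        labels = rng.choice([1, 2], size=len(ijk))
        border = find_border(labels, ijk, radius=2)
        expected = set()
        for a in range(len(ijk)):
            for b in range(len(ijk)):
                if labels[a] != labels[b]:
                    if np.max(np.abs(ijk[a] - ijk[b])) <= 2:
                        expected.add(a)
                        break
        assert set(border.indices.tolist()) == expected

    def test_needs_exactly_two_parcels(self):
        ijk, labels = slab_labels()
        with pytest.raises(ValueError, match="two parcels"):
            find_border(np.ones_like(labels), ijk, radius=2)


class TestPairSimilarities:
    def test_identities_and_counts(self):
        profiles = np.vstack([
            [1.0, 2.0, 3.0, 1.0],
            [1.0, 2.0, 3.0, 1.0],    # identical -> similarity 1
            [-1.0, -2.0, -3.0, -1.0],  # negation -> similarity -1
            [0.5, 0.1, 0.9, 0.2],
            [0.3, 0.8, 0.2, 0.9],
        ])
        border = BorderSet(indices=np.arange(5), labels=np.array([1, 1, 2, 2, 2]),
                           radius_voxels=2)
        pairs = pair_similarities(profiles, border)
        assert len(pairs) == 10  # C(5,2)
        sim01 = pairs.query("i == 0 and j == 1")["similarity"].iloc[0]
        sim02 = pairs.query("i == 0 and j == 2")["similarity"].iloc[0]
        assert sim01 == pytest.approx(1.0)
        assert sim02 == pytest.approx(-1.0)
        assert pairs.query("i == 0 and j == 1")["same_parcel"].iloc[0]
        assert not pairs.query("i == 0 and j == 2")["same_parcel"].iloc[0]

    def test_constant_profile_dropped_with_warning(self):
        profiles = np.vstack([
            np.ones(4),  # constant: undefined correlation
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [0.1, 0.5, 0.2, 0.9],
            [0.7, 0.2, 0.9, 0.1],
        ])
        border = BorderSet(indices=np.arange(5), labels=np.array([1, 1, 1, 2, 2]),
                           radius_voxels=2)
        with pytest.warns(UserWarning, match="constant"):
            pairs = pair_similarities(profiles, border)
        assert len(pairs) == 6  # C(4,2) after dropping the constant voxel
        assert 0 not in set(pairs["i"]) | set(pairs["j"])


class TestAuc:
    def test_toy_set_equals_concordant_pair_count(self):
        sims = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.1])
        same = np.array([True, True, False, True, False, False])
        concordant = 0.0
        pos, neg = sims[same], sims[~same]
        for p in pos:
            for q in neg:
                concordant += 1.0 if p > q else (0.5 if p == q else 0.0)
        expected = concordant / (len(pos) * len(neg))
        assert rank_auc(sims, same) == pytest.approx(expected)
        assert rank_auc(sims, same) == pytest.approx(roc_auc_score(same, sims))

    def test_agrees_with_sklearn_under_ties(self, rng):
        sims = rng.choice([0.1, 0.2, 0.3, 0.4], size=100)
        same = rng.uniform(size=100) > 0.5
        assert rank_auc(sims, same) == pytest.approx(roc_auc_score(same, sims))

    def test_perfect_separation(self):
        sims = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        same = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        assert rank_auc(sims, same) == 1.0

    def test_null_labels_centre_on_half(self, rng):
        """Labels independent of similarity: mean AUC within a 3-sigma MC band."""
        aucs = []
        sims = rng.normal(size=80)
        for _ in range(200):
            same = rng.uniform(size=80) > 0.5
            if same.all() or not same.any():
                continue
            aucs.append(rank_auc(sims, same))
        aucs = np.array(aucs)
        band = 3 * aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < band + 0.01


class TestBorderRoc:
    def _pairs(self, rng, n_vox=12, n_feat=30, signal=0.0):
        labels = np.r_[np.ones(n_vox // 2, int), np.full(n_vox - n_vox // 2, 2)]
        base = rng.normal(size=(2, n_feat))
        profiles = rng.normal(size=(n_vox, n_feat)) + signal * base[labels - 1]
        border = BorderSet(indices=np.arange(n_vox), labels=labels, radius_voxels=2)
        return pair_similarities(profiles, border), labels

    def test_auc_equals_trapezoid_of_stored_curve(self, rng):
        pairs, labels = self._pairs(rng, signal=1.0)
        res = BorderRoc(pairs, voxel_labels=labels).fit(n_permutations=0)
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr))
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)

    def test_permutation_p_deterministic_and_bounded(self, rng):
        pairs, labels = self._pairs(rng, signal=3.0)
        model = BorderRoc(pairs, voxel_labels=labels)
        a = model.fit(n_permutations=199, seed=42)
        b = model.fit(n_permutations=199, seed=42)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 200  # formula lower bound
        c = model.fit(n_permutations=199, seed=43)
        assert c.p_value >= 1 / 200

    def test_strong_signal_gives_small_p(self, rng):
        pairs, labels = self._pairs(rng, n_vox=16, signal=5.0)
        res = BorderRoc(pairs, voxel_labels=labels).fit(n_permutations=199, seed=0)
        assert res.auc > 0.9
        assert res.p_value <= 0.01

    def test_one_class_input_rejected(self, rng):
        pairs, labels = self._pairs(rng)
        same_only = pairs[pairs["same_parcel"]]
        with pytest.raises(ValueError, match="both"):
            BorderRoc(same_only, voxel_labels=labels)

    def test_pair_level_shuffle_is_anticonservative_on_dependent_data(self):
        """Pair similarities share voxels, so they are not exchangeable.

        Null construction: unbalanced parcels (3 vs 9 border voxels) and a
        per-voxel 'quality' factor that makes every pair touching a
        high-loading voxel more similar. Labels carry no information, yet
        pair-level shuffling rejects far above its nominal level while the
        voxel-level scheme stays calibrated.
        """
        alpha = 0.05
        n_sets = 150
        rej_voxel = rej_pair = 0
        for seed in range(n_sets):
            rng = np.random.default_rng(seed)
            labels = np.r_[np.ones(3, int), np.full(9, 2)]
            quality = rng.uniform(0, 2, size=12)
            profiles = (quality[:, None] * rng.normal(size=15)
                        + rng.normal(size=(12, 15)))
            border = BorderSet(indices=np.arange(12), labels=labels,
                               radius_voxels=2)
            model = BorderRoc(pair_similarities(profiles, border),
                              voxel_labels=labels)
            rej_voxel += model.fit(99, seed=seed).p_value <= alpha
            rej_pair += model.fit(99, seed=seed, scheme="pair").p_value <= alpha
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_sets)
        assert rej_pair / n_sets > alpha + band       # wrong baseline over-rejects
        assert rej_voxel / n_sets <= alpha + band     # correct scheme calibrated
        assert rej_pair > rej_voxel
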