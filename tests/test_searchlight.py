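"""Searchlight geometry, trial correlation matrices and kNN voting."""

import numpy as np
import pytest

from hyperclass.data_model import ACTIONS, DesignError
from hyperclass.searchlight import (
    TrialCorrelationMatrix, knn_classify, make_searchlight,
    searchlight_accuracy_contrast, trial_correlation_matrix,
)
from hyperclass.synth import pair_samples


class TestMakeSearchlight:
    @pytest.mark.parametrize("radius,voxel,expected", [
        (6.0, 4.0, 19),   # the canonical 19-voxel searchlight
        (0.0, 4.0, 1),
        (4.0, 4.0, 7),    # centre + 6 faces
    ])
    def test_offset_counts(self, radius, voxel, expected):
        sl = make_searchlight(radius, voxel)
        assert sl.n_voxels == expected

    def test_contains_origin_and_respects_radius(self):
        sl = make_searchlight(6.0, 4.0)
        offs = {tuple(o) for o in sl.offsets}
        assert (0, 0, 0) in offs
        norms = np.linalg.norm(sl.offsets * 4.0, axis=1)
        assert np.all(norms <= 6.0 + 1e-9)

    def test_symmetric_under_axis_permutation_and_sign_flip(self):
        sl = make_searchlight(6.0, 4.0)
        offs = {tuple(o) for o in sl.offsets}
        assert offs == {(-a, -b, -c) for a, b, c in offs}
        assert offs == {(b, c, a) for a, b, c in offs}

    def test_negative_radius_rejected(self):
        with pytest.raises(DesignError):
            make_searchlight(-1.0, 4.0)


class TestTrialCorrelationMatrix:
    def test_canonical_design_gives_120_by_120(self, small_samples):
        a, o = small_samples
        sl = make_searchlight(6.0, 4.0)
        m = trial_correlation_matrix(a, o, sl, (2, 2, 2))
        assert m.c.shape == (120, 120)
        assert not m.partial
        assert sl.n_voxels * 3 == 57  # data points per trial pattern

    def test_observer_copy_puts_ones_on_the_diagonal(self, small_samples):
        a, _ = small_samples
        sl = make_searchlight(6.0, 4.0)
        m = trial_correlation_matrix(a, a, sl, (2, 2, 2))
        assert np.allclose(np.diag(m.c), 1.0)

    def test_edge_searchlight_flagged_partial(self, small_samples):
        a, o = small_samples
        sl = make_searchlight(6.0, 4.0)
        m = trial_correlation_matrix(a, o, sl, (0, 0, 0))
        assert m.partial

    def test_entries_bounded(self, small_samples):
        a, o = small_samples
        m = trial_correlation_matrix(a, o, make_searchlight(4.0, 4.0), (2, 2, 2))
        assert np.all(np.abs(m.c) <= 1.0)


def _block_matrix(within=0.9, between=0.0, per_class=30, jitter=0.0, seed=0):
    """Trials grouped by class; within-class correlations dominate."""
    labels = np.repeat(ACTIONS, per_class).astype(object)
    n = len(labels)
    c = np.full((n, n), between)
    for k in range(4):
        sl = slice(k * per_class, (k + 1) * per_class)
        c[sl, sl] = within
    if jitter:
        c = c + np.random.default_rng(seed).uniform(-jitter, jitter, (n, n))
    return TrialCorrelationMatrix(np.clip(c, -1, 1), labels, labels.copy())


class TestKnnClassify:
    def test_block_structure_decodes_perfectly_up_to_class_size(self):
        m = _block_matrix()
        assert knn_classify(m, k_values=tuple(range(1, 31, 6))) == 100.0

    def test_label_shuffled_matrix_sits_near_chance(self):
        # single permutations are noisy (votes stay block-structured), so
        # average the accuracy over independent label shuffles
        base = _block_matrix(jitter=0.01)
        accs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            m = TrialCorrelationMatrix(
                base.c, base.actor_labels[rng.permutation(120)],
                base.observer_labels,
            )
            accs.append(knn_classify(m))
        assert abs(np.mean(accs) - 25.0) < 6.0

    def test_full_vote_degenerates_to_nearest_neighbour_tiebreak(self):
        m = _block_matrix(jitter=0.01, seed=2)
        # k = 120 over balanced classes: every class ties at 30 votes, so the
        # winner is the class of the single most correlated trial
        acc_full = knn_classify(m, k_values=(120,))
        acc_nn = knn_classify(m, k_values=(1,))
        assert acc_full == acc_nn

    def test_invariant_to_monotone_transform_of_correlations(self):
        m = _block_matrix(within=0.5, between=-0.2, jitter=0.3, seed=3)
        m2 = TrialCorrelationMatrix(np.tanh(3.0 * m.c), m.actor_labels,
                                    m.observer_labels)
        assert knn_classify(m) == knn_classify(m2)

    def test_oversized_k_clamped_with_warning(self):
        m = _block_matrix()
        with pytest.warns(UserWarning, match="clamped"):
            acc = knn_classify(m, k_values=(500,))
        assert 0.0 <= acc <= 100.0


class TestAccuracyContrast:
    def test_identical_maps_give_empty_mask(self):
        rng = np.random.default_rng(4)
        maps = rng.uniform(20, 30, (6, 50))
        out = searchlight_accuracy_contrast(maps, maps.copy(), n_perm=200)
        assert not out.significant.any()

    def test_planted_gain_region_flagged(self):
        rng = np.random.default_rng(5)
        n_sl = 80
        pre = rng.normal(25, 2, (8, n_sl))
        gain = np.zeros(n_sl)
        gain[10:30] = 20.0
        post = pre + gain + rng.normal(0, 2, (8, n_sl))
        out = searchlight_accuracy_contrast(pre, post, n_perm=500, seed=1)
        assert out.display_mask[10:30].mean() > 0.9
        assert out.display_mask[30:].sum() + out.display_mask[:10].sum() == 0

    def test_sign_flip_null_controls_false_positives(self):
        rng = np.random.default_rng(6)
        n_reject = []
        for rep in range(20):
            pre = rng.normal(25, 3, (8, 100))
            post = rng.normal(25, 3, (8, 100))
            out = searchlight_accuracy_contrast(pre, post, n_perm=300, seed=rep)
            n_reject.append(out.significant.sum())
        # under the global null, BH rejects anything at all in <= q of sims;
        # allow generous binomial slack over 20 repetitions
        assert sum(n > 0 for n in n_reject) <= 4

    def test_single_pair_rejected(self):
        with pytest.raises(DesignError):
            searchlight_accuracy_contrast(np.ones((1, 5)), np.ones((1, 5)))
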