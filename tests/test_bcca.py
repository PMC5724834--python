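"""Two-view Bayesian CCA: component recovery, ARD pruning, realignment."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from hyperclass.bcca import (
    ARD_REL_TOL, BccaError, fit_bcca, load_bcca, realign, realignment_transform,
    save_bcca,
)

from conftest import make_sampleset


def _coupled_views(n=500, d=60, k_true=3, noise_sd=1.0, seed=0,
                   n_obs_specific=0):
    """Two views driven by k_true common latents (per-component SNR 1)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k_true))
    wa = rng.standard_normal((d, k_true))
    wo = rng.standard_normal((d, k_true))
    xa = z @ wa.T + noise_sd * rng.standard_normal((n, d))
    xo = z @ wo.T + noise_sd * rng.standard_normal((n, d))
    if n_obs_specific:
        zs = rng.standard_normal((n, n_obs_specific))
        ws = 2.0 * rng.standard_normal((d, n_obs_specific))
        xo = xo + zs @ ws.T
    return xa, xo, z, wa, wo


class TestSharedComponentRecovery:
    def test_three_common_latents_recovered_from_k10(self):
        xa, xo, _, wa, _ = _coupled_views(seed=0)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=10, seed=1)
        assert m.n_shared == 3
        # compare in the model's (standardized) space
        wa_std = wa / m.std_["actor"][:, None]
        angles = np.degrees(
            subspace_angles(m.W_actor[:, m.shared_components], wa_std)
        )
        assert angles.max() < 10.0

    def test_independent_noise_gives_zero_shared(self):
        rng = np.random.default_rng(5)
        m = fit_bcca(
            make_sampleset(rng.standard_normal((400, 60))),
            make_sampleset(rng.standard_normal((400, 60))),
            K=10, seed=2,
        )
        assert m.n_shared == 0

    def test_noiseless_data_reconstructed_exactly(self):
        xa, xo, z, _, _ = _coupled_views(noise_sd=1e-4, seed=3)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=3, seed=3)
        recon = m.z_stats["mean"] @ m.W_actor.T
        target = m.standardize_actor(xa)
        err = np.linalg.norm(recon - target) / np.linalg.norm(target)
        assert err < 1e-2

    def test_ard_prunes_excess_components_in_low_noise(self):
        xa, xo, _, _, _ = _coupled_views(noise_sd=0.01, n=400, seed=4)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=10, seed=4)
        assert m.n_shared == 3
        for view in range(2):
            rel = np.sort(m.relevance[view])[::-1]
            assert np.all(rel[3:] < ARD_REL_TOL * rel[0])

    def test_observer_only_component_does_not_change_shared_structure(self):
        xa, xo_plain, _, _, _ = _coupled_views(seed=6)
        _, xo_boosted, _, _, _ = _coupled_views(seed=6, n_obs_specific=1)
        m1 = fit_bcca(make_sampleset(xa), make_sampleset(xo_plain), K=8, seed=6)
        m2 = fit_bcca(make_sampleset(xa), make_sampleset(xo_boosted), K=8, seed=6)
        assert m1.n_shared == m2.n_shared
        test = make_sampleset(np.random.default_rng(7).standard_normal((50, 60)))
        r1, r2 = realign(m1, test).x, realign(m2, test).x
        corr = np.corrcoef(r1.ravel(), r2.ravel())[0, 1]
        assert corr > 0.9


class TestFitContract:
    def test_k_exceeding_samples_rejected(self):
        xa, xo, *_ = _coupled_views(n=20)
        with pytest.raises(BccaError, match="exceeds sample count"):
            fit_bcca(make_sampleset(xa), make_sampleset(xo), K=30)

    def test_unpaired_views_rejected(self):
        xa, xo, *_ = _coupled_views(n=50)
        with pytest.raises(BccaError, match="not paired"):
            fit_bcca(make_sampleset(xa), make_sampleset(xo[:40]), K=5)

    def test_seed_determinism(self):
        xa, xo, *_ = _coupled_views(n=200)
        m1 = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=6, seed=9)
        m2 = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=6, seed=9)
        assert np.array_equal(m1.W_actor, m2.W_actor)
        assert np.array_equal(m1.W_observer, m2.W_observer)
        assert m1.elbo == m2.elbo

    def test_serialization_round_trip(self, tmp_path):
        xa, xo, *_ = _coupled_views(n=200)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=6, seed=9)
        save_bcca(m, tmp_path / "model")
        m2 = load_bcca(tmp_path / "model")
        assert np.array_equal(m.W_actor, m2.W_actor)
        assert list(m.component_type) == list(m2.component_type)
        test = make_sampleset(np.zeros((4, 60)))
        assert np.array_equal(realign(m, test).x, realign(m2, test).x)


class TestRealign:
    @pytest.fixture(scope="class")
    @staticmethod
    def model_on_standardized_data():
        xa, xo, *_ = _coupled_views(n=400, seed=10)
        xa = (xa - xa.mean(0)) / xa.std(0)
        xo = (xo - xo.mean(0)) / xo.std(0)
        return fit_bcca(make_sampleset(xa), make_sampleset(xo), K=6, seed=10)

    def test_zero_input_maps_to_zero(self, model_on_standardized_data):
        out = realign(model_on_standardized_data, make_sampleset(np.zeros((5, 60))))
        assert np.allclose(out.x, 0.0, atol=1e-8)

    def test_linearity(self, model_on_standardized_data):
        rng = np.random.default_rng(11)
        x = make_sampleset(rng.standard_normal((20, 60)))
        y = make_sampleset(rng.standard_normal((20, 60)))
        combo = make_sampleset(2.0 * x.x - 0.5 * y.x)
        lhs = realign(model_on_standardized_data, combo).x
        rhs = (2.0 * realign(model_on_standardized_data, x).x
               - 0.5 * realign(model_on_standardized_data, y).x)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_realigned_data_track_true_actor_signal(self):
        n, d = 360, 60
        rng = np.random.default_rng(12)
        z = rng.standard_normal((n, 3))
        wa = rng.standard_normal((d, 3))
        wo = rng.standard_normal((d, 3))
        signal_a = z @ wa.T
        xa = signal_a + rng.standard_normal((n, d))
        xo = z @ wo.T + rng.standard_normal((n, d))
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=10, seed=12)
        out = realign(m, make_sampleset(xo))
        corr = np.array([
            np.corrcoef(out.x[:, j], signal_a[:, j])[0, 1] for j in range(d)
        ])
        assert corr.mean() > 0.8

    def test_transform_rank_bounded_by_shared_count(self):
        xa, xo, *_ = _coupled_views(n=300, seed=13)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=8, seed=13)
        t = realignment_transform(m)
        assert np.linalg.matrix_rank(t.map) <= t.n_shared

    def test_zero_shared_components_warn_and_return_zeros(self):
        rng = np.random.default_rng(14)
        m = fit_bcca(
            make_sampleset(rng.standard_normal((300, 40))),
            make_sampleset(rng.standard_normal((300, 40))),
            K=5, seed=14,
        )
        assert m.n_shared == 0
        with pytest.warns(UserWarning, match="zero shared"):
            out = realign(m, make_sampleset(rng.standard_normal((10, 40))))
        assert np.all(out.x == 0.0)

    def test_voxel_mismatch_rejected(self):
        xa, xo, *_ = _coupled_views(n=100)
        m = fit_bcca(make_sampleset(xa), make_sampleset(xo), K=5, seed=0)
        with pytest.raises(BccaError, match="voxel count"):
            realign(m, make_sampleset(np.zeros((5, 10))))
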