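"""Equivariance, gradients and contracts of the GVP denoiser."""

import numpy as np
import pytest

from tmcdiff.config import Config
from tmcdiff.diffusion import forward_diffuse
from tmcdiff.embedding import build_embedding
from tmcdiff.gvp import DenoiserGVP, GVPFeatures
from tmcdiff.schedule import make_schedule

from conftest import random_rotation


@pytest.fixture()
def noised_embedding(hexa_mono, small_config):
    emb = build_embedding(hexa_mono, [0, 1], config=small_config)
    sched = make_schedule(small_config.steps)
    rng = np.random.default_rng(5)
    noised, targets = forward_diffuse(emb, 20, rng, sched)
    return noised, targets, sched


class TestFeaturize:
    def test_scalars_ignore_coordinates(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        f1 = small_model.featurize(emb, 20)
        rot = emb.copy()
        rot.r = emb.r @ random_rotation(1).T
        f2 = small_model.featurize(rot, 20)
        assert np.array_equal(f1.s, f2.s)      # bit-identical scalars

    def test_identically_coded_mirror_atoms_share_scalars(self, small_model, small_config):
        from tmcdiff.complexes import TMComplex, partition_ligands

        cx = TMComplex(elements=["Fe", "O", "O"],
                       coords=[[0, 0, 0], [2, 0, 0], [-2, 0, 0]])
        partition_ligands(cx)
        emb = build_embedding(cx, [0, 1], config=small_config)
        f = small_model.featurize(emb, 3)
        # the two aqua-like atoms carry different ligand codes; compare the
        # code-independent channels (atom type + time + mask)
        m = emb.h_a.shape[1]
        np.testing.assert_array_equal(f.s[1, :m], f.s[2, :m])

    def test_vectors_rotate_with_input(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        R = random_rotation(2)
        f1 = small_model.featurize(emb, 20)
        rot = emb.copy()
        rot.r = emb.r @ R.T
        f2 = small_model.featurize(rot, 20)
        np.testing.assert_allclose(f2.V, f1.V @ R.T, rtol=0, atol=1e-12)


class TestMessagePass:
    def test_atom_permutation_permutes_outputs(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        feats = small_model.featurize(emb, 20)
        out = small_model.message_pass(feats, emb.r)
        rng = np.random.default_rng(0)
        perm = rng.permutation(emb.n_atoms)
        fp = GVPFeatures(s=feats.s[perm], V=feats.V[perm])
        outp = small_model.message_pass(fp, emb.r[perm])
        np.testing.assert_allclose(outp.s, out.s[perm], atol=1e-10)
        np.testing.assert_allclose(outp.V, out.V[perm], atol=1e-10)

    def test_rotation_invariant_scalars_equivariant_vectors(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        feats = small_model.featurize(emb, 20)
        out = small_model.message_pass(feats, emb.r)
        R = random_rotation(3)
        fr = GVPFeatures(s=feats.s.copy(), V=feats.V @ R.T)
        outr = small_model.message_pass(fr, emb.r @ R.T)
        np.testing.assert_allclose(outr.s, out.s, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(outr.V, out.V @ R.T, rtol=1e-5, atol=1e-10)

    def test_zero_weights_are_residual_identity(self, small_config, noised_embedding):
        emb, _, _ = noised_embedding
        model = DenoiserGVP(small_config, seed=1)
        feats = model.featurize(emb, 20)
        s_in = model.embed_s.forward(feats.s)
        V_in = np.swapaxes(model.embed_v.forward(np.swapaxes(feats.V, -1, -2)), -1, -2)
        for lay in model.layers:
            for gvp in lay.modules():
                for k in gvp.params:
                    gvp.params[k][...] = 0.0
        out = model.message_pass(feats, emb.r)
        np.testing.assert_array_equal(out.s, s_in)
        np.testing.assert_array_equal(out.V, V_in)

    def test_single_atom_raises(self, small_model):
        feats = GVPFeatures(s=np.zeros((1, 5)), V=np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="neighbour"):
            small_model.message_pass(feats, np.zeros((1, 3)))


class TestPredictNoise:
    def test_output_shapes(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        eps_r, eps_h = small_model.predict_noise(emb, 20)
        k = emb.masked_indices.size
        assert eps_r.shape == (k, 3)
        assert eps_h.shape == (k, small_model.m)

    def test_deterministic_for_fixed_weights(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        a = small_model.predict_noise(emb, 20)
        b = small_model.predict_noise(emb, 20)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_eps_r_rotates_eps_h_does_not(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        eps_r, eps_h = small_model.predict_noise(emb, 20)
        R = random_rotation(4)
        rot = emb.copy()
        rot.r = emb.r @ R.T
        eps_r2, eps_h2 = small_model.predict_noise(rot, 20)
        np.testing.assert_allclose(eps_r2, eps_r @ R.T, rtol=1e-5, atol=1e-12)
        np.testing.assert_allclose(eps_h2, eps_h, rtol=1e-5, atol=1e-12)

    def test_reflection_equivariance(self, small_model, noised_embedding):
        emb, _, _ = noised_embedding
        M = np.diag([1.0, -1.0, 1.0])     # improper transformation
        eps_r, eps_h = small_model.predict_noise(emb, 20)
        rot = emb.copy()
        rot.r = emb.r @ M.T
        eps_r2, eps_h2 = small_model.predict_noise(rot, 20)
        np.testing.assert_allclose(eps_r2, eps_r @ M.T, rtol=1e-5, atol=1e-12)
        np.testing.assert_allclose(eps_h2, eps_h, rtol=1e-5, atol=1e-12)

    def test_context_ordering_irrelevance_via_mean_aggregation(
        self, small_model, noised_embedding
    ):
        # permuting only context atoms must not change masked-atom outputs
        emb, _, _ = noised_embedding
        eps_r, eps_h = small_model.predict_noise(emb, 20)
        ctx = emb.context_indices
        perm = np.arange(emb.n_atoms)
        perm[ctx] = ctx[::-1]
        rot = emb.copy()
        for arr in ("r", "h_a", "h_L", "h_c"):
            setattr(rot, arr, getattr(emb, arr)[perm])
        rot.masked_flags = emb.masked_flags[perm]
        eps_r2, eps_h2 = small_model.predict_noise(rot, 20)
        np.testing.assert_allclose(eps_r2, eps_r, atol=1e-10)
        np.testing.assert_allclose(eps_h2, eps_h, atol=1e-10)


class TestGradients:
    def test_finite_difference_matches_analytic_on_small_toy(self, small_config):
        """Central finite differences vs backprop on a 5-atom complex."""
        from tmcdiff.complexes import TMComplex, partition_ligands

        cx = TMComplex(
            elements=["Fe", "O", "N", "Cl", "C"],
            coords=[[0, 0, 0], [2, 0, 0], [0, 2, 0], [-2.2, 0, 0], [0, 0, 2]],
        )
        partition_ligands(cx)
        cfg = small_config.replace(n_layers=2, scalar_width=8, vector_channels=3)
        model = DenoiserGVP(cfg, seed=3)
        emb = build_embedding(cx, [0, 2], config=cfg)
        sched = make_schedule(cfg.steps)
        rng = np.random.default_rng(1)
        noised, (er, eh) = forward_diffuse(emb, 15, rng, sched)
        model.loss_and_grad(noised, 15, er, eh, T=cfg.steps)
        grads = model.get_grads()
        p0 = model.get_params()
        rngc = np.random.default_rng(9)
        h = 1e-6
        for name, arr in p0.items():
            for _ in range(2):
                idx = tuple(int(rngc.integers(0, s)) for s in arr.shape)
                pp = {k: v.copy() for k, v in p0.items()}
                pp[name][idx] += h
                model.set_params(pp)
                lp = model.loss_and_grad(noised, 15, er, eh, T=cfg.steps)
                pp[name][idx] -= 2 * h
                model.set_params(pp)
                lm = model.loss_and_grad(noised, 15, er, eh, T=cfg.steps)
                fd = (lp - lm) / (2 * h)
                an = grads[name][idx]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd), abs(an)), name
            model.set_params(p0)


class TestCheckpoint:
    def test_save_load_round_trip(self, small_model, noised_embedding, tmp_path):
        emb, _, _ = noised_embedding
        path = tmp_path / "model.npz"
        small_model.save(path, schedule_meta={"kind": "polynomial", "T": 40})
        clone = DenoiserGVP.load(path)
        a = small_model.predict_noise(emb, 20)
        b = clone.predict_noise(emb, 20)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
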