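"""Soft radial shells, encoder blocks, end-to-end forward, baseline, checkpoint."""

import numpy as np
import pytest

from awespec.autodiff import Tensor
from awespec.awe_model import (AoModel, AweModel, ResidualBlock, ShellSet,
                               ao_forward, forward_spectrum, load_checkpoint,
                               pack_descriptor_sets, save_checkpoint,
                               shell_summaries, shell_weights)
from awespec.descriptors import compute_descriptor_set
from awespec.io_formats import Molecule
from awespec.nn import gelu
from awespec.spectral_basis import BasisConfig, build_basis
from awespec.synthetic_data import SyntheticConfig, generate_complex
from awespec.train_eval_uq import PackedDataset, TrainConfig, train_model
from .conftest import random_rotation


class TestShellWeights:
    def test_single_atom_on_shell_gets_weight_near_one(self):
        shells = ShellSet(n_shells=1, cutoff=7.0)
        shells.radii.data = np.array([2.0])
        w = shell_weights(np.array([2.0]), shells)
        assert w[0, 0] == pytest.approx(1.0 / (1.0 + shells.epsilon), abs=1e-12)

    def test_two_atom_example_matches_hand_computation(self):
        # atoms at 2.0 and 3.0 Å, shell r_s = 2.0, b_s = 0.5:
        # unnormalized weights {1, e^-2}; normalized ~{0.8808, 0.1192}
        shells = ShellSet(n_shells=1, init_radii=np.array([2.0]),
                          init_blurs=np.array([0.5]))
        w = shell_weights(np.array([2.0, 3.0]), shells)
        assert w[:, 0] == pytest.approx([0.88080, 0.11920], abs=1e-4)

    def test_all_atoms_far_from_shell_no_nan(self):
        shells = ShellSet(n_shells=1, init_radii=np.array([1.0]),
                          init_blurs=np.array([0.1]))
        w = shell_weights(np.array([6.0, 6.5]), shells)
        assert np.all(np.isfinite(w))
        assert np.all(w >= 0) and np.all(w < 1e-6)

    def test_per_shell_normalization_sums_to_one_in_range(self, rng):
        # the epsilon guard (1e-8) bounds the deficit by eps / w_total, so
        # the 1e-6 normalization bound holds whenever some atom sits within
        # ~3 blur widths of the shell (w_total >= exp(-4.5) ~ 1.1e-2)
        shells = ShellSet(n_shells=4, cutoff=7.0)
        for _ in range(20):
            r = rng.uniform(0.5, 6.9, size=8)
            w = shell_weights(r, shells)
            sums = w.sum(axis=0)
            blurs = np.log1p(np.exp(shells.raw_blurs.data))
            for s in range(4):
                if np.any(np.abs(r - shells.radii.data[s]) < 3 * blurs[s]):
                    assert 1 - 1e-6 < sums[s] <= 1.0

    def test_atoms_beyond_cutoff_get_zero_weight(self):
        shells = ShellSet(n_shells=2, cutoff=7.0)
        w = shell_weights(np.array([3.0, 8.0]), shells)
        assert np.all(w[1] == 0.0)


class TestShellSummaries:
    def test_zero_features_give_zero_summary(self, rng):
        w = rng.random((5, 3))
        assert np.allclose(shell_summaries(np.zeros((5, 4)), w), 0.0)

    def test_single_environment_atom(self, rng):
        x = rng.normal(size=(1, 6))
        w = rng.random((1, 4))
        out = shell_summaries(x, w)
        expected = np.concatenate([w[0, s] * x[0] for s in range(4)])
        assert np.allclose(out, expected)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(5, 7))
        w = rng.random((5, 3))
        out = shell_summaries(x, w)
        oracle = np.zeros(3 * 7)
        for s in range(3):
            for i in range(5):
                oracle[s * 7:(s + 1) * 7] += w[i, s] * x[i]
        assert np.allclose(out, oracle, atol=1e-10)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=(6, 4))
        w = rng.random((6, 2))
        perm = rng.permutation(6)
        assert np.allclose(shell_summaries(x, w),
                           shell_summaries(x[perm], w[perm]), atol=1e-12)


class TestResidualBlock:
    def test_zero_weights_make_identity(self, rng):
        block = ResidualBlock(8, 16, rng)
        block.lin1.weight.data[:] = 0.0
        block.lin2.weight.data[:] = 0.0
        h = Tensor(rng.normal(size=(3, 8)))
        out = block(h, p=0.0, rng=None, training=False)
        assert np.allclose(out.data, h.data, atol=1e-12)

    def test_matches_step_by_step_oracle(self, rng):
        """LN -> linear -> GeLU -> linear -> residual, by independent numpy steps."""
        block = ResidualBlock(6, 12, rng)
        h = rng.normal(size=(2, 6))

        x = h - h.mean(axis=-1, keepdims=True)
        var = (x ** 2).mean(axis=-1, keepdims=True)
        ln = x / np.sqrt(var + 1e-5) * block.norm.gain.data + block.norm.bias.data
        pre = ln @ block.lin1.weight.data + block.lin1.bias.data
        from scipy.special import erf
        act = pre * 0.5 * (1 + erf(pre / np.sqrt(2)))
        oracle = h + act @ block.lin2.weight.data + block.lin2.bias.data

        out = block(Tensor(h), p=0.0, rng=None, training=False)
        assert np.allclose(out.data, oracle, atol=1e-6)

    def test_inference_deterministic(self, rng):
        block = ResidualBlock(5, 10, rng)
        h = Tensor(rng.normal(size=(4, 5)))
        a = block(h, p=0.5, rng=None, training=False).data
        b = block(h, p=0.5, rng=None, training=False).data
        assert np.array_equal(a, b)


def _complex_molecules(n, seed=3):
    cfg = SyntheticConfig(seed=seed)
    return [generate_complex(cfg, i) for i in range(n)]


class TestAweForward:
    @pytest.fixture(scope="class")
    def model(self, default_basis, wacsf_provider):
        return AweModel(wacsf_provider, default_basis,
                        np.random.default_rng(0))

    def test_coefficient_length_matches_basis(self, model):
        mol = _complex_molecules(1)[0]
        spec, coeffs = forward_spectrum(model, mol)
        assert coeffs.values.shape == (model.basis.n_functions,)
        assert spec.intensities.shape == (len(model.basis.grid),)

    def test_environment_permutation_invariance(self, model, rng):
        for mol in _complex_molecules(5):
            ref, _ = forward_spectrum(model, mol)
            env = [i for i in range(mol.n_atoms) if i != mol.absorber_index]
            perm = [mol.absorber_index] + list(rng.permutation(env))
            mol_p = Molecule(tuple(mol.elements[i] for i in perm),
                             mol.coords[perm], 0)
            out, _ = forward_spectrum(model, mol_p)
            assert np.allclose(out.intensities, ref.intensities, atol=1e-6)

    def test_rigid_motion_invariance(self, model, rng):
        for mol in _complex_molecules(5):
            ref, _ = forward_spectrum(model, mol)
            rot = random_rotation(rng)
            moved = Molecule(mol.elements, mol.coords @ rot.T + rng.uniform(-3, 3, 3),
                             mol.absorber_index)
            out, _ = forward_spectrum(model, moved)
            assert np.allclose(out.intensities, ref.intensities, atol=1e-6)

    def test_single_atom_molecule_uses_zero_environment(self, model):
        mol = Molecule(("Fe",), np.zeros((1, 3)))
        spec, coeffs = forward_spectrum(model, mol)
        assert np.all(np.isfinite(spec.intensities))

    def test_forward_matches_numpy_op_composition(self, model, wacsf_provider):
        """The batched tape forward agrees with composing the standalone ops."""
        mol = _complex_molecules(1)[0]
        ds = compute_descriptor_set(mol, wacsf_provider)
        x = (ds.X - model.scale_mean) / model.scale_std
        w = shell_weights(ds.r[1:], model.shells)
        summary = shell_summaries(x[1:], w)
        fused = summary @ model.shell_fuse.weight.data + model.shell_fuse.bias.data
        z = np.concatenate([fused, x[0]]) @ model.absorber_fuse.weight.data \
            + model.absorber_fuse.bias.data
        h = Tensor(z[None, :])
        for block in model.blocks:
            h = block(h, p=0.0, rng=None, training=False)
        h_out = model.final_norm(h).data[0]
        c = np.concatenate([h_out @ head.weight.data + head.bias.data
                            for head in model.heads])
        yhat = model.basis.phi @ c

        spec, coeffs = forward_spectrum(model, mol)
        assert np.allclose(coeffs.values, c, atol=1e-10)
        assert np.allclose(spec.intensities, yhat, atol=1e-10)

    def test_distinct_absorbers_give_distinct_latents(self, default_basis,
                                                      wacsf_provider, rng):
        """Two molecules with the same environment but different absorber
        features produce different predictions (generic nonzero heads)."""
        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(4))
        for head in model.heads:
            head.weight.data = rng.normal(size=head.weight.data.shape)
        mol_fe = Molecule(("Fe", "O", "O", "O", "O", "C"),
                          np.array([[0, 0, 0], [2, 0, 0], [-2, 0, 0],
                                    [0, 2, 0], [0, -2, 0], [0, 0, 3.4]], float))
        mol_cu = Molecule(("Cu",) + mol_fe.elements[1:], mol_fe.coords, 0)
        a, _ = forward_spectrum(model, mol_fe)
        b, _ = forward_spectrum(model, mol_cu)
        assert not np.allclose(a.intensities, b.intensities)


class TestShellLearnability:
    def test_shell_radius_moves_toward_informative_distance(self, grid, rng):
        """When only atoms near 4.0 Å carry signal, a 2.0 Å shell drifts out."""
        basis = build_basis(grid, BasisConfig(
            width_groups=(2.0,), placement_stride=10))
        moved = 0
        for seed in range(3):
            srng = np.random.default_rng(seed)
            b, m, d = 64, 6, 4

            class Dummy:
                name, dimension = "dummy", d
            model = AweModel(Dummy(), basis, srng, n_shells=2, dropout_p=0.0)
            model.shells.radii.data = np.array([2.0, 2.0])
            xenv = srng.normal(size=(b, m, d))
            renv = np.concatenate([srng.uniform(3.7, 4.3, size=(b, 3)),
                                   srng.uniform(1.0, 2.0, size=(b, 3))], axis=1)
            signal = xenv[:, :3, :].mean(axis=1) @ srng.normal(size=(d, basis.n_functions))
            batch = {"x0": np.zeros((b, d)), "xenv": xenv, "renv": renv,
                     "mask": np.ones((b, m))}
            data = PackedDataset(batch=batch,
                                 y_raw=signal @ basis.phi.T,
                                 y_target=signal @ basis.phi.T,
                                 c_ref=signal, molecules=[None] * b)
            train_model(model, data, TrainConfig(epochs=60, batch_size=16,
                                                 seed=seed))
            if np.max(model.shells.radii.data) > 2.2:
                moved += 1
        assert moved >= 2


class TestAoModel:
    def test_output_length_matches_grid(self, rng):
        model = AoModel(12, 100, rng)
        assert ao_forward(model, rng.normal(size=12)).shape == (100,)

    def test_zero_input_gives_zero_spectrum(self, rng):
        model = AoModel(8, 50, rng)  # biases are zero-initialized
        assert np.allclose(ao_forward(model, np.zeros(8)), 0.0)

    def test_seeded_params_match_layer_oracle(self, rng):
        from scipy.special import erf

        model = AoModel(4, 10, np.random.default_rng(9))
        x = rng.normal(size=4)

        def g(v):
            return v * 0.5 * (1 + erf(v / np.sqrt(2)))
        h1 = g(x @ model.lin1.weight.data + model.lin1.bias.data)
        h2 = g(h1 @ model.lin2.weight.data + model.lin2.bias.data)
        oracle = h2 @ model.out.weight.data + model.out.bias.data
        assert np.allclose(ao_forward(model, x), oracle, atol=1e-10)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, default_basis,
                                              wacsf_provider):
        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(3))
        model.scale_mean = np.random.default_rng(0).normal(size=model.d)
        mol = _complex_molecules(1)[0]
        ref, _ = forward_spectrum(model, mol)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)

        fresh = AweModel(wacsf_provider, default_basis, np.random.default_rng(99))
        meta = load_checkpoint(fresh, path)
        out, _ = forward_spectrum(fresh, mol)
        assert np.array_equal(out.intensities, ref.intensities)
        assert meta["provider"] == "wacsf"
        assert meta["basis"]["width_groups"] == [0.5, 1.0, 2.0, 4.0]
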