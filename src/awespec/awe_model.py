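"""Absorber-with-environment (AWE) network and the absorber-only baseline.

The AWE model aggregates the descriptors of the N-1 environment atoms into S
learnable soft radial shells centered on the absorbing atom.  Atom i
contributes to shell s with a Gaussian weight in its absorber distance r_i,

    w~_is = exp(-((r_i - r_s)^2) / (2 b_s^2)),   w_is = w~_is / (sum_j w~_js + eps)

so each shell summary m_s = sum_i w_is x_i is a normalized weighted mean of
neighbor features.  Shell radii r_s and blurs b_s are trainable (blurs through
a softplus reparameterization to stay positive).  The concatenated summaries
are fused to width d, concatenated with the absorber descriptor x_0, embedded
to a latent vector z, refined by L pre-layer-normalized residual MLP blocks

    h <- h + W2 gelu(W1 LN(h))        (dropout after the nonlinearity)

followed by a final layer normalization, and projected by one linear head per
basis width group to the spectral coefficients; the spectrum is Phi c.

The absorber-only (AO) baseline is a plain MLP (two hidden layers of 512)
that regresses the gridded spectrum directly from x_0 alone.

Atoms beyond the shell cutoff are excluded from the environment before
weighting; a molecule with no environment atoms contributes a zero summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .descriptors import DescriptorProvider, DescriptorSet, compute_descriptor_set
from .exceptions import ContractError
from .io_formats import Molecule, Spectrum
from .nn import (Adam, LayerNorm, Linear, Module, Parameter, dropout, gelu,
                 softplus, softplus_inverse)
from .spectral_basis import CoefficientVector, GaussianBasis

__all__ = ["ShellSet", "ResidualBlock", "AweModel", "AoModel", "shell_weights",
           "shell_summaries", "forward_spectrum", "ao_forward",
           "save_checkpoint", "load_checkpoint"]


class ShellSet(Module):
    """Learnable soft radial shells.

    Radii initialize evenly at cutoff * s / S for s = 1..S (even coverage of
    the cutoff ball) and are unconstrained afterwards; blurs initialize to
    half the shell spacing and stay positive via softplus.
    """

    def __init__(self, n_shells: int = 4, cutoff: float = 7.0,
                 epsilon: float = 1e-8,
                 init_radii: np.ndarray | None = None,
                 init_blurs: np.ndarray | None = None):
        if n_shells < 1:
            raise ValueError("need at least one shell")
        spacing = cutoff / n_shells
        radii = (np.asarray(init_radii, dtype=float) if init_radii is not None
                 else spacing * np.arange(1, n_shells + 1))
        blurs = (np.asarray(init_blurs, dtype=float) if init_blurs is not None
                 else np.full(n_shells, spacing / 2.0))
        if np.any(blurs <= 0):
            raise ValueError("blurs must be positive")
        self.radii = Parameter(radii)
        self.raw_blurs = Parameter([softplus_inverse(b) for b in blurs])
        self.n_shells = n_shells
        self.cutoff = cutoff
        self.epsilon = epsilon

    def blurs(self) -> Tensor:
        return softplus(self.raw_blurs)

    def weights(self, r: Tensor | np.ndarray, mask: np.ndarray) -> Tensor:
        """Normalized shell weights for distances r (..., N) with a 0/1 mask."""
        r = r if isinstance(r, Tensor) else Tensor(r)
        diff = (r.reshape(*r.shape, 1) - self.radii) / self.blurs()
        wt = (diff * diff * -0.5).exp() * mask[..., None]
        denom = wt.sum(axis=-2, keepdims=True) + self.epsilon
        return wt / denom


def shell_weights(r: np.ndarray, shells: ShellSet) -> np.ndarray:
    """Per-atom, per-shell normalized weights (pure numpy reference path).

    Atoms beyond the cutoff receive exactly zero weight.
    """
    r = np.asarray(r, dtype=float)
    radii = shells.radii.data
    blurs = np.log1p(np.exp(shells.raw_blurs.data))
    wt = np.exp(-0.5 * ((r[:, None] - radii[None, :]) / blurs[None, :]) ** 2)
    wt = wt * (r <= shells.cutoff)[:, None]
    return wt / (wt.sum(axis=0, keepdims=True) + shells.epsilon)


def shell_summaries(x_env: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Concatenated weighted means m_s = sum_i w_is x_i, length d * S."""
    x_env = np.asarray(x_env, dtype=float)
    w = np.asarray(w, dtype=float)
    if x_env.shape[0] != w.shape[0]:
        raise ContractError("feature matrix and weights disagree on atom count")
    return (w.T @ x_env).reshape(-1)


class ResidualBlock(Module):
    """Pre-layer-normalized residual MLP block with one GeLU bottleneck."""

    def __init__(self, d_latent: int, d_hidden: int, rng: np.random.Generator):
        self.norm = LayerNorm(d_latent)
        self.lin1 = Linear(d_latent, d_hidden, rng)
        self.lin2 = Linear(d_hidden, d_latent, rng)

    def __call__(self, h: Tensor, p: float, rng, training: bool) -> Tensor:
        inner = dropout(gelu(self.lin1(self.norm(h))), p, rng, training)
        return h + self.lin2(inner)


class AweModel(Module):
    """End-to-end absorber-with-environment spectral model.

    Raw descriptor components span orders of magnitude (element-weighted
    sums), so the model carries a per-feature affine input scaling fitted on
    the training descriptors (:meth:`fit_input_scaling`); it is stored with
    the checkpoint and applied identically at inference.
    """

    def __init__(self, provider: DescriptorProvider, basis: GaussianBasis,
                 rng: np.random.Generator, n_shells: int = 4,
                 cutoff: float = 7.0, n_blocks: int = 1,
                 dropout_p: float = 0.1, hidden_multiplier: int = 2):
        d = provider.dimension
        self.provider = provider
        self.basis = basis
        self.shells = ShellSet(n_shells=n_shells, cutoff=cutoff)
        self.shell_fuse = Linear(d * n_shells, d, rng)
        self.absorber_fuse = Linear(2 * d, d, rng)
        self.blocks = [ResidualBlock(d, hidden_multiplier * d, rng)
                       for _ in range(n_blocks)]
        self.final_norm = LayerNorm(d)
        # Output heads start at zero: the initial prediction is the zero
        # spectrum and early optimization is carried by the well-conditioned
        # coefficient term, which avoids the plateau the similarity loss has
        # around random initial spectra.
        self.heads = []
        for _ in range(basis.n_groups):
            head = Linear(d, basis.n_centers, rng)
            head.weight.data = np.zeros_like(head.weight.data)
            self.heads.append(head)
        self.dropout_p = dropout_p
        self.d = d
        self.scale_mean = np.zeros(d)
        self.scale_std = np.ones(d)

    def fit_input_scaling(self, batch: dict) -> None:
        """Fit per-feature standardization on training descriptors.

        Pools the absorber rows with the real (masked-in) environment rows;
        near-constant features keep unit scale.
        """
        rows = [batch["x0"]]
        sel = batch["mask"] > 0
        if sel.any():
            rows.append(batch["xenv"][sel])
        pooled = np.concatenate(rows, axis=0)
        self.scale_mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        self.scale_std = np.where(std < 1e-8, 1.0, std)

    # The batch dict carries padded per-molecule arrays:
    #   x0   (B, d)      absorber descriptors
    #   xenv (B, M, d)   environment descriptors, zero-padded
    #   renv (B, M)      absorber distances of environment atoms
    #   mask (B, M)      1 for real atoms within the cutoff, else 0
    def forward(self, batch: dict, rng: np.random.Generator | None = None,
                training: bool = False) -> tuple[Tensor, Tensor]:
        """Return (coefficients (B, K), spectra (B, N_E)) as tape tensors."""
        xenv = (batch["xenv"] - self.scale_mean) / self.scale_std
        xenv = xenv * (batch["mask"][..., None] > 0)  # keep padding rows inert
        x0 = (batch["x0"] - self.scale_mean) / self.scale_std
        w = self.shells.weights(batch["renv"], batch["mask"])      # (B, M, S)
        m = w.swapaxes(-1, -2) @ Tensor(xenv)                      # (B, S, d)
        summary = m.reshape(m.shape[0], -1)                        # (B, S d)
        fused = self.shell_fuse(summary)
        z = self.absorber_fuse(concat([fused, Tensor(x0)], axis=-1))
        h = z
        for block in self.blocks:
            h = block(h, self.dropout_p, rng, training)
        h_out = self.final_norm(h)
        c = concat([head(h_out) for head in self.heads], axis=-1)  # (B, K)
        yhat = c @ self.basis.phi.T
        return c, yhat

    def pack_molecule(self, mol: Molecule) -> dict:
        """Descriptor evaluation + padding-free batch of size one."""
        ds = compute_descriptor_set(mol, self.provider)
        return pack_descriptor_sets([ds], self.shells.cutoff)


class AoModel(Module):
    """Absorber-only baseline: x_0 -> 512 -> 512 -> gridded spectrum."""

    def __init__(self, d_in: int, n_grid: int, rng: np.random.Generator,
                 hidden: int = 512):
        self.lin1 = Linear(d_in, hidden, rng)
        self.lin2 = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, n_grid, rng)
        self.n_grid = n_grid
        self.scale_mean = np.zeros(d_in)
        self.scale_std = np.ones(d_in)

    def fit_input_scaling(self, batch: dict) -> None:
        x0 = batch["x0"]
        self.scale_mean = x0.mean(axis=0)
        std = x0.std(axis=0)
        self.scale_std = np.where(std < 1e-8, 1.0, std)

    def forward(self, x0: np.ndarray | Tensor) -> Tensor:
        if not isinstance(x0, Tensor):
            x0 = Tensor(np.atleast_2d(x0))
        x0 = (x0 - self.scale_mean) * (1.0 / self.scale_std)
        return self.out(gelu(self.lin2(gelu(self.lin1(x0)))))


def pack_descriptor_sets(dsets: list[DescriptorSet], cutoff: float) -> dict:
    """Pad descriptor sets to a common environment size for batched forward."""
    d = dsets[0].X.shape[1]
    m = max(1, max(ds.X.shape[0] - 1 for ds in dsets))
    b = len(dsets)
    x0 = np.zeros((b, d))
    xenv = np.zeros((b, m, d))
    renv = np.zeros((b, m))
    mask = np.zeros((b, m))
    for i, ds in enumerate(dsets):
        x0[i] = ds.absorber
        n_env = ds.X.shape[0] - 1
        if n_env:
            xenv[i, :n_env] = ds.environment
            renv[i, :n_env] = ds.r[1:]
            mask[i, :n_env] = (ds.r[1:] <= cutoff).astype(float)
    return {"x0": x0, "xenv": xenv, "renv": renv, "mask": mask}


def forward_spectrum(model: AweModel, mol: Molecule
                     ) -> tuple[Spectrum, CoefficientVector]:
    """Deterministic inference: molecule -> (predicted spectrum, coefficients)."""
    c, yhat = model.forward(model.pack_molecule(mol), training=False)
    return (Spectrum(model.basis.grid, yhat.data[0]),
            CoefficientVector(c.data[0], model.basis))


def ao_forward(model: AoModel, x0: np.ndarray) -> np.ndarray:
    """Baseline inference on an absorber descriptor; returns the gridded spectrum."""
    return model.forward(x0).data[0]


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(model: Module, path: str | Path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: parameters plus model/basis configuration."""
    import json

    meta: dict = {"model_class": type(model).__name__,
                  "init_scheme": "glorot-uniform"}
    if isinstance(model, AweModel):
        meta.update({
            "provider": model.provider.name,
            "descriptor_dim": model.provider.dimension,
            "n_shells": model.shells.n_shells,
            "cutoff": model.shells.cutoff,
            "dropout_p": model.dropout_p,
            "n_blocks": len(model.blocks),
            "basis": {
                "grid": model.basis.grid.energies.tolist(),
                "width_groups": list(model.basis.config.width_groups),
                "placement_stride": model.basis.config.placement_stride,
                "ridge_lambda": model.basis.config.ridge_lambda,
            },
        })
    if extra:
        meta["extra"] = extra
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    if hasattr(model, "scale_mean"):
        arrays["buffer::scale_mean"] = model.scale_mean
        arrays["buffer::scale_std"] = model.scale_std
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(model: Module, path: str | Path) -> dict:
    """Load parameters saved by :func:`save_checkpoint`; returns the metadata."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
        if "buffer::scale_mean" in data.files and hasattr(model, "scale_mean"):
            model.scale_mean = data["buffer::scale_mean"].copy()
            model.scale_std = data["buffer::scale_std"].copy()
    model.load_state_dict(state)
    return meta
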