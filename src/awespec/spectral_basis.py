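"""Multiscale Gaussian spectral basis with ridge-regularized projection.

A spectrum y on an energy grid is represented by coefficients c of Gaussian
basis functions phi_k(E) = exp(-((E - mu_k)^2) / (2 w_k^2)).  Centers mu_k sit
at every ``placement_stride``-th grid point; at each center one basis function
per width group is placed (default widths 0.5, 1.0, 2.0 and 4.0 eV), so sharp
near-edge structure and broad envelopes are captured simultaneously.  The
projection operator

    A = (Phi^T Phi + lambda I)^(-1) Phi^T

is the ridge pseudoinverse of the basis matrix: c* = A y minimizes
||Phi c - y||^2 + lambda ||c||^2.  A is formed once per (grid, config) via a
Cholesky solve of the symmetric positive-definite normal equations and cached
on the basis object; projecting a spectrum is then a single matvec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .exceptions import ConfigurationError, NumericalError, ValidationError
from .io_formats import EnergyGrid, Spectrum

__all__ = ["BasisConfig", "GaussianBasis", "CoefficientVector", "build_basis",
           "ridge_operator", "project_spectrum", "reconstruct_spectrum"]


@dataclass(frozen=True)
class BasisConfig:
    """Width groups (eV), center placement stride (grid points) and ridge lambda."""

    width_groups: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    placement_stride: int = 4
    ridge_lambda: float = 1e-3

    def __post_init__(self):
        widths = tuple(float(w) for w in self.width_groups)
        object.__setattr__(self, "width_groups", widths)
        if not widths or any(w <= 0 for w in widths):
            raise ConfigurationError("width groups must be positive")
        if len(set(widths)) != len(widths):
            raise ConfigurationError("width groups must be distinct")
        if self.placement_stride < 1:
            raise ConfigurationError("placement stride must be >= 1")
        if self.ridge_lambda <= 0:
            raise ConfigurationError("ridge lambda must be > 0")


@dataclass(frozen=True)
class GaussianBasis:
    """Basis matrix Phi, its ridge projection operator A, and bookkeeping.

    Basis functions are ordered group-major: all centers of width group 0,
    then all centers of group 1, and so on; ``group_index[k]`` maps basis
    function k to its width group.  The multihead projection of the model
    emits coefficients in this same order.
    """

    grid: EnergyGrid
    centers: np.ndarray       # (K,) eV
    widths: np.ndarray        # (K,) eV
    phi: np.ndarray           # (N_E, K)
    ridge_op: np.ndarray      # (K, N_E)
    group_index: np.ndarray   # (K,) int
    config: BasisConfig

    @property
    def n_functions(self) -> int:
        return self.phi.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.config.width_groups)

    @property
    def n_centers(self) -> int:
        return self.n_functions // self.n_groups


@dataclass(frozen=True)
class CoefficientVector:
    values: np.ndarray
    basis: GaussianBasis

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.basis.n_functions,):
            raise ValidationError(
                f"coefficient length {v.shape} != basis K {self.basis.n_functions}")


def build_basis(grid: EnergyGrid, config: BasisConfig = BasisConfig()) -> GaussianBasis:
    """Construct Phi on the grid and precompute the cached ridge operator."""
    energies = grid.energies
    n_e = energies.size
    if config.placement_stride >= n_e:
        raise ConfigurationError(
            f"placement stride {config.placement_stride} >= grid size {n_e}")
    center_energies = energies[::config.placement_stride]
    centers, widths, groups = [], [], []
    for g, w in enumerate(config.width_groups):
        centers.append(center_energies)
        widths.append(np.full(center_energies.size, w))
        groups.append(np.full(center_energies.size, g, dtype=int))
    centers = np.concatenate(centers)
    widths = np.concatenate(widths)
    groups = np.concatenate(groups)
    phi = np.exp(-0.5 * ((energies[:, None] - centers[None, :]) / widths[None, :]) ** 2)
    a = ridge_operator(phi, config.ridge_lambda)
    return GaussianBasis(grid=grid, centers=centers, widths=widths, phi=phi,
                         ridge_op=a, group_index=groups, config=config)


def ridge_operator(phi: np.ndarray, lam: float) -> np.ndarray:
    """Return A = (Phi^T Phi + lambda I)^(-1) Phi^T via an SPD Cholesky solve.

    lambda = 0 is permitted when Phi^T Phi is well-conditioned (falls back to
    a generic solve); a singular system then raises :class:`NumericalError`
    rather than returning garbage.
    """
    phi = np.asarray(phi, dtype=float)
    if lam < 0:
        raise ValueError(f"ridge lambda must be >= 0, got {lam}")
    gram = phi.T @ phi
    rhs = phi.T
    if lam > 0:
        gram = gram + lam * np.eye(gram.shape[0])
        try:
            cho = sla.cho_factor(gram)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - SPD by construction
            raise NumericalError(f"ridge system not positive definite: {exc}") from exc
        return sla.cho_solve(cho, rhs)
    # unregularized path, used by tests with orthonormal bases
    try:
        sol = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"normal equations singular at lambda=0: {exc}") from exc
    residual = np.linalg.norm(gram @ sol - rhs)
    if not np.isfinite(residual) or residual > 1e-6 * max(1.0, np.linalg.norm(rhs)):
        raise NumericalError("normal-equation solve at lambda=0 is unreliable")
    return sol


def project_spectrum(spectrum: Spectrum, basis: GaussianBasis) -> CoefficientVector:
    """c* = A y.  Linear and deterministic; requires y on the basis grid."""
    if spectrum.grid != basis.grid:
        raise ValidationError("spectrum grid does not match the basis grid")
    return CoefficientVector(basis.ridge_op @ spectrum.intensities, basis)


def reconstruct_spectrum(coeffs: CoefficientVector) -> Spectrum:
    """y_hat = Phi c on the basis grid."""
    basis = coeffs.basis
    return Spectrum(basis.grid, basis.phi @ coeffs.values)
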