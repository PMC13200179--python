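"""Per-atom geometric descriptors and descriptor-space similarity analysis.

The built-in descriptor is the weighted atom-centered symmetry function
(wACSF) set: rotation/translation-invariant sums of element-weighted Gaussian
radial terms and angular terms inside a smooth cosine cutoff, computed from
the perspective of every atom.  Element weight defaults to the atomic number.

Radial term, for center atom c and parameters (eta, mu):

    G_rad = sum_{j != c} w(Z_j) exp(-eta (r_cj - mu)^2) f_c(r_cj)

Angular term, for parameters (eta, zeta, s in {+1, -1}):

    G_ang = 2^(1-zeta) sum_{j<k; j,k != c} w(Z_j) w(Z_k)
            (1 + s cos(theta_jck))^zeta
            exp(-eta (r_cj^2 + r_ck^2 + r_jk^2)) f_c(r_cj) f_c(r_ck) f_c(r_jk)

with the cosine cutoff f_c(r) = 0.5 (cos(pi r / r_cut) + 1) for r < r_cut,
else 0.

External learned descriptors (e.g. per-atom features of a message-passing
network) plug in through the :class:`DescriptorProvider` contract or a
precomputed per-atom feature file; they are never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .exceptions import ContractError, FormatError
from .io_formats import Molecule
from .periodic import atomic_number

__all__ = ["WacsfConfig", "WacsfProvider", "FileDescriptorProvider",
           "DescriptorSet", "DescriptorProvider", "compute_wacsf_atom",
           "compute_descriptor_set", "absorber_distances",
           "nearest_neighbor_distance", "mean_nn_distance", "classify_regime",
           "REGIMES"]


def _default_radial_centers() -> tuple[float, ...]:
    # 16 centers evenly spaced on (0.5, 7.0]
    return tuple(np.linspace(0.5, 7.0, 17)[1:])


@dataclass(frozen=True)
class WacsfConfig:
    """Parameter grids of the wACSF descriptor.

    Defaults: 16 radial centers on (0.5, 7.0] Å with eta = 4 1/Å^2, and 8
    angular terms (zeta in {1, 4}, sign in {+1, -1}, eta in {0.01, 0.1}),
    cutoff 7.0 Å — matching the environment encoder's maximum cutoff.
    """

    radial_etas: tuple[float, ...] = (4.0,) * 16
    radial_centers: tuple[float, ...] = _default_radial_centers()
    angular_etas: tuple[float, ...] = (0.01, 0.01, 0.01, 0.01, 0.1, 0.1, 0.1, 0.1)
    angular_zetas: tuple[float, ...] = (1.0, 1.0, 4.0, 4.0, 1.0, 1.0, 4.0, 4.0)
    angular_signs: tuple[float, ...] = (1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0)
    cutoff_radius: float = 7.0
    weight_fn: Callable[[str], float] = atomic_number

    def __post_init__(self):
        if self.cutoff_radius <= 0:
            raise ValueError("cutoff radius must be positive")
        if len(self.radial_etas) != len(self.radial_centers):
            raise ValueError("radial eta and center lists must have equal length")
        if not self.radial_etas:
            raise ValueError("at least one radial term is required")
        n_ang = len(self.angular_etas)
        if not (len(self.angular_zetas) == len(self.angular_signs) == n_ang):
            raise ValueError("angular parameter lists must have equal length")
        if any(s not in (1.0, -1.0) for s in self.angular_signs):
            raise ValueError("angular signs must be +1 or -1")

    @property
    def dimension(self) -> int:
        return len(self.radial_etas) + len(self.angular_etas)


@runtime_checkable
class DescriptorProvider(Protocol):
    """Contract for per-atom feature providers.

    ``__call__`` returns an (N, d) matrix whose row order matches the atom
    order of the molecule; permuting non-absorber atoms must permute rows
    identically.
    """

    name: str
    dimension: int

    def __call__(self, mol: Molecule) -> np.ndarray: ...


def _cutoff_fn(r: np.ndarray, r_cut: float) -> np.ndarray:
    fc = 0.5 * (np.cos(np.pi * r / r_cut) + 1.0)
    return np.where(r < r_cut, fc, 0.0)


def compute_wacsf_atom(mol: Molecule, center: int,
                       config: WacsfConfig = WacsfConfig()) -> np.ndarray:
    """wACSF feature vector of one atom (length ``config.dimension``)."""
    if not 0 <= center < mol.n_atoms:
        raise IndexError(f"center index {center} out of range")
    coords = mol.coords
    others = np.array([i for i in range(mol.n_atoms) if i != center], dtype=int)
    d = config.dimension
    if others.size == 0:
        return np.zeros(d)
    rc = config.cutoff_radius
    vec = coords[others] - coords[center]
    dist = np.linalg.norm(vec, axis=1)
    weights = np.array([config.weight_fn(mol.elements[i]) for i in others], dtype=float)
    fc = _cutoff_fn(dist, rc)

    out = np.empty(d)
    # radial terms
    etas = np.asarray(config.radial_etas)
    mus = np.asarray(config.radial_centers)
    rad = (weights[:, None] * np.exp(-etas[None, :] * (dist[:, None] - mus[None, :]) ** 2)
           * fc[:, None]).sum(axis=0)
    out[: len(etas)] = rad

    # angular terms over unordered neighbor pairs
    n_ang = len(config.angular_etas)
    if n_ang:
        ang = np.zeros(n_ang)
        m = others.size
        if m >= 2:
            jj, kk = np.triu_indices(m, k=1)
            rj, rk = dist[jj], dist[kk]
            rjk = np.linalg.norm(coords[others[jj]] - coords[others[kk]], axis=1)
            cosang = (vec[jj] * vec[kk]).sum(axis=1) / (rj * rk)
            cosang = np.clip(cosang, -1.0, 1.0)
            wpair = weights[jj] * weights[kk]
            fcs = fc[jj] * fc[kk] * _cutoff_fn(rjk, rc)
            for a, (eta, zeta, sign) in enumerate(zip(
                    config.angular_etas, config.angular_zetas, config.angular_signs)):
                ang[a] = (2.0 ** (1.0 - zeta) * (
                    wpair * (1.0 + sign * cosang) ** zeta
                    * np.exp(-eta * (rj ** 2 + rk ** 2 + rjk ** 2)) * fcs).sum())
        out[len(etas):] = ang
    return out


@dataclass(frozen=True)
class WacsfProvider:
    """Descriptor provider computing wACSFs for every atom of a molecule."""

    config: WacsfConfig = WacsfConfig()
    name: str = "wacsf"

    @property
    def dimension(self) -> int:
        return self.config.dimension

    def __call__(self, mol: Molecule) -> np.ndarray:
        return np.stack([compute_wacsf_atom(mol, i, self.config)
                         for i in range(mol.n_atoms)])


@dataclass(frozen=True)
class FileDescriptorProvider:
    """Per-atom features loaded from text files, aligned to XYZ atom order.

    File format: first non-comment line is the feature dimension d, followed
    by N rows of d whitespace-separated values.
    """

    features: dict[str, np.ndarray]
    dimension: int
    name: str = "external"

    @classmethod
    def from_files(cls, mapping: dict[str, str | Path]) -> "FileDescriptorProvider":
        feats: dict[str, np.ndarray] = {}
        dim: int | None = None
        for key, path in mapping.items():
            rows = [ln.split() for ln in Path(path).read_text().splitlines()
                    if ln.strip() and not ln.lstrip().startswith("#")]
            try:
                d = int(rows[0][0])
                mat = np.array([[float(v) for v in row] for row in rows[1:]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed feature file {path}") from exc
            if mat.ndim != 2 or mat.shape[1] != d:
                raise FormatError(f"feature file {path}: rows do not match header d={d}")
            if dim is None:
                dim = d
            elif dim != d:
                raise FormatError("feature files disagree on dimension")
            feats[str(key)] = mat
        return cls(features=feats, dimension=int(dim))

    def __call__(self, mol: Molecule) -> np.ndarray:
        key = getattr(mol, "tag", None)
        if key is None or key not in self.features:
            raise ContractError("no precomputed features for this molecule")
        return self.features[key]


@dataclass(frozen=True)
class DescriptorSet:
    """Feature matrix with the absorber row first, plus absorber distances."""

    X: np.ndarray  # (N, d); row 0 is the absorber
    r: np.ndarray  # (N,); r[0] == 0

    def __post_init__(self):
        if self.X.shape[0] != self.r.shape[0]:
            raise ContractError("X and r disagree on atom count")
        if self.r[0] != 0.0 or np.any(self.r < 0):
            raise ContractError("distances must be nonnegative with r[0] == 0")
        if not np.all(np.isfinite(self.X)):
            raise ContractError("non-finite descriptor values")

    @property
    def absorber(self) -> np.ndarray:
        return self.X[0]

    @property
    def environment(self) -> np.ndarray:
        return self.X[1:]


def absorber_distances(mol: Molecule) -> np.ndarray:
    """Euclidean distance of every atom to the absorber (absorber entry 0)."""
    return np.linalg.norm(mol.coords - mol.coords[mol.absorber_index], axis=1)


def compute_descriptor_set(mol: Molecule,
                           provider: DescriptorProvider) -> DescriptorSet:
    """Evaluate a provider and reorder so the absorber row comes first."""
    feats = np.asarray(provider(mol), dtype=float)
    if feats.shape != (mol.n_atoms, provider.dimension):
        raise ContractError(
            f"provider {provider.name!r} returned shape {feats.shape}, expected "
            f"({mol.n_atoms}, {provider.dimension})")
    r = absorber_distances(mol)
    order = [mol.absorber_index] + [i for i in range(mol.n_atoms)
                                    if i != mol.absorber_index]
    return DescriptorSet(X=feats[order], r=r[order])


# ----------------------------------------------------- similarity and regimes
def nearest_neighbor_distance(test_x: np.ndarray, training_X: np.ndarray,
                              normalizer: float) -> float:
    """Normalized distance from a test descriptor to its nearest training point."""
    training_X = np.atleast_2d(training_X)
    if training_X.shape[0] == 0:
        raise ValueError("training set is empty")
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    d = np.min(np.linalg.norm(training_X - np.asarray(test_x)[None, :], axis=1))
    return float(d / normalizer)


def mean_nn_distance(training_X: np.ndarray) -> float:
    """Mean over training examples of each example's nearest-neighbor distance.

    This is the normalizer used when classifying test structures into
    similarity regimes.
    """
    x = np.atleast_2d(training_X)
    if x.shape[0] < 2:
        raise ValueError("need at least two training examples")
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.mean(np.sqrt(d2.min(axis=1))))


REGIMES = ("identical", "familiar", "unfamiliar", "strange")
_REGIME_BOUNDS = (1e-3, 10 ** -1.5, 1.0)


def classify_regime(d: float) -> str:
    """Map a normalized descriptor distance to its similarity regime.

    identical: d < 1e-3; familiar: d < 10^-1.5; unfamiliar: d < 1;
    strange: d >= 1.
    """
    if d < 0:
        raise ValueError(f"distance must be nonnegative, got {d}")
    for regime, bound in zip(REGIMES, _REGIME_BOUNDS):
        if d < bound:
            return regime
    return "strange"
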