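"""Molecular geometries, spectra, dataset manifests and run configuration.

Geometries travel as standard XYZ files whose comment line may carry an
``absorber=<i>`` key (0-based atom index of the absorbing atom; defaults to
atom 0).  Spectra are two-column whitespace-delimited text: energy (eV) and
intensity, with ``#`` comment lines.  A manifest pairs geometry and spectrum
files and is a small CSV with columns ``geometry,spectrum,absorber``.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .exceptions import (ConfigurationError, FormatError, RangeError,
                         ValidationError)
from .periodic import is_element

__all__ = ["Molecule", "EnergyGrid", "Spectrum", "DatasetManifest",
           "parse_xyz", "write_xyz", "parse_spectrum", "write_spectrum",
           "load_dataset", "load_config"]


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class Molecule:
    """Element symbols, Cartesian coordinates (Å) and the absorbing-atom index."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3), Å
    absorber_index: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        n = len(self.elements)
        if n < 1:
            raise ValidationError("a molecule needs at least one atom")
        if coords.shape != (n, 3):
            raise ValidationError(f"coords shape {coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        if not 0 <= self.absorber_index < n:
            raise ValidationError(f"absorber index {self.absorber_index} out of range")
        for sym in self.elements:
            if not is_element(sym):
                raise ValidationError(f"unknown element symbol {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing energies in eV."""

    energies: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 2:
            raise ValidationError("energy grid needs at least two points")
        if not np.all(np.isfinite(e)):
            raise ValidationError("non-finite grid energies")
        if not np.all(np.diff(e) > 0):
            raise ValidationError("energy grid must be strictly increasing")

    def __len__(self) -> int:
        return self.energies.size

    def __eq__(self, other) -> bool:
        return isinstance(other, EnergyGrid) and np.array_equal(
            self.energies, other.energies)

    def __hash__(self):
        return hash(self.energies.tobytes())


@dataclass(frozen=True)
class Spectrum:
    """Intensities on an energy grid (arbitrary units)."""

    grid: EnergyGrid
    intensities: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.shape != (len(self.grid),) or not np.all(np.isfinite(y)):
            raise ValidationError("intensities must be finite and match the grid length")


@dataclass
class ManifestRecord:
    geometry: str
    spectrum: str
    absorber: int | str | None = None  # index, element symbol, or None (use file key)


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)
    mode: str = "XAS"  # XAS | XES

    def __post_init__(self):
        if self.mode not in ("XAS", "XES"):
            raise ValidationError(f"mode must be XAS or XES, got {self.mode!r}")
        seen = set()
        for rec in self.records:
            key = (rec.geometry, rec.spectrum)
            if key in seen:
                raise ValidationError(f"duplicate manifest record {key}")
            seen.add(key)

    @classmethod
    def from_csv(cls, path: str | Path, mode: str = "XAS") -> "DatasetManifest":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                absorber: int | str | None = row.get("absorber") or None
                if absorber is not None and re.fullmatch(r"\d+", absorber):
                    absorber = int(absorber)
                records.append(ManifestRecord(row["geometry"], row["spectrum"], absorber))
        return cls(records=records, mode=mode)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["geometry", "spectrum", "absorber"])
            for rec in self.records:
                writer.writerow([rec.geometry, rec.spectrum,
                                 "" if rec.absorber is None else rec.absorber])


# ----------------------------------------------------------------- XYZ files
_ABSORBER_RE = re.compile(r"absorber\s*=\s*(\d+)")


def parse_xyz(source: str | io.TextIOBase | Path) -> Molecule:
    """Parse an XYZ file/string; the comment line may carry ``absorber=<i>``."""
    text = _read_text(source)
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty XYZ input")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise FormatError(f"first XYZ line must be the atom count: {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    match = _ABSORBER_RE.search(comment)
    absorber = int(match.group(1)) if match else 0
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise FormatError(f"XYZ header declares {n} atoms but {len(body)} listed")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"malformed XYZ atom line: {ln!r}")
        sym = parts[0]
        if not is_element(sym):
            raise ValidationError(f"unknown element symbol {sym!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise FormatError(f"non-numeric coordinate in line: {ln!r}") from exc
        elements.append(sym)
        coords.append(xyz)
    return Molecule(tuple(elements), np.array(coords, dtype=float), absorber)


def write_xyz(mol: Molecule, path: str | Path | None = None) -> str:
    """Serialize a molecule; round-trips through :func:`parse_xyz` to 1e-6 Å."""
    lines = [str(mol.n_atoms), f"absorber={mol.absorber_index}"]
    for sym, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ------------------------------------------------------------ spectrum files
def parse_spectrum(source: str | io.TextIOBase | Path) -> Spectrum:
    """Parse two-column ``energy intensity`` text with ``#`` comments."""
    text = _read_text(source)
    energies, values = [], []
    for ln in text.splitlines():
        stripped = ln.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise FormatError(f"expected two columns, got {len(parts)}: {ln!r}")
        try:
            e, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise FormatError(f"non-numeric spectrum row: {ln!r}") from exc
        energies.append(e)
        values.append(v)
    if len(energies) < 2:
        raise FormatError("a spectrum needs at least two rows")
    e = np.array(energies)
    if not np.all(np.diff(e) > 0):
        raise ValidationError("spectrum energies must be strictly increasing")
    return Spectrum(EnergyGrid(e), np.array(values))


def write_spectrum(spec: Spectrum, path: str | Path | None = None) -> str:
    lines = ["# energy_eV intensity"]
    for e, v in zip(spec.grid.energies, spec.intensities):
        lines.append(f"{e:.12g} {v:.12g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ------------------------------------------------------------------- loading
def load_dataset(manifest: DatasetManifest,
                 target_grid: EnergyGrid | None = None,
                 root: str | Path = ".") -> list[tuple[Molecule, Spectrum]]:
    """Load all manifest records onto one common energy grid.

    Spectra already on the common grid pass through unchanged; otherwise they
    are linearly interpolated onto ``target_grid``.  Extrapolation is refused.
    """
    root = Path(root)
    pairs: list[tuple[Molecule, Spectrum]] = []
    grids: list[EnergyGrid] = []
    for rec in manifest.records:
        mol = parse_xyz(root / rec.geometry)
        if isinstance(rec.absorber, int):
            mol = Molecule(mol.elements, mol.coords, rec.absorber)
        elif isinstance(rec.absorber, str):
            matches = [i for i, s in enumerate(mol.elements) if s == rec.absorber]
            if len(matches) != 1:
                raise ValidationError(
                    f"absorber element {rec.absorber!r} matches {len(matches)} atoms "
                    f"in {rec.geometry}; give an index instead")
            mol = Molecule(mol.elements, mol.coords, matches[0])
        spec = parse_spectrum(root / rec.spectrum)
        pairs.append((mol, spec))
        grids.append(spec.grid)

    if target_grid is None:
        if any(g != grids[0] for g in grids[1:]):
            raise ConfigurationError(
                "manifest spectra are on different grids; pass a target_grid")
        return pairs

    out = []
    for mol, spec in pairs:
        if spec.grid == target_grid:
            out.append((mol, spec))
            continue
        src = spec.grid.energies
        tgt = target_grid.energies
        if tgt[0] < src[0] or tgt[-1] > src[-1]:
            raise RangeError(
                f"target grid [{tgt[0]}, {tgt[-1]}] outside source range "
                f"[{src[0]}, {src[-1]}]")
        out.append((mol, Spectrum(target_grid,
                                  np.interp(tgt, src, spec.intensities))))
    return out


def resample_spectra(spectra: Sequence[Spectrum],
                     target_grid: EnergyGrid) -> list[Spectrum]:
    """Linear resampling of spectra onto a common grid (no extrapolation)."""
    out = []
    for spec in spectra:
        src = spec.grid.energies
        if target_grid.energies[0] < src[0] or target_grid.energies[-1] > src[-1]:
            raise RangeError("target grid outside source range")
        out.append(Spectrum(target_grid, np.interp(
            target_grid.energies, src, spec.intensities)))
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return cfg


def _read_text(source: str | io.TextIOBase | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str):
        # Heuristic: multi-line strings are content, single-line strings paths.
        if "\n" in source:
            return source
        return Path(source).read_text()
    raise TypeError(f"cannot read from {type(source)!r}")
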