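"""Gaussian cube file I/O and the in-memory volumetric grid model.

The cube format is the de-facto text standard for volumetric molecular
fields (electron density, electrostatic potential, local electronegativity
maps, ...): two free comment lines, a header with the atom count and grid
origin, three voxel-axis lines, one line per atom, then the scalar values
with the z index fastest-varying. Everything here is stored internally in
Bohr; cubes written with the Ångström convention (negative voxel counts)
are converted on read. The molecular-orbital cube variant (negative atom
count, extra orbital-index record) is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "BOHR_PER_ANGSTROM",
    "MoleculeGeometry",
    "VolumetricGrid",
    "TernaryMask",
    "CubeFormatError",
    "read_cube",
    "write_cube",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class CubeFormatError(ValueError):
    """Raised when a file does not follow the Gaussian cube layout."""


@dataclass(frozen=True)
class MoleculeGeometry:
    """Atomic numbers, nuclear charges and positions (Bohr) of one molecule."""

    atomic_numbers: Tuple[int, ...]
    nuclear_charges: Tuple[float, ...]
    positions: np.ndarray  # (n_atoms, 3), Bohr

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.atomic_numbers) == 0:
            raise ValueError("geometry must contain at least one atom")
        if pos.shape != (len(self.atomic_numbers), 3):
            raise ValueError(
                f"positions shape {pos.shape} inconsistent with "
                f"{len(self.atomic_numbers)} atoms"
            )
        if any(z < 1 for z in self.atomic_numbers):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)


@dataclass
class VolumetricGrid:
    """A scalar field on a regular 3D grid.

    The voxel at 0-based index (ix, iy, iz) sits at
    ``origin + ix*axes[0] + iy*axes[1] + iz*axes[2]`` (Bohr).  ``values``
    is indexed ``values[ix, iy, iz]``, matching the cube storage order
    (x outermost, z innermost).
    """

    origin: np.ndarray  # (3,), Bohr
    axes: np.ndarray  # (3, 3), rows are voxel step vectors, Bohr
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if not (np.all(np.isfinite(self.origin)) and np.all(np.isfinite(self.axes))):
            raise ValueError("origin and axes must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def voxel_positions(self) -> np.ndarray:
        """Cartesian position of every voxel, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix, iy, iz], axis=-1).astype(float)
        return self.origin + idx @ self.axes

    def with_values(self, values: np.ndarray) -> "VolumetricGrid":
        """Same geometry, different scalar field."""
        return VolumetricGrid(self.origin.copy(), self.axes.copy(), values)


@dataclass
class TernaryMask:
    """Per-voxel reactivity labels: 0 = medium, 1 = low, 2 = high."""

    labels: np.ndarray  # (nx, ny, nz) integers in {0, 1, 2}

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integral")
            lab = lab.astype(np.int8)
        if lab.min(initial=0) < 0 or lab.max(initial=0) > 2:
            raise ValueError("labels must lie in {0, 1, 2}")
        self.labels = lab.astype(np.int8)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape


def _parse_floats(tokens: Sequence[str], line_no: int, path: Path) -> list[float]:
    out = []
    for tok in tokens:
        try:
            out.append(float(tok))
        except ValueError as exc:
            raise CubeFormatError(
                f"{path}: non-numeric token {tok!r} on line {line_no}"
            ) from exc
    return out


def read_cube(path) -> Tuple[MoleculeGeometry, VolumetricGrid]:
    """Read a density-style Gaussian cube file.

    Returns the molecular geometry and the volumetric grid, both in Bohr.
    Ångström cubes (negative voxel counts on the axis lines) are converted.
    Orbital cubes (negative atom count) are rejected.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if len(text) < 6:
        raise CubeFormatError(f"{path}: file too short for a cube header")

    # line 3 (index 2): n_atoms and origin
    toks = text[2].split()
    if len(toks) < 4:
        raise CubeFormatError(f"{path}: malformed atom-count/origin line 3: {text[2]!r}")
    try:
        n_atoms = int(float(toks[0]))
    except ValueError as exc:
        raise CubeFormatError(f"{path}: bad atom count on line 3: {toks[0]!r}") from exc
    if n_atoms < 0:
        raise CubeFormatError(
            f"{path}: negative atom count ({n_atoms}) marks a molecular-orbital "
            "cube, which is not supported"
        )
    if n_atoms == 0:
        raise CubeFormatError(f"{path}: cube declares zero atoms")
    origin = np.array(_parse_floats(toks[1:4], 3, path))

    counts = []
    axes = []
    for i, line_no in enumerate((4, 5, 6)):
        toks = text[line_no - 1].split()
        if len(toks) < 4:
            raise CubeFormatError(f"{path}: malformed axis line {line_no}: {text[line_no - 1]!r}")
        try:
            counts.append(int(float(toks[0])))
        except ValueError as exc:
            raise CubeFormatError(
                f"{path}: bad voxel count on line {line_no}: {toks[0]!r}"
            ) from exc
        axes.append(_parse_floats(toks[1:4], line_no, path))
    axes = np.array(axes)

    # Negative voxel counts signal Ångström units: convert everything to Bohr.
    if any(c < 0 for c in counts):
        if not all(c < 0 for c in counts):
            raise CubeFormatError(f"{path}: mixed-sign voxel counts on axis lines")
        counts = [-c for c in counts]
        axes = axes * BOHR_PER_ANGSTROM
        origin = origin * BOHR_PER_ANGSTROM
    if any(c < 1 for c in counts):
        raise CubeFormatError(f"{path}: non-positive voxel count in header")
    nx, ny, nz = counts

    atom_lines = text[6 : 6 + n_atoms]
    if len(atom_lines) < n_atoms:
        raise CubeFormatError(f"{path}: fewer atom lines than declared atom count")
    atomic_numbers, charges, positions = [], [], []
    for i, line in enumerate(atom_lines):
        toks = line.split()
        if len(toks) < 5:
            raise CubeFormatError(f"{path}: malformed atom line {7 + i}: {line!r}")
        vals = _parse_floats(toks[:5], 7 + i, path)
        atomic_numbers.append(int(vals[0]))
        charges.append(vals[1])
        positions.append(vals[2:5])
    geom = MoleculeGeometry(tuple(atomic_numbers), tuple(charges), np.array(positions))

    n_expected = nx * ny * nz
    flat = np.empty(n_expected, dtype=float)
    pos = 0
    for offset, line in enumerate(text[6 + n_atoms :]):
        toks = line.split()
        if not toks:
            continue
        if pos + len(toks) > n_expected:
            raise CubeFormatError(
                f"{path}: volumetric block holds more than {n_expected} values"
            )
        for tok in toks:
            try:
                flat[pos] = float(tok)
            except ValueError as exc:
                raise CubeFormatError(
                    f"{path}: non-numeric volumetric token {tok!r} at voxel "
                    f"index {pos} (flat order)"
                ) from exc
            pos += 1
    if pos != n_expected:
        raise CubeFormatError(
            f"{path}: volumetric block truncated: {pos} values for shape "
            f"({nx}, {ny}, {nz}) = {n_expected}"
        )
    values = flat.reshape(nx, ny, nz)  # z fastest-varying in file order
    return geom, VolumetricGrid(origin, axes, values)


def write_cube(geom: MoleculeGeometry, grid: VolumetricGrid, path) -> Path:
    """Write a density-style Gaussian cube file (Bohr, positive counts).

    Values go 6 per line in scientific notation; the comment lines carry
    tool provenance only and are excluded from round-trip equality.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    lines = [
        "voxhazard cube file",
        f"scalar field, shape ({nx}, {ny}, {nz}), Bohr",
        f"{geom.n_atoms:5d} {grid.origin[0]:13.6f} {grid.origin[1]:13.6f} {grid.origin[2]:13.6f}",
    ]
    for count, axis in zip((nx, ny, nz), grid.axes):
        lines.append(f"{count:5d} {axis[0]:13.6f} {axis[1]:13.6f} {axis[2]:13.6f}")
    for z, q, r in zip(geom.atomic_numbers, geom.nuclear_charges, geom.positions):
        lines.append(f"{z:5d} {q:13.6f} {r[0]:13.6f} {r[1]:13.6f} {r[2]:13.6f}")
    flat = grid.values.reshape(-1)  # x outer, z inner
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append(" ".join(f"{v:16.8E}" for v in chunk))
    path.write_text("\n".join(lines) + "\n")
    return path
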