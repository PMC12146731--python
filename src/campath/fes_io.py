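"""Gridded free-energy surfaces: containers, file I/O and masking.

Free-energy surfaces (potentials of mean force) produced by enhanced-sampling
runs arrive as regular N-dimensional grids of energies over a set of
collective variables (here, ion z-positions). This module provides the
:class:`EnergyGrid` container used throughout the package, readers/writers for
two text dialects (the de-facto PLUMED grid layout and a plain TSV with a JSON
header), and the high-energy masking step that excludes unsampled regions from
path searches.

Internal units are fixed: energies in kJ/mol, axis coordinates in the unit
declared per axis (default Angstrom).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT_KJ_PER_MOL_K",
    "PLUMED_MASK_SENTINEL",
    "Axis",
    "Temperature",
    "EnergyGrid",
    "FesFormatError",
    "FesDimensionError",
    "read_fes_grid",
    "write_fes_grid",
    "mask_high_energy",
]

#: Molar gas constant in kJ/mol/K.
GAS_CONSTANT_KJ_PER_MOL_K = 0.0083144621

#: Energy written for masked nodes in the PLUMED dialect, which has no mask
#: column; values at or above this are re-read as masked.
PLUMED_MASK_SENTINEL = 1e9


class FesFormatError(ValueError):
    """Malformed grid file (bad header or data row)."""


class FesDimensionError(ValueError):
    """Declared grid shape inconsistent with the data."""


@dataclass(frozen=True)
class Temperature:
    """Absolute temperature with the derived thermal energy RT (kJ/mol)."""

    kelvin: float

    def __post_init__(self) -> None:
        if not self.kelvin > 0:
            raise ValueError(f"temperature must be positive, got {self.kelvin}")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KJ_PER_MOL_K * self.kelvin


@dataclass(frozen=True)
class Axis:
    """One grid dimension: name, closed range, node count, periodicity.

    Nodes sit at ``min + i * spacing``.  For a non-periodic axis both ends
    carry a node, so ``spacing = (max - min) / (n_bins - 1)``; a periodic axis
    omits the duplicate endpoint, ``spacing = (max - min) / n_bins``.
    """

    name: str
    min: float
    max: float
    n_bins: int
    periodic: bool = False
    unit: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "min", float(self.min))
        object.__setattr__(self, "max", float(self.max))
        object.__setattr__(self, "n_bins", int(self.n_bins))
        if self.n_bins < 1:
            raise ValueError(f"axis {self.name!r}: n_bins must be >= 1")
        if not self.min < self.max:
            raise ValueError(f"axis {self.name!r}: require min < max")

    @property
    def spacing(self) -> float:
        denom = self.n_bins if self.periodic else max(self.n_bins - 1, 1)
        return (self.max - self.min) / denom

    def coords(self) -> np.ndarray:
        return self.min + self.spacing * np.arange(self.n_bins)


@dataclass(frozen=True)
class EnergyGrid:
    """Regular N-dimensional grid of free energies with an exclusion mask.

    Parameters
    ----------
    axes:
        One :class:`Axis` per dimension; ``values.shape`` must equal the
        per-axis node counts.
    values:
        Free energy per node, kJ/mol.  Must be finite on unmasked nodes.
    mask:
        Boolean per node; ``True`` marks a node excluded from path searches.
    metadata:
        Free-form annotations (e.g. analytic facts of a synthetic landscape).
    """

    axes: tuple[Axis, ...]
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        shape = tuple(ax.n_bins for ax in self.axes)
        if values.shape != shape:
            raise FesDimensionError(
                f"values shape {values.shape} != axes shape {shape}"
            )
        mask = self.mask
        if mask is None:
            mask = np.zeros(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise FesDimensionError(
                    f"mask shape {mask.shape} != axes shape {shape}"
                )
        if not np.all(np.isfinite(values[~mask])):
            raise ValueError("non-finite energy on unmasked node")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(ax.spacing for ax in self.axes)

    def node_coords(self, index: tuple[int, ...]) -> np.ndarray:
        """Physical coordinates of a grid node (multi-index)."""
        return np.array(
            [ax.min + ax.spacing * i for ax, i in zip(self.axes, index)]
        )

    def coord_arrays(self) -> list[np.ndarray]:
        return [ax.coords() for ax in self.axes]


def mask_high_energy(grid: EnergyGrid, threshold: float) -> EnergyGrid:
    """Exclude nodes with energy above ``threshold`` (kJ/mol) from searches.

    Already-masked nodes stay masked; values are untouched.  Idempotent, and
    monotone: a lower threshold masks a superset of nodes.
    """
    if math.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    new_mask = grid.mask | (grid.values > threshold)
    return replace(grid, mask=new_mask)


# ---------------------------------------------------------------------------
# File dialects.
#
# plumed_grid: "#!" header lines declare FIELDS and per-axis SET
#   min/max/nbins/periodic; data rows list CV values then the energy (then
#   optional derivative columns, ignored).  The first field varies fastest.
#   Masked nodes carry the PLUMED_MASK_SENTINEL energy.
# tsv: one "#" line holding a JSON axis description, then tab-separated rows
#   of coordinates, energy and an explicit 0/1 mask column.  Masked energies
#   serialize as "inf".
# ---------------------------------------------------------------------------

_DIALECTS = ("plumed_grid", "tsv")


def read_fes_grid(path, dialect: str = "plumed_grid") -> EnergyGrid:
    """Read a gridded free-energy surface from a text file.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"plumed_grid"`` or ``"tsv"`` (see module notes on the layouts).

    Returns
    -------
    EnergyGrid
        Validated grid; derivative columns in the PLUMED dialect are ignored.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    with open(path) as fh:
        text = fh.read()
    if dialect == "plumed_grid":
        return _read_plumed(text)
    return _read_tsv(text)


def write_fes_grid(grid: EnergyGrid, path, dialect: str = "plumed_grid") -> None:
    """Write a grid so that :func:`read_fes_grid` recovers axes/values/mask."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    text = _format_plumed(grid) if dialect == "plumed_grid" else _format_tsv(grid)
    with open(path, "w") as fh:
        fh.write(text)


def _read_plumed(text: str) -> EnergyGrid:
    names: list[str] = []
    meta: dict[str, dict[str, str]] = {}
    rows: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line[2:].split()
            if not parts:
                raise FesFormatError(f"line {lineno}: empty header line")
            if parts[0] == "FIELDS":
                if len(parts) < 3:
                    raise FesFormatError(
                        f"line {lineno}: FIELDS needs at least one CV and one value column"
                    )
                # last field is the energy; anything after it would be
                # derivative columns declared der_<cv>
                fields = parts[1:]
                cv = [f for f in fields if not f.startswith("der_")]
                names = cv[:-1]
                if not names:
                    raise FesFormatError(f"line {lineno}: no CV columns in FIELDS")
            elif parts[0] == "SET":
                if len(parts) != 3:
                    raise FesFormatError(f"line {lineno}: malformed SET line: {raw!r}")
                key, value = parts[1], parts[2]
                for prefix in ("min_", "max_", "nbins_", "periodic_"):
                    if key.startswith(prefix):
                        axname = key[len(prefix):]
                        meta.setdefault(axname, {})[prefix[:-1]] = value
                        break
            # other #! lines (e.g. SET normalisation) tolerated
        elif line.startswith("#"):
            continue
        else:
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FesFormatError(f"line {lineno}: bad data row: {raw!r}") from exc
    if not names:
        raise FesFormatError("missing '#! FIELDS' header line")
    axes = []
    for name in names:
        m = meta.get(name)
        if m is None or not {"min", "max", "nbins"} <= m.keys():
            raise FesFormatError(f"missing SET min/max/nbins for axis {name!r}")
        periodic = m.get("periodic", "false").lower() in ("true", "pi", "yes", "1")
        axes.append(
            Axis(name, float(m["min"]), float(m["max"]), int(m["nbins"]), periodic)
        )
    shape = tuple(ax.n_bins for ax in axes)
    n_expected = int(np.prod(shape))
    if len(rows) != n_expected:
        raise FesDimensionError(
            f"expected {n_expected} data rows for nbins {shape}, found {len(rows)}"
        )
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < len(axes) + 1:
        raise FesFormatError(
            f"data rows have {data.shape[1]} columns; need >= {len(axes) + 1}"
        )
    energy = data[:, len(axes)]
    # first field varies fastest: row-major over reversed axes
    values = energy.reshape(shape[::-1]).transpose(range(len(shape))[::-1])
    mask = values >= PLUMED_MASK_SENTINEL
    values = values.copy()
    values[mask] = PLUMED_MASK_SENTINEL
    return EnergyGrid(tuple(axes), values, mask)


def _format_plumed(grid: EnergyGrid) -> str:
    lines = ["#! FIELDS " + " ".join(ax.name for ax in grid.axes) + " free"]
    for ax in grid.axes:
        lines.append(f"#! SET min_{ax.name} {ax.min!r}")
        lines.append(f"#! SET max_{ax.name} {ax.max!r}")
        lines.append(f"#! SET nbins_{ax.name} {ax.n_bins}")
        lines.append(f"#! SET periodic_{ax.name} {'true' if ax.periodic else 'false'}")
    coords = grid.coord_arrays()
    values = np.where(grid.mask, PLUMED_MASK_SENTINEL, grid.values)
    shape = grid.shape
    # emit with the first axis fastest-varying
    for flat in range(values.size):
        idx = []
        rem = flat
        for n in shape:
            idx.append(rem % n)
            rem //= n
        point = [coords[d][i] for d, i in enumerate(idx)]
        lines.append(
            " ".join(repr(float(c)) for c in point)
            + f" {float(values[tuple(idx)])!r}"
        )
        if idx[0] == shape[0] - 1:
            lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def _format_tsv(grid: EnergyGrid) -> str:
    header = {
        "axes": [
            {
                "name": ax.name,
                "min": ax.min,
                "max": ax.max,
                "n_bins": ax.n_bins,
                "periodic": ax.periodic,
                "unit": ax.unit,
            }
            for ax in grid.axes
        ],
        "energy_unit": "kJ/mol",
    }
    lines = ["#" + json.dumps(header)]
    coords = grid.coord_arrays()
    for flat in range(grid.values.size):
        idx = np.unravel_index(flat, grid.shape)
        point = [coords[d][i] for d, i in enumerate(idx)]
        masked = bool(grid.mask[idx])
        e = "inf" if masked else repr(float(grid.values[idx]))
        lines.append(
            "\t".join(repr(float(c)) for c in point) + f"\t{e}\t{int(masked)}"
        )
    return "\n".join(lines) + "\n"


def _read_tsv(text: str) -> EnergyGrid:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FesFormatError("tsv dialect requires a '#'-prefixed JSON header line")
    try:
        header = json.loads(lines[0][1:])
        axes = tuple(
            Axis(
                a["name"], float(a["min"]), float(a["max"]),
                int(a["n_bins"]), bool(a.get("periodic", False)),
                a.get("unit", "A"),
            )
            for a in header["axes"]
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FesFormatError(f"bad JSON header: {lines[0]!r}") from exc
    shape = tuple(ax.n_bins for ax in axes)
    n_expected = int(np.prod(shape))
    data_rows = lines[1:]
    if len(data_rows) != n_expected:
        raise FesDimensionError(
            f"expected {n_expected} data rows for n_bins {shape}, found {len(data_rows)}"
        )
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    ncols = len(axes) + 2
    for i, row in enumerate(data_rows):
        toks = row.split("\t")
        if len(toks) != ncols:
            raise FesFormatError(f"data row {i + 1}: expected {ncols} columns")
        idx = np.unravel_index(i, shape)
        m = toks[-1].strip() == "1"
        mask[idx] = m
        values[idx] = math.inf if m else float(toks[len(axes)])
    values[mask] = PLUMED_MASK_SENTINEL  # keep array finite for arithmetic
    return EnergyGrid(axes, values, mask)
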