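"""Spectrum container, file I/O and grid arithmetic.

A :class:`Spectrum` is a strictly ascending wavelength grid (nm) with one
signal value per grid point and a unit tag.  Circular-dichroism scans come
off the instrument in millidegrees of observed ellipticity; downstream
calibration converts them to molar ellipticity, mean-residue ellipticity or
molar circular dichroism (Δε).  All arithmetic here is deliberately strict:
two spectra combine only when their unit tags match and their grids agree to
within ``GRID_ATOL`` nm — resampling is an explicit, separate step so the
processing chain stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, FormatError, RangeError, UnitError, ValidationError

#: Unit tags a Spectrum may carry.
MILLIDEGREES = "millidegrees"
MOLAR_ELLIPTICITY = "molar_ellipticity"            # deg cm^2 dmol^-1
MEAN_RESIDUE_ELLIPTICITY = "mean_residue_ellipticity"  # deg cm^2 dmol^-1 per peptide bond
DELTA_EPSILON = "delta_epsilon"                    # M^-1 cm^-1

UNITS = (MILLIDEGREES, MOLAR_ELLIPTICITY, MEAN_RESIDUE_ELLIPTICITY, DELTA_EPSILON)

#: Two grids are "identical" when they agree pointwise to this absolute tolerance (nm).
GRID_ATOL = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """One spectral scan: ascending wavelength grid, values, unit tag, metadata.

    Parameters
    ----------
    wavelengths
        Wavelength grid in nm.  Stored strictly ascending; constructors and
        readers normalize descending input order.
    values
        Signal at each grid point, in the unit named by ``unit``.
    unit
        One of :data:`UNITS`.
    meta
        Free-form acquisition annotations (scan count, header lines, region).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = MILLIDEGREES
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValidationError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        if wl.size > 1:
            d = np.diff(wl)
            if np.all(d < 0):          # descending scan order: normalize
                wl, vals = wl[::-1], vals[::-1]
                d = -d
            if np.any(d <= 0):
                raise ValidationError("wavelength grid must be strictly monotonic")
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new values (and optionally a new unit tag)."""
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.wavelengths, np.asarray(values, float),
                        unit if unit is not None else self.unit, meta)

    def value_at(self, wavelength: float) -> float:
        """Signal at ``wavelength``: exact grid point if one lies within
        :data:`GRID_ATOL`, otherwise linear interpolation inside the support."""
        wl = self.wavelengths
        if wavelength < wl[0] - GRID_ATOL or wavelength > wl[-1] + GRID_ATOL:
            raise RangeError(
                f"{wavelength} nm outside spectral support [{wl[0]}, {wl[-1]}]")
        i = int(np.argmin(np.abs(wl - wavelength)))
        if abs(wl[i] - wavelength) <= GRID_ATOL:
            return float(self.values[i])
        return float(np.interp(wavelength, wl, self.values))


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata needed for calibration and normalization.

    protein_conc is carried in mol/L throughout the package; mM and µM exist
    only at the I/O boundary.  ``n_bonds`` is the peptide-bond count used for
    mean-residue conversion; ``label_ratio`` the chromophore:protein labeling
    stoichiometry (Ru per protein, from elemental analysis).
    """

    protein_conc: float            # mol/L
    pathlength: float              # cm
    n_bonds: int | None = None     # peptide bonds
    label_ratio: float | None = None
    region: str = ""

    def __post_init__(self):
        if not self.protein_conc > 0:
            raise ValidationError("protein_conc must be > 0 (mol/L)")
        if not self.pathlength > 0:
            raise ValidationError("pathlength must be > 0 (cm)")
        if self.n_bonds is not None and self.n_bonds < 1:
            raise ValidationError("n_bonds must be >= 1")
        if self.label_ratio is not None and not (0 < self.label_ratio <= 1.2):
            raise ValidationError("label_ratio must lie in (0, 1.2]")


def same_grid(a: Spectrum, b: Spectrum) -> bool:
    """True when the two grids agree pointwise within GRID_ATOL."""
    return len(a) == len(b) and bool(
        np.allclose(a.wavelengths, b.wavelengths, rtol=0.0, atol=GRID_ATOL))


def _require_compatible(a: Spectrum, b: Spectrum) -> None:
    if a.unit != b.unit:
        raise UnitError(f"unit mismatch: {a.unit} vs {b.unit}")
    if not same_grid(a, b):
        raise AlignmentError("wavelength grids differ; resample explicitly first")


def average_scans(scans: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of repeated scans (instrument practice: average of 3).

    All scans must share grid and unit; the result records the scan count.
    """
    scans = list(scans)
    if not scans:
        raise ValidationError("average_scans needs at least one spectrum")
    first = scans[0]
    for s in scans[1:]:
        _require_compatible(first, s)
    # per-wavelength sort before summation makes the mean exactly
    # permutation-invariant despite floating-point non-associativity
    stacked = np.sort(np.stack([s.values for s in scans]), axis=0)
    mean = stacked.sum(axis=0) / len(scans)
    return first.with_values(mean, scan_count=len(scans))


def subtract(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a − b (sample minus buffer background, conjugate minus parent)."""
    _require_compatible(a, b)
    return a.with_values(a.values - b.values)


def add(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a + b under the same compatibility rules as :func:`subtract`."""
    _require_compatible(a, b)
    return a.with_values(a.values + b.values)


def scale(a: Spectrum, factor: float) -> Spectrum:
    """Pointwise multiplication by a scalar; unit tag unchanged."""
    return a.with_values(a.values * factor)


def resample(s: Spectrum, grid: Iterable[float], method: str = "linear") -> Spectrum:
    """Linear interpolation of ``s`` onto ``grid``; extrapolation is refused."""
    if method != "linear":
        raise ValidationError(f"unsupported resampling method {method!r}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("empty target grid")
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    if grid.min() < lo - GRID_ATOL or grid.max() > hi + GRID_ATOL:
        raise RangeError(
            f"target grid [{grid.min()}, {grid.max()}] outside support [{lo}, {hi}]")
    vals = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, vals, s.unit, {**s.meta, "resampled": True})


# ---------------------------------------------------------------------------
# file I/O — two instrument-style text dialects

def read_spectrum(path, dialect: str | None = None, unit: str = MILLIDEGREES) -> Spectrum:
    """Read a two-column wavelength/signal file.

    ``dialect`` is ``two_column_text`` (whitespace- or comma-separated
    numbers, '#'-prefixed comment/header lines kept in ``meta``) or ``csv``
    (named columns ``wavelength,signal``).  Omitted, it is inferred from the
    extension (.csv → csv).  Rows may arrive in descending scan order; the
    returned grid is always ascending.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "two_column_text"

    if dialect == "csv":
        import pandas as pd
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        for col in ("wavelength", "signal"):
            if col not in df.columns:
                raise FormatError(f"{path}: csv dialect needs columns wavelength,signal")
        wl = df["wavelength"].to_numpy(float)
        vals = df["signal"].to_numpy(float)
        headers: list[str] = []
    elif dialect == "two_column_text":
        wl_list, val_list, headers = [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped:
                    continue
                if stripped.startswith("#"):
                    headers.append(stripped.lstrip("#").strip())
                    continue
                parts = stripped.replace(",", " ").split()
                try:
                    w, v = float(parts[0]), float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}: unparsable row at line {lineno}: "
                                      f"{stripped!r}") from exc
                wl_list.append(w)
                val_list.append(v)
        wl = np.asarray(wl_list)
        vals = np.asarray(val_list)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    if wl.size < 2:
        raise FormatError(f"{path}: fewer than 2 parsable numeric rows")
    if np.unique(wl).size != wl.size:
        raise ValidationError(f"{path}: duplicate wavelengths in input")
    order = np.argsort(wl)
    meta = {"source": str(path)}
    if headers:
        meta["header_lines"] = headers
    return Spectrum(wl[order], vals[order], unit, meta)


def write_spectrum(s: Spectrum, path, dialect: str | None = None) -> None:
    """Write ``s`` in a dialect :func:`read_spectrum` reads back losslessly.

    Values are serialized with repr-level (17 significant digit) precision so
    a write/read round trip preserves grid and values bit for bit.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "two_column_text"
    if dialect == "csv":
        lines = ["wavelength,signal"]
        lines += [f"{w:.17g},{v:.17g}" for w, v in zip(s.wavelengths, s.values)]
    elif dialect == "two_column_text":
        lines = [f"# unit: {s.unit}"]
        for key in ("scan_count", "region"):
            if key in s.meta:
                lines.append(f"# {key}: {s.meta[key]}")
        lines += [f"{w:.17g}  {v:.17g}" for w, v in zip(s.wavelengths, s.values)]
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")
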