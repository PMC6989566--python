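"""Per-frame minimum contact distances between atom sets in a trajectory.

The distance of closest approach between the aromatic atoms of a bound
photosensitizer and those of the nearest heme cofactor is a per-frame proxy
for donor–acceptor electronic coupling.  This module reads multi-frame
coordinate files (multi-MODEL PDB or concatenated XYZ, via MDAnalysis),
computes the exact minimum over all cross pairs of two user-supplied atom
selections in every frame, and summarizes the series (mean, sample SD,
threshold-based conformer split).

Selections are explicit atom-id lists — no automatic aromaticity perception;
hydrogens are excluded by element symbol (atom-name leading character when no
element column exists).  Coordinates are assumed pre-imaged (no periodic
boundary handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class Trajectory:
    """Multi-frame Cartesian coordinates with stable atom identities.

    coords : (n_frames, n_atoms, 3) array, Å.
    names / elements : per-atom labels, constant across frames.
    times : per-frame time stamps, ps.
    """

    coords: np.ndarray
    names: tuple[str, ...]
    elements: tuple[str, ...]
    times: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] == 0:
            raise ValidationError("trajectory has zero frames")
        n_atoms = coords.shape[1]
        if len(self.names) != n_atoms or len(self.elements) != n_atoms:
            raise ValidationError("names/elements length must equal atom count")
        times = np.asarray(self.times, dtype=float)
        if times.size != coords.shape[0]:
            raise ValidationError("times length must equal frame count")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "times", times)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class AtomSelection:
    """Named set of atom indices with an element filter.

    ``element_filter`` keeps only the listed element symbols; when None
    (default) hydrogens are excluded, matching the non-hydrogen contact
    convention.
    """

    name: str
    atom_ids: tuple[int, ...]
    element_filter: frozenset[str] | None = None

    def __post_init__(self):
        ids = tuple(int(i) for i in self.atom_ids)
        if not ids:
            raise ValidationError(f"selection {self.name!r} is empty")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"selection {self.name!r} has duplicate atom ids")
        object.__setattr__(self, "atom_ids", ids)
        if self.element_filter is not None:
            object.__setattr__(self, "element_filter",
                               frozenset(e.upper() for e in self.element_filter))

    def resolve(self, traj: Trajectory) -> np.ndarray:
        """Indices into ``traj`` after element filtering; errors if empty."""
        for i in self.atom_ids:
            if not 0 <= i < traj.n_atoms:
                raise ValidationError(
                    f"selection {self.name!r}: atom id {i} not resolvable "
                    f"(trajectory has {traj.n_atoms} atoms)")
        ids = np.asarray(self.atom_ids, dtype=int)
        elements = np.asarray([traj.elements[i].upper() for i in ids])
        if self.element_filter is not None:
            keep = np.isin(elements, sorted(self.element_filter))
        else:
            keep = elements != "H"
        ids = ids[keep]
        if ids.size == 0:
            raise ValidationError(
                f"selection {self.name!r} empty after element filtering")
        return ids


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame minimum inter-set distance with summary statistics."""

    frame_times: np.ndarray        # ps
    min_distances: np.ndarray      # Å
    pair_ids: tuple[tuple[int, int], ...]
    mean: float
    sd: float                      # sample (n-1) SD; 0 for a single frame

    def __len__(self) -> int:
        return self.min_distances.size


@dataclass(frozen=True)
class SubsetSummary:
    n_frames: int
    occupancy: float
    mean: float | None
    sd: float | None


@dataclass(frozen=True)
class ConformerSplit:
    threshold: float
    proximal: SubsetSummary        # min distance < threshold
    distal: SubsetSummary          # min distance >= threshold
    proximal_mask: np.ndarray = field(repr=False)
    empty_subset: bool = False


def _element_from_name(name: str) -> str:
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_trajectory(path, dialect: str | None = None, dt: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB or concatenated-XYZ trajectory.

    ``dialect`` ∈ {multi_model_pdb, xyz_frames}; inferred from the extension
    when omitted.  ``dt`` (ps) spaces the synthesized frame times.  The atom
    count must be constant across frames (MDAnalysis enforces this).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "xyz_frames" if path.suffix.lower() == ".xyz" else "multi_model_pdb"
    fmt = {"multi_model_pdb": "PDB", "xyz_frames": "XYZ"}.get(dialect)
    if fmt is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, topology_format=fmt)
            coords = np.array([u.atoms.positions.copy().astype(float)
                               for _ in u.trajectory])
            names = tuple(str(n) for n in u.atoms.names)
            try:
                elements = tuple(str(e).upper() if str(e).strip() else
                                 _element_from_name(n)
                                 for e, n in zip(u.atoms.elements, names))
            except Exception:
                elements = tuple(_element_from_name(n) for n in names)
    except (ValidationError, FormatError):
        raise
    except Exception as exc:
        raise FormatError(f"{path}: could not parse as {dialect}: {exc}") from exc
    if coords.shape[0] == 0:
        raise ValidationError(f"{path}: zero frames")
    times = np.arange(coords.shape[0], dtype=float) * dt
    return Trajectory(coords, names, elements, times)


def write_trajectory(traj: Trajectory, path, dialect: str | None = None) -> None:
    """Write a trajectory as multi-MODEL PDB or concatenated XYZ.

    PDB stores coordinates at 0.001 Å precision; XYZ at higher precision.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    if dialect is None:
        dialect = "xyz_frames" if path.suffix.lower() == ".xyz" else "multi_model_pdb"
    if dialect not in ("multi_model_pdb", "xyz_frames"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, n_residues=1,
                               atom_resindex=np.zeros(traj.n_atoms, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", list(traj.names))
        u.add_TopologyAttr("elements", [e.capitalize() for e in traj.elements])
        u.add_TopologyAttr("resnames", ["MOL"])
        u.add_TopologyAttr("resids", [1])
        u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def min_distance_series(traj: Trajectory, a: AtomSelection, b: AtomSelection,
                        skip_frames: int = 0) -> DistanceSeries:
    """Per-frame minimum Euclidean distance over all cross pairs of a × b.

    ``skip_frames`` discards an equilibration prefix before the statistics.
    The realizing atom pair is recorded per frame.  Selections must be
    disjoint (a shared atom would make the minimum trivially zero).
    """
    if set(a.atom_ids) & set(b.atom_ids):
        raise ValidationError("selections overlap; minimum distance is ambiguous")
    ia, ib = a.resolve(traj), b.resolve(traj)
    if skip_frames < 0 or skip_frames >= traj.n_frames:
        raise ValidationError("skip_frames must leave at least one frame")
    coords = traj.coords[skip_frames:]
    times = traj.times[skip_frames:]
    minima = np.empty(coords.shape[0])
    pairs = []
    for k, frame in enumerate(coords):
        d = cdist(frame[ia], frame[ib])
        flat = int(np.argmin(d))
        i, j = np.unravel_index(flat, d.shape)
        minima[k] = d[i, j]
        pairs.append((int(ia[i]), int(ib[j])))
    mean = float(np.mean(minima))
    sd = float(np.std(minima, ddof=1)) if minima.size > 1 else 0.0
    return DistanceSeries(frame_times=times, min_distances=minima,
                          pair_ids=tuple(pairs), mean=mean, sd=sd)


def _summarize(values: np.ndarray, total: int) -> SubsetSummary:
    n = values.size
    if n == 0:
        return SubsetSummary(0, 0.0, None, None)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return SubsetSummary(n, n / total, float(np.mean(values)), sd)


def conformer_split(series: DistanceSeries, threshold: float) -> ConformerSplit:
    """Partition frames at a distance threshold into proximal/distal conformers.

    Frames with minimum distance strictly below the threshold are proximal.
    A threshold outside the observed range yields one empty subset, flagged
    rather than raised.
    """
    d = series.min_distances
    mask = d < threshold
    prox = _summarize(d[mask], d.size)
    dist = _summarize(d[~mask], d.size)
    return ConformerSplit(threshold=threshold, proximal=prox, distal=dist,
                          proximal_mask=mask,
                          empty_subset=(prox.n_frames == 0 or dist.n_frames == 0))
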