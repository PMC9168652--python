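"""Contact geometry of the P450 active site.

The "butterfly" analysis tracks four atoms across a trajectory: the
Compound I (Cpd I) ferryl oxygen, the heme iron, and the two vinyl
carbons of the styrene substrate — C8 (position 1, the carbon attacked
by the oxygen in the anti-Markovnikov pathway) and C7 (position 2).
Per frame we compute the two carbon–oxygen distances and the two
near-attack-configuration (NAC) angles C–O–Fe with the vertex at the
oxygen.

Units are Å and degrees throughout.  Periodic boundary conditions are
deliberately not applied: all four atoms sit in a single binding
pocket, so the minimum-image convention is irrelevant for these
intramolecular-scale distances.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

import numpy as np

__all__ = [
    "AtomRef",
    "SiteSelection",
    "Trajectory",
    "ContactGeometry",
    "GeometrySeries",
    "SelectionError",
    "EmptyTrajectoryError",
    "GeometryDomainError",
    "read_trajectory",
    "distance",
    "nac_angle",
    "compute_contact_geometry",
]

#: Atom identifier: integer index (XYZ and other name-less formats) or a
#: "CHAIN:RESID:NAME" string (PDB-like formats).
AtomRef = Union[int, str]

SITE_ORDER = ("o_cpd", "fe", "c7", "c8")


class SelectionError(ValueError):
    """An atom reference did not resolve to exactly one atom."""


class EmptyTrajectoryError(ValueError):
    """A trajectory source contained zero frames."""


class GeometryDomainError(ValueError):
    """Geometrically invalid input (non-finite coordinates, zero-length ray)."""


@dataclass(frozen=True)
class SiteSelection:
    """The four tracked atoms of the butterfly model.

    Parameters
    ----------
    o_cpd : AtomRef
        Cpd I ferryl oxygen.
    fe : AtomRef
        Heme iron.
    c7 : AtomRef
        Substrate position-2 vinyl carbon.
    c8 : AtomRef
        Substrate position-1 vinyl carbon (the reactive site).

    String references have the form ``"CHAIN:RESID:NAME"``; integer
    references are 0-based atom indices.
    """

    o_cpd: AtomRef
    fe: AtomRef
    c7: AtomRef
    c8: AtomRef

    def __post_init__(self) -> None:
        refs = [self.o_cpd, self.fe, self.c7, self.c8]
        if len({repr(r) for r in refs}) != 4:
            raise SelectionError(f"the four site references must be distinct, got {refs}")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in SITE_ORDER}


@dataclass
class Trajectory:
    """Site-resolved trajectory: coordinates of the four tracked atoms.

    ``sites`` has shape ``(n_frames, 4, 3)`` in Å, with the second axis
    ordered (o_cpd, fe, c7, c8).
    """

    sites: np.ndarray
    dt_ps: float = 7.5
    label: str = ""

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float)
        if self.sites.ndim != 3 or self.sites.shape[1:] != (4, 3):
            raise ValueError(f"sites must have shape (n_frames, 4, 3), got {self.sites.shape}")
        if self.n_frames < 1:
            raise EmptyTrajectoryError("trajectory must contain at least one frame")
        if not self.dt_ps > 0:
            raise ValueError(f"dt_ps must be positive, got {self.dt_ps}")

    @property
    def n_frames(self) -> int:
        return self.sites.shape[0]

    @property
    def duration_ns(self) -> float:
        """Time span covered at the snapshot cadence, in ns."""
        return self.n_frames * self.dt_ps / 1000.0

    @classmethod
    def from_sites(cls, o, fe, c7, c8, dt_ps: float = 7.5, label: str = "") -> "Trajectory":
        """Build a trajectory from per-site coordinate arrays of shape (n, 3) or (3,)."""
        arrs = [np.atleast_2d(np.asarray(x, dtype=float)) for x in (o, fe, c7, c8)]
        n = arrs[0].shape[0]
        if any(a.shape != (n, 3) for a in arrs):
            raise ValueError("site arrays must all have shape (n_frames, 3)")
        return cls(np.stack(arrs, axis=1), dt_ps=dt_ps, label=label)

    def concat(self, other: "Trajectory") -> "Trajectory":
        if other.dt_ps != self.dt_ps:
            raise ValueError("cannot concatenate trajectories with different dt_ps")
        return Trajectory(np.concatenate([self.sites, other.sites]), dt_ps=self.dt_ps, label=self.label)


class ContactGeometry(NamedTuple):
    """Per-frame butterfly coordinates: distances in Å, NAC angles in degrees."""

    d7: float
    d8: float
    a7: float
    a8: float


@dataclass
class GeometrySeries:
    """Vectorised sequence of :class:`ContactGeometry` records (one per frame)."""

    d7: np.ndarray
    d8: np.ndarray
    a7: np.ndarray
    a8: np.ndarray
    dt_ps: float = 7.5
    label: str = ""

    def __post_init__(self) -> None:
        self.d7, self.d8, self.a7, self.a8 = (
            np.asarray(a, dtype=float).ravel() for a in (self.d7, self.d8, self.a7, self.a8)
        )
        n = len(self.d7)
        if not all(len(a) == n for a in (self.d8, self.a7, self.a8)):
            raise ValueError("d7, d8, a7, a8 must have equal length")

    def __len__(self) -> int:
        return len(self.d7)

    def __getitem__(self, i) -> ContactGeometry:
        if isinstance(i, slice):
            return GeometrySeries(self.d7[i], self.d8[i], self.a7[i], self.a8[i], self.dt_ps, self.label)
        return ContactGeometry(self.d7[i], self.d8[i], self.a7[i], self.a8[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def duration_ns(self) -> float:
        return len(self) * self.dt_ps / 1000.0

    @classmethod
    def from_frames(cls, frames: Iterable[ContactGeometry], dt_ps: float = 7.5, label: str = "") -> "GeometrySeries":
        fr = list(frames)
        if not fr:
            raise ValueError("empty frame list")
        arr = np.asarray(fr, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], dt_ps=dt_ps, label=label)

    def concat(self, other: "GeometrySeries") -> "GeometrySeries":
        return GeometrySeries(
            np.concatenate([self.d7, other.d7]),
            np.concatenate([self.d8, other.d8]),
            np.concatenate([self.a7, other.a7]),
            np.concatenate([self.a8, other.a8]),
            dt_ps=self.dt_ps,
            label=self.label,
        )


def distance(p, q) -> float:
    """Euclidean distance between two points, in Å."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise GeometryDomainError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def nac_angle(c, o, fe) -> float:
    """Near-attack-configuration angle C–O–Fe (vertex at the oxygen), degrees in [0, 180]."""
    c = np.asarray(c, dtype=float)
    o = np.asarray(o, dtype=float)
    fe = np.asarray(fe, dtype=float)
    if not all(np.all(np.isfinite(x)) for x in (c, o, fe)):
        raise GeometryDomainError("coordinates must be finite")
    v1 = c - o
    v2 = fe - o
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryDomainError("zero-length ray: the vertex atom coincides with an endpoint")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_contact_geometry(traj: Trajectory) -> GeometrySeries:
    """Compute per-frame distances d(C7–O), d(C8–O) and NAC angles C7/C8–O–Fe.

    Returns one record per frame, in frame order.  Raises
    :class:`GeometryDomainError` naming the (0-based) frame index on
    degenerate geometry.
    """
    o = traj.sites[:, 0]
    fe = traj.sites[:, 1]
    c7 = traj.sites[:, 2]
    c8 = traj.sites[:, 3]
    if not np.all(np.isfinite(traj.sites)):
        bad = int(np.argwhere(~np.isfinite(traj.sites).all(axis=(1, 2)))[0, 0])
        raise GeometryDomainError(f"non-finite coordinates in frame {bad}")
    v7 = c7 - o
    v8 = c8 - o
    vfe = fe - o
    d7 = np.linalg.norm(v7, axis=1)
    d8 = np.linalg.norm(v8, axis=1)
    dfe = np.linalg.norm(vfe, axis=1)
    for name, norms in (("c7", d7), ("c8", d8), ("fe", dfe)):
        if np.any(norms == 0.0):
            bad = int(np.argmin(norms))
            raise GeometryDomainError(f"zero-length {name}–o_cpd ray in frame {bad}")
    a7 = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", v7, vfe) / (d7 * dfe), -1.0, 1.0)))
    a8 = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", v8, vfe) / (d8 * dfe), -1.0, 1.0)))
    return GeometrySeries(d7, d8, a7, a8, dt_ps=traj.dt_ps, label=traj.label)


# ---------------------------------------------------------------------------
# File reading (MDAnalysis-backed)

_FORMAT_ALIASES = {
    ".pdb": "pdb",
    ".xyz": "xyz",
    ".dcd": "dcd",
    ".xtc": "xtc",
}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _FORMAT_ALIASES:
        raise ValueError(f"cannot infer trajectory format from extension {ext!r}; pass format=")
    return _FORMAT_ALIASES[ext]


def _resolve_ref(universe, ref: AtomRef) -> int:
    """Resolve one atom reference against an MDAnalysis universe to an atom index."""
    atoms = universe.atoms
    n = len(atoms)
    if isinstance(ref, (int, np.integer)):
        i = int(ref)
        if not 0 <= i < n:
            raise SelectionError(f"atom index {i} out of range for {n} atoms")
        return i
    try:
        chain, resid_s, name = str(ref).split(":")
        resid = int(resid_s)
    except ValueError as exc:
        raise SelectionError(
            f"malformed atom reference {ref!r}; expected 'CHAIN:RESID:NAME' or an integer index"
        ) from exc
    names = np.asarray(getattr(atoms, "names", np.array([""] * n)))
    resids = np.asarray(getattr(atoms, "resids", np.zeros(n, dtype=int)))
    chains = np.asarray(getattr(atoms, "chainIDs", np.array([""] * n)))
    segids = np.asarray(getattr(atoms, "segids", np.array([""] * n)))
    mask = (names == name) & (resids == resid) & ((chains == chain) | (segids == chain))
    hits = np.flatnonzero(mask)
    if len(hits) == 0:
        raise SelectionError(f"no atom matches {ref!r}")
    if len(hits) > 1:
        raise SelectionError(f"{ref!r} matches {len(hits)} atoms; references must be unique")
    return int(hits[0])


def read_trajectory(
    path,
    selection: SiteSelection,
    format: str | None = None,
    dt_ps: float = 7.5,
    label: str | None = None,
) -> Trajectory:
    """Read a trajectory file and resolve the four tracked atoms.

    Multi-model PDB (MODEL/ENDMDL) and XYZ are the supported text
    formats; DCD/XTC work through the same contract when a companion
    topology is unnecessary (atom references must then be integer
    indices).  Frame order is preserved.  ``dt_ps`` is the snapshot
    cadence (these formats do not carry a reliable time axis).
    """
    import MDAnalysis as mda

    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # zero-model / unparsable files
        raise EmptyTrajectoryError(f"could not read any frame from {path}: {exc}") from exc
    idx = [_resolve_ref(u, getattr(selection, k)) for k in SITE_ORDER]
    if len(set(idx)) != 4:
        raise SelectionError(f"site references resolve to non-distinct atoms {idx}")
    frames = [u.atoms.positions[idx].astype(float).copy() for _ in u.trajectory]
    if not frames:
        raise EmptyTrajectoryError(f"{path} contains zero frames")
    return Trajectory(np.stack(frames), dt_ps=dt_ps, label=label if label is not None else os.path.basename(str(path)))
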