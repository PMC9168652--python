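"""Simplified MM-GBSA per-residue decomposition of ligand binding energy.

For each receptor residue the ligand interaction is split into four
terms, per frame, then averaged:

* ``VDW`` — Lennard-Jones 12-6 with Lorentz–Berthelot combination,
* ``ELE`` — Coulomb with the interior dielectric,
* ``GB``  — generalized Born cross terms (OBC effective radii computed
  on the complex) with Debye–Hückel salt screening,
* ``NP``  — nonpolar solvation as surface tension times the residue's
  share of the ligand's buried SASA (nearest-residue assignment).

``Tot`` is their sum; summed over residues it equals the direct
ligand–receptor interaction plus GB cross-term total by construction
(no double counting, no entropy term).  This module reproduces the
*method* — its structure, conservation and ranking behaviour — not any
particular published table, which would require the original
force-field topology and trajectories.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sasa import shrake_rupley

__all__ = [
    "COULOMB_CONSTANT",
    "GBSettings",
    "ParameterizedStructure",
    "ResidueEnergyRow",
    "DecompositionResult",
    "AlanineCandidate",
    "Atom",
    "pairwise_nonbonded_energy",
    "effective_born_radii",
    "gb_cross_energy",
    "per_residue_decomposition",
    "average_decompositions",
    "rank_alanine_candidates",
]

#: Conversion e^2/Å -> kcal/mol.
COULOMB_CONSTANT = 332.0637

#: OBC tanh-rescaling parameter sets (alpha, beta, gamma).
OBC_I = (0.8, 0.0, 2.909125)   # Amber igb=2
OBC_II = (1.0, 0.8, 4.85)      # Amber igb=5


@dataclass(frozen=True)
class GBSettings:
    """Generalized Born / surface-area settings.

    Defaults follow the analysis protocol: interior dielectric 3.0,
    solvent dielectric 78.5, ionic strength 0.1 mol/L, OBC model I
    radii rescaling, surface tension 0.0005 kcal mol^-1 Å^-2.
    """

    interior_dielectric: float = 3.0
    solvent_dielectric: float = 78.5
    ionic_strength: float = 0.1
    obc_parameters: tuple = OBC_I
    surface_tension: float = 0.0005
    probe_radius: float = 1.4
    gb_offset: float = 0.09
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def kappa(self) -> float:
        """Debye screening constant, Å^-1 (aqueous, 25 °C)."""
        return float(np.sqrt(0.10806 * self.ionic_strength))

    @classmethod
    def obc1(cls, **kw) -> "GBSettings":
        return cls(obc_parameters=OBC_I, **kw)

    @classmethod
    def obc2(cls, **kw) -> "GBSettings":
        return cls(obc_parameters=OBC_II, **kw)


class Atom(NamedTuple):
    """A single parameterised atom for pairwise energy evaluation."""

    position: tuple
    charge: float
    rmin_half: float
    epsilon: float


@dataclass
class ParameterizedStructure:
    """Coordinates plus the per-atom parameters the decomposition needs.

    ``rmin_half`` is the LJ r_min/2 (Å), ``epsilon`` the LJ well depth
    (kcal/mol), ``gb_radius`` the intrinsic GB radius (Å), ``screen``
    the HCT descreening scale factor.  ``is_ligand`` marks the ligand
    atoms, which must form exactly one residue.
    """

    coords: np.ndarray
    charges: np.ndarray
    rmin_half: np.ndarray
    epsilon: np.ndarray
    gb_radius: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    is_ligand: np.ndarray
    screen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        self.charges = np.asarray(self.charges, dtype=float)
        self.rmin_half = np.asarray(self.rmin_half, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.gb_radius = np.asarray(self.gb_radius, dtype=float)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        if self.screen is None:
            self.screen = np.full(n, 0.8)
        else:
            self.screen = np.asarray(self.screen, dtype=float)
        for name in ("charges", "rmin_half", "epsilon", "gb_radius", "resid", "resname", "is_ligand", "screen"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match {n} atoms")
        if np.any(self.gb_radius <= 0) or np.any(self.rmin_half <= 0):
            raise ValueError("LJ and GB radii must be positive")
        lig = np.flatnonzero(self.is_ligand)
        if lig.size and len(set(self.resid[lig])) != 1:
            raise ValueError("ligand atoms must form exactly one residue")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_label(self, atom_index: int) -> str:
        return f"{self.resid[atom_index]}{self.resname[atom_index]}"

    def with_coords(self, coords: np.ndarray) -> "ParameterizedStructure":
        """A new frame sharing this topology."""
        return ParameterizedStructure(
            np.asarray(coords, dtype=float), self.charges, self.rmin_half, self.epsilon,
            self.gb_radius, self.resid, self.resname, self.is_ligand, self.screen,
        )

    _COLUMNS = ["x", "y", "z", "charge", "rmin_half", "epsilon", "gb_radius", "screen",
                "resid", "resname", "ligand"]

    @classmethod
    def from_table(cls, path) -> "ParameterizedStructure":
        """Read the flat one-atom-per-row TSV format."""
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in cls._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"structure table missing columns {missing}")
        return cls(
            df[["x", "y", "z"]].to_numpy(), df["charge"].to_numpy(), df["rmin_half"].to_numpy(),
            df["epsilon"].to_numpy(), df["gb_radius"].to_numpy(), df["resid"].to_numpy(),
            df["resname"].to_numpy(dtype=object), df["ligand"].to_numpy(dtype=bool),
            df["screen"].to_numpy(),
        )

    def to_table(self, path) -> None:
        df = pd.DataFrame({
            "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2],
            "charge": self.charges, "rmin_half": self.rmin_half, "epsilon": self.epsilon,
            "gb_radius": self.gb_radius, "screen": self.screen,
            "resid": self.resid, "resname": self.resname, "ligand": self.is_ligand.astype(int),
        })
        df.to_csv(path, sep="\t", index=False)


class PairEnergy(NamedTuple):
    vdw: float
    ele: float


def pairwise_nonbonded_energy(a1: Atom, a2: Atom, settings: GBSettings) -> PairEnergy:
    """LJ 12-6 (Lorentz–Berthelot) and screened Coulomb for one atom pair, kcal/mol."""
    p1 = np.asarray(a1.position, dtype=float)
    p2 = np.asarray(a2.position, dtype=float)
    r = float(np.linalg.norm(p1 - p2))
    if r == 0.0:
        raise ValueError("coincident atoms (r = 0)")
    rmin = a1.rmin_half + a2.rmin_half
    eps = np.sqrt(a1.epsilon * a2.epsilon)
    s6 = (rmin / r) ** 6
    vdw = eps * (s6 * s6 - 2.0 * s6)
    ele = COULOMB_CONSTANT * a1.charge * a2.charge / (settings.interior_dielectric * r)
    return PairEnergy(float(vdw), float(ele))


def _hct_integral(r: np.ndarray, rho_i: np.ndarray, s_j: np.ndarray) -> np.ndarray:
    """Hawkins–Cramer–Truhlar pairwise descreening integral (broadcasting, Å^-1)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        U = r + s_j
        L = np.maximum(rho_i, np.abs(r - s_j))
        I = 0.5 * (
            1.0 / L - 1.0 / U
            + 0.25 * (1.0 / U**2 - 1.0 / L**2) * (r - s_j**2 / r)
            + 0.5 * np.log(L / U) / r
        )
        # atom i fully inside the descreening sphere of j
        inside = rho_i < (s_j - r)
        I = I + np.where(inside, 1.0 / rho_i - 1.0 / L, 0.0)
        # neighbour sphere fully engulfed by atom i: no descreening
        I = np.where(U <= rho_i, 0.0, I)
    return I


def effective_born_radii(structure: ParameterizedStructure, settings: GBSettings) -> np.ndarray:
    """OBC effective Born radii for every atom, Å.

    Reduced radii rho_i = R_i - offset; the pairwise HCT descreening sum
    Psi = rho_i * sum_j I_ij enters the tanh rescaling
    ``1/R_eff = 1/rho_i - tanh(a Psi - b Psi^2 + c Psi^3) / R_i``.
    An isolated atom's effective radius is its reduced radius.
    """
    R = structure.gb_radius
    rho = R - settings.gb_offset
    if np.any(rho <= 0):
        raise ValueError("intrinsic GB radius must exceed the offset")
    x = structure.coords
    n = len(x)
    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    s_j = (structure.screen * rho)[None, :]
    I = _hct_integral(np.where(r == 0.0, np.inf, r), rho[:, None], s_j)
    np.fill_diagonal(I, 0.0)
    psi = rho * I.sum(axis=1)
    a, b, g = settings.obc_parameters
    inv = 1.0 / rho - np.tanh(a * psi - b * psi**2 + g * psi**3) / R
    if np.any(inv <= 0):
        raise ValueError("non-positive inverse effective radius; check input radii")
    return 1.0 / inv


def gb_cross_energy(q1, q2, r, R1, R2, settings: GBSettings):
    """Generalized Born pair (cross) energy with Debye–Hückel salt screening, kcal/mol.

    ``f_GB = sqrt(r^2 + R1 R2 exp(-r^2 / (4 R1 R2)))``;
    ``E = -k q1 q2 (1/eps_in - exp(-kappa f_GB)/eps_solv) / f_GB``.
    As ionic strength -> 0 and r -> infinity this tends to the Coulomb
    screening limit ``-(1/eps_in - 1/eps_solv) k q1 q2 / r``.
    """
    r = np.asarray(r, dtype=float)
    RR = np.asarray(R1, dtype=float) * np.asarray(R2, dtype=float)
    f = np.sqrt(r**2 + RR * np.exp(-(r**2) / (4.0 * RR)))
    pref = 1.0 / settings.interior_dielectric - np.exp(-settings.kappa * f) / settings.solvent_dielectric
    return -COULOMB_CONSTANT * np.asarray(q1) * np.asarray(q2) * pref / f


@dataclass
class ResidueEnergyRow:
    """One residue's mean ± sd binding-energy contribution, kcal/mol."""

    residue: str
    vdw: float
    ele: float
    gb: float
    np_: float
    tot: float
    vdw_sd: float = 0.0
    ele_sd: float = 0.0
    gb_sd: float = 0.0
    np_sd: float = 0.0
    tot_sd: float = 0.0


@dataclass
class DecompositionResult:
    """Per-residue rows (sorted most-binding first) plus the receptor-total 'All' row."""

    rows: list[ResidueEnergyRow]
    all_row: ResidueEnergyRow
    n_frames: int = 1

    def to_frame(self) -> pd.DataFrame:
        recs = self.rows + [self.all_row]
        return pd.DataFrame(
            {
                "residue": [r.residue for r in recs],
                "vdw": [r.vdw for r in recs], "vdw_sd": [r.vdw_sd for r in recs],
                "ele": [r.ele for r in recs], "ele_sd": [r.ele_sd for r in recs],
                "gb": [r.gb for r in recs], "gb_sd": [r.gb_sd for r in recs],
                "np": [r.np_ for r in recs], "np_sd": [r.np_sd for r in recs],
                "tot": [r.tot for r in recs], "tot_sd": [r.tot_sd for r in recs],
            }
        )


def _frame_terms(structure: ParameterizedStructure, settings: GBSettings):
    """Per-residue (vdw, ele, gb, np) sums for one frame, keyed by residue label."""
    lig = np.flatnonzero(structure.is_ligand)
    rec = np.flatnonzero(~structure.is_ligand)
    if lig.size == 0:
        raise ValueError("structure contains no ligand atoms")
    if rec.size == 0:
        raise ValueError("structure contains no receptor atoms")
    x = structure.coords
    diff = x[lig][:, None, :] - x[rec][None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r == 0.0):
        raise ValueError("coincident ligand/receptor atoms")
    rmin = structure.rmin_half[lig][:, None] + structure.rmin_half[rec][None, :]
    eps = np.sqrt(structure.epsilon[lig][:, None] * structure.epsilon[rec][None, :])
    s6 = (rmin / r) ** 6
    vdw = eps * (s6 * s6 - 2.0 * s6)
    qq = structure.charges[lig][:, None] * structure.charges[rec][None, :]
    ele = COULOMB_CONSTANT * qq / (settings.interior_dielectric * r)
    born = effective_born_radii(structure, settings)
    gb = gb_cross_energy(
        structure.charges[lig][:, None], structure.charges[rec][None, :],
        r, born[lig][:, None], born[rec][None, :], settings,
    )

    # residue bookkeeping over receptor atoms
    labels = [structure.residue_label(i) for i in rec]
    uniq: dict[str, int] = {}
    codes = np.array([uniq.setdefault(lab, len(uniq)) for lab in labels])
    n_res = len(uniq)
    per = {
        "vdw": np.bincount(codes, weights=vdw.sum(axis=0), minlength=n_res),
        "ele": np.bincount(codes, weights=ele.sum(axis=0), minlength=n_res),
        "gb": np.bincount(codes, weights=gb.sum(axis=0), minlength=n_res),
    }

    # nonpolar: ligand burial, assigned to the nearest receptor residue
    vdw_radii = structure.rmin_half  # LJ r_min/2 as the SASA radius
    sasa_complex = shrake_rupley(x, vdw_radii, settings.probe_radius, settings.sasa_points, subset=lig)
    sasa_alone = shrake_rupley(x[lig], vdw_radii[lig], settings.probe_radius, settings.sasa_points)
    burial = np.maximum(sasa_alone - sasa_complex, 0.0)
    # nearest-residue assignment; exact distance ties share the burial equally
    res_dist = np.full((len(lig), n_res), np.inf)
    np.minimum.at(res_dist.T, codes, r.T)
    np_acc = np.zeros(n_res)
    for li in range(len(lig)):
        tied = np.flatnonzero(res_dist[li] <= res_dist[li].min() + 1e-9)
        np_acc[tied] -= burial[li] / len(tied)
    per["np"] = settings.surface_tension * np_acc
    return list(uniq.keys()), per


def per_residue_decomposition(
    frames: Sequence[ParameterizedStructure],
    settings: GBSettings | None = None,
    frame_window: slice | None = None,
) -> DecompositionResult:
    """Decompose ligand binding energy per receptor residue, averaged over frames.

    ``frames`` share one topology (coordinates vary); ``frame_window``
    optionally restricts the averaging window (e.g. the tail of a
    production run).  Rows are sorted by total contribution ascending
    (most binding first); sd is the sample standard deviation over
    frames (0 for a single frame).
    """
    settings = settings or GBSettings()
    frames = list(frames)
    if frame_window is not None:
        frames = frames[frame_window]
    if not frames:
        raise ValueError("need at least one frame")
    n0 = frames[0].n_atoms
    if any(f.n_atoms != n0 for f in frames):
        raise ValueError("all frames must share one topology (atom-count mismatch)")

    labels0 = None
    acc: dict[str, list[np.ndarray]] = {k: [] for k in ("vdw", "ele", "gb", "np")}
    for f in frames:
        labels, per = _frame_terms(f, settings)
        if labels0 is None:
            labels0 = labels
        elif labels != labels0:
            raise ValueError("residue layout differs between frames")
        for k in acc:
            acc[k].append(per[k])
    stacked = {k: np.vstack(v) for k, v in acc.items()}  # (n_frames, n_res)
    tot = sum(stacked.values())
    ddof = 1 if len(frames) > 1 else 0

    def mean_sd(a):
        return a.mean(axis=0), (a.std(axis=0, ddof=ddof) if len(frames) > 1 else np.zeros(a.shape[1]))

    m = {k: mean_sd(v) for k, v in stacked.items()}
    tot_m, tot_sd = mean_sd(tot)
    rows = [
        ResidueEnergyRow(
            labels0[i],
            m["vdw"][0][i], m["ele"][0][i], m["gb"][0][i], m["np"][0][i], tot_m[i],
            m["vdw"][1][i], m["ele"][1][i], m["gb"][1][i], m["np"][1][i], tot_sd[i],
        )
        for i in range(len(labels0))
    ]
    rows.sort(key=lambda row: (row.tot, _resnum(row.residue)))

    frame_all = {k: v.sum(axis=1) for k, v in stacked.items()}  # (n_frames,)
    all_tot = sum(frame_all.values())
    all_row = ResidueEnergyRow(
        "All",
        *(float(frame_all[k].mean()) for k in ("vdw", "ele", "gb", "np")),
        float(all_tot.mean()),
        *(float(frame_all[k].std(ddof=ddof)) if len(frames) > 1 else 0.0 for k in ("vdw", "ele", "gb", "np")),
        float(all_tot.std(ddof=ddof)) if len(frames) > 1 else 0.0,
    )
    return DecompositionResult(rows, all_row, n_frames=len(frames))


def average_decompositions(results: Sequence[DecompositionResult]) -> DecompositionResult:
    """Average per-residue means over independent replicas (replicas after frames).

    The sd columns become the sample standard deviation across replica
    means.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one decomposition")
    if len(results) == 1:
        return results[0]
    order = [r.residue for r in results[0].rows]
    maps = [{row.residue: row for row in res.rows} for res in results]
    if any(set(m) != set(order) for m in maps):
        raise ValueError("replica decompositions cover different residues")
    rows = []
    for lab in order:
        vals = {k: np.array([getattr(m[lab], k) for m in maps]) for k in ("vdw", "ele", "gb", "np_", "tot")}
        rows.append(ResidueEnergyRow(
            lab, *(float(vals[k].mean()) for k in ("vdw", "ele", "gb", "np_", "tot")),
            *(float(vals[k].std(ddof=1)) for k in ("vdw", "ele", "gb", "np_", "tot")),
        ))
    rows.sort(key=lambda row: (row.tot, _resnum(row.residue)))
    alls = {k: np.array([getattr(res.all_row, k) for res in results]) for k in ("vdw", "ele", "gb", "np_", "tot")}
    all_row = ResidueEnergyRow(
        "All", *(float(alls[k].mean()) for k in ("vdw", "ele", "gb", "np_", "tot")),
        *(float(alls[k].std(ddof=1)) for k in ("vdw", "ele", "gb", "np_", "tot")),
    )
    return DecompositionResult(rows, all_row, n_frames=sum(r.n_frames for r in results))


_RES_RE = re.compile(r"^(\d+)([A-Za-z]{3})$")


def _resnum(label: str) -> int:
    m = _RES_RE.match(label)
    return int(m.group(1)) if m else 10**9


class AlanineCandidate(NamedTuple):
    residue: str
    resnum: int
    resname: str
    #: suggested substitution: alanines go to glycine, others to alanine
    substitution: str


def rank_alanine_candidates(rows: Sequence[ResidueEnergyRow], top_n: int) -> list[AlanineCandidate]:
    """Rank residues as alanine-scan candidates by binding contribution.

    Sorted by total contribution ascending (most negative first), ties
    broken by residue number.  Glycines cannot be alanine-scanned and
    are excluded (with a warning); alanines are flagged for the A→G
    substitution instead.  Rows whose label is not of the form
    ``<number><ThreeLetterName>`` (e.g. the 'All' total) are ignored.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    parsed = []
    n_gly = 0
    for row in rows:
        m = _RES_RE.match(row.residue)
        if not m:
            continue
        num, name = int(m.group(1)), m.group(2)
        if name.upper() == "GLY":
            n_gly += 1
            continue
        parsed.append((row.tot, num, name))
    if n_gly:
        warnings.warn(f"excluded {n_gly} glycine residue(s): glycine cannot be alanine-scanned")
    if not parsed:
        warnings.warn("no alanine-scannable residues among the input rows")
        return []
    parsed.sort(key=lambda t: (t[0], t[1]))
    out = []
    for tot, num, name in parsed[:top_n]:
        sub = "A→G" if name.upper() == "ALA" else f"{name}→A"
        out.append(AlanineCandidate(f"{num}{name}", num, name, sub))
    return out
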