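"""Synthetic active-site trajectories with dialed butterfly statistics.

No trajectories from the original enhanced-sampling study are deposited,
so the pipeline is exercised on a stochastic surrogate of the pocket
geometry.  The surrogate is *not* physical dynamics: each of the four
butterfly coordinates (d7, d8, a7, a8) follows a stationary first-order
autoregressive (mean-reverting) process whose stationary marginals are
Gaussian with the model's means and fluctuation scales; d7 and d8 share
an innovation correlation ``rho``; emitted distances are truncated at a
2.0 Å hard core.  The only thing the surrogate must get right is the
*statistical* structure the analysis consumes — contact propensities,
replica structure, reproducibility — and those are directly dialable.

Replica ``r`` of a model with master seed ``s`` draws from
``numpy.random.SeedSequence(entropy=s, spawn_key=(r,))``, so replicas
are mutually independent and individually reproducible.

An optional flat-bottom restraint biases the distance marginals through
a Metropolis accept/reject step on the AR proposal at a nominal
temperature, targeting the Boltzmann-reweighted stationary density
``N(mu, sigma^2) * exp(-E_restraint/kT)``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.signal import lfilter

from .geometry import GeometrySeries, SiteSelection, Trajectory
from .restraints import RestraintSpec, flat_bottom_energy

__all__ = [
    "SyntheticPocketModel",
    "CalibrationResult",
    "ConvergenceError",
    "sample_contact_series",
    "sample_all_replicas",
    "emit_cartesian_trajectory",
    "emitted_selection",
    "empirical_ratio",
    "calibrate_to_ratio",
    "HARD_CORE",
]

#: Hard-core lower bound on emitted C–O distances, Å.
HARD_CORE = 2.0

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: O–Fe bond length used when realising Cartesian frames, Å (ferryl Fe=O).
FE_O_BOND = 1.6


class ConvergenceError(RuntimeError):
    """Calibration failed to reach the target ratio."""


@dataclass(frozen=True)
class SyntheticPocketModel:
    """Stochastic pocket model generating butterfly coordinate series.

    Distances in Å, angles in degrees.  Defaults emulate the study's
    sampling protocol: 10 replicas of 4,000 frames at 7.5 ps cadence
    (30 ns each).  ``correlation_time_frames`` is the AR(1) relaxation
    time of all four coordinates; ``angle_distance_coupling`` (deg/Å)
    optionally tilts each carbon's NAC angle with its own distance
    fluctuation (0 by default: the angle was found non-limiting).
    """

    mean_d8: float = 3.4
    mean_d7: float = 4.2
    sigma_d: float = 0.4
    rho: float = 0.3
    angle_mean: float = 120.0
    angle_sigma: float = 15.0
    restraint: Optional[RestraintSpec] = None
    temperature_K: float = 300.0
    n_frames: int = 4000
    n_replicas: int = 10
    dt_ps: float = 7.5
    correlation_time_frames: float = 5.0
    angle_distance_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_d > 0:
            raise ValueError(f"sigma_d must be positive, got {self.sigma_d}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if not 0.0 < self.angle_mean < 180.0:
            raise ValueError(f"angle_mean must lie in (0, 180), got {self.angle_mean}")
        if not self.angle_sigma > 0:
            raise ValueError(f"angle_sigma must be positive, got {self.angle_sigma}")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")
        if not self.dt_ps > 0:
            raise ValueError(f"dt_ps must be positive, got {self.dt_ps}")
        if not self.correlation_time_frames > 0:
            raise ValueError("correlation_time_frames must be positive")
        if self.mean_d8 <= 0 or self.mean_d7 <= 0:
            raise ValueError("distance means must be positive")

    @property
    def phi(self) -> float:
        """AR(1) autoregression coefficient exp(-1/tau)."""
        return math.exp(-1.0 / self.correlation_time_frames)

    @property
    def kT(self) -> float:
        return KB * self.temperature_K


def _replica_rng(seed: int, replica_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replica_index,)))


def _ar1_exact(rng: np.random.Generator, n: int, mean: float, sigma: float, phi: float,
               innovations: np.ndarray | None = None) -> np.ndarray:
    """Stationary AR(1) path with N(mean, sigma^2) marginals (vectorised)."""
    z = rng.standard_normal(n) if innovations is None else innovations
    eps = z * sigma * math.sqrt(1.0 - phi * phi)
    x0 = rng.normal(mean, sigma)
    y = lfilter([1.0], [1.0, -phi], eps, zi=[phi * (x0 - mean)])[0]
    return mean + y


def _restrained_pair_walk(rng: np.random.Generator, model: SyntheticPocketModel) -> tuple[np.ndarray, np.ndarray]:
    """(d7, d8) latent paths under the restraint-biased target, via Metropolis on the AR proposal.

    The AR(1) kernel is reversible w.r.t. its Gaussian stationary law,
    so accepting joint proposals with probability
    ``min(1, exp(-dE_restraint/kT))`` targets the Boltzmann-reweighted
    density.  A burn-in of 20 correlation times is discarded.
    """
    spec = model.restraint
    pair = set(spec.atom_pair)

    def bias(d7: float, d8: float) -> float:
        e = 0.0
        if "c8" in pair:
            e += flat_bottom_energy(max(d8, HARD_CORE), spec).energy
        if "c7" in pair:
            e += flat_bottom_energy(max(d7, HARD_CORE), spec).energy
        return e

    phi = model.phi
    s = model.sigma_d * math.sqrt(1.0 - phi * phi)
    L = np.linalg.cholesky(np.array([[1.0, model.rho], [model.rho, 1.0]]))
    burn = int(20 * model.correlation_time_frames)
    n = model.n_frames + burn
    z = (L @ rng.standard_normal((2, n))) * s
    u = rng.random(n)
    kT = model.kT
    d7 = np.empty(n)
    d8 = np.empty(n)
    x7, x8 = model.mean_d7, model.mean_d8
    e_cur = bias(x7, x8)
    for t in range(n):
        p7 = model.mean_d7 + phi * (x7 - model.mean_d7) + z[0, t]
        p8 = model.mean_d8 + phi * (x8 - model.mean_d8) + z[1, t]
        e_new = bias(p7, p8)
        if e_new <= e_cur or u[t] < math.exp(-(e_new - e_cur) / kT):
            x7, x8, e_cur = p7, p8, e_new
        d7[t] = x7
        d8[t] = x8
    return d7[burn:], d8[burn:]


def sample_contact_series(model: SyntheticPocketModel, replica_index: int = 0) -> GeometrySeries:
    """Draw one replica's butterfly coordinate series.

    Deterministic given ``(model.seed, replica_index)``.  Distances are
    clipped at the 2.0 Å hard core; angles at [0, 180] degrees.
    """
    if replica_index < 0:
        raise ValueError("replica_index must be non-negative")
    rng = _replica_rng(model.seed, replica_index)
    phi = model.phi
    if model.restraint is None:
        L = np.linalg.cholesky(np.array([[1.0, model.rho], [model.rho, 1.0]]))
        z = L @ rng.standard_normal((2, model.n_frames))
        d7 = _ar1_exact(rng, model.n_frames, model.mean_d7, model.sigma_d, phi, innovations=z[0])
        d8 = _ar1_exact(rng, model.n_frames, model.mean_d8, model.sigma_d, phi, innovations=z[1])
    else:
        d7, d8 = _restrained_pair_walk(rng, model)
    a7 = _ar1_exact(rng, model.n_frames, model.angle_mean, model.angle_sigma, phi)
    a8 = _ar1_exact(rng, model.n_frames, model.angle_mean, model.angle_sigma, phi)
    if model.angle_distance_coupling != 0.0:
        a7 = a7 + model.angle_distance_coupling * (d7 - model.mean_d7)
        a8 = a8 + model.angle_distance_coupling * (d8 - model.mean_d8)
    return GeometrySeries(
        np.maximum(d7, HARD_CORE),
        np.maximum(d8, HARD_CORE),
        np.clip(a7, 0.0, 180.0),
        np.clip(a8, 0.0, 180.0),
        dt_ps=model.dt_ps,
        label=f"synthetic/r{replica_index}",
    )


def sample_all_replicas(model: SyntheticPocketModel) -> list[GeometrySeries]:
    """All ``model.n_replicas`` replicas, indices 0..n-1."""
    return [sample_contact_series(model, r) for r in range(model.n_replicas)]


# ---------------------------------------------------------------------------
# Cartesian realisation

#: Atom order in emitted files.
EMITTED_ATOMS = ("FE", "O1", "C8", "C7")


def emitted_selection(format: str = "pdb") -> SiteSelection:
    """Site selection matching files written by :func:`emit_cartesian_trajectory`."""
    if format == "pdb":
        return SiteSelection(o_cpd="A:1:O1", fe="A:1:FE", c7="A:2:C7", c8="A:2:C8")
    if format == "xyz":
        return SiteSelection(o_cpd=1, fe=0, c7=3, c8=2)
    raise ValueError(f"unsupported emit format {format!r}")


def _cartesian_frames(series: GeometrySeries) -> np.ndarray:
    """Realise each frame's four internal coordinates exactly in Cartesian space.

    Convention: Fe at the origin, O on the +z axis at the ferryl bond
    length; C8 in the xz half-plane (x >= 0), C7 in the yz half-plane
    (y >= 0).  The C7–C8 distance is an unconstrained degree of freedom
    of the butterfly coordinates and is fixed by this convention.
    """
    d7, d8, a7, a8 = series.d7, series.d8, series.a7, series.a8
    bad = ~(
        np.isfinite(d7) & np.isfinite(d8) & np.isfinite(a7) & np.isfinite(a8)
        & (d7 > 0) & (d8 > 0) & (a7 >= 0) & (a7 <= 180) & (a8 >= 0) & (a8 <= 180)
    )
    if np.any(bad):
        raise ValueError(f"geometrically unrealisable frame {int(np.flatnonzero(bad)[0])}")
    n = len(series)
    o = np.array([0.0, 0.0, FE_O_BOND])
    r7 = np.radians(a7)
    r8 = np.radians(a8)
    coords = np.zeros((n, 4, 3))
    coords[:, 1] = o  # O1 sits at index 1 in EMITTED_ATOMS order FE,O1,C8,C7
    # ray O->Fe is (0,0,-1); a carbon at angle a from that ray:
    coords[:, 2, 0] = d8 * np.sin(r8)
    coords[:, 2, 2] = FE_O_BOND - d8 * np.cos(r8)
    coords[:, 3, 1] = d7 * np.sin(r7)
    coords[:, 3, 2] = FE_O_BOND - d7 * np.cos(r7)
    return coords


def _build_universe(n_frames: int):
    import MDAnalysis as mda

    u = mda.Universe.empty(
        n_atoms=4, n_residues=2, n_segments=1,
        atom_resindex=[0, 0, 1, 1], residue_segindex=[0, 0], trajectory=True,
    )
    u.add_TopologyAttr("names", list(EMITTED_ATOMS))
    u.add_TopologyAttr("elements", ["Fe", "O", "C", "C"])
    u.add_TopologyAttr("resnames", ["HEM", "STY"])
    u.add_TopologyAttr("resids", [1, 2])
    u.add_TopologyAttr("segids", ["A"])
    u.add_TopologyAttr("chainIDs", ["A"] * 4)
    return u


def emit_cartesian_trajectory(
    series: GeometrySeries,
    path,
    dt_ps: float | None = None,
    format: str | None = None,
) -> Trajectory:
    """Write a Cartesian trajectory (multi-model PDB or XYZ) realising ``series``.

    Returns the equivalent in-memory :class:`Trajectory` (site order
    o, fe, c7, c8).  The written atom order is FE, O1, C8, C7; use
    :func:`emitted_selection` to read the file back.
    """
    import MDAnalysis as mda

    if len(series) == 0:
        raise ValueError("cannot emit an empty series")
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unsupported emit format {fmt!r}")
    dt = dt_ps if dt_ps is not None else series.dt_ps
    coords = _cartesian_frames(series)
    u = _build_universe(len(series))
    from MDAnalysis.coordinates.memory import MemoryReader

    u.load_new(coords.astype(np.float32), format=MemoryReader)
    with mda.Writer(str(path), n_atoms=4, multiframe=True) as w:
        for _ in u.trajectory:
            w.write(u.atoms)
    # site order (o, fe, c7, c8) from emitted order (FE, O1, C8, C7)
    sites = coords[:, [1, 0, 3, 2], :]
    return Trajectory(sites, dt_ps=dt, label=os.path.basename(str(path)))


# ---------------------------------------------------------------------------
# Calibration

class CalibrationResult(NamedTuple):
    model: SyntheticPocketModel
    achieved_ratio: float


#: Replica index reserved for calibration draws, outside the production range.
_CALIBRATION_REPLICA = 1_000_003


def empirical_ratio(model: SyntheticPocketModel, threshold: float,
                    n_frames: int | None = None, replica_index: int = 0) -> Optional[float]:
    """Empirical p(C8 only)/p(C7 or C8) at a distance threshold from one long draw."""
    m = replace(model, n_frames=n_frames or model.n_frames)
    s = sample_contact_series(m, replica_index)
    c7 = s.d7 < threshold
    c8 = s.d8 < threshold
    n_any = int(np.count_nonzero(c7 | c8))
    if n_any == 0:
        return None
    return int(np.count_nonzero(c8 & ~c7)) / n_any


def calibrate_to_ratio(
    target_ratio: float,
    threshold: float,
    base_model: SyntheticPocketModel,
    tol: float = 0.005,
    n_eval_frames: int = 200_000,
    max_iter: int = 60,
) -> CalibrationResult:
    """Dial ``mean_d7`` by bisection until the large-n empirical ratio matches the target.

    The ratio is monotone in ``mean_d7`` (pushing C7 out of the pocket
    can only raise the share of C8-only contact frames), so bisection on
    a fixed long evaluation draw converges.  Converges to ``tol``
    (default 0.005, well inside the ±0.02 contract); raises
    :class:`ConvergenceError` if the target is unreachable with the
    model's fluctuation scale.
    """
    if not 0.0 < target_ratio < 1.0:
        raise ValueError(f"target_ratio must lie in (0, 1), got {target_ratio}")

    def f(mean_d7: float) -> float:
        m = replace(base_model, mean_d7=mean_d7, restraint=base_model.restraint)
        r = empirical_ratio(m, threshold, n_frames=n_eval_frames, replica_index=_CALIBRATION_REPLICA)
        return -1.0 if r is None else r

    lo = HARD_CORE + 0.05
    hi = base_model.mean_d8 + 12.0 * base_model.sigma_d
    f_lo, f_hi = f(lo), f(hi)
    if f_hi < 0:
        raise ConvergenceError("no frame satisfies the criterion even with C7 fully withdrawn")
    if not f_lo <= target_ratio <= f_hi:
        raise ConvergenceError(
            f"target ratio {target_ratio} outside the reachable range [{f_lo:.3f}, {f_hi:.3f}]"
        )
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if best is None or abs(f_mid - target_ratio) < abs(best[1] - target_ratio):
            best = (mid, f_mid)
        if abs(f_mid - target_ratio) <= tol:
            best = (mid, f_mid)
            break
        if f_mid < target_ratio:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-5:
            break
    mean_d7, achieved = best
    if abs(achieved - target_ratio) > 0.02:
        raise ConvergenceError(
            f"calibration stalled at ratio {achieved:.3f} for target {target_ratio} "
            "(fluctuation scale too coarse for this threshold)"
        )
    return CalibrationResult(replace(base_model, mean_d7=mean_d7), achieved)
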