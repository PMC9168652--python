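"""Butterfly selectivity statistics.

A frame is classified by whether each vinyl carbon is "in contact" with
the Cpd I oxygen under a criterion: a distance threshold (strictly
``d < threshold``), optionally combined with a NAC-angle standard
(strictly ``angle > standard``, applied to that carbon's own C–O–Fe
angle).  Over a trajectory this yields

* ``p(C7 or C8)`` — fraction of frames with at least one carbon in contact,
* ``p(C8 only)`` — fraction with only the reactive position-1 carbon in contact,

and their ratio ``p(C8 only)/p(C7 or C8)``, the statistic that tracks
anti-Markovnikov selectivity across enzyme variants.  Replicas are
averaged at the statistic level (mean of per-replica fractions; the
aggregated ratio is the ratio of the mean fractions), and variant
ratios are rank-correlated against experimental selectivities with a
mid-rank (tie-corrected) Spearman coefficient.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import ContactGeometry, GeometrySeries

__all__ = [
    "Mode",
    "FrameClass",
    "Criterion",
    "SweepConfig",
    "ContactStatistics",
    "VariantRecord",
    "CorrelationReport",
    "classify_frame",
    "classify_series",
    "contact_statistics",
    "aggregate_replicas",
    "pool_replicas",
    "spearman_midrank",
    "correlation_report",
    "stats_by_criterion",
]


class Mode(str, enum.Enum):
    """Contact-criterion composition mode.

    ``distance_primary_with_angle`` and ``angle_primary_with_distance``
    apply the identical conjunctive predicate (distance AND angle); both
    are kept because the sweep was run in both orientations in the
    source analysis, differing only in which axis is swept first.
    """

    DISTANCE_ONLY = "distance_only"
    DISTANCE_PRIMARY_WITH_ANGLE = "distance_primary_with_angle"
    ANGLE_PRIMARY_WITH_DISTANCE = "angle_primary_with_distance"


class FrameClass(enum.Enum):
    NEITHER = "neither"
    C7_ONLY = "c7_only"
    C8_ONLY = "c8_only"
    BOTH = "both"


class ConfigError(ValueError):
    """Invalid sweep / criterion configuration."""


@dataclass(frozen=True)
class Criterion:
    """One contact criterion: distance threshold (Å), optional angle standard (deg), mode."""

    distance: float
    angle: Optional[float] = None
    mode: Mode = Mode.DISTANCE_ONLY

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ConfigError(f"distance threshold must be positive, got {self.distance}")
        if self.mode is not Mode.DISTANCE_ONLY and self.angle is None:
            raise ConfigError(f"mode {self.mode.value} requires an angle standard")
        if self.angle is not None and not 0 < self.angle < 180:
            raise ConfigError(f"angle standard must lie in (0, 180), got {self.angle}")

    def label(self) -> str:
        if self.angle is None:
            return f"d<{self.distance:g}"
        return f"d<{self.distance:g},a>{self.angle:g}"


@dataclass(frozen=True)
class SweepConfig:
    """Threshold sweep: distance thresholds in Å, angle standards in degrees."""

    distance_thresholds: tuple = (3.6, 3.8, 4.0, 4.2, 4.4)
    angle_standards: tuple = (90.0, 105.0, 120.0, 135.0)
    mode: Mode = Mode.DISTANCE_ONLY

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.distance_thresholds)
        if not d or any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ConfigError("distance thresholds must be strictly positive and strictly increasing")
        a = tuple(float(x) for x in self.angle_standards)
        if any(not 0 < x < 180 for x in a):
            raise ConfigError("angle standards must lie in (0, 180)")
        object.__setattr__(self, "distance_thresholds", d)
        object.__setattr__(self, "angle_standards", a)
        object.__setattr__(self, "mode", Mode(self.mode))

    def criteria(self) -> list[Criterion]:
        if self.mode is Mode.DISTANCE_ONLY:
            return [Criterion(d, None, self.mode) for d in self.distance_thresholds]
        if self.mode is Mode.DISTANCE_PRIMARY_WITH_ANGLE:
            pairs = itertools.product(self.distance_thresholds, self.angle_standards)
        else:  # angle primary: angles sweep in the outer loop
            pairs = ((d, a) for a, d in itertools.product(self.angle_standards, self.distance_thresholds))
        return [Criterion(d, a, self.mode) for d, a in pairs]


@dataclass
class ContactStatistics:
    """Butterfly statistics for one criterion.

    ``ratio`` is ``p_c8_only / p_any`` and is ``None`` (undefined, never
    0) when no frame satisfies the criterion.  For replica aggregates,
    ``ratio`` is recomputed from the mean fractions, ``replica_ratio_mean``
    is the mean of the per-replica ratios, and ``replica_sd`` the sample
    standard deviation of the per-replica ratios (replicas with an
    undefined ratio are excluded and counted in ``n_undefined_replicas``).
    """

    criterion: Criterion
    p_any: float
    p_c8_only: float
    ratio: Optional[float]
    n_frames: int
    n_replicas: int = 1
    replica_sd: Optional[float] = None
    replica_ratio_mean: Optional[float] = None
    n_undefined_replicas: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_c8_only <= self.p_any <= 1.0:
            raise ValueError(
                f"require 0 <= p_c8_only <= p_any <= 1, got {self.p_c8_only}, {self.p_any}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """An enzyme variant with its experimental anti-Markovnikov selectivity (fraction)."""

    name: str
    am_selectivity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.am_selectivity <= 1.0:
            raise ValueError(f"am_selectivity must lie in [0, 1], got {self.am_selectivity}")


def classify_series(series: GeometrySeries, criterion: Criterion) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-carbon contact booleans ``(c7_in_contact, c8_in_contact)``."""
    c7 = series.d7 < criterion.distance
    c8 = series.d8 < criterion.distance
    if criterion.mode is not Mode.DISTANCE_ONLY:
        c7 &= series.a7 > criterion.angle
        c8 &= series.a8 > criterion.angle
    return c7, c8


def classify_frame(
    geom: ContactGeometry,
    threshold: float,
    angle_standard: float | None = None,
    mode: Mode = Mode.DISTANCE_ONLY,
) -> FrameClass:
    """Classify one frame under a contact criterion.

    A carbon is in contact iff its C–O distance is strictly below the
    threshold, and — in the angle modes — its own NAC angle is strictly
    above the standard.
    """
    crit = Criterion(threshold, angle_standard, Mode(mode))
    series = GeometrySeries(
        np.array([geom.d7]), np.array([geom.d8]), np.array([geom.a7]), np.array([geom.a8])
    )
    c7, c8 = classify_series(series, crit)
    if c7[0] and c8[0]:
        return FrameClass.BOTH
    if c8[0]:
        return FrameClass.C8_ONLY
    if c7[0]:
        return FrameClass.C7_ONLY
    return FrameClass.NEITHER


def contact_statistics(series: GeometrySeries, config: SweepConfig) -> list[ContactStatistics]:
    """Compute butterfly statistics for every criterion of the sweep.

    Counts are exact integers before division; fractions are counts
    over the total number of frames.
    """
    n = len(series)
    if n == 0:
        raise ValueError("cannot compute contact statistics over zero frames")
    out = []
    for crit in config.criteria():
        c7, c8 = classify_series(series, crit)
        n_any = int(np.count_nonzero(c7 | c8))
        n_c8_only = int(np.count_nonzero(c8 & ~c7))
        p_any = n_any / n
        p_c8 = n_c8_only / n
        ratio = (n_c8_only / n_any) if n_any > 0 else None
        out.append(ContactStatistics(crit, p_any, p_c8, ratio, n))
    return out


def aggregate_replicas(per_replica: Sequence[ContactStatistics]) -> ContactStatistics:
    """Average one criterion's statistics over replicas.

    ``p_any`` and ``p_c8_only`` are unweighted means of the per-replica
    fractions (the replicas have equal length in the intended design,
    and the published averaging is at the trajectory level); the
    aggregated ratio is recomputed from the mean fractions.
    """
    if not per_replica:
        raise ValueError("need at least one replica")
    crit = per_replica[0].criterion
    if any(s.criterion != crit for s in per_replica):
        raise ValueError("cannot aggregate statistics computed under different criteria")
    if len(per_replica) == 1:
        return replace(per_replica[0])
    p_any = float(np.mean([s.p_any for s in per_replica]))
    p_c8 = float(np.mean([s.p_c8_only for s in per_replica]))
    ratio = (p_c8 / p_any) if p_any > 0 else None
    ratios = [s.ratio for s in per_replica if s.ratio is not None]
    n_undef = len(per_replica) - len(ratios)
    sd = float(np.std(ratios, ddof=1)) if len(ratios) >= 2 else None
    rmean = float(np.mean(ratios)) if ratios else None
    return ContactStatistics(
        crit,
        p_any,
        p_c8,
        ratio,
        n_frames=int(sum(s.n_frames for s in per_replica)),
        n_replicas=len(per_replica),
        replica_sd=sd,
        replica_ratio_mean=rmean,
        n_undefined_replicas=n_undef,
    )


def pool_replicas(per_replica: Sequence[ContactStatistics]) -> ContactStatistics:
    """Frame-pooled alternative to :func:`aggregate_replicas`.

    Weights each replica by its frame count, equivalent to concatenating
    the replicas into one long trajectory before counting.
    """
    if not per_replica:
        raise ValueError("need at least one replica")
    crit = per_replica[0].criterion
    if any(s.criterion != crit for s in per_replica):
        raise ValueError("cannot pool statistics computed under different criteria")
    n_tot = sum(s.n_frames for s in per_replica)
    n_any = sum(round(s.p_any * s.n_frames) for s in per_replica)
    n_c8 = sum(round(s.p_c8_only * s.n_frames) for s in per_replica)
    ratio = (n_c8 / n_any) if n_any > 0 else None
    return ContactStatistics(
        crit, n_any / n_tot, n_c8 / n_tot, ratio, n_frames=n_tot, n_replicas=len(per_replica)
    )


def spearman_midrank(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank (average-rank) tie handling.

    Ties receive the mean of the ranks they span; the coefficient is the
    Pearson correlation of the two rank vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant sequence")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def stats_by_criterion(stats: Sequence[ContactStatistics]) -> dict[Criterion, ContactStatistics]:
    out = {}
    for s in stats:
        if s.criterion in out:
            raise ValueError(f"duplicate criterion {s.criterion}")
        out[s.criterion] = s
    return out


@dataclass
class CorrelationReport:
    """Per-criterion Spearman coefficients between variant ratios and selectivities."""

    variants: list[VariantRecord]
    criteria: list[Criterion]
    coefficients: list[float]
    #: per-criterion ratio vectors, variant order as in ``variants``
    ratios: list[list[float]] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> list[float]:
        return [round(c, ndigits) for c in self.coefficients]

    def to_frame(self) -> pd.DataFrame:
        """Selectivity-table layout: one ratio row per variant plus the Spearman row."""
        cols = [f"Maxdist = {c.distance:g}" if c.angle is None else c.label() for c in self.criteria]
        rows = {
            v.name: [v.am_selectivity] + [self.ratios[j][i] for j in range(len(self.criteria))]
            for i, v in enumerate(self.variants)
        }
        rows["Spearman ranking power"] = [np.nan] + self.rounded()
        return pd.DataFrame.from_dict(rows, orient="index", columns=["AM selectivity"] + cols)


def correlation_report(
    variants: Sequence[VariantRecord],
    stats: Mapping[str, Mapping[Criterion, ContactStatistics]],
    criteria: Sequence[Criterion] | None = None,
) -> CorrelationReport:
    """Rank-correlate variant butterfly ratios with experimental selectivities.

    ``stats`` maps variant name → (criterion → aggregated statistics).
    Variants keep their input order.  An undefined ratio for any
    (variant, criterion) pair aborts with an error naming both, since a
    missing ratio cannot honestly participate in a ranking.
    """
    variants = list(variants)
    if len(variants) < 3:
        raise ValueError(f"rank correlation requires >= 3 variants, got {len(variants)}")
    for v in variants:
        if v.name not in stats:
            raise ValueError(f"no statistics supplied for variant {v.name!r}")
    if criteria is None:
        first = stats[variants[0].name]
        criteria = list(first.keys())
    sel = [v.am_selectivity for v in variants]
    coeffs, ratio_cols = [], []
    for crit in criteria:
        col = []
        for v in variants:
            try:
                s = stats[v.name][crit]
            except KeyError as exc:
                raise ValueError(f"variant {v.name!r} has no statistics for criterion {crit.label()}") from exc
            if s.ratio is None:
                raise ValueError(
                    f"undefined ratio (p_any = 0) for variant {v.name!r} at criterion {crit.label()}"
                )
            col.append(s.ratio)
        coeffs.append(spearman_midrank(sel, col))
        ratio_cols.append(col)
    return CorrelationReport(variants, list(criteria), coeffs, ratio_cols)
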