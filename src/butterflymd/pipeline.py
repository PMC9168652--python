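"""End-to-end orchestration of the butterfly analysis.

One structured YAML config drives the whole run: per variant, obtain
replica trajectories (read from files, or drawn from a synthetic pocket
model), sweep the contact criteria, aggregate replicas, rank-correlate
the aggregated ratios with experimental selectivities, and optionally
run the per-residue binding-energy decomposition and mutation-candidate
ranking.  Machine-readable outputs (TSV mirrors of the published table
layouts; JSON at full precision) are written with a manifest recording
the config hash, master seed, package version and input hashes, so an
identical config + seed reproduces byte-identical reports.

Replica randomness derives from the master seed: variant ``i`` uses a
model seed drawn from ``SeedSequence([master_seed, i])``, and replica
``r`` of that model from ``SeedSequence(entropy=model_seed,
spawn_key=(r,))``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energy import (
    DecompositionResult,
    GBSettings,
    ParameterizedStructure,
    per_residue_decomposition,
    rank_alanine_candidates,
)
from .geometry import GeometrySeries, SiteSelection, compute_contact_geometry, read_trajectory
from .restraints import RestraintSpec
from .stats import (
    ContactStatistics,
    CorrelationReport,
    Criterion,
    Mode,
    SweepConfig,
    VariantRecord,
    aggregate_replicas,
    contact_statistics,
    correlation_report,
    pool_replicas,
    stats_by_criterion,
)
from .synthetic import SyntheticPocketModel, sample_all_replicas

__all__ = [
    "VariantInput",
    "DecompositionConfig",
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "write_reports",
]

log = logging.getLogger("butterflymd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class VariantInput:
    """One enzyme system: either trajectory files or a synthetic pocket model."""

    name: str
    am_selectivity: Optional[float] = None
    synthetic: Optional[SyntheticPocketModel] = None
    trajectories: Sequence[str] = ()
    format: Optional[str] = None
    selection: Optional[SiteSelection] = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (not self.trajectories):
            raise ValueError(
                f"variant {self.name!r}: provide exactly one of a synthetic model or trajectory paths"
            )


@dataclass
class DecompositionConfig:
    frames: Sequence[str] = ()
    settings: GBSettings = field(default_factory=GBSettings)
    frame_window: Optional[tuple] = None
    top_n: int = 10


@dataclass
class PipelineConfig:
    variants: Sequence[VariantInput]
    sweep: SweepConfig = field(default_factory=SweepConfig)
    selection: Optional[SiteSelection] = None
    restraints: Sequence[RestraintSpec] = ()
    decomposition: Optional[DecompositionConfig] = None
    output_dir: str = "butterfly_out"
    seed: int = 0
    pooled: bool = False
    correlate: Optional[bool] = None  # None = run when >= 3 variants carry selectivities

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("at least one variant is required")


def _to_selection(d) -> SiteSelection:
    return SiteSelection(**{k: d[k] for k in ("o_cpd", "fe", "c7", "c8")})


def _to_restraint(d) -> RestraintSpec:
    kw = dict(d)
    if "atom_pair" in kw:
        kw["atom_pair"] = tuple(kw["atom_pair"])
    return RestraintSpec(**kw)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML/JSON mapping."""
    sweep = SweepConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.get("sweep", {}).items()})
    selection = _to_selection(raw["selection"]) if "selection" in raw else None
    restraints = tuple(_to_restraint(r) for r in raw.get("restraints", []))
    variants = []
    for v in raw.get("variants", []):
        model = None
        if "synthetic" in v:
            mk = dict(v["synthetic"])
            if "restraint" in mk and mk["restraint"] is not None:
                mk["restraint"] = _to_restraint(mk["restraint"])
            model = SyntheticPocketModel(**mk)
        variants.append(VariantInput(
            name=v["name"],
            am_selectivity=v.get("am_selectivity"),
            synthetic=model,
            trajectories=tuple(v.get("trajectories", ())),
            format=v.get("format"),
            selection=_to_selection(v["selection"]) if "selection" in v else None,
        ))
    deco = None
    if "decomposition" in raw and raw["decomposition"]:
        d = raw["decomposition"]
        deco = DecompositionConfig(
            frames=tuple(d.get("frames", ())),
            settings=GBSettings(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d.get("settings", {}).items()}),
            frame_window=tuple(d["frame_window"]) if d.get("frame_window") else None,
            top_n=int(d.get("top_n", 10)),
        )
    return PipelineConfig(
        variants=variants, sweep=sweep, selection=selection, restraints=restraints,
        decomposition=deco, output_dir=raw.get("output_dir", "butterfly_out"),
        seed=int(raw.get("seed", 0)), pooled=bool(raw.get("pooled", False)),
        correlate=raw.get("correlate"),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = config_from_dict(raw)
    cfg._raw = raw  # retained for hashing  # type: ignore[attr-defined]
    return cfg


@dataclass
class PipelineResult:
    sweep_tables: dict  # variant name -> DataFrame
    aggregated: dict    # variant name -> {Criterion: ContactStatistics}
    correlation: Optional[CorrelationReport] = None
    decomposition: Optional[DecompositionResult] = None
    candidates: Optional[list] = None
    manifest: dict = field(default_factory=dict)


def _derived_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


def _variant_series(variant: VariantInput, config: PipelineConfig, index: int) -> list[GeometrySeries]:
    if variant.synthetic is not None:
        model = replace(variant.synthetic, seed=_derived_seed(config.seed, index))
        return [compute_series for compute_series in sample_all_replicas(model)]
    selection = variant.selection or config.selection
    if selection is None:
        raise PipelineError("sweep", f"variant {variant.name!r} needs a site selection to read trajectories")
    out = []
    for p in variant.trajectories:
        traj = read_trajectory(p, selection, format=variant.format)
        out.append(compute_contact_geometry(traj))
    return out


def _sweep_frame(agg: dict) -> pd.DataFrame:
    rows = []
    for crit, s in agg.items():
        rows.append({
            "distance": crit.distance,
            "angle": crit.angle if crit.angle is not None else np.nan,
            "mode": crit.mode.value,
            "p_any": s.p_any,
            "p_c8_only": s.p_c8_only,
            "ratio": s.ratio if s.ratio is not None else np.nan,
            "replica_ratio_mean": s.replica_ratio_mean if s.replica_ratio_mean is not None else np.nan,
            "replica_sd": s.replica_sd if s.replica_sd is not None else np.nan,
            "n_frames": s.n_frames,
            "n_replicas": s.n_replicas,
            "label": f"{s.p_c8_only:.2f}/{s.p_any:.2f} ({s.ratio:.2f})" if s.ratio is not None else "undefined",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage and return the collected results (nothing written)."""
    t0 = time.perf_counter()
    sweep_tables: dict[str, pd.DataFrame] = {}
    aggregated: dict[str, dict[Criterion, ContactStatistics]] = {}
    combine = pool_replicas if config.pooled else aggregate_replicas

    for i, variant in enumerate(config.variants):
        t = time.perf_counter()
        try:
            series = _variant_series(variant, config, i)
            per_replica = [contact_statistics(s, config.sweep) for s in series]
            agg = [combine([rep[j] for rep in per_replica]) for j in range(len(per_replica[0]))]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("sweep", f"variant {variant.name!r}: {exc}") from exc
        agg_map = stats_by_criterion(agg)
        aggregated[variant.name] = agg_map
        sweep_tables[variant.name] = _sweep_frame(agg_map)
        undef = [c.label() for c, s in agg_map.items() if s.ratio is None]
        if undef:
            log.warning("variant %s: undefined ratio at %s", variant.name, ", ".join(undef))
        log.info("stage sweep [%s]: %d replicas in %.2f s", variant.name, len(series), time.perf_counter() - t)

    correlation = None
    with_sel = [v for v in config.variants if v.am_selectivity is not None]
    want_corr = config.correlate if config.correlate is not None else len(with_sel) >= 3
    if want_corr:
        if len(with_sel) < 3:
            raise PipelineError("correlate", f"≥3 variants required for rank correlation, got {len(with_sel)}")
        t = time.perf_counter()
        try:
            records = [VariantRecord(v.name, v.am_selectivity) for v in with_sel]
            correlation = correlation_report(records, aggregated, criteria=config.sweep.criteria())
        except Exception as exc:
            raise PipelineError("correlate", str(exc)) from exc
        log.info("stage correlate: %d criteria in %.2f s", len(correlation.criteria), time.perf_counter() - t)

    decomposition = None
    candidates = None
    if config.decomposition is not None and config.decomposition.frames:
        t = time.perf_counter()
        try:
            frames = [ParameterizedStructure.from_table(p) for p in config.decomposition.frames]
            window = slice(*config.decomposition.frame_window) if config.decomposition.frame_window else None
            decomposition = per_residue_decomposition(frames, config.decomposition.settings, frame_window=window)
            candidates = rank_alanine_candidates(decomposition.rows, config.decomposition.top_n)
        except Exception as exc:
            raise PipelineError("decompose", str(exc)) from exc
        log.info("stage decompose: %d frames in %.2f s", len(frames), time.perf_counter() - t)

    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return PipelineResult(sweep_tables, aggregated, correlation, decomposition, candidates)


# ---------------------------------------------------------------------------
# Report writing

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=_json_default) + "\n")


def write_reports(result: PipelineResult, config: PipelineConfig, formats=("tsv", "json")) -> dict:
    """Write the report bundle to ``config.output_dir`` and return the manifest.

    TSV files mirror the published table layouts (ratios at 2 dp in the
    bracket-label column); JSON carries full precision.  The manifest
    records the config hash, seed, package version, input hashes and
    the SHA-256 of every written report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, frame in result.sweep_tables.items():
        safe = name.replace(" ", "_").replace("/", "_")
        if "tsv" in formats:
            p = outdir / f"sweep_{safe}.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.6f")
            written.append(p)
        if "json" in formats:
            p = outdir / f"sweep_{safe}.json"
            _write_json(p, json.loads(frame.to_json(orient="records")))
            written.append(p)

    if result.correlation is not None:
        rep = result.correlation
        if "tsv" in formats:
            p = outdir / "correlation.tsv"
            rep.to_frame().to_csv(p, sep="\t", float_format="%.2f")
            written.append(p)
        if "json" in formats:
            p = outdir / "correlation.json"
            _write_json(p, {
                "variants": [{"name": v.name, "am_selectivity": v.am_selectivity} for v in rep.variants],
                "criteria": [c.label() for c in rep.criteria],
                "coefficients": rep.coefficients,
                "coefficients_2dp": rep.rounded(),
                "ratios": rep.ratios,
            })
            written.append(p)

    if result.decomposition is not None:
        if "tsv" in formats:
            p = outdir / "decomposition.tsv"
            result.decomposition.to_frame().to_csv(p, sep="\t", index=False, float_format="%.4f")
            written.append(p)
        if "json" in formats:
            p = outdir / "decomposition.json"
            _write_json(p, json.loads(result.decomposition.to_frame().to_json(orient="records")))
            written.append(p)
        if result.candidates is not None:
            p = outdir / "candidates.tsv"
            pd.DataFrame(result.candidates).to_csv(p, sep="\t", index=False)
            written.append(p)

    raw = getattr(config, "_raw", None)
    cfg_text = yaml.safe_dump(raw, sort_keys=True) if raw is not None else repr(config)
    inputs = {}
    for v in config.variants:
        for t in v.trajectories:
            inputs[str(t)] = _sha256(Path(t))
    if config.decomposition is not None:
        for t in config.decomposition.frames:
            inputs[str(t)] = _sha256(Path(t))
    manifest = {
        "package": "butterflymd",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "input_sha256": inputs,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "stages": {
            "sweep": sorted(result.sweep_tables),
            "correlate": result.correlation is not None,
            "decompose": result.decomposition is not None,
        },
    }
    _write_json(outdir / "manifest.json", manifest)
    result.manifest = manifest
    return manifest
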