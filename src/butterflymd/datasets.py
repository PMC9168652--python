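"""Bundled benchmark tables from the published aMOx selectivity study.

Two small tables ship with the package:

* the five-system selectivity benchmark — experimentally measured
  anti-Markovnikov selectivities for four directed-evolution rounds and
  the A275G mutant, together with the published replica-averaged
  p(C8 only)/p(C7 or C8) ratios at the 3.6/3.8/4.0 Å distance
  thresholds ("Maxdist" columns);
* the wild-type per-residue MM-GBSA decomposition (top-10 residues plus
  the receptor total), used as the reference input for mutation-candidate
  ranking.

In the residue table the published totals are rounded to two decimals
and contain a rounding tie that contradicts the published ranking;
totals are therefore recomputed as vdw + ele + gb + np from the printed
components, which restores a strict order consistent with the
publication.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energy import ResidueEnergyRow
from .stats import VariantRecord

__all__ = [
    "load_selectivity_benchmark",
    "benchmark_variants",
    "benchmark_ratio_columns",
    "load_residue_energy_benchmark",
]

_MAXDIST_COLS = {3.6: "ratio_maxdist_3.6", 3.8: "ratio_maxdist_3.8", 4.0: "ratio_maxdist_4.0"}


def _data(name: str):
    return resources.files("butterflymd.data").joinpath(name)


def load_selectivity_benchmark() -> pd.DataFrame:
    """The five-system selectivity/ratio benchmark as a DataFrame (input order preserved)."""
    with resources.as_file(_data("amox_selectivity_benchmark.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def benchmark_variants() -> list[VariantRecord]:
    df = load_selectivity_benchmark()
    return [VariantRecord(r.enzyme, float(r.am_selectivity)) for r in df.itertuples()]


def benchmark_ratio_columns() -> dict[float, list[float]]:
    """Published ratio columns keyed by distance threshold (Å), variant order as in the table."""
    df = load_selectivity_benchmark()
    return {thr: [float(x) for x in df[col]] for thr, col in _MAXDIST_COLS.items()}


def load_residue_energy_benchmark(include_all_row: bool = False) -> list[ResidueEnergyRow]:
    """The wild-type per-residue decomposition rows (totals recomputed from components)."""
    with resources.as_file(_data("amox_wt_residue_energies.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    rows = []
    for r in df.itertuples():
        if r.residue == "All" and not include_all_row:
            continue
        tot = r.vdw + r.ele + r.gb + r.np
        rows.append(ResidueEnergyRow(
            r.residue, r.vdw, r.ele, r.gb, r.np, tot,
            r.vdw_sd, r.ele_sd, r.gb_sd, r.np_sd, r.tot_sd,
        ))
    return rows
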