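# butterflymd

Contact-geometry analysis of P450 regioselectivity based on the
"butterfly" model of the aMOx active site.

P450 aMOx oxidises styrene to phenylacetaldehyde through the
anti-Markovnikov (AM) pathway: the Compound I (Cpd I) ferryl oxygen
attacks the terminal vinyl carbon (C8, position 1) rather than the
internal one (C7, position 2).  In the butterfly picture, what
separates a selective variant from an unselective one is *which* vinyl
carbon spends time close to the reactive oxygen.  Over an MD
trajectory this is summarised by two frame fractions at a distance
threshold *d*₀ (optionally combined with a near-attack-configuration
angle standard on the C–O–Fe angle):

- **p(C7 or C8)** — fraction of frames with at least one vinyl carbon
  within *d*₀ of the Cpd I oxygen,
- **p(C8 only)** — fraction with only the reactive carbon inside,

and their ratio **p(C8 only)/p(C7 or C8)**, which tracks the
experimental AM selectivity across enzyme variants.  Agreement is
quantified with a mid-rank (tie-corrected) Spearman coefficient,
ρ_s = Pearson correlation of the average-rank vectors.

The package is aimed at computational enzyme designers.  It provides:

- `geometry` — multi-model PDB / XYZ (optionally DCD/XTC) trajectory
  reading, atom-site resolution, per-frame distances and NAC angles;
- `stats` — strict-inequality frame classification, threshold sweeps
  (distance-only or distance × angle), replica averaging, mid-rank
  Spearman, and the variant-vs-selectivity correlation report;
- `restraints` — the flat-bottom ("NMR-type") upper-wall distance
  restraint E = k·(d − d₀)² for d > d₀ used to keep the vinyl group
  near the oxygen during sampling;
- `synthetic` — a stochastic pocket generator (stationary AR(1)
  butterfly coordinates, hard core, optional restraint bias,
  per-replica seeding) with calibration to a dialed ratio, plus exact
  Cartesian realisation of each frame for end-to-end tests;
- `energy` — a simplified MM-GBSA per-residue decomposition (LJ 12-6,
  screened Coulomb, OBC generalized Born with Debye–Hückel salt, and
  a Shrake–Rupley nonpolar term) and alanine-scan candidate ranking;
- `pipeline` / `butterflymd` CLI — one YAML config driving
  simulate → sweep → correlate → decompose → rank with deterministic,
  manifest-tracked TSV/JSON reports.

## Worked example

Rank-correlate the bundled five-system benchmark (four directed-evolution
rounds plus the A275G mutant) and sweep a synthetic pocket model:

```python
from butterflymd import (SyntheticPocketModel, SweepConfig, aggregate_replicas,
                         contact_statistics, sample_all_replicas, spearman_midrank)
from butterflymd.datasets import benchmark_variants, benchmark_ratio_columns

sel = [v.am_selectivity for v in benchmark_variants()]
for thr, col in sorted(benchmark_ratio_columns().items()):
    print(f"Maxdist = {thr}: rho_s = {spearman_midrank(sel, col):.4f}")

model = SyntheticPocketModel(mean_d8=3.4, mean_d7=4.2, sigma_d=0.4, seed=42)
cfg = SweepConfig(distance_thresholds=(3.6, 3.8, 4.0))
per_replica = [contact_statistics(s, cfg) for s in sample_all_replicas(model)]
for j, crit in enumerate(cfg.criteria()):
    agg = aggregate_replicas([rep[j] for rep in per_replica])
    print(f"d < {crit.distance} Å: p(C7 or C8) = {agg.p_any:.3f}, "
          f"p(C8 only) = {agg.p_c8_only:.3f}, ratio = {agg.ratio:.3f} ± {agg.replica_sd:.3f}")
```

prints

```
Maxdist = 3.6: rho_s = 0.9747
Maxdist = 3.8: rho_s = 1.0000
Maxdist = 4.0: rho_s = 0.9747
d < 3.6 Å: p(C7 or C8) = 0.696, p(C8 only) = 0.632, ratio = 0.909 ± 0.014
d < 4.0 Å: p(C7 or C8) = 0.943, p(C8 only) = 0.633, ratio = 0.672 ± 0.023
d < 3.8 Å: p(C7 or C8) = 0.850, p(C8 only) = 0.693, ratio = 0.816 ± 0.015
```

(lines reordered here for readability).  The first block says the
benchmark ratio columns rank the five systems essentially identically
to their measured AM selectivities — perfectly at the 3.8 Å threshold,
and at 0.97 where a tied ratio pair caps the coefficient.  The second
block is a replica-averaged sweep over ten 30 ns-equivalent synthetic
replicas: as the threshold loosens, p(C7 or C8) grows faster than
p(C8 only), so the ratio falls — the same trend the published sweeps
show on real trajectories.

From a shell, the same pipeline runs from one config:

```sh
butterflymd make-fixtures --outdir fx --seed 3     # calibrated 5-variant set
butterflymd run fx/config.yaml                     # sweep + correlation reports
butterflymd rank src/butterflymd/data/amox_wt_residue_energies.tsv --top-n 10
```

The `rank` call orders the published wild-type per-residue binding
energies (most binding first: 279Ala, 123Ile, 329Trp, …) and flags
alanines for the A→G substitution — the list that motivated the
experimental alanine scan and, ultimately, the >99 %-selective A275G
variant.

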