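# Methods

## The butterfly statistic

The analysis tracks four atoms per frame: the Cpd I ferryl oxygen (O),
the heme iron (Fe), and the substrate's two vinyl carbons — C8
(position 1, attacked by the oxygen in the anti-Markovnikov pathway)
and C7 (position 2).  The per-frame coordinates are the two distances
d(C7–O), d(C8–O) in Å and the two near-attack-configuration angles
∠C7–O–Fe, ∠C8–O–Fe in degrees (vertex at the oxygen).  Periodic
boundary conditions are not applied: all four atoms sit in one binding
pocket, so minimum-image corrections are irrelevant at these length
scales.

A carbon is *in contact* under a criterion iff its distance is
**strictly** below the threshold and — in the combined modes — its own
NAC angle is **strictly** above the angle standard ("smaller than" /
"more than" taken literally; boundary frames are excluded).  The two
combined modes (`distance_primary_with_angle`,
`angle_primary_with_distance`) apply the identical conjunctive
predicate and exist only to mirror the two sweep orientations of the
source analysis.  Whether the angle test uses each carbon's own angle
or either angle is ambiguous in the source; the per-carbon conjunction
is implemented.

Per trajectory, counts are exact integers before division:
p(C7 or C8) = #frames with ≥1 carbon in contact / n,
p(C8 only) = #frames with only C8 in contact / n,
ratio = p(C8 only)/p(C7 or C8).  A ratio with p(C7 or C8) = 0 is
*undefined* and propagates as missing — never as 0 — and aborts a
correlation that would need it.

**Replica averaging.**  Statistics are computed per replica and then
averaged (the published averaging is at the trajectory level):
aggregated fractions are unweighted means of the per-replica
fractions, and the aggregated ratio is recomputed as the ratio of the
mean fractions (identical to recomputing from averaged percentages).
The mean of per-replica ratios and their sample standard deviation are
reported alongside; a frame-pooled mode (replicas weighted by frame
count) is available behind a flag because the published text does not
fully pin the convention down.

**Rank correlation.**  The variant-level association between the ratio
and the experimental AM selectivity uses the mid-rank Spearman
coefficient: ties receive the average of the ranks they span and the
coefficient is the Pearson correlation of the rank vectors.  This tie
handling is load-bearing — the benchmark ratio columns at 3.6 and
4.0 Å each contain one tied pair, for which the mid-rank coefficient
is exactly 9.5/√95 ≈ 0.9747 while the naive 1 − 6Σd²/(n(n²−1)) formula
is wrong.  Reports round to two decimals; machine-readable output
keeps full precision.  No p-value is attached (n = 5 variants makes
one uninformative, and the source reports none).

The published sweep grid is the default: distance thresholds 3.6, 3.8,
4.0, 4.2, 4.4 Å and angle standards 90°, 105°, 120°, 135°.  One
reading note: the source text lists a second set of ratios "at 3.8 Å"
(0.25, 0.26, 0.30, 0.30) that matches its own 4.0 Å table column; the
bundled benchmark treats it as the 4.0 Å row.

## Flat-bottom restraint

The sampling protocol's "NMR-type" distance restraint is a one-sided
harmonic wall: E(d) = 0 for d ≤ d₀ and E(d) = k (d − d₀)² for d > d₀,
with the Amber convention (no ½ prefactor), so the quoted restraint
weight k = 3.0 kcal mol⁻¹ Å⁻² costs 3.0 kcal/mol at 1 Å past the
target.  Energy and force are continuous at the wall.  Only the upper
wall exists (no short-distance penalty) and the quadratic is not
linearised at large displacement — the protocol gives no evidence of a
linear tail.  Target distances of 3.5 Å (both vinyl carbons, contact
sampling) and 3.0 Å (C8 only, decomposition runs) are the protocol's
values.

## Synthetic pocket generator

No trajectories from the original enhanced-sampling study are
deposited, so the pipeline is exercised on a stochastic surrogate.
Each butterfly coordinate follows a stationary AR(1) (mean-reverting)
process whose stationary marginal is Gaussian with the model's mean
and fluctuation scale; d7 and d8 share an innovation correlation ρ
(default 0.3 — the two carbons ride the same substrate); emitted
distances are clipped at a 2.0 Å hard core (the dynamics run on the
latent Gaussian, only the emitted value is clipped).  Angles are AR(1)
as well, independent of the distances by default (the angle was found
non-limiting for selectivity); an optional linear coupling
(deg/Å) is available.

Defaults mirror the study conditions: 10 replicas × 4,000 frames at
7.5 ps cadence = 30 ns per replica; mean_d8 = 3.4 Å and
mean_d7 = 4.2 Å (inside the reported 3–5 Å reactive window, C7 farther
out), σ_d = 0.4 Å (sub-Å pocket fluctuations), angle mean 120° and
σ = 15°.

- **Correlation time.**  The AR(1) relaxation time defaults to
  5 frames (≈ 40 ps), a fast contact-fluctuation timescale.  It also
  keeps the replica-level sampling error of the aggregated ratio small
  (s.d. ≈ 0.005 at the default scale), so ten 4,000-frame replicas
  estimate a dialed ratio well inside ±0.03 — the regime the
  study-scale analysis assumes.  Much longer memory (tens of frames)
  makes ten 30 ns replicas visibly under-sampled for ±0.02-level
  comparisons.
- **Seeding.**  Replica r of a model with master seed s draws from
  `SeedSequence(entropy=s, spawn_key=(r,))`; the pipeline derives each
  variant's model seed from `SeedSequence([master_seed,
  variant_index])`.  Replicas are therefore independent, individually
  reproducible, and a master seed fixes the whole run.
- **Restraint bias.**  An optional flat-bottom restraint reweights the
  distance marginals by the Boltzmann factor at a nominal 300 K via a
  Metropolis accept/reject step on the AR proposal (the AR kernel is
  reversible w.r.t. its Gaussian law, so the chain targets
  N(μ,σ²)·e^{−E/kT}); a burn-in of 20 correlation times is discarded.
- **Cartesian realisation.**  Each frame's four internal coordinates
  are realised exactly with Fe at the origin, O at (0, 0, 1.6) Å
  (ferryl bond), C8 in the xz half-plane and C7 in the yz half-plane;
  the C7–C8 distance is not a butterfly coordinate and is fixed by
  this convention.  Files are written as multi-model PDB or XYZ
  through MDAnalysis.  PDB stores coordinates at fixed 3-decimal
  precision, which quantises round-trip distances to ~2×10⁻³ Å and
  angles to ~0.02°; XYZ round-trips at ~10⁻³ Å / 0.01°.
- **Calibration.**  `calibrate_to_ratio` bisects mean_d7 (ratio is
  monotone in it) against a 200,000-frame evaluation draw on a
  reserved replica index, converging to within 0.005 of the target
  (contract: ±0.02).  Calibration is single-threshold; matching a full
  multi-threshold ratio profile simultaneously is in general not
  achievable with one Gaussian model and is not attempted.

**What the surrogate is not.**  It is not physical dynamics: no force
field, no boost potential, no protein degrees of freedom, no
angle–distance physics beyond the optional linear coupling, Gaussian
rather than heavy-tailed fluctuations.  Passing tests demonstrate that
the *analysis* — classification, sweeps, averaging, correlation,
calibration recovery — is correct on series with known statistical
structure; they say nothing about whether a particular force field or
sampling protocol reproduces the published ratios on real
trajectories.

## Per-residue energy decomposition

A simplified MM-GBSA decomposition of the ligand binding energy, per
receptor residue and frame, averaged over frames (and optionally over
replicas, replicas after frames):

- **VDW** — Lennard-Jones 12-6 with Lorentz–Berthelot combination
  (r_min additive, ε geometric), summed over ligand × residue pairs.
- **ELE** — Coulomb q_i·q_j·332.0637/(ε_in·r) with interior dielectric
  ε_in = 3.0.
- **GB** — generalized Born cross terms between ligand and residue
  atoms, E = −332.0637·q_i·q_j·(1/ε_in − e^{−κf}/ε_solv)/f with
  f = √(r² + R_i·R_j·e^{−r²/4·R_i·R_j}), solvent dielectric 78.5, and
  Debye–Hückel κ = √(0.10806·I) Å⁻¹ from ionic strength I = 0.1 mol/L.
  Effective radii are OBC (pairwise HCT descreening with tanh
  rescaling) computed on the *complex*; the default parameter set is
  OBC model I (α = 0.8, β = 0, γ = 2.909125, Amber igb = 2 — the
  protocol's stated model), with OBC II available.  Offset 0.09 Å;
  per-atom descreening scale default 0.8.
- **NP** — surface tension (0.0005 kcal mol⁻¹ Å⁻²) times the residue's
  share of the ligand's buried SASA (ligand alone minus ligand in
  complex), assigned to the nearest receptor residue; exact distance
  ties share the burial equally so symmetric geometries decompose
  symmetrically.  SASA is numeric Shrake–Rupley (deterministic
  golden-spiral quadrature, 960 points, probe 1.4 Å) rather than the
  analytic LCPO approximation, whose element-specific coefficient
  tables add nothing here; the backend is a single pluggable function.

Tot = VDW + ELE + GB + NP per frame before averaging; summed over
residues it equals the direct ligand–receptor interaction plus GB
cross-term total by construction (verified to 10⁻⁶ against a brute
double loop).  No entropy term is computed.  Rows sort by total
ascending (most binding first); the "All" row sums every receptor
residue per frame before averaging.

This module reproduces the *method* — structure, conservation,
ranking — not any published table's numbers, which would require the
original force-field topology and trajectories.  The bundled reference
rows are published values; because their printed totals are rounded to
2 dp (producing a spurious tie that contradicts the printed order),
the loader recomputes totals from the printed components.

**Candidate ranking.**  Residues sort by total contribution ascending
with residue-number tie-break; glycines are excluded (cannot be
alanine-scanned, warned), alanines are flagged for the A→G
substitution.

## Pipeline, determinism, problem sizes

One YAML config drives the run; the master seed fixes every random
draw, so identical config + seed gives byte-identical TSV/JSON
reports, and the manifest records config hash, seed, package version
and the SHA-256 of every input and output.  TSV reports mirror the
published table layouts (selectivity + Maxdist ratio columns with the
Spearman row; decomposition columns VDW/ELE/GB/NP/Tot); JSON carries
full precision.

Test and acceptance problem sizes are chosen to exercise the study
conditions where they matter and small toys elsewhere: parameter
recovery runs the full emit → read → sweep → aggregate path at the
study scale (10 × 4,000 frames) for four dialed ratios; the
determinism check uses five calibrated variants at 4 × 800 frames
(determinism does not depend on length); decomposition oracles use
random ~30-atom toys where brute-force double loops are exact
references.

## Known limitations

- The synthetic generator cannot (and does not try to) jointly match
  ratio values at several thresholds for one variant; calibration is
  per-threshold.
- The NP residue assignment (nearest-residue with tie sharing) is one
  defensible convention among several; published decompositions do not
  state theirs.
- The GB salt screening uses the standard exp(−κf) factor with the
  aqueous 25 °C Debye constant; no empirical rescaling of κ is
  applied.
- DCD/XTC reading requires integer atom indices (no topology file is
  parsed); PDB selections use CHAIN:RESID:NAME triples.
- The Spearman report is descriptive; with five variants no
  significance claim is made.
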