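# Methods and numerical conventions

This note records the model conventions, tunable parameters, and design
choices behind the package, and what the synthetic generator does and
does not emulate.

## Radius conversions

All twelve conversions are linear and clamp to [0, 10]; out-of-limit
inputs clamp with a warning rather than erroring, because real powders
do occasionally exceed the tabulated limits (e.g. inter-particle
porosity above 1.2 for very dilated powders).

- **Cohesion index divisor.** The conversion used here is r = Icd/20,
  which maps the full 0–200 N hardness limit onto the 0–10 radius scale
  and reproduces the magnitudes seen in practice (a radius of ≈1.9 for
  ≈37 N tablets). A divisor of 290 circulates in parts of the SeDeM
  literature but cannot reach radius 10 within the stated 0–200 N limit,
  so 20 is the default; the divisor is exposed in the configuration
  (`icd_divisor`) for users who need the other convention.
- **Non-flowing powders.** A powder that never passes the funnel is the
  sentinel `None` for flow time and scores radius 0, identical to a
  measured 20 s/100 g; any t ≥ 20 s clamps to 0.
- **Rounding.** All arithmetic runs at full precision; reports round
  radii to 2 decimals and statistics to 4 only at serialization.

## Granulometry

- **Fraction diameters.** Sieve fractions take the arithmetic midpoint
  of their bounding apertures; the pan (< 50 µm) uses 25 µm; the
  open-ended top fraction uses the coarsest aperture itself unless a
  nominal upper bound is configured (then the midpoint). Diameters
  enter the homogeneity index in µm, which puts Iθ in the 0–0.02 range
  the 500·v conversion expects.
- **Homogeneity index.** The sum in the denominator runs symmetrically
  over *all* fractions present on either side of the majority fraction,
  weighted by their diameter distance from it. Empty fractions are
  dropped; percentages are renormalized to the recovered mass; ties for
  the majority resolve to the smallest diameter (deterministic).
- **%Pf precedence.** The dedicated < 50 µm vibration test overrides the
  pan percentage of the stack test when both are present, since fines
  adhering to coarser material bias the stack's pan fraction low.
- **PSD quantiles.** D10/D50/D90 interpolate the cumulative undersize
  curve linearly in (log₁₀ size, cumulative %) by default — laser
  diffraction grids are log-spaced — with a plain linear option.
  Quantiles outside the measured cumulative range raise an error rather
  than extrapolate. The breadth ratio is F′ = D90/D10; this relation
  reproduces every published F′ value to three decimals and is the
  definition adopted here (the ratio is used in the source literature
  without an explicit formula).

## Indices and verdict

- **Reliability factor.** f = 0.952 for the 12-parameter diagram, the
  constant used throughout SeDeM practice; it reproduces published
  GCI = IPP·f pairs bit-for-bit. The exact regular-dodecagon ratio
  3/π ≈ 0.95493 is available by configuration, and other axis counts
  fall back to the geometric ratio k·sin(2π/k)/(2π).
- **IPP** is the mean of *all* twelve radii (not a mean restricted to
  radii ≥ 5): the published PP values confirm this reading empirically.
- **IP acceptability** is read as IP ≥ 0.5 (IP is a fraction; published
  IP values run 0.25–0.58).
- **Verdict.** GCI > 5 (strict) is decisive; IPP ≥ 5 and IP ≥ 0.5 are
  reported as supporting flags but do not gate. A GCI of exactly 5 is
  not suitable.

## Batch statistics

- **Levene centering.** The variance check defaults to the
  median-centered statistic (Brown–Forsythe): it reproduces the
  published variance-check p-values exactly (e.g. 0.6607 for the
  Glenmarck Carr index), which the mean-centered variant does not.
  Mean centering remains available (`levene_center="mean"`).
- **Degenerate rows.** Parameters identical everywhere (flow time for
  non-flowing powders; the cohesion index of incompressible sources)
  are reported `not_testable`, never dropped silently.
- **Verdict rule.** A grouping shows `no_difference` only when every
  testable row keeps p > α (α = 0.05 by default, configurable). No
  multiplicity correction is applied; the report states the number of
  tests run. Note the statistical consequence: with ~13 testable rows
  the all-rows-pass probability under H0 is only ≈0.5–0.65 (bounded
  below by 1 − kα), so a single "difference" row in an otherwise
  unremarkable report is expected behaviour, not evidence of a fault.
- Statistics run on radii; for linearly converted parameters the ANOVA
  F is identical on raw values (affine invariance, property-tested).

## Synthetic generator

Each supplier archetype holds true densities, tablet hardness (or an
incompressible flag), cone angle, flow behaviour, moisture percentages,
a dedicated fines percentage, and two lognormal particle-size models:
one for the sieve stack and one for the laser-diffraction curve. Sieve
percentages are obtained by integrating the sieve lognormal analytically
over the 355/212/100/50 µm cuts. Noise is multiplicative lognormal with
unit mean, applied hierarchically — one factor per quantity per batch
(default CV 0.5 %), then one per replicate — and seeded per
(study, archetype, scale, batch), so adding batches never perturbs
existing ones.

Default replicate CVs reproduce the within-batch dispersion of
triplicate powder characterization: 1.5 % on settling densities, 10 %
on tablet hardness, 3.5 % on the cone angle, 2 % on particle-size
medians and 4 % on the fines test, with large relative CVs (30–50 %) on
the sub-percent moisture quantities.

The three presets mirror the published Linezolid suppliers; their sieve
lognormals were calibrated (two-parameter root solve) so the noise-free
pipeline lands on the published per-source mean fines and homogeneity
radii, and the laser-PSD lognormals reproduce the published D50 and
D90/D10. Two real-data features are deliberately *not* emulated: the
divergence between sieve-derived and laser-diffraction size
distributions beyond what the separate fines test captures (real
cohesive powders disagree more than a single lognormal can), and any
non-lognormal shape (bimodality, skew). Passing simulation tests
therefore demonstrates the pipeline and its statistics, not instrument
realism.

## Published-table fixtures and known inconsistencies

The packaged tables were transcribed from the published study and are
checksum-tested. Three internal inconsistencies of the published tables
surfaced during verification and are handled explicitly (the acceptance
tests prove each discrepancy exists between the printed tables
themselves before excluding it):

1. Two porosity cells printed as a clamped **10.00** (first replicates
   of the fifth and sixth USV batches) contradict the printed density
   radii of the same replicates, which imply 8.40 and 9.47. The
   density-consistency check covers the other 214 replicate cells at
   ±0.01.
2. The **UQUIFA industrial pooled column** disagrees with the printed
   UQUIFA industrial replicate radii (bulk density off by 0.010, PP by
   0.0086; even the mean of the printed per-replicate PP row contradicts
   the printed pooled PP). Pooled comparisons for that source × scale
   are checked against the internally consistent printed source (the
   per-scale merge identity) instead.
3. The published fines **F-ratio 4.74** for the Glenmarck pilot batches
   does not follow from the printed radii; the recomputed value 1.78 is
   pinned in the tests so the divergence stays visible.

Where published pooled statistics were evidently computed from
full-precision radii while only 2-decimal radii are printed,
comparisons use the analytically propagated print-rounding bound
(±0.005 per radius) rather than ad-hoc tolerances.

## Raw-measurement reconstruction

Raw bench data were not published; `fixtures.reconstruct_raw_batch`
builds a synthetic raw record per batch by inverting the conversions
(100 g settling sample, 40 mm repose base, a two-fraction sieve stack
solving the homogeneity index in closed form). It is one of many raw
datasets consistent with the published radii and is labelled synthetic;
the density-derived parameters round-trip to the 2-decimal printing
precision, the directly inverted ones exactly.

## Problem sizes

The test suite and acceptance script run at the study's own scale
(18 batches × 3 replicates) plus Monte-Carlo checks sized for stable
calibration at desk scale: 1000 repetitions for the type-I error of the
3 × 3 ANOVA, 200 seeds for generator unbiasedness, and 60 simulated
studies for the scale-equivalence verdict rate.
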