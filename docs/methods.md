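# Methods

## Model and assumptions

The package computes a two-source attribution of grain N from a
dual-phase ¹⁵N pulse-chase design. A plant is labelled in exactly one
phase; at maturity each organ's excess ¹⁵N (abundance above the
natural-abundance baseline, times organ N content) measures the N that
organ received from the labelled phase. The calculus is valid under four
assumptions: no isotopic discrimination within the plant, none in N
metabolism, no N losses from the plant between silking and maturity, and
uniform mixing of the label in the root medium (hence one enrichment for
all N incorporated during a phase). The `simulate` module can violate
the third and fourth assumptions deliberately (`perturb_assumptions`)
to study the resulting estimator bias.

Two reference constants are kept separate throughout: the atmospheric-N₂
standard (0.3663 atom%), which defines the δ scale, and the empirical
natural-abundance baseline A₀ of unlabelled tissue (default
0.3733 atom%), which anchors the excess calculation. δ ↔ atom%
conversions use exact ratio algebra (R = A/(100−A)); the linear
approximation would corrupt the fourth decimal of atom% at
natural-abundance precision, exactly where leach-validation δ values of
a few per mil live.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| standard_atom_percent | 0.3663 | atom% | atmospheric N₂, δ reference |
| baseline_atom_percent (A₀) | 0.3733 | atom% | unlabelled greenhouse maize tissue |
| negative_excess_tolerance | 1e-3 | g ¹⁵N | clamp-vs-error threshold for depleted organs |
| label_atom_percent | 10 | atom% | enrichment of the K¹⁵NO₃ salt |
| dose (vegetative / reproductive) | 40 / 90 | mg ¹⁵N | phase label applications |
| noise_sd_atom_percent | 0.002 | atom% | IRMS-scale additive error |
| noise_cv_n_content | 0.05 | — | tissue sampling/combustion error (lognormal, unit mean) |
| leach_efficiency | 0.99 | — | fraction of residual medium label removed at silking |

Q(wps) for a maturity plant is the mean whole-plant N of the
silking-harvested cohort of its vegetative treatment (n = 12 in the
default design); a per-plant override exists for sensitivity analysis.
No correction factor for residual label uptake is applied by default —
the design leaches the medium at silking — but `budget_assemble` accepts
a correction hook.

Dose entry: a tracer application can be specified by salt mass
(stoichiometric ¹⁵N mass, using the label-weighted mean N molar mass) or
by a protocol-stated mg ¹⁵N. The two are not forced to agree:
680 mg of 10 atom% salt gives 10 mg ¹⁵N, but a protocol stating 40 mg
for 2.25 g of the same salt is stoichiometrically ≈33 mg; `TracerDose`
carries both and reports the stated value when given.

## What the generator emulates

The synthetic experiment reproduces the design's structure: 2 vegetative
N levels × 4 post-silking N×water treatments, six blocks in two
greenhouses (four blocks labelled), one vegetative- and one
reproductive-labelled plant per block and cell at maturity, plus a
silking-harvested cohort (12 plants per vegetative treatment) that
furnishes the Q(wps) reference. Per plant it draws pre-silking uptake,
a true remobilized fraction, and post-silking uptake; allocates
pre-silking N over four silking organ groups (stalk-heavy under high N),
moves remobilized N to the grain from fixed source weights (stalk and
leaves 45% each, roots 8%, reproductive 2%); splits residual leaf N into
green and senesced fractions; and allocates post-silking N over six
maturity organs by per-cell partition vectors. Enrichment follows the
minimal well-mixed-pool model: each phase's incorporated N carries one
enrichment, baseline + φ·(label − baseline), where φ is the
fertilizer-derived fraction of that phase's N; organ abundances are
mass-weighted mixtures of the two pools. Every plant is exactly mass-
and isotope-consistent before measurement noise, and the generator
returns its true fluxes for recovery testing.

Cell-level means (pre-silking uptake 2.76/1.61 g, remobilized grams,
post-silking uptake, partition vectors, yield components) are the
published treatment means of the emulated experiment; between-plant SDs
are reconstructed from the published standard errors as SD = SE·√n at
each table's n (12 at silking, 4 labelled plants per cell, 6 for
phenotypes). The organ-level split of pre-silking N and the
remobilization source weights are package choices constrained by the
published stalk-N contrast (1.0 vs 0.5 g at silking) and feasibility
(no source pool may be over-drained; the config validator enforces
this). φ defaults come from dose arithmetic: 0.4 g labelled N applied
pre-silking against 2.76/1.61 g uptake, 0.9 g post-silking against
0.5–1.75 g uptake, attenuated by the unlabelled fertigation supplied in
parallel (0.10/0.17 pre; 0.35–0.70 post). Per-plant enrichment variance
has no published value; the noise defaults are stated as conventions.

What it does **not** emulate: mechanistic coupling of yield to N supply
(kernel and grain-mass phenotypes are drawn from cell-level
distributions, independent of that plant's N draws), in-season flux
trajectories (single maturity sampling only), soil/medium N transport,
and block or greenhouse random effects (blocks are structural labels,
not variance components). Passing recovery tests therefore demonstrates
correctness of the estimator under the stated assumptions and noise
model, not robustness to field realism.

### Leaching

`leach_event` removes a configurable fraction (default 0.99) of the
unabsorbed vegetative label from the medium at silking; a
`residual_uptake_fraction` (default 0.5) of what survives re-enters the
post-silking pool of vegetative-labelled plants. At the defaults this
perturbs rem% by under 0.02 percentage points. The idealized
configuration (`SimConfig.noiseless()`) uses perfect leaching along with
zero noise and zero between-plant variance — it is the regime in which
all mass-balance assumptions hold exactly, and the budget must then
recover every true flux to numerical precision (the suite asserts
1e-6; observed error is ~1e-13). Setting efficiency to 0 reproduces the
upward rem% bias that motivates leaching in cells where the grain's
post-silking partition exceeds the true remobilized fraction.

## Numerical choices and degenerate inputs

- **Negative excess.** Unlabelled or depleted tissue can sit below A₀.
  `excess_n15_mass` returns the signed value; the budget layer clamps
  organ excess to zero (with a logged warning) when its magnitude is
  within `negative_excess_tolerance`, and raises beyond it.
- **Out-of-range ratios.** Grain_rem outside [0, 100] (possible with
  noisy data and a cohort-mean Q(wps) reference) is reported raw with a
  `grain_rem_out_of_range` quality flag — never silently clipped.
  Negative post-silking uptake (net N loss) warns and flags, it does not
  raise.
- **Degenerate label.** Whole-plant excess ≤ 0 on a labelled plant makes
  every label ratio undefined and raises `DegenerateLabelError`.
- **Truncation of draws.** Gaussian draws for uptakes and fractions are
  clipped to their physical ranges (and the remobilized fraction to the
  feasibility cap implied by the source weights); recorded truth is the
  realized, post-clip value, so recovery tests remain exact.
- **Rounding.** Report layer only: 1 d.p. for percentages, 2 d.p. for
  grams, halves away from zero; machine-readable CSVs keep full
  precision.
- **Aggregation.** Cell summaries are mean ± SE with the sample SD
  (n−1); SE is reported missing at n = 1. Cross-treatment headline
  numbers are unweighted averages of cell means. Two published aggregate
  constructions ("proportion of total pre-silking N", 55.6/62.5%, and
  the 85.9/31.8% pair) are not exactly reproducible from the printed
  cell means under either ratio-of-means or mean-of-ratios; both
  aggregation modes are available but neither is asserted against those
  numbers.
- **Leaf-area models.** The dimensions regression defaults to the
  shape-factor form area = k·L·W through the origin (k ≈ 0.75 is the
  standard maize value); the dry-weight regression defaults to an
  intercept model. Both forms are selectable since the original
  calibration coefficients are not published.

## Problem sizes

The default design generates 104 plants (80 maturity + 24 silking) in
well under a second. Monte-Carlo unbiasedness is checked at 32 labelled
plants per block/cell/phase (1,024 vegetative-labelled plants), chosen
to make the 0.5-point bias bound a meaningful test at the default noise
level while keeping the whole suite in a few seconds.

## Known limitations

- The Q(wps) reference is a cohort mean, so per-plant Q_rem(grain) and
  Grain_rem inherit between-plant Q(wps) variance as bias-free but
  high-variance noise; cells with large pre-silking variance can show
  flagged Grain_rem values above 100%.
- Mixed-effects inference, beta/Poisson regressions and multiple-means
  comparisons are out of scope; the CSV outputs are designed to feed
  external statistics tools.
- Statistical recovery guarantees hold under the generator's noise
  model (additive Gaussian atom%, multiplicative lognormal N content);
  heavier-tailed instrument error was not modelled.
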