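# n15budget

Mass-balance analysis of ¹⁵N pulse-chase labelling in maize: where does
grain nitrogen come from?

In maize, N taken up before silking can be stored — beyond what growth
requires ("luxury" uptake, mainly in the stalk and leaves) — and later
remobilized to the developing grain, while roots continue to take up new
N after silking. Quantifying the two sources requires isotope tracers:
plants grown in an inert, leachable medium are labelled with
¹⁵N-enriched KNO₃ during exactly one phase (vegetative or reproductive),
the medium is flushed at silking so vegetative label cannot be absorbed
later, and organ ¹⁵N enrichments at maturity are converted to N fluxes
by mass balance. `n15budget` implements that calculus, the treatment
aggregation around it, the yield-component arithmetic (spikelet
abortion, kernel weight, leaf-area regressions), and a synthetic
generator of the whole experiment with per-plant ground truth, so every
stage is testable by parameter recovery.

## The mass balance

For organ *x* with N content *Q(x)* (g) and ¹⁵N abundance *A(x)* (atom%),
the tracer-derived ("excess") ¹⁵N is

    q(x) = (A(x) − A₀)/100 · Q(x)

with *A₀* the natural-abundance baseline of unlabelled tissue
(0.3733 atom% for greenhouse maize; the atmospheric-N₂ standard is
0.3663 atom%). For a plant labelled **before** silking,

    rem%        = 100 · q(grain)/q(wpm)          (wpm = whole plant, maturity)
    Q_rem(grain) = Q(wps) · rem%/100             (wps = whole plant, silking)
    Grain_rem    = 100 · Q_rem(grain)/Q(grain)

For a plant labelled **after** silking, for every organ *x*,

    Post%(x)  = 100 · q(x)/q(wpm)
    Q_post(x) = (Q(wpm) − Q(wps)) · Post%(x)/100
    Grain_rem = 100 · (1 − Q_post(grain)/Q(grain))

*Q(wps)* is the silking-cohort mean of the plant's vegetative treatment
(it cannot be measured on a maturity-harvested plant). δ¹⁵N ↔ atom%
conversions use exact isotope-ratio algebra, never the linear
approximation.

## Worked example

```python
from n15budget import SimConfig, generate_experiment, compute_budgets
from n15budget.io import budgets_to_frame
from n15budget.report import treatment_summary, summaries_to_frame

records, truth = generate_experiment(SimConfig(), seed=42)
budgets = compute_budgets(records)          # Q(wps) estimated from the
frame = budgets_to_frame(budgets, records)  # silking cohort automatically
veg = frame[frame["label_phase"] == "vegetative"]
print(summaries_to_frame(treatment_summary(veg, "rem_pct")).round(1).to_string(index=False))
```

```
 metric veg_treatment rep_treatment  n  mean  se
rem_pct          Nveg            NW  4  57.3 1.0
rem_pct          nveg            NW  4  58.4 1.0
rem_pct          Nveg            nW  4  62.3 1.9
rem_pct          nveg            nW  4  51.7 2.0
rem_pct          Nveg            Nw  4  60.1 1.7
rem_pct          nveg            Nw  4  46.4 1.7
rem_pct          Nveg            nw  4  50.8 2.1
rem_pct          nveg            nw  4  34.4 4.0
```

Each row is a (vegetative × reproductive) treatment cell: `rem_pct` is
the estimated percent of pre-silking N remobilized to the grain,
averaged over the four vegetative-labelled plants of the cell, with its
standard error. High vegetative N (`Nveg`) remobilizes more than half of
its pre-silking N in every cell; the low-N/water-stressed cell
(`nveg`–`nw`) remobilizes the least. These estimates sit within
measurement noise of the generator's configured true fractions (e.g.
57.6% for `Nveg`–`NW`).

The same pipeline runs from the shell:

```sh
n15budget simulate --seed 42 --out plants.csv --truth truth.csv
n15budget budget plants.csv --out budgets.csv
n15budget summarize budgets.csv --metric grain_rem_pct
n15budget report plants.csv --out-dir report/
```

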