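# Methods

## The circuit

The adaptive response of *E. coli* to DNA alkylation is controlled by a
single protein, Ada, which acts as both repair enzyme and damage sensor.
Repair of methylated DNA transfers methyl groups irreversibly onto Ada;
the methylated form (meAda) activates the P_Ada promoter and so closes a
positive feedback loop. The package models three species —
unmethylated Ada, meAda, and an inactivated species inAda fed from meAda
at a lumped rate ρ (proteolysis/autorepression) — with time measured in
cell generations, so that dilution by growth appears as a first-order
loss at rate ln 2.

Deterministic rate equations (per reference cell, gene dosage g):

    d[Ada]/dt   = g·(k_basal + k_ind·[meAda]/(K + [meAda]))
                  − (ln2 + k_me·M)·[Ada]
    d[meAda]/dt = k_me·M·[Ada] − (ln2 + ρ)·[meAda]
    d[inAda]/dt = ρ·[meAda] − ln2·[inAda]

with M the MMS concentration (mM) and K = k_off/k_on the promoter
dissociation constant. The methylation flux is debited from the Ada
balance, so that summing the three equations gives
d(total)/dt = production − ln2·total: methylation and inactivation are
conversions, not losses, of the fluorophore-carrying total. The measured
observable in the experiments this emulates (a fluorescent Ada fusion) is
exactly that total.

Setting the derivatives to zero gives [Ada] as the positive root of
a·x² + b·x + c = 0 with

    a = k_me·M/(ln2 + ρ)
    b = K − g·(k_basal + k_ind)·k_me·M / ((ln2 + k_me·M)(ln2 + ρ))
    c = −g·k_basal·K/(ln2 + k_me·M)

then [meAda] = k_me·M·[Ada]/(ln2 + ρ) and [inAda] = (ρ/ln2)·[meAda].
Since c ≤ 0 there is exactly one non-negative root at every dose — the
dose response is single-valued and monotone (no hysteresis), as expected
for noncooperative promoter binding.

## Parameters

One parameter set is used everywhere (per-generation units, anchored to
the 42-min reference generation):

| parameter | default | units | meaning |
|---|---|---|---|
| k_basal | 1.25 | molecules·gen⁻¹ | basal production per gene copy |
| k_ind | 1250 | molecules·gen⁻¹ | fully induced production per copy |
| k_on | 10 | gen⁻¹ | promoter association (at unit volume) |
| k_off | 1200 | gen⁻¹ (K in molecules) | promoter dissociation |
| k_me | 1.25 | mM⁻¹·gen⁻¹ | effective methylation coefficient |
| ρ | 0.65 | gen⁻¹ | meAda inactivation |
| generation time | 42 | min | reference (75 min for glycerol growth) |
| gene copies | 1 | — | production scales per copy |

`convert_rates_for_generation_time` re-expresses the set for a different
division interval holding real-time rates fixed: every production and
conversion rate scales by T_new/T_ref while dilution remains ln 2 per
(new) generation. Slower growth therefore raises production relative to
dilution — the mechanism behind the growth-rate dependence of the
response for a terminus-proximal gene whose copy number does not rise
with growth rate.

## Stochastic simulator

The same kinetics are unfolded into six elementary reactions on integer
counts (basal and induced production per promoter copy, methylation,
inactivation, binding, unbinding) and simulated exactly with Gillespie's
algorithm. Conventions:

- **Growth and division.** Volume grows deterministically as 2^age over
  one generation (birth volume 1); at each integer generation time the
  followed daughter keeps Binomial(n, 1/2) of each free species and the
  volume resets. There is no explicit dilution reaction — all molecule
  loss is partitioning. Division times are deterministic (the measured
  ±8-min cycle-length variability is not modeled), so divisions are
  synchronized across cells that start together.
- **Volume-scaled binding.** The association propensity is
  (k_on/volume)·n_me·free_copies; it is the only volume-dependent rate.
  Waiting times are drawn exactly while it is zero; while it is active,
  steps are capped at 0.01 generation and propensities re-evaluated, so
  the error of treating volume as constant within a step is bounded by a
  0.7% volume change.
- **Bound meAda** is sequestered (no ρ-inactivation, no methylation) but
  counted in the total; at division it is released before partitioning
  and the promoter resets to free.
- **Initial condition.** n_ada ~ Poisson(1) (the measured basal mean per
  cell at birth), other species absent; an alternative initializer draws
  Poisson counts around the deterministic steady state at a given dose,
  used to study deactivation without simulating the slow approach.
- **RNG.** One master seed; per-cell streams are spawned with
  `numpy.random.SeedSequence`, so populations are reproducible and cell i
  is invariant to the population size.

In the damage-free regime the simulator has an exact law: the count at
cell age a is Poisson with mean k_basal·(1 + a) (fresh production
Poisson(k_basal·a) plus binomially thinned Poisson production of all past
generations, Σ_j 2^{-j} = 1). This is the strongest oracle in the test
suite (chi-square at 10⁴ lineages) and the basis of the
`recover_k_basal` moment estimator, mean count = k_basal·(1 + mean age).

### Perturbation modes

- `no_division`: divisions suppressed; volume grows as 2^t unbounded and
  the gene copy number doubles at each nominal generation boundary
  (replication without septation, as under cephalexin).
- `gene_duplication`: two gene copies throughout (low-copy plasmid
  carrying the same promoter); both copies use per-copy rates.
- `growth_time(T)`: rates converted as above; divisions every T minutes.

## Trace analysis

- **Activation time**: first sampled time (3-min grid, matching the
  imaging interval) at which the total count is at or above the
  threshold, default 23 molecules — the experimental detection limit.
  Crossings are evaluated on samples, not event times.
- **Deactivation time**: first post-removal sample below threshold that
  stays below for one generation (the window may be truncated by the end
  of the trace). The sustain requirement suppresses flicker at the
  boundary; the original analysis did not define this statistic, so the
  convention is the package's own.
- **Conditional delays**: mean time from MMS addition to the first
  methylation event, grouped by initial copy number {0, 1, 2, >2}.
  Empty groups are reported as missing, never as zero.
- **Exponential fit**: maximum-likelihood rate 1/mean with a
  Kolmogorov–Smirnov goodness-of-fit p-value.
- **recover_rho**: after MMS removal no new meAda is made, so the
  log-linear slope of meAda gives −(ln2 + ρ). On deterministic input the
  recovery is exact. On population means of the stochastic model the
  decay is a sawtooth (continuous ρ-loss within a cycle, a halving at
  each synchronized division), so the estimator should be fed
  phase-matched samples — one per generation at a fixed cycle phase —
  which removes the sawtooth bias entirely (recovery within ~1% at 1000
  cells in the tests).

## Synthetic fluorescence data

`emulate_fluorescence` maps a count trace to what the microscope
records: signal = intensity·detected_fraction·total/volume (a mean-pixel
concentration-like signal), optionally times a per-cell log-normal
extrinsic factor (default off — the circuit model deliberately contains
only intrinsic noise), plus Gaussian camera background per sample, with
the per-cell pre-treatment baseline subtraction the experimental
pipeline applies. Maturation is a static detected fraction
1/(1 + t_half/T) — 0.81 for the 9.7-min fluorophore at 42-min
generations — not an explicit maturation reaction; this matches the
correction applied to the real data and keeps ground truth comparable.
What is *not* emulated: segmentation errors, photobleaching, shot noise,
cell-cycle-length variability. Passing round-trip tests therefore show
estimator correctness on the model's own observables, not robustness to
every imaging artifact.

## Two-site methylation variant

Ada methylation occurs at two cysteines (Cys38, Cys321). The variant
model requires both, in sequence (rates k_me_1·M then k_me_2·M), before
the doubly methylated species activates transcription; the singly
methylated intermediate is inert but counted in the total. Its steady
state is solved by bracketing the largest fixed point of the monotone
chain map in [meAda] (Brent). The variant collapses onto the single-rate
model as k_me_2/k_me_1 → ∞, with the dose-response deviation scaling as
the inverse rate ratio (2.8% at 10³ near the switch, <10⁻⁴ at 10⁶);
with comparable per-site rates the response is right-shifted and cannot
be matched by any single effective rate — the argument for the lumped
k_me. Sequential rather than independent-site methylation is the
minimal scheme consistent with the biology; an unordered variant is out
of scope.

## Numerical choices

- ODE integration: adaptive RK45 (scipy `solve_ivp`), rtol 1e-10,
  atol 1e-12, restarted at every MMS breakpoint so the input
  discontinuities are exact; output on a regular grid.
- Steady state: the quadratic is solved with the cancellation-free root
  form (2c/(−b−√D) when b > 0), which remains accurate in the
  near-degenerate low-dose limit a → 0.
- Tie-breaks and degenerate inputs: zero dose (or k_me = 0) returns the
  basal fixed point g·k_basal/ln2 directly; zero total propensity in the
  simulator jumps to the next scheduled boundary.

## Known limitations

- **Induced-level bias.** With k_on calibrated at birth volume 1, the
  cell is always at least as large as the calibration volume, so the
  stochastic promoter occupancy — and hence the induced quasi-steady
  level — sits systematically below the volume-free deterministic
  occupancy (measured factor ≈ 0.63 at 1 mM). The deterministic and
  stochastic models agree exactly in the basal regime and in decay
  rates; the induced plateau differs by this structural factor.
- **Deterministic switch position.** The deterministic dose response
  rises steeply near 0.08 mM and is already high (≈930 molecules) at
  0.2 mM; the broadly delayed, pulse-like behavior observed at
  0.05–0.35 mM is a property of the stochastic model only.
- **Delay distributions.** Activation delays of initially Ada-free cells
  are the memoryless basal wait (exactly Exp(k_basal)) *plus* a ~1
  generation feedback climb to the detection threshold; the compound is
  exponential-like in the tail but not strictly exponential.
- Divisions are synchronized and equidistant; there is no mRNA step, no
  explicit DNA-lesion counter (damage is absorbed into the constant
  methylation coefficient), and no extrinsic noise unless enabled in the
  fluorescence emulator.

## Problem sizes

The test suite and analysis scripts use 150–1000 cells per stochastic
condition (10⁴ lineages for the basal Poisson chi-square), 20–40
generations of simulated time, and 3-min sampling — population sizes at
which every asserted effect is many standard errors wide while the full
suite completes in about a minute on one core.
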