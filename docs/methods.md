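# Methods

## Life-table model

The unit of data is a synchronized cohort of `n0` self-fertilizing
hermaphrodites observed individually at checkpoint times `t_1 < t_2 < …`
(hours since cohort hatch). Checkpoint `i` closes the half-open interval
`(t_i − D_i, t_i]`. For each interval the pipeline records, per individual,
the eggs laid, the juveniles that hatched from those eggs (the drop is left
undisturbed for 48 h after transfer, so hatch counts are credited to the
interval in which the egg was *laid*), and vital status.

The cohort life table assigns to each interval

- `l_x` — fraction of the initial cohort alive at the closing checkpoint.
  A death is counted at the first checkpoint at or after the death time;
  this end-of-interval convention is the only one consistent with the
  bundled published table, where a death at 89 h lowers `l_x` at the 93 h
  row rather than the 87 h row.
- `m_x` — hatched juveniles in the interval per individual alive at the
  closing checkpoint. The normalizing population is configurable
  (`interval_end`, default, or `interval_start`); with the default, the
  identity `Σ l_x m_x = total juveniles / n0` holds exactly, which is also
  how the Monte-Carlo convergence test interprets `R0`.

Tables are trimmed to the reproductive window (first to last interval with
juveniles) but interior zero-production rows are retained. Individuals that
die before laying any egg stay in `l_x` (and hence in all rate-of-increase
calculations) but are excluded from the fecundity-percentage means and from
the trait summaries; they are reported as juvenile mortality instead. The
record schema carries a `censored_at` field for individuals alive at the end
of observation; censored individuals leave the risk set at their censoring
checkpoint (the bundled table has none — that experiment ran to the last
death — and the simulator produces none by default).

Sexual maturity is operationalized as the first interval with eggs laid.
Interval-censored event times (death, first egg, peak laying rate) are
point-estimated at the midpoint of their interval, which is unbiased when
the event time is roughly uniform within the interval.

## Rate metrics

All rates derive from the discrete Euler–Lotka identity
`Σ_x e^(−r_m·x) l_x m_x = 1`, with interval ages `x` under a selectable
convention: `interval_end` (the checkpoint times, default),
`interval_midpoint`, or `interval_start`. Ages are stored in hours and
`r_m` is reported per day; every exponent converts units explicitly.
The default convention is the one validated by the published cohort
generation time (`G0 = Σ x l_x m_x / Σ l_x m_x ≈ 137.2 h` against the
printed 137 h); the other two are provided because the field's literature
is not consistent about the choice.

The left-hand side is strictly decreasing in `r_m` whenever any
reproduction occurs at a positive age, so the root is unique. It is
bracketed on `[−5, 10] d⁻¹` (expanded geometrically if needed), solved by
Brent's method and polished with Newton steps until `|LHS − 1| < 1e−10`.
Degenerate inputs: an empty or zero-reproduction table raises a no-root
error; `R0 = 1` yields `r_m = 0` exactly; doubling time and `G1` are
undefined (refused) at `r_m ≤ 0` / `r_m = 0`.

`Gh = Σ x e^(−r_m x) l_x m_x` presupposes that `r_m` is the Euler–Lotka
root, where the discounted sum is 1; called with any other rate the
implementation divides by the discounted sum so the result remains a
weighted mean age.

**Leslie-matrix cross-check.** `leslie_growth_oracle` resamples the table
onto a uniform age grid (step ≤ the finest interval): each reproductive
mass `l_x m_x` acts at the end of the grid class containing its age,
fertilities are mass divided by survivorship at the class start, and
subdiagonal survival entries are ratios of the survivorship step function.
Because the survival entries cancel in the characteristic equation, the log
of the dominant eigenvalue reproduces the Euler–Lotka root exactly when the
ages are multiples of the step — making the eigenvalue computation an
independent oracle for the root-finder rather than a discretized
approximation.

**A note on the published point estimates.** For the bundled table the
solver gives `r_m = 1.027 d⁻¹` (end), `1.065` (midpoint) or `1.106`
(start), in all cases agreeing with the Leslie eigenvalue to ~1e−13 but not
with the published 1.125 d⁻¹ (at which the discounted sum is ≈ 0.69, not
1). The published `G1 = 98 h` and `Gh = 80 h` are likewise mutually
inconsistent with `G1 = ln R0 / r_m` at `r_m = 1.125` (≈ 100 h). The
aggregation behind those published values is unstated; this package
therefore treats the printed life table as the ground truth and reports the
rates it implies, and validates the solver structurally (closed forms,
monotonicity, eigenvalue oracle) rather than against those three numbers.

## Hatching-time estimator

`Ht = N_eggs / (N_juv + N_eggs) × T_h` estimates the egg-to-hatch time from
a snapshot after `T_h` hours of continuous laying: under steady-state laying
the unhatched fraction of all eggs produced equals the fraction of the
observation window occupied by unhatched development. Undefined when no
eggs or juveniles were scored.

## Synthetic cohort generator

The simulator emulates the hanging-drop assay on a shared cohort clock.
Per individual: with probability 2/33 it dies as a juvenile, uniformly
between 24 h and its (would-be) maturation age, laying nothing. Otherwise
it matures at a truncated-normal age (65.1 ± 8.4 h, > 24 h) — maturation
*is* the first egg deposition — dies at a truncated-normal age
(22.5 ± 7.3 d, conditioned to exceed maturation), and lays a
truncated-normal number of eggs (269.6 ± 73.4, ≥ 1): the first at
maturation, the rest at ages drawn from a gamma-shaped laying intensity
(shape 6, mode 140.8 h — the published age at peak laying rate) restricted
to [maturation, min(death, 14 d)]. Each egg is fertile with probability
given by the product of two logistic ramps whose falling branch is solved
in closed form through the two published anchors (97.4 % at 6.1 d, 0.21 %
at 12.8 d; clamped to 0 after 13 d) and whose rising branch (midpoint 60 h,
scale 12 h) makes fertility moderate at first reproduction and saturated by
the peak. Fertile eggs hatch after a truncated-normal delay (25.3 ± 1.6 h).

Design choices worth flagging:

- **Egg totals are compressed, not truncated, by early death**: the drawn
  lifetime egg count is always laid within the realized life. The
  configured 269.6 is a *realized* lifetime mean in the source data
  (individuals dying mid-laying included), so right-truncating by death
  would systematically undershoot it; the compression keeps the configured
  mean recoverable at the cost of letting short-lived adults lay at a
  higher instantaneous rate.
- **Unimodal laying intensity**: the apparent second egg-laying peak in
  such assays is an artifact of coarsening time resolution late in the
  schedule; the simulator's intensity is unimodal and the observer's
  unequal binning reproduces the artifact.
- **Internal tension in the published summaries**: 269.6 eggs combined
  with the published fertility-curve anchors implies ≈ 207 juveniles per
  individual, far above the published `R0 ≈ 109` (which implies a mean egg
  fertility of ~42 %). The generator honors the printed anchors and egg
  total, so its realized `R0` is ≈ 207, and no recovery claim is made for
  `R0 = 109`.
- **Trait independence**: maturation, lifespan and egg number are drawn
  independently; no published data constrain their correlations.
- Matricidal hatching (*endotokia matricida*), male/outcrossed
  reproduction, food dynamics and temperature dependence are out of scope.

Randomness: one `SeedSequence` per simulation spawns an independent
substream per individual, so enlarging a cohort preserves the individuals
already drawn.

The observer censors an event log to any checkpoint schedule: eggs binned to
the interval containing the lay time, juveniles credited to the same
interval, death reported at the first checkpoint ≥ the death time. Egg
totals are conserved exactly under any cadence. The default schedule mirrors
the study cadence contiguously: daily checks to 45 h, 6 h intervals to
123 h, 12 h to 291 h, 24 h thereafter. (The published table itself has a
9 h gap at its 6 h→12 h transition; schedules therefore need not be
contiguous, only non-overlapping.)

**What the simulator does and does not establish.** Passing recovery tests
shows the pipeline correctly inverts the generator's censoring and
aggregation at the study's sample size: means of lifespan, first-egg age
and egg totals are recovered within Monte-Carlo plus half-bin tolerances,
and `R0` estimated from observed records converges (CLT-bounded) to an
expectation computed by direct numerical integration of the model
(`expected_r0`, a quadrature over the maturation and lifespan distributions
and the within-life lay-age density — independent of the simulation path).
It does not validate the biological realism of the parametric forms
(normal traits, gamma intensity, logistic fertility), nor correlations
between traits, nor behaviour under food or temperature variation.

## Numerical conventions

- Hours everywhere internally; days only at the user surface (`r_m`,
  lifespan).
- Printed-table comparisons use the two-decimal rounding of the source;
  internal arithmetic is full precision. The printed `l_x·m_x` column is
  never used for computation: it is recomputed from `l_x` and `m_x`, with a
  logged warning if the printed product deviates by more than 0.01.
- `n0` for a life table read from disk: explicit argument, else an
  `# n0 = N` header comment, else the smallest cohort size whose fractions
  round to every printed `l_x` (strictly within 0.005, the half-ulp of
  two-decimal printing — for the bundled table this uniquely gives 33).
- Ties in the per-individual peak laying rate resolve to the earliest
  interval.
- Problem sizes in the test suite and acceptance script: 100 random tables
  per solver property, 200 replicate cohorts of n = 33 for trait recovery,
  n = 1500 for the `R0` convergence check — sizes at which the Monte-Carlo
  bounds above are already far tighter than the effects being checked.

## Known limitations

- `l_x` treats a censored individual as leaving the cohort (risk set) at
  its censoring checkpoint rather than Kaplan–Meier-weighting the tail;
  with no censoring (the intended regime) the two coincide.
- The fecundity percentage is an unweighted mean over individuals, so
  intervals where few individuals lay are noisy; points with no layers are
  reported without a percentage.
- The simulator draws egg lay times conditionally i.i.d. given the count,
  not as a true point process; inter-egg intervals are therefore not
  exchangeable with real laying dynamics at fine time scales.
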