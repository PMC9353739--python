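# Methods

## Model structure

The model is a three-state Markov cohort: progression-free (PFS),
progressed disease (PD), and death (absorbing). The whole cohort starts
progression-free. Cycles are 21 days — the chemotherapy administration
interval — and the horizon is 174 cycles (`ceil(10 × 365.25 / 21)`), ten
years, by which point over 98% of both simulated cohorts have died, so the
truncation loses almost nothing. There is no half-cycle correction
anywhere: costs and utilities attach to start-of-cycle state occupancy,
consistent with treatment costs being incurred at the start of each cycle.

## Survival

Each arm's PFS and overall survival (OS) are Weibull,
`S(t) = exp(−λ t^γ)` with `t` in cycles. The packaged parameters are the
fitted values for the two arms (combination λ/γ: PFS 0.021350/1.210605,
OS 0.006578/1.263333; chemotherapy: PFS 0.057642/1.019433, OS
0.010970/1.216254). The medians these imply — 12.2 / 7.9 months PFS and
27.5 / 20.9 months OS — sit within 10% (OS within 2%) of the trial's
reported 11.3 / 8.3 / 27.9 / 20.5 months, which is the package's fitted-
curve validation.

Per-cycle exit probabilities use the exact conditional form
`p_u = 1 − S(u)/S(u−1)`, i.e. the declining-exponential (DEALE) conversion
`p = 1 − e^(−rt)` evaluated with the average hazard over each cycle. A
single constant hazard cannot represent a Weibull with `γ ≠ 1`, so the
conversion is applied per cycle; the product `Π(1 − p_u)` then
reconstructs `S(t)` to machine precision, which is tested.

### Fitting

Two fitting routes are provided, matching the two kinds of input a
reproduction can have:

* **Digitized curve coordinates** (`fit_weibull`): ordinary least squares
  on the complementary log-log linearization
  `ln(−ln S) = ln λ + γ ln t`, excluding `S = 1` and `t = 0` points, then
  a nonlinear least-squares refinement on the survival scale (Levenberg–
  Marquardt, log-parameterized for positivity). On noise-free Weibull
  input the linearization alone is exact; the refinement matters only
  under digitization noise.
* **Pseudo individual-patient data** (`fit_weibull_ipd`): censored maximum
  likelihood via `lifelines.WeibullFitter`, the efficient estimator when
  patient-level times exist.

A caveat worth stating plainly: in the `(λ, γ)` parameterization the
scale is hard to estimate from small samples. Errors in `γ` propagate into
`ln λ` multiplied by the log of the characteristic time (≈3.4 here), so
the relative standard error of `λ̂` at n = 200 is roughly 20% even for the
MLE, while `γ̂` and stable functionals such as the median are far tighter.
Recovery tests therefore check a fixed replicate (and exactness on
noise-free input, and shrinking error with n) rather than asserting a
universally tight per-sample bound that no estimator attains.

## Transition engine

The default (`transition`) engine walks the chain cycle by cycle. The PFS
exit probability comes from the PFS curve; of that exit, a background
all-cause mortality probability (annual 0.0071, approximating China's 2020
crude death rate, converted to the 21-day cycle by compounding) goes
PFS→death and the remainder PFS→PD. Patients progressing in a cycle are at
risk of dying within it (a jump-through transition), and the PD→death
probability is calibrated each cycle so cumulative deaths equal
`1 − S_os(t)`. The alternative `occupancy` engine evaluates the
partitioned-survival identities directly: `PFS = S_pfs`,
`PD = max(0, S_os − S_pfs)`, `death = 1 − S_os`.

Because the calibration pins deaths to the OS curve, the two engines agree
to machine precision whenever no probability clipping occurs — and, less
obviously, the trace is *invariant to the background mortality level*: the
background rate only re-routes PFS exits between PD and death, and the
calibration immediately compensates. Both facts are property-tested. The
published description (background mortality for PFS→death, fitted curves
for everything else) is thus honored without the results depending on an
unpublished mortality constant. If the fitted curves ever cross
(`S_os < S_pfs`), PD occupancy floors at zero, the clipped probability is
forced into `[0, 1]`, and each event is counted and logged — silent
negative occupancy being the classic partitioned-survival bug.

## Costs and utilities

All costs are USD (the source analysis converted at 6.8974 CNY/USD, 2020
average; the rate is kept in the config for provenance). Per cycle in PFS:

| phase | combination arm | chemotherapy arm |
|---|---|---|
| cycles 1–4 (induction) | camrelizumab 424.51 + pemetrexed 393.99 + carboplatin 11.96 + pretreatment 1.52 + administration 72.54 | pemetrexed + carboplatin + pretreatment + administration 71.85 |
| cycles 5–34 | camrelizumab + pemetrexed + pretreatment + administration 66.27 | pemetrexed + pretreatment + administration 56.36 |
| cycles > 34 | pemetrexed + pretreatment + administration 65.58 | unchanged |

Induction is fixed at 4 cycles (the lower limit of the 4–6 cycle course);
pemetrexed maintenance continues until progression in both arms;
camrelizumab stops at 34 cycles of total exposure. Every alive cycle adds
disease management: 60.64 for model cycles ≤ 18, 48.68 after, counted from
model entry regardless of state. The grade ≥3 adverse-event management
cost (120.06 combination / 80.32 chemotherapy) is charged once at cycle 1
(discount factor exactly 1): a single lump is all the source provides, and
severe treatment-related events concentrate early.

**Progressed-disease costing.** The PD state accrues *both* second-line
components — docetaxel chemotherapy (392.61/cycle) and
nivolumab/camrelizumab immunotherapy (698.77/cycle) — in *both* arms, plus
disease management, for the entire PD sojourn. This is the one place where
the parameter table's row labels ("second-line therapy in the … group")
admit two readings, and the joint reading is adopted deliberately: with
per-arm-exclusive second-line costs the model's discounted totals come out
25–35% below the published per-arm totals, while the implied PD cost per
cycle that reproduces them is ≈$1,135/cycle in both arms — precisely the
sum of the two rows plus disease management. With the joint rule the
published totals are matched to 0.1–0.5% (ICER to 4%), so it is evidently
what the original computation did. Both rows still enter one-way and
probabilistic sensitivity analysis separately.

QALYs weight PFS cycles by 0.804 and PD cycles by 0.321, times
21/365.25 years per cycle. Costs and QALYs are discounted at 5%/year as
`(1 + r)^(−(u−1) × 21/365.25)` for cycle `u`, so the first cycle is
undiscounted.

With these rules the base case gives: chemotherapy $30,614.41 / 1.1037
QALYs, combination $45,508.57 / 1.4334 QALYs, increments $14,894.16 and
0.3297 QALYs, ICER $45,172.64 per QALY — within 0.5% of the published
per-arm totals and within 4.4% of the published ICER of $43,275.43 (the
residual traces to the published ΔQALY being the rounded 0.34).

## Sensitivity analysis

**One-way (tornado).** Every parameter-table row is set to its low and
high bound in turn, the full deterministic model re-run, and rows sorted
by ICER spread. The camrelizumab price, fixed by national reimbursement
negotiation with no room to rise, varies downward only ([low, base]). The
discount rate varies over 0–8%. At the packaged inputs the PFS utility
dominates the tornado and no parameter's interval crosses the
willingness-to-pay threshold — the model's conclusion is robust — both of
which are asserted in tests.

**Probabilistic.** 1,000 draws (configurable); costs sampled from gamma,
utilities from beta distributions built by method of moments with
`mean = base` and `sd = (high − low)/2`, i.e. the low–high range read as
mean ± 1 sd. The range here is a spread of observed provincial prices
(e.g. pemetrexed 187.78–402.11 around 393.99), not a confidence interval;
reading it as a 95% CI (`sd = range/3.92`) makes the extremes practically
unreachable and yields an acceptability curve far steeper than the
published one (15/81/98% vs 27.1/66.7/88.0% at $40k/50k/60k), whereas the
±1 sd reading reproduces the published probabilities within a few points.
The divisor is an explicit argument (`range_z`) for anyone preferring the
other convention. The discount rate and the survival parameters are not
sampled (the distribution column of the source covers only costs and
utilities); sampled values are shared across arms where the parameter is
shared. Draws are generated by a dedicated `numpy` generator seeded per
run, making the PSA bit-reproducible; the acceptability curve is the
fraction of draws with nonnegative incremental net monetary benefit
`wtp × ΔQALY − ΔCost`.

Since the survival curves are fixed, the state traces are computed once
and reused across draws and tornado evaluations — an exact optimization,
not an approximation.

## Synthetic data

No patient-level data are published, so the generator produces what the
pipeline's inputs would look like: pseudo-IPD drawn from known Weibull
truths by inverse transform with independent exponential censoring
(default annual rate 0.12, chosen so roughly a fifth of chemotherapy-arm
OS records censor within ~52 cycles), product-limit curves from them, and
a digitization-noise operator (subsample + truncated Gaussian jitter +
re-imposed monotonicity) emulating manual curve extraction. What this
deliberately does not emulate: treatment switching, informative censoring,
number-at-risk tables, or PD-L1 subgroups — so passing recovery tests
show the fitting machinery is sound, not that real digitized curves carry
this little error.

## Problem sizes and runtime

The default test and reproduction runs use the study's own sizes: 174
cycles, 1,000 PSA draws, pseudo-IPD at n = 200–2,000 (with one n = 10⁵
draw-moment check). The base case evaluates in ~50 ms and the full PSA in
well under a minute on a single core.

## Known limitations

* The model reproduces a published analysis; it does not re-estimate
  survival from trial data, and the Weibull family is the only one
  offered (the source fit no other).
* The joint second-line costing above is inferred from the published
  totals, not stated by the source in so many words.
* Costs are Chinese 2020 prices; transferring the model elsewhere means
  replacing the whole parameter table, not just the exchange rate.
* The PSA treats parameters as independent; no correlation structure is
  available in the source.
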