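# nsclc-cea

A Markov cohort cost-utility model comparing **camrelizumab plus
pemetrexed/carboplatin** against **pemetrexed/carboplatin alone** as
first-line treatment for advanced nonsquamous non-small-cell lung cancer
(NSCLC), from the perspective of the Chinese health-care system.

The package is aimed at health-economics analysts who want a transparent,
fully tested re-implementation of this published class of analysis: every
input sits in one YAML configuration, every modeling rule is a plain
library function, and the deterministic and probabilistic sensitivity
analyses are reproducible down to the bit for a fixed seed.

## The model

Three health states — progression-free (PFS), progressed disease (PD), and
death (absorbing) — are simulated over a 10-year horizon in 21-day cycles
(174 cycles). Survival in each arm is extrapolated with Weibull curves
fitted to digitized Kaplan–Meier coordinates,

```
S(t) = exp(−λ t^γ),   t in cycles,
```

with per-cycle transition probabilities taken as the exact conditional
exit probability `p_u = 1 − S(u)/S(u−1)` (the DEALE conversion
`p = 1 − e^(−rt)` with the cycle-averaged hazard). PFS→death carries a
background all-cause mortality; PD→death is calibrated each cycle so
cumulative deaths track the overall-survival curve. Each alive cycle
accrues phase-dependent costs (4-cycle platinum induction, pemetrexed
maintenance, a 34-cycle camrelizumab cap, second-line therapy in PD,
disease management, a lump adverse-event cost) and utility-weighted life
time (PFS 0.804, PD 0.321), both discounted at 5% per year with no
half-cycle correction. The headline statistic is the incremental
cost-effectiveness ratio

```
ICER = ΔCost / ΔQALY   (USD per quality-adjusted life year),
```

judged against a willingness-to-pay threshold of three times China's 2020
per-capita GDP ($31,510.57/QALY). Uncertainty is assessed by one-way
sensitivity analysis (tornado) and a 1,000-draw probabilistic sensitivity
analysis with gamma-distributed costs and beta-distributed utilities,
summarized as a cost-effectiveness acceptability curve. See
`docs/methods.md` for assumptions, parameter provenance, and numerical
conventions.

## Worked example

```sh
nsclc-cea --mode base
```

prints

```
chemotherapy:        cost    30,614.41 USD   QALYs 1.1037
camrelizumab+chemo:  cost    45,508.57 USD   QALYs 1.4334
increment:           cost    14,894.16 USD   QALYs 0.3297
ICER 45,172.64 USD/QALY > WTP 31,510.57: combination therapy is not cost-effective
```

Adding camrelizumab buys 0.33 QALYs at an extra discounted cost of
$14,894 — about $45,173 per QALY gained, above the $31,511 threshold, so
the combination is not cost-effective at that willingness-to-pay. The same
numbers are available programmatically:

```python
from nsclc_cea import load_config, evaluate_model, run_psa, ceac

bundle = load_config()                 # packaged base case
result = evaluate_model(bundle)        # CEResult with costs, QALYs, ICER
samples = run_psa(bundle, seed=1)      # 1,000 probabilistic draws
curve = ceac(samples, [40000, 50000, 60000])
```

`nsclc-cea --mode full --seed 1 --outdir results` additionally writes the
per-arm traces, the tornado table and plot, the PSA draws and scatter, the
acceptability curve, and a JSON report of deviations from the published
results this analysis reproduces.

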