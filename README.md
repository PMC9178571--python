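# milkpay

Scoring and statistical analysis of **payment programs based on milk
quality (PPBMQ)** for monthly bulk-tank-milk (BTM) panels.

Dairy cooperatives in Thailand price raw milk by quality: each monthly
BTM sample is classified into payment bands by its fat %, solids-not-fat
(SNF) %, and somatic cell count (SCC), and each band carries a signed
price adjustment in baht per 1000 kg (bonus, base, or penalty).  The
**final price** FP of a farm-month is the sum of the three component
adjustments; its sign places the farm-month in the *benefit-gain*
(FP > 0), *benefit-loss* (FP < 0), or *no-benefit* (FP = 0) group.
`milkpay` is aimed at veterinary epidemiologists and dairy-economics
analysts who want to score such panels reproducibly, summarize who
benefits where and when, and test regional differences while accounting
for repeated measurements on the same farms.

The package provides:

* **schedule** — the Thai payment schedule as data (a YAML config, so
  what-if schedules need no code changes), band classification, final
  price and benefit group per record, and the national raw-milk
  standards check (SCC ≤ 500,000 cells/mL, fat ≥ 3.35 %, SNF ≥ 8.25 %).
* **summarize** — payment-category percentages per component, benefit
  proportions by region and month, and the most frequent
  (fat, snf, scc) payment-pattern triples per region.
* **glmm** — a farm-random-intercept logistic model of the monthly
  benefit indicator, fitted by maximizing the exact marginal likelihood
  with adaptive Gauss–Hermite quadrature, plus multiplicity-adjusted
  monthly region contrasts.
* **synthetic** — a calibrated generator of realistic two-region BTM
  panels (farm clustering, regional shifts, seasonality) for testing,
  power studies, and worked examples.
* a `milkpay` command-line interface chaining all stages.

## The model

For farm *i* in region *k* at panel month *t* (t = 1…24), let
*y<sub>ikt</sub>* = 1 if the farm-month falls in the benefit-gain group.
The model is

logit P(*y<sub>ikt</sub>* = 1 | *u<sub>i</sub>*) =
β₀ + β₁·region<sub>k</sub> + β₂ₜ·month<sub>t</sub> +
β₃ₜ·(region<sub>k</sub>×month<sub>t</sub>) + *u<sub>i</sub>*,
  *u<sub>i</sub>* ~ N(0, σ<sub>u</sub>²)

with month as a categorical factor so that the central−north contrast is
estimable in every month.  The farm intercept *u<sub>i</sub>* captures
the correlation among a farm's monthly outcomes.  The marginal
likelihood integrates *u<sub>i</sub>* out per farm with adaptive
Gauss–Hermite quadrature (posterior-mode recentering, 15 nodes), and the
T monthly contrasts are tested with a single-step max-|z| adjustment
over the family, using the estimated contrast covariance and a seeded
Monte-Carlo multivariate-normal quantile.  See `docs/methods.md` for
assumptions, numerics, and limitations.

## Worked example

Score a single record:

```python
import milkpay as mp

rec = mp.BTMRecord("TH0042", "central", 2018, 6, fat=3.85, snf=8.40, scc=650)
res = mp.score_record(rec)
for comp, a in res.assignments.items():
    print(f"{comp.value:>4s}: class {a.label:<3s} {a.category.value:<7s} {a.adjustment:+.0f} baht")
print(f"final price: {res.final_price:+.0f} baht per 1000 kg -> {res.group.value}")
```

```
 fat: class A+  bonus   +300 baht
 snf: class B   base    +0 baht
 scc: class C   penalty -200 baht
final price: +100 baht per 1000 kg -> gain
```

The fat bonus (+300) outweighs the SCC penalty (−200), so this
farm-month gains 100 baht per 1000 kg on top of the base price even
though its SCC (650,000 cells/mL) violates the raw-milk standard.

Generate the default synthetic panel (3,142 farms over 24 months,
thinned to 37,077 records), score it, and summarize:

```python
from milkpay import generate_panel, score_panel, PanelDataset, benefit_proportions
from milkpay.glmm import fit_glmm, monthly_contrasts

scored = PanelDataset(score_panel(generate_panel().df))
print(benefit_proportions(scored, {"region"}).to_string(index=False))
```

```
 region  n_records  n_gain  n_loss  n_none  pct_gain
central      18438   10515    6692    1231 57.028962
  north      18639   16500    1607     532 88.524062
```

Central-region farm-months gain far less often (57.0 %) than northern
ones (88.5 %), mirroring the published study's 57.1 % / 88.7 %.  The
mixed model quantifies the gap on the log-odds scale per month:

```python
fit = fit_glmm(scored)
print(monthly_contrasts(fit, seed=0).head(4).round(4).to_string(index=False))
```

```
 month  estimate     se        z  p_raw  p_adj
     1   -2.5796 0.2101 -12.2780    0.0    0.0
     2   -2.3376 0.1899 -12.3085    0.0    0.0
     3   -2.6602 0.1927 -13.8069    0.0    0.0
     4   -2.2512 0.1680 -13.4016    0.0    0.0
```

Each row is the central−north log-odds difference for one month with its
family-adjusted p-value; here the central region's deficit is 2.3–2.7
log-odds units in early 2018, significant in every month.  The fitted
farm-intercept SD is σ̂ᵤ ≈ 1.5, i.e. strong farm-to-farm heterogeneity.

The same pipeline runs from the shell:

```bash
milkpay report --seed 11 --out results/demo --plots
```

writing the panel, scored records, summary tables, model coefficients,
contrasts, figures, and a run log.

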