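# ntsg

Sine-amplified lifetime distribution families for survival and reliability
data, with maximum-likelihood fitting, goodness-of-fit model comparison,
Monte-Carlo parameter-recovery studies, and an attribute *np* control chart
for percentile life under truncated life tests.

## The model

The package builds lifetime models by amplifying a baseline CDF
*G*(*t*; **κ**) through a sine transform:

```
F(t; λ, κ) = 1 − λ(1 − s)/(λ − s),   s = sin[(π/2) G(t; κ)],   λ > 1
```

with density `f = πλ(λ−1) g cos[(π/2)G] / (2(λ−s)²)`. The amplification
parameter λ interpolates between a heavy-tailed tilt of the baseline (λ near
1) and the plain sine transform `sin[(π/2)G]` (λ → ∞). With a Weibull
baseline `G = 1 − exp(−α t^δ)` this gives a three-parameter model
(δ shape, α rate-scale, λ) whose hazard can be decreasing, increasing,
bathtub-shaped, or decreasing–increasing–decreasing, and whose quantile
function is closed-form — so percentile life, inverse-CDF sampling, and
truncated-test failure probabilities are all analytic.

On that last point rests the chart: items are tested only until
`t₀ = τ·ξ₀` (ξ₀ the specified median life), the failure count *D* per
subgroup of *n* is compared with binomial *np* limits
`np₀ ± k√(np₀(1−p₀))`, and the design constants (*k*, τ) are chosen so the
in-control average run length `ARL₀ = 1/(1 − P_in)` hits a target.

See `docs/methods.md` for the numerics (tail-stable evaluation, the λ → 1
likelihood ridge, shift semantics of the chart) and the design choices.

## Worked example

Fit the bundled survival-time data (128 lifetimes in months, shipped as
`ntsg/data/survival_times.csv`) and compare candidate models:

```python
from ntsg import compare_models, comparison_table, load_survival_times, summarize

sample = load_survival_times()
print(summarize(sample))           # n=128  mean=9.366  sd=10.50833 ...
models = ["nts_weibull", "weibull", "exp_weibull", "napc_weibull",
          "sine_weibull", "sine_inv_weibull"]
table = comparison_table(compare_models(sample, models, seed=0))
print(table[["model", "loglik", "cvm", "ad", "ks", "ks_pvalue"]])
```

which prints (see `examples/fit_survival_times.py`):

```
           model  loglik      cvm       ad       ks  ks_pvalue  rank_ks
     nts_weibull  -409.5 0.013595 0.085102 0.028279    0.99995        1
    napc_weibull -409.72 0.018812  0.12287 0.033153    0.99896        2
     exp_weibull -410.68 0.040342  0.27036 0.045025    0.95761        3
         weibull -414.09   0.1537  0.95771 0.070017    0.55696        4
    sine_weibull -414.32  0.15453  0.98562 0.070942     0.5399        5
sine_inv_weibull -429.84  0.53483   3.4122  0.11156   0.082665        6
```

The amplified Weibull attains the highest log-likelihood and the smallest
distance between fitted and empirical CDF on every criterion. Its λ̂ sits
essentially at its lower bound — on this data the likelihood maximises on
the λ → 1 boundary ridge (a proper logistic-type limit family;
`FitResult.at_bound` and the methods note explain how to read this).

Design a chart for an in-control process with δ = 2.5, λ = 1.5 and apply it:

```python
from ntsg import ChartConfig, design_chart, arl_profile
cfg = ChartConfig(n=30, delta=2.5, lambda_=1.5, r0=370.0, xi0=1000.0)
d = design_chart(cfg)       # k=2.911 tau=1.051 p0=0.5635 ARL0=370.01 t0=1051
arl_profile(d, cfg, c_grid=[1.0, 1.5, 2.0])
# ARL1: 370.01 at c=1 (no shift), 6.55 at c=1.5, 1.78 at c=2
```

A false alarm occurs once per ~370 subgroups in control, while a doubling of
median life is flagged within ~2 subgroups. The other example scripts cover
the recovery study (`examples/recovery_study.py`), the chart applied to the
survival-time series (`examples/chart_design.py`), and the generic transform
over custom baselines (`examples/family_api.py`). A thin CLI mirrors the
library: `ntsg fit|gof|simulate|chart-design|chart-arl|chart-apply|sample|summary`.

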