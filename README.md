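# egosig

Tie strengths in egocentric communication networks — who gets how many of an
ego's calls, messages or posts — are shaped by two competing reinforcement
mechanisms: **cumulative advantage** (already-active ties attract further
events) and **random choice** (events land on alters uniformly). `egosig`
implements a minimal, analytically solvable urn model of this competition,
together with the estimators and event-log statistics needed to fit it to
time-stamped communication data, one ego at a time.

It is aimed at computational social scientists and network scientists
working with communication logs (and, more broadly, anyone modelling
contact heterogeneity, e.g. for epidemic contact networks).

## The model

An ego has `k` alters, each starting at activity `a0`. At event time `τ`,
the alter with current activity `a` receives the next event with
probability

```
π_a = (a + α) / (τ + k α)
```

In reduced coordinates `α_r = α + a0`, `t = τ/k`, `t_r = t − a0`, the shape
of the resulting alter-activity distribution `p_a` is governed by a single
**preferentiality parameter** `β = t_r / α_r`:

```
p_a = C(a_r + α_r − 1, a_r) (1+β)^{−α_r} (β/(1+β))^{a_r},    a_r = a − a0
```

a negative binomial shifted by `a0`, with mean `t`, variance `t_r (1+β)`,
and dispersion index `d = (σ² − t_r)/(σ² + t_r) = β/(2+β)`. `β = 1`
(`d = 1/3`) is the crossover between **homogeneous** (Poisson-like,
`β < 1`) and **heterogeneous** (gamma-like, `β > 1`) social signatures.

Given an ego's activities, `β` is estimated by maximum likelihood through
the digamma equation `β̂ = e^{F_α} − 1`,
`F_α = mean_i[ψ(a_r,i + α_r) − ψ(α_r)]`, and the fit is vetted by a
parametric bootstrap (default 2500 replicates) of the Kolmogorov–Smirnov
statistic — or discrete Cramér–von Mises, Anderson–Darling or Watson
variants — retaining egos with `p > 0.1`.

The package also computes the data-side statistics: per-ego dispersion
indices, pooled activity CCDFs by dispersion quartile or regime, the
empirical connection kernel `π_a − ⟨1/k⟩` (flat under random choice,
increasing under cumulative advantage), and two-interval persistence
(`Δβ/β` against alter turnover `J`).

## Worked example

Simulate one strongly preferential ego (`k = 150`, `a0 = 1`, `α_r = 0.8`,
1200 events, hence true `β = t_r/α_r = 8/0.8 = 10`) and fit it:

```python
import numpy as np
from egosig import AlterActivityModel, ModelParams, simulate_ego_events

params = ModelParams.from_reduced(k=150, a0=1, alpha_r=0.8)
ego = simulate_ego_events(params, 1200, np.random.default_rng(3), method="urn")

model = AlterActivityModel(ego.final_activities, ego="demo-ego")
res = model.fit(n_sim=2500, seed=0)
print(res.summary())
```

```
Alter activity model (cumulative advantage vs random choice)
==============================================================
ego                             demo-ego
alters k                             150
events tau                          1350
a0 / a_m                          1 / 38
mean activity t                        9
dispersion d                      0.8158
--------------------------------------------------------------
beta_hat                         10.6433
alpha_r_hat                     0.751646
regime                     heterogeneous
log-likelihood                  -468.418
KS statistic D                 0.0487872
CvM W2                         0.0714371
CvM A2                          0.380892
CvM U2                         0.0709779
bootstrap n_sim                     2500
p-value                           0.2164
accepted (p > 0.1)                  True
status                         converged
==============================================================
```

The ego's 1350 total events (1200 drawn plus the `k·a0 = 150` baseline)
spread over 150 alters with strong heterogeneity: `d = 0.82` is far above
the crossover `1/3`, and the estimate `β̂ = 10.6` (true value 10) lands in
the heterogeneous regime. The bootstrap p-value 0.22 > 0.1 means the
closed-form distribution is not rejected for this ego.

The same pipeline runs from the shell on TSV event logs
(`ego  alter  timestamp`):

```
egosig simulate --n-egos 1000 --seed 7 --out events.tsv
egosig fit      --in events.tsv --seed 7 --out fits.tsv
egosig kernel   --in events.tsv --out kernel.tsv
egosig persist  --in events.tsv --out persistence.tsv
```

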