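# popjoint

Integrated population modelling from two cheap-to-combine data streams —
repeated **detection/non-detection point-count surveys** and **annual
banding (capture/resight) histories** — plus the bookkeeping needed to
decide whether combining them is worth the money.

Monitoring programs often face this trade-off: occupancy-style survey
data are cheap and cover many sites but carry weak information about
survival; capture–recapture data pin down survival but are expensive and
cover few sites. `popjoint` fits three Bayesian hierarchical models to
the same landscape —

- **point**: a dynamic N-occupancy model (Poisson initial abundance
  `N_{j1} ~ Pois(λ_j)`, binomial survivors `S_{jt} ~ Bin(N_{j,t-1},
  φ_{jt})`, Poisson recruits `G_{jt} ~ Pois(γ_{jt})`, Royle–Nichols
  observation `Y_{jkt} ~ Bern(1-(1-p_{jkt})^{N_{jt}})`),
- **band**: a state-space Cormack–Jolly–Seber model
  (`Z_{it} ~ Bern(Z_{i,t-1} φ_{jt})`, `Y_{it} ~ Bern(Z_{it} p_{B,i})`),
- **joint**: both likelihoods sharing the apparent-survival block φ —

and quantifies the precision gain as the relative difference in 95%
credible-interval length, `(single − joint)/joint`, per site, next to
exact cost functions for each design. A synthetic-data generator with
the full statistical structure of the models stands in for field data,
so everything is testable offline. Inference is a numba-compiled
Metropolis-within-Gibbs sampler with integer latent-abundance moves,
forward-algorithm marginalization of the CJS alive matrix, Kuo–Mallick
indicator variable selection, Brooks–Gelman R-hat and squared-loss
posterior-predictive checks. See `docs/methods.md` for the model and
sampler details.

## Worked example

Simulate a 75-station, 5-year study (boxes at half the stations, ~60
banded birds), fit all three models, and compare precision:

```python
import popjoint as pj
from popjoint.inference import run_mcmc, McmcConfig, summarize
from popjoint.effort import precision_report

design = pj.generate_design(n_sites=75, n_transects=8, n_sessions=3,
                            n_years=5, nbox_fraction=0.48, n_observers=9,
                            seed=7)
cov    = pj.generate_covariates(design, seed=8)
params = pj.default_params(design, seed=9)
ds     = pj.simulate_dataset(design, cov, params, marking_rule=0.3, seed=10)

cfg  = McmcConfig(n_chains=3, n_iter=8000, burn_in=4000, thin=4, seed=11)
fits = {m: run_mcmc(m, design, cov, detection=ds.detection,
                    banding=ds.banding, config=cfg)
        for m in ("point", "band", "joint")}

print(summarize(fits["joint"]).set_index("parameter")
      .loc[["a0", "b0", "c0", "d0", "d1", "e0"]].round(3))
print(precision_report({"point": fits["point"], "band": fits["band"]},
                       fits["joint"]).round(3))
```

Output (seeds as above; ~109 banded birds in this draw):

```
           median  lower  upper   rhat  indicator_mean
parameter
a0          0.957  0.483  1.363  1.008             NaN
b0          0.256 -1.077  0.719  1.356             NaN
c0          0.455  0.126  0.808  1.056             NaN
d0         -1.276 -1.739 -0.857  1.066             NaN
d1          0.825  0.308  1.224  1.196            0.99
e0          0.429 -0.139  1.061  1.000             NaN

single_model quantity  mean    sd  n_cells
       point      phi 0.962 0.813      300
       point        N 0.077 0.134      375
       point        G 0.150 0.153      300
        band      phi 0.142 0.514      300
```

Reading this: every generating intercept (a0 = 1.1, b0 = 0.2, c0 = 0.3,
d0 = −1.2) sits inside its 95% BCI; the one real covariate effect in
the generating world — the nest-box detection boost d1 = 0.8 — is
recovered (median 0.825) with full indicator support (0.99), while null
covariates are shrunk to exact zeros by the selection indicators. (b0's
R-hat of 1.36 flags the short demo chains; the survival intercept rides
a weakly identified ridge at this scale and production runs should use
the 20,000-iteration defaults.) The precision table says survey-only
survival intervals are on average 96% longer than the joint model's —
survival is where combining data pays — while abundance and recruitment
gain far less at this scale.

Costs for the bundled study-scale design (149 points / 216 boxes /
8 years):

```python
from popjoint.effort import (PointCostSpec, BandCostSpec, JointCostSpec,
                             cost_detection, cost_banding, cost_joint)
cost_detection(PointCostSpec())   # 69179   ($)
cost_banding(BandCostSpec())      # 143232
cost_joint(JointCostSpec())       # 171431
```

A CLI wraps the same functionality (`popjoint simulate | fit | compare |
cost | pipeline`); `popjoint pipeline --scenario scenario.yaml --out dir/`
runs simulate → three fits → precision comparison → cost report and
writes all tables, a violin plot and a run log with seeds and R-hat
flags.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's end-to-end pipeline from scratch on a
reduced-scale synthetic study (simulate, fit the three models by MCMC,
compare precision, itemize costs; artifacts are written next to the
report) and writes the JSON report to `--out`.
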