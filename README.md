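# netattack

Agent-based simulation of intentional attacks on criminal market
networks — specifically, bipartite darknet-style drug markets in which
buyers choose vendors partly on the vendors' cumulative sales ratings.
The package is aimed at computational social scientists and network
researchers who want to study *network responsiveness*: not just how a
static network fragments when nodes are deleted, but how a population of
adaptive actors keeps trading (or stops) in the months after an attack.

## The model

The market is a bipartite graph: buyers `b`, vendors `v`, and an
unweighted tie `(b, v)` meaning "b has purchased from v", plus a
reputation score per vendor (cumulative sales rating). Network change is
a stochastic actor-oriented model (SAOM): a continuous-time Markov chain
in which buyers receive tie-change opportunities at rate λ and choose
among candidate states — toggling any one of their possible ties, or
doing nothing — by a multinomial logit over the objective function

    f(β, x) = Σₖ βₖ sₖ(x)

where the effect statistics `sₖ` of a buyer's personal network are, by
default, the outdegree, the summed reputation of tied vendors, and the
summed √degree of tied vendors (degree popularity). β is estimated from
a two-wave network panel by method of moments via Robbins–Monro
stochastic approximation, with chains conditioned on the observed amount
of change and convergence judged by t-ratios (|t| < 0.1).

Three attack operators manipulate the observed network before forward
simulation, each at intervention levels 20/40/60/80 (percent):

| strategy    | operation |
|-------------|-----------|
| `targeted`  | delete the top n% of vendors by degree |
| `weak_link` | delete the bottom n% of buyers by degree |
| `signal`    | multiply every vendor's reputation by (1 − n/100) |

The full experiment is 3 strategies × 4 levels + control, R replicates
per condition (default 30, `--full` for 100 → 1,300 simulated
networks). Per network the pipeline records ties, isolates, per-actor
degrees, the degree-degree correlation (assortativity; negative values
flag hub-and-spoke vulnerability) and the degree-scaling exponent γ of
the vendor degree distribution (discrete power-law fit with KS-minimal
cutoff selection and a semiparametric bootstrap goodness-of-fit p).

Because the real transaction data is not public, a synthetic generator
stands in for it: a reputation-reinforced purchase process (urn-style
rich-get-richer) calibrated to the stylized facts of the observed
market — heavy-tailed vendor degrees (γ roughly 1.5), slightly negative
assortativity, and strong concentration of trade in the top decile of
vendors. See `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

```python
import numpy as np
from netattack import (MarketGenConfig, generate_market, fit_degree_scaling,
                       degree_degree_correlation, concentration_share)
from netattack.experiment import run_synthetic_experiment, proportion_of_control

# a small early-stage market: 505 buyers, 50 vendors, 1,110 purchases
panel = generate_market(MarketGenConfig.desk_scale(seed=7))
net = panel.waves[-1]
deg = net.degrees()
fit = fit_degree_scaling([deg[v] for v in net.vendors if deg[v] > 0],
                         bootstrap_reps=100, seed=7)
print(f"ties={net.tie_count()}  gamma={fit.gamma:.2f} (KS={fit.ks_stat:.2f}, p={fit.ks_p:.2f})")
print(f"assortativity={degree_degree_correlation(net):.3f}  "
      f"top-decile share={concentration_share(net, 0.10):.2f}")

results, mfit = run_synthetic_experiment(replicates=10, seed=7, force=True)
print(f"fitted beta={np.round(mfit.beta_hat, 4)}  rate={mfit.rate_hat:.2f}")
ratios = proportion_of_control(results, "tie_count")
print(ratios.groupby(["strategy", "level"])["ratio"].mean().round(3))
```

prints

```
ties=800  gamma=1.28 (KS=0.19, p=0.15)
assortativity=-0.249  top-decile share=0.86
fitted beta=[2.4489 0.0228]  rate=0.69
strategy   level
signal     20       0.997
           40       0.979
           60       0.986
           80       0.988
targeted   20       0.420
           40       0.442
           60       0.419
           80       0.439
weak_link  20       0.894
           40       0.812
           60       0.623
           80       0.392
```

The cross-sectional lines say this market looks *vulnerable*: a heavy
vendor tail (γ ≈ 1.3, the bootstrap does not reject the power law),
negative assortativity, and 86% of distinct trading ties concentrated on
the top five vendors. The fitted choice model has a positive reputation
coefficient (0.0228 per rating unit): buyers prefer reputable vendors.
The ratio table is each treatment condition's mean tie count divided by
the control mean: deleting the two most-connected vendors (`targeted`
level 20) already halves long-run trading, deleting low-degree buyers
(`weak_link`) bites roughly in proportion to the share deleted, and
reputation (`signal`) attacks barely dent tie formation in this
growth-phase market — see `docs/methods.md` for why, and for how this
relates to markets with tie dissolution.

The same workflow is scriptable from the shell: `netattack synth`,
`netattack attack`, `netattack estimate`, `netattack simulate`,
`netattack metrics`, `netattack experiment` (see `--help` on each).

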