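# patchhop

Which social cues drive a fish's decision to cross between two habitat
patches?  Small shoals of humbug damselfish (*Dascyllus aruanus*) placed in
a two-patch arena cross back and forth over the centre line, and competing
hypotheses predict *which side moves next*: **static** rules respond to the
current split of the group between the sides (attraction to the larger
group, quorum-like responses), while **dynamic** rules respond to the
direction of recent crossings (follow the last mover).  `patchhop`
implements the full analysis pipeline for such crossing experiments:
event-log handling, the candidate decision models, Bayesian model
selection by marginal likelihood, an event-driven simulator for
large-scale consistency checks, descriptive pattern statistics, and a
synthetic-data generator with known ground truth.

It is aimed at behavioural ecologists and modellers working with
sequential binary-choice event streams from small animal groups.

## The model

Each crossing event is observed at a *decision point*: `n_L` fish on the
left, `n_R` on the right, plus the direction of recent moves.  A model
assigns every fish a crossing propensity (weight) `w`; the probability
that the next crossing originates from the left is

    P(L) = n_L w_L / (n_L w_L + n_R w_R).

For a fish on side *s*, let `Δ = n_opp − (n_same − 1)` be the count
difference it sees (itself excluded).  The candidate rules:

| model | weight | class |
|-------|--------|-------|
| M0 | 1 | asocial null |
| S1 | γ if Δ>0, 1 if Δ=0, 1/γ if Δ<0 | static, binary |
| S2 | max(ε, 1 + βΔ) | static, linear |
| S3 | g^Δ | static, geometric |
| S4 | 1 / (1 + a·s^−Δ) | static, quorum |
| D1 | α if the last move came from *s*, else 1 | dynamic |
| D2 | α^m, m = net recent moves (window τ = 3.5 s) | dynamic |
| C1 | S1 × D1 | combined |

Multiplying `P(outcome side)` over all informative decision points (those
with both sides occupied) gives the sequence likelihood `P(D | θ, M)`;
integrating over a parameter prior gives the evidence

    log2 P(D | M) = log2 ∫ P(D | θ, M) π(θ) dθ,

computed on a deterministic grid (log-uniform priors on multiplicative
parameters over [2⁻⁶, 2⁶], uniform on β over [−5, 5]) with a seeded Monte
Carlo integrator as cross-check.  The model with the largest evidence is
selected; differences are log2 Bayes factors.

Simulation uses the same weights as competing exponential hazards
(per-fish rate `λ0·w`), so the simulator and the likelihood share one
definition of every rule.

## Worked example

Generate a synthetic experiment from the follow-the-last-mover rule
(α = 4) and see whether model selection recovers it:

```python
import patchhop as ph
from patchhop.synth import default_design, generate_dataset

data, truth = generate_dataset(
    default_design(model="D1", params={"alpha": 4.0},
                   trials_per_group={3: 4, 4: 4, 5: 3, 6: 3}, seed=7)
)
res = ph.ModelComparison(data).fit()
print(res.summary())
```

```
Model comparison (log2 marginal likelihoods)
============================================
priors: alpha~log_uniform[0.015625,64], ..., beta~uniform[-5,5]
best model: D1

model   class  n_params  log2_evidence   delta_log2          map_params  rank
   D1 dynamic         1   -3370.026477     0.000000       alpha=3.91429     1
   D2 dynamic         1   -4201.243823  -831.217346       alpha=1.23515     2
   S4  static         2   -4358.569258  -988.542781 a=2.40431;s=1.20376     3
   S3  static         1   -4359.375127  -989.348650           g=1.13879     4
   S2  static         1   -4360.901828  -990.875351       beta=0.136719     5
   S1  static         1   -4361.292656  -991.266179       gamma=1.38391     6
   M0    null         0   -4521.940552 -1151.914075                         7
```

The generating rule wins by over 800 log2 units against every competitor,
and its MAP follow strength (3.91) sits next to the truth (4).  The
posterior localizes it tightly:

```python
print(ph.CrossingDecisionModel(data, "D1").fit().posterior_summary())
```

```
      transform    mean     sd    mode  ci_low  ci_high
param
alpha      log2  1.9684  0.052  3.9143  3.6163   4.1682
```

(`mean` is the posterior mean of log2 α; the truth is log2 4 = 2.)

A command-line interface wraps the same machinery:

```bash
patchhop synth --model D1 --params alpha=4 --seed 7 --out-dir synth/
patchhop fit synth/events.csv synth/metadata.csv --out table.csv
patchhop patterns synth/events.csv synth/metadata.csv --out-dir results/
patchhop simulate --model S1 --params gamma=2 --groups 4:16 --out sim.csv
patchhop validate synth/events.csv synth/metadata.csv synth/roster.csv
```

## Layout

- `patchhop.eventlog` — domain types, CSV I/O, replay validation, decision points
- `patchhop.models` — the decision rules and the sequence likelihood
- `patchhop.selection` — priors, evidence integrals, model comparison
  (`CrossingDecisionModel`/`ModelComparison` with `.fit()` results)
- `patchhop.simulate` — competing-hazards event simulator
- `patchhop.patterns` — occupancy, crossing groups/pools, interval analysis,
  sign test, leadership and hierarchy statistics
- `patchhop.synth` — synthetic experiments with ground truth
- `patchhop.cli` — the `patchhop` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
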