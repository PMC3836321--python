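# Methods

## The decision process

The data are event streams: a group of G fish split between two patches,
and a totally ordered sequence of crossings, each with a time, a fish
identity and a direction.  The modelling target is the *side* the next
crossing originates from, not its timing and not the identity of the
crossing fish.  Every event therefore contributes one categorical
observation (left or right origin) conditioned on the pre-event state:
the side occupancies `(n_L, n_R)`, the direction of the last crossing,
and the set of crossings within a recent memory window.

A decision point with an empty side is *uninformative* — the next move
can only come from the occupied side — and contributes nothing to the
likelihood or the evidence.  This matters in practice: strong following
drives the group to consensus configurations, where many events occur
from states with an empty opposite side.

Each candidate rule assigns a per-fish weight `w(side, state)` (table in
the README).  The side probability is occupancy-weighted,
`P(L) = n_L w_L / (n_L w_L + n_R w_R)`, which is simultaneously the
competing-exponential-hazards race used by the simulator.  Weights are
evaluated in log2 space throughout, so extreme parameters (large follow
factors, long same-direction runs under the memory rule D2) never
overflow, and `P(L) + P(R) = 1` holds to machine precision.

Conventions that the data do not pin down, fixed here once:

- **Focal exclusion.** The count difference a fish responds to is
  `Δ = n_opp − (n_same − 1)`: a fish responds to its neighbours, not to
  itself.  `include_focal=True` switches to raw side counts for
  sensitivity analyses.
- **First event of a trial.** No last mover exists, so all dynamic
  weights are 1 (the only uninformative choice).
- **Last mover vs memory window.** The follow rule D1 uses the last
  crossing regardless of its age; only the memory rule D2 ages moves out
  of its window (τ = 3.5 s by default, matching the empirical timescale
  at which successive crossings stop being predominantly same-direction).
- **Linear-response floor.** S2's weight is floored at 1e−9 so strongly
  negative slopes approximate a hard zero while keeping the likelihood
  finite.
- **Geometric family S3.** Declared as a stand-in spanning convex
  response shapes between the binary (S1) and linear (S2) rules, and
  labelled as such in its registry description.
- **Simultaneous frames.** Events at identical times keep input order;
  replay and run lengths are therefore deterministic.
- **Asymmetric arenas.** For refuge/open-water experiments the left side
  denotes the refuge and all refuge-side weights are multiplied by a bias
  factor `b`, which enters the evidence as one extra log-uniform
  parameter for every model.

## Evidence integration

Priors are log-uniform on multiplicative parameters over `[2^-6, 2^6]`
(`s` over `[1 + 2^-6, 2^6]`, since quorum steepness below 1 would invert
the rule) and uniform on the linear slope β over `[−5, 5]`.  These are
declared in every output header because the selection outcome depends on
them through the Occam factor.

The default integrator is a tensor grid in the prior's flat coordinate
(log2 for multiplicative parameters, linear for β) with trapezoid masses
and 513 points per dimension; the evidence is a log-sum-exp over the
grid, the posterior is the normalized grid mass, and the MAP is the
best grid point.  Doubling the grid changes evidences by well under 0.05
log2 units on reference datasets (tested).  A seeded Monte Carlo
estimator (log of the mean likelihood under prior draws, 20 000 draws by
default) serves as an independent cross-check and agrees with the grid
within 0.2 log2 units on 500-event datasets (tested).

Models with no free parameters have a zero-dimensional integral: the
evidence *is* the log-likelihood, exactly.  Datasets with no informative
decision points give evidence 0 for every model and return the prior as
the posterior.

The likelihood of every rule depends on a decision point only through
`(n_L, n_R, last-mover side, net recent movement, outcome side)`, so
decision points are pooled into sufficient-statistic counts before grid
evaluation; the cost of an evidence integral scales with the number of
distinct states (tens) rather than events (tens of thousands).  Pooling
is further specialized per model family for parameter batches.  For
single parameter points the shared state table is kept so that parameter
choices which reduce a model to the null (γ=1, β=0, g=1, α=1) reproduce
the null's log-likelihood bit for bit.

## Simulation

Crossing sequences are generated event by event: each fish carries hazard
`λ0 · w(side, state)`, the waiting time is exponential in the summed
hazard, the origin side is drawn with probability proportional to its
total hazard, and the crossing fish is drawn uniformly within that side
(the likelihood is side-level, so any within-side assignment is
admissible; a round-robin option and per-fish multipliers exist for
leadership studies).  Hazards are frozen between events; for the memory
rule D2, whose weights also change as moves age out of the window, the
origin side is re-drawn from the weights at the realized event time, so
simulated side outcomes follow the likelihood's side probability exactly
while waiting times remain a piecewise-constant-hazard approximation.

`λ0` defaults to 0.08 s⁻¹ per fish.  Under the null rule this gives a
constant total hazard `G·λ0` (the embedded occupancy chain is then the
classical Ehrenfest urn, whose event-step stationary law Binomial(G, ½)
the simulator reproduces to total variation < 0.02 at 10⁵ events) and
median inter-crossing intervals of about 2 s for G = 4–5, the scale seen
in such arena experiments.  Termination is by trial duration, by event
count, or whichever comes first; a hard cap of 5·10⁵ events per trial
guards against runaway cascades under extreme dynamic parameters.

## Synthetic experiments

The generator reproduces the study design: 57 trials (16, 16, 11 and 14
trials at group sizes 3, 4, 5 and 6), 600 s each, with at least one fish
per side initially (the left count uniform over 1..G−1) and event times
quantized to the 15 fps frame grid *after* simulation, emulating the
recording pipeline.  Body lengths are drawn from a normal with mean 35 mm
and SD 5 mm, truncated positive; these values are invented (real lengths
enter the source analyses only through correlations) and configurable.
The default generating rule is the asocial null M0, so that the
generator's out-of-the-box behaviour is a neutral baseline; analyses pass
the rule of interest explicitly.  A `leadership_effect` of e per mm
multiplies a fish's chance of being the crosser by
`1 + e·(length − mean)`, creating a length–initiation correlation without
altering side-level dynamics.

What the generator does *not* emulate: spatial behaviour within a side,
refractory periods after crossing, per-trial heterogeneity in baseline
activity, observation error in fish identity, and the pre-crossing
"assessment" behaviour suggested for refuge experiments.  Passing tests
on synthetic data therefore demonstrate correctness of the inference
machinery under the stated generative assumptions, not ecological
validity of those assumptions.

## Pattern statistics

- **Occupancy** is time-weighted: every inter-event interval (plus head
  and tail segments) contributes its duration to the prevailing left
  count.
- **Crossing groups** are maximal runs of same-direction crossings with
  *no* maximum gap — two crossings an arbitrary time apart in the same
  direction share a group.  The *pool* is the origin-side occupancy when
  the run starts, so group size never exceeds pool.
- **Direction-versus-interval** tables classify consecutive pairs within
  a trial as same/opposite direction in right-closed interval bins
  (default split at 3.5 s).
- **The coral-association sign test** is the exact binomial tail
  `P(X ≥ k)`, X ~ Binomial(N, ½).
- **Leadership scores** count solo crossings (groups of size 1),
  initiations (first mover of a larger group) and follows per fish,
  pooled across trials; Pearson correlations use the two-sided t-based
  p-value and are flagged (not computed) under zero variance.

## Hierarchy test

Per trial, the follow matrix F counts immediate within-group successions
(F[i,j]: j crossed right after i).  The dominance digraph takes i → j
when F[i,j] > F[j,i]; tied dyads (including 0–0) are excluded, triads
containing them are skipped, and the maximum circular-triad count
`d_max(n)` (`(n³−n)/24` for odd n, `(n³−4n)/24` for even) is scaled by
the decided-triad share.  Kendall's linearity is `K = 1 − d/d_max`.

The Monte Carlo null redirects each dyad's observed events with a fair
coin.  Because K has discrete support, the plain exceedance fraction
cannot be uniform under the null; the p-value therefore uses randomized
tie-breaking, `p = (#{K' > K} + U·(#{K' = K} + 1)) / (n_mc + 1)` with
U ~ Uniform(0,1), which is exactly uniform under the null (verified by a
Kolmogorov–Smirnov check over 200 null trials) and makes the downstream
Fisher combination `χ² = −2·Σ ln pᵢ` on `2k` degrees of freedom exact.
Trials with fewer than three fish or without any decided triad are
excluded and reported; the Fisher degrees of freedom count only combined
trials.

## Known limitations

- The evidence grid is dense but bounded by the prior box; a posterior
  concentrated at the boundary (pathological data) would be truncated.
  The MAP is grid-resolution limited (~0.023 in log2 for 513 points over
  12 octaves).
- The follow-rule signature "modal crossing group = whole pool" is not a
  universal property of D1: cascade survival
  `∏ₖ α(m−k) / (α(m−k) + n_opp+k)` falls below the stop probability for
  large pools at moderate α (for example α = 4, G = 6: P(group = 6) ≈
  0.20 < P(group = 5) ≈ 0.24), so whole-pool modality requires strong
  following.  The simulator reproduces this closed-form prediction.
- Likelihoods are side-level by design; per-fish heterogeneous
  propensities and time-to-event terms are out of scope (the simulator's
  leadership multipliers affect only fish identity assignment).
- Problem sizes used by the shipped checks (replicate counts, event
  counts, Monte Carlo draws) are the package's reference settings chosen
  to make each quantity's sampling error small relative to its assertion
  band; all are configurable.
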