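# Methods

This note documents the models implemented in `socialforage`, the
assumptions and defaults behind them, what the synthetic-data
generators do and do not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## The social hidden Markov decision model

**States.** Three behavioral states per player-second: *individual
exploration* (I), *social relocation* (S) and *exploitation* (E).
E is directly observed (the extracting flag), so only I and S are
latent; seconds at which the focal is exploiting, or at which no group
member is exploiting, are omitted from the likelihood because the
state is known there. The remaining seconds form maximal contiguous
*segments*, and the latent chain restarts in I at every segment start
— both after an omission and at the round start, treated symmetrically.
The first second of a round has no turning angle (two headings are
needed) and is never modeled.

**Emissions.** Conditional on the state, three channels are
independent: turning angle θ ~ von Mises(μ, κ) (a tractable stand-in
for the wrapped normal on (−π, π]); smallest change in distance to
visible exploiting players Δd ~ Normal(μ, σ); smallest absolute
relative bearing to them φ ~ LogNormal(μ, σ). When no exploiting
player is in the focal's field of view, the two social channels are
missing and simply drop out of the likelihood (marginalization, never
imputation). A bearing of exactly zero is floored at 10⁻⁶ rad before
the log-normal is evaluated, since its support is strictly positive;
the floor is far below any measurable bearing resolution.

**Transitions.** The switch I → S at second *t* is a logistic
regression in the state predictors — visibility V ∈ {0, 1}, z-scored
distance to the closest visible exploiter D, the number of other
players extracting at that exploiter's patch N (0 = lone exploiter,
used raw given its small integer support), and z-scored time since the
focal's last coin T. D and N are multiplied by V so they act only when
something is actually visible. All five coefficients are specific to
the incentive condition × environment cell. The reverse switch S → I
is a condition-specific intercept γ: the model's job is to explain
*entering* social relocation; leaving it is treated as a memoryless
exit (covariates on γ would be an extension, not a default).

**Time-varying coefficients.** Any switch coefficient can carry a
monotonic (ordered-categorical) minute-of-round effect: a total effect
β^MAX times the cumulative sum of a 12-simplex δ, reaching exactly
β^MAX in minute 12. This constrains the profile to be monotone while
leaving step sizes free. In the implementation the monotonic term is
*added* to the static coefficient; a purely time-varying coefficient
is the special case with the static part at zero, and a constant
effect is recovered with β^MAX ≈ 0, which keeps the parameterization
usable for both regimes. The simplex is parameterized by 11 free
logits with the twelfth pinned at zero (softmax).

**Hierarchy.** Individual- and group-level offsets attach to the five
switch coefficients with independent Gaussian priors of scale `re_sd`
(default 0.5). This is a diagonal simplification of a full
correlated-random-effects structure: with the penalized-likelihood
backend (below), the extra O(k²) correlation parameters buy little and
cost a lot of Hessian work, while diagonal offsets already deliver the
shrinkage that matters for per-individual decision weights. In
time-varying mode, offsets attach to the static (average) effects
only.

**Identification.** Mixture labels are anchored structurally: the
relocation state's distance-change mean is the exploration mean minus
a positive gap (and analogously κ_S > κ_I, bearing-median_S <
median_I), so no retained draw can label-switch. Priors on the
unconstrained scale are weakly informative (logit-scale coefficients
N(0, 1.5²), intercept N(−2, 1.5²), log-scales N(·, 1²)); the gap
priors are the "informative about the nature of the states" part and
keep the gaps away from zero.

**Estimation.** The default backend maximizes the log posterior
(L-BFGS-B on the unconstrained scale) and draws from the Laplace
approximation at the mode, with the Hessian from central finite
differences. This is exact for the Gaussian-prior, zero-data case and
very accurate in the data-rich regimes used here, at a small fraction
of MCMC cost; an emcee ensemble-MCMC backend is provided where a
sampling cross-check is wanted. Every fit computes split-chain R-hat
(≤ 1.01 required) and bulk effective sample sizes on the retained
draws; failure flags the result with a warning rather than passing
silently. Numerical guards: exponentials in the parameter transforms
are clipped at ±30 and non-finite likelihood excursions return −10¹⁵,
which keeps line searches finite; finite-difference Hessian
eigenvalues are floored at the smallest prior precision (the true
curvature cannot be below it for this log-concave likelihood), so a
noisy flat direction cannot inflate draw variance. Viterbi ties are
broken toward I at every backtracking choice and at the final state —
arbitrary but fixed, and matched by the enumeration oracle in the
tests.

## The agent-based simulator

The simulator reproduces the virtual experiment's mechanics: a square
walled arena (90 m side), non-overlapping circular patches (radius
3 m; concentrated = 5 patches × 48 coins, distributed = 15 × 16,
equal totals), four avatars with forward-only motion at ≤ 2 m/s, a
bounded turn rate (default 90°/s, mirroring turn-key controls), a 108°
horizontal field of view with no distance cutoff (the arena is small
and walled; the planar layout makes the vertical cone non-binding),
extraction at one coin per two seconds shared proportionally among
co-extractors, and respawn of depleted patches at random locations
that overlap neither surviving patches (center distance ≥ 2r) nor any
avatar (≥ r). Initial patch placement also avoids the avatars' start
positions. Walls reflect the heading; a 25 Hz tick matches the
original server rate.

The behavioral policy is deliberately minimal so that its one-second
discretization *is* the statistical model's generative process:
exploration is a correlated random walk (per-second heading
concentration κ = 4); once per second a non-exploiting avatar applies
the logistic switch rule to its current V/D/N/T (D in meters, T in
minutes — the policy sees raw quantities; z-scoring is an estimation
convention) and, on switching, pursues the nearest exploiting player
in a straight line with slight heading jitter (κ = 400) so bearings
stay continuous; relocation reverts with a per-second probability
(default 0.05) and immediately when no one exploits. Avatars crossing
an active patch always start extracting, whether they arrived by
exploration or pursuit.

Time alignment: the ground-truth label at second *t* is the state in
effect during (t−1, t] (with E read off the flag at *t*), so the
movement features ending at *t* are generated by the state labeled
*t*. The decision taken at *t* uses the covariates visible at *t* and
governs (t, t+1] — one second of covariate lag relative to the exact
model indexing, which is immaterial for state recovery (emissions are
aligned) and avoided entirely in parameter recovery, which uses the
exact generative sampler instead.

What the simulator does **not** emulate: human route planning and
spatial memory (explorers are memoryless random walkers), the
metal-detector discovery radius as distinct from the patch disc,
visual occlusion by in-game geometry (visibility is FOV-only), and
any heterogeneity across avatars unless policies are varied
explicitly. Passing state-recovery tests on this generator therefore
demonstrates that the inference machinery works when the data obey
the model's assumptions — not that real trajectories do.

## Recovery-study conditions

The canonical parameter-recovery study uses 40 synthetic players (two
incentive groups of 20, each completing one round per environment,
~300–360 modeled seconds per round, i.e. roughly 600–700 per player).
Ground-truth coefficients (`sim.recovery_study_params`) echo the
qualitative empirical pattern — higher baseline switching in
concentrated environments and under individual incentives, negative
distance and crowding effects, short relocation bouts (γ = −0.2,
about two seconds dwell) so many transitions are observed. Covariates
mimic the empirical structure: visibility alternates in persistent
bouts with a roughly balanced stationary rate (0.70/0.30 stay
probabilities), which matters for separating α from β_V; distance is
a persistent AR(1); N is 0/1/2 with probabilities 0.83/0.14/0.03
(matching how rarely several players share a patch); T ramps with
random resets. These values were chosen once, on identifiability
grounds, as the study's design — the point of a recovery study is to
be well-posed.

## Feature conventions

Z-scoring pools all modeled seconds of a dataset (one scale across
conditions, so condition contrasts stay interpretable); per-round
scoping is a config option. D is standardized over the seconds where
it exists (V = 1); T over all modeled seconds, measured from the
round start before the first success. Resampling to 1 Hz is
sample-and-hold at the tick nearest each second; gaps beyond one
second are an error, not silently bridged. Coordinates are meters
with the origin at an arena corner, headings in (−π, π] with 0 along
+x.

## Scrounging and collective dynamics

A scrounging *opportunity* is one (focal, patch-lifetime) pair during
which the focal, while free to move, saw at least one group member
extracting there; it converts to a *join* if the focal's first
extraction at that patch falls after that first observation and
before depletion — joining requires having seen, so independent
discovery during an approach does not count. The empirical
joined/observed ratio is the default estimator; rates are undefined
(not zero) without opportunities.

The exploitation time-course model is a Bernoulli regression of the
per-second exploiting flag on condition intercepts plus the monotonic
minute effect, fitted with the same MAP + Laplace backend on
per-minute binomial counts.

The lag-GP model regresses the exploiting count at *t* (binomial out
of group size) on the z-scored group predictor (mean pairwise
distance, or directed visibility links — an exploiting player sees no
one) at all grid lags simultaneously; the weight at lag τ is an
average effect plus a lag offset with a squared-exponential prior
K(τx, τy) = η·exp(−ρ(τy−τx)²/τ_max²). Amplitude η and decay ρ are
estimated per condition with log-normal-style priors (log η ~
N(−2.5, 1.5²), log ρ ~ N(0.5, 1.5²)); a 10⁻⁸-scale jitter keeps the
kernel Cholesky stable. Distance and visibility are fitted in
separate models; conditions are fitted independently (no parameters
are shared across cells, so this is exact, not an approximation). The
default lag grid is every second to 30 s plus 5-s steps to 180 s (60
distinct lags). Because predictors are strongly autocorrelated, the
joint distributed-lag formulation shares one mechanical coupling with
the data definition: at very short lags, many players exploiting
implies low visibility, which shows up as a negative short-lag
visibility effect.

## Problem sizes and tolerances in the tests

The suite verifies the forward algorithm and Viterbi against explicit
path enumeration on hundreds of short random segments (log-likelihood
tolerance 10⁻⁹, exact path match under the fixed tie-break); emission
densities against quadrature (10⁻⁶); the recovery study above against
its known truth (switch intercept and visibility weight within 0.25
logits per cell, normal means and log-normal medians within 5%,
circular means within 0.05 rad — a relative criterion on a
near-zero-magnitude log-location would be vacuous, so locations are
compared on their natural scales); and unsupervised state recovery on
four simulated rounds (≥ 90% of modeled seconds). Lag-GP checks use a
reduced grid (every 2 s to 30 s plus 5-s steps to 90 s) and four-to-
six simulated rounds: a 90%-interval family over ~30 lags cannot be
expected to cover zero everywhere jointly, so the null check requires
coverage at ≥ 85% of lags together with a bound on the largest mean
effect. These sizes keep the full suite to a few minutes while
leaving every estimate's Monte-Carlo error far below its tolerance.

## Known limitations

* The Laplace posterior is Gaussian on the unconstrained scale;
  strongly skewed posteriors (tiny data, boundary effects) are better
  served by the emcee backend.
* The BFGS-approximate Hessian option is fast but its draw covariance
  is crude; it is intended for point-estimate workflows (e.g. quick
  decoding), not for reported intervals.
* Random effects are diagonal; correlations among decision weights
  are not estimated.
* The simulator's visibility model has no occlusion and its explorers
  no memory, so absolute behavioral rates (e.g. discovery counts) are
  not calibrated to human data — only the inferential machinery is.
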