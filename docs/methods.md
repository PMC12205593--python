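# Methods

## The task

The twenty-one task is a partially observable variant of blackjack played
in games of 16 trials. On each trial the player holds a face-up card
(score uniform on the integers 8–18) and a face-down card (score 1 or 4).
The face-down deck is announced at game start: deck L draws the 1-point
card with probability 0.2 (expected score 3.4), deck H with probability
0.5 (expected score 2.5). The player may *hit*, adding one card from a
hidden additional deck — Deck 4 with scores ~ B(10, 0.4) or Deck 6 with
scores ~ B(10, 0.6) — or *stay*. Totals of at most 21 pay their own score;
anything above 21 pays zero. Crucially, the additional card is revealed at
the end of every trial, hit or stay, so the hidden deck identity can be
inferred within a game. On every trial the player reports: the inferred
deck (4/6), deck confidence (4-point scale), the hit/stay action, and
decision confidence (4-point scale). The behavioral protocol is 20 games
(320 trials), the scanning protocol 8 games (128 trials), training 4 games
(64 trials); all use a balanced 2 (additional deck) × 2 (face-down deck)
design.

Two text-level discrepancies in the task description are resolved as
follows: the additional-card support is 0–10 (the binomial definition wins
over a caption stating 1–10), and the face-up score distribution is taken
to be uniform over 8..18 (only the range is stated; uniform is the minimal
assumption).

## The DC-MD model

The deck-confidence-modulated decision (DC-MD) model couples a
deck-inference phase to a decision phase.

**Evidence updating.** After the trial-(t−1) card A* is revealed, the
evidence for the deck it favors is incremented by the normalized
likelihood:

    E_t,D4 = E_{t-1},D4 + P(A*|D4) / (P(A*|D4) + P(A*|D6))   if A* < 5
    E_t,D6 = E_{t-1},D6 + P(A*|D6) / (P(A*|D4) + P(A*|D6))   if A* > 5

A score of exactly 5 (equal likelihood) updates neither total; evidence
resets to (0, 0) at each game start. The reported deck follows
P(D6) = σ(β_k·(1, ΔE)) with ΔE = E_D6 − E_D4, and graded deck confidence
is c_k = σ(β_ck·(1, |ΔE|, κ)), where κ is the fraction of the game's deck
reports (including the current one) that agree with the current report —
κ = 1 on trial 1 by construction.

**Decision phase.** The expected additional score mixes the reported
deck's expectation (4 or 6) with the alternative's, with weight
ω = ε − γ(1 − c_k), clamped to [0, 1]: low deck confidence pulls the
estimate toward the alternative deck. ε ∈ (0.5, 1) bounds the weight from
above even at full confidence; γ ∈ (0, 0.5) scales the confidence
modulation (so γ < ε always). The value-belief is
V_hit = 21 − (faceup + E[facedown] + Â); the choice is
P(hit) = σ(u) with utility u = β_i·(1, V, V|V|); decision simplicity is
DS = |u|; decision confidence is c_i = σ(β_ci·(1, DS, c_k)) — the c_k term
is the cross-level "confidence bias". Both graded confidences are
discretized to 4-point reports by an ordinal-probit model with noise σ and
thresholds (θ_1|2, 0.5, θ_3|4): P(C = c) = Φ((θ_c − c)/σ) differences.
(The division by σ inside Φ is required for normalization; treating σ as
an outer multiplier would not yield a distribution.)

**Fitting convention.** When evaluating the likelihood of observed data,
the *observed* deck reports drive κ and the reported-deck expectations,
while the continuous model c_k (not the discrete report) feeds ω and c_i.
Missing reports drop only their own likelihood term; the κ recursion
carries the last available report forward. Because the evidence trajectory
depends only on the revealed cards and κ only on the observed reports,
everything except the parameters can be precomputed per session, and the
likelihood is a pure vectorized function — JIT-compiled kernels mirror the
readable numpy implementation exactly (a regression test enforces
agreement to 1e-10).

## Alternative models

* **DC-ID** drops the confidence modulation: Â is the reported deck's
  expectation and c_i = σ(β_ci·(1, DS)). It is exactly nested in DC-MD
  (ε → 1, γ → 0, zero c_k weight), which the tests exploit.
* **HGF**: a three-level binary hierarchical Gaussian filter driven by the
  normalized Deck-6 likelihood l of each revealed card. Level 1 is the
  deck belief (μ̂1 = σ(μ̂2)), level 2 the deck tendency, level 3 its
  volatility; deck confidence reads out μ̂3. Two interpolations were
  necessary and are deliberate: (i) the level-3 *mean* update is not given
  in the source description, so the standard binary-HGF form
  μ3 = μ̂3 + (κ/2)(w2/π3)δ2 is used; (ii) the level-3 prediction variance
  is *additive*, σ̂3 = σ3 + ω3, implemented verbatim with a positivity
  guard. Under the additive form ω3 acts as a diffusion variance and must
  be positive in the long run; the package default is ω3 = 0.1 (the
  familiar negative log-volatility defaults of the exp(ω3) convention do
  not transfer and diverge immediately). Initial state defaults
  (μ2 = 0, σ2 = 1, μ3 = 1, σ3 = 1) are configurable.
* **Averaging**: deck inference from the running mean of revealed scores
  minus 5 (cards revealed before the current decision; empty history gives
  ΔE = 0).
* **Optimal Bayes**: exact two-deck posterior, confidence read out from
  the posterior entropy (natural log, so the maximum is ln 2 at uniform).

## Synthetic cohorts

Individual raw-scale parameter vectors are drawn φ_i ~ N(μ_φ, σ_φ) and
pushed through the constraining transforms (log for σ's; 0.5 ± exp for the
outer thresholds with the middle threshold fixed at 0.5; scaled logits
mapping ε into (0.5, 1) and γ into (0, 0.5)). Sampling on the
unconstrained scale is a deliberate deviation from naive normal sampling
on the constrained scale, forced by the parameter bounds. Agents then play
full protocols, sampling all four reports from the model likelihoods.

The default group parameters (versioned `v1` in `synth.py`) are documented
stand-ins chosen once to produce behaviorally sensible agents: deck-report
accuracy above chance by late trials, both confidence scales used across
their full ranges, hit rates responsive to the face-up score. They do not
claim to equal any fitted posterior. The generator emulates the protocol
structure and the model's own stochasticity; it does not emulate reaction
times, missed-trial patterns, fatigue or learning across games — so
passing tests demonstrate internal consistency of the pipeline, not
goodness of fit to human behavior.

## Hierarchical inference

All individual parameters get a normal hierarchy on the raw scale,
φ_ip ~ N(μ_p, τ_p), with weakly informative hyperpriors: μ_p ~ N(0, 5²)
for regression weights, N(0, 2²) for transformed parameters, and
τ_p ~ half-normal(1). The sampler is an adaptive Metropolis-within-Gibbs
scheme written for this model:

1. scalar random-walk Metropolis on every individual parameter
   (Robbins-Monro step-size adaptation toward 0.44 acceptance, burn-in
   only, so the retained chain is a fixed Markov kernel);
2. two joint random-walk proposals per participant per iteration using a
   running estimate of the participant's posterior covariance
   (Haario-style adaptive Metropolis, target acceptance 0.23) — these
   carry the strongly correlated blocks (ordinal intercept/threshold/noise
   trade-offs, the κ-collinear deck-confidence block);
3. conjugate Gibbs for the group means; log-scale random-walk Metropolis
   for the group SDs.

Chains start overdispersed (μ ~ N(0, 1) per chain). Proposals landing in
nonfinite-likelihood regions are rejected and counted
(`diagnostics["n_divergent"]`), never silently dropped. Chain bookkeeping
follows the three-chain scheme of 20,000 post-burn-in iterations after
10,000 burn-in with thinning 20, i.e. 3,000 retained draws, and is checked
by arithmetic tests. Convergence is assessed with the rank-normalized
split R-hat (arviz); model comparison uses PSIS-LOO with *trial-level*
pointwise terms (a trial's four report log-likelihoods are summed into one
observation — the observation grain is a documented choice, configurable
in principle by recomputing the pointwise matrix).

MAP-prediction agreement computes, at posterior-mean (or supplied point)
parameters, the argmax of each of the four report distributions per trial,
breaking exact ties uniformly at random with a fixed seed, and reports the
fraction of matches per report type with missing reports excluded from
denominators.

Problem sizes used in the shipped tests and in the acceptance script are
deliberately small — e.g. a 4-participant × 5-game cohort fit with a
three-chain, 60,000-iteration budget (several minutes), recovery with 12
participants at a reduced budget, model comparison on 3-participant
cohorts over three seeded replicates — chosen so the suite exercises every pipeline
stage at desk scale while the statistical claims remain directional
(signs, orderings, calibration bands) rather than numerical matches to any
particular dataset.

## Behavioral analyses

* **Mean split**: values strictly above the participant's mean are "high";
  ties go to "low" (the tie side is not determined by the source
  description; low is the documented choice).
* **Shift/slope psychometrics**: P(hit) = σ(slope·(faceup − shift)),
  equivalent to intercept = −slope·shift in an ordinary logistic
  regression. The participant mode is a plain ML fit; the hierarchical
  mode fits per participant and partially pools by shrinking estimates
  toward the group mean. Separation and degenerate designs are reported as
  non-converged (|slope| > 10 is treated as separation).
* **Higher-reward choice**: because both hidden cards are revealed on
  every trial, the counterfactual payoff of the unchosen action is always
  computable; a choice is "higher-reward" when its realized payoff is at
  least the alternative's (ties count for the chosen action).
* **Decision-confidence V fits**: decision confidence is modeled as
  bias + slope·|faceup − vertex| with the vertex anchored per participant
  at the face-up score minimizing mean decision confidence (empirically
  near 13, where the hit proportion crosses 0.5). The piecewise-linear V
  is an interpretation; the source description does not print the
  functional form.
* Correlations are Pearson, reported both at group level (participant ×
  level aggregates) and as the mean of per-participant coefficients.
  Significance machinery (Wilcoxon, ART ANOVA) is out of scope; the module
  produces the statistics those tests consume.

## Known limitations

* The sampler is a random-walk scheme: adequate at the package's cohort
  sizes, but gradient-based samplers would scale better to large cohorts.
* Group-level priors and the LOO observation grain are implementation
  choices (documented above), not reproductions of any particular fitted
  pipeline.
* The HGF level-3 mean update is an interpolation (see above).
* Hierarchical pooling of psychometric fits uses two-stage shrinkage, not
  a joint mixed-effects likelihood.
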