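# twentyone

Simulation and hierarchical Bayesian modeling of a "blind blackjack"
(twenty-one) card task: a value-based decision problem in which the
context — which deck the hidden additional card comes from — must itself
be inferred from evidence that accrues across trials, and in which
subjective confidence at the *inference* level cascades into the
*decision* level.

The package is aimed at computational cognitive scientists who want a
fully synthetic, end-to-end testbed for confidence-modulated decision
models: a task engine, generative agents, hierarchical MCMC fitting,
convergence diagnostics, PSIS-LOO model comparison, MAP-prediction
agreement, parameter recovery, and the descriptive behavioral analyses
that go with them. No human data are required anywhere.

## The model in brief

On every 16-trial game, an agent infers which additional-card deck is in
play — Deck 4 with card scores ~ B(10, 0.4) or Deck 6 ~ B(10, 0.6) — from
the cards revealed at the end of each trial. The deck-confidence-modulated
decision (DC-MD) model:

* accumulates per-deck evidence by adding the normalized likelihood of
  each revealed card to the deck it favors (scores < 5 → Deck-4 evidence,
  > 5 → Deck-6; exactly 5 → neither);
* reports the deck via P(D6) = σ(β_k·(1, ΔE)) and graded deck confidence
  c_k = σ(β_ck·(1, |ΔE|, κ)), where κ is the within-game consistency of
  its own reports;
* estimates the additional score as Â = ω E_d(A) + (1 − ω) E_d̄(A) with
  confidence-dependent weight ω = ε − γ(1 − c_k);
* chooses hit/stay from the value-belief V_hit = 21 − (F_u + E[F_d] + Â)
  via P(hit) = σ(β_i·(1, V, V|V|)), and reports decision confidence
  c_i = σ(β_ci·(1, DS, c_k)) with decision simplicity DS = |β_i·(…)|;
* discretizes both confidences to 4-point reports through an
  ordinal-probit model with noise σ and thresholds (θ_1|2, 0.5, θ_3|4).

Alternative models — DC-ID (no confidence modulation), a three-level
hierarchical Gaussian filter, running-average and exact-Bayes deck
inference — are implemented for comparison. See `docs/methods.md` for the
full treatment, all conventions and the deliberate interpolations.

## Worked example

```python
from twentyone.synth import CohortSpec, sample_cohort
from twentyone.behavior import confidence_accuracy_curves, joint_confidence_matrix
from twentyone.inference import map_agreement

params, sessions = sample_cohort(CohortSpec(n_participants=6, seed=11))
acc = confidence_accuracy_curves(sessions)
print(acc["deck_accuracy"].groupby("deck_conf")["rate"].mean().round(3).to_dict())
print(round(acc["deck_individual_r"], 3))
print(map_agreement(params, sessions, seed=0))
```

prints (deck-report accuracy by reported deck-confidence level 1–4):

```
{1: 0.566, 2: 0.755, 3: 0.88, 4: 0.987}
0.325
AgreementReport(fraction_deck=0.894, fraction_deck_conf=0.666,
                fraction_decision=0.903, fraction_dec_conf=0.729, ...)
```

Accuracy rises monotonically with reported confidence (mean
per-participant correlation 0.325), and the generating parameters predict
the agents' own deck reports and hit/stay decisions at ~90% — the
qualitative signatures the model is built around. The same pipeline runs
from the shell:

```bash
twentyone simulate --n 6 --seed 11 --out runs/cohort
twentyone analyze --sessions runs/cohort/sim000.csv --out runs/analysis
twentyone fit --model dcmd --sessions runs/cohort/sim000.csv \
    --chains 3 --iters 2000 --burnin 1000 --thin 4 --out runs/fit
```

Each command writes a `manifest.json` recording the seed, package version
and produced files.

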