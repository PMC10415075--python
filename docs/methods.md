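# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of the pipeline. It is the companion to
the analysis drivers under `analysis/` and to the library in
`src/reguframe/`.

## 1. The study design being emulated

A two-week message-based physical-activity intervention: participants
complete a pre-intervention questionnaire (regulatory focus — promotion
and prevention; cognitive and affective attitude; subjective norm;
perceived behavioral control; intention), are randomized to one of four
prefactual message frames (gain, non-loss, non-gain, loss), and afterwards
report message-induced emotions (anger, anxiety, fear, calm, hope),
involvement, depth of processing, and intention again. Three analysis
stages build on each other:

1. a theory-driven structural equation model (SEM) with mediation
   (regulatory focus → emotions → involvement → deep processing →
   post-intervention intention, controlling for pre-intervention
   intention);
2. a discrete ("dynamic" in the two-time-slice sense: pre → post
   intention) Bayesian network whose backbone is the SEM, used as a
   probabilistic predictor of post-intervention intention;
3. an adaptive fast-profiling policy — which trait to ask about next,
   which frame to send — learned by Monte-Carlo tree search against the
   network used as a respondent simulator.

The original participant data are not deposited, so a synthetic-cohort
generator parameterized by the published standardized coefficients and
scale reliabilities stands in for them. Every quantitative claim the
test-suite or `scripts/acceptance.py` makes is computed against that
generator or against closed-form/enumerative oracles.

## 2. Synthetic cohort generator (`reguframe.cohort`)

**Latent system.** All latent traits are standardized (unit variance).
Exogenous: promotion, prevention (correlation configurable, default 0,
the conventional neutral choice where no value is reported), the four TPB
antecedents (independent standard normal). Endogenous variables are
linear in their parents with standardized coefficients; the default path
values are the published ones:

| path | value | | path | value |
|---|---|---|---|---|
| promotion → calm | 0.35 | | calm → involvement | −0.33 |
| promotion → hope | 0.51 | | hope → involvement | 0.87 |
| prevention → calm | −0.23 | | anger → involvement | −0.55 |
| prevention → hope | −0.13 | | involvement → deep processing | 0.50 |
| TPB → pre-intention | .25/.25/.15/.30 | | deep processing → post-intention | 0.40 |
| | | | pre-intention → post-intention | 0.40 |

Paths that the source reports only as present-and-estimated (focus →
anger) default to 0; the ELM-chain and intention-slice values (0.5 / 0.4 /
0.4) are plausible mid-range defaults the source does not print; TPB →
pre-intention weights follow the usual meta-analytic ordering (control ≈
attitude > norm). Residual variances are derived from the requirement
that every latent have variance exactly one; configurations whose implied
R² ≥ 1 are rejected.

**Feasibility of the published involvement equation.** With unit
variances, the three paths into involvement imply
R² = 0.33² + 0.87² + 0.55² − 2·0.33·0.87·cov(calm, hope) and the
focus-induced covariance of calm and hope is only 0.208 — giving
R² = 1.05 ≥ 1. The published coefficients can therefore only have arisen
from data in which calm and hope correlate well beyond what the foci
induce. The generator encodes this with a default calm–hope residual
covariance of 0.20 (total latent correlation ≈ 0.41, involvement
R² ≈ 0.93). This is a feasibility derivation, not a free parameter: with
a residual covariance near 0 the configuration is mathematically
inadmissible.

**Frame effects.** Negative-valence frames (non-gain, loss) raise
anger/anxiety/fear by 0.15 SD; a "matching" interaction raises hope by
0.2 SD for promotion-focused respondents under gain framing and for
prevention-focused respondents under non-loss framing. Both main effects
and interactions are centered across the four balanced arms, which makes
them orthogonal to the traits: the configured structural paths remain the
exact generating truths. (Uncentered matching effects would shift both
focus → hope paths by +0.05 and silently corrupt every recovery
experiment.) Magnitudes are scenario parameters — the source asserts fit
effects without printing sizes — fixed once at values a framing
experiment would call moderate.

**Measurement.** Each scale has the questionnaire's item count (6 per
focus; 3 per emotion, involvement and intention; 5 for deep processing
and PBC; 3 for norm and each attitude) and its published Cronbach α.
α is converted to a common standardized loading by inverting the
parallel-item identity α = k·λ² / (1 + (k−1)·λ²). Items are
λ·latent + √(1−λ²)·noise mapped onto the 7-point scale as
round(4 + 1.5·score), clamped to [1, 7]. The rounding step attenuates
observed reliabilities by ~0.01–0.03 (measured: α(calm) ≈ 0.85 against a
target of 0.86 at n = 5000), which the α-recovery tests bound at 0.02.
Composites are item means. Demographics: age ~ N(30, 9.44) clipped to
18–65 for the healthy cohort; gender 50/50; education 10/50/40.

**What the generator does not emulate:** response styles (acquiescence,
straight-lining), dropout, item-level floor/ceiling asymmetries, and any
real-data association between demographics and psychology (age, gender
and education are generated independent of the traits). Passing tests
therefore certify the *machinery* — estimation, search, inference, policy
learning — under the published effect structure, not robustness to
real-data artifacts.

## 3. SEM engine (`reguframe.sem`)

Fitting minimizes the maximum-likelihood discrepancy
F = ln|Σ(θ)| + tr(S·Σ(θ)⁻¹) − ln|S| − p over a RAM parameterization
(directed-coefficient matrix for loadings and paths; symmetric matrix for
variances and free covariances; Σ = G·Ψ·Gᵀ with G the observed rows of
(I−A)⁻¹). Items are standardized before fitting (Pearson correlations of
the 7-point items, the conventional continuous treatment), so the
reported solution is standardized and directly comparable to path
diagrams; χ² = (n−1)·F_min.

- Identification: first loading per latent fixed to 1; standardized
  solution derived post hoc from model-implied variances.
- The theory model frees the covariances among exogenous latents
  (foci ↔ foci, foci ↔ pre-intention) and among the three emotion
  residuals. The emotion residual covariances are required for the
  published coefficients to be jointly representable (section 2); freeing
  exogenous covariances is standard practice and is what makes the
  "drop pre-intention" comparison model testable rather than trivially
  equivalent.
- Gradients are analytic (trace identities on the RAM derivatives;
  verified against finite differences in the tests), keeping a
  75-parameter fit under 0.1 s; variances are log-parameterized; a
  non-PD proposal returns a large penalty, and up to three jittered
  restarts are attempted before flagging non-convergence (never raising).
- Standard errors come from the numerically differentiated Hessian of F
  (observed information); standardized SEs scale by the standardization
  factors with the latent SDs treated as fixed — an approximation that is
  immaterial for the delta-method indirect-effect tests it feeds.
- Fit indices: RMSEA = √(max(χ²−df,0)/(df·(n−1))); CFI and TLI against
  the independence baseline (TLI reported raw and truncated at 1); SRMR
  on the correlation metric.
- Indirect effects are the *exact* product of the standardized path
  estimates (an algebraic identity the tests assert), with delta-method
  SE/p by default and a seeded percentile row-bootstrap as an option.
- Model comparison requires fits of the same source table (fingerprinted)
  and ranks by CFI, then RMSEA; an AIC-style χ² + 2q column is reported
  but not used for ranking across different indicator sets.

**A-priori sample size** (`reguframe.power`) combines two published lower
bounds: (i) the effect-detection bound
⌈((z₁₋ₐ*/₂ + z_power)/δ)² + 3⌉ with a* the Šidák-corrected significance
level over the j(j−1)/2 latent-pair correlations an SEM implicitly tests,
and (ii) the model-structure bound ⌈50r² − 450r + 1100⌉ in the
indicators-per-latent ratio r, clamped at its vertex (r = 4.5) so it is
non-increasing. On α = 0.05, power 0.90, effect 0.30, 11 latents and 41
indicators this gives max(238, 118) = 238. A Bonferroni correction gives
the same integer (237.99 vs 237.27 before the ceiling); Šidák is the
documented default.

## 4. Discrete network (`reguframe.bayesnet`, `reguframe.discretize`, `reguframe.elicit`)

Composites are tertile-coded at the empirical 1/3 and 2/3 quantiles of
the *training* data (v ≤ t₁ → low, v ≤ t₂ → medium, else high); cut-offs
are never re-estimated on held-out or transferred data. Variables with
fewer than three distinct values are dropped with a log entry; heavily
tied Likert vectors may collapse categories but the coding stays total
and deterministic. Age is tertiled like other numerics; gender,
education and frame keep their observed categories.

CPTs are smoothed counts (count + s)/(Σ + s·k), s = 1 by default, which
guarantees every state reachable; more than six parents is refused with a
pointer to the search constraints. Inference is exact variable
elimination (min-degree heuristic; networks here have ≤ ~16 small-card
nodes), tested against full-joint enumeration to 1e-12 on random
networks. Conditional sampling draws from the exact posterior.

**Backbone.** One node per latent composite; every structural edge of the
theory SEM, plus frame → {anger, calm, hope} as the intervention entry
point; pre-intention → post-intention is the two-time-slice element.
Backbone edges are immutable during search.

**Evidence tier.** Predictions condition on the pre-intervention tier —
demographics, foci, TPB, pre-intention — plus the frame; post-intervention
responses (emotions, involvement, deep processing) are always
marginalized, matching the intended deployment where only traits are
observable before sending a message.

**Structure elicitation.** Greedy forward search over single-edge
additions from candidate variables (demographics, TPB) into the current
network (candidate-to-candidate edges included; edges into the exogenous
foci from TPB variables excluded to preserve the backbone's causal
reading; parent cap 4; acyclicity enforced). Moves are ranked by the
combined score w·AUC_in + (1−w)·AUC_out (w = 0.5; AUC = Hand-and-Till M
for the tertile-coded target; out-of-sample = leave-one-out with
per-fold refitting of cut-offs and CPTs, or k-fold for speed).

Acceptance is deliberately stricter than the combined score alone. The
in-sample AUC of a CPT predictor is non-decreasing in added parents —
resubstitution optimism, exactly as R² never decreases — so a pure
combined-score gate admits pure-noise parents almost always (measured:
~19/20 at n = 120). Scalar AUC differences are also too noisy to gate on
(σ ≈ 0.04 at n = 120). A move is therefore accepted only if (a) the
combined score and its out-of-sample component both improve by ≥ ε
(0.005) and (b) a one-sided paired t-test on the per-row held-out
log-scores favors the candidate at α = 0.005 — rows are independent, so
this test is approximately exact, and it calibrates itself to any sample
size. Measured operating characteristics: 0/40 pure-noise acceptances,
8/8 planted-signal acceptances (LOO AUC ≈ 0.99) at n = 120.

On the default synthetic cohort the search retains *no* additional
variable — correctly: the generator routes all TPB influence through
pre-intervention intention, which is already evidence, so the candidates
are conditionally independent of the target. Real-data structure
elicitation retained such variables because the data carried signal the
generator does not posit. Each run's elicited structure is therefore
documented per run (`results/search_trace.json`, `results/net.dot`)
rather than asserted against a fixed target structure.

**Leakage discipline.** The LOO protocol refits discretization cut-offs
per fold (stricter than merely refitting CPTs); the tests assert that
poisoning a held-out row's target leaves that row's own fold model
bit-identical.

## 5. Profiling policy (`reguframe.policy`, `reguframe.guidance`)

The interaction is a finite-horizon decision problem: evidence over
askable variables (the pre-intervention tier); moves are query(v) or
send(frame); sending ends the episode with reward = posterior probability
that post-intervention intention is in its top tertile given the evidence
and the frame (a probability objective; an expected-ordinal reward is a
config switch). Sending is always legal; the question budget (default
max 6) caps queries; the 3-question lower bound of the deployed chatbot
is treated as a reporting bound on extracted trees (a warning, not an
illegal move) because a network in which immediate sending is optimal
would otherwise force provably useless questions.

Search is PUCT MCTS: selection by Q + c·P·√N/(1+N) (c = 1.5); send edges
are terminal and evaluated by the exact posterior reward; query answers
are chance events sampled per traversal from the exact posterior (their
values average over visits); unexpanded nodes are evaluated by the
guidance network (uniform priors / neutral value when none is given).
The guidance function is a two-hidden-layer (width 64, tanh) map from the
one-hot-with-unobserved state encoding to masked move logits and a
sigmoid value head, trained by Adam on (visit-distribution,
realized-reward) targets from self-play with temperature 1 for the first
half of the budget and greedy afterwards. Training is fully seeded; the
log records held-out cross-entropy and value MSE per fit (divergence
aborts with a diagnostic).

Two exact oracles validate the stack: a dynamic program over the evidence
lattice, V(e,b) = max(max_f E[r|e,f], max_v Σ_a P(a|e)·V(e∪a, b−1)), with
ties preferring shallower trees, refused above ~10⁵ configurations; and
exact tree evaluation by enumeration over answer distributions. On toy
networks with up to four askable ternary traits the extracted tree
reaches the DP optimum within 0.02 across seeds.

**Study-scale finding.** On the network elicited from the default
cohort, the extracted tree is a single leaf (send immediately). This is
the network being read correctly, not a search failure: the 0.2 SD
matching effect on hope attenuates through hope → involvement → deep
processing → intention (×0.87 ×0.5 ×0.4 ≈ 0.035 SD) and then through
tertile coding, leaving frame-conditional rewards within < 0.01 of each
other; the DP optimum gains only +0.002 from asking. The ask-then-match
regime — three-to-six-question trees — appears exactly when the frame
response depends strongly on observable traits, as in the toy contrast
case run by `analysis/05_learn_policy.py` and the oracle-equivalence
tests.

## 6. Evaluation (`reguframe.evaluation`)

Multi-class AUC is Hand & Till's M: the average over ordered class pairs
(i, j) of the probability that a random class-i case receives a higher
class-i score than a random class-j case, ties at half credit; pairs with
an absent class are skipped with a warning; macro one-vs-rest AUC is
available as a secondary view. M is checked against explicit pair
enumeration and against scikit-learn's one-vs-one score.

The recovery experiment simulates R cohorts at n = 564, refits the theory
model, and aggregates the standardized structural estimates and the four
product-of-paths indirect effects against the generating truths
(replicate r uses seed base+r; non-converged replicates are excluded and
counted; more than 10% failures flags the report invalid). At 50
replicates every structural mean lands within ±0.01 of its generating
value (empirical SEs 0.03–0.05).

The in/out transfer analysis fits discretization and CPTs on one cohort
and scores a second without refitting. The published headline AUCs (0.66
in-cohort, 0.58 on the patient cohort) are facts about the undeposited
study data and are not reproduction targets; on synthetic cohorts the
backbone's LOO AUC sits near 0.5 because almost all target signal flows
through a single tertile-coded parent chain. The qualitative degradation
property (transfer above chance but below the in-cohort LOO AUC when the
generating signal is preserved) is asserted on a compact
pre + frame → post network with a strong direct effect and a mean shift
that miscalibrates the training cut-offs.

## 7. Problem sizes and seeds

Defaults used by the tests and the acceptance script, chosen as the
study-scale quantities the analyses are about: cohorts of n = 564 (the
study sample size), 50 recovery replicates, LOO at n ≤ 600, 200 random
networks for the inference oracle, 20 replicates for the noise-rejection
check at n = 120, toy policy networks with ≤ 4 ternary traits and 3
seeds. All randomness flows from named integer seeds (per-stage children
derived by hashing in the pipeline); two runs with the same seed produce
byte-identical JSON artifacts.

## 8. Known limitations

- Likert items are treated as continuous in the SEM (no
  categorical/WLSMV estimator); the induced attenuation is measured by
  the α-recovery tests and absorbed into the measurement model.
- Standardized SEs treat latent SDs as fixed; bootstrap is the fallback
  where that approximation matters.
- The greedy forward search explores single-edge additions only (no
  removals or reversals, no score-equivalence classes); the backbone is
  trusted, not tested.
- The two-time-slice reading of "dynamic" is the only temporal structure
  the design measures; no unrolled temporal process is modelled.
- Missing data are handled by row-wise deletion; the generator produces
  complete records.
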