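# Methods

## The paradigm

`wagework` studies the subjective cost of cognitive work through a
*wage-for-work* design. A subject plays 32 rounds. Before each round they
are shown one of three **rated tasks** — the 1-back, the 2-back, or the
3-detect (respond when any letter repeats three times in a row) — and
state, on a 1–5 slider, the wage they consider fair for completing one
round of it. An **inverted Becker–DeGroot–Marschak (BDM) auction** then
draws a computer offer uniformly on [1, 5]: if the offer is at or above
the stated wage the subject completes the rated task and earns the offer;
otherwise they complete the default 1-detect task (respond to the letter
T) for 1 point. For a risk-neutral agent the expected-payoff-maximizing
policy is to state the true subjective cost of the round (plus the
default task's value), which is what licenses reading the wages as costs.

Every round is 15 letters (1.5 s each, 300 ms ISI) with 3–5 targets, so
target rates sit between 20% and 33%. 2-back sequences contain 1–3
**lure** trials — the letter matches the stimulus one trial back without
being a 2-back target — the event behind the interference cost. Accuracy
is tracked online as a weighted rate giving hits three times the weight of
correct rejections; a subject whose running weighted accuracy drops below
60% at one of the every-8-rounds checks is flagged and their session ends
early.

## The process model

Cost decomposition assumes a perfect working-memory gating model that
completes each round with 100% accuracy. A FIFO buffer holds the task's
instructed load (0 items for 1-detect, 1 for 1-back, 2 for 2-back and
3-detect). Each trial the incoming letter is compared to the newest
buffered item: on a match no gating is needed; otherwise one **update** is
tallied and the buffer shifts. The first `load` trials each tally one
update (initial gate-in). Whether those gate-in trials should count is
genuinely open; we count them, and expose `match_any` to compare against
any buffered item instead of the newest. **Maintenance** is the per-round
instructed load (not load × trials): it is a between-task quantity and
that is the role it plays in the cost sum. **Interference** counts lure
trials and exists only on the 2-back by default. The behavioral
components — responses, misses, false alarms — are tallied from the
observed (simulated) responses and never generated by the process model.

## The rating models

A round's total cost is

    cost_r(k) = Σ_j components_j^r · c_j(t)

over the model's cost set (subsets of update, maintenance, interference,
response, miss, fa), and the mean rating for task k follows a delta rule
driven only by *completed* rounds of that task:

    m_{r+1}(k) = m_r(k) + α · (cost_r(k) − m_r(k)),      rating ~ N(m, σ²).

Mechanism classes: `alpha` (constant costs, fitted α, one init per rated
task); `delta` (α ≡ 1, costs drift linearly with the global round number,
c_j(t) = c_j·(1 + δ_j·t/T), a single shared init to limit its parameter
count); and two joint classes (`alpha_delta_linear`, `alpha_delta_exp`
with c_j(t) = c_j·t^δ_j) that are implemented but excluded from the
default comparison set, which crosses the 63 non-empty cost subsets with
`alpha` and `delta` (126 models). The global round index t runs over all
32 rounds regardless of auction outcome, since fatigue-like drift should
track time on task, not completions.

Fitting happens in an unconstrained space — α through a logistic sigmoid,
σ through an exponential, all other parameters unbounded — with an
analytic forward-mode gradient of the Gaussian log-likelihood (checked
against central differences in the tests). The likelihood is *not*
truncated to the slider: the generative equations specify plain additive
Gaussian noise. The synthetic experiment, by contrast, clamps the emitted
rating to [1, 5] before the auction sees it, because the slider physically
bounds what a subject can state. Both views of a simulated session are
kept (`ratings("raw")` / `ratings("slider")`); the model-validation loop
fits the raw emission (see *Generate-and-recover* below) while behavioral
summaries use the slider record.

## Hierarchical fitting and model comparison

Each (subject, model) pair is fit by MAP under a diagonal Gaussian group
prior in the unconstrained space (L-BFGS-B, 5 prior-drawn restarts on the
first sweep, warm starts after), with the model evidence approximated by
Laplace's method: log joint at the mode + (d/2)·log 2π − ½·log det H,
where H is the ridge-regularized (1e-6), eigenvalue-floored Hessian from
central differences of the analytic gradient. An outer loop alternates
per-subject fits, per-subject **responsibilities** (evidence-proportional
under a uniform model prior), and responsibility-weighted re-estimation of
each model's group mean and variance, so subjects a model describes badly
do not distort its group distribution. The group variance update adds the
subjects' Laplace posterior variances to the weighted squared deviations
plus one pseudo-observation at the initial prior variance (6.25) — a
deliberate regularizer that keeps a model's group distribution proper when
few subjects load on it. Convergence: relative group-mean change < 1e-4,
cap 50 iterations. **Model frequency** is the responsibility sum;
group-level selection uses the **protected exceedance probability** from
the standard random-effects construction (variational Dirichlet posterior
with α₀ = 1; exceedance by 100,000 seeded Monte-Carlo argmax draws;
protected by blending with the equal-frequency null at the Bayes omnibus
risk). The contract — responsibilities, frequencies, PXP, group moments —
is the target, not bit-compatibility with any particular toolbox.

## Cross-model cost posteriors

Group parameter estimates live inside single models, so cost magnitudes
are compared across the model set with responsibility-weighted mixtures:
each subject's posterior over a cost mixes their per-model Laplace
posteriors; a model that omits the cost contributes the across-model group
prior (frequency-weighted mixture of the group Gaussians of the models
that contain it; the base fitting prior if none does). Only models with
frequency ≥ 1 enter by default. Within-model posteriors are treated as
axis-aligned Gaussians, so the 4-D joint over (update, interference,
maintenance, fa) factorizes per mixture component and every quantity is
computed marginal-by-marginal on an 81-point per-cost grid spanning all
mixture components' means ± 4 SD; doubling the resolution moves the means
by < 1% (tested). The **hierarchical SEM** divides the marginal SD by
√(Σ_s Σ_{m∋cost} ρ_ms) — the effective number of subjects whose data the
cost explains. Group posteriors (questionnaire tertiles) multiply the
group's subject densities per axis in log space and renormalize on the
grid; groups are normalized independently of their size.

## Synthetic cohorts

The generator's defaults are the paradigm's stated conditions: 32 rounds,
3 rated tasks offered 10/11/11 times in random order, 15-trial sequences
with 3–5 targets (1–3 lures on the 2-back), continuous uniform offers on
[1, 5] (a 0.1-step discrete grid is available), ties awarded to the rated
task, 1 point for the default. Per-task hit/false-alarm probabilities
(0.98/0.005, 0.85/0.05, 0.92/0.02, 0.70/0.10 for 1-detect, 1-back,
3-detect, 2-back) and RT distributions (means 550/611/530/720 ms) are
calibrated so weighted accuracies land near the canonical profile
(~98/89/94/80%) with the 2-back slowest and least accurate; responses
slower than the 1.5 s deadline are scored as non-responses. Questionnaire
items are generated from a subject-level latent tendency (NFC ~ N(3.4,
0.9) on a 1–5 scale over 18 items with 9 reverse-coded; SAPS ~ N(4.4,
1.3) on a 1–7 scale over 8 items), with ~1% missing items and a 95%
screener pass rate. End-of-session difficulty ratings are the agent's
final rating state plus noise, clamped to the slider.

What the generator does *not* emulate: practice-phase training, real
RT–accuracy coupling, within-subject correlation between cost components
beyond what the task structure induces, sequential questionnaire response
styles, and attrition beyond the accuracy rule. Passing tests therefore
certify the machinery — identifiability, conservation laws, the auction's
incentive structure — on data whose noise is exactly the model's, not that
the same numbers would be obtained from human cohorts.

## Generate-and-recover

Recovery cohorts draw parameters uniformly within declared ranges
(σ ∈ [0.1, 1.5] points, α ∈ [0.05, 0.95], inits ∈ [1, 5], costs and
drifts ∈ [−1, 1] per component unit), push every agent through the full
paradigm (task-engine sequences, auction censoring of which rounds update
the rating state), refit the generating model hierarchically, and report
per-parameter Pearson correlations between generating and recovered
(posterior-mode, natural-scale) values. The fitted observations are by
default the ratings **as the generative model emits them** (mean + untruncated
Gaussian noise) rather than their slider-clamped counterparts: model
validation asks whether the fitter inverts the model, and under the
declared cost ranges clamping censors roughly half the observations,
destroying identifiability of the learning rate rather than testing it.
`generate_recover(observe="slider")` runs the fully-embodied variant for
anyone who wants to study exactly that censoring.

With 50 subjects this yields learning-rate recovery around r ≈ 0.8–0.9,
init recovery around 0.85–0.95, maintenance-cost recovery around 0.65,
and near-ceiling update-cost recovery (≈ 0.97): with task-engine
sequences the update tally is high-variance and near-orthogonal to the
other components, so its cost is the best-identified parameter. Screening
a model space keeps models whose parameters all reach r ≥ 0.5 with
max |cost–cost fit correlation| ≤ 0.7 (both configurable; the thresholds
are declared, as no canonical values exist).

**Simulation fidelity** re-simulates each subject's ratings from their
best-responsibility model and fitted parameters with fresh noise
(slider-clamped), pools subjects, correlates simulated with observed
ratings, and averages r² over repeats × iterations.

## Statistics layer

Questionnaires are scored by reversing masked items (scale_max + 1 −
response), summing answered items and dividing by their count, so missing
answers do not deflate scores; screener failures flag the score excluded.
Tertile splits cut at the empirical 1/3 and 2/3 quantiles with ties
assigned en bloc, so groups can be unequal. The self-report regression
trims exhaustively over the 15 non-empty subsets of {NFC, NFC², SAPS,
SAPS²} (intercept always kept), retains subsets whose omnibus F-test has
p < 0.05 (per-term criterion by flag), and picks the significant subset
with the lowest MSE. Behavioral summaries produce the task × {accuracy,
RT, difficulty, wage} table, two-way (task × iteration) ANOVAs via
statsmodels, paired post-hoc t-tests (Holm correction by flag, off by
default to match conventional reporting), first-half/second-half
comparisons, and the offer-matching check (Spearman correlation of the
rating at round t with the offer at round t−1, per subject and pooled).

## Problem sizes and numerical choices

Default desk-scale sizes: recovery cohorts of 50 subjects (the headline
run, ~15 s on one CPU), screening at 30, pipeline smoke runs at 20
subjects with two models. Optimizer tolerance 1e-6 on the objective;
log-σ is clamped to ±20 during evaluation purely to keep exp()
representable; Dirichlet sampling for PXP uses 100,000 draws (stable to
three decimals). All randomness descends from one seed through named
substreams (sequence/behavior/noise/offers/fitting/PXP).

## Known limitations

* The Gaussian rating likelihood ignores the slider bounds; fitted σ for
  subjects who rail at a bound is biased low in the slider-observed view.
* Laplace evidences are asymptotic; with 32 ratings per subject the
  Occam penalty between nested models is approximate (the tests verify
  ≤ 0.5 nat error only on a 2-parameter toy).
* The update-cost tally's near-orthogonality in synthetic sequences makes
  its recovery stronger than one should expect on real letter streams,
  where components co-vary within subject.
* Group posteriors multiply subject densities per axis; cross-cost
  dependence between subjects is not represented.
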