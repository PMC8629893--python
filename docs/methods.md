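# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `revlearn3`.

## The task

Three stimuli, 80 trials, binary feedback λ ∈ {−1, +1}. One stimulus is
rewarded with probability 0.75 during the first 40 trials and 0.25 after the
reversal ("R-P"), a second has the mirrored contingencies ("P-R"), and a
neutral stimulus pays off with probability 0.5 throughout ("N-N"). Roles are
defined behaviourally: whichever stimulus is chosen first becomes R-P. A
consequence worth keeping in mind when reading trajectories: on trial 1 the
probability of "choosing R-P" is 1 by construction, for participants and
simulated agents alike.

Feedback schedules are choice-independent: every stimulus has a
predetermined outcome on every trial, so agents sharing a seed face
comparable environments and counterfactual outcomes are well defined. Two
generation modes exist:

* `exact_ratio` (default): within each phase each stimulus realises its
  programmed reward count exactly (30/40, 10/40, 20/40). For the two
  reversing stimuli, arrangements containing a run of 5 or more identical
  outcomes are excluded (`max_run = 4`); long runs distort probabilistic
  learning and make schedules unrepresentative. Sampling is exactly uniform
  over the admissible arrangements, via a dynamic-programming count of valid
  completions rather than rejection.
* `iid`: independent Bernoulli outcomes; reward counts hold in expectation
  only, with no run constraint.

The exact sequence constraints used in the original experiment are not
public; both modes are provided and the choice is a config field.

## Model family

**EWA** (experience-weighted attraction). Per option: experience weight
`n` (init 1) and value `V` (init 0). After choosing option c and observing λ:

    n_c ← n_c·ρ + 1
    V_c ← (V_c·φ·n_c_old + λ) / n_c_new

φ ∈ [0,1] is the decay of previous payoffs — the *inverse learning rate*
(high φ = slow updating); ρ ∈ [0,1] governs growth of the experience
weight, so the effective learning rate 1/n shrinks with use. Unchosen
values are unchanged in the base model.

**Forgetting (+F)**: unchosen options decay toward their initial value,
`V_j ← (1−α_f)·V_j`, α_f ∈ [0,1]. With α_f = 0 the +F models are exactly
the base models (asserted bit-comparably in tests).

**Pearce–Hall hybrid**: per option an associability `a` (init 1) tracks
recent surprise. With δ = λ − V_c:

    V_c ← V_c + min(η·a_c, 1)·δ
    a_c ← (1−κ)·a_c + κ·|δ|

The cap on the effective learning rate η·a is a numerical choice made here:
with feedback coded ±1 the associability can exceed 1/η, and the uncapped
recursion diverges on unlucky sequences. The cap binds rarely at fitted
parameter values and keeps the likelihood finite everywhere, which the
optimiser requires.

**Choice rule**: softmax with inverse temperature β ≥ 0,
p(c = i) ∝ exp(β·V_i), computed via log-sum-exp.

**Drug-split variants**: any single EWA+F parameter can be estimated
separately for the placebo and methylphenidate sessions (φ, ρ, β or α_f),
giving the five-model drug family {EWA+F, +Δφ, +Δρ, +Δβ, +Δα_f}. Learner
state resets between sessions; both sessions enter one likelihood.

**Parameterisation**: all fitting happens on an unconstrained scale —
logistic sigmoid for unit-interval parameters, exp for β — with independent
N(0, 10) priors on the unconstrained scale. The exp transform is capped at
exp(50) so optimizer line searches cannot overflow the likelihood; the cap
is far beyond any interpretable inverse temperature.

## Fitting

Subject-level MAP estimation minimises NLL + negative log prior with
multi-start BFGS (default 20 restarts for standalone fits; initial points
drawn from the prior, first start at the prior mean). Gradients are
analytic: the derivative recursions of the value trajectories are
propagated forward in the compiled likelihood kernels, and a test checks
them against finite differences to 1e−5. The Hessian at the optimum is
obtained by central differences of the analytic gradient; if it is not
positive definite it is ridge-regularised and the repair is recorded on the
fit object. Model evidence uses the Laplace approximation

    log Z ≈ −f(x*) + (d/2)·ln 2π − ½·ln det H .

Against the conjugate-Gaussian closed form this is exact to 1e−8 (test).
Laplace standard errors are somewhat anticalibrated for the weakly
identified parameters (ρ, α_f trade off over 160 trials): in recovery
simulations ~86% of true values fall within 3 SE rather than the nominal
99.7%. φ itself is tightly identified.

## Hierarchical model comparison

The random-effects scheme iterates: (1) subject-level MAP fits and Laplace
evidences `L_nm` under per-model group priors (diagonal Gaussians on the
unconstrained scale), warm-started between iterations; (2) responsibilities
`r_nm ∝ exp(L_nm + ψ(α_m) − ψ(Σα))`; (3) Dirichlet update
`α = α₀ + Σ_n r_n` (α₀ = 1); (4) group moments re-estimated from the
responsibility-weighted subject posteriors, with a weak regulariser
(`b0 = 1` added to the scatter, one pseudo-observation) so a model claiming
few subjects keeps a finite group variance. The variational free energy

    F = Σ_n logsumexp_m [L_nm + E ln p_m] − KL(Dir(α) ‖ Dir(α₀))

is recorded each iteration; convergence is declared when successive values
differ by less than the tolerance, and a non-converged result is flagged
rather than hidden.

Model comparison statistics: model frequency α/Σα; exceedance probability
by the exact Beta tail integral for two models and seeded Monte Carlo
(10⁶ draws) otherwise; Bayes omnibus risk BOR = 1/(1 + exp(F₁ − F₀)) where
F₀ = Σ_n logsumexp_m (L_nm − ln K) is the bound under equal frequencies;
protected exceedance probability pxp = (1 − BOR)·xp + BOR/K.

All drug-effect statistics downstream (t-test, correlations) use the
*non-hierarchical* per-subject fits, not the hierarchical ones, to avoid
shrinkage-induced coupling between the drug conditions.

## Behavioural statistics

Accuracy per phase: probability of selecting the currently-rewarded
stimulus (pReward, chance 1/3) and of avoiding the currently-punished one
(pAvoidPunish, chance 2/3), with "currently" re-evaluated after the
reversal. Chance correction defaults to subtracting each metric's own
chance level so a uniform chooser scores 0 on both (the `"chance"`
convention); the `"third"` convention (subtract 1/3 from both) is also
provided, since published descriptions of the correction are ambiguous.
Both are computed by the same code path from per-trial choice
probabilities, so observed sessions (one-hot) and posterior-predictive
averages are scored identically.

The omnibus test is the 2×2×2 within-subject ANOVA (Valence × Phase ×
Drug) with mean-centred continuous covariates (WM span, BIS-11). Because
every factor has two levels, each within-subject effect reduces to one
subject-wise contrast, and its F (and its interaction with each covariate)
is the squared t from regressing that contrast on [1, covariates]. This is
algebraically the classical repeated-measures ANCOVA for 2-level designs —
cross-checked against statsmodels `AnovaRM` and pingouin to numerical
precision — and gives the familiar (1, n−1−p) degrees of freedom. The
Huynh-Feldt ε is identically 1 for 2-level factors and is reported as such;
designs with >2-level factors are outside this implementation's scope.
Simple effects refit the model within each level of the split factor, using
that level's own error term.

RT filtering removes trials faster than 200 ms (strictly; 200 ms is kept),
preserving each surviving trial's phase. Stay probabilities condition
P(repeat choice) on the current trial's outcome and phase; empty bins are
NaN, never silently 0.

## Synthetic cohorts

`generate_cohort` emulates the study's structure: 102 subjects × 2
counterbalanced sessions (50 receive methylphenidate first) × 80 trials,
EWA+F agents with unconstrained-scale group Gaussians whose constrained
medians sit near φ ≈ 0.77, ρ ≈ 0.63, β ≈ 4.2, α_f ≈ 0.35. WM span is an
integer score ~N(35, 8²) clipped to [10, 60]; BIS-11 ~N(63, 9²) clipped to
[35, 95]. The drug effect is injected on the logit scale,

    φ_MPH = φ_placebo + b·z(WM) + σ_drug·ε   (unconstrained),

defaults b = 0.35, σ_drug = 0.55. Under these defaults a fitted cohort
shows a Δφ–WM Spearman correlation around +0.35 and an acquisition-specific
drug-by-WM simple effect of modest power — the intended regime of a real,
noisy drug effect. Optional RTs are uniform on [300, 1500] ms with a 0.2%
admixture of fast (<200 ms) trials, solely to exercise the filter.

What the generator does *not* emulate: reaction-time structure, trial-level
stimulus positions, session-order effects, within-session drift of
parameters, or any correlation between group parameters (they are drawn
independently). Passing tests on these cohorts therefore demonstrates
correctness of the machinery under the model's own assumptions, not that
the model is true of human data.

### Effect sizes used in the recovery experiments

Two experimental conditions deviate deliberately from the defaults, both
chosen from pilot detectability analyses and then frozen:

* **Drug-split recovery** uses σ_drug = 1.5 (≈0.3 in φ at the group
  median). At the default paper-scale split the five-model comparison does
  **not** reliably identify the split model at n = 50 × (2 × 80 trials) —
  the median per-subject evidence gain is negative — which is itself an
  informative statement about the resolution of this design. At a split of
  1.5 logit units the generating model is selected essentially always.
* **The acquisition-specific simple-effect demonstration** uses b = 0.8,
  where the acquisition drug-by-WM simple effect has ~95% power while the
  reversal-phase effect remains rare; at the default b = 0.35 power is
  ≈50%.

The statistics-level power test for `simple_effects` is separate: it
injects an acquisition-only Drug×WM interaction directly on accuracy
scores (slope 0.02 per WM z-unit per drug level against cell noise
σ = 0.1), sized for ~95% power at n = 102.

## Optimal learning rate

Accuracy (fraction of trials choosing the phase-appropriate best stimulus)
and mean reward are both reported over a φ grid, other EWA+F parameters
fixed at reference values (default: the group medians of the cohort under
analysis). The comparison task is the predecessor 2-option design with
70:30 contingencies and otherwise identical structure. Because the two
curves peak within ~0.01 of each other at the reference parameters, the
peak is located by a quadratic fit through the grid points around the
argmax, with common random numbers across the grid; at 3-option vs 2-option
the peak sits consistently at higher φ (≈0.905 vs ≈0.896 with 4000
simulations per grid point), i.e. the 3-option task rewards slower
learning. The separation grows sharply at α_f = 0 and can invert at low ρ
or very high β, so the statement is tied to the reference regime.

## Problem sizes

Recovery and calibration experiments run at the sizes stated with each
result: model recovery at 50 subjects and 20 replicates per family;
type-I-error calibration at 400 null cohorts of 102 subjects;
`scripts/acceptance.py` reruns single replicates of each experiment plus a
200-cohort calibration. Hierarchical fits inside the recovery loops use 4
initial restarts, warm-started EM refits and 10 iterations, which pilot
traces showed is past the point of decision-relevant change in pxp.

## Known limitations

* Diagonal group covariances in the hierarchical scheme (no parameter
  correlations at the group level).
* Laplace evidences inherit MAP bias for strongly skewed posteriors; the
  non-hierarchical estimates used for correlations are shrunk toward the
  prior mean.
* The ANOVA machinery is specialised to 2-level within factors (the
  design's own shape); Huynh-Feldt correction never engages.
* The hybrid model uses the standard surprise-modulated form with the
  learning-rate cap described above; the original study's exact hybrid
  equations were not available for comparison.
* No reaction-time modelling anywhere.
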