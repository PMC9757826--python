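# Methods

This note documents the models, numerical choices, and design decisions
behind `decoychoice`, in the spirit of the methods documentation of
packages such as statsmodels or msprime.

## Task structure and data model

Options are risky prospects (X, P) on normalised [0, 1] attribute scales;
loaders rescale raw units via a schema-declared (min, max) per attribute.
Commensurate scales are required because both the additive-utility (AU)
weighting and the Euclidean decoy proximity only make sense when magnitude
and probability are comparable. Targets are labelled by expected value
(EV = X·P), H ≥ L; relabelling at load time also recodes recorded choices.
The response deadline (default 1.5 s) is table metadata; RTs above it are
rejected at load, and non-responses are kept as rows but excluded from all
likelihoods and accuracies, as are trials where the unavailable distractor
was (accidentally) chosen.

Ternary conditions are matched to binary baselines by exact equality of the
(HX, HP, LX, LP) quadruple, with a configurable absolute tolerance (default
1e-9) for float round-trips. The matching is many-to-one — several ternary
conditions share an (H, L) pair, and several binary trials can repeat it —
and the matched-trial count per condition becomes the observation weight in
the GLMs. Unmatched ternary conditions are flagged explicitly (weight 0)
and excluded from combined analyses with a logged count, never silently
dropped.

## Utility models

* **EV**: U = X·P.
* **AU**: U = λX + (1−λ)P, 0 ≤ λ ≤ 1 (weighted-mean convention). An
  attribute-sum convention (X + P) is provided for unweighted worked
  examples; the two are rank-equivalent and differ by a factor 2 at
  λ = 0.5, so correlation-based analyses are unaffected by the choice.
* **Non-linear distortions**: probability via a log-odds transform with
  slope η and fixed point P0 (endpoints 0 and 1 map to themselves, with a
  warning, as the limit behaviour), or the one-parameter inverse-S form
  P^τ/(P^τ+(1−P)^τ)^(1/τ); magnitude via X^γ. Expected utility fixes the
  probability linear (free γ); the prospect-theory variant frees τ and γ
  and multiplies the distorted attributes.
* **Selective integration (SI)**: within each attribute, alternatives are
  ranked; the top value is unchanged (w₁ ≡ 0), the intermediate multiplied
  by (1−w₂), the lowest by (1−w₃), 0 ≤ w₂ ≤ w₃ ≤ 1 — "suppressed by w"
  means a proportional gain reduction, so w = 1 drives the losing value to
  0. Ties: values sharing the row maximum stay unchanged; values sharing
  the minimum (without being maximal) are suppressed by w₃; a full
  three-way tie leaves the row unchanged (no rank information to act on).
  With two alternatives only one losing rank exists, so a single gate (w₂)
  applies. Utilities are then AU of the gated attributes.
* **Adaptive gain**: each attribute value is centred on the context mean
  across the displayed alternatives and passed through
  1/(1+exp((b−v)/s)); separate (s, b) per attribute with a tied option
  (the tied form is the default in the registry, keeping the parameter
  count at two; nothing in the model requires sharing, so the untied form
  is available via `s_x, b_x, s_p, b_p`).
* **Divisive normalisation**: U_i / ΣU over the alternatives present
  (H+L binary, H+L+D ternary).

Context-dependent transforms always see the full displayed choice set —
including the unavailable distractor — even though only H and L race.

## Race likelihoods

Each alternative drives an independent unit-variance diffusion
dx = (kI + I0)dt + ξ√dt from x₀ = 0 to an absorbing bound θ, with
I_i = U_i − c·mean_{j≠i}(U_j). σ = 1 and x₀ = 0 are fixed: bounding the
diffusion in units of σ removes the scaling degeneracy between k, θ and
the noise. Single-accumulator first-passage times are inverse Gaussian;
the joint likelihood of choice i at decision time T = RT − t_nd is the
chosen accumulator's first-passage density times every competitor's
survival. The survival function's term e^{2θμ}Φ(−(μT+θ)/√T) is evaluated
in log space (via `log_ndtr`) so large θμ cannot overflow.

The dual-route model races two processes per alternative — one on raw
EVs with mutual inhibition U_i − f_MI·mean(U) (mean over *all*
alternatives), one on divisively normalised EVs — and the response is
whichever of the 2n accumulators absorbs first; the likelihood of choice
i sums the two routes' terms, each the route density times the survival
of all other accumulators in both routes. In ternary trials the
distractor's accumulators participate (a six-way race), although fitting
only uses H/L responses.

Predicted choice probabilities and conditional mean RTs integrate the
trialwise likelihood by the trapezoid rule on a dt = 0.001 s grid out to
t_max = 100 s (both configurable); unabsorbed mass beyond the horizon
above 1e-4 raises a warning. Trial likelihoods are floored at 1e-10
before logging so that RTs faster than a candidate non-decision time
leave the objective finite (how such trials were treated originally is
unstated; the floor is this package's choice).

### Stochastic oracle

`simulate_race` integrates the same dynamics by Euler–Maruyama. Two
refinements control the O(√dt) first-passage discretisation bias: a
Brownian-bridge crossing test between successive steps (probability
exp(−2(θ−x_t)(θ−x_{t+dt})/dt), on by default), and recording the
absorption at the *midpoint* of the crossing step. With these, 10⁵ paths
at dt = 0.001 match the analytic choice probabilities within Monte-Carlo
error and the conditional RT distributions within a Kolmogorov–Smirnov
distance well below 0.02, which is what the acceptance tests verify
across random parameter sets. Simultaneous crossings within a step are
broken uniformly at random; paths unabsorbed at t_max are reported as
censored, and simulated agents record deadline-censored trials as
non-responses.

## Fitting, cross-validation, and comparison

Static models map utilities through a softmax with inverse temperature β
and are scored by the weighted binomial log-likelihood of per-condition
choice proportions (weights = trial counts), which for integer weights
equals the expanded Bernoulli likelihood. Dynamic models are scored by
the joint choice/RT likelihood summed over included trials.

Optimisation is bounded L-BFGS-B from Latin-hypercube starting values
(default 10 starts, seed-controlled, ftol = 1e-10), reporting the best
start with per-start diagnostics. Default bounds — k > 0, θ > 0,
c ∈ [0,1], λ ∈ [0,1], 0 ≤ w₂ ≤ w₃ ≤ 1, β ∈ [0,100],
t_nd ∈ [0, 0.9·min RT], f_MI ∈ [0,1], distortion parameters in
(0.05, 20) — are this package's choices, wide enough to cover plausible
behaviour while keeping the search stable; point estimates can therefore
differ slightly from fits under other (unpublished) bounds. During
optimisation the SI gates are canonicalised to (min, max) so the w₂ ≤ w₃
constraint never creates a non-smooth boundary; results are reported in
canonical order.

Cross-validation uses k = 5 random folds, stratified by binary/ternary
condition type when both are present (so each fold mirrors the design),
fitting on k−1 folds and scoring the held-out fold; the criterion is the
mean held-out log-likelihood. BIC = p·ln(n) − 2·LL.

Group-level comparison re-implements the standard variational
random-effects scheme: a Dirichlet prior (α₀ = 1 per model) over
population model frequencies, iterated posterior updates until the change
in α falls below 1e-6, exceedance probabilities by sampling the converged
Dirichlet (default 10⁵ draws, seeded; under an exactly exchangeable
posterior the uniform value is returned analytically), and protection via
the Bayes omnibus risk computed from the variational free energy against
the equal-frequency null: pxp = xp·(1−BOR) + BOR/K. Evidence can be
cross-validated log-likelihoods or −BIC/2.

Model recovery simulates each candidate with chosen (or fitted)
parameters, refits all candidates, and summarises each generating model's
row with the random-effects comparison (−BIC/2 evidence by default, so
unequal parameter counts do not tilt the confusion matrix); parameter
recovery reports per-parameter correlation, bias, and RMSE over
simulate-and-refit pairs.

## Behavioural analyses

The relative-accuracy GLM regresses logit p(H over L) on a z-scored value
difference, a z-scored distractor variable (relative D−H or absolute D;
EV or AU basis), and their product — formed *after* z-scoring the
components, never by z-scoring the raw product — optionally with a value-
sum covariate. Binary baseline rows use the matched ternary condition's
*notional* distractor and the matched-trial observation weights; combined
models add a condition dummy C (0 = binary, 1 = ternary) and every effect
crossed with C. Fits use iteratively reweighted least squares
(statsmodels binomial GLM with variance weights); zero-variance columns
are dropped with a warning and complete separation is flagged rather than
raised. Group inference is one-sample t-tests per coefficient with Holm's
sequential Bonferroni correction (configurable off), plus Spearman or
Pearson across-subject correlations between effects.

The condition-unspecific bias of adding a third option is estimated by
shuffling, within subject, the mapping between ternary conditions and
their matched binary baselines (default 5000 permutations, seeded,
uniform shuffles; whether the original weighting was preserved under the
shuffle is unknown, so weights are optional and off by default) and
averaging the permuted T − B contrast; the corrected per-condition
contrast subtracts this single subject-level constant, leaving the
condition-specific structure intact.

Binned maps average an outcome in a sliding square window whose edge
spans 30% of each coordinate's quantile range, stepping by 1%: grid
length = floor((100−window)/step)+1 = 71 per axis at the defaults.
Quantiles are linearly interpolated from the empirical distribution;
empty windows are reported as missing.

The decoy analysis classifies each ternary condition by the distractor's
Euclidean proximity (closer to H vs L; exact ties form a category that is
excluded from the 2×2 table, since only clear cases are analysed) and its
AU dominance (superior if AU(D) exceeds both targets, inferior if below
both, otherwise neither — also excluded). Per-subject 2×2 cell means of
the bias-corrected T − B contrast feed a closed-form repeated-measures
ANOVA via orthogonal within-subject contrasts (for a 2×2 design each
effect is a one-sample t on a contrast score: F = t², df = (1, n−1),
partial η² = t²/(t²+n−1)); cellwise t-tests are Holm-corrected. Subjects
with an empty cell are excluded from the ANOVA with a warning.

## Synthetic designs and agents

The generator reproduces the structural facts the analyses rely on, with
defaults matching the study conditions: 150 ternary trials over 149
unique (H, L, D) conditions built on 95 unique (H, L) pairs, 150 binary
trials covering every pair at least once (so some baselines carry weight
> 1), uniform attribute sampling on [0.1, 0.9] (interior ranges keep
EVs away from degenerate corners), and H/L labelling by EV. Distractor
assignment resamples and then greedily swaps D's between conditions until
|r(DV−HV, HV−LV)| ≤ 0.1 across unique ternary conditions (the original
threshold is unpublished; 0.1 is configurable). Because DV−HV and HV−LV
share −HV, plain rejection cannot reach small |r|; the swap pass
preserves the sampled D marginal while steering the correlation.

Two variants probe the covariation diagnostic. The *confounded* mode
drives r(DV−HV, dAU⊥) up to a target (default test value 0.4), where
dAU⊥ is the component of the AU difference orthogonal to HV−LV — the
component that surfaces as a notional distractor slope once HV−LV is a
regressor. The *decorrelated* mode caps its magnitude as well. An
additive-utility agent then shows a clearly positive binary notional
distractor slope under the confounded design, shrinking away under the
decorrelated one.

Agents: static agents draw softmax choices over the two targets (no RT);
dynamic agents draw (choice, RT) from the race simulator with deadline
censoring recorded as non-responses. Only dual-route agents can ever
"choose" D (they race all accumulators); context-transformed agents see
D but race H and L.

## What the synthetic tests do and do not show

The generator emulates the *structure* of the task's designs, not any
particular deposited stimulus list: passing tests demonstrate that the
pipeline's inferences are correct on data whose generating process is
known and design-faithful (decorrelation constraint, matched baselines,
EV ordering), not that any empirical dataset exhibits a particular
effect. Analyses that target participant-level statistics of the
published datasets run unchanged on a trials CSV of those data when
supplied. Simulated-cohort sizes in the test suite (e.g. 30–50 agents,
3 agents per model in the recovery confusion matrix, 20 random parameter
sets for the oracle equivalence) are the package's desk-scale defaults;
the recovery study uses deliberately well-separated ("strong") generating
parameters — e.g. SI with w₂ ≪ w₃, adaptive gain with a steep transducer
— because the question there is whether the comparison machinery can
discriminate the models at all, not how confusable weakly-identified
cohorts are.

## Known limitations

* No collapsing bounds, leak, multiplicative noise, or trial-to-trial
  drift variability in the race models; no losses in the utility models.
* Censored (non-response) trials are excluded from likelihoods rather
  than modelled by a truncation term, which slightly biases bound
  estimates for slow agents; recovery correlations remain high at the
  study's deadline.
* Static fits operate on per-condition proportions, so they cannot
  capture within-condition sequential effects.
* The rmANOVA is the closed-form 2×2 case only; larger designs would need
  a general mixed-model route.
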