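# Methods

## Overview

The package implements a five-stage modelling chain for lung-cancer risk
transfer in longitudinal survey cohorts: (1) synthetic cohort generation
with known risk dynamics, (2) harmonization of two survey coding dialects
and preprocessing, (3) neural weight-score risk stratification, (4)
estimation of a risk-transfer Markov decision process and deep Q-learning
of an intervention policy, and (5) pathway, incidence and survival
evaluation. Real HRS/CHARLS extracts are access-controlled; all empirical
claims made by the test suite therefore concern simulated cohorts whose
generating process is known exactly, which is what makes parameter-recovery
and oracle-equivalence checks possible at all.

## Synthetic cohorts

Each subject carries a latent risk state in {high, medium, low, non-risk}
that evolves once per follow-up cycle (default 2 years, baseline 1992)
according to a per-action 5×5 row-stochastic matrix over the four ladder
states plus an absorbing lung-cancer state. A per-state hazard h_s adds an
extra per-cycle lung-cancer probability on top of the matrix column; the
effective row is (1 − h_s)·P[a][s] + h_s·e_lc. Default hazards (0.0106,
0.0067, 0.0033, 0.0003 per cycle for high→non) put per-cycle incidence on
the order of 10³ per 100,000 in the high stratum, matching the scale of
reported per-100,000 incidences in this population. Death is modelled as
censoring-with-flag (per-state per-cycle probabilities, elevated after
diagnosis), not as a sixth MDP state: the decision process optimises risk
transfer before occurrence, while mortality only enters the survival
analyses.

Covariates are drawn each wave from state-conditional distributions.
Smoking intensity and lung-disease prevalence are constrained to be
monotone in the latent state, so covariates carry recoverable signal; BMI,
activity, drinking, prevention behaviour and cancer history are also
state-dependent. Demographics (birth year, sex, marital status, education)
are person-level and state-independent. The generator's behaviour policy —
which transfer action each subject "takes" between waves — defaults to risk
maintenance and is configurable (uniform random, or a callable), since
observational data do not identify a single data-generating behaviour.

Two emission dialects mimic the naming conventions of the two surveys:
HRS-like tables code education in years (RAEDYRS) and include the
cholesterol-prevention column (R1CHOLST); CHARLS-like tables code education
as categories (RAEDUC_C, with "no formal education illiterate" anchoring 0
years) and omit the prevention column. Missingness is injected
missing-completely-at-random over covariate cells only; identifiers, event
flags and the hidden state are never masked. MCAR is a simplification — the
package makes no claim about informative nonresponse.

What the generator does **not** emulate: survey weights, demographic
calibration to the US/China populations, panel attrition correlated with
health, measurement error in self-reports, or item-level nonresponse
mechanisms. Passing tests therefore demonstrate correctness of the
estimators under the stated dynamics, not real-world transportability.

## Preprocessing

Cessation duration is derived from the smoking-ever/smoking-now pair: a
person last observed smoking at wave w and not smoking at wave w′ has
duration (w′ − w)·interval years, discretized into half-open brackets
[0,1) → "<1 month", [1,3) → "1 year", [3,5) → "3 years", [5,∞) → ">5
years"; ever-smokers never observed smoking are treated as having quit one
interval before baseline. Rows reporting current smoking without ever
smoking are repaired to smoke_ever=true with a warning.

The feature encoding is fixed at 56 columns: a 27-column wave block (age,
BMI, education years, sex, 7 marital levels, smoking ever/now, 4 frequency
levels, 5 cessation levels, activity, drinking, prevention, cancer history,
lung disease), the same block lagged one wave (first waves reuse their own
values), plus the wave index and a normalized calendar year. The lag block
reflects the wave-matching of consecutive follow-ups; a column structurally
absent from a dialect (prevention in CHARLS-like data) becomes a constant
zero channel, distinct from item nonresponse.

Imputation initializes missing cells at column means and iteratively
re-predicts each incomplete column by linear regression on the others
(defaults max_iter=10, tol=1e-3), never altering observed cells; an
all-missing column is an error. SVD denoising replaces the standardized
feature block by its best rank-r approximation, with r chosen to retain 95%
of squared singular-value mass by default. SMOTE oversamples each minority
class to the majority count by convex combinations of a minority row and
one of its k=5 nearest minority neighbours, and is applied to the training
split only; synthetic rows are tagged so they can never cross a split.
Splits are person-level (all waves of a person on one side), 70/30 by
default.

## Risk stratification

The weight-score network is 56–22–22–22–1 with rectifier activations.
Nested rectifiers are unbounded, so the single output node applies a
logistic squash to place the score on [0,1], where the thresholds are
defined; for 1992 the cuts are 0.2 / 0.5 / 0.71 / 0.93 with half-open
intervals closed at the top and scores above 0.93 clamped into high risk.
Later follow-up years default to the 1992 cuts unless a year table is
supplied. Training is mini-batch SGD on cross-entropy (learning rate 0.01,
batch 32, 30 epochs, seed 42), with inputs standardized by training
moments.

The training target is deliberately configurable, because a weight score
has no single operational definition: `target="event"` uses binary
cross-entropy against the lung-cancer outcome; `target="ordinal"` regresses
the score onto soft targets at the stratum-interval midpoints (0.82, 0.605,
0.35, 0.10 for high→non) and is the mode used when a ground-truth ordinal
state exists, i.e. on synthetic cohorts, so that thresholding the score is
consistent with the label that generated the data. Calibration reports the
Brier score and log loss (probabilities clipped at 1e-15) with equal-width
reliability bins.

On the "separable" preset (sticky states, strongly state-separated
covariates — the regime standing in for well-separated real-data strata),
held-out four-level stratification accuracy against the hidden state is
≈0.87–0.88; the preset's independent classification ceiling (a gradient
boosting classifier on the same features) is ≈0.94, the gap being the cost
of compressing four classes through one scalar score.

## Risk-transfer MDP and deep Q-learning

Observed wave pairs are labelled with actions by a fixed rule: a frequency
drop (everyday→someday, someday→quit, everyday→quit) wins over a
cessation-bucket increase (→1y, →3y, →>5y); anything else is maintenance.
Transition rows per (state, action) are additively smoothed ML frequencies
(pseudo-count 0.5 by default); unobserved cells default to self-transition
with a warning. Rewards order the three transfer directions (+1 per level
improved, 0 maintenance, −1 per level deteriorated, −10 for lung-cancer
occurrence, configurable with per-triple overrides; the lung-cancer entry
must stay strictly smallest). One shared transition model serves four
initial-state-restricted environment views, one per risk group; the episode
horizon defaults to 14 cycles (28 years of follow-up).

The Q-network's tested default is the flat mode: the one-hot state encoding
feeding a small feed-forward stack. With no hidden layer this
parameterization is exactly tabular and is used wherever precise
convergence matters (the oracle comparisons and the analysis pipeline); a
hidden layer and a 32×32 convolutional mode (three stages with 5×5, 4×4,
3×3 kernels over a tiled state image) are provided for architectural
fidelity, though a CNN over a tiled one-hot tabular state adds no
information. Training is plain SGD on the squared temporal-difference
error with uniform replay sampling (capacity 10,000), an ε-greedy policy
decaying 1.0→0.05 over the first 60% of episodes, and a target network
copied every 100 gradient steps (50 in the tabular configuration). An
optional linearly decaying step size (0.15→0.01 in the tabular
configuration) implements the classical stochastic-approximation schedule
and markedly tightens final Q estimates. Divergent (non-finite) TD loss
aborts with a diagnostic.

Correctness is checked against exact value iteration (successive
approximation to tolerance, ties broken by action order): across 20 random
finite MDPs (5 states, 2–6 actions) the greedy DQN policy matches the
optimal policy on ≥18, with small Q-gaps where it matches. On the
risk-transfer environment itself the top improvement actions are often
near-tied in value (margins down to ~0.01 on a value scale of ~1); the DQN
then returns one of the near-optimal actions, whose simulated transfer
effect is indistinguishable from the optimum, while the *printed* optimal
pathway is taken from the exact solver on the estimated MDP. The
most-probable-successor walk that turns a policy into a pathway breaks ties
toward lower risk, stops at non-risk, lung-cancer, a stationary state or
the cycle budget, and keeps the longest direction-consistent prefix.

## Evaluation

The pathway catalog contains exactly 20 pathways: 6 improvement (the
stepwise chains to non-risk, the direct jumps, and the one-skip chain
high→low→non), 10 deterioration (the mirror chains toward high risk with
the one-skip chain non→medium→high, plus the four single-step drops into
lung-cancer occurrence) and 4 maintenance singletons. The catalog is a
fixed taxonomy, not an exhaustive enumeration of monotone sequences —
chains such as high→medium→non are deliberately absent.

Incidence decline is 100·(before − after)/before on per-100,000 rates,
reported to 2 decimals. Trend simulation rolls a policy forward: each cycle
a subject first draws a lung-cancer event from its current state's hazard,
then moves along the ladder by the policy action's transition row
renormalized over the four ladder states; cumulative events convert to
per-100,000 rates with the starting cohort as denominator (person-cycles at
pathway start). Under a maintenance policy with identity rows this equals
the closed form 1 − (1 − h)^cycles, which the tests verify within three
Monte-Carlo standard errors at n = 50,000. Both the per-cycle cumulative
trajectory and the final cumulative incidence are reported, since a single
"incidence after transfer" number is ambiguous between the two.

Survival uses the hand-rolled product-limit estimator (S(t) = ∏(1 −
d_i/n_i), right-censoring leaves the risk set after the censoring time),
cross-checked against lifelines to 1e-10 on random data. Endpoints: time to
first lung-cancer event, overall survival, and death with a lung-cancer
event, all from the first observed wave. Baseline tables report level
counts and percentages to 2 decimals with missing as its own level and
declared-but-empty categorical levels as 0 (0.00); ages bin as ≤45, 45–65,
>65 and education as 0–3 … ≥17 years.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script are chosen for
precision per CPU-second: 20,000 subjects × 8 waves for transition
recovery (≥5,000 transitions per (state, action) cell, max-abs error
≈0.01), 3,000 subjects × 6 waves for the separable stratification check,
50,000 subjects for trend closed-form checks, 500-episode DQN runs. All
randomness flows through explicit integer seeds (numpy Generator);
identical seeds reproduce byte-identical emitted tables, masks, splits,
network parameters and rollouts. Tolerances: row-stochasticity 1e-12,
value-iteration 1e-8 to 1e-10, SVD identity 1e-8, binomial checks at three
standard errors.

## Known limitations

The MCAR missingness, state-conditional-but-iid covariate draws and
configurable behaviour policy are simplifications of real panel data; the
reward scale is a design choice (only its ordering is principled); the
weight-score training target is an assumption isolated behind
configuration; accuracy/AUROC of next-state prediction depend on the
chosen operational definition (most-probable next state under the observed
action, one-vs-rest areas over next-state probability vectors); and
real-data performance figures for these surveys are not reproducible here
by construction.
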