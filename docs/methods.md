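# Methods

`chotwin` implements a hybrid digital twin for fed-batch CHO cell culture.
Five modeling layers are combined: Bayesian estimation of specific metabolic
rates from concentration time series, a recurrent neural growth-rate
predictor, kinetic ODE models of the cell population and of five core
("FLEX") metabolites, stepwise reduction of a constraint-based metabolic
network, and a PCA-constrained dynamic flux balance analysis (PC-dFBA) that
predicts the remaining exchange fluxes. A forward simulator couples the
layers so that a complete culture trajectory — viable cell density (VCD),
product titer and extracellular metabolite concentrations — is predicted
from the initial state and the feed schedule alone.

## Units and conventions

* Time is in **days** throughout. The canonical kinetic parameter set is
  kept verbatim, but its rate constants are interpreted per day: read per
  hour, the same magnitudes imply a baseline death rate of 0.43/d and a
  glucose maintenance demand roughly forty-fold above physiological uptake,
  under which a 14-day fed-batch cannot exist. Read per day they are
  physiologic (maintenance ≈ 0.9 g per 10⁹ cells per day, baseline death
  ≈ 0.018/d), and the growth-rate truncation threshold is itself quoted in
  d⁻¹.
* Specific rates are in g per 10⁹ cells per day, signed with **production
  positive**; with VCD in 10⁶ cells/ml the concentration derivative is
  numerically `rate × VCD` in g/(l·d). The same sign convention is shared by
  the exchange fluxes of the flux-balance layer.
* Concentrations recorded at an event time are **post-event** (samples are
  drawn after feeding); queries at an event time return post-event values.

## Synthetic study conditions

No public dataset accompanies the problem, so a generator emulates the
structure of the target campaign: 23 fed-batch cultures in 8 media groups,
inoculated at 0.3 × 10⁶ cells/ml, sampled daily over 14 days, with two
nutrient feeds (FMA + FMB) bolused daily from day 3 and a 400 g/l glucose
stock (FMG) from day 5 keeping glucose above a 5 g/l floor. Latent dynamics
are the package's own kinetic equations driven by a four-sigmoid effective
growth profile (exponential phase ≈ 0.75/d, main decline near day 5, late
decline near day 9.5), perturbed per media group (±8% amplitude, ±0.8 d
shift of the main decline). Measurement noise is multiplicative lognormal
with unit mean; the assay coefficient of variation defaults to 5% (a choice;
no value is stated for the real assays).

Design choices worth knowing:

* **Glucose feeding is predictive.** With the canonical parameters, daily
  glucose consumption at peak VCD exceeds the 5 g/l floor, so a literal
  "feed when below floor" rule checked daily necessarily produces an
  intra-day zero crossing. The generator therefore feeds whenever the
  projected next-day glucose (current level minus the growth-scaled previous
  day's consumption) would fall below the floor, restoring to the floor plus
  max(8 g/l, 1.2 × projected demand). Basal glucose (15 g/l) and feed
  glucose contents (60/40 g/l in FMA/FMB) are chosen so the culture survives
  until the day-5 FMG start in the fastest-growing groups.
* **Glutamine starts at 3 g/l**, above its half-saturation constant, so the
  uptake kinetics traverse both the saturated and sub-saturated regimes.
  At sub-saturation only the ratio `vGln_max/KGln²` is identifiable; the
  recovery targets require the parameters separately.
* **Amino acids outside the FLEX panel** are consumed linearly in the
  effective growth rate with group-specific loading vectors plus batch-level
  latent factor scores (±15% on the growth-linked loading, ±30% on
  maintenance), giving the group-matched window-PCA a known within-group
  low-rank structure to recover. A smooth `tanh` depletion guard
  (half-saturation 0.1 g/l) keeps all concentrations non-negative.
* Feed volumes within a group are scaled per batch by uniform factors in
  [0.7, 1.3]; compositions are shared within a group.

What the generator does **not** emulate: pH/DO control, osmolality,
temperature shifts, assay dropout, cell-cycle structure, and any metabolic
regulation beyond the kinetic rate laws. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
generating model, not predictive skill on real cultures.

## Rate estimation

Raw concentration series are first corrected for feeding/sampling events:
each bolus produces an instantaneous mixing jump, which is removed
additively so the pseudo-concentration series is continuous and its
derivative reflects cellular exchange only. The transformation is exactly
invertible given the event log. Each event correction is an affine function
of the measured value at the event time, so assay noise accumulates along
the correction chain; the propagated per-point standard deviation is carried
with the series.

Pseudo-concentrations are fitted with sums of 1–3 logistic basis functions
under a **known heteroscedastic noise model** (the propagated assay sd).
With ten parameters on ~15 points, estimating the noise scale from residuals
collapses the posterior; referencing it to the assay noise keeps posterior
widths honest. Model size is selected by Laplace-approximated log evidence
(a larger model must gain > 1 nat). Posterior ensembles are drawn with an
affine-invariant ensemble MCMC sampler (3000 steps, half discarded; chain
length set from autocorrelation diagnostics, τ ≈ 500 steps); a fast Laplace
backend is available behind the same interface.

Two deliberate choices:

* **Uncertainty ensembles come from the richest fitted model** (selection is
  still reported). Daily sampling aliases within-day rate structure; a small
  selected model's posterior understates between-sample derivative
  ambiguity, and its 90% bands cover the generating truth at only ~60% of
  time points. The largest model's posterior contains every simpler fit
  compatible with the noise and restores calibration (measured ≈ 0.8
  coverage at inter-sample midpoints over the full analyte panel).
* Specific rates **at** feed times are left/right-limit ambiguous (fed
  metabolites' own uptake rates jump with the bolus), so calibration is
  assessed at inter-sample midpoints.

Growth rates come from the same machinery applied to the log of the
volume-corrected VCD series; the derivative of each posterior draw is a net
growth-rate trajectory.

## Kinetic models and identification

The population model tracks viable, dead and lysed cells plus the
cumulative "biomaterial" variable (the time integral of VCD, a proxy for
accumulated inhibitory by-products). Death and lysis rates are base rates
plus linear toxicity terms in biomaterial and lysed cells respectively. The
effective (biosynthetic) growth rate is the net rate plus death and lysis
rates, floored at 10⁻⁶/d. Cell pools are diluted by feed boluses.

The FLEX model covers glucose, lactate, glutamine, glutamate and ammonium:
`tanh`-of-squared-reduced-concentration saturation, cubic lactate inhibition
of glucose uptake, overflow lactate metabolism (production only above the
oxidative capacity, reuptake only below it — the two branches are mutually
exclusive), and maintenance terms. Lactate and ammonium carry no feed source
term (washout only). Cell balances use a negative dilution sign — feeding
dilutes cell density — and ammonium washes out like lactate.

Identification is Nelder–Mead on log-parameters (positivity by construction)
with five-fold multi-start and successive restarts, on per-metabolite
standardized squared error. The fitting path uses a JIT-compiled fixed-step
RK4 with precomputed imposed profiles and affine bolus maps (equivalence
with the generic event-driven integrator is asserted to 10⁻¹⁰); one
objective evaluation costs ~0.3 ms per batch, so a full 15-parameter
identification takes ~25 s. The dead/lysed comparability constraint is a
soft penalty `λ·max(0, |log(Xl/Xd)| − log 3)²` (λ = 10): the lysed pool is
unobservable and only this penalty keeps it in a plausible range, so the
base lysis parameters are *not* identified — by design. Practically
identifiable and recovered within 5% from ±30% perturbed starts on
noise-free cohorts: `mGlc`, `vOx_max`, `vGln_max`, `KGln`, yields, and
`kd`/`kTd` on the population side. Confounded under any realistic operating
regime: `YG/KG` (sub-saturation), `KI` (lactate never approaches it),
`KLac` (half-saturation ≈ 53 g/l versus physiological lactate of a few
g/l), `YGlu/KGlu` (their joint contribution is ~10⁻⁷ of the glutamate
rate).

## Growth network

The VCD predictor is a shared 4-sigmoid baseline (least-squares fit of the
pooled mean growth rate) plus a dense deviation network: widths 64, 64, 64,
16, 8, 1 with GeLU, layer normalization and dropout (0.1). Features per time
step are `2k + 3` for `k` metabolites: specific rates, concentrations, the
previous growth rate, the previous biomaterial value, and the time step
(45 at the standard 21-metabolite panel, which excludes glucose, lactate
and ammonium). The biomaterial recurrence serves as the temporal coordinate
— no absolute timestamps — which is what permits generalization across
sampling frequencies. Constant training features (e.g. a fixed sampling
step) pass through standardization unscaled, and standardized inputs are
clamped at ±4 sd: closed-loop simulation can drift outside the training
envelope where an unclamped dense net extrapolates arbitrarily.

The composite loss combines a trajectory- and time-weighted MSE, a
mean-matching term, and an integrated |second-derivative| smoothness
penalty. As an equally-weighted sum the two regularizers dominate — their
gradients are scale-free, and the global optimum degenerates to a flat
trajectory — so training uses weights of 0.01 on both (the values at which
the data-fit term governs while the regularizers still measurably help).
Trajectory weights are inverse distances of each trajectory's mean growth
from the ensemble mean, regularized by half the standard deviation of those
means: a near-zero regularizer would hand ~half the total weight to
whichever single trajectory happens to sit closest to the mean. During
training the previous-growth feature is teacher-forced but randomly replaced
by the baseline value (probability 0.5): the lagged target is such a strong
shortcut that without this the network ignores the metabolic features and
its deviations collapse at self-fed inference.

Training is batch-wise sequential (one optimizer step per bioreactor batch
per epoch, random order) with Adam at 10⁻³, 250 epochs by default,
trajectories capped at 200 and time points at 32, and a batch-level
train/validation split. Measured on the synthetic cohort, the network
reduces held-out growth-rate RMSE to ~0.6× the baseline-only error pooled
over validation batches; batches whose group deviation sits at the ensemble
noise floor see no improvement (there is nothing left to predict).

## Network reduction

Four stages, with dead-end/blocked cleanup to a fixpoint after each:
(a) demand reactions added greedily (smallest bound magnitude first) until
the rate-constrained model is feasible; (b) unmeasured exchanges retained
only if closing them breaks feasibility; (c) reactions with parsimonious-FBA
flux below 10⁻⁹ under *all* conditions removed one at a time, each removal
verified to preserve feasibility and the biomass optimum within 10⁻⁶
relative; (d) internal cycles able to carry flux with all boundary reactions
closed broken by removing the lexicographically smallest member that
preserves the optimum, falling back to directionality restriction. Pinned
reactions are reinstated from the source model with prescribed bounds
regardless of pruning. All standard analyses (FBA, pFBA, FVA, SBML I/O) are
delegated to COBRApy.

## PC-dFBA

Empirical constraints come from media-group-matched PCA of exchange-rate
trajectories in 0.5-day windows (retaining the smallest number of components
reaching 90% cumulative variance, capped at 5). Small per-component neural
regressors (scikit-learn MLPs behind standardizing scalers fitted on
training data only) map the instantaneous exchange-rate vector to the
loading vectors, replacing static windowed PCA at run time; missing
components are zero-filled to a fixed output dimensionality. Direct,
leave-one-media-group-out and leave-one-batch-out validation schemes are
provided.

Each 0.1-day step solves a linear program over fluxes and PCA scores:
biomass is maximized and the L1 norm of the scores penalized, subject to
mass balance, reaction bounds, hard bounds pinning the growth + FLEX subset
to the supplied rates, a robust band `med ± RF·iqr` (RF = 1.5 by default)
linking measured exchange fluxes to their PCA reconstruction, and a score
box (training-score range ±20% by default in the pipeline wrappers). The
band statistics are medians/IQRs over two culture phases split at day 3; the
IQR is floored at 5% of the median magnitude because a rate that is
near-identical across training batches would otherwise produce a zero-width
equality band no pinned measurement can satisfy. In the semi-mechanistic
validation mode the statistics come from the simulated batch's own rate
ensembles; in fully predictive mode from the training cohort.

Temporal continuity is lexicographic: stage one solves the hybrid LP
(HiGHS); stage two fixes the stage-one objective within 10⁻⁶ relative and
minimizes the squared flux change from the previous step (SLSQP on the
fixed-optimum polytope; an L1 mode solved as a pure LP is available). The
first step has no continuity stage. Infeasibility escalates strictly:
hard bounds relax from pinned means to the 5th–95th posterior percentiles;
if still infeasible the band becomes elastic with an exact penalty (weight
10³) and the violation is minimized and reported per step — near phase
boundaries the pinned rates can sit outside the phase-pooled band in
directions the predicted loadings do not span. A PC-dFVA diagnostic reports
per-exchange flux ranges at the fixed optimum.

State updates use midpoint-sampled hard-bound rates, a midpoint VCD factor
and an exponential VCD update, making the advance second-order in the step
size (halving the step changes terminal concentrations by well under 2% on
the toy problem); free exchanges keep their piecewise-constant LP flux, the
dFBA convention.

## Twin integration

Per step: the growth network predicts the net growth rate from the previous
step's predicted rates and concentrations (one-step lag breaks the layer
simultaneity; before the first step, rate features fall back to the training
median at day 0 — prior knowledge, not a measurement); the kinetic layer
supplies death/lysis rates, the effective growth rate and the five FLEX
rates; PC-dFBA pins those as hard bounds and predicts the free exchanges and
titer; the bioreactor mass balance advances all concentrations, the
population recurrences advance the cell pools, and bolus feeds apply
instantaneous mixing (diluting cells and biomaterial too). Nothing measured
after time zero is read. Concentrations are floored at zero with events
logged.

Measured behavior on the synthetic cohort (six batches, two groups, one
held out): terminal VCD within 6–34% of the latent truth for batches of the
well-learned media group, but ~85% for the group whose growth deviation the
network under-corrects — the concentration→growth feedback loop amplifies a
persistent growth-rate bias exponentially. This mirrors the known
reinforcement-loop sensitivity of fully predictive operation; the end-to-end
sanity test pins one representative leave-one-batch-out configuration.

## Problem sizes used in tests and the acceptance script

Cohorts of 4–8 batches in 2 media groups, 14-day horizon, daily sampling;
toy metabolic networks of ≤ 30 reactions (8 exchanges, extendable to a
25-exchange variant for the partition counts); kinetic recovery from 3
batches; growth-network training with 30-trajectory ensembles for 80–150
epochs. These sizes keep every result reproducible on a single CPU in
minutes while exercising the full pipeline.

## Known limitations

* Lactate re-accumulation beyond the overflow switch is not modeled.
* Free-exchange tracking in fully predictive mode is only as good as the
  band statistics plus the loading-mediated score channel; analytes whose
  within-group variance is weakly coupled to the pinned rates revert toward
  the phase medians.
* The elastic band stage trades constraint satisfaction for solvability and
  must be monitored through the reported violations.
* Posterior rate calibration is assessed against the package's own
  generator; real assay error structure (drift, analyte-specific CVs) is
  not represented.
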