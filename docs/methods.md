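# Methods

`narsense` models the dynamic response of a whole-cell naringenin biosensor
— an *E. coli* circuit in which the LysR-family activator FdeR, induced at a
saturating 400 µM reference ligand concentration, drives a GFP reporter —
across a categorical space of contexts: growth medium (M0–M3), carbon
supplement (S0–S3), the promoter driving FdeR (P1–P4) and its ribosome
binding site (R1–R5), 320 combinations in all. Around that mechanistic core
the package implements a Design–Build–Test–Learn loop: D-optimal selection
of which contexts to measure, weighted least-squares calibration with
bootstrap-bagged ensembles, machine-learning surrogates that map encoded
contexts to mechanistic parameters, and rank-based selection of designs for
high gain or fast response.

## The mechanistic model

**Growth.** Cell density follows a double logistic,

    N(t) = L1 / (1 + exp(-a1 (t - t1))) + k1 / (1 + exp(-(k1 a1)(t - k2 t1))),

with context-dependent asymptote `L1` (OD units), rate `a1` (1/h) and
midpoint `t1` (h), and globally shared second-wave coefficients `k1` (OD
units; note it also scales the second wave's rate) and `k2`
(dimensionless). The dilution rate µ(t) = (1/N) dN/dt is evaluated
analytically and dilutes every intracellular species.

**Sensing cascade.** Three states — FdeR transcript `mRNA`, FdeR protein
`FDER`, and the normalized reporter `GFP/OD`:

    d(mRNA)/dt   = vmax_PROM · K_Pk · K_mRNAp,Mi − µ·mRNA − k_deg·K_mRNAdeg,Mi·mRNA
    d(FDER)/dt   = k_FDER · R · RBS · mRNA/(mRNA + K_NFDER) − k_deg,FDER·K_lysis,Mi·FDER − µ·FDER
    d(GFP/OD)/dt = vmax_NAR · K_P,Mi · R · FDER²/(FDER² + 0.5²) − k_deg,GFP·K_lysis,Mi·(GFP/OD) − µ·(GFP/OD)

Parameter scopes: `K_Pk` per promoter; `K_mRNAp`, `K_mRNAdeg`, `K_P`,
`K_lysis` per medium; the RBS translation strength per full context; all
other constants global. The Hill half-saturation (0.5) and exponent (2) are
fixed, not estimated — no FdeR concentration data exist to identify them.
Ribosome availability is R = A·(1−R_basal) + (1−A)·R_basal + A·R_basal
(algebraically A + R_basal(1−A)). The coupling coefficient A is not pinned
down by the biology beyond "adjusts with growth"; the package's default is
A(t) = µ(t)/max_horizon µ(t), clipped to [0,1] — ribosomes are most
available at peak growth — and `simulate` accepts a custom profile.
Induction is fixed at the saturating reference dose, folded into
`vmax_NAR`; dose–response behavior is out of scope.

**Numerics.** LSODA with rtol 1e-8 / atol 1e-10 (1e-6/1e-9 inside
calibration loops), states clamped at zero inside the right-hand side and
clipped on output; the default grid is 10-min sampling over 16 h (97
points). Against a fixed-step RK4 reference at 1000× finer resolution the
adaptive solution agrees to ~1e-9 relative; the test suite enforces 1e-5
over 20 random parameter sets. Response features: *gain* is the horizon
maximum of GFP/OD (screens summarize wells by their peak), *half-time* is
the first linearly interpolated crossing of 50% of that maximum, reported
in seconds (conventionally printed as s×10³); if the first sample already
exceeds half-maximum the first grid time is returned.

## Calibration

The fit minimizes Σ_t,outputs w_t (y_m − y(k))² — a plain sum over the
sampling grid, since the measurements are the grid — with the replicate
mean as y_m and diagonal inverse-variance weights 1/max(s_t², floor),
floor = (1e-3 × range)². With only three replicates the raw s_t² is
χ²₂-distributed and its inverse is heavy-tailed, which measurably biases
growth-rate estimates; `fit_growth` therefore stabilizes the variances with
a 7-sample (~1 h) rolling mean before inversion. Rates are searched on a
log10 scale inside [1e-4, 1e3] boxes. `calibrate` runs a budget-capped
population global stage (differential evolution) followed by a
trust-region least-squares polish; any population global stage plus local
polish is acceptable here, and the known-truth test (final cost ≤ cost at
the generating parameters + 1e-6 on noise-free data) is the conformance
oracle. Everything is deterministic per seed.

`fit_growth` is multistart local least squares (20 seeded starts around a
data-informed anchor). A weak ridge on `k1` (1e-4 × median weight)
resolves a genuine non-identifiability: when the optimizer pushes the
second wave's midpoint `k2·t1` beyond the assay window the wave contributes
nothing on-support and any `k1` fits equally well; the ridge collapses that
degeneracy onto the nested single-logistic model.

For a single context only products of parameters are identifiable (e.g.
vmax_PROM·K_Pk·K_mRNAp), so the standard per-context problem estimates one
representative factor per product (`K_mRNAp[medium]`,
`RBS_strength[context]`, `k_deg_FDER`, `vmax_NAR`, `k_deg_GFP`,
`K_NFDER`); rank order across contexts, not absolute values, is what the
pipeline relies on downstream.

**Bagging.** Bootstrap realizations resample replicate values per time
point, uniformly with replacement, keeping OD and GFP/OD paired by
replicate slot (the two outputs are co-measured in one well). Each of the
(default 300; desk profile 50) iterations re-estimates weights and refits
locally from the full-data optimum — a warm-started polish rather than a
fresh global search, which keeps a 50-member ensemble near two minutes of
compute. Members that fail are dropped and logged; more than 20% failures
aborts. The ensemble mean trajectory is the bagged predictor and is
verified to beat the median single member against ground truth.

## Experimental design

The design model is a main-effects linear response on reference-coded
one-hot factors (first level dropped per factor): 1 + 3 + 4 + 3 + 3 = 14
columns, so X'X is invertible for sensible designs and D-optimality —
maximizing det(X'X) — is well defined. The search is coordinate exchange
with Fedorov's determinant-lemma delta, vectorized over the 320-candidate
set, with seeded restarts; a small ridge (1e-8·I) inside the search lets it
climb out of singular starts, and reported log-determinants exclude it.
Augmentation runs the same exchange over the new rows only, holding
existing runs immutable; information matrices only grow, so the combined
log-det never decreases. For a main-effects categorical model the balanced
full factorial attains the continuous D-optimum, which gives an exact
optimality oracle at n = 320.

## Surrogates

**Encoding.** A context becomes an 11-vector: one quantitative promoter
value plus reference-coded one-hot blocks for RBS (4), medium (3) and
supplement (3), standardized with a scaler fitted on training contexts
only. Promoter values live in [0,1] and are learned by a small
sequential-model-based optimizer: a Gaussian-process surrogate with
expected-improvement acquisition, seeded with "anchor" points (evenly
spaced scalars assigned under random promoter orderings) because the
objective is driven almost entirely by the ordering. The objective scores
an encoding by the LOO R² of a *linear-kernel* regressor on the chosen
targets: a smooth kernel can interpolate any assignment of four scalars and
would leave the ordering unidentified, whereas a linear fit rewards
encodings aligned with the target effect. Each predictive model gets its
own promoter values: the growth surrogate's are optimized against (a1, t1),
the reporter surrogate's against the training ensembles' consensus
promoter strength — with an arbitrary promoter scalar the promoter-scoped
parameter simply does not generalize to held-out contexts.

**Growth surrogate.** One support-vector regressor per target (default a1,
t1), hyperparameters chosen per target from {linear, rbf} × C ∈
{0.1, 1, 10, 100} by inner leave-one-out MSE; the report carries LOO R² per
target. Unpredicted growth fields (L1, k1, k2) fall back to training-set
means when composing full trajectories.

**Reporter surrogate.** A feed-forward network — hidden widths 64-64-32-16,
ReLU, batch normalization and inverted dropout after each hidden layer,
Adam on mean squared error — maps the encoded context to the log of the
context-resolvable reporter parameters (K_Pk, K_mRNAp, K_mRNAdeg, K_P,
K_lysis, RBS_strength), standardized per target. Every bagging member is
one training sample, so the ensemble acts as an augmented, noise-injected
training set. Two details matter for stable held-out error: the learning
rate steps down 10× over the final fifth of training, and after training
the batch-norm running statistics are recomputed exactly on the full
training set at the final weights. Training is bitwise reproducible per
seed. Held-out contexts are scored against the per-context ensemble means.

**Scores.** R² per target is the ordinary coefficient of determination on
held-out pairs. Q² = 1 − PRESS/TSS, pooled over targets after scaling each
by its observed standard deviation. Relative RMSE is RMSE divided by the
observed range, in percent, averaged over targets.

## Selection

Candidates are ranked by predicted gain (descending) or half-time
(ascending), ties broken by context id with tie groups sharing the minimum
rank. Validation against observations uses (a) the top-k overlap — how
many predicted top-k land in the observed top-k — and (b) a one-tailed
Kendall test for positive association: tau-b with tie corrections; the
p-value comes from exact enumeration of all permutations for n ≤ 8 (ties
handled, since the tau-b denominator is permutation-invariant for fixed tie
patterns) and from the classical tie-corrected normal approximation with a
one-unit continuity correction on the S statistic for larger n (within
0.006 of exact at n = 8 tie-free; the uncorrected approximation errs by up
to 0.05). On the shipped reference ranking of top-10 high-gain constructs
the overlap is 8/10 and the one-tailed p is ≈0.054 (exact enumeration
0.0542) — rank-test conventions straddle the conventional 0.05 line on
these ten rows, so no significance claim is hard-coded anywhere.

The package also ships the analogous fast-response reference table; note
that counting its printed rank column with the overlap definition above
gives 9, an inconsistency inherited from the source table's own tie
bookkeeping.

## Synthetic data

No public dataset accompanies this biosensor design space, so the
generator is a first-class module that defines the study conditions:
3-replicate, 10-min-sampled, 16-h OD and GFP/OD curves with
heteroscedastic noise y(1+ε_p)+ε_a (defaults: proportional sd 0.05,
additive sd 0.01 of range; 0.03 proportional for fit-quality checks),
clipped at zero. Ground-truth parameters honor the scope structure exactly
— contexts sharing a medium share all medium-scoped values bitwise.
Context-scoped quantities (growth triplet, RBS strength) are built as
multiplicative factor-level effects (log-normal, sd 0.05–0.15 per factor)
plus a small log-normal jitter (sd 0.02–0.05): systematic factor effects
are the premise that makes context dependence learnable at all, and the
jitter keeps all 320 values distinct. Default ranges (e.g. L1 ~ 0.7–1.2,
a1 ~ 0.6–1.1 /h, t1 ~ 5–7 h; reporter constants spanning roughly
[0.05, 4]) were chosen once so that OD starts near 0.05, saturates within
16 h, and the reporter rises over hours — the qualitative regime of
plate-reader biosensor assays.

`synthetic_ensemble_matrix` emulates a bagged calibration ensemble directly
(truth × log-normal member noise, default sd 0.05). It exists so surrogate
experiments over 64 contexts are affordable — fully calibrating 64
contexts with bagging is hours of compute — and so surrogate tests isolate
the learning problem from calibration error. The calibration path itself is
validated separately on single-context problems.

**What passing on synthetic data does not show.** Real plate-reader data
have correlated residuals (drift, edge effects), non-Gaussian outliers,
and context effects that need not decompose additively in the log; the
generator has none of these. Recovery and Q² results here demonstrate the
pipeline's correctness and internal consistency under its stated noise
model, not its performance on any particular laboratory dataset — the
published headline figures for that setting (e.g. a reporter-surrogate Q²
of 0.91) cannot be recomputed because the underlying data were never
deposited.

## Problem sizes and profiles

Defaults mirror the two-round study layout: a 32-run D-optimal design
augmented to 64, a 48/16 train/validation split, 8 of 64 contexts held out
for the network, 300 bagging iterations. The `desk` profile (and the test
suite and acceptance script) scale bagging to 50 iterations, use 25
ensemble members per context, 5–10 exchange restarts, optimizer budgets of
~1500 evaluations and 40 encoding-search evaluations — sizes chosen so the
whole verification cycle runs on a laptop-class single core in minutes
while leaving every qualitative property intact.

## Known limitations

- Absolute kinetic constants are not identifiable from single contexts;
  only scoped products and cross-context rank structure are meaningful.
- The ribosome-coupling profile A(t) is a modeling choice, not measured.
- The network predicts only context-scoped reporter parameters; global
  constants come from calibration.
- No dose–response, plasmid copy number, or assembly-failure modeling.
- No formal identifiability or profile-likelihood analysis; bagging spread
  is the only uncertainty summary.
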