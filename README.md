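# narsense

Context-dependent modeling and model-driven design of whole-cell
naringenin biosensors.

Transcription-factor biosensors — here an *E. coli* circuit in which the
LysR-family activator FdeR, induced by the flavonoid naringenin, drives a
GFP reporter — behave very differently depending on their genetic parts
(promoter P1–P4, ribosome binding site R1–R5) and their environment
(medium M0–M3, carbon supplement S0–S3). `narsense` is a
Design–Build–Test–Learn workbench for that 320-context space, aimed at
synthetic biologists who need to pick a construct/condition combination for
a given job: maximum reporter gain for screening, or fastest response for
dynamic pathway regulation.

The pipeline couples a mechanistic ODE model with machine learning:

1. **Mechanistic core** (`model_core`) — growth is a double logistic
   N(t) = L1/(1+e^{−a1(t−t1)}) + k1/(1+e^{−k1·a1(t−k2·t1)}), whose
   per-capita rate µ = Ṅ/N dilutes all intracellular species; the sensing
   cascade is d(mRNA)/dt, d(FDER)/dt, d(GFP/OD)/dt with medium-, promoter-
   and context-scoped rate constants, ribosome availability
   R = A + R_basal(1−A), and a fixed Hill activation FDER²/(FDER²+0.5²).
2. **Optimal design** (`experimental_design`) — D-optimal (max det X'X)
   coordinate-exchange designs over a reference-coded one-hot main-effects
   model, plus augmentation with existing runs held fixed.
3. **Calibration** (`calibration`) — weighted least squares with
   heteroscedastic inverse-variance weights, global+local hybrid
   optimization on a log scale, and bootstrap bagging of replicates to
   produce parameter ensembles.
4. **Surrogates** (`surrogate`) — SVR for growth parameters and a
   4-hidden-layer network (dropout, batch norm) trained on the bagged
   ensembles for reporter parameters, over an 11-feature context encoding
   whose quantitative promoter values are learned by Bayesian optimization;
   scored by LOO/held-out R², Q² = 1 − PRESS/TSS, and range-relative RMSE.
5. **Selection** (`selection`) — rank candidates by predicted gain or
   half-time; validate with top-k overlap and a one-tailed Kendall tau-b
   test (exact permutation p for n ≤ 8, tie-corrected normal approximation
   with continuity correction above).
6. **Synthetic data** (`synthetic_data`) — seeded generator of
   ground-truth parameter sets with the correct variability scopes and
   replicated, heteroscedastic 16-h / 10-min plate-reader-style curves, so
   every stage is testable end to end without external data.

A `narsense` CLI (`workbench`) chains the stages (`doe`, `generate`,
`fit`, `bag`, `train`, `predict`, `rank`, `validate`) into reproducible,
manifest-stamped runs.

See `docs/methods.md` for the model equations, parameter scopes, numerical
choices and known limitations.

## Worked example

Simulate one context from a seeded synthetic ground truth and summarize its
response, then score the shipped reference ranking of top-10 high-gain
constructs (predicted vs experimentally observed relative gains):

```python
import narsense as ns

gt = ns.draw_ground_truth(seed=7)
ctx = ns.ContextKey("M0", "S2", "P3", "R4")
traj = ns.simulate(ctx, gt.growth[ctx], gt.kinetics)
print(f"OD range         : {traj.od[0]:.3f} -> {traj.od[-1]:.3f}")
print(f"gain (max GFP/OD): {ns.steady_state_gain(traj):.3f}")
print(f"half-time        : {ns.half_time(traj)/1e3:.2f} x 10^3 s")

from narsense.io import load_reference_ranking
from narsense.selection import top_k_overlap, kendall_one_tailed
ref = load_reference_ranking("high_gain")
tau, p = kendall_one_tailed(ref["predicted_value"], ref["observed_value"])
print(f"top-10 overlap   : {top_k_overlap(ref, k=10)}/10")
print(f"Kendall tau-b    : {tau:.3f}  (one-tailed p = {p:.3f})")
```

which prints:

```
OD range         : 0.065 -> 0.923
gain (max GFP/OD): 21.965
half-time        : 29.84 x 10^3 s
top-10 overlap   : 8/10
Kendall tau-b    : 0.422  (one-tailed p = 0.054)
```

The cells grow from OD 0.065 to 0.92 over the 16-h assay; the reporter
peaks at ≈22 fluorescence/OD units and crosses half of that peak after
≈8.3 h (29.8×10³ s). On the reference ranking, 8 of the 10
predicted-best high-gain constructs fall in the observed top 10, with a
positive rank correlation (tau-b 0.42).

Or from the shell:

```bash
narsense doe      --outdir runs/demo --seed 1
narsense generate --outdir runs/demo --seed 1
narsense fit      --outdir runs/demo --seed 1
narsense validate --outdir runs/demo --seed 1   # scores the reference ranking
```

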