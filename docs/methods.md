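# Methods

## Synthetic cohort

The generator stands in for MRI-derived data that cannot be shipped. It
reproduces the study's demographic table exactly: eight age bands from 14 to
89 years with fixed male/female counts per band (totals 1157 = 607 M +
550 F), which yields the bimodal young/elderly age profile of multi-site
collections. Ages are drawn **uniformly within each band** — the simplest
distribution consistent with banded counts — and subject ids are sequential
(`SYN-000001`, ...), so a (spec, seed) pair is bit-reproducible.

Each of the 34 volumes follows a linear-Gaussian model

    v = baseline + slope · (age − 50) + sex_offset · 1[M] + N(0, sd)   [mm³]

centred at age 50 for numerical conditioning. Signs follow the aging
literature (ventricles, CSF and choroid plexus expand; cortical, subcortical
and white-matter volumes shrink; male volumes larger), and baselines are
order-of-magnitude anatomical values. The noise scale is the one genuinely
free choice: the default sd is 2.5× the volume change accrued over one
cohort age-sd (≈19 years), which puts the best achievable pooled age R² near
0.85 and realised model R² in the 0.8 range, with sex offsets at 0.3·sd
giving a Bayes accuracy near 0.8 — the performance regime of published
morphometry-based models. `default_effects(noise_scale=0.25)` is the
strong-signal variant used for the scaled-down convergence studies.

What the generator does **not** emulate: anatomical covariance between
structures (features are conditionally independent given age and sex),
non-linear aging trajectories, site/scanner effects, and physiological
positivity — small CSF spaces can produce negative draws in the far tails.
Passing tests therefore demonstrate that the pipeline recovers planted
age/sex signal of realistic strength, not that it reproduces metric values
attainable only on the real MRI cohorts.

## Preprocessing

Min-max scaling to [0, 1] per feature, then PCA to k components (default
17), both fitted on the training partition only; test rows are clipped to
[0, 1] after scaling so the downstream angle encoding stays in its designed
domain (re-scaling was the alternative; clipping was chosen because it
leaves training data untouched). PCA component signs are normalised so the
largest-magnitude loading is positive, making serialisation reproducible.

The 80/20 split takes floors independently: |train| = ⌊0.8N⌋,
|test| = ⌊0.2N⌋, dropping up to four remainder subjects — the only rounding
rule consistent with both the 925/231 partition and the learning-curve sizes
⌊f·N⌋ ∈ {57, 115, 231, 462, 694, 925} at N = 1157. Learning-curve
subsamples are drawn without replacement from the training ids and are not
nested across fractions. In the sweep harness the preprocessing is refitted
on each training subsample, the no-leakage reading of the protocol.

## Quantum simulation

States are complex double-precision vectors of length 2ⁿ, big-endian
(qubit 0 = leftmost bit, so CNOT truth tables read |control, target⟩).
Single-qubit rotations use the standard half-angle conventions
(RX/RY/RZ = exp(−iθP/2)) and are applied by axis-wise contraction, O(2ⁿ)
per gate — at 17 qubits (131 072 amplitudes) dense 2ⁿ×2ⁿ matrices are
infeasible, and they are retained only as the brute-force test oracle for
n ≤ 4. CNOT is a cached basis-index permutation. Gate kernels broadcast
over leading batch axes, so a mini-batch of encoded samples evolves in one
vectorised pass.

Training gradients use reverse-mode **adjoint differentiation**: one
forward pass, then a backward sweep un-applying each gate while carrying the
observable-weighted state, giving every parameter's derivative in O(#gates ·
2ⁿ) total. The parameter-shift rule — exact for rotation generators — is
deliberately kept as an independent oracle rather than the training path,
because it costs two circuit runs per parameter. Tolerance ladder: 1e-10
for norms and closed forms, 1e-9 for oracle equivalence, 1e-4 relative for
finite-difference checks (h = 1e-5, where truncation error dominates).

## The VQC learner

Angle encoding RY(π·x_q) requires inputs in [0, 1]; PCA scores are not
bounded, so the model owns a second min-max rescale of the component scores,
fitted on training scores and clipped at prediction time. Each block
applies an RX, then RY, then RZ trainable layer (one rotation per qubit)
followed by the CNOT chain q→q+1 (a ring closure is available by
configuration); the published architecture specifies the gate set, block
count and "three layers" but not the intra-block order or wiring, so this
fixed order is a design choice. All qubits are measured, summed at a single
node, and passed through a sigmoid; the node is given a trainable affine
head (w, b) initialised at (1/n_qubits, 0) — whether the published single
node was weighted is unstated, and a config flag can freeze (w, b) = (1, 0).

Regression targets are min-max encoded from training ages, so decoded
predictions always lie inside the training age range — a structural property
the classical baselines lack. Sex labels encode F → 0, M → 1; a raw output
of exactly 0.5 decodes to M. Losses are MSE (regression) and binary
cross-entropy (classification); the optimiser is ADAM with the published
learning rate 0.01 (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Batch size (32),
epoch budget (100) and early stopping (10 % validation split, patience 10)
are unstated in the source protocol and mirror the MLP baseline's
early-stopping style. Parameters start near identity, U(−0.1, 0.1), to
avoid a flat start at this depth.

## Baselines and metrics

The six regressors (LR, BR, "XGBoost", RF, SVR, MLP) and six classifiers
(LR, KNN, "XGBoost", RF, SVC, MLP) are scikit-learn estimators constructed
with the published hyperparameter lists. The published "XGBoost"
hyperparameters (`loss='squared_error'`, `criterion='friedman_mse'`) are
scikit-learn gradient-boosting parameters, so the model is implemented as a
gradient-boosting machine. Obvious typos in the printed lists are
normalised, and `BayesianRidge(n_iter=300)` maps to `max_iter=300` under
current scikit-learn. All stochastic learners are seeded even where the
printed lists say `random_state: None`, since reproducibility is a package
contract.

Metrics are computed from the standard formulas; R² uses the evaluation
set's own mean. Zero denominators in precision/recall/F1 return 0 with a
warning, and a zero-variance target makes R² NaN with a warning — both so a
model sweep never aborts; a failing model contributes an error row instead
of stopping the learning-curve harness.

## Problem sizes and determinism

The default test suite and the acceptance script run the full 1157-subject
cohort for everything classical and a scaled-down quantum configuration
(6 qubits, 3 blocks, ~300 strong-signal subjects, k = 6) for VQC training
studies; the full 17-qubit, 10-block circuit is exercised structurally and
through single forward passes. These sizes were chosen so the whole battery
completes in well under a minute of simulation per training run while still
demonstrating convergence. All randomness flows from one root seed through
a fixed per-stage counter scheme (`SeedSequence([root, stage_index])`), so
every stage is independently re-runnable and every CSV output is
byte-reproducible.

## Known limitations

- Printed headline metrics of the original MRI study depend on data that is
  not redistributable; this package demonstrates procedure, arithmetic and
  convergence on synthetic cohorts instead and makes no claim to reproduce
  those table values.
- The synthetic generator's feature independence inflates the effectiveness
  of PCA pooling relative to real, covaried anatomy.
- Exact statevector simulation scales as O(2ⁿ); 17 qubits is practical for
  forward passes but full-size training is slow on one CPU — the learning
  dynamics are therefore validated at reduced width/depth.
- No shot noise, hardware noise models or Ising ZZ entanglers (the source
  architecture explicitly replaced ZZ couplings with CNOTs).
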