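# Methods

## Model and assumptions

The package attributes two kinds of quantities to individual binary features:

1. a single Gaussian RBF kernel evaluation `K(x, x') = exp(-γ‖x-x'‖²)`
   between two binary vectors, and
2. the decision-function distance `dist(x) = b + Σₙ yₙwₙ K(x, Vₙ)` of an
   RBF-kernel SVM, plus its Platt-calibrated log-odds.

Both rest on the same observation: on 0/1 vectors each symmetric-difference
feature adds exactly 1 to the squared Euclidean distance and intersecting or
jointly-absent features add nothing, so `K = exp(-γD)` where `D` is the
symmetric-difference count. The cooperative game of one kernel evaluation
has as players the `U = I + D` features active in either vector; a coalition
`S` is worth `v(S) = exp(-γ·N_d(S))` when nonempty and `v(∅) = 0` by the
Shapley convention for the empty set. Because `v` depends only on the count
of symmetric-difference players, all intersecting features are exchangeable,
as are all symmetric-difference features: the whole attribution is two
scalars.

* Intersecting feature: adding it changes nothing unless the coalition was
  empty, where the value jumps 0 → 1. Hence
  `φ₊ = (I+D-1)!/(I+D)! = 1/(I+D)`, independent of γ.
* Symmetric-difference feature: the coalition sum groups into three terms —
  the empty coalition (jump 0 → e^{-γ}), intersecting-only coalitions
  (jump 1 → e^{-γ}), and mixed coalitions with `N_d ≥ 1`
  (jump e^{-γN_d} → e^{-γ(N_d+1)}), each weighted by the coalition-class
  multiplicity `C(I,N_i)·C(D-1,N_d)` and the Shapley permutation weight
  `(N_i+N_d)!(I+D-N_i-N_d-1)!/(I+D)!`. Cost `O(D·(I+1))`.

The SVM lift is pure linearity: `φ_f = Σₙ yₙwₙ φ_{f,n}` with the bias booked
as a feature whose Shapley value is `b` itself, so
`b + Σ_f φ_f = dist(x)` exactly. Platt scaling
`p = 1/(1+exp(A·dist+B))` has logit `-A·dist - B`, linear in the distance,
so log-odds attributions are the distance attributions scaled by `-A` around
the expected value `-(A·b + B)`. Only binary feature vectors and binary
classification are supported; integer or real-valued features would change
the per-feature distance increments and are out of scope.

## Numerical choices

* Every factorial/binomial ratio is evaluated in log space through
  `lgamma` and exponentiated per summand. Individual binomials overflow
  floats already around `I+D ≈ 200`, while each complete summand is ≤ 1;
  the log-space route keeps `log_coalition_weight` finite beyond
  `I+D = 10⁵` and the closed form accurate at fingerprint scale
  (efficiency verified at `I = 600, D = 400`).
* The mixed term loops `N_d` outer, `N_i` inner, accumulating in a plain
  float. Against exhaustive enumeration the deviation stays below 1e-10 for
  all `I+D ≤ 15` and all tested γ; efficiency identities are asserted at
  1e-8 relative, absorbing accumulation over thousands of summands in the
  SVM case.
* `(I, D, γ)` results are memoized (`lru_cache`). A model explanation
  evaluates one closed form per distinct overlap signature against the
  instance, not per support vector; this realises the per-instance
  `O(U²)·N_v` bound with a small constant. The spec'd alternative —
  explicitly grouping support vectors by signature first — would reuse
  identically; the cache was chosen as the simpler mechanism.
* The inner loops are deliberately plain Python rather than vectorized:
  at validation sizes the cost is negligible (whole suite ~2 s), and the
  measured wall-clock cost then tracks the `D·(I+1)` summand count, which
  is what the quadratic-scaling check asserts (log-log slope 2 ± 0.3 over
  union sizes 50–400).
* Degenerate pair of two all-zero vectors: the kernel value is 1 but the
  game has no players, so no attribution can sum to 1 while `v(∅) = 0`.
  The explanation returns an empty attribution with `kernel_value = 1` and a
  `degenerate` flag; the SVM explainer lists such support-vector indices in
  `degenerate_pairs` and excludes their kernel contribution from the
  efficiency identity rather than inventing an allocation.
* γ vs σ: both parameterizations are accepted (`γ = 1/(2σ²)` converted on
  construction); only γ is stored.

## Synthetic data

No external dataset is required. `generate_random_vectors` draws independent
Bernoulli bits (default density 0.3 — sparse, fingerprint-like, and at
universe 15 it produces union sizes spanning the full 0–15 range so the
enumeration comparison exercises every regime). `generate_toy_svm` builds a
structurally valid model: non-empty random support vectors, signed dual
weights with magnitudes in [0.1, 2], bias in [-1, 1], γ in [0.05, 1] and a
negative Platt slope, as fitted calibrations on a working classifier come
out. Both are reproducible per seed.

What the generators do not emulate: feature correlation (real fingerprints
have strongly correlated bits), the scale of real models (thousands of
support vectors over ~5000-bit universes), or class structure learned from
chemistry. Passing tests therefore certify the *exactness and algebraic
properties* of the attribution — efficiency, dummy, symmetry, linearity,
agreement with brute-force enumeration — not anything about the scientific
quality of explanations on a particular chemical dataset.

## Validation experiment sizes

The enumeration agreement experiment uses 20 vectors over a 15-feature
universe (190 pairs, ~1500 paired values), the largest size at which literal
coalition enumeration is comfortable; the bitmask route re-checks the
count-class enumeration subset by subset up to 15 players. Efficiency
properties are swept over ≥500 randomized (pair, model, instance) cases
across γ from 0.01 to 5.

## Platt-parameter extraction

`extract_model_spec` maps a fitted scikit-learn `SVC(kernel="rbf")` onto the
model spec: support vectors, signed dual coefficients, intercept, resolved γ,
and — when fitted with `probability=True` — the internal sigmoid parameters
as (A, B) under `p = 1/(1+exp(A·dist+B))`. The extracted spec reproduces
`decision_function` to machine precision. Note the library fits its sigmoid
on cross-validated decision values and its sign handling depends on the class
order seen at fit time, so the calibrated probability is self-consistent for
the positive decision side rather than guaranteed to match `predict_proba`
byte for byte; the log-odds decomposition only needs the (A, B) pair itself.

## Known limitations

* Binary features only; no Tanimoto or other kernels; no multiclass or
  regression SVMs.
* The exhaustive oracle refuses unions above 20 players (count-class mode)
  or 15 (bitmask mode) — it exists to validate, not to compute.
* Attributions explain the model's geometry, not causality in the underlying
  chemistry.
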