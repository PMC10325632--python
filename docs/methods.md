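# Methods

This note documents the models, estimators, numerical choices and known
limitations of `factorlens`. It is the package's own account of its science;
every number mentioned here is recomputed by the test suite or by
`scripts/acceptance.py`, not quoted from elsewhere.

## 1. Equation-learner symbolic regression

### Model

A factor matrix is flattened to (i, j, value) triplets, indices mapped
affinely to X1, X2 ∈ [−1, 1] per axis (an axis of extent 1 maps to 0). The
regression network is a stack of layers, each a linear stage
`g = W x + b` followed by a fixed bank of operator units: unary units
(identity, (·)², e^x, sin, cos, relu, log|·|) consume one linear output,
binary units (+, −, ×, ÷) consume two consecutive outputs. A final linear
read-out produces ŷ(i, j). Because each unit is an elementary mathematical
operator, a sparse trained network *is* a formula: pruning coefficients and
composing the surviving structure layer by layer yields a closed-form
expression.

All operators are total on the reals after safeguarding:

* quotient: denominator replaced by `sign(d)·max(|d|, ε)`, ε = 1e−3;
* log-abs: `log(max(|x|, ε))`, natural log;
* exp: argument clipped at 6 (e⁶ ≈ 403). The clip bounds activations through
  deep compositions; its backward pass uses the unclipped slope so saturated
  units keep a restoring gradient instead of dying.

The same safeguarded primitives are shared by the network forward pass, the
extracted-formula evaluator, and the synthetic surface generators, so
"formula equals pruned network" holds to floating tolerance by construction
and is tested to 1e−9.

An optional input feature `dy` carries the first finite difference of the
target along the row index (np.gradient convention: central differences
inside, one-sided at the edges, index-unit spacing). It is a precomputed
feature, not an in-network operator, and is off by default.

### Loss and sparsity

Training minimizes squared error plus λ times a smoothed-L1/2 penalty on
every weight and bias:

    L12*(w) = |w|^(1/2)                                   if |w| ≥ a
            = |−w⁴/(8a³) + 3w²/(4a) + 3a/8|^(1/2)         if |w| < a

with a = 0.01. The quartic branch matches the square-root norm at |w| = a
and removes the singular gradient at 0. The public `loss()` function returns
the summed squared residual (plus λ·penalty); the optimizer divides the fit
term by the sample count so that the default λ is dataset-size independent.

The penalty weight follows a phased schedule: λ = 0 for the first 25% of
epochs (structure forms before sparsification), constant λ in the middle,
and a final polish phase (last 10% of epochs) with λ = 0 in which
coefficients below the pruning threshold θ = 0.01 are frozen at zero and the
survivors are fine-tuned. The polish phase is this package's extension of
the plain warm-up-then-constant schedule; it measurably improves held-out
accuracy because the penalty's bias on surviving coefficients is removed
after the support has stabilized.

Optimization is full-batch Adam (implemented directly on numpy arrays) with
cosine learning-rate decay, global-norm gradient clipping (the early
transient of exp/square compositions is otherwise violent), and internal
target standardization whose scale is folded back into the read-out after
training. Optimization runs in float32 by default (configurable); parameters
are returned in float64. Weights initialize N(0, 0.4²/n_in) from the config
seed, with trig-unit rows scaled by a uniform factor in [0.5, 4] so that
oscillatory structure at several frequencies is reachable. Training is
bit-reproducible given the seed.

### Extraction and verification

`extract_formula` zeroes coefficients with magnitude strictly below θ
(exactly θ is retained), composes the remainder into an expression tree with
constant folding only (no aggressive rewriting), flags the degenerate
all-pruned case as a constant formula, and renders both a plain string and a
sympy expression.

Because the "accuracy" of a regression needs a convention to become a
percentage, verification accuracy is defined as the share of held-out
triplets whose prediction falls within τ·(max y − min y) of the truth,
boundary inclusive, τ = 0.05 by default. It is invariant to target scaling
and maps any fit onto a 0–100% scale.

### Surface-distillation protocol

`workflow.distill_surface` is the standard recipe: split 80/20 with a seeded
shuffle; inside the training split hold out 10% for validation; train a
two-layer network (2 restarts, 1800 epochs); if validation accuracy stays
below 97%, escalate to a three-layer network (3 restarts, 2500 epochs); the
candidate with the best validation accuracy is pruned at θ = 0.01 and scored
once on the untouched 20% test split. The distillation default λ = 3e−4
(smaller than the generic training default 1e−3) because formula recovery
benefits from biasing coefficients less once the escalation/validation
machinery already guards against overfitting.

## 2. Built-in factor surfaces

The six built-in surfaces (one per anatomical plane — coronal, sagittal,
axial — and per group — autism, control) are closed-form expressions over
the normalized grid, evaluated with the safeguarded primitives above. Their
printed sources reached this package through lossy text extraction
(superscripts and fraction bars collapse), so the implemented readings
resolve the ambiguous spots by two rules, applied once and documented here:
adjacent tokens multiply (e.g. `X1 0.05` → 0.05·X1), and a leading isolated
`1` before a delimiter is a numerator (`1|…|` → 1/|…|; the axial-control
frequency token is read as the fraction 1/7.65). The deciding criterion was
learnability: each surface must admit a high-accuracy symbolic fit, since
readings that produce sub-Nyquist oscillation on the generation grid would
contradict the very accuracies reported for these formulas. The implemented
equations are:

| name | expression |
|---|---|
| coronal-autism | 0.14·cos(sin(log\|−0.165·cos(0.05·X1)\|) − 0.11·X2) |
| coronal-normal | 1/\|relu(sin(0.624 − X2))·0.568 + X1 − 5.29\| |
| sagittal-autism | cos(\|27.709 + relu(sin(X1 + cos(\|4.71·X2\|)))\|) |
| sagittal-normal | cos(e^(0.017·log\|X1·X2 − 4.2·X2\|)) |
| axial-autism | y = 0.431·y′ − 0.055·cos(X1·e^(cos X1 + X2)) |
| axial-normal | sin(cos((1/7.65)·\|log\|X1\|\|)·sin(X2)) |

The axial-autism row is implicit in y through its first derivative. With
the package's index-unit difference convention y′_i = y_i − y_{i−1}, the
equation rearranges to the stable forward recursion
`y_i = −(0.431·y_{i−1} + 0.055·c_i)/0.569` (|pole| ≈ 0.757 < 1), with the
first row set to the non-derivative part −0.055·c_0. The start-up transient
decays geometrically and the surface converges to a smooth response to the
cosine forcing.

Noise is additive Gaussian; the headline protocol uses SD = 1% of the clean
value range. Generators are pure functions of their spec, seed included.

## 3. Mode-product tensor reconstruction

Frames are rebuilt as X = G ×₁ f(A) ×₂ f(S) ×₃ f(C): a Tucker-style mode
product of a fixed 3-way core G with one factor matrix per spatial mode,
optionally through an elementwise non-linearity f (identity, relu, or
sigmoid; identity by default). Frames merge along a trailing axis into a 4D
reference tensor; split/merge are exact inverses.

The default core is superdiagonal (identity-like, ones on G[k,k,k]), with
loaders for user-supplied cores. A superdiagonal core makes the
reconstruction a CP model of rank min(r₁,r₂,r₃); consequently ranks equal to
the frame extents do *not* make the factorization universal — a generic
d×d×d tensor has CP rank larger than d. The fitter's contract is therefore
reconstruction error on representable frames, not identifiability and not
universality.

`fit_factors` minimizes mean squared reconstruction error over the raw
factors by plain gradient descent with analytic gradients, seeded N(0, 0.1)
initialization, backtracking step halving on any loss increase (the recorded
history is non-increasing by construction) and a multiplicative step-size
recovery. On frames generated from random rank-(2,2,2) factors it reaches
relative reconstruction error below 1e−3 within the default 6000 iterations.

## 4. Mutual-information connectivity

ROI mean time series come from an integer label volume (one mean per label
per frame). Dependence between regions is plug-in mutual information in
bits: each series is discretized into equal-width bins over its observed
range (default 16 bins), the joint histogram reuses the per-axis marginal
edges, and I(R1;R2) = H(R1) + H(R2) − H(R1,R2). Reusing the marginal edges
makes the estimator symmetric, non-negative, and exactly self-consistent
(I(X;X) = H(X)); a constant series occupies one bin and has zero entropy by
convention. The R×R matrix carries marginal entropies on its diagonal;
the diagonal is excluded from thresholding and testing. The binary adjacency
uses a strict threshold (edge present iff MI > t); the default threshold is
the pooled median off-diagonal MI, and thresholding affects only graph
rendering — group statistics always use the unthresholded values.

The plug-in estimator is biased upward at small T (roughly bins²/(2T·ln 2)
bits under independence); the bias is common to both groups and cancels in
the comparison, but absolute MI values should be read with this in mind.

### Edgewise group comparison

Each unordered ROI pair is modeled as `MI ~ intercept + group (+ covariates)`
— an ANCOVA whose group effect is the partial F with one numerator degree of
freedom. With no covariates this is exactly one-way ANOVA, i.e. the squared
pooled-variance two-sample t statistic (verified to 1e−10 against both the
t-test and a statsmodels OLS fit). The fits for all R(R−1)/2 edges share one
design matrix and are computed in a single vectorized least-squares pass.
Benjamini–Hochberg (non-adaptive) correction is applied over all edges;
an edge is significant when its adjusted q-value is ≤ 0.05. The 8×8
subnetwork summary counts significant edges (or averages MI) within and
between blocks of the ROI→subnetwork map.

## 5. Synthetic two-group study

`group_timeseries` emulates the comparison study: every ROI of every subject
is unit-variance Gaussian noise plus a weak common background (pairwise
correlation 0.1 by default). In group B, both ROIs of each planted edge
additionally mix a shared latent source. The mixing weight is calibrated by
a short seeded pilot simulation that measures, under the default 16-bin
estimator at the spec's frame count, (i) the between-subject SD of null edge
MI and (ii) the mean MI gain as a function of mixing weight; the weight is
then interpolated so the expected MI difference equals the requested number
of pooled SDs. Effect 0 yields exactly exchangeable groups. With one edge
planted at 5 pooled SD and 20 subjects per group, the edge survives FDR in
well over 95% of seeded runs; with effect 0, the mean false-discovery
proportion over 200 simulations stays at the nominal 0.05 within Monte-Carlo
error (both recomputed in the test suite at 12 ROIs, 100–150 frames — sizes
chosen so the full calibration study runs in seconds while the MI estimator
operates in its usual regime).

What the simulation does *not* emulate: fMRI noise spectra (1/f, physiological
cycles), scanner drift and motion, hemodynamic smoothing, spatial
autocorrelation of the parcellation signals, or marginal non-Gaussianity.
Passing tests demonstrate the statistical machinery is calibrated and
powered under its stated model, not that real acquisitions meet that model.
If a ROI participates in several planted edges, it mixes only the latent of
its last-listed edge — plant disjoint edges when exact multi-edge semantics
matter.

The phantom parcellation is a seeded Voronoi tessellation (every label
occupies at least one voxel) with ROI ids partitioned into eight contiguous,
near-equal blocks named DMN, AN, VN, SMN, BiN, SCN, CCN, Cerebellum. The
block assignment is a shipped convention for testing, not an anatomical
claim; real analyses should supply their own label volume and map.

## 6. Default parameters

| parameter | default | meaning |
|---|---|---|
| a | 0.01 | penalty smoothing threshold (weight units) |
| θ | 0.01 | pruning threshold for extraction (weight units) |
| λ | 1e−3 train / 3e−4 distill | sparsity weight (per-sample loss scale) |
| τ | 0.05 | verification tolerance (fraction of target range) |
| ε | 1e−3 | quotient/log safeguard floor |
| bins | 16 | MI histogram bins per axis |
| q | 0.05 | FDR level |
| train fraction | 0.8 | seeded 80/20 split |
| R | 116 | default ROI count of the parcellation |

## 7. Known limitations

* Formula recovery is seed- and data-dependent; the distillation protocol
  guarantees a verified approximation, not the unique generating expression.
* The gradient factor fitter is a desk-scale stand-in for a full deep
  factorization model; it fits one frame at a time against a fixed core and
  claims nothing about factor uniqueness.
* Histogram MI needs on the order of bins² effective samples; with short
  series, reduce the bin count.
* The edgewise linear model assumes independent subjects and homoscedastic
  groups; it is vectorized for thousands of edges but applies no spatial or
  graph-aware correction beyond BH.
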