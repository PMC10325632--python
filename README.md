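# factorlens

Interpretability tooling for deep non-linear tensor factorizations of fMRI.

Deep factorization models compress a 4D fMRI series into three mode factor
matrices coupled by a small constant core tensor, X = G ×₁ f(A) ×₂ f(S) ×₃
f(C). The factors are predictive but opaque. `factorlens` makes them
interpretable along two complementary routes:

1. **Symbolic distillation.** A factor matrix is rewritten as (i, j, value)
   triplets and an *equation-learner* network — linear stages interleaved
   with elementary operator units (ID, +, −, ×, ÷, (·)², eˣ, sin, cos, relu,
   log|·|) — is trained to map coordinates to values under a smoothed-L1/2
   sparsity penalty,

       L = ‖y − ŷ‖² + λ·L1/2*(W),
       L1/2*(w) = |w|^½ for |w| ≥ a,  smooth quartic surrogate below (a = 0.01).

   Pruning coefficients below θ = 0.01 and composing the surviving structure
   layer by layer yields a closed-form formula whose evaluation provably
   matches the pruned network. Fit quality is reported as *verification
   accuracy*: the percentage of held-out matrix entries predicted within
   τ = 5% of the value range.

2. **Brain-network comparison.** Frames reconstructed from the factors merge
   into a 4D reference tensor; ROI mean signals over a 116-region
   parcellation give pairwise histogram mutual information
   I(R1;R2) = H(R1) + H(R2) − H(R1,R2), a 116×116 connectivity matrix per
   subject, and an eight-subnetwork partition (DMN, AN, VN, SMN, BiN, SCN,
   CCN, Cerebellum). Edgewise ANCOVA (group + optional covariates) with
   Benjamini–Hochberg FDR control at q = 0.05 localizes group differences.

A `simulate` module regenerates every input — six built-in factor surfaces
in closed form, random factorized tensors, phantom parcellations, and
two-group time series with planted connectivity effects — so the whole
pipeline runs and is tested with no external data. See `docs/methods.md`
for the full model description and numerical conventions.

## Worked example

Distill a closed-form law from a noisy surface and verify it on held-out
entries:

```python
import factorlens as fl
from factorlens.workflow import distill_surface

_, dataset = fl.formula_surface(fl.FormulaSpec("sin(X1)", (50, 50), seed=3))
result = distill_surface(dataset, seed=5, lam=2e-2)
print(result.formula)
print(f"{result.report.accuracy:.2f}% of {result.report.n_test} held-out "
      f"points within 5% of the value range (nrmse {result.report.nrmse:.4f})")
```

prints

```
(-1.01193)*sin((-0.984904)*X1) + 0.00873799
100.00% of 500 held-out points within 5% of the value range (nrmse 0.0052)
```

— the generating law recovered up to sign and small coefficient noise, with
every held-out entry inside the tolerance band. Smaller λ trades compactness
for fit: the same protocol at the default λ keeps more terms but typically
reaches nrmse ≈ 0.01 on the built-in surfaces.

The same machinery drives the statistical pipeline:

```python
spec = fl.PlantedDifferenceSpec(n_rois=12, n_frames=150, n_per_group=20,
                                edges=((2, 9),), effect_size=5.0, seed=0)
group_a, group_b = fl.group_timeseries(spec)
mats_a = [fl.build_connectivity(ts, bins=16) for ts in group_a]
mats_b = [fl.build_connectivity(ts, bins=16) for ts in group_b]
result = fl.edgewise_group_comparison(mats_a, mats_b, q_level=0.05)
print(result.significance_matrix()[2, 9], int(result.mask.sum()))
```

prints `True 1`: the planted edge — and only it — survives FDR correction.

Everything is also reachable from the shell via the `factorlens` console
script (`simulate`, `sr-fit`, `sr-extract`, `sr-eval`, `reconstruct`,
`fit-factors`, `connectome`, `compare`, and a YAML-driven `run` pipeline
that writes a digest manifest).

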