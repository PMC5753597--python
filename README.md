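# perturbtensor

Predict unmeasured, cell-specific drug-perturbation expression profiles from
the profiles that *have* been measured.

Large perturbation compendia profile thousands of compounds across dozens of
human cell lines, but the combinatorial drug × cell space is mostly empty:
a typical signature tensor has ~10% of its (drug, cell) conditions measured.
Because drug responses are often strongly cell-specific, simply reusing a
drug's profile from another cell line is unreliable. `perturbtensor` fills
these gaps by arranging unit-norm differential-expression signatures
(characteristic-direction vectors over landmark genes) into a three-way
array **T** ∈ ℝ^{D×G×C} indexed by drug *d*, gene *g* and cell *c*, and
predicting every missing profile T<sub>d,:,c</sub> with either local or
global structure:

- **DNPP** (Drug Neighbor Profile Prediction, local): the similarity of two
  drugs is the mean Pearson correlation of their profiles over shared cells,

  S(d, d′) = (1 / |C_d ∩ C_d′|) Σ_{c′ ∈ C_d ∩ C_d′} cor(T_{d,:,c′}, T_{d′,:,c′}),

  and the prediction for (d, c) is a convex, similarity-weighted average of
  up to K = 10 positively-similar drugs that were measured in cell c.
- **FaLRTC-style tensor completion** (global): iterated singular-value
  soft-thresholding (the proximal operator of the trace norm) applied to the
  three mode unfoldings of T, recombined with weights α that down-weight the
  gene mode 100× (whole-profile missingness removes entire columns of the
  gene-mode unfolding, making gene–gene correlations uninformative), with
  observed profiles reset to their measured values every iteration.
- **1D-Mean / 2D-Mean baselines**: within-drug and λ-blended
  within-drug/within-cell averages (λ = ½).

The package also provides replicate-consistency QC (average cosine distance
against an empirical per-batch null), profile-holdout cross-validation with
the Pearson-correlation-with-truth (PCT) metric, differential-expression ROC
analysis, accuracy-versus-density experiments, per-profile winner maps,
per-drug cell-specificity scores, and seeded synthetic-data generators for
all of the above.

## Worked example

```python
import numpy as np
from perturbtensor import (
    gen_lowrank_tensor, apply_missingness,
    complete_tensor_falrtc, complete_tensor_dnpp, pct,
)

# a rank-2 drugs x genes x cells tensor, 50% of profiles hidden
_, truth = gen_lowrank_tensor(D=60, G=50, C=12, rank=2, noise_sd=0.0, seed=3)
masked = apply_missingness(truth, density=0.5, seed=4)
held = [p for p in truth.observed_pairs() if not masked.mask[p]]

pred_t, report = complete_tensor_falrtc(masked)
pred_n, abstained = complete_tensor_dnpp(masked)
print(f"tensor completion: PCT = {pct(truth, pred_t, held):.4f} "
      f"({report.iterations} iterations, converged={report.converged})")
print(f"DNPP:              PCT = {pct(truth, pred_n, held, abstained):.4f}")
```

prints

```
tensor completion: PCT = 0.9758 (65 iterations, converged=True)
DNPP:              PCT = 0.9225
```

i.e. on globally low-rank data at 50% density the tensor method predicts
held-out profiles with a pooled Pearson correlation of about 0.98 against
the true values, while the neighbor method reaches about 0.92 — the global
method wins when the latent factor structure spans the whole tensor, whereas
DNPP wins when near-duplicate drugs are present (see `docs/methods.md`).

A command-line interface mirrors the library
(`perturbtensor simulate|qc|build|complete|evaluate`), reading and writing
GCT-dialect signature matrices, metadata TSVs and a tensor-on-disk format
(genes × `drug::cell` GCT plus a 0/1 mask TSV) that round-trips
bit-exactly.

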