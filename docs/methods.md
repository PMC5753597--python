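# Methods

## The data model

The object of study is a three-way array **T** ∈ ℝ^{D×G×C} of
differential-expression signatures: T[d, g, c] is the characteristic-direction
(CD) value of gene g when drug d perturbs cell line c.  A CD signature is a
unit vector in gene space — the direction that best separates treated from
control samples — so every measured profile T[d, :, c] has Euclidean norm 1
and entries in [−1, 1], with sign encoding up-/down-regulation.  Missingness
is *column-structured*: a (drug, cell) condition is either fully assayed or
entirely absent, recorded in a D×C boolean mask.  This structure is what
distinguishes the problem from ordinary expression-matrix imputation: the
target condition has no observed genes at all, so any predictor must borrow
strength from other drugs and other cells.

Axis order is fixed as (drug, gene, cell); mode-1/2/3 unfoldings refer to
these axes in that order, with the remaining axes indexing columns
earlier-axis-fastest.  Any consistent column convention is equivalent for
rank computations; this one is fixed so that fold(unfold(·)) is an exact
inverse.

## Ingestion and quality control

Each experiment contributes one replicate-averaged CD signature keyed by
(drug, cell, dose, time, batch).  Reliability is scored by the **average
cosine distance (ACD)** between the experiment's replicate signatures — the
mean of (1 − cosine similarity) over all replicate pairs, ranging from 0
(identical) through 1 (orthogonal) to 2 (anti-parallel).  Significance comes
from an empirical null: 10,000 random same-sized replicate sets drawn from
the same batch (without replacement within a draw, with replacement across
draws), yielding a left-tail p-value with an add-one pseudo-count,
p = (1 + #{null ≤ ACD}) / (1 + n).  Small p means the experiment's
replicates agree more than random batch members do.  The pseudo-count keeps
finite sampling from reporting p = 0; the left tail is used because
downstream filtering *keeps* small p (the most reproducible experiments).
Each experiment is compared against random sets of its own replicate count,
the only size-fair comparison, so one null is built per (batch, k).

Filtering then proceeds in three steps: (1) drug-id synonyms are collapsed
to canonical identifiers (exact-string identity unless a synonym table is
supplied; records without a p-value are dropped with a logged count);
(2) experiments with ACD p > 0.1 are discarded; (3) drugs and cells with
fewer than 3 surviving experiments are pruned *jointly to a fixed point* —
removing a drug can push a cell below threshold and vice versa, and the
fixed-point iteration is the only order-independent reading of a joint
threshold.  Surviving signatures are averaged over doses and time points per
(drug, cell) — arithmetic mean, then renormalization to unit norm, in that
order — and assembled into the tensor with lexicographically ordered axes.

## Prediction methods

**DNPP** adapts K-nearest neighbors to de-novo profile prediction by
defining similarity between *drugs* rather than profiles: the mean Pearson
correlation over the cells both drugs were measured in.  Similarity is
undefined (a sentinel, not a number) when two drugs share no cell, or when a
shared-cell profile is constant.  To predict (d, c), candidate neighbors are
the drugs measured in c with defined, strictly positive similarity to d; the
top K = 10 by similarity (ties broken lexicographically by drug id, for
determinism) are averaged with weights S(d, d′)/ΣS.  Restricting to S > 0
keeps the weights a convex combination — the method never extrapolates
through anti-correlated "anti-neighbors".  When no eligible neighbor exists
the method abstains rather than guessing; callers may backfill abstentions
with a baseline explicitly.  Predictions are not renormalized to unit norm
by default: a convex combination of unit vectors has norm ≤ 1, the shrinkage
toward 0 reflects neighborhood disagreement, and the correlation-based
evaluation metric is scale-free.  A `--renormalize` flag restores unit norm
when profiles must satisfy the input contract.

**Tensor completion** assumes the signature tensor is approximately
low-rank: a small set of latent factors (shared targets, pathway programs,
lineage effects) explains most variation.  Since tensor rank is intractable,
the algorithm works on the three mode unfoldings and shrinks each toward low
rank with the trace-norm proximal operator (soft-thresholding of singular
values by τ).  One sweep computes

X ← α_drug · fold(SVT_τ(unfold_drug X)) + α_gene · fold(SVT_τ(unfold_gene X)) + α_cell · fold(SVT_τ(unfold_cell X)),

then resets observed profiles to their measured values, and repeats until
the relative Frobenius change drops below tolerance.  This is the simple
block-shrinkage (SiLRTC-style) scheme; the Nesterov-smoothed acceleration of
the original FaLRTC reference changes speed, not the fixed point, and is not
implemented.

Because missing data are whole (drug, cell) columns, the gene-mode unfolding
G×(DC) is missing entire *columns*; estimates leaning on gene–gene
correlation alone cannot reconstruct them, so the gene mode is down-weighted
100× relative to the drug and cell modes: α ∝ (100, 1, 100) over
(drug, gene, cell), normalized to sum to one.

### Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ACD p-value cutoff | 0.1 | keep only experiments whose replicates beat the batch null at the 10% level |
| min experiments per drug/cell | 3 | below this, condition averages are dominated by single-experiment noise |
| K (DNPP neighbors) | 10 | enough neighbors to denoise, few enough to stay local |
| min_overlap | 1 | minimum shared cells for a defined drug similarity |
| λ (2D-Mean blend) | 0.5 | equal weight to within-cell and within-drug averages |
| α (mode weights) | (100, 1, 100)/201 | gene mode down-weighted 100× (column-structured missingness) |
| τ (shrinkage) | 0.1 · σ_max per mode | scale-free; σ_max taken from each mode's initial unfolding |
| tol / max_iter | 1e-5 / 500 | relative Frobenius change; non-convergence is reported, never raised |
| init | 2D-Mean fill | warm start; zeros optional (affects speed, not the fixed point of the convex surrogate) |

τ trades bias for rank: larger values converge faster and regularize harder
but shrink the magnitude of imputed profiles.  Since signatures are unit
vectors and both evaluation metrics (PCT, DEG ROC) are invariant to
per-profile positive scaling, this bias is immaterial in practice; tests of
exact numerical recovery compare *directions* (renormalized profiles).

## Evaluation

Cross-validation holds out entire (drug, cell) profiles — 10 folds of equal
size (±1) over the observed pairs — predicts each fold with the other nine
tenths, and compiles all held-out predictions into a tensor T̂ with the
original missingness pattern.  A partition is redrawn (up to 50 times) if a
fold would strip a drug or cell of *all* its observations while it had two
or more, since a condition with no anchors is unpredictable for every
method; singleton conditions are exempt because emptying them is
unavoidable.  Accuracy is **PCT_Ω = cor(T_Ω, T̂_Ω)**, the element-wise
Pearson correlation pooled over any entry subset Ω (one profile, one fold,
or the whole tensor).  Abstained or undefined profiles are skipped with a
logged count; a constant pooled vector yields a NaN sentinel, never an
exception.

**DEG ROC.** A gene is a "true" differentially expressed gene (DEG) in a
measured profile when its absolute value is at or above the (100 − p)-th
percentile of that profile's absolute values (linear-interpolation
percentile; ties flagged jointly), for p = 1% or 10%.  Predictions are
scored by their within-profile percentile of |value|, a single threshold is
swept from 0 to 100, and TP/FP/TN/FN are pooled across all profiles
(micro-averaged, giving one aggregate curve per method); the AUC is
trapezoidal.  Scoring by within-profile percentile makes the pooled curve
invariant to any strictly monotone within-profile transform of the
predictions and lets one global threshold mean the same percentile cut in
every profile.

**Winner maps** label each held-out profile with the method of highest
per-profile PCT (ties broken by the caller's method ordering; abstentions
rank below any finite correlation).  **Density experiments** repeatedly
(25×) hold out 10% of observed profiles for evaluation, subsample the rest
to a target density, and record held-out PCT per method, reporting
mean ± sd.  **Cell-specificity** of a drug is the mean pairwise cosine
distance between its profiles across cells: 0 for an identical response
everywhere, 2 for perfect anti-correlation.

## Synthetic data

The generators reproduce the structural assumptions the methods rely on,
with all randomness a pure function of the seed:

- `gen_lowrank_tensor` draws CP-rank-r factor matrices with unit-variance
  gaussian entries, forms Σ_k a_k ⊗ b_k ⊗ c_k, adds isotropic gaussian noise,
  and renormalizes each (drug, cell) profile to unit norm.  Default sizes
  D=60, G=50, C=12 keep a full cross-validation over all four methods in the
  range of seconds on one CPU.
- `apply_missingness` removes whole profiles down to ⌊density·D·C⌋, either
  uniformly or with per-drug inclusion weight ∝ 1/(rank of drug), emulating
  the heavily skewed sampling of real compendia; when feasible every drug
  and cell keeps at least one profile.
- `gen_paired_drug_tensor` creates drugs in identical twin pairs with
  independent profiles across pairs and cells — the neighbor-favorable
  fixture whose exact answer for any held-out profile is the twin's measured
  profile in that cell.  Accordingly, its defining evaluation uses K = 1 and
  restricts to held-out pairs whose twin is measured in the target cell and
  shares at least one observed cell (otherwise the twin similarity is
  undefined and no oracle answer exists).
- `gen_replicate_sets` draws a latent unit direction per experiment and
  replicates as direction + noise, renormalized, with round-robin batches.

What these fixtures do **not** emulate: dose–response and kinetic structure
(collapsed by design), platform measurement noise models, batch effects
beyond exchangeability within a batch, and the correlated gene modules of
real transcriptomes.  Passing tests therefore demonstrate algorithmic
correctness and the direction of the local/global trade-off, not the
absolute accuracy attainable on real compendium data.

## A note on exact low-rank recovery

Per-profile unit renormalization divides each fiber T[d, :, c] by a
(d, c)-dependent scalar.  For rank 1 this preserves rank in every mode (each
profile is ± a common unit vector).  For rank ≥ 2 it preserves *exact* low
rank only in the gene-mode unfolding, whose columns are individually
rescaled — and that is precisely the mode that column-structured missingness
makes uninformative and that the algorithm down-weights.  The drug- and
cell-mode unfoldings of a renormalized rank-2 tensor are full-rank with
rapidly decaying spectra.  Consequently, held-out recovery on noiseless
renormalized fixtures is essentially exact at rank 1 (PCT ≥ 0.99) but caps
near PCT ≈ 0.97–0.98 (rank 2) and ≈ 0.95 (rank 3) at 50% density regardless
of τ; the tensor method still clearly dominates the neighbor method there.
This is a property of unit-norm signature data itself, not of the
implementation.

## Numerical choices and degenerate inputs

- Pearson correlations of constant vectors, drug similarities without
  overlap, and cell-specificity of singleton drugs return NaN sentinels.
- A zero-norm condition mean (perfectly cancelling signatures) cannot be
  renormalized; the pair is dropped with a warning.
- Completion of a tensor with no observations is an error; full observation
  makes both completion methods exact pass-throughs.
- The drug-similarity matrix is explicitly symmetrized (BLAS products are
  not bit-symmetric), and DNPP neighbor ties are broken by drug id.
- Text serialization writes floats with 17 significant digits and parses
  with correctly-rounded conversion, so write → read round-trips are
  bit-exact.

## Known limitations

- DNPP abstains for drugs with no positively-similar measured neighbor; on
  very sparse tensors this can leave a sizable abstention set.
- The completion methods impute values, not uncertainties; there is no
  probabilistic output.
- Similarity uses expression only; chemical-structure or target-annotation
  side information is out of scope.
- Dose and time are averaged away; the tensor has no kinetic axis.
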