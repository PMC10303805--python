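# Methods

`msiflnp` predicts unobserved microbe–disease associations from a single
binary association matrix **A** (rows = microbes, columns = diseases).
The method has three stages: (1) three association-derived similarity
matrices per entity type, (2) similarity-network fusion with SVD
denoising, and (3) closed-form bidirectional label propagation.

## Similarities

All similarities derive from A alone; no external disease ontology or
microbial taxonomy is used.

* **Cosine.** S(i,j) = P(i)·P(j) / (‖P(i)‖‖P(j)‖) between binary
  association profiles (rows of A for microbes, columns for diseases).
  If either profile is all-zero the similarity is 0, including the
  diagonal entry of a zero-profile entity — this avoids 0/0 and lets
  the selective normalization downstream skip the resulting all-zero
  columns.
* **Gaussian interaction profile (GIP).**
  S(i,j) = exp(−γₑ ‖P(i) − P(j)‖²) with bandwidth
  γₑ = γ / mean‖P‖², γ = 1 by default. The bandwidth adapts to the
  overall association density of the axis. Two zero profiles have GIP
  similarity 1 (zero distance); as a consequence every zero-degree
  entity belongs to a mutual-similarity clique, which matters below.
* **Linear neighborhood (LN).** For each entity i, the nonnegative
  weights summing to one that best reconstruct its profile from its k
  nearest neighbors' profiles (Euclidean distance, self excluded):
  a simplex-constrained quadratic program per entity, solved with
  SLSQP on the Gram system. A ridge of 1e-6 on the neighbor Gram matrix
  keeps the program well-posed when neighbor profiles are identical
  (common with binary data). Ties at the k-th neighbor break toward
  the smaller entity index. A zero profile yields an all-zero LN row.

The neighbor counts Nm (microbes) and Nd (diseases) are shared between
the LN similarity and the fusion neighbor kernels; since the LN program
excludes self it uses min(k, n−1).

## Fusion and denoising

For each axis the three similarities give

* three **initial kernels** MS_l: selective *column* normalization
  (columns with positive sum divided by the sum; all-zero columns kept
  at zero), and
* three **neighbor-constraint kernels** LMS_l: each row sparsified to
  its top-N entries by similarity (self always kept), then selectively
  row-normalized.

Cross-iteration then updates, for x rounds and all l simultaneously,

    LMS_l ← MS_l · ( Σ_{r≠l} LMS_r / 2 ) · MS_lᵀ

and the fused network K is the entrywise mean of the three iterated
kernels. Note two deliberate readings of this scheme: updates are
Jacobi-style (all three from the previous iterate), and no
renormalization is applied between iterations. The iteration places the
dense column-normalized kernel on the outside and the sparsified kernel
inside; the output is therefore not symmetric in general and is
consumed as a directed graph — no re-symmetrization is applied.

K is denoised by truncated SVD: keep the top r = ⌈fraction × n⌉
singular triplets (fraction 0.5 by default, i.e. half the singular
values of the square matrix) and reconstruct U_r Σ_r V_rᵀ. The
reconstruction is the Frobenius-optimal rank-r approximation
(Eckart–Young), which the tests verify against an independent
eigendecomposition of KᵀK. Low-rank reconstructions can contain small
negative entries; these are clipped to zero (a negative similarity is
meaningless and would break the propagation normalization), and the
clipped mass fraction is recorded on the returned network.

## Propagation

Known associations are the label matrix: H0 = A on the microbe network
KM, H0 = Aᵀ on the disease network KD (the disease network is nd×nd, so
the disease-side labels are necessarily the transposed associations;
the disease-side scores are transposed back before averaging). Each
propagation step keeps a fraction θ of diffused neighbor labels and
1−θ of the initial labels; the fixed point is

    Y = (1−θ) (I − θK)⁻¹ H0,

computed by a dense linear solve. Convergence requires ρ(θK) < 1,
which the raw fused network does not guarantee, so the denoised K is
row-normalized to a (sub)stochastic transition matrix first (rows
summing to zero stay zero; such nodes keep (1−θ) of their own labels).
θ is interpreted as a transition probability, consistent with this
normalization. The closed form is verified against 500 steps of the
explicit recurrence to 1e-10.

Both score matrices are min–max normalized per row (per microbe on the
microbe side, per disease on the disease side, following the row-wise
index range of the normalization formula), a constant row mapping to
zeros, and the final score is Y = (YM + YD)/2, a microbe×disease
matrix in [0, 1].

## Defaults

| parameter | default | meaning |
|---|---|---|
| Nm | 5 | microbe neighbor count (LN similarity + neighbor kernel) |
| Nd | 26 | disease neighbor count |
| x | 2 | cross-iteration rounds |
| θ | 0.2 | propagation probability, strictly in (0,1) |
| γ | 1.0 | GIP bandwidth scale |
| svd_keep_fraction | 0.5 | fraction of singular values kept |
| cv_folds / cv_repeats | 10 / 10 | evaluation protocol |

The neighbor defaults target catalogue-scale data (hundreds of
microbes, a few dozen diseases); Nd = 26 presumes ≥ 26 diseases. On
the smaller synthetic datasets used by the tests and the acceptance
script we keep Nm = 5 and scale Nd to the disease count (13 for
nd = 20, 10 for nd = 15, roughly the same two-thirds ratio as the
default), since a neighbor count may not exceed the entity count.

## Evaluation protocol

Repeated k-fold cross-validation splits only the known associations.
Per fold, the test positives are zeroed in A, **all similarities are
recomputed from the masked matrix** (they all derive from A, so
anything else would leak test labels — a guard assertion enforces
this), and the fold AUC ranks the held-out positives against every
pair that is zero in the original matrix (training positives are
excluded from the ranked set). Fold AUCs are averaged per repeat; the
reported spread is the standard deviation over repeats. Parameter
sweeps reuse one set of fold assignments across the grid so that
differences reflect parameters rather than fold noise, with ties in
mean AUC broken toward smaller parameter values.

## Synthetic data

The planted-block generator samples a binary bipartite matrix in which
microbes and diseases carry latent block labels and co-membership
raises the association probability (defaults: 80×20, 4 blocks,
p_within = 0.35, p_between = 0.02 — overall density ≈ 10%, block
structure strong enough for every kernel to detect). It emulates the
*shape* of curated association catalogues — sparse, with zero-degree
entities retained — but not real name distributions, degree
heterogeneity, or curation biases; passing tests on it demonstrate
internal correctness and better-than-chance recoverability, not
clinical-scale accuracy. Structureless data (p_within = p_between)
provides a null calibration: CV AUC is statistically indistinguishable
from 0.5 there.

## Numerical choices and known limitations

* **Tie-breaking is index-based** (k-th-neighbor distance ties and
  top-N similarity ties break toward the smaller entity index). This
  makes every run deterministic, but it also means exact permutation
  equivariance of the whole pipeline holds only on instances without
  ties at the neighbor cutoffs; with binary profiles such ties are
  common. All stages downstream of neighbor selection are exactly
  equivariant, and the tests assert exactly that.
* **Min–max amplification.** Per-row min–max normalization stretches
  every row to [0,1], including rows whose raw propagated scores are
  mere noise — notably rows of zero-degree microbes, whose GIP clique
  (pairwise similarity 1 among zero profiles) gives them arbitrary
  propagated rankings. On sparse synthetic data this inflates the
  *mean* score of unknown cells in those rows even though the rank
  separation of held-out positives stays above chance; before the
  min–max step the mean separation is positive on every seed tested.
  Users comparing mean scores across rows (rather than rankings)
  should be aware of this.
* The linear solve uses a dense LU factorization of (I − θK); the
  design envelope is a few thousand entities per axis.
* The SLSQP simplex QP is verified against exhaustive grid search
  (step 1e-4) to 1e-3 in objective value on small instances.
* All-zero input matrices are rejected up front (the GIP bandwidth is
  undefined); all-zero rows or columns within a nonempty matrix are
  handled by the selective normalizations and propagate harmlessly.

## Problem sizes used in tests and the acceptance script

Cross-validation runs use the generator defaults (80×20, ~150
associations; 10 folds × 3 repeats) and a 60×15 null dataset, with
masked-recovery checks over five generator seeds — sizes chosen so the
planted structure is comfortably recoverable while a full test run
completes in well under a minute.
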