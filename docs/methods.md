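# Methods

## Model

The scorer treats microbe–disease association inference as bipartite link
prediction on a heterogeneous network. Three networks enter: the known
binary association matrix `A` (`nd` diseases × `nm` microbes), a microbe
similarity `MS`, and a disease similarity `DS`. The score of pair `(i, j)`
is the sum of two vector-space projections — the projection of microbe `j`'s
similarity vector onto disease `i`'s association vector, and of disease
`i`'s similarity vector onto microbe `j`'s association vector — normalised
by the lengths of the two similarity vectors:

    msp(i,j) = ⟨A'_i·, MS_·j⟩ / ‖A'_i·‖
    dsp(i,j) = ⟨DS_i·, A'_·j⟩ / ‖A'_·j‖
    ncp(i,j) = (msp + dsp) / (‖DS_i·‖ + ‖MS_·j‖)

The intuition: a pair scores highly when the microbes already associated
with disease `i` are similar to microbe `j` (microbe space), and when the
diseases already associated with microbe `j` are similar to disease `i`
(disease space). Consistency between the similarity networks and the
association network is rewarded; no training or tuning is involved.

Assumptions worth stating explicitly:

- *Guilt by association*: microbes associated with similar diseases are
  similar, and vice versa. Both GIP kernels inherit any ascertainment bias
  of the catalogue (well-studied diseases have richer profiles).
- The symptom-based similarity assumes disease–symptom co-occurrence counts
  are informative about disease relatedness; the TF-IDF weighting
  `w(i,m) = W(i,m) log(N/n_m)` downweights ubiquitous symptoms.
- Interaction profiles are treated as complete negatives: a zero in `A` is
  "unknown", yet the kernels treat it as absence. This is standard for this
  family of methods and is exactly what cross-validation probes.

## Parameters (all with defaults; none requires tuning)

| name | default | meaning |
| --- | --- | --- |
| `gamma_prime` | 1 | GIP bandwidth numerator; the effective bandwidth is `γ'`/mean squared profile norm, i.e. adapted to the mean association count per entity |
| `delta` | 1e-30 | value substituted for zeros of `A` inside the projection arithmetic so row/column norms are strictly positive |
| `log_base` | 10 | base of the TF-IDF logarithm; cosine similarity is invariant to it (the base rescales all weights uniformly), property-tested |
| `k`, `seed` | 5, 0 | fold count and partition seed for k-fold CV |

## Numerical and design choices

- **δ scope.** The substitution is applied to the copy of `A` used in both
  the dot products and the norms of the projections. With `δ = 1e-30` the
  numerator perturbation is ≤ `nm·δ` and invisible at double precision;
  scores agree to < 1e-6 across `δ ∈ {1e-30, 1e-20, 1e-12}` (tested). A
  consequence embraced rather than hidden: an entity with *no* remaining
  associations has an all-δ association vector, whose normalised form is the
  uniform direction, so its disease-space projection becomes the mean
  similarity to all diseases. This is what lets a held-out degree-1 microbe
  remain scoreable during LOOCV.
- **Norms.** "Length of a vector" is the Euclidean norm throughout,
  consistent with the projection geometry; L1 would not be a projection.
- **Ablation modes.** The single-space diagnostics are each projection term
  normalised by its own similarity-vector length:
  `msp(i,j)/‖MS_·j‖` and `dsp(i,j)/‖DS_i·‖`. The combined-score
  normalisation is the natural per-term analogue; other readings exist, and
  rankings within a disease are unaffected for the disease-space variant.
- **Degenerate inputs.** An all-zero profile *set* (no associations at all)
  makes the kernel bandwidth undefined; this raises an explicit error rather
  than silently returning identity. A disease with an all-zero symptom
  vector gets symptom similarity 0 to everything and is excluded from the
  presence mask, so integration falls back to the GIP kernel for it.
- **Presence, not magnitude.** The integrated similarity uses the
  symptom-based score for exactly those pairs that *have* one — an explicit
  0 counts as present; an unlisted pair is absent. Loaded similarity files
  therefore carry a presence mask distinct from the scores.
- **Ties.** Written rankings break ties by microbe label for byte
  reproducibility; evaluation uses average ranks so ties carry no
  information either way.
- **ROC pooling.** Candidate sets differ in size across diseases, so trials
  are pooled on the percentile-rank scale `(rank−1)/(n_candidates−1)`: at
  threshold θ, sensitivity is the fraction of test samples at or above the
  θ-percentile cut and the false-positive rate is the mean fraction of
  non-test candidates at or above it. AUC is the trapezoidal area; it
  equals 1 for perfect retrieval and 0.5 in expectation for random ranking
  (Monte-Carlo checked). An exhaustive threshold-enumeration oracle verifies
  the sweep on small trial sets.
- **Per-trial recomputation.** Both GIP kernels are recomputed inside every
  CV trial/fold because they depend on `A`; the symptom similarity does not
  depend on `A` and is computed once per run.

## Synthetic data

The generator emulates the scale and community structure of a genus-level
association catalogue with a bipartite planted-partition model: 20 diseases
and 94 microbes split into 4 paired blocks; within-block association
probability `p_in = 0.28`, cross-block `p_out = 0.016`, giving ≈154 expected
edges, mean disease degree ≈7.7 and mean microbe degree ≈1.6 — the sparsity
regime of real catalogues. Empty rows/columns are retained: some simulated
entities end up with no associations, as some real entities have only one.

Symptom profiles: a `symptom_coverage = 0.8` fraction of diseases receive
Poisson count vectors over 40 symptoms (10 per block); `symptom_signal = 0.9`
is the expected fraction of a disease's total count mass
(`total_symptom_mass = 50`) landing on its own block's symptoms. Same-block
diseases therefore have high expected cosine similarity — a planted,
recoverable signal for the integrated disease similarity. Coverage below 1
exercises the presence-mask fallback path.

What the generator does *not* emulate: text-mining noise, taxonomic
hierarchy among microbes, degree heterogeneity beyond what Bernoulli
sampling produces, or correlated missingness. Passing the synthetic
recovery tests shows the pipeline extracts planted block structure at
catalogue scale; it does not certify performance on any real catalogue.

Two structural consequences of this sparse Bernoulli regime are worth
knowing when reading cross-validation numbers. First, ~15% of simulated
microbes are isolated; during LOOCV their all-δ columns tie with the
held-out microbe whenever it loses its last association, capping
recovery. Second, because of exactly that disease-space noise, the
microbe-space-only ablation can outperform the kernel-only combined score
on these synthetic networks, whereas on real catalogues the combined score
is reported to dominate both single spaces — the ablation ordering is a
property of the data's correlation structure, not of the method.

## Problem sizes

Default test and acceptance runs use genus-scale networks (20×94, ~154
edges), 10 generator seeds for cross-validated averages, 20 seeds for the
random-ranking null, and 200 random small instances (≤8×8) for oracle
equivalence. These sizes give stable averages (seed-to-seed SD of the
LOOCV AUC ≈ 0.04) while keeping any single run in seconds.

## Known limitations

- Scores are comparable within a disease (the ranking unit), less so across
  diseases with very different degrees.
- The GIP kernels bias toward well-annotated entities; with very few known
  associations the kernel contrast, and hence the signal, shrinks.
- Published AUCs for real catalogues depend on the exact curated export and
  the ROC pooling rule; reproducing them requires supplying that export to
  the CLI, not the bundled synthetics.
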