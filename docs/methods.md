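# Methods

This note records the model implemented by `bganmda`, the readings chosen
where the printed formulas are ambiguous or ill-defined, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Similarity pipeline

**Weighted edit distance.** Classic dynamic program with substitution cost 2
and insertion/deletion cost 1. With these costs the distance between two
sequences never exceeds the sum of their lengths, so the raw sequence score
`1 − x/(Len_i + Len_j)` lies in [0, 1]. The *difference* of lengths
sometimes quoted as a denominator for this score is zero for equal-length
sequences and negative for shorter first arguments; the length *sum* is the
only reading that keeps the score well-defined and the subsequent min–max
rescaling meaningful, and is what we implement.

**Sequence similarity (MSS).** Raw scores are min–max rescaled over
off-diagonal entries only, the diagonal is pinned to 1, and pairs involving
an unknown sequence are set to 0 (the GIP fallback covers them at
integration). If all off-diagonal raw scores are equal the rescaling is
undefined; the raw values are then kept (clipped to [0, 1]).

**Disease semantic similarity.** Model 1 is the decay recursion: the disease
itself contributes 1 and an ancestor contributes `μ` times the maximum
contribution of its children on paths toward the disease, `μ = 0.5`. When a
disease sits in several DAGs, per-DAG contributions are merged by maximum.
Model 2 assigns every term the information content `−ln(NG(d)/n)`, where
`NG(d)` is the number of DAGs containing the term and `n` the number of
distinct diseases in the forest; the logarithm base is a free choice that
rescales both numerator and denominator of the similarity ratio, and we use
the natural log. Because model-2 contributions are unnormalized, the ratio
can exceed 1 on small forests; values are clipped to [0, 1] and every clip
is logged. Pairwise similarity for both models is
`Σ_{x shared} (C_i(x) + C_j(x)) / (SV_i + SV_j)`; diseases absent from the
forest get zero rows (diagonal 1). The disease network DSN is the
elementwise mean of the two models.

**Functional similarity (MFS).** `D(m)` is the set of diseases associated
with miRNA `m` in the (possibly masked) association matrix; a disease's
similarity to a set is its best DSN match in that set. The default
`intersection` mode sums the two set-similarities of each disease in
`D(m_i) ∩ D(m_j)`; the classical variant (`union_max`) sums each disease of
one set against the other set, both normalized by `|D(m_i)| + |D(m_j)|`.
Both modes give 1 for identical non-empty sets. The intersection form is the
default because it is the form stated for this pipeline; the discrepancy
with the classical formula is surfaced as a mode rather than silently
resolved.

**GIP kernels.** `exp(−λ‖p_i − p_j‖²)` with
`λ = λ′ / mean_k(‖p_k‖²)` by default (`gip_norm="squared"`, the convention
of the GIP literature); `gip_norm="linear"` divides by the mean unsquared
norm instead. `λ′ = 1`. An all-zero association matrix leaves the bandwidth
undefined and raises. Entities with all-zero profiles are not special-cased:
two such profiles have kernel 1 (distance 0), which the integration step
inherits — documented behaviour, covered by the fallback semantics below.

**Integration.** `MS(i,j) = MSN(i,j)` if `MSN(i,j) > 0`, else the miRNA GIP
value; `DS` analogously. "Existence" of a network similarity is defined as
a strictly positive value, applied uniformly to both entity types, so the
operation is a pure function of its four matrix inputs. Missing sequences
and diseases without DAG membership therefore fall through to the GIP
kernel, which is the motivation for the integration step.

**Feature vectors.** Pair `(m_i, d_j)` gets `[MS row i ‖ DS row j]`, length
`nm + nd`; at the reference corpus scale (1,207 miRNAs, 984 diseases) this
is 2,191. Feature sets are lazy; the full `nm × nd` matrix is only
materialized on request.

## Adversarial model

Encoder, generator and discriminator are three-layer fully connected
networks (two hidden layers with LeakyReLU slope η = 0.01 and dropout 0.5).
Hidden widths default to a geometric interpolation between input and output
widths; the discriminator's hidden widths interpolate from its input
(feature + latent width, 2,291 at reference scale with a 100-dimensional
latent code) toward the *latent* width rather than toward scalar width — a
discriminator with capacity comparable to the encoder is required for its
decision boundary to track the data manifold, which is what the scoring
rule exploits.

Training follows the bidirectional objective with real pairs `(x, E(x))`
labelled 1 and generated pairs `(G(z), z)` labelled 0, `z ~ N(0, I)` (the
latent prior is otherwise unspecified; the standard normal is the
conventional choice). The encoder/generator update uses the non-saturating
form — `G` maximizes `log D(G(z), z)` and `E` maximizes
`log(1 − D(x, E(x)))` — which leaves the optimum unchanged but avoids
vanishing early gradients. Optimization is Adam with betas (0.5, 0.999), the
usual adversarial-training choice; all log terms clip probabilities to
`(1e-7, 1 − 1e-7)`. Only known-association feature vectors are real samples;
unknown pairs are scored at inference only. Scores are
`sigmoid(D(x, E(x)))` with dropout disabled — the only per-pair probability
the architecture produces. (The expression `1/(1−exp(−θ))` occasionally
quoted for the sigmoid is not a probability; the standard
`1/(1+exp(−θ))` is implemented.)

The "remove 20% of training samples five times" protocol is implemented as
an ensemble: each of `n_repetitions = 5` members trains from the same
initialization on an independent random 80% subsample, and the final score
is the ensemble mean. Everything is seeded: same seed, bit-identical loss
traces and scores.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.6 | functional-vs-sequence weight in the miRNA network |
| `mu` | 0.5 | semantic decay per DAG level (model 1) |
| `lambda_prime` | 1.0 | base GIP bandwidth |
| `sub_cost`, `indel_cost` | 2, 1 | edit-operation costs |
| `functional_mode` | intersection | MFS summation domain |
| `gip_norm` | squared | bandwidth normalization |
| `latent_dim` | 100 | encoder output width |
| `eta` | 0.01 | LeakyReLU negative slope |
| `dropout` | 0.5 | hidden-layer dropout rate |
| `lr` | 2e-4 | Adam learning rate |
| `batch_size`, `epochs` | 128, 20000 | reference training schedule |
| `holdout_fraction`, `n_repetitions` | 0.2, 5 | subsample ensemble |

## Evaluation protocols

In k-fold CV the test positives are zeroed out of the association matrix
and the functional similarity and both GIP kernels are recomputed from the
masked matrix before feature construction and training — the association
matrix feeds the features, so skipping this recomputation would leak test
labels. Sequence similarity and the disease semantic network do not depend
on the matrix and are computed once. Test positives are scored against a
seeded random sample of unknown pairs (1:1 by default; scoring all ~10⁵–10⁶
unknown pairs per fold is configurable but not the default); thresholded
metrics use a 0.5 cutoff, with the F1-maximizing threshold reported
alongside, since no canonical cutoff exists for these scores. AUPR uses
step-wise interpolation (average precision), avoiding the optimistic bias
of trapezoidal interpolation on PR curves.

LOOCV masks each known association in turn, recomputes similarities,
retrains and ranks the left-out pair against all unknown pairs (global) or
the unknown pairs of its disease (local); a disease with no unknown pairs is
skipped with a warning in local mode. The reported AUC is the mean
per-case fraction of candidates ranked below the left-out pair (ties ½).
Full retraining per case is the faithful protocol and the default; a
`warm_start` option trains once on the full data and fine-tunes per case,
trading fidelity for tractability.

Candidate ranking for a disease sorts its unknown pairs by descending score
with deterministic lexicographic tie-breaks.

## Synthetic data

The generator emulates the three real inputs under a planted block model:
round-robin assignment of miRNAs and diseases to `latent_rank` blocks;
pair affinity = block-match indicator + N(0, 0.1²) jitter, thresholded to
exactly `⌈density·nm·nd⌉` positives, then independent label flips at
`noise_rate`. Same-block miRNAs are mutated copies (substitution rate 0.05)
of a shared ancestor sequence of miRNA-typical length (20–24 nt); same-block
diseases attach preferentially under same-block parents within a shared DAG,
depth-bounded. Block-matched pairs left unobserved by the threshold are
recorded as held-out truth: the pairs a good ranker should surface.

Defaults: `nm=60, nd=40, latent_rank=4, density=0.08, n_dags=4, dag_depth=4,
noise_rate=0, seed=7` — sized so that the full CV pipeline runs in minutes
on one CPU while leaving ~190 positives (≈38 per fold).

What the generator does **not** emulate: the heavy-tailed degree
distributions of real association databases, miRNA families with shared seed
regions but divergent arms, multi-parent DAG terms (generated DAGs are
trees), term depth distributions of real ontologies, or annotation bias.
Passing tests on this fixture show that the pipeline recovers planted
low-rank structure under its own assumptions; they do not certify
performance on real HMDD/miRBase/MeSH data.

## Scaled-down experiment sizes

The acceptance script and test suite run the protocols at sizes chosen as a
deliberate compromise between statistical resolution and a desk-scale
runtime: the default 60×40 fixture with 3-repetition 5-fold CV; training at
500 epochs, batch 64, learning rate 1e-3, latent width 16, ensemble of 5.
The shorter schedule uses a larger learning rate than the reference
schedule (2e-4 over 20,000 epochs) because Adam at 2e-4 does not approach
the adversarial equilibrium within 500 epochs at these widths. LOOCV in the
acceptance script uses warm-start fine-tuning (50 epochs per case).

## Numerical conventions and degenerate inputs

- Similarity matrices are symmetrized (`(V + Vᵀ)/2`) and their diagonals
  pinned to 1 after every construction step; `SimilarityMatrix.check`
  enforces symmetry to 1e-9, unit diagonal and [0, 1] bounds.
- Empty disease sets give zero MFS rows; missing sequences give zero MSS
  rows; both fall back to GIP at integration.
- `epochs=0` returns an identical copy of the input model; an all-zero
  association matrix or an empty positive set raises rather than producing
  NaNs; a non-finite training loss raises naming the epoch.
- Score tables are written sorted by descending score with
  (disease, miRNA) lexicographic tie-breaks, so output files are
  reproducible byte-for-byte under a fixed seed.

## Known limitations

- The discriminator-based score approaches 0.5 everywhere as adversarial
  training approaches its equilibrium; the score is informative in the
  pre-equilibrium regime the schedules here target. Scoring by
  reconstruction error or discriminator features is out of scope.
- Whether the reference protocol ensembled or sequentially fine-tuned its
  five 20%-removal repetitions is not specified; ensembling was chosen.
- Model-2 semantic similarity depends on forest size through the
  information-content denominator; on very small forests most terms have
  equal content and the model degenerates toward ancestor-set overlap.
- The evaluation samples negatives (unknown pairs) for the thresholded
  metrics; precision/recall/F1/MCC are therefore estimates at a 1:1
  class balance, not at the true (unknown) prevalence.
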