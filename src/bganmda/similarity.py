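"""Similarity networks for miRNAs and diseases, and per-pair feature vectors.

The pipeline builds, from an association matrix plus sequences and disease
DAGs:

* miRNA sequence similarity (weighted edit distance, min-max rescaled),
* miRNA functional similarity induced by the semantic similarity of the
  associated disease sets,
* two DAG-based disease semantic similarities (decay-based contributions and
  information-content contributions) averaged into a disease network,
* Gaussian interaction-profile (GIP) kernels on both axes of the association
  matrix, and
* integrated miRNA/disease matrices where the GIP kernel fills in pairs for
  which the similarity networks carry no signal.

The per-pair feature vector of (miRNA i, disease j) is the concatenation of
row i of the integrated miRNA matrix and row j of the integrated disease
matrix, length nm + nd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_formats import AssociationMatrix, DiseaseDagForest, EntityIndex, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateInputError",
    "SimilarityParams",
    "SimilarityMatrix",
    "SemanticValueTable",
    "PairFeatureSet",
    "weighted_edit_distance",
    "sequence_similarity",
    "dag_semantic_values",
    "disease_semantic_similarity",
    "disease_similarity_network",
    "functional_similarity",
    "mirna_similarity_network",
    "gip_kernel",
    "integrate_similarity",
    "build_pair_features",
    "build_feature_matrices",
]


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. all-zero association matrix)."""


@dataclass
class SimilarityParams:
    """Tunable knobs of the similarity pipeline.

    alpha           weight of functional vs sequence similarity in the miRNA
                    network (convex combination).
    mu              semantic decay per DAG level in the first disease model.
    lambda_prime    base bandwidth of the GIP kernel.
    sub_cost        substitution cost of the weighted edit distance.
    indel_cost      insertion/deletion cost of the weighted edit distance.
    functional_mode 'intersection' sums disease contributions over the
                    intersection of the two associated-disease sets;
                    'union_max' sums each set's diseases against the other
                    set (the classical functional-similarity form).
    gip_norm        'squared' normalizes the bandwidth by the mean squared
                    profile norm, 'linear' by the mean norm.
    """

    alpha: float = 0.6
    mu: float = 0.5
    lambda_prime: float = 1.0
    sub_cost: int = 2
    indel_cost: int = 1
    functional_mode: str = "intersection"
    gip_norm: str = "squared"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.lambda_prime <= 0:
            raise ValueError(f"lambda_prime must be positive, got {self.lambda_prime}")
        if self.sub_cost <= 0 or self.indel_cost <= 0:
            raise ValueError("edit costs must be positive")
        if self.functional_mode not in ("intersection", "union_max"):
            raise ValueError(f"unknown functional_mode {self.functional_mode!r}")
        if self.gip_norm not in ("squared", "linear"):
            raise ValueError(f"unknown gip_norm {self.gip_norm!r}")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    index: EntityIndex
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"{self.kind}: shape {self.values.shape} does not match index size {n}"
            )

    def check(self, atol: float = 1e-9) -> None:
        v = self.values
        if np.abs(v - v.T).max(initial=0.0) > atol:
            raise ValueError(f"{self.kind}: matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError(f"{self.kind}: diagonal not 1")
        if v.min(initial=1.0) < -atol or v.max(initial=0.0) > 1 + atol:
            raise ValueError(f"{self.kind}: entries outside [0, 1]")


def weighted_edit_distance(s1: str, s2: str, sub_cost: int = 2, indel_cost: int = 1) -> int:
    """Minimum cost of turning ``s1`` into ``s2`` with weighted edit operations.

    Substitution costs ``sub_cost``; insertion and deletion each cost
    ``indel_cost``.  Classic dynamic program, symmetric in its arguments.
    """
    n, m = len(s1), len(s2)
    if n == 0:
        return m * indel_cost
    if m == 0:
        return n * indel_cost
    prev = [j * indel_cost for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * indel_cost] + [0] * m
        c1 = s1[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if c1 == s2[j - 1] else sub_cost)
            cur[j] = min(sub, prev[j] + indel_cost, cur[j - 1] + indel_cost)
        prev = cur
    return prev[m]


def sequence_similarity(
    seqs: SequenceSet, index: EntityIndex, params: SimilarityParams | None = None
) -> SimilarityMatrix:
    """miRNA sequence similarity from the weighted edit distance.

    Raw score for a pair is ``1 - x / (len_i + len_j)`` where ``x`` is the
    weighted edit distance; with costs (sub=2, indel=1) the distance never
    exceeds the length sum, so the raw score lies in [0, 1].  Off-diagonal
    entries are then min-max rescaled (over pairs where both sequences are
    known); the diagonal is pinned to 1 and pairs involving a missing
    sequence are set to 0.
    """
    params = params or SimilarityParams()
    n = len(index)
    have = [seqs.get_for(name) for name in index.names]
    if all(s is None for s in have):
        raise DegenerateInputError("no indexed miRNA has a sequence")
    n_missing = sum(s is None for s in have)
    if n_missing:
        logger.warning("%d indexed miRNA(s) lack a sequence; their rows are 0", n_missing)

    raw = np.zeros((n, n))
    known = np.array([s is not None for s in have])
    for i in range(n):
        if have[i] is None:
            continue
        for j in range(i + 1, n):
            if have[j] is None:
                continue
            x = weighted_edit_distance(have[i], have[j], params.sub_cost, params.indel_cost)
            raw[i, j] = raw[j, i] = 1.0 - x / (len(have[i]) + len(have[j]))

    values = np.zeros((n, n))
    mask = np.outer(known, known)
    np.fill_diagonal(mask, False)
    if mask.any():
        off = raw[mask]
        lo, hi = off.min(), off.max()
        if hi > lo:
            values[mask] = (raw[mask] - lo) / (hi - lo)
        else:  # constant raw scores: rescaling is undefined, keep them as-is
            values[mask] = np.clip(raw[mask], 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, index, "MSS")


@dataclass
class SemanticValueTable:
    """Per-disease ancestor contribution maps and semantic values for one model."""

    model: int
    contributions: dict[str, dict[str, float]] = field(default_factory=dict)
    sv: dict[str, float] = field(default_factory=dict)

    def contribution(self, disease: str) -> dict[str, float]:
        if disease not in self.contributions:
            raise KeyError(f"disease not in semantic table: {disease!r}")
        return self.contributions[disease]


def _decay_contributions(forest: DiseaseDagForest, disease: str, mu: float) -> dict[str, float]:
    """Decay-model contribution of every ancestor of ``disease`` (self = 1).

    An ancestor's contribution is ``mu`` times the maximum contribution of
    its children on paths toward the disease; merged by max across DAGs when
    the disease sits in several.
    """
    merged: dict[str, float] = {}
    for gid, anc in forest.ancestors_with_self(disease).items():
        g = forest.dags[gid]
        contrib: dict[str, float] = {}

        def value(node: str) -> float:
            if node in contrib:
                return contrib[node]
            if node == disease:
                contrib[node] = 1.0
            else:
                kids = [v for v in g.successors(node) if v in anc]
                contrib[node] = mu * max(value(v) for v in kids)
            return contrib[node]

        for node in anc:
            value(node)
        for node, c in contrib.items():
            merged[node] = max(merged.get(node, 0.0), c)
    return merged


def dag_semantic_values(
    forest: DiseaseDagForest, model: int, params: SimilarityParams | None = None
) -> SemanticValueTable:
    """Semantic contribution maps and values for every disease in the forest.

    Model 1: each ancestor contributes a factor decayed by ``mu`` per level
    below, the disease itself contributing 1; the semantic value is the sum.
    Model 2: each term contributes its information content
    ``-ln(NG(d) / n)`` where ``NG(d)`` is the number of DAGs containing it
    and ``n`` the number of distinct diseases in the forest; terms appearing
    in fewer DAGs (more specific) contribute more.
    """
    params = params or SimilarityParams()
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model}")
    table = SemanticValueTable(model=model)
    n_total = len(forest.diseases)
    for disease in sorted(forest.diseases):
        if model == 1:
            contrib = _decay_contributions(forest, disease, params.mu)
        else:
            terms = set().union(*forest.ancestors_with_self(disease).values())
            contrib = {
                t: -np.log(len(forest.membership[t]) / n_total) for t in terms
            }
        table.contributions[disease] = contrib
        table.sv[disease] = float(sum(contrib.values()))
    return table


def disease_semantic_similarity(
    forest: DiseaseDagForest,
    index: EntityIndex,
    model: int,
    params: SimilarityParams | None = None,
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity under one of the two models.

    For diseases sharing ancestors, similarity is the summed joint
    contribution of the shared terms over the sum of the two semantic
    values.  Diseases absent from the forest get zero rows (diagonal 1).
    Model-2 ratios are clipped to [0, 1] (contributions are unnormalized
    information contents).
    """
    table = dag_semantic_values(forest, model, params)
    n = len(index)
    values = np.zeros((n, n))
    names = index.names
    present = [name in forest for name in names]
    n_clipped = 0
    for i in range(n):
        if not present[i]:
            continue
        ci, svi = table.contributions[names[i]], table.sv[names[i]]
        for j in range(i + 1, n):
            if not present[j]:
                continue
            cj, svj = table.contributions[names[j]], table.sv[names[j]]
            shared = ci.keys() & cj.keys()
            if not shared or svi + svj == 0:
                continue
            s = sum(ci[x] + cj[x] for x in shared) / (svi + svj)
            if s > 1.0:
                n_clipped += 1
                s = 1.0
            values[i, j] = values[j, i] = s
    if n_clipped:
        logger.info("model-%d semantic similarity: clipped %d value(s) to 1", model, n_clipped)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, index, f"DSS{model}")


def disease_similarity_network(
    dss1: SimilarityMatrix, dss2: SimilarityMatrix
) -> SimilarityMatrix:
    """Elementwise mean of the two disease semantic similarity matrices."""
    if dss1.index != dss2.index:
        raise ValueError("disease semantic matrices have mismatched indices")
    values = (dss1.values + dss2.values) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, dss1.index, "DSN")


def functional_similarity(
    bm: AssociationMatrix,
    dsn: SimilarityMatrix,
    params: SimilarityParams | None = None,
) -> SimilarityMatrix:
    """miRNA functional similarity induced by associated-disease semantics.

    For each miRNA, its disease set D(m) is the set of diseases with a known
    association.  A disease's similarity to a set is the max of its network
    similarity to any member.  ``intersection`` mode sums the two set
    similarities of each disease in D(m_i) ∩ D(m_j); ``union_max`` sums each
    disease of D(m_i) against D(m_j) and vice versa.  Both are divided by
    |D(m_i)| + |D(m_j)|.  miRNAs with an empty disease set get zero rows.
    """
    params = params or SimilarityParams()
    if dsn.index != bm.disease_index:
        raise ValueError("disease network index does not match association matrix")
    B = bm.bm.astype(bool)  # (nd, nm); column m is D(m)
    nm = bm.nm
    sizes = B.sum(axis=0).astype(float)  # |D(m)|

    # col_max[d, m] = max similarity of disease d to any disease in D(m)
    col_max = np.zeros((bm.nd, nm))
    for m in range(nm):
        if sizes[m] > 0:
            col_max[:, m] = dsn.values[:, B[:, m]].max(axis=1)

    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        if params.functional_mode == "intersection":
            # sum over d in D(mi) ∩ D(mj) of col_max[d,i] + col_max[d,j]
            t = (B * col_max).T @ B  # t[i,j] = sum_{d in Di∩Dj} col_max[d,i]
            values = np.where(denom > 0, (t + t.T) / denom, 0.0)
        else:
            # sum_{d in Di} col_max[d,j] + sum_{d in Dj} col_max[d,i]
            t = B.T @ col_max  # t[i,j] = sum_{d in Di} col_max[d,j]
            values = np.where(denom > 0, (t + t.T) / denom, 0.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    empty = sizes == 0
    values[empty, :] = 0.0
    values[:, empty] = 0.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, bm.mirna_index, "MFS")


def mirna_similarity_network(
    mfs: SimilarityMatrix, mss: SimilarityMatrix, alpha: float = 0.6
) -> SimilarityMatrix:
    """Convex combination of functional and sequence miRNA similarity."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if mfs.index != mss.index:
        raise ValueError("miRNA similarity matrices have mismatched indices")
    values = alpha * mfs.values + (1.0 - alpha) * mss.values
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, mfs.index, "MSN")


def gip_kernel(
    bm: AssociationMatrix, axis: str, params: SimilarityParams | None = None
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel on one axis of the association matrix.

    The profile of a miRNA is its column of the matrix, of a disease its
    row.  Kernel entry is ``exp(-lam * ||p_i - p_j||^2)`` with bandwidth
    ``lam = lambda_prime / mean(||p_k||^2)`` (``gip_norm='squared'``) or
    ``lambda_prime / mean(||p_k||)`` (``'linear'``).
    """
    params = params or SimilarityParams()
    if axis not in ("mirna", "disease"):
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    profiles = (bm.bm.T if axis == "mirna" else bm.bm).astype(float)
    index = bm.mirna_index if axis == "mirna" else bm.disease_index
    sq_norms = (profiles**2).sum(axis=1)
    if sq_norms.sum() == 0:
        raise DegenerateInputError("association matrix is all zeros; GIP bandwidth undefined")
    if params.gip_norm == "squared":
        lam = params.lambda_prime / sq_norms.mean()
    else:
        lam = params.lambda_prime / np.sqrt(sq_norms).mean()
    if len(profiles) > 1:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        d2 = np.zeros((1, 1))
    values = np.exp(-lam * d2)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    kind = "MGS" if axis == "mirna" else "DGS"
    return SimilarityMatrix(values, index, kind)


def integrate_similarity(
    msn: SimilarityMatrix,
    mgs: SimilarityMatrix,
    dsn: SimilarityMatrix,
    dgs: SimilarityMatrix,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Fill similarity-network zeros with the GIP kernel, per entity type.

    A network similarity "exists" where its value is positive; elsewhere the
    GIP kernel value is used.  Applied independently to the miRNA and
    disease sides.
    """
    if msn.index != mgs.index:
        raise ValueError("miRNA matrices have mismatched indices")
    if dsn.index != dgs.index:
        raise ValueError("disease matrices have mismatched indices")
    ms = np.where(msn.values > 0, msn.values, mgs.values)
    ds = np.where(dsn.values > 0, dsn.values, dgs.values)
    for v in (ms, ds):
        v[:] = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
    return (
        SimilarityMatrix(ms, msn.index, "MS"),
        SimilarityMatrix(ds, dsn.index, "DS"),
    )


class PairFeatureSet:
    """Lazily materialized per-pair feature vectors.

    The feature vector of (miRNA i, disease j) is the concatenation of the
    integrated miRNA similarity row i (length nm) and the integrated disease
    similarity row j (length nd); its label is the association matrix entry.
    """

    def __init__(
        self,
        ms: SimilarityMatrix,
        ds: SimilarityMatrix,
        bm: AssociationMatrix,
        pairs: list[tuple[int, int]] | None = None,
    ):
        if ms.index != bm.mirna_index or ds.index != bm.disease_index:
            raise ValueError("similarity indices do not match association matrix")
        self.ms = ms
        self.ds = ds
        self.bm = bm
        self._pairs = pairs  # (mirna_id, disease_id); None = all nm x nd

    @property
    def n_features(self) -> int:
        return self.bm.nm + self.bm.nd

    @property
    def pairs(self) -> list[tuple[int, int]]:
        if self._pairs is None:
            return [(i, j) for i in range(self.bm.nm) for j in range(self.bm.nd)]
        return list(self._pairs)

    def __len__(self) -> int:
        if self._pairs is None:
            return self.bm.nm * self.bm.nd
        return len(self._pairs)

    def vector(self, mirna: int | str, disease: int | str) -> np.ndarray:
        i = mirna if isinstance(mirna, int) else self.bm.mirna_index.position(mirna)
        j = disease if isinstance(disease, int) else self.bm.disease_index.position(disease)
        return np.concatenate([self.ms.values[i], self.ds.values[j]])

    def label(self, mirna_id: int, disease_id: int) -> int:
        return int(self.bm.bm[disease_id, mirna_id])

    def matrix(self, pairs: Iterable[tuple[int, int]] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack feature vectors and labels for the given (mirna, disease) id pairs."""
        plist = self.pairs if pairs is None else list(pairs)
        if not plist:
            return np.zeros((0, self.n_features)), np.zeros(0, dtype=int)
        mi = np.fromiter((p[0] for p in plist), dtype=int, count=len(plist))
        dj = np.fromiter((p[1] for p in plist), dtype=int, count=len(plist))
        X = np.hstack([self.ms.values[mi], self.ds.values[dj]])
        y = self.bm.bm[dj, mi].astype(int)
        return X, y

    def __iter__(self) -> Iterator[tuple[int, int, np.ndarray, int]]:
        for i, j in self.pairs:
            yield i, j, self.vector(i, j), self.label(i, j)


def build_pair_features(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    bm: AssociationMatrix,
    pairs: list[tuple[int, int]] | None = None,
) -> PairFeatureSet:
    """Assemble the lazy per-pair feature set from the integrated matrices."""
    return PairFeatureSet(ms, ds, bm, pairs)


def build_feature_matrices(
    bm: AssociationMatrix,
    mss: SimilarityMatrix,
    dsn: SimilarityMatrix,
    params: SimilarityParams | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated (MS, DS) from the association-dependent pipeline stages.

    Sequence similarity and the disease semantic network do not depend on
    the association matrix and are passed in precomputed; the functional
    similarity and both GIP kernels are recomputed here, which is what
    cross-validation folds call after masking test associations.
    """
    params = params or SimilarityParams()
    mfs = functional_similarity(bm, dsn, params)
    msn = mirna_similarity_network(mfs, mss, params.alpha)
    mgs = gip_kernel(bm, "mirna", params)
    dgs = gip_kernel(bm, "disease", params)
    return integrate_similarity(msn, mgs, dsn, dgs)
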