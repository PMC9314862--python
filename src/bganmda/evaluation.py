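"""Cross-validation protocols and the metric panel.

Two protocols are provided over a dataset of known associations:

* repeated k-fold CV: the known (label-1) pairs are partitioned into k
  folds; for each fold the test positives are zeroed out of the association
  matrix and every association-dependent similarity (functional similarity,
  both GIP kernels, the integration) is recomputed from the masked matrix,
  so no test information leaks into the features; the model is trained on
  the remaining positives and the test positives are scored against a
  seeded random sample of unknown pairs;
* global/local leave-one-out CV: each known pair is left out in turn, the
  matrix is masked and similarities recomputed, and the left-out pair is
  ranked either against all unknown pairs (global) or against the unknown
  pairs of the same disease (local).

The metric panel reports AUC, AUPR, F1, recall, precision and MCC; the
thresholded metrics use a configurable cutoff (default 0.5) and the
F1-maximizing threshold is reported alongside.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .bgan_model import (
    NetworkSpec,
    TrainConfig,
    build_networks,
    score_vectors,
    train,
)
from .io_formats import AssociationMatrix, DiseaseDagForest, ScoredPair, SequenceSet
from .similarity import (
    PairFeatureSet,
    SimilarityMatrix,
    SimilarityParams,
    build_feature_matrices,
    disease_semantic_similarity,
    disease_similarity_network,
    sequence_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "Dataset",
    "MetricPanel",
    "FoldPlan",
    "RankResult",
    "CVResult",
    "roc_auc",
    "metric_panel",
    "make_fold_plan",
    "five_fold_cv",
    "loocv",
    "rank_candidates",
]


class UndefinedMetricError(ValueError):
    """Metric requested on degenerate input (e.g. a single class)."""


@dataclass
class Dataset:
    """The three inputs of the pipeline, bundled."""

    bm: AssociationMatrix
    seqs: SequenceSet
    forest: DiseaseDagForest

    def base_similarities(
        self, params: SimilarityParams
    ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Sequence similarity and disease semantic network.

        These do not depend on the association matrix and are therefore
        computed once and reused across CV folds.
        """
        mss = sequence_similarity(self.seqs, self.bm.mirna_index, params)
        dss1 = disease_semantic_similarity(self.forest, self.bm.disease_index, 1, params)
        dss2 = disease_semantic_similarity(self.forest, self.bm.disease_index, 2, params)
        dsn = disease_similarity_network(dss1, dss2)
        return mss, dsn


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals Mann-Whitney concordance (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(_skm.roc_auc_score(labels, scores))


@dataclass
class MetricPanel:
    auc: float
    aupr: float
    f1: float
    recall: float
    precision: float
    mcc: float
    threshold: float
    best_f1_threshold: float

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


def metric_panel(scores, labels, threshold: float = 0.5) -> MetricPanel:
    """Full metric panel at a score threshold.

    AUPR is the area under the precision-recall curve with step-wise
    interpolation (no trapezoids, avoiding optimistic bias); thresholded
    metrics come from the confusion matrix at ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(scores, labels)
    aupr = float(_skm.average_precision_score(labels, scores))

    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    mcc = float(_skm.matthews_corrcoef(labels, pred))

    prec_c, rec_c, thr_c = _skm.precision_recall_curve(labels, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_c = np.where(prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0)
    best = int(np.argmax(f1_c[:-1])) if len(thr_c) else 0
    best_thr = float(thr_c[min(best, len(thr_c) - 1)]) if len(thr_c) else threshold

    return MetricPanel(auc, aupr, f1, recall, precision, mcc, threshold, best_thr)


@dataclass
class FoldPlan:
    """Disjoint, exhaustive partition of the known-association pair ids."""

    folds: list[np.ndarray]
    repetition: int
    seed: int


def make_fold_plan(n_positives: int, k: int, seed: int, repetition: int = 0) -> FoldPlan:
    if n_positives < k:
        raise ValueError(f"need at least k={k} positives, got {n_positives}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, repetition]))
    order = rng.permutation(n_positives)
    return FoldPlan([np.sort(chunk) for chunk in np.array_split(order, k)],
                    repetition, seed)


@dataclass
class CVResult:
    panels: list[MetricPanel]          # one per repetition (fold scores pooled)
    fold_aucs: list[float]             # per (repetition, fold)
    k: int = 5
    n_repetitions: int = 1

    @property
    def mean_auc(self) -> float:
        return float(np.mean([p.auc for p in self.panels]))


def _sample_negatives(
    bm: AssociationMatrix, n: int, rng: np.random.Generator,
    exclude: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Random unknown (mirna, disease) pairs from the unmasked matrix."""
    rows, cols = np.nonzero(bm.bm == 0)
    unknown = [(int(i), int(j)) for j, i in zip(rows.tolist(), cols.tolist())]
    if exclude:
        unknown = [p for p in unknown if p not in exclude]
    if n >= len(unknown):
        return unknown
    take = rng.choice(len(unknown), size=n, replace=False)
    return [unknown[t] for t in take]


def five_fold_cv(
    dataset: Dataset,
    sim_params: SimilarityParams | None = None,
    train_cfg: TrainConfig | None = None,
    latent_dim: int = 16,
    k: int = 5,
    n_repetitions: int = 1,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation with per-fold similarity recomputation.

    Per fold, the test positives are zeroed in the association matrix and
    the functional similarity and both GIP kernels are recomputed from the
    masked matrix before training.  Test positives are scored against
    ``negative_ratio`` times as many seeded random unknown pairs; metrics
    are pooled over folds within each repetition.
    """
    sim_params = sim_params or SimilarityParams()
    train_cfg = train_cfg or TrainConfig()
    positives = [(i, j) for j, i in dataset.bm.positive_pairs()]  # (mirna, disease)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} known associations")
    mss, dsn = dataset.base_similarities(sim_params)

    panels: list[MetricPanel] = []
    fold_aucs: list[float] = []
    for rep in range(n_repetitions):
        plan = make_fold_plan(len(positives), k, seed, rep)
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 10_007]))
        rep_scores: list[float] = []
        rep_labels: list[int] = []
        for fold_id, test_ids in enumerate(plan.folds):
            test_pairs = [positives[t] for t in test_ids]
            train_pairs = [p for t, p in enumerate(positives) if t not in set(test_ids.tolist())]
            masked = dataset.bm.masked((j, i) for i, j in test_pairs)
            ms, ds = build_feature_matrices(masked, mss, dsn, sim_params)
            feats = PairFeatureSet(ms, ds, masked)
            X_train, _ = feats.matrix(train_pairs)
            spec = NetworkSpec(input_dim=feats.n_features, latent_dim=latent_dim)
            fold_seed = int(np.random.SeedSequence([seed, rep, fold_id]).generate_state(1)[0] % (2**31))
            cfg = TrainConfig(
                lr=train_cfg.lr, batch_size=train_cfg.batch_size,
                epochs=train_cfg.epochs, holdout_fraction=train_cfg.holdout_fraction,
                n_repetitions=train_cfg.n_repetitions, betas=train_cfg.betas,
                seed=fold_seed,
            )
            model = build_networks(spec, seed=fold_seed)
            model = train(model, X_train, cfg)

            negatives = _sample_negatives(
                dataset.bm, int(round(negative_ratio * len(test_pairs))), rng,
            )
            eval_pairs = test_pairs + negatives
            X_eval, _ = feats.matrix(eval_pairs)
            scores = score_vectors(model, X_eval)
            labels = [1] * len(test_pairs) + [0] * len(negatives)
            fold_aucs.append(roc_auc(scores, labels))
            rep_scores.extend(scores.tolist())
            rep_labels.extend(labels)
        panels.append(metric_panel(np.array(rep_scores), np.array(rep_labels)))
    return CVResult(panels, fold_aucs, k=k, n_repetitions=n_repetitions)


@dataclass
class RankResult:
    """Per left-out association: its rank among the candidate set."""

    mode: str
    ranks: list[dict] = field(default_factory=list)  # mirna, disease, rank, n_candidates
    auc: float = float("nan")


def loocv(
    dataset: Dataset,
    sim_params: SimilarityParams | None = None,
    train_cfg: TrainConfig | None = None,
    latent_dim: int = 16,
    mode: str = "global",
    seed: int = 0,
    warm_start: bool = False,
    warm_epochs: int | None = None,
) -> RankResult:
    """Leave-one-association-out ranking.

    Each known pair is masked in turn, similarities recomputed and the model
    retrained, then the left-out pair is ranked among all unknown pairs
    (``global``) or the unknown pairs of its disease (``local``).  With
    ``warm_start`` a model trained once on the full data seeds each per-case
    retrain, which then runs ``warm_epochs`` epochs (default a tenth of the
    configured epochs).

    The reported AUC is the mean over cases of the fraction of candidates
    ranked below the left-out pair (ties counted 1/2) — the Mann-Whitney
    statistic of the rank list.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    sim_params = sim_params or SimilarityParams()
    train_cfg = train_cfg or TrainConfig()
    mss, dsn = dataset.base_similarities(sim_params)
    positives = [(i, j) for j, i in dataset.bm.positive_pairs()]
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    unknown_mask = dataset.bm.bm == 0  # (nd, nm)

    base_model = None
    if warm_start:
        ms, ds = build_feature_matrices(dataset.bm, mss, dsn, sim_params)
        feats = PairFeatureSet(ms, ds, dataset.bm)
        X_all, _ = feats.matrix(positives)
        spec = NetworkSpec(input_dim=feats.n_features, latent_dim=latent_dim)
        base_cfg = TrainConfig(
            lr=train_cfg.lr, batch_size=train_cfg.batch_size, epochs=train_cfg.epochs,
            holdout_fraction=train_cfg.holdout_fraction,
            n_repetitions=train_cfg.n_repetitions, betas=train_cfg.betas, seed=seed,
        )
        base_model = train(build_networks(spec, seed=seed), X_all, base_cfg)
        if warm_epochs is None:
            warm_epochs = max(1, train_cfg.epochs // 10)

    result = RankResult(mode=mode)
    per_case_auc: list[float] = []
    for case_id, (i, j) in enumerate(positives):
        masked = dataset.bm.masked([(j, i)])
        ms, ds = build_feature_matrices(masked, mss, dsn, sim_params)
        feats = PairFeatureSet(ms, ds, masked)
        train_pairs = [p for p in positives if p != (i, j)]
        X_train, _ = feats.matrix(train_pairs)
        spec = NetworkSpec(input_dim=feats.n_features, latent_dim=latent_dim)
        case_seed = int(np.random.SeedSequence([seed, case_id]).generate_state(1)[0] % (2**31))
        cfg = TrainConfig(
            lr=train_cfg.lr, batch_size=train_cfg.batch_size,
            epochs=warm_epochs if warm_start else train_cfg.epochs,
            holdout_fraction=train_cfg.holdout_fraction,
            n_repetitions=1, betas=train_cfg.betas, seed=case_seed,
        )
        init = copy.deepcopy(base_model) if warm_start else build_networks(spec, seed=case_seed)
        model = train(init, X_train, cfg)

        if mode == "global":
            rows, cols = np.nonzero(unknown_mask)
            candidates = [(int(ci), int(cj)) for cj, ci in zip(rows.tolist(), cols.tolist())]
        else:
            cand_m = np.nonzero(unknown_mask[j])[0]
            candidates = [(int(ci), j) for ci in cand_m]
            if not candidates:
                logger.warning(
                    "local LOOCV: disease %s has no unknown pairs; case skipped",
                    dataset.bm.disease_index.names[j],
                )
                continue
        X_eval, _ = feats.matrix([(i, j)] + candidates)
        scores = score_vectors(model, X_eval)
        s, cand_scores = scores[0], scores[1:]
        greater = int((cand_scores > s).sum())
        ties = int((cand_scores == s).sum())
        rank = 1 + greater + 0.5 * ties
        result.ranks.append({
            "mirna": dataset.bm.mirna_index.names[i],
            "disease": dataset.bm.disease_index.names[j],
            "rank": rank,
            "n_candidates": len(candidates),
        })
        per_case_auc.append((int((cand_scores < s).sum()) + 0.5 * ties) / len(candidates))
    result.auc = float(np.mean(per_case_auc)) if per_case_auc else float("nan")
    return result


def rank_candidates(scores: list[ScoredPair], disease: str, k: int) -> list[ScoredPair]:
    """Top-k unknown-pair candidates for one disease, by descending score.

    Ties are broken lexicographically by (disease, mirna) for determinism.
    """
    from .io_formats import normalize_name

    key = normalize_name(disease)
    if not any(r.disease == key for r in scores):
        raise KeyError(f"disease not in score list: {disease!r}")
    pool = [r for r in scores if r.disease == key and (r.label is None or r.label == 0)]
    pool.sort(key=lambda r: (-r.score, r.disease, r.mirna))
    return pool[:k]
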