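"""Evaluation protocol: negative sampling, 5-fold splits, metrics, ranking.

Known associations are positives; an equal number of unobserved pairs are
drawn uniformly as presumed negatives.  Both lists are shuffled and split
into five folds; each rotation trains on four folds of each and scores the
held-out fold as an independent test set, with the test positives optionally
masked out of the network the encoder sees (leakage control).  Metrics are
the usual seven: AUC, AUPR, F1, accuracy, specificity, precision, recall.

AUC uses the rank (Mann-Whitney) formulation with ties counted 0.5; AUPR
uses step-wise integration of the tie-grouped precision-recall curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .hetnet import AssociationMatrix, build_association_matrix, build_heterogeneous_network, mask_test_edges
from .pair_cnn import CNNConfig, CNNParams, PairPrediction, predict_pairs, train_classifier
from .similarity import SimilarityMatrix
from .vgae import NodeEmbeddings, VGAEConfig, train_vgae

__all__ = [
    "LabelledPairSet",
    "CVSplit",
    "MetricsReport",
    "PipelineConfig",
    "sample_negatives",
    "make_cv_split",
    "auc_score",
    "aupr_score",
    "confusion_and_metrics",
    "roc_curve_points",
    "pr_curve_points",
    "run_cross_validation",
    "rank_candidates",
    "mean_report",
]

METRIC_NAMES = ("auc", "aupr", "f1", "accuracy", "specificity", "precision", "recall")


@dataclass
class LabelledPairSet:
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]

    def __post_init__(self) -> None:
        pos, neg = set(self.positives), set(self.negatives)
        if len(pos) != len(self.positives) or len(neg) != len(self.negatives):
            raise ValueError("duplicate pairs within a label list")
        overlap = pos & neg
        if overlap:
            raise ValueError(f"pair {next(iter(overlap))} appears as both positive and negative")


@dataclass
class CVSplit:
    """k disjoint folds of positives and negatives plus rotation views."""

    pos_folds: list[list[tuple[str, str]]]
    neg_folds: list[list[tuple[str, str]]]

    @property
    def k(self) -> int:
        return len(self.pos_folds)

    def rotation(self, r: int):
        """(cv_pos, cv_neg, test_pos, test_neg) with fold r held out."""
        cv_pos = [p for i, f in enumerate(self.pos_folds) if i != r for p in f]
        cv_neg = [p for i, f in enumerate(self.neg_folds) if i != r for p in f]
        return cv_pos, cv_neg, list(self.pos_folds[r]), list(self.neg_folds[r])


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    auc: float
    aupr: float

    tpr: float = field(init=False)
    fpr: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        self.tpr = tp / (tp + fn) if tp + fn else 0.0
        self.fpr = fp / (tn + fp) if tn + fp else 0.0
        self.recall = self.tpr
        self.precision = tp / (tp + fp) if tp + fp else 0.0
        self.specificity = tn / (tn + fp) if tn + fp else 0.0
        total = tp + fp + tn + fn
        self.accuracy = (tp + tn) / total if total else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "threshold": self.threshold,
            **{m: getattr(self, m) for m in METRIC_NAMES},
        }


def sample_negatives(m_rd: AssociationMatrix, count: int, seed: int) -> list[tuple[str, str]]:
    """Uniform sample without replacement from the zero cells of m_rd."""
    zero_i, zero_j = np.nonzero(m_rd.values == 0)
    available = len(zero_i)
    if count > available:
        raise ValueError(f"requested {count} negatives but only {available} unobserved pairs exist")
    rng = np.random.default_rng(seed)
    sel = rng.choice(available, size=count, replace=False)
    return [(m_rd.drug_ids[zero_i[s]], m_rd.disease_ids[zero_j[s]]) for s in sel]


def make_cv_split(pairs: LabelledPairSet, k: int = 5, seed: int = 0) -> CVSplit:
    """Seeded shuffle then round-robin folding of positives and negatives."""
    if len(pairs.positives) < k or len(pairs.negatives) < k:
        raise ValueError(f"need at least k={k} pairs in each list")
    rng = np.random.default_rng(seed)

    def fold(items):
        perm = rng.permutation(len(items))
        folds = [[] for _ in range(k)]
        for pos, idx in enumerate(perm):
            folds[pos % k].append(items[idx])
        return folds

    return CVSplit(fold(pairs.positives), fold(pairs.negatives))


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: mean normalized rank of positives, ties counted 0.5."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class labels", stacklevel=2)
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-integrated precision-recall area over tie-grouped thresholds."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        warnings.warn("AUPR undefined for single-class labels", stacklevel=2)
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group indices where the threshold actually changes
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # step integration: area += (R_i - R_{i-1}) * P_i
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


def confusion_and_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold at ``score >= threshold`` and compute the seven metrics."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return MetricsReport(tp, fp, tn, fn, threshold,
                         auc=auc_score(labels, scores), aupr=aupr_score(labels, scores))


def roc_curve_points(labels, scores):
    """(fpr, tpr, threshold) triples over distinct descending thresholds."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    points = [(0.0, 0.0, np.inf)]
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = float(np.sum(pred * labels))
        fp = float(np.sum(pred * (1 - labels)))
        points.append((fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0, thr))
    return points


def pr_curve_points(labels, scores):
    """(recall, precision, threshold) triples over distinct descending thresholds."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    points = []
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = float(np.sum(pred * labels))
        points.append((tp / n_pos if n_pos else 0.0, tp / pred.sum(), thr))
    return points


@dataclass
class PipelineConfig:
    """End-to-end settings for one cross-validated experiment."""

    vgae: VGAEConfig = field(default_factory=VGAEConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    k_folds: int = 5
    threshold: float = 0.5
    mask_test: bool = True  # remove test positives from the network the encoder sees


def _train_and_score(m_r, m_d, cv_pos, cv_neg, test_pos, test_neg,
                     drug_ids, disease_ids, config, seed):
    train_matrix = build_association_matrix(cv_pos + test_pos, drug_ids, disease_ids)
    if config.mask_test:
        train_matrix = mask_test_edges(train_matrix, test_pos)
    net = build_heterogeneous_network(m_r, m_d, train_matrix)
    _, emb, _ = train_vgae(net, config.vgae, seed=seed)
    pairs = cv_pos + cv_neg
    labels = [1] * len(cv_pos) + [0] * len(cv_neg)
    params, _ = train_classifier(emb, pairs, labels, drug_ids, disease_ids,
                                 config.cnn, seed=seed + 1)
    test_pairs = test_pos + test_neg
    test_labels = [1] * len(test_pos) + [0] * len(test_neg)
    preds = predict_pairs(emb, params, test_pairs, drug_ids, disease_ids, test_labels)
    return preds, test_labels, emb, params


def run_cross_validation(
    m_r: SimilarityMatrix,
    m_d: SimilarityMatrix,
    positives: list[tuple[str, str]],
    config: PipelineConfig | None = None,
    seed: int = 0,
    negatives: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, float], list[MetricsReport]]:
    """Full k-fold protocol; returns (unweighted mean metrics, per-rotation reports).

    Negatives are sampled once for the whole experiment (1:1 with positives)
    unless supplied.  Each rotation rebuilds the heterogeneous network with
    the test positives masked (by default), trains the encoder and classifier
    on the cross-validation folds, and scores the independent test fold.
    """
    config = config or PipelineConfig()
    drug_ids, disease_ids = m_r.ids, m_d.ids
    full = build_association_matrix(positives, drug_ids, disease_ids)
    if negatives is None:
        negatives = sample_negatives(full, len(positives), seed=seed)
    pairset = LabelledPairSet(list(positives), list(negatives))
    split = make_cv_split(pairset, k=config.k_folds, seed=seed)
    reports: list[MetricsReport] = []
    for r in range(split.k):
        cv_pos, cv_neg, test_pos, test_neg = split.rotation(r)
        try:
            preds, test_labels, _, _ = _train_and_score(
                m_r, m_d, cv_pos, cv_neg, test_pos, test_neg,
                drug_ids, disease_ids, config, seed=seed * 10 + r)
        except Exception as exc:
            raise RuntimeError(f"cross-validation rotation {r} failed: {exc}") from exc
        scores = [p.probability for p in preds]
        reports.append(confusion_and_metrics(test_labels, scores, config.threshold))
    return mean_report(reports), reports


def mean_report(reports: list[MetricsReport]) -> dict[str, float]:
    """Unweighted mean of the seven metrics across rotations."""
    return {m: float(np.mean([getattr(rep, m) for rep in reports])) for m in METRIC_NAMES}


def rank_candidates(
    emb: NodeEmbeddings,
    params: CNNParams,
    query: str,
    drug_ids: list[str],
    disease_ids: list[str],
    known: AssociationMatrix | None = None,
    exclude_known: bool = False,
    top: int | None = None,
) -> list[PairPrediction]:
    """Score every drug against one disease and sort by probability.

    Descending probability with a stable tie-break on drug id; drugs already
    associated in ``known`` can be excluded (the repositioning query).
    """
    if query not in disease_ids:
        raise KeyError(f"unknown disease id {query!r}")
    drugs = list(drug_ids)
    if exclude_known:
        if known is None:
            raise ValueError("exclude_known requires the known association matrix")
        j = known.disease_ids.index(query)
        known_drugs = {known.drug_ids[i] for i in np.nonzero(known.values[:, j])[0]}
        drugs = [d for d in drugs if d not in known_drugs]
    preds = predict_pairs(emb, params, [(d, query) for d in drugs], drug_ids, disease_ids)
    preds.sort(key=lambda p: (-p.probability, p.drug_id))
    return preds[:top] if top is not None else preds
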