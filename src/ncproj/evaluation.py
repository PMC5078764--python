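"""Evaluation protocol: LOOCV, ROC/PR curves, ablations, isolated diseases.

Leave-one-out cross validation removes each known association in turn and
rebuilds the *entire* model — the profile Jaccard similarities, the
integrated networks and the projection scores — on the reduced association
matrix, so no information about the held-out link leaks through the
similarity side. The held-out pair's score is a positive; the scores of
all pairs unknown in the full data, computed under the same fold's model,
are that fold's negatives. Pools across folds feed the ROC and
precision-recall curves.

The ROC construction groups tied scores into one threshold step, which
makes the trapezoidal area coincide exactly with the rank-sum (Mann-
Whitney) estimator P(pos > neg) + 0.5 P(pos = neg) — a property the test
suite exploits as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .data import Dataset, ValidationError
from .projection import score_arrays
from .similarity import IntegrationConfig

__all__ = [
    "CurvePoints",
    "FoldRecord",
    "LoocvResult",
    "RankRecord",
    "IsolatedResult",
    "roc_auc",
    "pr_aupr",
    "loocv",
    "run_ablations",
    "ABLATION_TAGS",
    "isolated_disease_eval",
    "rank_unknown",
]

#: Ablation tags in the order they are reported.
ABLATION_TAGS = ("full", "no_family", "no_sn", "mirna_space", "disease_space")


@dataclass(frozen=True)
class CurvePoints:
    """One operating curve: per-threshold x/y coordinates.

    For ROC, x is FPR and y is TPR; for PR, x is recall and y is
    precision. Thresholds descend; x is non-decreasing along the sweep.
    Anchor points (ROC (0,0)/(1,1); the PR zero-recall anchor) carry
    threshold NaN / +inf sentinels.
    """

    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class FoldRecord:
    """One LOOCV fold: the held-out association and how it scored."""

    mirna: str
    disease: str
    score: float
    rank: float  # average rank among the disease's candidate pairs


@dataclass
class LoocvResult:
    fold_records: list[FoldRecord]
    pooled_positive_scores: np.ndarray
    pooled_negative_scores: np.ndarray
    roc: CurvePoints
    pr: CurvePoints
    auc: float
    aupr: float
    config_tag: str = "full"

    @property
    def n_folds(self) -> int:
        return len(self.fold_records)


@dataclass(frozen=True)
class RankRecord:
    rank: int
    mirna: str
    disease: str
    score: float


@dataclass
class IsolatedResult:
    """Ranking of all miRNAs for one fully blinded disease."""

    disease: str
    records: list[RankRecord]
    hidden_mirnas: list[str]
    hidden_ranks: list[float]

    @property
    def mean_rank_percentile(self) -> float:
        """Mean of (rank - 0.5)/n over the hidden true miRNAs.

        0.5 is the expectation under random ranking; smaller is better.
        """
        n = len(self.records)
        return float(np.mean([(r - 0.5) / n for r in self.hidden_ranks]))


# ----------------------------------------------------------------------
# curves


def _threshold_counts(pos: np.ndarray, neg: np.ndarray):
    """Distinct thresholds (descending) and cumulative TP/FP counts."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # number of scores >= t for each distinct threshold t
    tp = len(pos) - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = len(neg) - np.searchsorted(neg_sorted, thresholds, side="left")
    return thresholds, tp.astype(float), fp.astype(float)


def roc_auc(pos, neg) -> tuple[CurvePoints, float]:
    """ROC curve and trapezoidal AUC from two score pools.

    Tied scores enter a threshold group together, so the area equals the
    rank-sum estimator P(pos > neg) + 0.5 P(pos = neg).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score pools must be non-empty")
    thresholds, tp, fp = _threshold_counts(pos, neg)
    tpr = np.concatenate([[0.0], tp / len(pos)])
    fpr = np.concatenate([[0.0], fp / len(neg)])
    thresholds = np.concatenate([[np.inf], thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(thresholds, fpr, tpr), auc


def pr_aupr(pos, neg) -> tuple[CurvePoints, float]:
    """Precision-recall curve and trapezoidal AUPR.

    The curve is anchored at recall 0 with the precision of the highest
    threshold group; tied scores enter together.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0:
        raise ValidationError("positive score pool must be non-empty")
    thresholds, tp, fp = _threshold_counts(pos, neg)
    with np.errstate(invalid="ignore"):
        precision = tp / (tp + fp)
    precision = np.nan_to_num(precision, nan=1.0)
    recall = tp / len(pos)
    # zero-recall anchor at the first group's precision
    recall_full = np.concatenate([[0.0], recall])
    precision_full = np.concatenate([[precision[0]], precision])
    thresholds_full = np.concatenate([[np.inf], thresholds])
    aupr = float(np.trapezoid(precision_full, recall_full))
    return CurvePoints(thresholds_full, recall_full, precision_full), aupr


# ----------------------------------------------------------------------
# LOOCV


def _fold_order(dataset: Dataset) -> list[tuple[int, int]]:
    """Positive cells ordered lexicographically by (disease, miRNA) label."""
    rows, cols = np.nonzero(dataset.as_matrix.values)
    keyed = sorted(
        zip(rows, cols),
        key=lambda rc: (
            dataset.disease_index.labels[rc[1]],
            dataset.mirna_index.labels[rc[0]],
        ),
    )
    return [(int(i), int(j)) for i, j in keyed]


def _average_rank(value: float, others: np.ndarray) -> float:
    """1-based average rank of `value` among itself plus `others`."""
    greater = int(np.sum(others > value))
    equal = int(np.sum(others == value))
    return greater + 1 + equal / 2.0


def loocv(
    dataset: Dataset,
    config: Optional[IntegrationConfig] = None,
    mode: str = "combined",
    shared_negatives: bool = False,
    config_tag: str = "full",
) -> LoocvResult:
    """Leave-one-out cross validation over the known associations.

    For every known association the link is removed, the whole pipeline is
    recomputed on the reduced matrix, and the held-out pair's score enters
    the positive pool. Negatives are the full-data unknown pairs; by
    default they are re-scored under each fold's model and pooled across
    folds. With ``shared_negatives=True`` they are scored once under the
    full-data model — a faster approximation that leaves the positives'
    per-fold treatment unchanged.

    A disease whose only association is held out is handled, not
    rejected: the epsilon substitution keeps its score finite.
    """
    config = config or IntegrationConfig()
    as_full = dataset.as_matrix.values
    n_assoc = int(as_full.sum())
    if n_assoc < 2:
        raise ValidationError("LOOCV requires at least 2 known associations")
    mm = dataset.mm.values
    dd = dataset.dd.values
    fam = dataset.family_values() if config.use_family else None
    neg_mask = as_full == 0
    folds = _fold_order(dataset)

    neg_cols = [np.nonzero(neg_mask[:, j])[0] for j in range(as_full.shape[1])]

    shared_scores = None
    if shared_negatives:
        shared_scores = score_arrays(mm, dd, fam, as_full, config, mode)

    fold_records: list[FoldRecord] = []
    pos_pool = np.empty(n_assoc)
    neg_chunks: list[np.ndarray] = []
    as_work = as_full.astype(np.int8).copy()
    for k, (i, j) in enumerate(folds):
        as_work[i, j] = 0
        scores = score_arrays(mm, dd, fam, as_work, config, mode)
        as_work[i, j] = 1
        s = float(scores[i, j])
        if not np.isfinite(s):
            raise ValidationError(
                f"non-finite fold score for ({dataset.mirna_index.labels[i]},"
                f" {dataset.disease_index.labels[j]})"
            )
        pos_pool[k] = s
        fold_neg_src = shared_scores if shared_negatives else scores
        if not shared_negatives:
            neg_chunks.append(scores[neg_mask])
        disease_negs = fold_neg_src[neg_cols[j], j]
        fold_records.append(
            FoldRecord(
                mirna=dataset.mirna_index.labels[i],
                disease=dataset.disease_index.labels[j],
                score=s,
                rank=_average_rank(s, disease_negs),
            )
        )
    if shared_negatives:
        neg_pool = shared_scores[neg_mask]
    else:
        neg_pool = np.concatenate(neg_chunks) if neg_chunks else np.array([])

    roc, auc = roc_auc(pos_pool, neg_pool)
    pr, aupr = pr_aupr(pos_pool, neg_pool)
    return LoocvResult(
        fold_records=fold_records,
        pooled_positive_scores=pos_pool,
        pooled_negative_scores=neg_pool,
        roc=roc,
        pr=pr,
        auc=auc,
        aupr=aupr,
        config_tag=config_tag,
    )


def run_ablations(
    dataset: Dataset,
    base_config: Optional[IntegrationConfig] = None,
    shared_negatives: bool = False,
    tags=ABLATION_TAGS,
) -> dict[str, LoocvResult]:
    """LOOCV under the five standard configurations.

    full: all components, combined projection. no_family: FAM dropped.
    no_sn: association-profile Jaccard terms dropped. mirna_space /
    disease_space: single-space (cosine) scoring with all components.
    Fold order is identical across tags.
    """
    base = base_config or IntegrationConfig()
    variants = {
        "full": (base, "combined"),
        "no_family": (replace(base, use_family=False), "combined"),
        "no_sn": (replace(base, use_sn=False), "combined"),
        "mirna_space": (base, "mirna_only"),
        "disease_space": (base, "disease_only"),
    }
    results: dict[str, LoocvResult] = {}
    for tag in tags:
        cfg, mode = variants[tag]
        results[tag] = loocv(
            dataset,
            cfg,
            mode=mode,
            shared_negatives=shared_negatives,
            config_tag=tag,
        )
    return results


# ----------------------------------------------------------------------
# isolated diseases and ranking


def isolated_disease_eval(
    dataset: Dataset,
    target_disease: str,
    config: Optional[IntegrationConfig] = None,
    mode: str = "combined",
) -> IsolatedResult:
    """Blind one disease completely and rank all miRNAs for it.

    The target's entire association column is zeroed *before* any
    similarity computation, emulating a disease with no known miRNA
    (cold start); the epsilon pathway keeps its scores defined. Ranks of
    the hidden true miRNAs are reported. Ties rank by average; the output
    listing breaks ties by miRNA label.
    """
    config = config or IntegrationConfig()
    if target_disease not in dataset.disease_index:
        raise ValidationError(f"unknown disease label: {target_disease!r}")
    j = dataset.disease_index.position(target_disease)
    hidden = np.nonzero(dataset.as_matrix.values[:, j])[0]
    as_blind = dataset.as_matrix.values.astype(np.int8).copy()
    as_blind[:, j] = 0
    fam = dataset.family_values() if config.use_family else None
    scores = score_arrays(
        dataset.mm.values, dataset.dd.values, fam, as_blind, config, mode
    )
    col = scores[:, j]
    labels = dataset.mirna_index.labels
    order = sorted(range(len(col)), key=lambda i: (-col[i], labels[i]))
    records = [
        RankRecord(rank=r + 1, mirna=labels[i], disease=target_disease,
                   score=float(col[i]))
        for r, i in enumerate(order)
    ]
    hidden_ranks = [
        _average_rank(float(col[i]), np.delete(col, i)) for i in hidden
    ]
    return IsolatedResult(
        disease=target_disease,
        records=records,
        hidden_mirnas=[labels[i] for i in hidden],
        hidden_ranks=hidden_ranks,
    )


def rank_unknown(
    dataset: Dataset,
    config: Optional[IntegrationConfig] = None,
    mode: str = "combined",
    top_k: int = 40,
) -> list[RankRecord]:
    """Top-k unknown pairs by score under the full-data model.

    Pairs already known (AS=1) are excluded. Ties break by
    (disease label, miRNA label) for determinism. If top_k exceeds the
    number of unknown pairs, all of them are returned.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    config = config or IntegrationConfig()
    fam = dataset.family_values() if config.use_family else None
    scores = score_arrays(
        dataset.mm.values,
        dataset.dd.values,
        fam,
        dataset.as_matrix.values,
        config,
        mode,
    )
    rows, cols = np.nonzero(dataset.as_matrix.values == 0)
    mlabels = dataset.mirna_index.labels
    dlabels = dataset.disease_index.labels
    cells = sorted(
        zip(rows, cols),
        key=lambda rc: (-scores[rc[0], rc[1]], dlabels[rc[1]], mlabels[rc[0]]),
    )
    return [
        RankRecord(
            rank=r + 1,
            mirna=mlabels[i],
            disease=dlabels[j],
            score=float(scores[i, j]),
        )
        for r, (i, j) in enumerate(cells[:top_k])
    ]
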