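"""Ranked-list assessment for partially labeled gold standards.

Because unverified (protein, location) pairs are unknown rather than
negative, only TP and FP counts are trusted directly: ROC and
precision-recall curves are computed by sweeping a cutoff k down the
ranked node list.  The confusion table for F-score and MCC is anchored at
the *intersection k* — the first cutoff where precision(k) falls to
recall(k) — rather than at any score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LOCATIONS, GoldStandard, MetalocError

NodeId = tuple[str, str]


def _order_labels(
    scores: np.ndarray,
    labels: np.ndarray,
    ids: Sequence | None = None,
) -> np.ndarray:
    """Labels reordered by descending score; ties broken by node id.

    The deterministic tie order makes every cutoff-k count reproducible.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if ids is None:
        ids = np.arange(len(scores))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
    return labels[np.array(order, dtype=int)] if len(scores) else labels


@dataclass
class RocCurve:
    points: np.ndarray  # (k+1, 2) array of (FPR, TPR), starting at (0,0)
    auroc: float


@dataclass
class PrCurve:
    points: np.ndarray  # (k, 2) array of (recall, precision)
    aupr: float
    k_star: int


def roc(
    scores: np.ndarray, labels: np.ndarray, ids: Sequence | None = None
) -> RocCurve:
    """ROC curve and trapezoidal AUROC of a ranked node list.

    TPR(k) = TP(k)/P and FPR(k) = FP(k)/N as the cutoff k sweeps the
    list.  On tie-free lists the trapezoidal area equals the Mann-Whitney
    statistic (fraction of correctly ordered positive/negative pairs).
    """
    ordered = _order_labels(scores, labels, ids)
    p = int(ordered.sum())
    n = len(ordered) - p
    if p == 0 or n == 0:
        missing = "positive" if p == 0 else "negative"
        raise MetalocError(f"ROC undefined: no {missing} nodes in the list")
    tp = np.cumsum(ordered)
    fp = np.arange(1, len(ordered) + 1) - tp
    tpr = np.concatenate([[0.0], tp / p])
    fpr = np.concatenate([[0.0], fp / n])
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auroc=auroc)


def pr(
    scores: np.ndarray, labels: np.ndarray, ids: Sequence | None = None
) -> PrCurve:
    """Precision-recall curve, trapezoidal AUPR, and the intersection k.

    precision(k) = TP(k)/k and recall(k) = TP(k)/P; the intersection
    ``k_star`` is the smallest k with precision(k) <= recall(k).  The area
    uses linear interpolation in (recall, precision).
    """
    ordered = _order_labels(scores, labels, ids)
    p = int(ordered.sum())
    if p == 0:
        raise MetalocError("PR curve undefined: no positive nodes")
    k = np.arange(1, len(ordered) + 1)
    tp = np.cumsum(ordered)
    precision = tp / k
    recall = tp / p
    # anchor at recall 0 with the k=1 precision so the area spans [0, 1]
    aupr = float(
        np.trapezoid(np.concatenate([[precision[0]], precision]),
                     np.concatenate([[0.0], recall]))
    )
    crossing = np.nonzero(precision <= recall)[0]
    k_star = int(crossing[0]) + 1 if len(crossing) else len(ordered)
    return PrCurve(points=np.column_stack([recall, precision]), aupr=aupr, k_star=k_star)


def confusion_at_k(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int,
    ids: Sequence | None = None,
) -> tuple[int, int, int, int]:
    """Confusion table (tp, tn, fp, fn) when the top k nodes are called positive."""
    ordered = _order_labels(scores, labels, ids)
    if not 1 <= k <= len(ordered):
        raise MetalocError(f"cutoff k={k} outside 1..{len(ordered)}")
    p = int(ordered.sum())
    tp = int(ordered[:k].sum())
    fp = k - tp
    fn = p - tp
    tn = len(ordered) - k - fn
    return tp, tn, fp, fn


def f_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall at a fixed confusion table."""
    if tp + fp == 0 or tp + fn == 0:
        raise MetalocError("F-score undefined: empty predicted-positive or positive set")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 by convention when any
    marginal of the confusion table is empty."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class EvalRow:
    auroc: float
    aupr: float
    f_score: float
    mcc: float
    k_star: int
    tp: int
    tn: int
    fp: int
    fn: int
    n_nodes: int
    n_pos: int


@dataclass
class EvalReport:
    """Per-location and pooled-overall assessment of one score table.

    A location with no nodes, or with a single judge class, gets ``None``
    instead of a fabricated row.
    """

    per_location: dict[str, EvalRow | None]
    overall: EvalRow

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for loc in LOCATIONS:
            row = self.per_location.get(loc)
            if row is not None:
                rows[loc] = vars(row)
        rows["overall"] = vars(self.overall)
        return pd.DataFrame.from_dict(rows, orient="index")

    def auroc_by_location(self) -> dict[str, float]:
        return {
            loc: row.auroc
            for loc, row in self.per_location.items()
            if row is not None
        }


def _eval_row(scores: np.ndarray, labels: np.ndarray, ids: Sequence) -> EvalRow:
    roc_curve = roc(scores, labels, ids)
    pr_curve = pr(scores, labels, ids)
    tp, tn, fp, fn = confusion_at_k(scores, labels, pr_curve.k_star, ids)
    return EvalRow(
        auroc=roc_curve.auroc,
        aupr=pr_curve.aupr,
        f_score=f_score(tp, fp, fn) if (tp + fp and tp + fn) else 0.0,
        mcc=mcc(tp, tn, fp, fn),
        k_star=pr_curve.k_star,
        tp=tp, tn=tn, fp=fp, fn=fn,
        n_nodes=len(labels),
        n_pos=int(labels.sum()),
    )


def evaluate(
    score_map: Mapping[NodeId, float],
    gold: GoldStandard,
    proteins: Sequence[str] | None = None,
) -> EvalReport:
    """Full per-location + overall report for a node score table.

    ``score_map`` maps (protein, location) -> confidence score (group-
    voting output, a network output, or a single predictor's raw scores).
    Judge labels come from the gold standard; ``proteins`` optionally
    restricts the evaluation (e.g. to the test split).
    """
    keep = set(proteins) if proteins is not None else None
    ids = sorted(
        nid for nid in score_map
        if (keep is None or nid[0] in keep) and nid[0] in gold.positives
    )
    if not ids:
        raise MetalocError("no scorable nodes in the requested scope")
    scores = np.array([score_map[nid] for nid in ids])
    labels = np.array([1 if gold.is_positive(*nid) else 0 for nid in ids], dtype=int)
    per_location: dict[str, EvalRow | None] = {}
    for loc in LOCATIONS:
        mask = np.array([nid[1] == loc for nid in ids])
        loc_labels = labels[mask]
        if mask.sum() == 0 or loc_labels.sum() in (0, mask.sum()):
            per_location[loc] = None
            continue
        loc_ids = [nid for nid, m in zip(ids, mask) if m]
        per_location[loc] = _eval_row(scores[mask], loc_labels, loc_ids)
    overall = _eval_row(scores, labels, ids)
    return EvalReport(per_location=per_location, overall=overall)


def overall_auroc(score_map: Mapping[NodeId, float], gold: GoldStandard,
                  proteins: Sequence[str] | None = None) -> float:
    return evaluate(score_map, gold, proteins).overall.auroc


def bootstrap_auroc_diff(
    score_map_a: Mapping[NodeId, float],
    score_map_b: Mapping[NodeId, float],
    gold: GoldStandard,
    proteins: Sequence[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Paired bootstrap of AUROC(a) - AUROC(b) over the shared node set.

    Nodes are resampled with replacement jointly for both score tables,
    so shared sampling noise cancels.  Returns (observed difference,
    2.5th, 97.5th percentile of the bootstrap distribution).
    """
    keep = set(proteins) if proteins is not None else None
    ids = sorted(
        nid for nid in set(score_map_a) & set(score_map_b)
        if (keep is None or nid[0] in keep) and nid[0] in gold.positives
    )
    if not ids:
        raise MetalocError("no shared nodes to bootstrap")
    sa = np.array([score_map_a[nid] for nid in ids])
    sb = np.array([score_map_b[nid] for nid in ids])
    labels = np.array([1 if gold.is_positive(*nid) else 0 for nid in ids], dtype=int)
    observed = roc(sa, labels, ids).auroc - roc(sb, labels, ids).auroc
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(ids)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.sum() in (0, n):
            continue
        diffs.append(roc(sa[idx], lab).auroc - roc(sb[idx], lab).auroc)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return float(observed), float(lo), float(hi)


# ---------------------------------------------------------------------------
# SVD independence analysis

@dataclass
class SvdResult:
    singular_values: np.ndarray
    variance_fraction: np.ndarray  # s_i^2 / sum(s^2)


def svd_independence(rank_matrix: np.ndarray) -> SvdResult:
    """Singular-value spectrum of a column-centered rank matrix.

    Rows are nodes shared by all predictors, columns are per-predictor
    rank vectors (smaller rank = higher confidence).  A flat spectrum —
    no dominant component beyond what one column alone explains — is the
    signature of mutually independent predictors; a near-zero trailing
    singular value exposes a (linearly) redundant predictor.
    """
    m = np.asarray(rank_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise MetalocError(
            f"need a 2-D matrix with >=2 rows and >=2 columns, got shape {m.shape}"
        )
    centered = m - m.mean(axis=0, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    total = float(np.sum(s**2))
    fractions = s**2 / total if total > 0 else np.zeros_like(s)
    return SvdResult(singular_values=s, variance_fraction=fractions)


def shared_rank_matrix(lists: Mapping[str, "RankedList"]) -> tuple[list[NodeId], np.ndarray]:
    """Assemble the node x predictor rank matrix over shared node ids."""
    ranks = {
        p: {n.id: r for n, r in zip(rl.nodes, rl.ranks)}
        for p, rl in lists.items()
    }
    common: set[NodeId] | None = None
    for per_pred in ranks.values():
        common = set(per_pred) if common is None else common & set(per_pred)
    if not common:
        raise MetalocError("predictors share no common nodes")
    ids = sorted(common)
    predictors = sorted(ranks)
    matrix = np.array([[ranks[p][nid] for p in predictors] for nid in ids])
    return ids, matrix
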