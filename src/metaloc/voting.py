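"""Rank-based group voting over a community of predictors.

Each predictor's full node set (all proteins x covered locations) is
ranked by raw score, descending; a node's rank percentage is its rank
divided by the predictor's rank range (the length of that list).  The
group-voting score of a node is

    score = 1 - (1/K) * sum_k rank_{i,k} / rank_range_k

averaged over the K predictors that actually scored the node, so a score
near 1 means the community consistently placed the node near the top of
its lists.  Ranking a predictor's whole node list (never one protein at a
time) keeps predictors with different coverage comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GoldStandard, MetalocError, Node, PredictorOutput, split_to_nodes

NodeId = tuple[str, str]


@dataclass
class RankedList:
    """One predictor's nodes ordered by descending raw score.

    Ties in raw score receive the mean of the tied rank positions
    (fractional ranks), which preserves the rank-sum invariant
    sum(ranks) = R(R+1)/2 with R the rank range.
    """

    predictor: str
    nodes: list[Node]           # descending raw score, ties broken by node id
    ranks: np.ndarray           # fractional ranks aligned with ``nodes``
    rank_range: int

    @property
    def percentages(self) -> np.ndarray:
        return self.ranks / self.rank_range

    def percentage_of(self) -> dict[NodeId, float]:
        return {n.id: r / self.rank_range for n, r in zip(self.nodes, self.ranks)}

    def sorted_scores(self) -> np.ndarray:
        """Raw scores in ascending order, for percentile lookup of new scores."""
        return np.sort(np.array([n.raw_score for n in self.nodes]))

    def percentage_of_score(self, raw_score: float) -> float:
        """Rank percentage an unseen raw score would receive in this list.

        The new score is placed after all stored scores strictly greater
        than it: rank = #{stored > s} + 1, percentage = rank / rank_range.
        Monotone decreasing in the score and bounded in (0, 1].
        """
        scores = self.sorted_scores()
        n_greater = len(scores) - np.searchsorted(scores, raw_score, side="right")
        return float(min(n_greater + 1, self.rank_range)) / self.rank_range


def rank_nodes(nodes: Sequence[Node]) -> RankedList:
    """Rank one predictor's nodes by raw score, descending."""
    if not nodes:
        raise MetalocError("cannot rank an empty node collection")
    predictors = {n.predictor for n in nodes}
    if len(predictors) != 1:
        raise MetalocError(f"nodes from multiple predictors: {sorted(predictors)}")
    ordered = sorted(nodes, key=lambda n: (-n.raw_score, n.protein, n.location))
    scores = np.array([n.raw_score for n in ordered])
    if not np.all(np.isfinite(scores)):
        raise MetalocError("non-finite raw scores cannot be ranked")
    ranks = stats.rankdata(-scores, method="average")
    return RankedList(
        predictor=predictors.pop(),
        nodes=ordered,
        ranks=ranks,
        rank_range=len(ordered),
    )


@dataclass
class VoteTable:
    """Normalized group-voting scores per node id.

    ``entries`` maps (protein, location) -> (score in [0,1], K) where K is
    the number of community predictors that scored the node.
    """

    entries: dict[NodeId, tuple[float, int]]

    def score(self, node_id: NodeId) -> float:
        return self.entries[node_id][0]

    def scores(self) -> dict[NodeId, float]:
        return {nid: sk[0] for nid, sk in self.entries.items()}

    def ids(self) -> list[NodeId]:
        return sorted(self.entries)

    def score_arrays(
        self, gold: GoldStandard | None = None
    ) -> tuple[list[NodeId], np.ndarray, np.ndarray | None]:
        """Node ids (sorted), scores, and judge labels if a gold is given."""
        ids = self.ids()
        scores = np.array([self.entries[i][0] for i in ids])
        labels = None
        if gold is not None:
            labels = np.array(
                [1 if gold.is_positive(*i) else 0 for i in ids], dtype=int
            )
        return ids, scores, labels


def normalized_score(
    node_id: NodeId, lists: Sequence[RankedList]
) -> tuple[float, int]:
    """Group-voting score of one node over the given ranked lists.

    Returns (1 - mean rank percentage, K).  Only predictors that actually
    emitted the node contribute; a predictor covering the location but
    missing this protein is excluded from K.
    """
    percentages = []
    for rl in lists:
        pct = rl.percentage_of().get(node_id)
        if pct is not None:
            percentages.append(pct)
    if not percentages:
        raise MetalocError(f"node {node_id} appears in no ranked list")
    k = len(percentages)
    return 1.0 - float(np.mean(percentages)), k


def build_ranked_lists(
    outputs: Iterable[PredictorOutput],
    predictors: Sequence[str] | None = None,
) -> dict[str, RankedList]:
    """Group outputs by predictor, split to nodes and rank each list."""
    outputs = list(outputs)
    available = sorted({o.predictor for o in outputs})
    if predictors is None:
        predictors = available
    unknown = sorted(set(predictors) - set(available))
    if unknown:
        raise MetalocError(f"unknown predictor names: {unknown}")
    if not predictors:
        raise MetalocError("empty predictor community")
    per_pred: dict[str, list[Node]] = {p: [] for p in predictors}
    for out in outputs:
        if out.predictor in per_pred:
            per_pred[out.predictor].extend(split_to_nodes(out))
    return {p: rank_nodes(nodes) for p, nodes in per_pred.items() if nodes}


def vote(
    outputs: Iterable[PredictorOutput],
    predictors: Sequence[str] | None = None,
) -> VoteTable:
    """Group-voting table over the selected predictor community.

    One entry per distinct node id emitted by any included predictor;
    deterministic given the inputs.
    """
    lists = build_ranked_lists(outputs, predictors)
    acc: dict[NodeId, list[float]] = {}
    for rl in lists.values():
        for nid, pct in rl.percentage_of().items():
            acc.setdefault(nid, []).append(pct)
    entries = {
        nid: (1.0 - float(np.mean(pcts)), len(pcts))
        for nid, pcts in sorted(acc.items())
    }
    return VoteTable(entries=entries)


@dataclass
class RankTestResult:
    t_statistic: float
    p_value: float
    mean_tp: float
    mean_fp: float


def tp_fp_rank_test(vote_table: VoteTable, gold: GoldStandard) -> RankTestResult:
    """Welch two-sample t-test between TP and FP group-voting scores.

    A well-behaved community places verified (judge=1) nodes above
    unverified (judge=0) ones, so mean_tp should exceed mean_fp.
    """
    _, scores, labels = vote_table.score_arrays(gold)
    tp = scores[labels == 1]
    fp = scores[labels == 0]
    if len(tp) < 2 or len(fp) < 2:
        raise MetalocError(
            f"need >=2 nodes per group for the t-test (got {len(tp)} TP, {len(fp)} FP)"
        )
    t, p = stats.ttest_ind(tp, fp, equal_var=False)
    return RankTestResult(
        t_statistic=float(t),
        p_value=float(p),
        mean_tp=float(np.mean(tp)),
        mean_fp=float(np.mean(fp)),
    )


def frequency_histogram(
    vote_table: VoteTable, gold: GoldStandard, band: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TP and FP score histograms over [0, 1] with bin width ``band``.

    Returns (tp_counts, fp_counts, bin_edges); counts conserve totals.
    """
    if not 0 < band < 1:
        raise ValueError(f"band must be in (0,1), got {band}")
    n_bins = int(round(1.0 / band))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    _, scores, labels = vote_table.score_arrays(gold)
    tp_counts, _ = np.histogram(scores[labels == 1], bins=edges)
    fp_counts, _ = np.histogram(scores[labels == 0], bins=edges)
    return tp_counts, fp_counts, edges
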