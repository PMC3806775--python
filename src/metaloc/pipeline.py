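"""End-to-end meta-predictor: group voting feeding a neural network.

The two-stage combination model first converts the community's raw
scores into the ten per-compartment group-voting scores of each protein,
then lets a small logsig network re-weight and mix them.  The vote stage
supplies rank-calibrated, coverage-aware inputs (its K-aware averaging
absorbs heterogeneous predictor panels); the network recovers whatever
cross-compartment structure a plain rank average ignores.

Statistical confidence is reported as an empirical P-value: sequences
that exist in no compartment define a per-location null distribution of
meta-predictor scores, and a prediction's P-value is the (add-one
smoothed) fraction of null scores at least as large.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    LOCATIONS,
    GoldStandard,
    MetalocError,
    PredictorOutput,
    split_train_test,
)
from .evaluation import EvalReport, evaluate, roc
from .nn import (
    MLPModel,
    TrainConfig,
    init_mlp,
    topology_search,
    train,
)
from .synthetic import (
    PredictorProfile,
    generate_negative_outputs,
    preset_config,
    generate_ensemble,
    random_protein_sequences,
)
from .voting import RankedList, VoteTable, build_ranked_lists

logger = logging.getLogger(__name__)

NodeId = tuple[str, str]


class VoteStage:
    """Fitted ranking stage of the combination model.

    Stores each community predictor's full ranked list so that unseen
    proteins can be scored later: a new raw score is assigned the rank
    percentage it would have received in the stored list.
    """

    def __init__(self, lists: Mapping[str, RankedList]):
        if not lists:
            raise MetalocError("vote stage needs at least one ranked list")
        self.lists = dict(lists)
        self.community = sorted(self.lists)

    @classmethod
    def fit(
        cls,
        outputs: Iterable[PredictorOutput],
        community: Sequence[str] | None = None,
    ) -> "VoteStage":
        return cls(build_ranked_lists(outputs, community))

    def table(self) -> VoteTable:
        """Group-voting table over the node universe seen at fit time."""
        acc: dict[NodeId, list[float]] = {}
        for rl in self.lists.values():
            for nid, pct in rl.percentage_of().items():
                acc.setdefault(nid, []).append(pct)
        entries = {
            nid: (1.0 - float(np.mean(p)), len(p)) for nid, p in sorted(acc.items())
        }
        return VoteTable(entries=entries)

    def transform(
        self, outputs: Iterable[PredictorOutput]
    ) -> dict[NodeId, tuple[float, int]]:
        """K-aware vote scores for new proteins' predictor outputs."""
        acc: dict[NodeId, list[float]] = {}
        for out in outputs:
            rl = self.lists.get(out.predictor)
            if rl is None:
                continue
            for loc, raw in out.scores.items():
                pct = rl.percentage_of_score(raw)
                acc.setdefault((out.protein, loc), []).append(pct)
        return {
            nid: (1.0 - float(np.mean(p)), len(p)) for nid, p in sorted(acc.items())
        }

    @staticmethod
    def feature_matrix(
        entries: Mapping[NodeId, tuple[float, int]], proteins: Sequence[str]
    ) -> np.ndarray:
        """Per-protein 10-vector of vote scores; uncovered locations are 0."""
        X = np.zeros((len(proteins), len(LOCATIONS)))
        for i, prot in enumerate(proteins):
            for j, loc in enumerate(LOCATIONS):
                entry = entries.get((prot, loc))
                if entry is not None:
                    X[i, j] = entry[0]
        return X


class RawFeatureBuilder:
    """Concatenated per-predictor per-location raw-score features.

    Each predictor contributes one column per covered location, min-max
    normalized to [0, 1] over everything that predictor scored; absent
    scores (outside coverage, or missed proteins) are filled with 0.
    This is the feature map of the network-only integration model.
    """

    def __init__(self, outputs: Iterable[PredictorOutput]):
        self.by_predictor: dict[str, dict[str, dict[str, float]]] = {}
        for out in outputs:
            per_prot = self.by_predictor.setdefault(out.predictor, {})
            per_prot[out.protein] = dict(out.scores)
        self.columns: dict[str, list[str]] = {}
        self.lo: dict[str, float] = {}
        self.hi: dict[str, float] = {}
        for pred, per_prot in self.by_predictor.items():
            locs = sorted(
                {loc for scores in per_prot.values() for loc in scores},
                key=LOCATIONS.index,
            )
            self.columns[pred] = locs
            values = [s for scores in per_prot.values() for s in scores.values()]
            self.lo[pred] = min(values)
            self.hi[pred] = max(values)

    def n_features(self, community: Sequence[str]) -> int:
        return sum(len(self.columns[p]) for p in community)

    def matrix(self, community: Sequence[str], proteins: Sequence[str]) -> np.ndarray:
        unknown = sorted(set(community) - set(self.by_predictor))
        if unknown:
            raise MetalocError(f"unknown predictors: {unknown}")
        cols = []
        for pred in community:
            lo, hi = self.lo[pred], self.hi[pred]
            span = (hi - lo) or 1.0
            block = np.zeros((len(proteins), len(self.columns[pred])))
            per_prot = self.by_predictor[pred]
            for i, prot in enumerate(proteins):
                scores = per_prot.get(prot, {})
                for j, loc in enumerate(self.columns[pred]):
                    if loc in scores:
                        block[i, j] = (scores[loc] - lo) / span
            cols.append(block)
        return np.concatenate(cols, axis=1)


def label_matrix(gold: GoldStandard, proteins: Sequence[str]) -> np.ndarray:
    Y = np.zeros((len(proteins), len(LOCATIONS)))
    for i, prot in enumerate(proteins):
        for loc in gold.positives.get(prot, ()):
            Y[i, LOCATIONS.index(loc)] = 1.0
    return Y


def scores_to_map(
    proteins: Sequence[str], scores: np.ndarray
) -> dict[NodeId, float]:
    return {
        (prot, loc): float(scores[i, j])
        for i, prot in enumerate(proteins)
        for j, loc in enumerate(LOCATIONS)
    }


@dataclass
class CombinationConfig:
    community: Sequence[str] | None = None   # None = every available predictor
    hidden: tuple[int, ...] = (10,)          # the selected 1x10 structure
    repeats: int = 3                         # trainings; best test AUROC kept
    train: TrainConfig = field(default_factory=TrainConfig)
    topology_grid: Sequence[Sequence[int]] | None = None  # set to grid-search
    seed: int = 0


@dataclass
class CombinationModel:
    """Group-voting stage plus the trained 10-input, 10-output network."""

    vote_stage: VoteStage
    mlp: MLPModel
    config: CombinationConfig
    profiles: list[PredictorProfile] | None = None  # null-generator hook
    train_auroc: float = float("nan")
    test_auroc: float = float("nan")

    def score_proteins(
        self, entries: Mapping[NodeId, tuple[float, int]], proteins: Sequence[str]
    ) -> np.ndarray:
        X = VoteStage.feature_matrix(entries, proteins)
        return self.mlp.forward(X)


def fit_combination(
    outputs: Iterable[PredictorOutput],
    gold: GoldStandard,
    config: CombinationConfig | None = None,
    profiles: Sequence[PredictorProfile] | None = None,
) -> CombinationModel:
    """Train the two-stage combination model.

    The vote stage is fit on the full node universe (ranking needs no
    labels).  The network is trained on training-split proteins' vote
    vectors against their multi-label gold vectors; among ``repeats``
    runs the one with the highest test-split overall AUROC is kept.  If
    ``config.topology_grid`` is set, the structure is instead chosen by
    the grid-search protocol on the same inputs.
    """
    cfg = config or CombinationConfig()
    outputs = list(outputs)
    if gold.split_assignment is None:
        gold = split_train_test(gold, fraction=0.2, seed=cfg.seed)
    vote_stage = VoteStage.fit(outputs, cfg.community)
    entries = vote_stage.table().entries
    train_prots = gold.split_proteins("train")
    test_prots = gold.split_proteins("test")
    per_loc_train = label_matrix(gold, train_prots).sum(axis=0)
    starved = [LOCATIONS[i] for i in range(len(LOCATIONS)) if per_loc_train[i] < 2]
    if len(LOCATIONS) - len(starved) < 2:
        raise MetalocError(
            f"insufficient training data; starved locations: {starved}"
        )
    X_train = VoteStage.feature_matrix(entries, train_prots)
    Y_train = label_matrix(gold, train_prots)
    X_test = VoteStage.feature_matrix(entries, test_prots)
    Y_test = label_matrix(gold, test_prots)
    if cfg.topology_grid is not None:
        topo = topology_search(
            X_train, Y_train, X_test, Y_test,
            structures=cfg.topology_grid,
            repeats=max(cfg.repeats, 3),
            seed=cfg.seed,
            config=cfg.train,
        )
        best_model = topo.best_model
    else:
        ss = np.random.SeedSequence([cfg.seed, 0xC0]).spawn(cfg.repeats)
        best_model, best_auc = None, -np.inf
        for child in ss:
            seed = int(child.generate_state(1)[0] % (2**31))
            model = init_mlp(X_train.shape[1], cfg.hidden, len(LOCATIONS), seed=seed)
            result = train(model, X_train, Y_train, cfg.train)
            auc = roc(
                result.model.forward(X_test).ravel(),
                Y_test.ravel().astype(int),
            ).auroc
            if auc > best_auc:
                best_auc, best_model = auc, result.model
    train_auc = roc(
        best_model.forward(X_train).ravel(), Y_train.ravel().astype(int)
    ).auroc
    test_auc = roc(
        best_model.forward(X_test).ravel(), Y_test.ravel().astype(int)
    ).auroc
    return CombinationModel(
        vote_stage=vote_stage,
        mlp=best_model,
        config=cfg,
        profiles=list(profiles) if profiles is not None else None,
        train_auroc=train_auc,
        test_auroc=test_auc,
    )


# ---------------------------------------------------------------------------
# Prediction reports

@dataclass
class PredictionReport:
    """Per-protein 10-location meta scores with optional P-values."""

    proteins: list[str]
    scores: np.ndarray                    # (n, 10) in (0, 1)
    p_values: np.ndarray | None = None    # (n, 10) in (0, 1]
    flagged: list[str] = field(default_factory=list)  # no usable predictor output
    p_threshold: float | None = None

    def to_frame(self, filtered: bool = False) -> pd.DataFrame:
        rows = []
        for i, prot in enumerate(self.proteins):
            for j, loc in enumerate(LOCATIONS):
                p = float(self.p_values[i, j]) if self.p_values is not None else np.nan
                rows.append((prot, loc, float(self.scores[i, j]), p))
        frame = pd.DataFrame(rows, columns=["protein", "location", "score", "p_value"])
        if filtered:
            if self.p_threshold is None or self.p_values is None:
                raise MetalocError("no P-value threshold to filter by")
            frame = frame[frame["p_value"] <= self.p_threshold].reset_index(drop=True)
        return frame

    def score_map(self) -> dict[NodeId, float]:
        return scores_to_map(self.proteins, self.scores)


def predict(
    model: CombinationModel, outputs: Iterable[PredictorOutput]
) -> PredictionReport:
    """Score new proteins through vote stage then network.

    Proteins with no output from any community predictor are flagged and
    reported with an all-zero vote vector rather than silently dropped.
    """
    outputs = list(outputs)
    proteins = sorted({o.protein for o in outputs})
    if not proteins:
        raise MetalocError("no predictor outputs to score")
    entries = model.vote_stage.transform(outputs)
    covered = {prot for (prot, _loc) in entries}
    flagged = sorted(set(proteins) - covered)
    if flagged:
        logger.warning(
            "%d proteins had no usable predictor output: %s%s",
            len(flagged), flagged[:5], "..." if len(flagged) > 5 else "",
        )
    scores = model.score_proteins(entries, proteins)
    return PredictionReport(proteins=proteins, scores=scores, flagged=flagged)


# ---------------------------------------------------------------------------
# Empirical P-values

@dataclass
class NullDistribution:
    """Per-location sorted meta-predictor scores of negative sequences."""

    scores: dict[str, np.ndarray]   # location -> ascending array, length M
    m: int

    def __post_init__(self):
        for loc, arr in self.scores.items():
            if not np.all(np.diff(arr) >= 0):
                raise ValueError(f"null scores for {loc} are not sorted")


SimilarityFilter = Callable[[list], list]


def build_null(
    model: CombinationModel,
    n_null: int = 1000,
    length_range: tuple[int, int] = (50, 300),
    seed: int = 0,
    similarity_filter: SimilarityFilter | None = None,
    profiles: Sequence[PredictorProfile] | None = None,
) -> NullDistribution:
    """Null meta-score distributions from compartment-free sequences.

    Random amino-acid sequences are generated (and optionally screened by
    a similarity filter hook against a reference proteome; the default is
    pass-through), then scored by the community's negative-score model
    and pushed through the full meta-predictor.
    """
    if n_null < 100:
        raise MetalocError("need n_null >= 100 for usable P-value resolution")
    profiles = list(profiles) if profiles is not None else model.profiles
    if profiles is None:
        raise MetalocError(
            "no predictor profiles available to simulate null outputs; "
            "pass profiles= or fit the model with them attached"
        )
    records = random_protein_sequences(n_null, length_range, seed)
    if similarity_filter is not None:
        records = similarity_filter(records)
        if not records:
            raise MetalocError("similarity filter removed every null sequence")
    ids = [rec.id for rec in records]
    neg_outputs = generate_negative_outputs(profiles, ids, seed)
    entries = model.vote_stage.transform(neg_outputs)
    scores = model.score_proteins(entries, ids)
    return NullDistribution(
        scores={
            loc: np.sort(scores[:, j]) for j, loc in enumerate(LOCATIONS)
        },
        m=len(ids),
    )


def p_value(score: float, null: NullDistribution, location: str) -> float:
    """Add-one empirical P-value: (1 + #{null >= score}) / (M + 1).

    Anti-monotone in the score and never exactly zero, so it is usable
    at null sizes as small as 100.
    """
    arr = null.scores.get(location)
    if arr is None:
        raise MetalocError(f"no null distribution for location {location!r}")
    n_ge = len(arr) - int(np.searchsorted(arr, score, side="left"))
    return (1 + n_ge) / (len(arr) + 1)


def attach_p_values(
    report: PredictionReport, null: NullDistribution,
    p_threshold: float | None = None,
) -> PredictionReport:
    pv = np.empty_like(report.scores)
    for j, loc in enumerate(LOCATIONS):
        arr = null.scores[loc]
        n_ge = len(arr) - np.searchsorted(arr, report.scores[:, j], side="left")
        pv[:, j] = (1 + n_ge) / (len(arr) + 1)
    report.p_values = pv
    report.p_threshold = p_threshold
    return report


# ---------------------------------------------------------------------------
# Config-driven pipeline

DEFAULT_PIPELINE_CONFIG: dict = {
    "preset": "paperlike-11",
    "n_proteins": 800,
    "seed": 0,
    "community": "all",
    "test_fraction": 0.2,
    "hidden": [10],
    "repeats": 3,
    "epochs": 200,
    "n_null": 300,
    "p_threshold": 0.05,
    "outdir": "metaloc-run",
}


def _fmt_frame(frame: pd.DataFrame) -> str:
    return frame.to_csv(sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: str | Path | Mapping) -> dict:
    """Simulate, integrate, evaluate, predict and report, per a YAML config.

    Writes to ``outdir``: ``results.tsv`` (every protein/location score
    and P-value — nothing filtered), ``results_view.tsv`` (the
    P-value-thresholded view), ``eval_report.tsv`` (per-location and
    overall test metrics for vote and combination), and ``summary.json``.
    Fully deterministic for a fixed config: two runs produce
    byte-identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user_cfg = yaml.safe_load(fh) or {}
    else:
        user_cfg = dict(config)
    unknown_keys = set(user_cfg) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown_keys:
        raise MetalocError(f"unknown config keys: {sorted(unknown_keys)}")
    cfg = {**DEFAULT_PIPELINE_CONFIG, **user_cfg}

    ens_cfg = preset_config(cfg["preset"], n_proteins=int(cfg["n_proteins"]),
                            seed=int(cfg["seed"]))
    available = [p.name for p in ens_cfg.profiles]
    community = available if cfg["community"] == "all" else list(cfg["community"])
    unknown = sorted(set(community) - set(available))
    if unknown:
        raise MetalocError(f"community names {unknown} not in preset {cfg['preset']!r}")

    outputs, gold = generate_ensemble(ens_cfg)
    gold = split_train_test(gold, float(cfg["test_fraction"]), seed=int(cfg["seed"]))
    test_prots = gold.split_proteins("test")

    comb_cfg = CombinationConfig(
        community=community,
        hidden=tuple(int(h) for h in cfg["hidden"]),
        repeats=int(cfg["repeats"]),
        train=TrainConfig(epochs=int(cfg["epochs"])),
        seed=int(cfg["seed"]),
    )
    model = fit_combination(outputs, gold, comb_cfg, profiles=ens_cfg.profiles)

    vote_scores = model.vote_stage.table().scores()
    vote_report = evaluate(vote_scores, gold, proteins=test_prots)
    comb_entries = model.vote_stage.table().entries
    comb_scores = scores_to_map(
        test_prots, model.score_proteins(comb_entries, test_prots)
    )
    comb_report = evaluate(comb_scores, gold, proteins=test_prots)

    null = build_null(model, n_null=int(cfg["n_null"]), seed=int(cfg["seed"]))
    test_outputs = [o for o in outputs if o.protein in set(test_prots)]
    report = predict(model, test_outputs)
    report = attach_p_values(report, null, p_threshold=float(cfg["p_threshold"]))

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "results.tsv").write_text(_fmt_frame(report.to_frame()))
    (outdir / "results_view.tsv").write_text(_fmt_frame(report.to_frame(filtered=True)))
    eval_frame = pd.concat(
        {
            "vote": vote_report.to_frame(),
            "combination": comb_report.to_frame(),
        },
        names=["model", "scope"],
    ).reset_index()
    (outdir / "eval_report.tsv").write_text(_fmt_frame(eval_frame))
    summary = {
        "config": {k: cfg[k] for k in sorted(cfg) if k != "outdir"},
        "community": community,
        "n_test_proteins": len(test_prots),
        "vote_overall_auroc": round(vote_report.overall.auroc, 10),
        "combination_overall_auroc": round(comb_report.overall.auroc, 10),
        "combination_test_auroc_at_fit": round(model.test_auroc, 10),
        "n_null": null.m,
        "n_flagged": len(report.flagged),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
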