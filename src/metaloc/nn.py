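"""Single- and double-hidden-layer logistic-sigmoid perceptron combiner.

Every non-input layer computes logsig(W x + b); the output layer has ten
units, one per subcellular compartment, so one forward pass yields a
multi-label confidence vector.  Training is full-batch gradient descent
on mean binary cross-entropy with an accept/reject step-size control: a
step that would increase the training loss is rejected and the learning
rate halved, so the recorded loss history is non-increasing.

The module also implements the two model-selection protocols used around
the network: a topology grid search in which each structure is trained
several times and summarised by its best repeats, and greedy stepwise
predictor selection in descending order of individual AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import MetalocError
from .evaluation import roc


def logsig(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic sigmoid 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MLPModel:
    """Feed-forward network with logsig activations on every layer.

    ``weights[l]`` has shape (fan_out, fan_in); ``biases[l]`` has shape
    (fan_out,).  The output layer must have exactly 10 units.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int = 0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple([self.weights[0].shape[1]] + [w.shape[0] for w in self.weights])

    def copy(self) -> "MLPModel":
        return MLPModel(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            seed=self.seed,
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Activations of the output layer, shape (n_samples, 10)."""
        return self.forward_all(X)[-1]

    def forward_all(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations of every non-input layer (for backprop)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise MetalocError(
                f"input dimension {X.shape[1]} != model input size "
                f"{self.layer_sizes[0]}"
            )
        if not np.all(np.isfinite(X)):
            raise MetalocError("non-finite network input")
        activations = []
        a = X
        for w, b in zip(self.weights, self.biases):
            a = logsig(a @ w.T + b)
            activations.append(a)
        return activations

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "seed": self.seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            weights=[np.array(w, dtype=float) for w in d["weights"]],
            biases=[np.array(b, dtype=float) for b in d["biases"]],
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def init_mlp(
    n_inputs: int, hidden: Sequence[int], n_outputs: int = 10, seed: int = 0
) -> MLPModel:
    """Random small-weight initialisation, scaled by 1/sqrt(fan_in)."""
    sizes = [n_inputs, *hidden, n_outputs]
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return MLPModel(weights=weights, biases=biases, seed=seed)


def bce_loss(outputs: np.ndarray, targets: np.ndarray, eps: float = 1e-12) -> float:
    """Mean over samples of the summed per-location binary cross-entropy."""
    a = np.clip(outputs, eps, 1.0 - eps)
    y = np.asarray(targets, dtype=float)
    per_sample = -(y * np.log(a) + (1.0 - y) * np.log(1.0 - a)).sum(axis=1)
    return float(per_sample.mean())


def gradients(
    model: MLPModel, X: np.ndarray, Y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Analytic gradients of :func:`bce_loss` w.r.t. weights and biases.

    With logsig outputs and cross-entropy, the output-layer error is
    simply (activation - target) / n_samples; hidden layers follow the
    standard backprop recursion with the logsig derivative a(1-a).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    activations = model.forward_all(X)
    n = X.shape[0]
    grads_w: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore
    delta = (activations[-1] - Y) / n
    for layer in range(len(model.weights) - 1, -1, -1):
        a_prev = X if layer == 0 else activations[layer - 1]
        grads_w[layer] = delta.T @ a_prev
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            a = activations[layer - 1]
            delta = (delta @ model.weights[layer]) * a * (1.0 - a)
    return grads_w, grads_b


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 1.0
    momentum: float = 0.9
    l2: float = 0.0            # weight decay on weights (not biases)
    lr_grow: float = 1.05      # accepted step: mild learning-rate growth
    lr_shrink: float = 0.5     # rejected step: halve and retry next epoch
    val_interval: int = 10     # epochs between held-out AUROC checks
    patience: int = 10         # val checks without improvement before stopping
    val_tol: float = 1e-4


@dataclass
class TrainResult:
    model: MLPModel
    loss_history: list[float]
    val_history: list[float] = field(default_factory=list)


def _flat_auroc(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Overall AUROC with every (sample, location) cell as one node."""
    return roc(outputs.ravel(), targets.ravel().astype(int)).auroc


def train(
    model: MLPModel,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig | None = None,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> TrainResult:
    """Full-batch gradient descent with momentum and step accept/reject.

    Deterministic given the model's initial weights and the config.  If a
    validation split is supplied, held-out overall AUROC is checked every
    ``val_interval`` epochs and training stops once it has not improved
    for ``patience`` consecutive checks; the weights at the best check
    are restored.
    """
    cfg = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise MetalocError("X and Y row counts differ")
    work = model.copy()
    lr = cfg.learning_rate

    def objective(m: MLPModel) -> float:
        loss = bce_loss(m.forward(X), Y)
        if cfg.l2:
            loss += 0.5 * cfg.l2 * sum(float(np.sum(w**2)) for w in m.weights)
        return loss

    vel_w = [np.zeros_like(w) for w in work.weights]
    vel_b = [np.zeros_like(b) for b in work.biases]
    loss = objective(work)
    if not np.isfinite(loss):
        raise MetalocError("initial loss is not finite")
    history = [loss]
    val_history: list[float] = []
    best_val = -np.inf
    best_weights = None
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        gw, gb = gradients(work, X, Y)
        if cfg.l2:
            gw = [g + cfg.l2 * w for g, w in zip(gw, work.weights)]
        cand_vw = [cfg.momentum * v - lr * g for v, g in zip(vel_w, gw)]
        cand_vb = [cfg.momentum * v - lr * g for v, g in zip(vel_b, gb)]
        cand = MLPModel(
            weights=[w + dv for w, dv in zip(work.weights, cand_vw)],
            biases=[b + dv for b, dv in zip(work.biases, cand_vb)],
            seed=work.seed,
        )
        cand_loss = objective(cand)
        if not np.isfinite(cand_loss):
            raise MetalocError(f"loss diverged to {cand_loss} at epoch {epoch}")
        if cand_loss <= loss:
            work, loss = cand, cand_loss
            vel_w, vel_b = cand_vw, cand_vb
            lr *= cfg.lr_grow
            history.append(loss)
        else:
            # reject: keep weights, damp the step for the next attempt
            vel_w = [np.zeros_like(w) for w in work.weights]
            vel_b = [np.zeros_like(b) for b in work.biases]
            lr *= cfg.lr_shrink
        if X_val is not None and epoch % cfg.val_interval == 0:
            val_auc = _flat_auroc(work.forward(X_val), np.asarray(Y_val))
            val_history.append(val_auc)
            if val_auc > best_val + cfg.val_tol:
                best_val = val_auc
                best_weights = work.copy()
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_weights is not None:
        work = best_weights
    return TrainResult(model=work, loss_history=history, val_history=val_history)


# ---------------------------------------------------------------------------
# Topology grid search

DEFAULT_TOPOLOGY_GRID: tuple[tuple[int, ...], ...] = (
    (5,), (10,), (15,), (5, 5), (10, 10), (15, 15),
)


@dataclass
class TopologyResult:
    grid: dict[tuple[int, ...], list[float]]      # structure -> repeat test AUROCs
    best3: dict[tuple[int, ...], list[float]]     # top-3 repeats per structure
    chosen: tuple[int, ...]
    best_model: MLPModel


def topology_search(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    structures: Sequence[Sequence[int]] = DEFAULT_TOPOLOGY_GRID,
    repeats: int = 10,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> TopologyResult:
    """Grid search over hidden-layer structures.

    Each structure is trained ``repeats`` times from different random
    initialisations; the best 3 repeats summarise it and the structure
    with the highest best-3 median test AUROC is chosen.  The single
    best repeat overall (by test AUROC) is returned as the deployable
    model.
    """
    if not structures:
        raise MetalocError("empty topology grid")
    if repeats < 3:
        raise MetalocError("need >=3 repeats to pick the best 3")
    n_inputs = np.atleast_2d(X_train).shape[1]
    n_outputs = np.atleast_2d(Y_train).shape[1]
    ss = np.random.SeedSequence(seed)
    grid: dict[tuple[int, ...], list[float]] = {}
    models: dict[tuple[int, ...], list[MLPModel]] = {}
    for si, structure in enumerate(structures):
        structure = tuple(int(h) for h in structure)
        aucs, mods = [], []
        for r in range(repeats):
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            model = init_mlp(n_inputs, structure, n_outputs, seed=child_seed)
            result = train(model, X_train, Y_train, config)
            auc = _flat_auroc(result.model.forward(X_test), Y_test)
            aucs.append(auc)
            mods.append(result.model)
        grid[structure] = aucs
        models[structure] = mods
    best3 = {s: sorted(a, reverse=True)[:3] for s, a in grid.items()}
    chosen = max(best3, key=lambda s: (float(np.median(best3[s])), -len(s), s))
    best_idx = int(np.argmax(grid[chosen]))
    return TopologyResult(
        grid=grid, best3=best3, chosen=chosen, best_model=models[chosen][best_idx]
    )


# ---------------------------------------------------------------------------
# Stepwise predictor selection

@dataclass
class CommunitySelection:
    candidate_order: list[str]      # descending individual AUROC
    kept: list[str]
    trajectory: list[float]         # test AUROC evaluated at each step
    kept_flags: list[bool]


def stepwise_select(
    candidates: dict[str, float],
    feature_builder: Callable[[Sequence[str]], tuple[np.ndarray, np.ndarray]],
    Y_train: np.ndarray,
    Y_test: np.ndarray,
    hidden: Sequence[int] = (10,),
    config: TrainConfig | None = None,
    repeats: int = 3,
    seed: int = 0,
    tol: float = 1e-4,
    se_factor: float = 2.0,
) -> CommunitySelection:
    """Greedy forward selection of predictors by descending individual AUROC.

    ``candidates`` maps predictor name -> its individual AUROC;
    ``feature_builder(names)`` must return the (train, test) feature
    matrices for a community.  At each step the network is retrained
    ``repeats`` times and the mean test AUROC is compared; the repeat
    seeds are shared across steps (common random numbers), so step-to-
    step differences reflect the added features as far as possible.

    Network training is stochastic, so "the test AUROC increased" is
    read against the training noise: a candidate is kept only if the
    mean gain exceeds both ``tol`` and ``se_factor`` standard errors of
    the mean difference, with the SE estimated from the repeat spread of
    the two communities being compared.  With ``se_factor=0`` the rule
    degenerates to the plain fixed-tolerance comparison.
    """
    if not candidates:
        raise MetalocError("no candidate predictors")
    order = sorted(candidates, key=lambda p: (-candidates[p], p))
    kept: list[str] = []
    trajectory: list[float] = []
    kept_flags: list[bool] = []
    best_auc = 0.5  # an input-free model ranks nodes arbitrarily
    best_var = 0.0  # variance of the mean AUROC of the incumbent community
    repeat_seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(seed).spawn(repeats)
    ]
    n_outputs = np.atleast_2d(Y_train).shape[1]
    for name in order:
        trial = kept + [name]
        X_train, X_test = feature_builder(trial)
        aucs = []
        for child_seed in repeat_seeds:
            model = init_mlp(X_train.shape[1], tuple(hidden), n_outputs, seed=child_seed)
            result = train(model, X_train, Y_train, config)
            aucs.append(_flat_auroc(result.model.forward(X_test), Y_test))
        step_auc = float(np.mean(aucs))
        step_var = float(np.var(aucs, ddof=1) / len(aucs)) if len(aucs) > 1 else 0.0
        trajectory.append(step_auc)
        margin = max(tol, se_factor * float(np.sqrt(step_var + best_var)))
        if step_auc > best_auc + margin:
            kept.append(name)
            best_auc = step_auc
            best_var = step_var
            kept_flags.append(True)
        else:
            kept_flags.append(False)
    return CommunitySelection(
        candidate_order=order, kept=kept, trajectory=trajectory, kept_flags=kept_flags
    )
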