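"""Model training: the hard-parameter-sharing multitask network,
single-task baselines (random forest, gradient boosting, single-task
network), hyperparameter random search, and prediction.

All learners consume the same fingerprint matrix and Split objects so
that deep and tree-based methods are compared on identical data.  Tree
baselines come from scikit-learn and LightGBM; the networks are the
package's own seeded NumPy implementation (see :mod:`mtqsar.network`).
"""

from __future__ import annotations

import dataclasses
import pickle
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .network import FeedForwardNet, masked_mse  # re-exported
from .split import Split, kfold

__all__ = [
    "TaskMatrix", "TrainingConfig", "HyperparameterSpace", "TrainedModel",
    "masked_mse", "train_mt_dnn", "train_st", "predict",
    "save_model", "load_model",
]


@dataclasses.dataclass
class TaskMatrix:
    """Dense compound x task potency matrix plus observation mask."""

    values: np.ndarray
    mask: np.ndarray
    task_ids: list[str]
    compound_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask).astype(np.int8)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask.astype(bool)])):
            raise ValueError("non-finite value in an observed cell")

    @property
    def sparsity(self) -> float:
        return 1.0 - float(self.mask.mean())

    @classmethod
    def from_entries(
        cls,
        entries: pd.DataFrame,
        compounds: Sequence[str] | None = None,
        tasks: Sequence[str] | None = None,
    ) -> "TaskMatrix":
        """Build from a curated entry table (smiles, task_id, p_value).

        Row/column universes default to the sorted distinct structures
        and tasks of the table; pass explicit lists to align with an
        external fingerprint matrix.
        """
        if compounds is None:
            compounds = sorted(entries["smiles"].unique())
        if tasks is None:
            tasks = sorted(entries["task_id"].unique())
        ci = {c: i for i, c in enumerate(compounds)}
        ti = {t: i for i, t in enumerate(tasks)}
        values = np.zeros((len(compounds), len(tasks)))
        mask = np.zeros_like(values, dtype=np.int8)
        for row in entries.itertuples(index=False):
            i, j = ci.get(row.smiles), ti.get(row.task_id)
            if i is None or j is None:
                continue
            values[i, j] = row.p_value
            mask[i, j] = 1
        return cls(values, mask, list(tasks), list(compounds))


@dataclasses.dataclass
class TrainingConfig:
    """Network training configuration.

    Defaults are the selected optimum of the hyperparameter search this
    workflow reproduces: batch size 48, Nadam, learning rate 1e-3, with
    early stopping at patience 10 within a 2000-epoch budget.  The trunk
    architecture (two hidden layers, 512 and 256 units) is configurable.
    """

    hidden: tuple[int, ...] = (512, 256)
    activation: str = "relu"
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 48
    optimizer: str = "nadam"
    l1: float = 0.0
    l2: float = 0.0
    max_epochs: int = 2000
    patience: int = 10

    def __post_init__(self):
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclasses.dataclass
class HyperparameterSpace:
    """Random-search space for the networks: dropout 0.1-0.6, learning
    rate log-uniform on [1e-8, 1e-1], batch size 24-96, the six
    activations, L1/L2 regularization, and four optimizers."""

    dropout: tuple[float, float] = (0.1, 0.6)
    learning_rate: tuple[float, float] = (1e-8, 1e-1)
    batch_size: tuple[int, int] = (24, 96)
    activations: tuple[str, ...] = ("gelu", "elu", "selu", "tanh", "relu", "linear")
    regularization: tuple[str, ...] = ("l1", "l2")
    reg_strength: tuple[float, float] = (1e-6, 1e-3)
    optimizers: tuple[str, ...] = ("adam", "nadam", "sgd", "rmsprop")

    def sample(self, rng: np.random.Generator, **overrides) -> TrainingConfig:
        reg_kind = self.regularization[rng.integers(len(self.regularization))]
        reg = 10.0 ** rng.uniform(
            np.log10(self.reg_strength[0]), np.log10(self.reg_strength[1])
        )
        cfg = dict(
            dropout=float(rng.uniform(*self.dropout)),
            learning_rate=float(10.0 ** rng.uniform(
                np.log10(self.learning_rate[0]), np.log10(self.learning_rate[1])
            )),
            batch_size=int(rng.integers(self.batch_size[0], self.batch_size[1] + 1)),
            activation=self.activations[rng.integers(len(self.activations))],
            optimizer=self.optimizers[rng.integers(len(self.optimizers))],
            l1=reg if reg_kind == "l1" else 0.0,
            l2=reg if reg_kind == "l2" else 0.0,
        )
        cfg.update(overrides)
        return TrainingConfig(**cfg)


@dataclasses.dataclass
class TrainedModel:
    kind: str                      # random_forest | gradient_boosting | st_dnn | mt_dnn
    model: object                  # FeedForwardNet or fitted sklearn/LightGBM model
    config: object
    history: dict | None
    split: Split | None
    task_ids: list[str]
    n_bits: int


def _check_task_coverage(data: TaskMatrix, split: Split) -> None:
    bad = []
    for j, tid in enumerate(data.task_ids):
        if data.mask[split.train, j].sum() == 0 or (
            len(split.validation) > 0 and data.mask[split.validation, j].sum() == 0
        ):
            bad.append(tid)
    if bad:
        warnings.warn(
            f"tasks with empty observed train/validation cells: {bad}",
            stacklevel=3,
        )


def train_mt_dnn(
    data: TaskMatrix,
    fingerprints: np.ndarray,
    split: Split,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the multitask network: shared trunk, one linear output head
    per task, masked-MSE loss, early stopping on validation loss."""
    config = config or TrainingConfig()
    X = np.asarray(fingerprints, dtype=float)
    if X.shape[0] != data.values.shape[0]:
        raise ValueError("fingerprint and task-matrix row counts differ")
    _check_task_coverage(data, split)
    net = FeedForwardNet(
        X.shape[1], config.hidden, data.values.shape[1],
        activation=config.activation, dropout=config.dropout,
        l1=config.l1, l2=config.l2, seed=seed,
    )
    history = net.fit(
        X, data.values, data.mask, split.train, split.validation,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        optimizer=config.optimizer, max_epochs=config.max_epochs,
        patience=config.patience, seed=seed + 1,
    )
    return TrainedModel("mt_dnn", net, config, history, split,
                        list(data.task_ids), X.shape[1])


def _st_dnn_once(X, y, mask, split, config, seed):
    net = FeedForwardNet(
        X.shape[1], config.hidden, 1,
        activation=config.activation, dropout=config.dropout,
        l1=config.l1, l2=config.l2, seed=seed,
    )
    history = net.fit(
        X, y[:, None], mask[:, None], split.train, split.validation,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        optimizer=config.optimizer, max_epochs=config.max_epochs,
        patience=config.patience, seed=seed + 1,
    )
    return net, history


_TREE_GRIDS = {
    "random_forest": dict(
        n_estimators=(100, 500), max_depth=(4, 32), max_features=(0.1, 1.0),
        min_samples_leaf=(1, 8),
    ),
    "gradient_boosting": dict(
        n_estimators=(100, 500), learning_rate=(0.01, 0.3),
        num_leaves=(15, 127), min_child_samples=(2, 30),
    ),
}


def _sample_tree_params(learner: str, rng: np.random.Generator) -> dict:
    g = _TREE_GRIDS[learner]
    if learner == "random_forest":
        return dict(
            n_estimators=int(rng.integers(*g["n_estimators"])),
            max_depth=int(rng.integers(*g["max_depth"])),
            max_features=float(rng.uniform(*g["max_features"])),
            min_samples_leaf=int(rng.integers(*g["min_samples_leaf"])),
        )
    return dict(
        n_estimators=int(rng.integers(*g["n_estimators"])),
        learning_rate=float(10.0 ** rng.uniform(
            np.log10(g["learning_rate"][0]), np.log10(g["learning_rate"][1])
        )),
        num_leaves=int(rng.integers(*g["num_leaves"])),
        min_child_samples=int(rng.integers(*g["min_child_samples"])),
    )


def _make_tree(learner: str, params: dict, seed: int):
    if learner == "random_forest":
        from sklearn.ensemble import RandomForestRegressor
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    from lightgbm import LGBMRegressor
    return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)


def train_st(
    values: np.ndarray,
    mask: np.ndarray,
    fingerprints: np.ndarray,
    split: Split | list[Split],
    learner: str = "st_dnn",
    n_iter: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
    space: HyperparameterSpace | None = None,
    task_id: str = "task",
) -> TrainedModel:
    """Train one single-task model with a budgeted random search.

    The network is selected by validation RMSE on the provided Split;
    tree models by cross-validated RMSE (internal 5-fold over the
    observed train + validation cells, or the supplied fold Splits),
    then refit on all selection data.  ``n_iter`` is the search budget;
    passing an explicit ``config`` (networks only) skips the search.
    """
    if n_iter < 1:
        raise ValueError("search budget must be >= 1")
    X = np.asarray(fingerprints, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if int(mask.sum()) < 30:
        raise ValueError(
            f"need >= 30 observed values, got {int(mask.sum())}"
        )
    rng = np.random.default_rng(seed)
    space = space or HyperparameterSpace()
    folds = split if isinstance(split, list) else None
    base_split = split if not isinstance(split, list) else None

    if learner == "st_dnn":
        if base_split is None:
            raise ValueError("st_dnn requires a train/validation/test Split")
        candidates = (
            [config] if config is not None
            else [space.sample(rng) for _ in range(n_iter)]
        )
        best = None
        for i, cfg in enumerate(candidates):
            try:
                net, history = _st_dnn_once(X, values, mask.astype(np.int8),
                                            base_split, cfg, seed + 17 * i)
            except (RuntimeError, ValueError):
                continue  # diverged configuration (e.g. lr 1e-1 with SGD)
            score = history["val_loss"][history["best_epoch"] - 1]
            if best is None or score < best[0]:
                best = (score, net, history, cfg)
        if best is None:
            raise RuntimeError("every sampled configuration diverged")
        _, net, history, cfg = best
        return TrainedModel("st_dnn", net, cfg, history, base_split, [task_id],
                            X.shape[1])

    if learner not in _TREE_GRIDS:
        raise ValueError(f"unknown learner: {learner}")
    if folds is None:
        sel_idx = np.concatenate([base_split.train, base_split.validation])
        sel_idx = sel_idx[mask[sel_idx]]
        folds_local = kfold(len(sel_idx), k=5, seed=seed)
        fold_pairs = [(sel_idx[f.train], sel_idx[f.test]) for f in folds_local]
        refit_idx = sel_idx
    else:
        obs = np.where(mask)[0]
        fold_pairs = [
            (np.intersect1d(f.train, obs), np.intersect1d(f.test, obs))
            for f in folds
        ]
        refit_idx = obs
    best = None
    for i in range(n_iter):
        params = _sample_tree_params(learner, rng)
        errs = []
        for tr, te in fold_pairs:
            m = _make_tree(learner, params, seed)
            m.fit(X[tr], values[tr])
            errs.append(float(np.sqrt(np.mean((m.predict(X[te]) - values[te]) ** 2))))
        score = float(np.mean(errs))
        if best is None or score < best[0]:
            best = (score, params)
    model = _make_tree(learner, best[1], seed)
    model.fit(X[refit_idx], values[refit_idx])
    return TrainedModel(learner, model, best[1], None, base_split, [task_id],
                        X.shape[1])


def predict(
    model: TrainedModel, fingerprints: np.ndarray, task_id: str | None = None
) -> np.ndarray:
    """Predict p-scale potencies; multitask models return an (n, T)
    matrix (or one column when ``task_id`` is given) regardless of
    training-mask status."""
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_bits:
        raise ValueError(
            f"fingerprint length {X.shape[1]} != training length {model.n_bits}"
        )
    if model.kind in ("mt_dnn", "st_dnn"):
        pred = model.model.predict(X)
        if model.kind == "st_dnn":
            return pred[:, 0]
        if task_id is None:
            return pred
        if task_id not in model.task_ids:
            raise KeyError(f"unknown task_id: {task_id}")
        return pred[:, model.task_ids.index(task_id)]
    return np.asarray(model.model.predict(X), dtype=float)


def save_model(model: TrainedModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
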