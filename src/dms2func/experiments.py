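"""Dataset splitting, model training with early stopping, and evaluation.

Splits: random 81/9/10, reduced-size training subsets, and the two
extrapolation strategies (mutational and positional) in which variants mixing
train- and test-designated mutations/positions are discarded to rule out
information leaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from dms2func.models import Adam, Model
from dms2func.sequence_data import DMSDataset


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    strategy: str
    seed: int
    train: np.ndarray
    tune: np.ndarray
    test: np.ndarray
    discarded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.tune), set(self.test), set(self.discarded)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split index sets are not pairwise disjoint")


def split_random(
    ds: DMSDataset,
    fractions: tuple[float, float, float] = (0.81, 0.09, 0.10),
    seed: int = 0,
) -> SplitSpec:
    """Random train/tune/test split; floor-based sizes, remainder to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ds)
    if n < 3:
        raise ValueError("dataset must have at least 3 variants to split")
    n_tune = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    perm = np.random.default_rng(seed).permutation(n)
    tune = perm[:n_tune]
    test = perm[n_tune : n_tune + n_test]
    train = perm[n_tune + n_test :]
    return SplitSpec("random", seed, np.sort(train), np.sort(tune), np.sort(test))


def _extrapolation_split(ds, keys_of, designated_name, fraction, seed, strategy):
    """Shared machinery for mutational/positional extrapolation splits.

    ``keys_of(variant)`` returns the set of keys (single mutations or mutated
    positions); 80% of the distinct keys are designated train, the rest test.
    Variants using only train keys form the training pool (split 90/10 into
    train/tune), variants using only test keys form the test set, and mixed
    variants are discarded.
    """
    all_keys = sorted({k for v in ds for k in keys_of(v)})
    if len(all_keys) < 2:
        raise ValueError(f"dataset has fewer than 2 distinct {designated_name}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(all_keys))
    n_train_keys = int(round(fraction * len(all_keys)))
    train_keys = {all_keys[i] for i in perm[:n_train_keys]}
    test_keys = {all_keys[i] for i in perm[n_train_keys:]}

    pool, test, discarded = [], [], []
    for i, v in enumerate(ds):
        keys = keys_of(v)
        if keys <= train_keys:
            pool.append(i)
        elif keys <= test_keys and keys:
            test.append(i)
        else:
            discarded.append(i)
    if not test:
        raise ValueError(
            f"empty test pool for {strategy} split; try a different seed"
        )
    pool = np.array(pool, dtype=int)
    pool_perm = rng.permutation(len(pool))
    n_tune = int(np.floor(0.10 * len(pool)))
    tune = pool[pool_perm[:n_tune]]
    train = pool[pool_perm[n_tune:]]
    return SplitSpec(
        strategy,
        seed,
        np.sort(train),
        np.sort(tune),
        np.array(sorted(test), dtype=int),
        np.array(sorted(discarded), dtype=int),
    )


def split_mutational(
    ds: DMSDataset, mutation_fraction: float = 0.8, seed: int = 0
) -> SplitSpec:
    """Hold out variants whose substitutions were never seen in training."""
    return _extrapolation_split(
        ds,
        lambda v: set(v.substitutions),
        "single mutations",
        mutation_fraction,
        seed,
        "mutational",
    )


def split_positional(
    ds: DMSDataset, position_fraction: float = 0.8, seed: int = 0
) -> SplitSpec:
    """Hold out variants mutated only at positions never mutated in training."""
    return _extrapolation_split(
        ds,
        lambda v: set(v.mutated_positions()),
        "mutated positions",
        position_fraction,
        seed,
        "positional",
    )


def reduced_training_sets(
    pool: np.ndarray, sizes: Sequence[int], replicates: int = 5, seed: int = 0
) -> dict[int, list[np.ndarray]]:
    """Seeded random subsets of the training pool, ``replicates`` per size.

    Downstream summaries should report the median metric over the replicates.
    """
    pool = np.asarray(pool)
    rng = np.random.default_rng(seed)
    out: dict[int, list[np.ndarray]] = {}
    for size in sizes:
        if not 1 <= size <= len(pool):
            raise ValueError(f"requested size {size} exceeds pool of {len(pool)}")
        out[size] = [
            np.sort(rng.choice(pool, size=size, replace=False))
            for _ in range(replicates)
        ]
    return out


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 15
    min_delta: float = 0.00001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainingHistory:
    train_loss: list[float]
    tune_loss: list[float]
    best_epoch: int  # 0-based index into the loss lists

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _mse(model: Model, X: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict(X)
    return float(np.mean((pred - y) ** 2))


def train(
    model: Model,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_tune: np.ndarray,
    y_tune: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Minibatch Adam on mean squared error with early stopping.

    Stops when the tuning loss has not improved by at least ``min_delta`` for
    ``patience`` consecutive epochs (or at ``max_epochs``) and restores the
    parameters of the best tuning-loss epoch.  The tuning loss is the exact
    unweighted mean over tuning examples.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate)
    y_train = np.asarray(y_train, dtype=float)
    y_tune = np.asarray(y_tune, dtype=float)
    n = X_train.shape[0]

    best_loss = np.inf
    best_params = model.get_params()
    best_epoch = -1
    epochs_since_improvement = 0
    history = TrainingHistory([], [], -1)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            model.zero_grads()
            pred = model.forward(xb, train=True, rng=rng)
            resid = pred.ravel() - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            epoch_loss += loss * len(idx)
            model.backward((2.0 * resid / len(idx))[:, None])
            opt.step()
        history.train_loss.append(epoch_loss / n)
        tune_loss = _mse(model, X_tune, y_tune)
        history.tune_loss.append(tune_loss)

        if best_loss - tune_loss >= cfg.min_delta:
            best_loss = tune_loss
            best_params = model.get_params()
            best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= cfg.patience:
                break

    model.set_params(best_params)
    model.trained = True
    history.best_epoch = best_epoch
    return history


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    pearson: float
    spearman: float
    mse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "mse": self.mse,
            "n": self.n,
        }


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Pearson/Spearman/MSE; degenerate correlations are NaN with a warning."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mse = float(np.mean((y_true - y_pred) ** 2))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        warnings.warn("zero-variance predictions or truth; correlation undefined")
        return EvalReport(np.nan, np.nan, mse, len(y_true))
    pearson = float(stats.pearsonr(y_true, y_pred).statistic)
    spearman = float(stats.spearmanr(y_true, y_pred).statistic)
    return EvalReport(pearson, spearman, mse, len(y_true))


def _top_indices(values: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest values; ties broken by lower index (stable)."""
    order = np.argsort(-values, kind="stable")
    return order[:n]


def recall_at_budget(
    pred: np.ndarray, truth: np.ndarray, budget: int, top_k: int = 100
) -> float:
    """Fraction of the true top-k variants inside the model's top-``budget``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if len(truth) < top_k:
        raise ValueError(f"test set smaller than top_k={top_k}")
    true_top = set(_top_indices(truth, top_k).tolist())
    chosen = set(_top_indices(pred, budget).tolist())
    return len(true_top & chosen) / top_k


def top_n_stats(pred: np.ndarray, truth: np.ndarray, n: int) -> tuple[float, float]:
    """(mean, max) of the true scores of the top-n predicted variants."""
    idx = _top_indices(np.asarray(pred), n)
    chosen = np.asarray(truth)[idx]
    return float(chosen.mean()), float(chosen.max())


def random_baseline(
    test_size: int,
    budgets: Sequence[int],
    top_k: int = 100,
    n_rankings: int = 1000,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Recall of random rankings: budget -> (mean, 1.96 * SD half-width CI)."""
    rng = np.random.default_rng(seed)
    budgets = list(budgets)
    recalls = np.empty((n_rankings, len(budgets)))
    true_top = np.arange(top_k)  # which k indices are "true best" is arbitrary
    for r in range(n_rankings):
        ranking = rng.permutation(test_size)
        hits = np.isin(ranking, true_top)
        cum = np.cumsum(hits)
        for j, b in enumerate(budgets):
            recalls[r, j] = cum[min(b, test_size) - 1] / top_k
    means = recalls.mean(axis=0)
    half = 1.96 * recalls.std(axis=0)
    return {b: (float(m), float(h)) for b, m, h in zip(budgets, means, half)}
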