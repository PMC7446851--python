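"""Regression models, chain-grouped evaluation protocol and grid search.

Six model families predict normalized B-factors from topological feature
vectors: ridge and lasso regression (squared loss with L2/L1 penalty),
random forest, gradient-boosted trees (XGBoost), support vector regression
with an RBF kernel, and a small feed-forward neural network (sigmoid hidden
layers, leaky-ReLU output, 20% dropout).

The evaluation protocol is chain-grouped throughout: chains — never
individual nucleotides — are split 75/25 into train and test sets, and
hyperparameters are picked by five-fold cross-validation over train chains,
scoring each candidate by the Pearson correlation of the pooled
out-of-fold predictions.  Grouping by chain matters because nucleotides of
one chain share a normalization and are spatially correlated; a random
per-sample split would leak.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import Dataset, FeatureConfig

__all__ = [
    "ModelSpec",
    "SearchGrid",
    "EvalResult",
    "PRESETS",
    "model_from_preset",
    "split_chains",
    "make_cv_folds",
    "pcc",
    "train_model",
    "cross_validate",
    "grid_search",
    "evaluate",
    "assert_no_chain_leakage",
]

logger = logging.getLogger(__name__)

FAMILIES = ("ridge", "lasso", "rf", "xgboost", "svr", "ann")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters and seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


#: optimal hyperparameter presets for single-element and four-element
#: feature sets
PRESETS: dict[str, dict[str, dict]] = {
    "esph-single": {
        "ridge": {"alpha": 500.0},
        "lasso": {"alpha": 0.01},
        "rf": {"n_trees": 500, "min_samples_leaf": 5},
        "xgboost": {"n_trees": 50, "max_depth": 3},
        "svr": {"gamma": 0.01, "C": 0.1, "epsilon": 0.1},
        "ann": {"n_hidden_layers": 4, "nodes_per_layer": 68,
                "dropout": 0.2, "epochs": 15},
    },
    "esph-cnop": {
        "ridge": {"alpha": 500.0},
        "lasso": {"alpha": 1.0},
        "rf": {"n_trees": 2000, "min_samples_leaf": 5},
        "xgboost": {"n_trees": 50, "max_depth": 3},
        "svr": {"gamma": 0.001, "C": 0.1, "epsilon": 0.1},
        "ann": {"n_hidden_layers": 3, "nodes_per_layer": 900,
                "dropout": 0.2, "epochs": 10},
    },
}


def model_from_preset(family: str, preset: str = "esph-cnop", seed: int = 0) -> ModelSpec:
    return ModelSpec(family, dict(PRESETS[preset][family]), seed)


@dataclass(frozen=True)
class SearchGrid:
    """Feature-config grid crossed with per-family model-parameter grids."""

    cutoffs: tuple = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
    fe_ratios: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    bin_sizes: tuple = (0.15, 0.5, 1.0, 1.5)
    model_params: tuple = ({},)  # each entry a params dict for the family

    def feature_configs(self, base: FeatureConfig) -> list[FeatureConfig]:
        return [
            replace(base, cutoff=e, fe_ratio=r, bin_size=f)
            for e, r, f in itertools.product(self.cutoffs, self.fe_ratios, self.bin_sizes)
        ]


@dataclass
class EvalResult:
    """Predictions and Pearson correlations of one evaluation."""

    predictions: np.ndarray
    pcc: float
    per_chain_pcc: dict
    spec: ModelSpec | None = None
    feature_config: FeatureConfig | None = None


# ---------------------------------------------------------------------------
# protocol: splits, folds, metric
# ---------------------------------------------------------------------------


def split_chains(chains: Sequence, train_frac: float = 0.75, seed: int = 0):
    """Random chain-level train/test partition (no chain straddles)."""
    chains = list(chains)
    if len(chains) < 2:
        raise ValueError("need at least 2 chains to split")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chains))
    n_train = int(round(train_frac * len(chains)))
    n_train = min(max(n_train, 1), len(chains) - 1)
    train = [chains[i] for i in sorted(order[:n_train])]
    test = [chains[i] for i in sorted(order[n_train:])]
    return train, test


def make_cv_folds(chains: Sequence, k: int = 5, seed: int = 0) -> list[list]:
    """k chain-level folds with sizes differing by at most one."""
    chains = list(chains)
    if len(chains) < k:
        raise ValueError(f"cannot make {k} folds from {len(chains)} chains")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chains))
    base, extra = divmod(len(chains), k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append([chains[j] for j in sorted(order[start:start + size])])
        start += size
    return folds


def pcc(y, y_hat) -> float:
    """Pearson correlation between actual and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    dy = y - y.mean()
    dh = y_hat - y_hat.mean()
    denom = math.sqrt(float(dy @ dy) * float(dh @ dh))
    if denom == 0.0:
        raise ValueError("PCC undefined: a vector has zero variance")
    return float(dy @ dh) / denom


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------


class _LeakyMLP:
    """Minimal feed-forward net: sigmoid hidden layers, leaky-ReLU output,
    inverted dropout, Adam on mean-squared error.  Deterministic per seed."""

    def __init__(self, n_hidden_layers=3, nodes_per_layer=64, dropout=0.2,
                 epochs=10, batch_size=32, lr=1e-3, leak=0.01, seed=0):
        self.n_hidden_layers = int(n_hidden_layers)
        self.nodes = int(nodes_per_layer)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.leak = float(leak)
        self.seed = int(seed)

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd

        sizes = [X.shape[1]] + [self.nodes] * self.n_hidden_layers + [1]
        self._W = [
            rng.normal(scale=np.sqrt(2.0 / (a + b)), size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self._b = [np.zeros(b) for b in sizes[1:]]
        mW = [np.zeros_like(w) for w in self._W]
        vW = [np.zeros_like(w) for w in self._W]
        mb = [np.zeros_like(b) for b in self._b]
        vb = [np.zeros_like(b) for b in self._b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = Xs.shape[0]
        for _ in range(self.epochs):
            for idx in np.array_split(rng.permutation(n), max(1, n // self.batch_size)):
                xb, yb = Xs[idx], y[idx]
                acts, masks = [xb], []
                h = xb
                for li in range(self.n_hidden_layers):
                    h = self._sigmoid(h @ self._W[li] + self._b[li])
                    if self.dropout > 0:
                        keep = rng.random(h.shape) >= self.dropout
                        h = h * keep / (1.0 - self.dropout)
                        masks.append(keep)
                    else:
                        masks.append(None)
                    acts.append(h)
                z_out = h @ self._W[-1] + self._b[-1]
                pred = np.where(z_out > 0, z_out, self.leak * z_out).ravel()

                # backprop of mean squared error
                g = (2.0 / len(yb)) * (pred - yb)[:, None]
                g = g * np.where(z_out > 0, 1.0, self.leak)
                grads_W = [None] * len(self._W)
                grads_b = [None] * len(self._b)
                grads_W[-1] = acts[-1].T @ g
                grads_b[-1] = g.sum(axis=0)
                delta = g @ self._W[-1].T
                for li in range(self.n_hidden_layers - 1, -1, -1):
                    h = acts[li + 1]
                    if masks[li] is not None:
                        delta = delta * masks[li] / (1.0 - self.dropout)
                    delta = delta * h * (1.0 - h)  # sigmoid'
                    grads_W[li] = acts[li].T @ delta
                    grads_b[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = delta @ self._W[li].T

                t += 1
                for li in range(len(self._W)):
                    for store, mom, vel, grad in (
                        (self._W, mW, vW, grads_W),
                        (self._b, mb, vb, grads_b),
                    ):
                        mom[li] = beta1 * mom[li] + (1 - beta1) * grad[li]
                        vel[li] = beta2 * vel[li] + (1 - beta2) * grad[li] ** 2
                        mhat = mom[li] / (1 - beta1**t)
                        vhat = vel[li] / (1 - beta2**t)
                        store[li] = store[li] - self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict(self, X):
        h = (np.asarray(X, dtype=float) - self._mu) / self._sd
        for li in range(self.n_hidden_layers):
            h = self._sigmoid(h @ self._W[li] + self._b[li])
        z = h @ self._W[-1] + self._b[-1]
        return np.where(z > 0, z, self.leak * z).ravel()


def train_model(spec: ModelSpec, X, y):
    """Fit one model family; returns an object with ``predict``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    params = dict(spec.params)
    if spec.family == "ridge":
        from sklearn.linear_model import Ridge

        return Ridge(alpha=params.get("alpha", 1.0)).fit(X, y)
    if spec.family == "lasso":
        from sklearn.linear_model import Lasso

        return Lasso(alpha=params.get("alpha", 1.0), max_iter=50_000).fit(X, y)
    if spec.family == "rf":
        from sklearn.ensemble import RandomForestRegressor

        mtry = min(p, math.ceil(math.sqrt(p)))  # Breiman's sqrt(p) rule
        return RandomForestRegressor(
            n_estimators=int(params.get("n_trees", 500)),
            min_samples_leaf=int(params.get("min_samples_leaf", 5)),
            max_features=mtry,
            random_state=spec.seed,
            n_jobs=1,
        ).fit(X, y)
    if spec.family == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=int(params.get("n_trees", 50)),
            max_depth=int(params.get("max_depth", 3)),
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        ).fit(X, y)
    if spec.family == "svr":
        from sklearn.svm import SVR

        return SVR(
            kernel="rbf",
            gamma=params.get("gamma", "scale"),
            C=params.get("C", 1.0),
            epsilon=params.get("epsilon", 0.1),
        ).fit(X, y)
    if spec.family == "ann":
        return _LeakyMLP(
            n_hidden_layers=params.get("n_hidden_layers", 3),
            nodes_per_layer=params.get("nodes_per_layer", 64),
            dropout=params.get("dropout", 0.2),
            epochs=params.get("epochs", 10),
            batch_size=params.get("batch_size", 32),
            lr=params.get("lr", 1e-3),
            seed=spec.seed,
        ).fit(X, y)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# protocol drivers
# ---------------------------------------------------------------------------


def cross_validate(spec: ModelSpec, dataset: Dataset, k: int = 5, seed: int = 0):
    """Pooled out-of-fold PCC over chain-level folds.

    Each fold's samples are predicted by a model trained on the other
    folds' chains only; all out-of-fold predictions are pooled into one
    Pearson correlation.  Returns ``(pcc, predictions)`` with predictions
    aligned to ``dataset`` rows.
    """
    folds = make_cv_folds(dataset.chains, k=k, seed=seed)
    preds = np.full(len(dataset), np.nan)
    for fold in folds:
        held = set(fold)
        test_mask = np.array([c in held for c in dataset.chain_labels])
        model = train_model(spec, dataset.X[~test_mask], dataset.y[~test_mask])
        preds[test_mask] = model.predict(dataset.X[test_mask])
    assert not np.isnan(preds).any()
    return pcc(dataset.y, preds), preds


def grid_search(
    dataset_builder: Callable[[FeatureConfig], Dataset],
    grid: SearchGrid,
    family: str,
    base_config: FeatureConfig | None = None,
    k: int = 5,
    seed: int = 0,
):
    """Exhaustive search over feature configs x model params by CV PCC.

    ``dataset_builder`` maps a :class:`FeatureConfig` to a train
    :class:`Dataset` (it must always use the same chains).  Returns
    ``(best_feature_config, best_model_spec, best_pcc, table)`` where
    ``table`` is a DataFrame of all scores; failed combinations score NaN.
    """
    base = base_config or FeatureConfig()
    records = []
    best = (None, None, -np.inf)
    for fc in grid.feature_configs(base):
        try:
            ds = dataset_builder(fc)
        except Exception as exc:  # noqa: BLE001 - scored as missing
            logger.warning("feature config %s failed: %s", fc, exc)
            ds = None
        for params in grid.model_params:
            rec = {
                "cutoff": fc.cutoff, "fe_ratio": fc.fe_ratio,
                "bin_size": fc.bin_size, **{f"m_{k_}": v for k_, v in params.items()},
            }
            if ds is None:
                rec["cv_pcc"] = np.nan
            else:
                spec = ModelSpec(family, dict(params), seed=seed)
                try:
                    score, _ = cross_validate(spec, ds, k=k, seed=seed)
                except Exception as exc:  # noqa: BLE001
                    logger.warning("combination %s failed: %s", rec, exc)
                    score = np.nan
                rec["cv_pcc"] = score
                if np.isfinite(score) and score > best[2]:
                    best = (fc, ModelSpec(family, dict(params), seed=seed), score)
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    if best[0] is None:
        raise RuntimeError("no grid combination trained successfully")
    return best[0], best[1], best[2], table


def evaluate(model, test: Dataset, spec: ModelSpec | None = None) -> EvalResult:
    """Overall and per-chain PCC of a fitted model on held-out chains."""
    if len(test) == 0:
        raise ValueError("empty test set")
    preds = np.asarray(model.predict(test.X), dtype=float)
    overall = pcc(test.y, preds)
    per_chain: dict = {}
    for chain in test.chains:
        mask = test.chain_labels == chain
        if mask.sum() < 2:
            logger.warning("chain %s: < 2 samples, per-chain PCC skipped", chain)
            continue
        try:
            per_chain[chain] = pcc(test.y[mask], preds[mask])
        except ValueError:
            logger.warning("chain %s: zero variance, per-chain PCC skipped", chain)
    return EvalResult(preds, overall, per_chain, spec, test.config)


def assert_no_chain_leakage(train_chains: Sequence, test_chains: Sequence) -> None:
    """Raise if any chain appears on both sides of a split."""
    overlap = set(train_chains) & set(test_chains)
    if overlap:
        raise ValueError(f"chain leakage: {sorted(overlap)} in both train and test")
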