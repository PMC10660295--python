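"""Regressors behind a single train/predict contract.

Three learners share the contract: the one-hidden-layer MLP trained with
RAdam + MSE (the primary model), and random-forest (RF) and gradient-boosting
(GBX) comparators.  All consume the same 3810-wide pair features and the same
split plans, so algorithm comparisons differ only in the learner.

Deployed predictions are made order-invariant *exactly* by averaging the raw
model output over both compound orders; inversion-augmented training makes the
raw outputs approximately symmetric, and the averaging turns that approximate
behaviour into a hard contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .features import (
    COMPOUND_WIDTH,
    PAIR_WIDTH,
    PUBCHEM_WIDTH,
    CompoundRecord,
    PairFeature,
    featurize_pair,
    feature_layout_id,
    swap_pair_vector,
)


def fingerprint_mask(combination: str) -> np.ndarray | None:
    """0/1 column mask selecting the fingerprint blocks a model uses, or
    ``None`` for the full dual-fingerprint layout."""
    if combination == "pubchem+morgan":
        return None
    mask = np.zeros(PAIR_WIDTH, dtype=np.float32)
    for offset in (0, COMPOUND_WIDTH):
        if combination == "pubchem":
            mask[offset : offset + PUBCHEM_WIDTH] = 1.0
        else:  # morgan
            mask[offset + PUBCHEM_WIDTH : offset + COMPOUND_WIDTH] = 1.0
    return mask
from .mlp import NumpyMLP
from .evaluation import pcc

ALGORITHMS = ("mlp", "rf", "gbx")


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the MLP path.

    The defaults reproduce the winning configuration: a single hidden layer
    trained with RAdam on MSE for 2048 epochs.  Hidden width, batch size and
    learning rate are first-class tuning axes; tests and desk-scale runs
    override ``epochs`` downwards.
    """

    hidden_layers: int = 1
    hidden_width: int = 1024
    optimizer: str = "radam"
    loss: str = "mse"
    epochs: int = 2048
    learning_rate: float = 1e-3
    batch_size: int = 256
    #: fingerprint combination used by the model ("pubchem+morgan",
    #: "pubchem", or "morgan") — a tuning axis; unused blocks are masked out
    #: of the fixed 3810-wide layout rather than re-shaping it
    fingerprints: str = "pubchem+morgan"
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers < 1 or self.hidden_width < 1 or self.epochs < 0:
            raise ValueError("invalid MLP configuration")
        if self.optimizer != "radam" or self.loss != "mse":
            raise ValueError("supported optimizer/loss: radam + mse")
        if self.fingerprints not in ("pubchem+morgan", "pubchem", "morgan"):
            raise ValueError(f"unknown fingerprint combination {self.fingerprints!r}")

    def n_parameters(self, n_features: int = PAIR_WIDTH) -> int:
        dims = [n_features] + [self.hidden_width] * self.hidden_layers + [1]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 200
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    min_samples_split: int = 2
    seed: int = 0


@dataclass(frozen=True)
class GBXConfig:
    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    min_child_weight: float = 1.0
    seed: int = 0


_CONFIG_TYPES = {"mlp": MLPConfig, "rf": RFConfig, "gbx": GBXConfig}


def default_config(algorithm: str):
    if algorithm not in _CONFIG_TYPES:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return _CONFIG_TYPES[algorithm]()


@dataclass
class TrainedModel:
    """A fitted per-cell-line regressor plus its provenance."""

    cell_line: str
    algorithm: str
    config: object
    fold_index: int
    validation_pcc: float | None
    feature_layout: str
    plan_hash: str = ""
    _impl: object = field(repr=False, default=None)

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Raw (order-sensitive) model output on pair feature rows."""
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != PAIR_WIDTH:
            raise ValueError(
                f"feature width {X.shape[1]} does not match pair width {PAIR_WIDTH}"
            )
        mask = fingerprint_mask(getattr(self.config, "fingerprints", "pubchem+morgan"))
        if mask is not None:
            X = X * mask
        return np.asarray(self._impl.predict(X), dtype=np.float64)

    def predict_symmetric(self, X: np.ndarray) -> np.ndarray:
        """Order-invariant prediction: mean of raw outputs on both orders."""
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        return 0.5 * (self.predict_raw(X) + self.predict_raw(swap_pair_vector(X)))


def _as_matrix(rows) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(rows, tuple) and len(rows) == 2 and isinstance(rows[0], np.ndarray):
        return rows
    X_list, y_list = [], []
    for i, (feat, score) in enumerate(rows):
        vec = feat.vector if isinstance(feat, PairFeature) else np.asarray(feat)
        if vec.shape[0] != PAIR_WIDTH:
            raise ValueError(
                f"row {i}: feature width {vec.shape[0]} != {PAIR_WIDTH}"
            )
        X_list.append(vec)
        y_list.append(score)
    return np.asarray(X_list, dtype=np.float32), np.asarray(y_list, dtype=np.float64)


def train_regressor(
    algorithm: str,
    train_rows,
    config=None,
    *,
    cell_line: str = "",
    fold_index: int = -1,
    init_from: TrainedModel | None = None,
) -> TrainedModel:
    """Fit a regressor on (pair feature, score) rows.

    ``train_rows`` is a sequence of ``(PairFeature | vector, score)`` tuples or
    a pre-built ``(X, y)`` matrix pair; the MLP path expects rows already
    augmented with inversion.  ``init_from`` warm-starts the MLP from an
    existing model's weights instead of a fresh random initialization.
    Training is deterministic under a fixed config seed.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    config = config if config is not None else default_config(algorithm)
    X, y = _as_matrix(train_rows)
    if len(X) == 0:
        raise ValueError("empty training set")

    if algorithm == "mlp":
        mask = fingerprint_mask(config.fingerprints)
        if mask is not None:
            X = X * mask
        net = NumpyMLP(
            n_features=X.shape[1],
            hidden_width=config.hidden_width,
            hidden_layers=config.hidden_layers,
            seed=config.seed,
        )
        if init_from is not None:
            if init_from.algorithm != "mlp":
                raise ValueError("can only warm start from an MLP model")
            if init_from.feature_layout != feature_layout_id():
                raise ValueError("feature layout mismatch between base and new model")
            net.load_weights_from(init_from._impl)
        if config.epochs > 0:
            net.fit(
                X,
                y,
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                shuffle_seed=config.seed + 1,
            )
        impl = net
    elif algorithm == "rf":
        from sklearn.ensemble import RandomForestRegressor

        if init_from is not None:
            raise ValueError("warm start is only supported for the MLP")
        impl = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            max_features=config.max_features,
            min_samples_split=config.min_samples_split,
            random_state=config.seed,
            n_jobs=1,
        ).fit(X, y)
    else:  # gbx
        from xgboost import XGBRegressor

        if init_from is not None:
            raise ValueError("warm start is only supported for the MLP")
        impl = XGBRegressor(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            min_child_weight=config.min_child_weight,
            random_state=config.seed,
            n_jobs=1,
            verbosity=0,
        ).fit(X, y)

    return TrainedModel(
        cell_line=cell_line,
        algorithm=algorithm,
        config=config,
        fold_index=fold_index,
        validation_pcc=None,
        feature_layout=feature_layout_id(),
        _impl=impl,
    )


def predict_pair(model: TrainedModel, c1: CompoundRecord, c2: CompoundRecord) -> float:
    """Order-invariant Bliss-score prediction for a compound pair."""
    if model.feature_layout != feature_layout_id():
        raise ValueError(
            "model feature layout does not match the runtime featurizer: "
            f"{model.feature_layout} vs {feature_layout_id()}"
        )
    vec = featurize_pair(c1, c2).vector.astype(np.float32)
    return float(model.predict_symmetric(vec)[0])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (weights, config, provenance, feature-layout
    fingerprint) into a single archive file."""
    payload = {
        "cell_line": model.cell_line,
        "algorithm": model.algorithm,
        "config": asdict(model.config),
        "fold_index": model.fold_index,
        "validation_pcc": model.validation_pcc,
        "feature_layout": model.feature_layout,
        "plan_hash": model.plan_hash,
    }
    if model.algorithm == "mlp":
        payload["state"] = model._impl.state_dict()
    else:
        payload["state"] = model._impl
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    algorithm = payload["algorithm"]
    config = _CONFIG_TYPES[algorithm](**payload["config"])
    if payload["feature_layout"] != feature_layout_id():
        raise ValueError(
            "archived model was trained with a different feature layout: "
            f"{payload['feature_layout']!r}"
        )
    impl = (
        NumpyMLP.from_state_dict(payload["state"])
        if algorithm == "mlp"
        else payload["state"]
    )
    return TrainedModel(
        cell_line=payload["cell_line"],
        algorithm=algorithm,
        config=config,
        fold_index=payload["fold_index"],
        validation_pcc=payload["validation_pcc"],
        feature_layout=payload["feature_layout"],
        plan_hash=payload.get("plan_hash", ""),
        _impl=impl,
    )


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def _config_size(algorithm: str, config) -> float:
    """Tie-break size: prefer the smaller model."""
    if algorithm == "mlp":
        return config.n_parameters()
    return float(config.n_estimators) * float(config.max_depth or 64)


def tune_hyperparameters(
    algorithm: str,
    grid: dict[str, Sequence],
    plan,
    cell_data,
    base_config=None,
    *,
    feature_table=None,
):
    """Evaluate every grid point with the identical split plan.

    ``grid`` maps config field names to candidate values.  Every grid point is
    cross-validated on the same folds (no per-config resplitting) and ranked by
    mean validation PCC; ties break toward the smaller configuration, then
    lexicographically on the config repr.  Returns a pandas DataFrame ranked
    best-first with columns ``config``, ``mean_validation_pcc``.
    """
    import pandas as pd

    from .training import FeatureTable, _run_folds

    base = base_config if base_config is not None else default_config(algorithm)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    table = feature_table if feature_table is not None else FeatureTable(cell_data)
    axes = sorted(grid.items())
    results = []
    for values in itertools.product(*(v for _, v in axes)):
        config = replace(base, **dict(zip((k for k, _ in axes), values)))
        try:
            fold_results = [fr for fr, _ in _run_folds(table, plan, algorithm, config)]
        except Exception as exc:
            raise RuntimeError(f"grid point {config} failed: {exc}") from exc
        mean_pcc = float(np.mean([fr.validation_pcc for fr in fold_results]))
        results.append(
            {
                "config": config,
                "mean_validation_pcc": mean_pcc,
                "_size": _config_size(algorithm, config),
            }
        )
    results.sort(
        key=lambda r: (-r["mean_validation_pcc"], r["_size"], repr(r["config"]))
    )
    df = pd.DataFrame(
        [
            {"rank": i + 1, "config": r["config"],
             "mean_validation_pcc": r["mean_validation_pcc"]}
            for i, r in enumerate(results)
        ]
    )
    return df
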