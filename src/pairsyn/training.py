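"""Experiment orchestration: per-cell k-fold CV with best-network selection,
warm-start retraining across datasets, combined stratified training, and the
single-network-for-all-cells probe.

The protocol for every cell line: split its unordered pair groups 90/10 into
working/test, k-fold the working set, train one fresh network per fold on the
inversion-augmented training rows, validate on the held-out fold, pick the
fold with the highest validation PCC, and evaluate that single best model
exactly once on the untouched test groups.  The epoch-0 validation PCC of
every fold is recorded: it must sit near zero for cold starts (fresh random
weights carry no signal) and materially above zero after a warm start from a
model trained on correlated data — the bookkeeping that proves no model reuse
or, respectively, real transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, GroupKey, SplitPlan, make_split_plan, per_cell_partition
from .evaluation import bootstrap_pcc_se, pcc
from .features import augment_matrix, compound_features, COMPOUND_WIDTH
from .models import (
    MLPConfig,
    TrainedModel,
    default_config,
    train_regressor,
)


class FeatureTable:
    """Cached pair-feature matrix for one dataset.

    Replicate rows of the same (cell line agnostic) unordered pair are
    aggregated by mean, giving one modelling row per pair group.  Features are
    assembled from per-compound blocks, so each compound is fingerprinted
    once.  A test-access counter backs the test-set hygiene invariant.
    """

    def __init__(self, data: Dataset):
        comp_feats: dict[str, np.ndarray] = {}
        scores: dict[GroupKey, list[float]] = {}
        for rec in data.records:
            for c in (rec.compound_a, rec.compound_b):
                if c.smiles not in comp_feats:
                    comp_feats[c.smiles] = compound_features(c).astype(np.float32)
            scores.setdefault(rec.pair_key, []).append(rec.bliss_score)
        self._comp_feats = comp_feats
        self._y = {k: float(np.mean(v)) for k, v in scores.items()}
        self.test_access_count = 0

    def groups(self) -> list[GroupKey]:
        return sorted(self._y)

    def matrix(
        self, groups, *, is_test: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for the given pair groups, one row per group, compound
        blocks in sorted-canonical-SMILES order."""
        if is_test:
            self.test_access_count += 1
        X = np.empty((len(groups), 2 * COMPOUND_WIDTH), dtype=np.float32)
        y = np.empty(len(groups), dtype=np.float64)
        for i, key in enumerate(groups):
            a, b = key
            X[i, :COMPOUND_WIDTH] = self._comp_feats[a]
            X[i, COMPOUND_WIDTH:] = self._comp_feats[b]
            y[i] = self._y[key]
        return X, y


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    validation_pcc: float
    epoch0_validation_pcc: float | None
    n_train: int
    n_validation: int


@dataclass
class CVResult:
    """Cross-validation outcome for one cell line."""

    cell_line: str
    algorithm: str
    per_fold: list[FoldResult]
    best_fold: int
    test_pcc: float
    test_pcc_se: float
    n_test: int
    seed: int
    plan_hash: str
    test_access_count: int
    best_model: TrainedModel = field(repr=False, default=None)

    @property
    def validation_pccs(self) -> list[float]:
        return [f.validation_pcc for f in self.per_fold]

    def to_dict(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "algorithm": self.algorithm,
            "per_fold": [
                {
                    "fold_index": f.fold_index,
                    "validation_pcc": f.validation_pcc,
                    "epoch0_validation_pcc": f.epoch0_validation_pcc,
                    "n_train": f.n_train,
                    "n_validation": f.n_validation,
                }
                for f in self.per_fold
            ],
            "best_fold": self.best_fold,
            "test_pcc": self.test_pcc,
            "test_pcc_se": self.test_pcc_se,
            "n_test": self.n_test,
            "seed": self.seed,
            "plan_hash": self.plan_hash,
            "test_access_count": self.test_access_count,
        }


def _fold_seed(base_seed: int, fold: int) -> int:
    return (base_seed * 100003 + 7919 * fold + 1) % (2**31)


def _epoch0_probe(algorithm, config, X_train, y_train, X_val, y_val, init_from):
    """Validation PCC of the untrained (epoch-0) network."""
    if algorithm != "mlp":
        return None
    probe = train_regressor(
        "mlp",
        (X_train[:1], y_train[:1]),
        replace(config, epochs=0),
        init_from=init_from,
    )
    try:
        return pcc(y_val, probe._impl.predict(X_val))
    except Exception:
        return None


def _run_folds(
    table: FeatureTable,
    plan: SplitPlan,
    algorithm: str,
    config,
    init_from: TrainedModel | None = None,
    cell_line: str = "",
):
    """Train one model per fold; returns (FoldResult, model) pairs flattened
    into FoldResults with models attached."""
    out = []
    for fold_index, (train_groups, val_groups) in enumerate(plan.folds):
        X_tr, y_tr = table.matrix(train_groups)
        X_va, y_va = table.matrix(val_groups)
        if len(np.unique(y_va)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {fold_index}: fewer than 2 distinct target values; "
                "PCC undefined"
            )
        fold_config = (
            replace(config, seed=_fold_seed(config.seed, fold_index))
            if algorithm == "mlp"
            else config
        )
        epoch0 = _epoch0_probe(
            algorithm, fold_config, X_tr, y_tr, X_va, y_va, init_from
        )
        # comparators consume the same augmented rows as the MLP path
        X_fit, y_fit = augment_matrix(X_tr, y_tr)
        model = train_regressor(
            algorithm,
            (X_fit, y_fit),
            fold_config,
            cell_line=cell_line,
            fold_index=fold_index,
            init_from=init_from,
        )
        val_pred = model.predict_symmetric(X_va)
        val_pcc = pcc(y_va, val_pred)
        model.validation_pcc = val_pcc
        fr = FoldResult(
            fold_index=fold_index,
            validation_pcc=val_pcc,
            epoch0_validation_pcc=epoch0,
            n_train=len(y_tr),
            n_validation=len(y_va),
        )
        out.append((fr, model))
    return out


def cross_validate(
    cell_data: Dataset,
    plan: SplitPlan,
    config=None,
    algorithm: str = "mlp",
    *,
    init_from: TrainedModel | None = None,
    cell_line: str | None = None,
) -> CVResult:
    """Run the full per-cell protocol and return its :class:`CVResult`.

    Each fold trains a freshly initialized network (or a warm-started one when
    ``init_from`` is given); the best-by-validation-PCC model alone touches
    the 10% test groups, exactly once.
    """
    config = config if config is not None else default_config(algorithm)
    cell = cell_line or (cell_data.cell_lines[0] if cell_data.cell_lines else "")
    table = FeatureTable(cell_data)
    fold_pairs = _run_folds(
        table, plan, algorithm, config, init_from=init_from, cell_line=cell
    )
    fold_results = [fr for fr, _ in fold_pairs]
    models = [m for _, m in fold_pairs]
    best = int(np.argmax([fr.validation_pcc for fr in fold_results]))
    for m in models:
        m.plan_hash = plan.plan_hash()
    X_te, y_te = table.matrix(plan.test_groups, is_test=True)
    test_pred = models[best].predict_symmetric(X_te)
    test_pcc = pcc(y_te, test_pred)
    return CVResult(
        cell_line=cell,
        algorithm=algorithm,
        per_fold=fold_results,
        best_fold=best,
        test_pcc=test_pcc,
        test_pcc_se=bootstrap_pcc_se(y_te, test_pred, seed=config.seed),
        n_test=len(y_te),
        seed=config.seed,
        plan_hash=plan.plan_hash(),
        test_access_count=table.test_access_count,
        best_model=models[best],
    )


def retrain_warm_start(
    base: TrainedModel,
    new_data: Dataset,
    plan: SplitPlan,
    config=None,
    *,
    cell_line: str | None = None,
) -> CVResult:
    """Retrain on a second dataset, initializing every fold from the base
    model's weights instead of a random initialization.

    The new dataset gets its own split plan; the overlap of its test groups
    with the base data is not controlled here and should be reported by the
    caller when the two datasets share pairs.
    """
    return cross_validate(
        new_data,
        plan,
        config,
        algorithm="mlp",
        init_from=base,
        cell_line=cell_line,
    )


@dataclass
class StrategyReport:
    """Comparison table for a training-strategy study."""

    strategy: str
    per_cell: dict[str, dict[str, float]]
    details: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"cell_line": cell, **vals} for cell, vals in sorted(self.per_cell.items())]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"strategy": self.strategy, "per_cell": self.per_cell}, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def combined_stratified_cv(
    data_a: Dataset,
    data_b: Dataset,
    k: int = 10,
    seed: int = 0,
    config=None,
    *,
    cell_lines: list[str] | None = None,
) -> StrategyReport:
    """Combined-dataset training with source-stratified folds, compared
    against the warm-start retraining strategy under matched seeds.

    Both datasets are merged per cell line; folds preserve the A:B group
    ratio within one group per source.  For a fair comparison both strategies
    are scored on the same test groups — the B-source test groups, which both
    protocols hold out.  Cell lines missing one source run unstratified with
    a warning.
    """
    import logging

    from .data import make_stratified_split_plan

    logger = logging.getLogger(__name__)
    config = config if config is not None else MLPConfig()
    cells_a = per_cell_partition(data_a)
    cells_b = per_cell_partition(data_b)
    cells = cell_lines or sorted(set(cells_a) | set(cells_b))
    per_cell: dict[str, dict[str, float]] = {}
    details: dict = {}
    for cell in cells:
        da = cells_a.get(cell, Dataset())
        db = cells_b.get(cell, Dataset())
        if len(da) == 0 or len(db) == 0:
            logger.warning(
                "cell line %s missing from one source; running unstratified", cell
            )
            present = da if len(da) else db
            plan = make_split_plan(present, k=k, seed=seed)
            cv = cross_validate(present, plan, config, cell_line=cell)
            per_cell[cell] = {"combined_test_pcc": cv.test_pcc}
            continue

        groups_a = set(da.group_keys())
        groups_b = set(db.group_keys()) - groups_a  # shared pairs stay with A
        by_source = {
            src: sorted(g)
            for src, g in (("A", groups_a), ("B", groups_b))
            if g
        }
        if len(by_source) > 1:
            plan_combined = make_stratified_split_plan(by_source, k=k, seed=seed)
        else:  # full pair overlap: stratification is degenerate
            plan_combined = make_split_plan(sorted(groups_a | groups_b), k=k, seed=seed)
        merged = Dataset(da.records + db.records)
        cv_combined = cross_validate(merged, plan_combined, config, cell_line=cell)

        # matched-seed retraining baseline: train on A, warm-start on B
        plan_a = make_split_plan(da, k=k, seed=seed)
        plan_b = make_split_plan(db, k=k, seed=seed)
        cv_base = cross_validate(da, plan_a, config, cell_line=cell)
        cv_retrain = retrain_warm_start(
            cv_base.best_model, db, plan_b, config, cell_line=cell
        )

        # score both strategies on the identical B-source test groups
        table_b = FeatureTable(db)
        test_b = [g for g in plan_b.test_groups]
        X_te, y_te = table_b.matrix(test_b, is_test=True)
        pcc_combined_on_b = pcc(y_te, cv_combined.best_model.predict_symmetric(X_te))
        pcc_retrain_on_b = pcc(y_te, cv_retrain.best_model.predict_symmetric(X_te))
        per_cell[cell] = {
            "combined_test_pcc": pcc_combined_on_b,
            "retrain_test_pcc": pcc_retrain_on_b,
            "delta_retrain_minus_combined": pcc_retrain_on_b - pcc_combined_on_b,
        }
        details[cell] = {
            "combined": cv_combined.to_dict(),
            "retrain": cv_retrain.to_dict(),
            "base": cv_base.to_dict(),
        }
    return StrategyReport(
        strategy="combined_stratified", per_cell=per_cell, details=details
    )


def single_network_experiment(
    data: Dataset,
    cell_subset: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    config=None,
    max_cells: int = 6,
) -> StrategyReport:
    """Train one pooled network over several cell lines (cell identity is NOT
    encoded in the features) and compare per-cell test PCC against per-cell
    baselines trained on the same splits.

    Reports the per-cell PCCs of both setups and their dispersion
    (max - min); with heterogeneous per-cell synergy landscapes the pooled
    network's performance is dominated by a few cell lines.
    """
    config = config if config is not None else MLPConfig()
    cells_map = per_cell_partition(data)
    if len(cells_map) < 1:
        raise ValueError("no cell lines in dataset")
    cells = cell_subset or sorted(cells_map)
    if cell_subset is None and len(cells) > max_cells:
        rng = np.random.default_rng(seed)
        cells = sorted(rng.choice(sorted(cells_map), size=max_cells, replace=False))

    plans = {cell: make_split_plan(cells_map[cell], k=k, seed=seed) for cell in cells}
    tables = {cell: FeatureTable(cells_map[cell]) for cell in cells}

    # pooled training rows: union of each cell's fold-0 training partition
    X_parts, y_parts = [], []
    for cell in cells:
        X_tr, y_tr = tables[cell].matrix(plans[cell].folds[0][0])
        X_parts.append(X_tr)
        y_parts.append(y_tr)
    X_pool, y_pool = augment_matrix(np.vstack(X_parts), np.concatenate(y_parts))
    pooled = train_regressor(
        "mlp", (X_pool, y_pool), config, cell_line="(pooled)", fold_index=0
    )

    per_cell: dict[str, dict[str, float]] = {}
    for cell in cells:
        X_te, y_te = tables[cell].matrix(plans[cell].test_groups, is_test=True)
        pooled_pcc = pcc(y_te, pooled.predict_symmetric(X_te))
        # per-cell baseline on the identical fold-0 split and test groups
        X_tr, y_tr = tables[cell].matrix(plans[cell].folds[0][0])
        solo = train_regressor(
            "mlp", augment_matrix(X_tr, y_tr), config, cell_line=cell, fold_index=0
        )
        solo_pcc = pcc(y_te, solo.predict_symmetric(X_te))
        per_cell[cell] = {
            "single_network_test_pcc": pooled_pcc,
            "per_cell_test_pcc": solo_pcc,
        }
    pooled_vals = [v["single_network_test_pcc"] for v in per_cell.values()]
    solo_vals = [v["per_cell_test_pcc"] for v in per_cell.values()]
    details = {
        "single_network_dispersion": float(np.max(pooled_vals) - np.min(pooled_vals)),
        "per_cell_dispersion": float(np.max(solo_vals) - np.min(solo_vals)),
        "n_cells": len(cells),
    }
    return StrategyReport(
        strategy="single_network", per_cell=per_cell, details=details
    )


# ---------------------------------------------------------------------------
# Model/Results front end
# ---------------------------------------------------------------------------


class CellLineSynergyModel:
    """Per-cell-line synergy regression model.

    A thin, statsmodels-flavoured front end over the split/train/select
    pipeline: build the model from a dataset (or normalized dataframe), call
    :meth:`fit`, and read estimates and diagnostics off the returned results
    object.

    Examples
    --------
    >>> scen = SyntheticScenario.default(n_compounds=12, seed=0)   # doctest: +SKIP
    >>> model = CellLineSynergyModel(generate_screen(scen), cell_line="CELL_A")
    >>> res = model.fit(k=3, seed=1)                                # doctest: +SKIP
    >>> print(res.summary())                                        # doctest: +SKIP
    """

    def __init__(
        self,
        data: Dataset,
        cell_line: str | None = None,
        algorithm: str = "mlp",
        config=None,
    ):
        cells = data.cell_lines
        if cell_line is None:
            if len(cells) != 1:
                raise ValueError(
                    f"dataset has cell lines {cells}; pass cell_line explicitly"
                )
            cell_line = cells[0]
        if cell_line not in cells:
            raise ValueError(f"cell line {cell_line!r} not in dataset ({cells})")
        self.data = data.subset(cell_line)
        self.cell_line = cell_line
        self.algorithm = algorithm
        self.config = config if config is not None else default_config(algorithm)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CellLineSynergyModel":
        from .features import validate_smiles
        from .data import SynergyRecord

        records = [
            SynergyRecord(
                cell_line=str(row.cell_line),
                compound_a=validate_smiles(str(row.smiles_a)),
                compound_b=validate_smiles(str(row.smiles_b)),
                bliss_score=float(row.bliss_score),
                source=str(getattr(row, "source", "")),
            )
            for row in df.itertuples()
        ]
        return cls(Dataset(records), **kwargs)

    def fit(
        self, k: int = 10, seed: int = 0, plan: SplitPlan | None = None
    ) -> "CellLineSynergyResults":
        if plan is None:
            plan = make_split_plan(self.data, k=k, seed=seed)
        config = (
            replace(self.config, seed=seed)
            if hasattr(self.config, "seed")
            else self.config
        )
        cv = cross_validate(
            self.data, plan, config, algorithm=self.algorithm, cell_line=self.cell_line
        )
        return CellLineSynergyResults(self, cv, plan)


class CellLineSynergyResults:
    """Fitted results: per-fold diagnostics, the selected network, and
    order-invariant prediction."""

    def __init__(self, model: CellLineSynergyModel, cv: CVResult, plan: SplitPlan):
        self.model = model
        self.cv = cv
        self.plan = plan

    # estimator-style accessors
    @property
    def test_pcc(self) -> float:
        return self.cv.test_pcc

    @property
    def test_pcc_se(self) -> float:
        return self.cv.test_pcc_se

    @property
    def validation_pccs(self) -> list[float]:
        return self.cv.validation_pccs

    @property
    def best_model(self) -> TrainedModel:
        return self.cv.best_model

    def predict(self, smiles_a: str, smiles_b: str) -> float:
        from .features import validate_smiles
        from .models import predict_pair

        return predict_pair(
            self.cv.best_model, validate_smiles(smiles_a), validate_smiles(smiles_b)
        )

    def save(self, path: str | Path) -> None:
        from .models import save_model

        save_model(self.cv.best_model, path)

    def summary(self) -> str:
        cv = self.cv
        lines = [
            "Cell-line synergy regression results",
            "=" * 54,
            f"cell line:        {cv.cell_line}",
            f"algorithm:        {cv.algorithm}",
            f"folds (k):        {len(cv.per_fold)}",
            f"seed:             {cv.seed}",
            f"split plan hash:  {cv.plan_hash}",
            "-" * 54,
            "fold   val PCC    epoch-0 val PCC",
        ]
        for f in cv.per_fold:
            e0 = "-" if f.epoch0_validation_pcc is None else f"{f.epoch0_validation_pcc:+.3f}"
            marker = "  <- best" if f.fold_index == cv.best_fold else ""
            lines.append(f"{f.fold_index:>4}   {f.validation_pcc:+.3f}     {e0}{marker}")
        lines += [
            "-" * 54,
            f"test PCC:         {cv.test_pcc:.3f} (bootstrap se {cv.test_pcc_se:.3f}, "
            f"n={cv.n_test})",
            "=" * 54,
        ]
        return "\n".join(lines)
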