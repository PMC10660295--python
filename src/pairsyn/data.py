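"""Synergy tables, per-cell partitions and the 90/10 + k-fold split plan.

The normalized ingestion schema is a CSV with columns ``cell_line``,
``smiles_a``, ``smiles_b``, ``bliss_score`` and an optional ``source`` tag.
Replicate rows for the same (cell line, unordered pair) are aggregated at the
reader boundary (mean by default).  All partitioning operates on *unordered
pair groups* rather than raw rows so that a pair and its mirror or replicate
can never straddle a train/test boundary.

The split follows the working/test + k-fold protocol: 90% of pair groups form
the working set and 10% the untouched test set; the working set is k-folded
into train/validation combinations, giving effective 81/9/10 fractions at
k = 10.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CompoundRecord, InvalidSMILESError, validate_smiles

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_line", "smiles_a", "smiles_b", "bliss_score")

GroupKey = tuple[str, str]


@dataclass(frozen=True)
class SynergyRecord:
    """One (cell line, compound pair, Bliss score) observation.

    ``bliss_score`` is the Bliss excess: observed combined fractional effect
    minus the Bliss-independence expectation.  Positive values mean synergy
    under the adopted convention.
    """

    cell_line: str
    compound_a: CompoundRecord
    compound_b: CompoundRecord
    bliss_score: float
    source: str = ""

    @property
    def pair_key(self) -> GroupKey:
        """Unordered-pair identity key (canonical SMILES, sorted)."""
        return tuple(sorted((self.compound_a.smiles, self.compound_b.smiles)))


@dataclass
class Dataset:
    """A collection of synergy records with per-cell-line views."""

    records: list[SynergyRecord] = field(default_factory=list)
    ingest_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cell_lines(self) -> list[str]:
        return sorted({r.cell_line for r in self.records})

    def group_keys(self) -> list[GroupKey]:
        return sorted({r.pair_key for r in self.records})

    def subset(self, cell_line: str) -> "Dataset":
        return Dataset([r for r in self.records if r.cell_line == cell_line])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": [r.cell_line for r in self.records],
                "smiles_a": [r.compound_a.smiles for r in self.records],
                "smiles_b": [r.compound_b.smiles for r in self.records],
                "bliss_score": [r.bliss_score for r in self.records],
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        # fixed float formatting so identical datasets export byte-identically
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def per_cell_partition(data: Dataset) -> dict[str, Dataset]:
    """Partition records by cell line (disjoint; sizes sum to the input)."""
    out: dict[str, Dataset] = {}
    for rec in data.records:
        out.setdefault(rec.cell_line, Dataset()).records.append(rec)
    return dict(sorted(out.items()))


def bliss_excess(effect_a, effect_b, effect_ab_observed):
    """Bliss excess score of an observed combination effect.

    All arguments are fractional effects (e.g. fraction of growth inhibition)
    in [0, 1].  Returns ``observed - (Ea + Eb - Ea*Eb)``; positive values mean
    the combination beats Bliss independence (synergy).
    """
    a = np.asarray(effect_a, dtype=float)
    b = np.asarray(effect_b, dtype=float)
    o = np.asarray(effect_ab_observed, dtype=float)
    for name, v in (("effect_a", a), ("effect_b", b), ("effect_ab_observed", o)):
        if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must be a fractional effect in [0, 1]")
    result = o - (a + b - a * b)
    return float(result) if result.ndim == 0 else result


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------


def read_synergy_csv(
    path: str | Path,
    source_tag: str = "",
    *,
    aggregate: str = "mean",
    percent_units: bool = False,
    negate_scores: bool = False,
    rejects_path: str | Path | None = None,
) -> Dataset:
    """Read a normalized synergy CSV into a validated :class:`Dataset`.

    Replicate rows for the same (cell line, unordered pair) are aggregated
    with ``aggregate`` ("mean", "median" or "keep-all").  Invalid rows (bad
    SMILES, non-finite scores, empty cell line) are collected into a rejects
    report — available as ``dataset.ingest_log["rejects"]`` and optionally
    written to ``rejects_path`` — never silently dropped.

    ``percent_units=True`` divides scores by 100 at the boundary;
    ``negate_scores=True`` flips the sign for sources using the opposite
    synergy convention.
    """
    if aggregate not in ("mean", "median", "keep-all"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    df = pd.read_csv(path, dtype={"cell_line": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")

    smiles_cache: dict[str, CompoundRecord] = {}

    def _compound(smi) -> CompoundRecord:
        smi = str(smi)
        if smi not in smiles_cache:
            smiles_cache[smi] = validate_smiles(smi)
        return smiles_cache[smi]

    rows: list[SynergyRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        try:
            score = float(row["bliss_score"])
            if not np.isfinite(score):
                raise ValueError("non-finite bliss_score")
            cell = str(row["cell_line"]).strip()
            if not cell or cell.lower() == "nan":
                raise ValueError("empty cell_line")
            a = _compound(row["smiles_a"])
            b = _compound(row["smiles_b"])
        except (ValueError, InvalidSMILESError) as exc:
            rejects.append({"row": int(idx), "reason": str(exc)})
            continue
        if percent_units:
            score /= 100.0
        if negate_scores:
            score = -score
        src = str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else source_tag
        rows.append(SynergyRecord(cell, a, b, score, source=src or source_tag))

    n_before = len(rows)
    if aggregate != "keep-all":
        agg_fn = np.mean if aggregate == "mean" else np.median
        grouped: dict[tuple, list[SynergyRecord]] = {}
        for rec in rows:
            grouped.setdefault((rec.cell_line, rec.pair_key, rec.source), []).append(rec)
        rows = [
            SynergyRecord(
                recs[0].cell_line,
                recs[0].compound_a,
                recs[0].compound_b,
                float(agg_fn([r.bliss_score for r in recs])),
                source=recs[0].source,
            )
            for recs in grouped.values()
        ]

    rejects_df = pd.DataFrame(rejects, columns=["row", "reason"])
    if rejects_path is not None:
        rejects_df.to_csv(rejects_path, index=False)
    logger.info(
        "read %s: %d rows before aggregation, %d after, %d rejected",
        path, n_before, len(rows), len(rejects),
    )
    ds = Dataset(rows)
    ds.ingest_log = {
        "rows_before_aggregation": n_before,
        "rows_after_aggregation": len(rows),
        "rejects": rejects_df,
    }
    return ds


#: Column mappings from raw export dialects to the normalized schema.
#: Values are (cell_line, smiles_a, smiles_b, score) source column names plus
#: reader flags applied at the boundary.
DIALECTS: dict[str, dict] = {
    # NCI-ALMANAC-style export: upper-case screen columns, scores in percent
    "nci-almanac": {
        "columns": ("CELLNAME", "SMILES1", "SMILES2", "SCORE"),
        "percent_units": True,
        "negate_scores": False,
    },
    # DrugCombDB-style export: row/col drug naming, fractional Bliss scores
    "drugcombdb": {
        "columns": ("cell_line", "drug_row_smiles", "drug_col_smiles",
                    "synergy_bliss"),
        "percent_units": False,
        "negate_scores": False,
    },
}


def convert_synergy_table(
    path: str | Path,
    dialect: str,
    out_path: str | Path | None = None,
    **reader_kwargs,
) -> Dataset:
    """Convert a raw source-dialect synergy export into the normalized schema.

    ``dialect`` selects a documented column mapping (see :data:`DIALECTS`);
    the renamed table is then read through :func:`read_synergy_csv` with the
    dialect's unit/sign flags, so the core pipeline never branches on source
    conventions.  ``out_path`` optionally keeps the normalized CSV.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]
    df = pd.read_csv(path)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{dialect} table missing column(s) {missing}")
    renamed = df.rename(
        columns=dict(zip(spec["columns"], REQUIRED_COLUMNS))
    )[list(REQUIRED_COLUMNS)]
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        renamed.to_csv(fh, index=False)
        tmp = fh.name
    try:
        ds = read_synergy_csv(
            tmp,
            source_tag=reader_kwargs.pop("source_tag", dialect),
            percent_units=spec["percent_units"],
            negate_scores=spec["negate_scores"],
            **reader_kwargs,
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    if out_path is not None:
        ds.to_csv(out_path)
    return ds


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic assignment of unordered-pair groups to test and k-fold
    train/validation partitions."""

    test_groups: tuple[GroupKey, ...]
    folds: tuple[tuple[tuple[GroupKey, ...], tuple[GroupKey, ...]], ...]
    seed: int
    k: int

    @property
    def working_groups(self) -> tuple[GroupKey, ...]:
        train0, val0 = self.folds[0]
        return tuple(sorted(set(train0) | set(val0)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "k": self.k,
            "test_groups": [list(g) for g in self.test_groups],
            "folds": [
                {"train": [list(g) for g in tr], "validation": [list(g) for g in va]}
                for tr, va in self.folds
            ],
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            test_groups=tuple(tuple(g) for g in payload["test_groups"]),
            folds=tuple(
                (
                    tuple(tuple(g) for g in fold["train"]),
                    tuple(tuple(g) for g in fold["validation"]),
                )
                for fold in payload["folds"]
            ),
            seed=int(payload["seed"]),
            k=int(payload["k"]),
        )

    def plan_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def make_split_plan(
    data: Dataset | Iterable[GroupKey],
    k: int = 10,
    seed: int = 0,
    test_fraction: float = 0.10,
) -> SplitPlan:
    """Build the 90/10 working/test split plus k-fold plan over pair groups.

    ``|test| = round(test_fraction * n_groups)``; the working remainder is
    dealt into k validation chunks whose sizes differ by at most one, each
    working group serving exactly once as validation.
    """
    groups = sorted(data.group_keys() if isinstance(data, Dataset) else set(data))
    n = len(groups)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} pair groups, got {n}")
    n_test = int(round(test_fraction * n))
    if n - n_test < k:
        raise ValueError(
            f"{n} groups leave {n - n_test} working groups, too few for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = tuple(groups[i] for i in perm[:n_test])
    working = [groups[i] for i in perm[n_test:]]
    chunks = np.array_split(np.arange(len(working)), k)
    folds = []
    for chunk in chunks:
        val_idx = set(chunk.tolist())
        val = tuple(working[i] for i in sorted(val_idx))
        train = tuple(w for i, w in enumerate(working) if i not in val_idx)
        folds.append((train, val))
    return SplitPlan(test_groups=test, folds=tuple(folds), seed=seed, k=k)


def make_stratified_split_plan(
    groups_by_source: Mapping[str, Sequence[GroupKey]],
    k: int = 10,
    seed: int = 0,
    test_fraction: float = 0.10,
) -> SplitPlan:
    """Source-stratified variant: each source's groups are split 90/10 and
    k-folded independently (same seed), then merged fold-wise, so every
    train/validation set preserves the source ratio within one group."""
    plans = {
        src: make_split_plan(list(g), k=k, seed=seed, test_fraction=test_fraction)
        for src, g in sorted(groups_by_source.items())
    }
    test: list[GroupKey] = []
    folds: list[list[list[GroupKey]]] = [[[], []] for _ in range(k)]
    for plan in plans.values():
        test.extend(plan.test_groups)
        for i, (tr, va) in enumerate(plan.folds):
            folds[i][0].extend(tr)
            folds[i][1].extend(va)
    return SplitPlan(
        test_groups=tuple(test),
        folds=tuple((tuple(tr), tuple(va)) for tr, va in folds),
        seed=seed,
        k=k,
    )
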