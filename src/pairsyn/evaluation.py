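"""Performance evaluation: Pearson correlation between measured and predicted
Bliss scores, bootstrap uncertainty, and fold-summary tables.

The Pearson correlation coefficient (PCC) is the single comparison criterion
across learners and training strategies: it is independent of each learner's
training objective, so models trained on different losses remain comparable.
Evaluation always runs on unaugmented rows (one row per unordered pair) so
mirrored training duplicates cannot double-count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Raised when PCC is undefined (constant vector or fewer than 3 rows)."""


def pcc(measured, predicted) -> float:
    """Pearson product-moment correlation between two vectors.

    Symmetric in its arguments and invariant to positive affine rescaling of
    either.  Raises :class:`DegenerateInputError` for n < 3 or a constant
    vector rather than returning NaN.
    """
    x = np.asarray(measured, dtype=np.float64).ravel()
    y = np.asarray(predicted, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise DegenerateInputError(f"need at least 3 rows, got {x.shape[0]}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("PCC undefined for a constant vector")
    return float(np.dot(xc, yc) / (sx * sy))


def bootstrap_pcc_se(measured, predicted, n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of the PCC (resampling rows with
    replacement)."""
    x = np.asarray(measured, dtype=np.float64).ravel()
    y = np.asarray(predicted, dtype=np.float64).ravel()
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            stats.append(pcc(x[idx], y[idx]))
        except DegenerateInputError:  # tiny-n resample collapsed
            continue
    if len(stats) < 2:
        return float("nan")
    return float(np.std(stats, ddof=1))


@dataclass(frozen=True)
class EvalReport:
    partition: str  # train / validation / test
    n: int
    pcc: float
    pcc_se: float

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "n": self.n,
            "pcc": self.pcc,
            "pcc_se": self.pcc_se,
        }


def evaluate(measured, predicted, partition: str, seed: int = 0) -> EvalReport:
    return EvalReport(
        partition=partition,
        n=int(np.asarray(measured).shape[0]),
        pcc=pcc(measured, predicted),
        pcc_se=bootstrap_pcc_se(measured, predicted, seed=seed),
    )


def format_mean_sd(values) -> str:
    """Render a fold/seed series as a ``0.68 ± 0.02`` table cell."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    if values.size == 1:
        return f"{values[0]:.2f}"
    return f"{values.mean():.2f} ± {values.std():.2f}"


def summarize(results) -> pd.DataFrame:
    """Summarize cross-validation results per cell line and algorithm.

    Accepts a list of CVResult-like objects (``cell_line``, ``algorithm``,
    ``test_pcc`` attributes).  Multiple results for the same (cell line,
    algorithm) — e.g. across seeds — are folded into a mean ± sd cell.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    rows: dict[tuple[str, str], list[float]] = {}
    for r in results:
        rows.setdefault((r.cell_line, r.algorithm), []).append(r.test_pcc)
    table = [
        {
            "cell_line": cell,
            "algorithm": algo,
            "n_results": len(v),
            "test_pcc": format_mean_sd(v),
        }
        for (cell, algo), v in sorted(rows.items())
    ]
    return pd.DataFrame(table)
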