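"""SMILES validation and dual-fingerprint pair featurization.

A compound pair is encoded as the concatenation of both compounds' fingerprint
blocks, ``[pubchem(c1) | morgan(c1) | pubchem(c2) | morgan(c2)]``, giving a
binary vector of length ``2 x (881 + 1024) = 3810``.  Because the encoding is
ordered, training additionally duplicates every row with the inverted compound
order (same target) so the learned regressor becomes order-insensitive; see
:func:`augment_with_inversion`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from . import pubchem

RDLogger.DisableLog("rdApp.error")

PUBCHEM_WIDTH = 881
MORGAN_WIDTH = 1024
MORGAN_RADIUS = 1
COMPOUND_WIDTH = PUBCHEM_WIDTH + MORGAN_WIDTH  # 1905
PAIR_WIDTH = 2 * COMPOUND_WIDTH  # 3810

#: Identifier of the feature layout, stored in model archives so a model
#: refuses to score features produced by a different featurizer setup.
def feature_layout_id(morgan_radius: int = MORGAN_RADIUS) -> str:
    return f"pubchem{PUBCHEM_WIDTH}+morgan{MORGAN_WIDTH}r{morgan_radius}|pair{PAIR_WIDTH}"


class InvalidSMILESError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        self.detail = detail
        msg = f"invalid SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class CompoundRecord:
    """An identified compound with a canonical SMILES string."""

    compound_id: str
    smiles: str  # canonical form


@dataclass(frozen=True)
class Fingerprint:
    scheme: str  # "pubchem881" or "morgan1024"
    bits: np.ndarray

    def __post_init__(self):
        self.bits.setflags(write=False)

    @property
    def length(self) -> int:
        return int(self.bits.shape[0])


@dataclass(frozen=True)
class PairFeature:
    """Concatenated fingerprint vector for an ordered compound pair."""

    vector: np.ndarray  # uint8, length 3810
    order: tuple[str, str]  # (compound_id_1, compound_id_2)

    def __post_init__(self):
        self.vector.setflags(write=False)


def validate_smiles(smiles: str, compound_id: str | None = None) -> CompoundRecord:
    """Parse and canonicalize a SMILES string.

    Two spellings of the same molecule map to the same canonical SMILES, so
    downstream featurization cannot depend on input spelling.  Raises
    :class:`InvalidSMILESError` for empty or unparseable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSMILESError(str(smiles), "empty SMILES string")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(smiles, _parse_failure_detail(smiles))
    canonical = Chem.MolToSmiles(mol)
    return CompoundRecord(compound_id=compound_id or canonical, smiles=canonical)


def _parse_failure_detail(smiles: str) -> str:
    """Best-effort position context for a failed parse (unclosed rings,
    unbalanced brackets/parentheses, or a first offending character)."""
    depth = 0
    for pos, ch in enumerate(smiles):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return f"unbalanced ')' at position {pos}"
    if depth > 0:
        return f"{depth} unclosed '(' group(s)"
    digits = [ch for ch in smiles if ch.isdigit()]
    odd = [d for d in set(digits) if digits.count(d) % 2]
    if odd:
        return f"unclosed ring bond number(s) {sorted(odd)}"
    if smiles.count("[") != smiles.count("]"):
        return "unbalanced square brackets"
    return "not parseable as a molecule"


@lru_cache(maxsize=1)
def _morgan_generator(radius: int = MORGAN_RADIUS):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=MORGAN_WIDTH
    )


def pubchem_fingerprint(compound: CompoundRecord) -> Fingerprint:
    """881-bit substructure-key fingerprint (CACTVS-layout; see
    :mod:`pairsyn.pubchem`)."""
    bits = np.frombuffer(
        pubchem.pubchem_bits_from_smiles(compound.smiles), dtype=np.uint8
    ).copy()
    return Fingerprint(scheme="pubchem881", bits=bits)


@lru_cache(maxsize=65536)
def _morgan_bits_cached(smiles: str, radius: int) -> bytes:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(smiles)
    fp = _morgan_generator(radius).GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8).tobytes()


def morgan_fingerprint(
    compound: CompoundRecord, radius: int = MORGAN_RADIUS
) -> Fingerprint:
    """1024-bit folded binary circular (Morgan) fingerprint at the given
    radius (default 1)."""
    bits = np.frombuffer(
        _morgan_bits_cached(compound.smiles, radius), dtype=np.uint8
    ).copy()
    return Fingerprint(scheme="morgan1024", bits=bits)


def compound_features(
    compound: CompoundRecord, morgan_radius: int = MORGAN_RADIUS
) -> np.ndarray:
    """Per-compound block ``[pubchem | morgan]`` of width 1905."""
    return np.concatenate(
        [
            pubchem_fingerprint(compound).bits,
            morgan_fingerprint(compound, radius=morgan_radius).bits,
        ]
    )


def featurize_pair(
    c1: CompoundRecord, c2: CompoundRecord, morgan_radius: int = MORGAN_RADIUS
) -> PairFeature:
    """Concatenated pair feature ``[pub(c1)|mor(c1)|pub(c2)|mor(c2)]``."""
    vec = np.concatenate(
        [compound_features(c1, morgan_radius), compound_features(c2, morgan_radius)]
    )
    return PairFeature(vector=vec, order=(c1.compound_id, c2.compound_id))


def swap_pair_vector(vector: np.ndarray) -> np.ndarray:
    """Exchange the two compound blocks of a pair feature vector (or of each
    row of a 2-D feature matrix)."""
    if vector.shape[-1] != PAIR_WIDTH:
        raise ValueError(f"expected pair width {PAIR_WIDTH}, got {vector.shape[-1]}")
    first = vector[..., :COMPOUND_WIDTH]
    second = vector[..., COMPOUND_WIDTH:]
    return np.concatenate([second, first], axis=-1)


def augment_with_inversion(
    rows: Sequence[tuple[PairFeature, float]],
) -> list[tuple[PairFeature, float]]:
    """Duplicate every training row with inverted compound order.

    Returns exactly ``2 x len(rows)`` rows: the originals followed by the
    mirrored copies (same score).  Apply to training folds only; evaluation
    rows are instead scored symmetrically by two-order averaging at predict
    time.
    """
    out = list(rows)
    for feat, score in rows:
        out.append(
            (
                PairFeature(
                    vector=swap_pair_vector(feat.vector),
                    order=(feat.order[1], feat.order[0]),
                ),
                score,
            )
        )
    return out


def augment_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix form of :func:`augment_with_inversion`."""
    X2 = np.vstack([X, swap_pair_vector(X)])
    y2 = np.concatenate([y, y])
    return X2, y2


# ---------------------------------------------------------------------------
# Bulk input (FASTA-like) and drug-name lookup
# ---------------------------------------------------------------------------


def read_fasta_smiles(path: str | Path) -> list[CompoundRecord]:
    """Read a FASTA-like bulk file: ``>compound_id`` header lines, each
    followed by one SMILES line.  Blank lines are ignored; duplicate ids and
    headerless SMILES are rejected."""
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current_id is not None:
                raise ValueError(
                    f"line {lineno}: header {current_id!r} has no SMILES line"
                )
            current_id = line[1:].strip()
            if not current_id:
                raise ValueError(f"line {lineno}: empty compound id")
            if current_id in seen:
                raise ValueError(f"line {lineno}: duplicate compound id {current_id!r}")
            seen.add(current_id)
        else:
            if current_id is None:
                raise ValueError(f"line {lineno}: SMILES line without '>' header")
            records.append(validate_smiles(line, compound_id=current_id))
            current_id = None
    if current_id is not None:
        raise ValueError(f"header {current_id!r} at end of file has no SMILES line")
    return records


def load_name_lookup(path: str | Path | None = None) -> dict[str, str]:
    """Load a two-column (name, smiles) CSV mapping drug names to SMILES.

    Defaults to the bundled example table used by the drug-name prediction
    modes.  Name matching is case-insensitive.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "drug_names.csv"
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "smiles"} <= set(
            reader.fieldnames
        ):
            raise ValueError("lookup table needs 'name' and 'smiles' columns")
        for row in reader:
            table[row["name"].strip().lower()] = row["smiles"].strip()
    return table


def resolve_drug_name(name: str, table: dict[str, str]) -> CompoundRecord:
    """Resolve a drug name via the lookup table; suggests near matches on
    failure."""
    key = name.strip().lower()
    if key not in table:
        import difflib

        close = difflib.get_close_matches(key, table.keys(), n=3)
        hint = f"; nearest matches: {close}" if close else ""
        raise KeyError(f"unknown drug name {name!r}{hint}")
    return validate_smiles(table[key], compound_id=name)
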