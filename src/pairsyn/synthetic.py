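"""In-silico combination screens with known ground truth.

The generator emulates a per-cell-line synergy screen: for every unordered
compound pair the "measured" Bliss excess equals a cell-specific ground-truth
synergy plus Gaussian replicate noise.  The ground truth is a function of the
same fingerprint features the regressors see, built from two standardized
components: a small *additive* part (a sparse linear functional of the
symmetrised per-compound blocks, share ``linear_share``) and a dominant
*purely non-additive* part (sparse weights on the feature-wise AND of the two
blocks, with the best additive fit over compound incidence removed).  The mix
is squashed through a tanh so scores live in a realistic band (roughly ±0.25).
The decomposition mirrors what Bliss excess measures — departure from
additivity — so pair-specific interaction, not compound potency, carries most
of the variance.  Because truth is symmetric and feature-expressible,
recovery tests measure the pipeline rather than feature mismatch;
``hard_mode_sd`` adds a fixed per-pair component *outside* the feature space
to create an irreducible gap when wanted.

The replicate-noise level is set from a target replicate correlation: with
truth variance ``v`` and noise s.d. ``s``, two replicates of the same screen
correlate as ``v / (v + s^2)`` in expectation.  That closed-form ceiling plays
the role the interclass correlation of replicated experimental screens plays
for real data: no regressor evaluated against noisy observations can beat it
by more than estimation error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .data import Dataset, SynergyRecord
from .features import CompoundRecord, compound_features, validate_smiles

#: Curated drug-like fixture SMILES (name, SMILES); all parse with RDKit.
#: Kept in data/drug_names.csv for the drug-name prediction modes.
def fixture_compounds(n: int | None = None) -> list[CompoundRecord]:
    """The bundled fixture library of valid drug-like compounds (>= 60)."""
    from .features import load_name_lookup

    table = load_name_lookup()
    records = [
        validate_smiles(smiles, compound_id=name)
        for name, smiles in sorted(table.items())
    ]
    if n is not None:
        if n > len(records):
            raise ValueError(f"fixture library has only {len(records)} compounds")
        records = records[:n]
    return records


def alkane_library(n: int) -> list[CompoundRecord]:
    """Programmatic library of simple distinct molecules for large-n tests."""
    out: list[CompoundRecord] = []
    hetero = ["O", "N", "S"]
    i = 0
    for length in itertools.count(3):
        for h_pos in range(length + 1):
            chain = ["C"] * length
            if h_pos > 0:
                chain[h_pos % length] = hetero[h_pos % 3]
            smiles = "".join(chain)
            rec = validate_smiles(smiles, compound_id=f"syn{i}")
            if all(r.smiles != rec.smiles for r in out):
                out.append(rec)
                i += 1
            if len(out) >= n:
                return out
    raise AssertionError("unreachable")


def diverse_library(n: int) -> list[CompoundRecord]:
    """Combinatorial substituted-scaffold library.

    Systematic enumeration of common ring scaffolds carrying two substituents
    from a fixed fragment set.  Each member toggles a distinct combination of
    substructure and circular-fingerprint bits, so the library spans a much
    higher-rank slice of feature space per compound than the curated drug
    list — useful for studies whose statistics depend on the effective
    dimensionality of the feature population (e.g. the fresh-initialization
    probe).  Deterministic order; duplicates removed by canonical SMILES.
    """
    subs = (
        "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
        "F", "Cl", "Br", "I", "C#N", "C(=O)O", "C(=O)N", "C(F)(F)F", "S", "SC",
    )
    scaffolds = (
        "{a}c1ccc({b})cc1",      # para-benzene
        "{a}c1cccc({b})c1",      # meta-benzene
        "{a}c1ccc({b})cn1",      # pyridine
        "{a}c1ncc({b})cn1",      # pyrimidine
        "{a}c1ccc({b})s1",       # thiophene
        "{a}c1ccc({b})o1",       # furan
        "{a}c1cnc({b})s1",       # thiazole
        "{a}C1CCC({b})CC1",      # cyclohexane
        "{a}C1CCN({b})CC1",      # piperidine
        "{a}c1ccc2cc({b})ccc2c1",  # naphthalene
    )
    out: list[CompoundRecord] = []
    seen: set[str] = set()
    i = 0
    for scaffold in scaffolds:
        for a in subs:
            for b in subs:
                smiles = scaffold.format(a=a, b=b)
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical in seen:
                    continue
                seen.add(canonical)
                out.append(CompoundRecord(compound_id=f"lib{i}", smiles=canonical))
                i += 1
                if len(out) >= n:
                    return out
    raise ValueError(f"library enumeration exhausted at {len(out)} < {n}")


@dataclass(frozen=True)
class SyntheticScenario:
    """Specification of an in-silico combination screen.

    ``replicate_ceiling`` sets the expected correlation between two replicate
    measurement vectors; the matching ``noise_sd`` is derived from the exact
    truth variance over the full pair population.  Passing ``noise_sd``
    explicitly overrides the ceiling.
    """

    compounds: tuple[CompoundRecord, ...]
    cell_lines: tuple[str, ...] = ("CELL_A", "CELL_B", "CELL_C")
    replicate_count: int = 2
    seed: int = 0
    replicate_ceiling: float | None = 0.9
    noise_sd: float | None = None
    amplitude: float = 0.25
    n_linear_terms: int = 120
    n_interaction_terms: int = 300
    linear_share: float = 0.2
    hard_mode_sd: float = 0.0
    pairs_fraction: float = 1.0
    source: str = "SYN"

    @classmethod
    def default(
        cls,
        n_compounds: int = 60,
        n_cell_lines: int = 3,
        seed: int = 0,
        **overrides,
    ) -> "SyntheticScenario":
        """The default study scenario: 60 fixture compounds, 3 cell lines,
        2 replicates, replicate-correlation ceiling 0.9."""
        cells = tuple(f"CELL_{chr(65 + i)}" for i in range(n_cell_lines))
        return cls(
            compounds=tuple(fixture_compounds(n_compounds)),
            cell_lines=cells,
            seed=seed,
            **overrides,
        )

    # -- ground truth -------------------------------------------------------

    def _feature_matrix(self) -> np.ndarray:
        return np.asarray(
            [compound_features(c) for c in self.compounds], dtype=np.float32
        )

    def _pairs(self) -> list[tuple[int, int]]:
        return list(itertools.combinations(range(len(self.compounds)), 2))

    def _informative_columns(self, F: np.ndarray) -> np.ndarray:
        """Feature columns with prevalence in (5%, 95%) across the library —
        bits that actually vary, so weighted terms are non-degenerate."""
        prevalence = F.mean(axis=0)
        cols = np.flatnonzero((prevalence > 0.05) & (prevalence < 0.95))
        return cols if cols.size >= 32 else np.arange(F.shape[1])

    def _cell_weights(self, cell_index: int, F: np.ndarray):
        rng = np.random.default_rng([self.seed, 7, cell_index])
        cols = self._informative_columns(F)
        n_lin = min(self.n_linear_terms, cols.size)
        n_int = min(self.n_interaction_terms, cols.size)
        lin_idx = rng.choice(cols, size=n_lin, replace=False)
        lin_w = rng.standard_normal(n_lin)
        int_idx = rng.choice(cols, size=n_int, replace=False)
        int_w = rng.standard_normal(n_int)
        return lin_idx, lin_w, int_idx, int_w

    def truth_table(self) -> dict[str, np.ndarray]:
        """Exact ground-truth synergy per cell line over all unordered pairs
        (ordered as ``itertools.combinations`` over the compound list)."""
        F = self._feature_matrix()
        pairs = self._pairs()
        if len(pairs) == 0:
            raise ValueError("need at least 2 compounds")
        i_idx = np.array([p[0] for p in pairs])
        j_idx = np.array([p[1] for p in pairs])
        if not 0 <= self.linear_share <= 1:
            raise ValueError("linear_share must be in [0, 1]")

        def _z(v: np.ndarray) -> np.ndarray:
            sd = v.std()
            return (v - v.mean()) / (sd if sd > 0 else 1.0)

        # incidence design of compound main effects over the full pair set,
        # used to make the interaction component purely non-additive
        n = len(self.compounds)
        M = np.zeros((len(pairs), n), dtype=np.float64)
        M[np.arange(len(pairs)), i_idx] = 1.0
        M[np.arange(len(pairs)), j_idx] = 1.0

        out: dict[str, np.ndarray] = {}
        for ci, cell in enumerate(self.cell_lines):
            lin_idx, lin_w, int_idx, int_w = self._cell_weights(ci, F)
            phi = F[i_idx][:, lin_idx] + F[j_idx][:, lin_idx]  # symmetric sum
            inter = F[i_idx][:, int_idx] * F[j_idx][:, int_idx]  # symmetric AND
            # Bliss excess measures departure from additivity, so the truth is
            # decomposed explicitly: a purely non-additive interaction
            # component (AND terms with their best additive fit removed)
            # carries most of the variance, plus a small additive component
            # for broadly synergistic/antagonistic compounds.
            additive = _z(phi @ lin_w.astype(np.float64))
            inter_v = inter @ int_w.astype(np.float64)
            coef, *_ = np.linalg.lstsq(M, inter_v, rcond=None)
            non_additive = _z(inter_v - M @ coef)
            raw = (
                np.sqrt(self.linear_share) * additive
                + np.sqrt(1.0 - self.linear_share) * non_additive
            )
            out[cell] = self.amplitude * np.tanh(_z(raw))
        return out

    def truth_variance(self) -> float:
        """Population variance of the truth over all cells and pairs."""
        values = np.concatenate(list(self.truth_table().values()))
        return float(values.var())

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        if self.replicate_ceiling is None:
            return 0.0
        if not 0 < self.replicate_ceiling <= 1:
            raise ValueError("replicate_ceiling must be in (0, 1]")
        v = self.truth_variance()
        return float(np.sqrt(v * (1.0 / self.replicate_ceiling - 1.0)))

    def replicate_correlation(self) -> float:
        """Closed-form expected correlation between two replicate vectors:
        ``var(truth) / (var(truth) + noise_sd**2)``."""
        v = self.truth_variance()
        s2 = self.resolved_noise_sd() ** 2
        return v / (v + s2) if (v + s2) > 0 else 1.0


def generate_screen(scenario: SyntheticScenario) -> Dataset:
    """Emit a synthetic screen as a normalized :class:`Dataset`.

    One record per (cell line, sampled unordered pair, replicate), with
    ``bliss_score = truth + N(0, noise_sd)`` (plus the optional hard-mode
    per-pair offset).  Deterministic under the scenario seed.
    """
    if len(scenario.compounds) < 2:
        raise ValueError("need at least 2 compounds to form pairs")
    truth = scenario.truth_table()
    pairs = scenario._pairs()
    noise_sd = scenario.resolved_noise_sd()
    records: list[SynergyRecord] = []
    for ci, cell in enumerate(scenario.cell_lines):
        cell_truth = truth[cell]
        selector = np.random.default_rng([scenario.seed, 11, ci])
        if scenario.pairs_fraction < 1.0:
            n_keep = max(2, int(round(scenario.pairs_fraction * len(pairs))))
            keep = np.sort(selector.choice(len(pairs), size=n_keep, replace=False))
        else:
            keep = np.arange(len(pairs))
        noise_rng = np.random.default_rng([scenario.seed, 13, ci])
        hard_rng = np.random.default_rng([scenario.seed, 17, ci])
        hard = (
            hard_rng.normal(0.0, scenario.hard_mode_sd, size=len(pairs))
            if scenario.hard_mode_sd > 0
            else np.zeros(len(pairs))
        )
        for p in keep:
            i, j = pairs[p]
            base = cell_truth[p] + hard[p]
            for _ in range(scenario.replicate_count):
                score = base + (
                    noise_rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                records.append(
                    SynergyRecord(
                        cell_line=cell,
                        compound_a=scenario.compounds[i],
                        compound_b=scenario.compounds[j],
                        bliss_score=float(score),
                        source=scenario.source,
                    )
                )
    return Dataset(records)


def truth_map(scenario: SyntheticScenario) -> dict[tuple[str, tuple[str, str]], float]:
    """Ground truth keyed by (cell line, unordered pair key) — for tests."""
    truth = scenario.truth_table()
    pairs = scenario._pairs()
    out = {}
    for cell in scenario.cell_lines:
        for p, (i, j) in enumerate(pairs):
            key = tuple(
                sorted((scenario.compounds[i].smiles, scenario.compounds[j].smiles))
            )
            out[(cell, key)] = float(truth[cell][p])
    return out


class _PerturbedScenario(SyntheticScenario):
    """Scenario whose truth weights are a perturbation of a base scenario's."""

    # set via object.__setattr__ because the dataclass is frozen
    _base: SyntheticScenario
    _perturbation: float

    def _cell_weights(self, cell_index: int, F: np.ndarray):
        lin_idx, lin_w, int_idx, int_w = self._base._cell_weights(cell_index, F)
        rng = np.random.default_rng([self._base.seed, 23, cell_index])
        lin_w = lin_w + self._perturbation * rng.standard_normal(lin_w.shape)
        int_w = int_w + self._perturbation * rng.standard_normal(int_w.shape)
        return lin_idx, lin_w, int_idx, int_w


def perturbed_scenario(
    scenario: SyntheticScenario, perturbation: float, source: str = "B"
) -> SyntheticScenario:
    """A second scenario whose truth weights are the base weights plus a
    perturbation-scaled Gaussian offset (perturbation 0 => identical truth)."""
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    second = _PerturbedScenario(
        **{**scenario.__dict__, "source": source, "seed": scenario.seed + 1}
    )
    object.__setattr__(second, "_base", scenario)
    object.__setattr__(second, "_perturbation", float(perturbation))
    return second


def generate_transfer_pair(
    scenario: SyntheticScenario, perturbation: float
) -> tuple[Dataset, Dataset]:
    """Two correlated screens for warm-start / combined-training studies.

    Dataset A is the scenario itself (source tag "A"); dataset B shares its
    compounds and cell lines but its truth weights are offset by
    ``perturbation``-scaled Gaussian noise (source tag "B", fresh noise seed).
    """
    scen_a = replace(scenario, source="A")
    scen_b = perturbed_scenario(scen_a, perturbation, source="B")
    return generate_screen(scen_a), generate_screen(scen_b)


def truth_correlation(
    scenario_a: SyntheticScenario, scenario_b: SyntheticScenario
) -> float:
    """Correlation of the two scenarios' truth vectors (pooled over cells)."""
    ta = np.concatenate(list(scenario_a.truth_table().values()))
    tb = np.concatenate(list(scenario_b.truth_table().values()))
    return float(np.corrcoef(ta, tb)[0, 1])
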