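"""Ingestion, replicate aggregation, Bliss excess, and the 90/10 + k-fold
split plan over unordered pair groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pairsyn.data import (
    Dataset,
    SplitPlan,
    SynergyRecord,
    bliss_excess,
    make_split_plan,
    make_stratified_split_plan,
    per_cell_partition,
    read_synergy_csv,
)
from pairsyn.features import validate_smiles


def _write_csv(path, rows):
    pd.DataFrame(
        rows, columns=["cell_line", "smiles_a", "smiles_b", "bliss_score"]
    ).to_csv(path, index=False)


class TestBlissExcess:
    @pytest.mark.parametrize(
        "a, b, obs, expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.5, 0.5, 0.75, 0.0),     # exact Bliss independence
            (0.2, 0.3, 0.60, 0.16),    # 0.60 - (0.2 + 0.3 - 0.06)
        ],
    )
    def test_hand_computed_cases(self, a, b, obs, expected):
        assert bliss_excess(a, b, obs) == pytest.approx(expected, abs=1e-12)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_symmetric_and_bounded(self, a, b, obs):
        x = bliss_excess(a, b, obs)
        assert x == bliss_excess(b, a, obs)
        assert -1.0 <= x <= 1.0

    @pytest.mark.parametrize("bad", [(-0.1, 0, 0), (0, 1.5, 0.2), (0, 0, float("nan"))])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bliss_excess(*bad)


class TestReadSynergyCsv:
    def test_replicates_aggregate_by_mean(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(
            p,
            [
                ("A", "CCO", "CCC", 0.10),
                ("A", "CCC", "CCO", 0.30),  # same unordered pair, mirrored
                ("A", "CCO", "CCN", 0.20),
                ("B", "CCO", "CCC", 0.50),
                ("A", "CCN", "CCC", -0.40),
            ],
        )
        ds = read_synergy_csv(p, source_tag="T")
        assert len(ds) == 4
        scores = {
            (r.cell_line, r.pair_key): r.bliss_score for r in ds.records
        }
        key = tuple(sorted((validate_smiles("CCO").smiles, validate_smiles("CCC").smiles)))
        assert scores[("A", key)] == pytest.approx(0.20)  # mean of 0.10, 0.30
        assert ds.ingest_log["rows_before_aggregation"] == 5

    def test_empty_csv_with_header_gives_empty_dataset(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, [])
        assert len(read_synergy_csv(p)) == 0

    def test_bad_rows_routed_to_rejects_not_dropped_silently(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(
            p,
            [
                ("A", "CCO", "CCC", 0.1),
                ("A", "C1CC", "CCC", 0.1),        # invalid SMILES
                ("A", "CCO", "CCN", float("nan")),  # non-finite score
            ],
        )
        ds = read_synergy_csv(p, rejects_path=tmp_path / "rej.csv")
        assert len(ds) == 1
        rejects = ds.ingest_log["rejects"]
        assert len(rejects) == 2
        assert (tmp_path / "rej.csv").exists()

    def test_missing_column_is_a_schema_error_naming_it(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"cell_line": ["A"], "smiles_a": ["CCO"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="smiles_b"):
            read_synergy_csv(p)

    def test_percent_and_negate_flags(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, [("A", "CCO", "CCC", 25.0)])
        ds = read_synergy_csv(p, percent_units=True, negate_scores=True)
        assert ds.records[0].bliss_score == pytest.approx(-0.25)


class TestPerCellPartition:
    def test_partitions_are_disjoint_and_conserve_rows(self, small_screen):
        _, ds = small_screen
        rec = lambda smi, cell, s: SynergyRecord(
            cell, validate_smiles("CCO"), validate_smiles(smi), s
        )
        data = Dataset(
            [rec("CCC", "A", 0.1), rec("CCN", "B", 0.2), rec("CCC", "B", 0.3)]
        )
        parts = per_cell_partition(data)
        assert sorted(parts) == ["A", "B"]
        assert sum(len(p) for p in parts.values()) == len(data)

    def test_single_cell_input_is_identity(self, small_screen):
        _, ds = small_screen
        parts = per_cell_partition(ds)
        assert list(parts) == ["CELL_A"]
        assert len(parts["CELL_A"]) == len(ds)


def _groups(n):
    return [(f"c{i:04d}", f"c{i:04d}x") for i in range(n)]


class TestSplitPlan:
    def test_thousand_groups_split_81_9_10(self):
        plan = make_split_plan(_groups(1000), k=10, seed=1)
        assert len(plan.test_groups) == 100
        for train, val in plan.folds:
            assert len(val) == 90
            assert len(train) == 810
            assert not set(train) & set(val)

    def test_five_fold_variant_720_180(self):
        plan = make_split_plan(_groups(1000), k=5, seed=1)
        assert len(plan.test_groups) == 100
        for train, val in plan.folds:
            assert (len(train), len(val)) == (720, 180)

    def test_same_seed_reproduces_the_plan_exactly(self):
        a = make_split_plan(_groups(137), k=7, seed=3)
        b = make_split_plan(_groups(137), k=7, seed=3)
        assert a == b
        assert a != make_split_plan(_groups(137), k=7, seed=4)

    @given(st.integers(min_value=30, max_value=300), st.integers(min_value=2, max_value=8))
    def test_every_group_appears_exactly_once_in_validation(self, n, k):
        plan = make_split_plan(_groups(n), k=k, seed=n)
        all_groups = set(_groups(n))
        seen_val = []
        for train, val in plan.folds:
            assert set(train) | set(val) == all_groups - set(plan.test_groups)
            assert not set(train) & set(val)
            seen_val.extend(val)
            assert abs(len(val) - (n - len(plan.test_groups)) / k) <= 1
        assert sorted(seen_val) == sorted(all_groups - set(plan.test_groups))
        assert not set(seen_val) & set(plan.test_groups)

    def test_too_few_groups_raise_sizing_error(self):
        with pytest.raises(ValueError, match="groups"):
            make_split_plan(_groups(5), k=10, seed=0)

    def test_json_roundtrip_preserves_plan(self, tmp_path):
        plan = make_split_plan(_groups(60), k=4, seed=9)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        assert SplitPlan.from_json(path) == plan
        assert SplitPlan.from_json(path).plan_hash() == plan.plan_hash()

    def test_stratified_folds_preserve_source_ratio(self):
        ga = _groups(700)
        gb = [(f"b{i:04d}", f"b{i:04d}x") for i in range(300)]
        plan = make_stratified_split_plan({"A": ga, "B": gb}, k=10, seed=2)
        assert len(plan.test_groups) == 100
        for train, val in plan.folds:
            n_a = sum(1 for g in val if g in set(ga))
            n_b = len(val) - n_a
            assert abs(n_a - 63) <= 1  # 630 working A-groups over 10 folds
            assert abs(n_b - 27) <= 1


class TestGroupAtomicity:
    def test_no_pair_group_straddles_a_partition_boundary(self, small_screen):
        scenario, ds = small_screen
        plan = make_split_plan(ds, k=4, seed=5)
        test = set(plan.test_groups)
        for rec in ds.records:  # replicate rows share their group's side
            sides = []
            for train, val in plan.folds:
                in_train = rec.pair_key in set(train)
                in_val = rec.pair_key in set(val)
                in_test = rec.pair_key in test
                assert in_train + in_val + in_test == 1
                sides.append((in_train, in_val, in_test))


class TestDialectConverters:
    def test_nci_style_table_normalizes_with_percent_units(self, tmp_path):
        from pairsyn.data import convert_synergy_table

        raw = tmp_path / "nci.csv"
        pd.DataFrame(
            {
                "CELLNAME": ["MCF7", "MCF7"],
                "SMILES1": ["CCO", "CCN"],
                "SMILES2": ["CCC", "CCC"],
                "SCORE": [12.0, -5.0],  # percent scale
                "EXTRA": [1, 2],
            }
        ).to_csv(raw, index=False)
        ds = convert_synergy_table(raw, "nci-almanac", out_path=tmp_path / "n.csv")
        scores = sorted(r.bliss_score for r in ds.records)
        assert scores == pytest.approx([-0.05, 0.12])
        assert {r.source for r in ds.records} == {"nci-almanac"}
        assert (tmp_path / "n.csv").exists()

    def test_drugcombdb_style_table_normalizes(self, tmp_path):
        from pairsyn.data import convert_synergy_table

        raw = tmp_path / "dcdb.csv"
        pd.DataFrame(
            {
                "cell_line": ["A"],
                "drug_row_smiles": ["CCO"],
                "drug_col_smiles": ["CCC"],
                "synergy_bliss": [0.2],
            }
        ).to_csv(raw, index=False)
        ds = convert_synergy_table(raw, "drugcombdb")
        assert len(ds) == 1 and ds.records[0].bliss_score == pytest.approx(0.2)

    def test_unknown_dialect_and_missing_columns_error(self, tmp_path):
        from pairsyn.data import convert_synergy_table

        raw = tmp_path / "x.csv"
        pd.DataFrame({"CELLNAME": ["A"]}).to_csv(raw, index=False)
        with pytest.raises(ValueError, match="dialect"):
            convert_synergy_table(raw, "nope")
        with pytest.raises(ValueError, match="missing column"):
            convert_synergy_table(raw, "nci-almanac")
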