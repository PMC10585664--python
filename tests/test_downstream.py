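"""Differential expression, phosphopeptide accounting, upset intersections,
and the expression-matrix export."""

import numpy as np
import pandas as pd
import pytest

from tpp2d import (
    QuantTable,
    differential_expression,
    export_expression_matrix,
    intersect_hits,
    phospho_accounting,
)

from conftest import make_long_df


def _de_table(treated, vehicle, pid="P1", extra=None):
    rows = []
    for r, v in enumerate(vehicle, start=1):
        rows.append((pid, "", "vehicle", 0.0, 37.0, r, v))
    for r, v in enumerate(treated, start=1):
        rows.append((pid, "", "ACTH", 500.0, 37.0, r, v))
    rows += extra or []
    return QuantTable(make_long_df(rows))


class TestDifferentialExpression:
    def test_doubling_called_up_with_degenerate_flag(self):
        out = differential_expression(_de_table([16, 16, 16], [8, 8, 8]), "ACTH", 500.0)
        row = out.iloc[0]
        assert row["log2_fold_change"] == pytest.approx(1.0)
        assert row["call"] == "up"
        assert bool(row["degenerate"])

    def test_identical_groups_unchanged(self):
        out = differential_expression(_de_table([8, 8, 8], [8, 8, 8]), "ACTH", 500.0)
        assert out.iloc[0]["log2_fold_change"] == 0.0
        assert out.iloc[0]["call"] == "unchanged"

    def test_halving_called_down(self):
        out = differential_expression(_de_table([4, 4, 4], [8, 8, 8]), "ACTH", 500.0)
        assert out.iloc[0]["log2_fold_change"] == pytest.approx(-1.0)
        assert out.iloc[0]["call"] == "down"

    def test_missing_vehicle_raises(self):
        rows = [("P1", "", "ACTH", 500.0, 37.0, r, 8.0) for r in (1, 2)]
        with pytest.raises(ValueError, match="vehicle"):
            differential_expression(QuantTable(make_long_df(rows)), "ACTH", 500.0)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        rows = []
        for pid in ("P1", "P2", "P3"):
            for r in (1, 2, 3):
                rows.append((pid, "", "vehicle", 0.0, 37.0, r, float(rng.lognormal(8, 0.3))))
                rows.append((pid, "", "ACTH", 500.0, 37.0, r, float(rng.lognormal(8.5, 0.3))))
        df = make_long_df(rows)
        fwd = differential_expression(QuantTable(df), "ACTH", 500.0)
        swapped = df.copy()
        treated = swapped["concentration_nM"] == 500.0
        swapped.loc[treated, ["ligand", "concentration_nM"]] = ["vehicle", 0.0]
        swapped.loc[~treated, ["ligand", "concentration_nM"]] = ["ACTH", 500.0]
        rev = differential_expression(QuantTable(swapped), "ACTH", 500.0)
        merged = fwd.merge(rev, on="protein_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(
            merged["log2_fold_change_f"], -merged["log2_fold_change_r"], rtol=1e-9
        )
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert list(merged["call_r"]) == [swap[c] for c in merged["call_f"]]


class TestPhospho:
    def _table(self):
        rows = [
            # induced: only under treatment
            ("P1", "AAS*K", "ACTH", 500.0, 37.0, 1, 200.0),
            # constitutive: in vehicle and treatment, 2x up
            ("P2", "TT*GK", "vehicle", 0.0, 37.0, 1, 100.0),
            ("P2", "TT*GK", "ACTH", 500.0, 37.0, 1, 200.0),
            # vehicle_only
            ("P3", "S*PPK", "vehicle", 0.0, 37.0, 1, 50.0),
            # unmodified peptide: ignored
            ("P4", "LLLK", "ACTH", 500.0, 37.0, 1, 10.0),
        ]
        return QuantTable(make_long_df(rows), level="peptide")

    def test_presence_classes_partition(self):
        rec, flags = phospho_accounting(self._table())
        by_pep = rec.drop_duplicates(["protein_id", "peptide"]).set_index("protein_id")["presence"]
        assert by_pep["P1"] == "induced"
        assert by_pep["P2"] == "constitutive"
        assert by_pep["P3"] == "vehicle_only"
        assert "P4" not in rec["protein_id"].values
        assert set(rec["presence"]) <= {"induced", "constitutive", "vehicle_only"}

    def test_relative_abundance_vs_vehicle(self):
        rec, _ = phospho_accounting(self._table())
        p2 = rec[rec["protein_id"] == "P2"].iloc[0]
        assert p2["relative_abundance"] == pytest.approx(2.0)

    def test_protein_flags(self):
        _, flags = phospho_accounting(self._table())
        assert set(flags["protein_id"]) == {"P1", "P2", "P3"}
        assert flags["phosphorylated"].all()


class TestIntersect:
    def test_nested_lists_exclusive_counts(self):
        out = intersect_hits({"L1": {"A", "B", "C"}, "L2": {"B", "C"}, "L3": {"C"}})
        counts = out.set_index("combination")["count"]
        assert counts["L1"] == 1
        assert counts["L1&L2"] == 1
        assert counts["L1&L2&L3"] == 1
        assert counts.sum() == 3  # = |union|

    def test_identical_lists_all_in_full_intersection(self):
        out = intersect_hits({"A": {"x", "y"}, "B": {"x", "y"}})
        assert list(out["combination"]) == ["A&B"]
        assert out["count"].iloc[0] == 2

    def test_disjoint_lists_only_singletons(self):
        out = intersect_hits({"A": {"x"}, "B": {"y"}})
        assert set(out["combination"]) == {"A", "B"}
        assert (out["degree"] == 1).all()

    def test_per_ligand_totals_match(self):
        rng = np.random.default_rng(1)
        pool = [f"P{i}" for i in range(30)]
        sets = {lig: set(rng.choice(pool, size=rng.integers(5, 20), replace=False)) for lig in "XYZ"}
        out = intersect_hits(sets)
        assert out["count"].sum() == len(set.union(*sets.values()))
        for lig, s in sets.items():
            total = out.loc[out["combination"].str.split("&").map(lambda c: lig in c), "count"].sum()
            assert total == len(s)

    def test_needs_two_lists(self):
        with pytest.raises(ValueError):
            intersect_hits({"A": {"x"}})


class TestExportMatrix:
    def _table(self):
        rows = []
        for pid in ("P1", "P2", "P3"):
            for c, r in [(0.0, 1), (0.0, 2), (0.0, 3), (500.0, 1), (500.0, 2), (500.0, 3)]:
                lig = "vehicle" if c == 0 else "ACTH"
                rows.append((pid, "", lig, c, 37.0, r, 1024.0))
        return QuantTable(make_long_df(rows))

    def test_shape_and_log2(self, tmp_path):
        out = tmp_path / "mat.tsv"
        mat = export_expression_matrix(self._table(), path=out, log_base=2.0)
        assert mat.shape == (3, 6)
        assert np.allclose(mat.to_numpy(), 10.0)  # log2(1024)
        assert out.exists()

    def test_mapping_applied_and_unmapped_kept(self):
        mapping = pd.DataFrame({"protein_id": ["P1"], "gene_symbol": ["GENE1"]})
        mat = export_expression_matrix(self._table(), mapping=mapping)
        assert "GENE1" in mat.index and "P2" in mat.index

    def test_empty_mapping_keeps_accessions(self):
        mat = export_expression_matrix(self._table(), mapping=pd.DataFrame(columns=["protein_id", "gene_symbol"]))
        assert set(mat.index) == {"P1", "P2", "P3"}
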