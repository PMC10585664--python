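"""Table IO, design validation, and TOP3 protein quantitation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tpp2d import (
    DesignSummary,
    QuantTable,
    Top3Aggregator,
    read_quant_table,
    top3_quantify,
    validate_design,
    write_quant_table,
)
from tpp2d.quant_io import ConfigError, QuantTableError

from conftest import make_long_df


class TestReadWrite:
    def test_identity_read(self, tmp_path):
        df = make_long_df(
            [(f"P{i}", "", "ACTH", c, 37.0, 1, 10.0 + i) for i, c in enumerate([0.0, 20.0, 100.0, 500.0])]
        )
        p = tmp_path / "t.tsv"
        df.to_csv(p, sep="\t", index=False)
        qt = read_quant_table(p)
        assert len(qt) == 4
        assert qt.level == "protein"

    def test_column_mapping_and_missing_column(self, tmp_path):
        df = make_long_df([("P1", "", "ACTH", 0.0, 37.0, 1, 5.0)]).rename(
            columns={"intensity": "signal"}
        )
        p = tmp_path / "t.tsv"
        df.to_csv(p, sep="\t", index=False)
        qt = read_quant_table(p, {"columns": {"intensity": "signal"}})
        assert qt.data["intensity"].iloc[0] == 5.0
        with pytest.raises(ConfigError, match="intensity"):
            read_quant_table(p)

    def test_negative_intensity_dropped_and_counted(self, tmp_path):
        df = make_long_df(
            [
                ("P1", "", "ACTH", 0.0, 37.0, 1, 5.0),
                ("P1", "", "ACTH", 0.0, 37.0, 2, -1.0),
                ("P1", "", "ACTH", 0.0, 37.0, 3, 7.0),
                ("P1", "", "ACTH", 20.0, 37.0, 1, 2.0),
            ]
        )
        p = tmp_path / "t.tsv"
        df.to_csv(p, sep="\t", index=False)
        qt = read_quant_table(p)
        assert len(qt) == 3
        assert qt.n_dropped == 1

    def test_duplicate_key_rejected(self):
        df = make_long_df(
            [("P1", "", "ACTH", 0.0, 37.0, 1, 5.0), ("P1", "", "ACTH", 0.0, 37.0, 1, 6.0)]
        )
        with pytest.raises(QuantTableError, match="duplicate"):
            QuantTable(df)

    def test_wide_format_melts_to_one_row_per_run(self, tmp_path):
        runs = []
        for lig in ("ACTH",):
            for c in (20.0, 100.0):
                for r in (1, 2):
                    runs.append((f"run_{lig}_{c:g}_{r}", lig, c, 37.0, r))
        ann = pd.DataFrame(runs, columns=["run", "ligand", "concentration_nM", "temperature_C", "replicate"])
        wide = pd.DataFrame({"protein_id": ["P1", "P2"], "peptide": ["", ""]})
        for i, run in enumerate(ann["run"]):
            wide[run] = [10.0 + i, 20.0 + i]
        wp, ap = tmp_path / "wide.tsv", tmp_path / "ann.tsv"
        wide.to_csv(wp, sep="\t", index=False)
        ann.to_csv(ap, sep="\t", index=False)
        qt = read_quant_table(wp, {"format": "wide", "run_annotation": ap})
        assert len(qt) == 2 * len(ann)  # one row per (protein, run)

    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        df = make_long_df(
            [("P1", "", "ACTH", c, 37.0, r, float(v))
             for (c, r), v in zip([(0.0, 1), (0.0, 2), (20.0, 1), (500.0, 1)], rng.lognormal(10, 1, 4))]
        )
        qt = QuantTable(df)
        p = tmp_path / "rt.tsv"
        write_quant_table(qt, p, metadata={"seed": 0})
        back = read_quant_table(p)
        pd.testing.assert_frame_equal(
            back.data[df.columns], qt.data[df.columns], check_exact=True
        )


class TestTop3:
    def test_hand_computed_mean_of_top3(self, toy_peptides):
        prot = top3_quantify(toy_peptides)
        p1 = prot.data.set_index("protein_id").loc["PROT1"]
        assert p1["intensity"] == pytest.approx((100 + 80 + 60) / 3)
        assert not p1["low_evidence"]

    def test_singleton_peptide_flagged_low_evidence(self, toy_peptides):
        prot = top3_quantify(toy_peptides)
        p2 = prot.data.set_index("protein_id").loc["PROT2"]
        assert p2["intensity"] == 50.0
        assert bool(p2["low_evidence"])

    def test_no_cross_protein_leakage(self):
        rows = []
        for pid in ("A", "B"):
            for j, v in enumerate([30.0, 20.0, 10.0]):
                rows.append((pid, f"pep{j}", "ACTH", 20.0, 37.0, 1, v))
        prot = top3_quantify(QuantTable(make_long_df(rows), level="peptide"))
        vals = prot.data.set_index("protein_id")["intensity"]
        assert vals["A"] == vals["B"] == 20.0

    def test_transformer_wrapper_matches_function(self, toy_peptides):
        via_class = Top3Aggregator().fit_transform(toy_peptides)
        via_fn = top3_quantify(toy_peptides)
        pd.testing.assert_frame_equal(via_class.data, via_fn.data)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.5, 1e6), min_size=1, max_size=8),
        st.floats(0.01, 100.0),
        st.randoms(use_true_random=False),
    )
    def test_top3_order_invariant_and_homogeneous(self, intensities, k, rnd):
        rows = [("P", f"pep{i}", "L", 20.0, 37.0, 1, v) for i, v in enumerate(intensities)]
        shuffled = list(rows)
        rnd.shuffle(shuffled)
        base = top3_quantify(QuantTable(make_long_df(rows), level="peptide"))
        perm = top3_quantify(QuantTable(make_long_df(shuffled), level="peptide"))
        assert base.data["intensity"].iloc[0] == perm.data["intensity"].iloc[0]
        scaled_rows = [(p, s, l, c, t, r, v * k) for p, s, l, c, t, r, v in rows]
        scaled = top3_quantify(QuantTable(make_long_df(scaled_rows), level="peptide"))
        assert scaled.data["intensity"].iloc[0] == pytest.approx(
            base.data["intensity"].iloc[0] * k, rel=1e-12
        )


class TestDesign:
    def test_design_invariants(self):
        with pytest.raises(ValueError):
            DesignSummary(temperatures=(42.0, 37.0))
        with pytest.raises(ValueError):
            DesignSummary(concentrations=(20.0, 100.0))  # no vehicle

    def _grid_table(self, skip=None):
        design = DesignSummary(ligands=("ACTH",))
        rows = []
        for t in design.temperatures:
            for c in design.concentrations:
                for r in range(1, design.replicates + 1):
                    if skip and skip((c, t, r)):
                        continue
                    lig = "vehicle" if c == 0 else "ACTH"
                    rows.append(("P1", "", lig, c, t, r, 100.0 + c + t + r))
        return QuantTable(make_long_df(rows)), design

    def test_complete_grid_zero_missing(self):
        qt, design = self._grid_table()
        report = validate_design(qt, design)
        assert report["n_missing"].sum() == 0

    def test_single_missing_cell_located(self):
        qt, design = self._grid_table(skip=lambda k: k == (500.0, 67.0, 3))
        report = validate_design(qt, design)
        assert report["n_missing"].sum() == 1
        miss = report.attrs["missing"].iloc[0]
        assert (miss["temperature_C"], miss["concentration_nM"], miss["replicate"]) == (67.0, 500.0, 3)

    def test_absent_temperature_counts_twelve_cells(self):
        qt, design = self._grid_table(skip=lambda k: k[1] == 67.0)
        report = validate_design(qt, design)
        assert report["n_missing"].sum() == 12  # 4 concentrations x 3 replicates
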