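"""Descriptor-table I/O, splitting, standardization, fusion thermodynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dooit import (
    CANONICAL_DESCRIPTORS,
    FusionData,
    TableSchema,
    gibbs_fusion,
    load_table,
    solvent_weighted_descriptor,
    split_train_test,
    standardize,
)
from dooit.dataset import relative_descriptor_deviation
from dooit.errors import (
    CompositionError,
    DegenerateInputError,
    ParseError,
    SchemaError,
)


def _toy_frame(n=3, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 16)), columns=CANONICAL_DESCRIPTORS)
    # make relative descriptors consistent: rel = API - solv
    for q in ("E_int", "E_misfit", "E_HB", "E_vdW", "mu"):
        df[f"{q}_rel"] = df[f"{q}_API"] - df[f"{q}_solv"]
    df["log_x"] = rng.normal(size=n)
    return df


class TestLoadTable:
    def test_reads_full_schema(self, tmp_path):
        path = tmp_path / "toy.csv"
        _toy_frame().to_csv(path, index=False)
        table = load_table(path, TableSchema.cosmo_rs())
        assert table.n == 3 and table.p == 16
        assert table.feature_names == CANONICAL_DESCRIPTORS
        assert not table.provenance["rejections"]

    def test_blank_target_row_is_rejected_with_report(self, tmp_path):
        df = _toy_frame()
        df.loc[1, "log_x"] = np.nan
        path = tmp_path / "toy.csv"
        df.to_csv(path, index=False)
        table = load_table(path, TableSchema.cosmo_rs())
        assert table.n == 2
        rej = table.provenance["rejections"]
        assert len(rej) == 1 and rej[0]["row"] == 1 and rej[0]["column"] == "log_x"

    def test_missing_column_names_it(self, tmp_path):
        df = _toy_frame().drop(columns=["mu_rel"])
        path = tmp_path / "toy.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="mu_rel"):
            load_table(path, TableSchema.cosmo_rs())

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        df = _toy_frame()
        df["mu_API"] = df["mu_API"].astype(object)
        df.loc[2, "mu_API"] = "oops"
        path = tmp_path / "toy.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match=r"row 2.*mu_API"):
            load_table(path, TableSchema.cosmo_rs())

    def test_write_read_round_trip(self, tmp_path):
        path = tmp_path / "toy.csv"
        _toy_frame(n=5, seed=3).to_csv(path, index=False)
        schema = TableSchema.cosmo_rs()
        table = load_table(path, schema)
        out = tmp_path / "echo.csv"
        table.write(out)
        again = load_table(out, schema)
        pd.testing.assert_frame_equal(
            table.df[list(table.feature_names) + [table.target_name]],
            again.df[list(again.feature_names) + [again.target_name]],
            check_exact=True,
        )

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "toy.tsv"
        _toy_frame().to_csv(path, index=False, sep="\t")
        assert load_table(path, TableSchema.cosmo_rs()).n == 3

    def test_schema_file_round_trip(self, tmp_path):
        schema = TableSchema.cosmo_rs()
        p = tmp_path / "schema.json"
        import json

        p.write_text(json.dumps(schema.to_dict()))
        assert TableSchema.from_file(p).feature_names == schema.feature_names

    def test_relative_consistency_deviation(self):
        df = _toy_frame()
        assert relative_descriptor_deviation(df) <= 1e-12
        df.loc[0, "mu_rel"] += 1.0
        assert relative_descriptor_deviation(df) == pytest.approx(1.0)


class TestSplit:
    @pytest.mark.parametrize("n,frac,expected_train", [
        (10, 0.8, 8),
        (1148, 0.8, 918),  # round-half-up of 918.4
        (11, 0.5, 6),      # 5.5 rounds up
    ])
    def test_train_count_rounding(self, tmp_path, n, frac, expected_train):
        df = pd.DataFrame({"a": np.arange(n, dtype=float),
                           "y": np.arange(n, dtype=float)})
        from dooit.dataset import ModelingTable

        table = ModelingTable(df=df, feature_names=("a",), target_name="y")
        out = split_train_test(table, frac, seed=42)
        assert int(out.mask("train").sum()) == expected_train
        assert int(out.mask("test").sum()) == n - expected_train

    def test_deterministic_and_column_order_invariant(self):
        from dooit.dataset import ModelingTable

        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "y"])
        t1 = ModelingTable(df=df, feature_names=("a", "b"), target_name="y")
        t2 = ModelingTable(df=df[["b", "y", "a"]], feature_names=("b", "a"),
                           target_name="y")
        s1 = split_train_test(t1, 0.8, seed=7).df["split"]
        s2 = split_train_test(t2, 0.8, seed=7).df["split"]
        s3 = split_train_test(t1, 0.8, seed=7).df["split"]
        assert (s1 == s2).all() and (s1 == s3).all()

    def test_single_row_is_degenerate(self):
        from dooit.dataset import ModelingTable

        df = pd.DataFrame({"a": [1.0], "y": [0.0]})
        table = ModelingTable(df=df, feature_names=("a",), target_name="y")
        with pytest.raises(DegenerateInputError):
            split_train_test(table, 0.8, seed=0)


class TestStandardize:
    def test_hand_computed_column(self):
        train = np.array([[1.0], [2.0], [3.0]])
        out, _, mean, sd = standardize(train)
        assert mean[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(np.sqrt(2 / 3))  # population convention
        np.testing.assert_allclose(out[:, 0], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_idempotent_on_train(self, rng):
        X = rng.normal(size=(40, 4)) * 3 + 1
        once, _, _, _ = standardize(X)
        twice, _, _, _ = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-8)
        assert np.abs(once.mean(0)).max() < 1e-8
        assert np.abs(once.std(0) - 1).max() < 1e-8

    def test_apply_uses_train_parameters_only(self, rng):
        X = rng.normal(size=(30, 2)) * 2 + 5
        holdout = rng.normal(size=(10, 2))
        _, ho, mean, sd = standardize(X, holdout)
        np.testing.assert_allclose(ho, (holdout - mean) / sd)

    def test_constant_column_names_offender(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(DegenerateInputError, match="b"):
            standardize(X, feature_names=["a", "b"])


class TestFusion:
    @pytest.mark.parametrize("dh,tm,t,expected", [
        (20.0, 400.0, 400.0, 0.0),
        (20.0, 400.0, 300.0, 5.0),
        (20.0, 400.0, 0.0, 20.0),
    ])
    def test_closed_form(self, dh, tm, t, expected):
        assert gibbs_fusion(dh, tm, t) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(dh=st.floats(1, 100), tm=st.floats(200, 600),
           t=st.floats(0, 600))
    def test_linear_in_temperature_and_zero_at_melting(self, dh, tm, t):
        assert gibbs_fusion(dh, tm, tm) == pytest.approx(0.0, abs=1e-9)
        mid = gibbs_fusion(dh, tm, t / 2)
        ends = (gibbs_fusion(dh, tm, 0.0) + gibbs_fusion(dh, tm, t)) / 2
        assert mid == pytest.approx(ends, rel=1e-9, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gibbs_fusion(20.0, -1.0, 300.0)

    def test_fusion_data_derived_quantities(self):
        fd = FusionData(dH_fus=25.0, T_m=450.0)
        assert fd.dS_fus == pytest.approx(25.0 / 450.0)
        assert fd.dCp_fus == fd.dS_fus
        assert fd.dG_fus(450.0) == pytest.approx(0.0)
        assert fd.dG_fus(300.0) > fd.dG_fus(400.0)  # decreasing in T


class TestSolubilitySystem:
    def test_valid_system(self):
        from dooit import SolubilitySystem

        s = SolubilitySystem(
            solute_id="syringic_acid",
            solvent_components=(("ChCl", 1 / 3), ("TEG", 2 / 3)),
            temperature=298.15,
            target_log_x=-1.29,
        )
        assert s.temperature > 0

    def test_composition_and_domain_violations(self):
        from dooit import SolubilitySystem

        with pytest.raises(CompositionError):
            SolubilitySystem("x", (("a", 0.5), ("b", 0.6)), 298.15, -1.0)
        with pytest.raises(ValueError):
            SolubilitySystem("x", (("a", 1.0),), -5.0, -1.0)
        with pytest.raises(ValueError):
            SolubilitySystem("x", (("a", 1.0),), 298.15, float("nan"))


class TestSolventWeighting:
    @pytest.mark.parametrize("values,fracs,expected", [
        ([7.0], [1.0], 7.0),
        ([0.0, 4.0], [0.25, 0.75], 3.0),
        ([2.0, 8.0], [0.5, 0.5], 5.0),
    ])
    def test_dot_product(self, values, fracs, expected):
        assert solvent_weighted_descriptor(values, fracs) == pytest.approx(expected)

    def test_composition_violation(self):
        with pytest.raises(CompositionError):
            solvent_weighted_descriptor([1.0, 2.0], [0.5, 0.6])
        with pytest.raises(CompositionError):
            solvent_weighted_descriptor([1.0], [0.5, 0.5])
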