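"""Dataset ingestion, validation, aggregation, and design preparation."""

import logging

import numpy as np
import pandas as pd
import pytest

from mltve.exceptions import ConfigurationError, DomainError, ValidationError
from mltve.hierdata import (HierarchicalDataset, aggregate_level1, dichotomize,
                            load_dataset, prepare_design)
from mltve.simulate import SIM1_ROLES, Sim1Config, gen_sim1, sim2_transforms
from mltve.transforms import TransformSpec

ROLES_MAP = {
    "group": "g",
    "outcome": "y",
    "exposures": {"level1": ["x1"], "level2": ["x2"]},
    "mediators": {"level1": ["m1"], "level2": ["m2"]},
}


class TestLoadDataset:
    def test_simulated_csv_roundtrip(self, sim1_data, tmp_path):
        path = tmp_path / "sim1.csv"
        sim1_data.df.to_csv(path, index=False)
        ds = load_dataset(path, ROLES_MAP)
        assert ds.n_records == 600
        assert ds.n_groups == 30
        assert np.all(ds.group_sizes == 20)

    def test_missing_column_named(self, sim1_data, tmp_path):
        path = tmp_path / "sim1.csv"
        sim1_data.df.drop(columns=["m2"]).to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="m2"):
            load_dataset(path, ROLES_MAP)

    def test_single_group_rejected(self, sim1_data):
        df = sim1_data.df[sim1_data.df["g"] == 0]
        with pytest.raises(ValidationError, match="2 groups"):
            HierarchicalDataset(df, SIM1_ROLES)

    def test_level2_constancy_enforced(self, sim1_data):
        df = sim1_data.df.copy()
        df.loc[df.index[5], "m2"] = 1 - df.loc[df.index[5], "m2"]
        with pytest.raises(ValidationError, match=r"m2.*group"):
            HierarchicalDataset(df, SIM1_ROLES)

    def test_missing_rows_dropped_and_logged(self, sim1_data, caplog):
        df = sim1_data.df.copy()
        df.loc[df.index[:7], "y"] = np.nan
        with caplog.at_level(logging.INFO, logger="mltve.hierdata"):
            ds = HierarchicalDataset(df, SIM1_ROLES)
        assert ds.n_records == 593
        assert any("7 rows" in r.message for r in caplog.records)


class TestAggregateLevel1:
    def test_small_example(self):
        df = pd.DataFrame({"g": ["A", "A", "B"], "y": [0.0, 1.0, 2.0],
                           "x1": [1.0, 3.0, 5.0], "x2": [9.0, 9.0, 7.0]})
        ds = HierarchicalDataset(df, {"group": "g", "outcome": "y",
                                      "exposures": {"level1": ["x1"], "level2": ["x2"]}})
        agg = aggregate_level1(ds, "x1")
        np.testing.assert_allclose(agg.to_numpy(), [2.0, 2.0, 5.0])

    def test_constant_column_is_fixed_point(self, sim1_data):
        ds = sim1_data
        const = aggregate_level1(ds, "m2")  # level-2 column is constant within group
        np.testing.assert_allclose(const.to_numpy(), ds.column("m2"))

    def test_matches_bruteforce_group_loop(self, rng):
        df = pd.DataFrame({
            "g": rng.integers(0, 12, 200),
            "y": rng.normal(size=200),
            "x1": rng.normal(size=200),
        })
        ds = HierarchicalDataset(df, {"group": "g", "outcome": "y",
                                      "exposures": {"level1": ["x1"]}})
        agg = aggregate_level1(ds, "x1")
        for lbl in ds.group_labels:
            mask = ds.df["g"] == lbl
            np.testing.assert_allclose(agg[mask.to_numpy()].to_numpy(),
                                       ds.df.loc[mask, "x1"].mean())

    def test_unknown_variable(self, sim1_data):
        with pytest.raises(ConfigurationError):
            aggregate_level1(sim1_data, "nope")


class TestDichotomize:
    def test_reference_coding(self):
        ind, ref = dichotomize(pd.Series(["a", "b", "c", "a"], name="v"))
        assert ref == "a"
        assert list(ind.columns) == ["v[b]", "v[c]"]
        np.testing.assert_array_equal(ind.to_numpy()[0], [0, 0])
        assert set(ind.sum(axis=1)) <= {0, 1}

    def test_binary_column_single_indicator(self):
        ind, ref = dichotomize(pd.Series([0, 1, 1, 0], name="v"))
        assert ref == 0 and ind.shape[1] == 1
        np.testing.assert_array_equal(ind.iloc[:, 0], [0, 1, 1, 0])

    def test_roundtrip_decodes_labels(self, rng):
        labels = rng.choice(list("xyz"), 100)
        ind, ref = dichotomize(pd.Series(labels, name="v"))
        decoded = np.where(ind["v[y]"] == 1, "y", np.where(ind["v[z]"] == 1, "z", ref))
        np.testing.assert_array_equal(decoded, labels)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize(pd.Series([1, 1, 1], name="v"))


class TestPrepareDesign:
    def test_identity_config_has_unit_derivatives(self, sim1_data):
        design = prepare_design(sim1_data)
        for block in design.outcome.values():
            for tv in block.values():
                np.testing.assert_array_equal(tv.derivs, np.ones_like(tv.derivs))

    def test_quadratic_mediator_block_derivatives(self, sim2_data):
        design = prepare_design(sim2_data, sim2_transforms())
        tv = design.mediator["m"]["f1ke1"]["x1"]
        x = sim2_data.column("x1")
        np.testing.assert_allclose(tv.values, np.column_stack([x, x**2]))
        np.testing.assert_allclose(tv.derivs, np.column_stack([np.ones_like(x), 2 * x]))
        # outcome-side log transform of the level-2 exposure
        tv2 = design.outcome["f2e"]["x2"]
        np.testing.assert_allclose(tv2.derivs[:, 0], 1.0 / sim2_data.column("x2"))

    def test_deterministic(self, sim2_data):
        d1 = prepare_design(sim2_data, sim2_transforms())
        d2 = prepare_design(sim2_data, sim2_transforms())
        for block in ("f1e", "f2e", "f3k"):
            for var in d1.outcome[block]:
                np.testing.assert_array_equal(d1.outcome[block][var].values,
                                              d2.outcome[block][var].values)

    def test_derivative_spotcheck_vs_finite_difference(self, sim1_data):
        cfg = {"x2": {"outcome": TransformSpec("ns", df=4)}}
        design = prepare_design(sim1_data, cfg)
        tv = design.outcome["f2e"]["x2"]
        x = sim1_data.column("x2")
        h = 1e-6 * np.maximum(np.abs(x), 1.0)
        fd = (tv.transform.values(x + h) - tv.transform.values(x - h)) / (2 * h)[:, None]
        np.testing.assert_allclose(tv.derivs, fd, rtol=1e-5, atol=1e-7)

    def test_unknown_variable_in_config(self, sim1_data):
        with pytest.raises(ConfigurationError, match="ghost"):
            prepare_design(sim1_data, {"ghost": TransformSpec("log")})

    def test_domain_violation_names_variable(self, sim1_data):
        with pytest.raises(DomainError, match="x2"):
            prepare_design(sim1_data, {"x2": TransformSpec("log")})  # x2 ~ N(0,1)

    def test_export_frame_pairs_values_and_derivatives(self, sim1_data):
        frame = prepare_design(sim1_data).to_frame()
        value_cols = [c for c in frame.columns if not c.endswith("__d")]
        assert all(f"{c}__d" in frame.columns for c in value_cols)
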