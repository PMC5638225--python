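"""Design enumeration, range shifts and the per-cell ANOVA partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichevar as nv


def brute_force_ss(y, rows, nesting="forecast_within_rcp"):
    """Sum-of-squares oracle by explicit enumeration of group means.

    y: 1-D responses, one per design row; rows: DataFrame of factor levels.
    Returns dict factor -> SS plus 'total' and 'residual'.
    """
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    out = {"total": float(((y - grand) ** 2).sum())}
    nested = nesting == "forecast_within_rcp" and {"rcp", "forecast"} <= set(rows.columns)
    for fac in rows.columns:
        if nested and fac == "forecast":
            continue
        ss = 0.0
        for level in rows[fac].unique():
            sel = rows[fac] == level
            ss += sel.sum() * (y[sel.to_numpy()].mean() - grand) ** 2
        out[fac] = float(ss)
    if nested:
        ss = 0.0
        for r in rows["rcp"].unique():
            in_r = (rows["rcp"] == r).to_numpy()
            mr = y[in_r].mean()
            for f in rows.loc[in_r, "forecast"].unique():
                sel = in_r & (rows["forecast"] == f).to_numpy()
                ss += sel.sum() * (y[sel].mean() - mr) ** 2
        out["forecast"] = float(ss)
    explained = sum(v for k, v in out.items() if k != "total")
    out["residual"] = out["total"] - explained
    return out


def full_design(method_levels=3):
    factors = {
        "data_type": ["range_map", "points"],
        "family": ["envelope", "statistical", "machine_learning"][:method_levels],
        "rcp": ["rcp26", "rcp85"],
        "forecast": [f"gcm{i}" for i in range(1, 6)],
    }
    import itertools

    rows = pd.DataFrame(
        list(itertools.product(*factors.values())), columns=list(factors)
    )
    return nv.DesignTable(factors, rows)


class TestBuildDesign:
    @pytest.mark.parametrize(
        "stage,expected",
        [("fit", 180), ("current_single", 90), ("current_ensemble", 6), ("future_ensemble", 60)],
    )
    def test_study_counts(self, stage, expected):
        table = nv.build_design(2, 9, 2, 5, 10, stage)
        assert table.n_rows == expected

    def test_all_ones_single_row(self):
        assert nv.build_design(1, 1, 1, 1, 1, "fit").n_rows == 1

    def test_no_duplicate_rows(self):
        table = nv.build_design(2, 9, 2, 5, 10, "fit")
        assert not table.rows.duplicated().any()

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            nv.build_design(2, 9, 2, 5, 10, "warp")


class TestRangeShift:
    @pytest.mark.parametrize("C,F,expected", [(50, 50, 0.0), (50, 0, -1.0), (100, 30, -0.7)])
    def test_relative_shift(self, C, F, expected):
        assert nv.range_shift(C, F).delta_rel == pytest.approx(expected)

    def test_absent_species_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            nv.range_shift(0, 10)


class TestCountTotalLoss:
    def records(self, deltas_by_species):
        out = []
        for sp, deltas in deltas_by_species.items():
            for d in deltas:
                out.append(nv.range_shift(100.0, 100.0 * (1 + d), sp))
        return out

    def test_no_total_loss(self):
        assert nv.count_total_loss(self.records({"a": [-0.5, -0.9], "b": [0.1]})) == 0

    def test_single_combination_suffices(self):
        recs = self.records({"a": [-0.2] * 59 + [-1.0], "b": [-0.5]})
        assert nv.count_total_loss(recs) == 1

    def test_all_species_lost(self):
        assert nv.count_total_loss(self.records({"a": [-1.0], "b": [-1.0]})) == 2

    def test_monotone_in_added_combinations(self):
        base = self.records({"a": [-0.2], "b": [-0.3]})
        more = base + self.records({"b": [-1.0]})
        assert nv.count_total_loss(more) >= nv.count_total_loss(base)


class TestRichnessChangeStack:
    def surfaces(self, design, offset):
        grid = nv.GridSpec(3, 3, 25.0)
        current = nv.RichnessSurface(np.full(9, 5.0), grid, ["a"], nv.CURRENT)
        futures = {
            tuple(row): nv.RichnessSurface(np.full(9, 5.0 - offset(tuple(row))), grid, ["a"], nv.CURRENT)
            for _, row in design.rows.iterrows()
        }
        return current, futures

    def test_identity_futures_give_zero(self):
        design = full_design()
        current, futures = self.surfaces(design, lambda k: 0.0)
        y = nv.richness_change_stack(current, futures, design)
        assert y.shape == (9, 60)
        np.testing.assert_allclose(y, 0.0)

    def test_uniform_loss_appears_in_the_right_column(self):
        design = full_design()
        target = tuple(design.rows.iloc[7])
        current, futures = self.surfaces(design, lambda k: 2.0 if k == target else 0.0)
        y = nv.richness_change_stack(current, futures, design)
        np.testing.assert_allclose(y[:, 7], 2.0)
        assert np.allclose(np.delete(y, 7, axis=1), 0.0)


class TestAnovaPartition:
    def test_constant_response_flagged(self):
        design = full_design()
        y = np.full((4, design.n_rows), 3.0)
        comp = nv.anova_partition(y, design)
        assert comp.flagged.all()
        np.testing.assert_allclose(comp.proportions, 0.0)
        np.testing.assert_allclose(comp.total_ss, 0.0)

    def test_single_factor_response_gets_full_component(self):
        design = full_design()
        fam_effect = {"envelope": 0.0, "statistical": 1.0, "machine_learning": 2.0}
        y = np.array([[fam_effect[f] for f in design.rows["family"]]])
        comp = nv.anova_partition(y, design)
        i = comp.factor_names.index("family")
        assert comp.proportions[0, i] == pytest.approx(1.0)
        others = np.delete(comp.proportions[0], i)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    @pytest.mark.parametrize("nesting", ["forecast_within_rcp", "fully_crossed"])
    def test_matches_brute_force_oracle(self, nesting):
        design = full_design()
        rng = np.random.default_rng(17)
        y = rng.standard_normal((20, design.n_rows))
        comp = nv.anova_partition(y, design, nesting)
        for cell in range(20):
            oracle = brute_force_ss(y[cell], design.rows, nesting)
            for i, fac in enumerate(comp.factor_names):
                got = comp.proportions[cell, i] * comp.total_ss[cell]
                assert got == pytest.approx(oracle[fac], abs=1e-9)
            resid = comp.proportions[cell, -1] * comp.total_ss[cell]
            assert resid == pytest.approx(oracle["residual"], abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_components_sum_to_one_property(self, seed):
        design = full_design()
        y = np.random.default_rng(seed).standard_normal((3, design.n_rows))
        comp = nv.anova_partition(y, design)
        sums = comp.proportions.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert np.all(comp.proportions >= -1e-12)

    def test_unbalanced_design_rejected(self):
        design = full_design()
        rows = pd.concat([design.rows, design.rows.iloc[[0]]], ignore_index=True)
        bad = nv.DesignTable(design.factors, rows)
        y = np.zeros((1, len(rows)))
        with pytest.raises(ValueError, match="balanced"):
            nv.anova_partition(y, bad)

    def test_shape_mismatch_rejected(self):
        design = full_design()
        with pytest.raises(ValueError, match="columns"):
            nv.anova_partition(np.zeros((2, 10)), design)


class TestUncertaintyMaps:
    def test_single_factor_map_is_one_and_sums_hold(self):
        design = full_design()
        grid = nv.GridSpec(4, 5, 25.0)
        rcp_effect = {"rcp26": 0.0, "rcp85": 1.0}
        base = np.array([rcp_effect[r] for r in design.rows["rcp"]])
        y = np.tile(base, (grid.n_cells, 1))
        y[0] = 0.0  # one degenerate cell
        comp = nv.anova_partition(y, design)
        maps = nv.uncertainty_maps(comp, grid)
        flat_rcp = maps["rcp"].ravel()
        assert np.isnan(flat_rcp[0])  # flagged cell rendered missing
        np.testing.assert_allclose(flat_rcp[1:], 1.0)
        total = sum(maps[k] for k in comp.factor_names + ["residual"])
        np.testing.assert_allclose(total.ravel()[1:], 1.0)


class TestShiftSdVsRange:
    def make_records(self, sds, n_comb=6, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i, sd in enumerate(sds):
            deltas = -0.5 + sd * rng.standard_normal(n_comb)
            for d in deltas:
                recs.append(nv.range_shift(100.0, max(100.0 * (1 + d), 0.0), f"s{i}"))
        return recs

    def test_identical_shifts_give_zero_sds_and_slope(self):
        recs = []
        for i in range(5):
            for _ in range(6):
                recs.append(nv.range_shift(100.0, 60.0, f"s{i}"))
        out = nv.shift_sd_vs_range(recs, {f"s{i}": 50 + i for i in range(5)})
        np.testing.assert_allclose(out["table"]["std"], 0.0)
        assert out["slope"] == pytest.approx(0.0)

    def test_negative_relationship_recovered(self):
        sds = [0.5, 0.4, 0.3, 0.2, 0.1]
        ranges = {f"s{i}": (i + 1) * 40 for i in range(5)}
        out = nv.shift_sd_vs_range(self.make_records(sds, n_comb=60, seed=1), ranges)
        assert out["slope"] < 0

    def test_f_statistic_matches_closed_form(self):
        recs = self.make_records([0.1, 0.25, 0.2, 0.4, 0.35], n_comb=8, seed=2)
        ranges = {f"s{i}": float(r) for i, r in enumerate([120, 80, 100, 30, 40])}
        out = nv.shift_sd_vs_range(recs, ranges)
        tab = out["table"]
        x = tab["range_size"].to_numpy(float)
        y = tab["std"].to_numpy(float)
        slope = np.cov(x, y, bias=True)[0, 1] / x.var()
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        ss_model = ((intercept + slope * x) - y.mean()) ** 2
        f = ss_model.sum() / 1 / (resid @ resid / (len(x) - 2))
        assert out["slope"] == pytest.approx(slope)
        assert out["F"] == pytest.approx(f, rel=1e-6)
        assert out["df_resid"] == len(x) - 2

    def test_single_combination_species_excluded_with_warning(self):
        recs = self.make_records([0.1, 0.2, 0.3], n_comb=5, seed=3)
        recs.append(nv.range_shift(100.0, 50.0, "lonely"))
        ranges = {f"s{i}": 50.0 * (i + 1) for i in range(3)}
        ranges["lonely"] = 10.0
        with pytest.warns(UserWarning, match="single combination"):
            out = nv.shift_sd_vs_range(recs, ranges)
        assert "lonely" not in set(out["table"]["species_id"])
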