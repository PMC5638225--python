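"""ROC thresholding, TSS, consensus ensembles and richness stacking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichevar as nv
from nichevar.evaluation import BinarySurface

GRID = nv.GridSpec(4, 4, 25.0)


def sweep_oracle(scores, labels):
    """Exhaustive cutpoint sweep: best sensitivity+specificity and threshold."""
    best_j, best_t = -np.inf, None
    for t in np.append(np.unique(scores), np.inf):
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        if sens + spec > best_j + 1e-12:
            best_j, best_t = sens + spec, t
    return best_j, best_t


class TestTss:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(1, 1, 1.0), (0.5, 0.5, 0.0), (0.8, 0.7, 0.5), (0, 0, -1.0)]
    )
    def test_formula(self, sens, spec, expected):
        assert nv.tss(sens, spec) == pytest.approx(expected)

    def test_symmetry(self):
        assert nv.tss(0.9, 0.3) == nv.tss(0.3, 0.9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nv.tss(1.2, 0.5)


class TestRocThreshold:
    def test_perfect_separation(self):
        scores = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        ev = nv.roc_threshold(scores, labels)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0 and ev.tss == 1.0

    def test_constant_scores_give_zero_tss(self):
        scores = np.full(10, 0.5)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert nv.roc_threshold(scores, labels).tss == pytest.approx(0.0)

    def test_six_point_toy_matches_sweep(self):
        scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        ev = nv.roc_threshold(scores, labels)
        best_j, best_t = sweep_oracle(scores, labels)
        assert ev.sensitivity + ev.specificity == pytest.approx(best_j)
        # smallest maximizing cutpoint wins the tie
        assert ev.threshold == pytest.approx(0.3)
        assert ev.tss == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            nv.roc_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 200))
    def test_agrees_with_sweep_on_random_instances(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.round(rng.random(10), 2), size=n)  # many ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        ev = nv.roc_threshold(scores, labels)
        best_j, best_t = sweep_oracle(scores, labels)
        assert ev.sensitivity + ev.specificity == pytest.approx(best_j)
        assert ev.threshold == pytest.approx(best_t)


class TestBinarize:
    def make_surface(self, scores):
        return nv.SuitabilitySurface(
            np.asarray(scores, float), GRID, "s", "points", "glm", 1, nv.CURRENT
        )

    def test_threshold_above_max_all_zero(self):
        b = nv.binarize(self.make_surface(np.linspace(0, 0.5, 16)), 0.9)
        assert b.values.sum() == 0

    def test_threshold_at_or_below_min_all_one(self):
        b = nv.binarize(self.make_surface(np.linspace(0.2, 0.5, 16)), 0.2)
        assert b.values.sum() == 16

    def test_idempotent_on_binary_surface(self):
        b = nv.binarize(self.make_surface(np.tile([0.0, 1.0], 8)), 0.5)
        again = nv.binarize(self.make_surface(b.values.astype(float)), 0.5)
        np.testing.assert_array_equal(b.values, again.values)


def member(values, tss_value, rep=1):
    binary = BinarySurface(np.asarray(values, int), GRID, "s", "points", "glm", rep, nv.CURRENT)
    sens = (1 + tss_value) / 2
    return binary, nv.Evaluation(0.5, sens, sens)


class TestEnsemble:
    def test_identical_members_reproduce_the_map(self):
        pattern = np.tile([1, 0], 8)
        binaries, evals = zip(member(pattern, 0.7, 1), member(pattern, 0.9, 2))
        cons = nv.ensemble(list(binaries), list(evals))
        np.testing.assert_allclose(cons.frequency, pattern.astype(float))

    def test_weighted_disagreement(self):
        a = np.zeros(16, int)
        b = np.ones(16, int)
        binaries, evals = zip(member(a, 0.6, 1), member(b, 0.8, 2))
        cons = nv.ensemble(list(binaries), list(evals))
        np.testing.assert_allclose(cons.frequency, 0.8 / 1.4)

    def test_low_skill_member_excluded(self):
        good = member(np.ones(16, int), 0.8, 1)
        bad = member(np.zeros(16, int), 0.4, 2)
        cons = nv.ensemble([good[0], bad[0]], [good[1], bad[1]], min_tss=0.5)
        assert len(cons.members) == 1
        np.testing.assert_allclose(cons.frequency, 1.0)

    def test_no_survivors_rejected(self):
        bad = member(np.zeros(16, int), 0.2)
        with pytest.raises(ValueError, match="no models passed"):
            nv.ensemble([bad[0]], [bad[1]], min_tss=0.5)

    def test_mixed_provenance_rejected(self):
        a = BinarySurface(np.zeros(16, int), GRID, "s", "points", "glm", 1, nv.CURRENT)
        b = BinarySurface(np.zeros(16, int), GRID, "s", "range_map", "gam", 1, nv.CURRENT)
        e = nv.Evaluation(0.5, 0.9, 0.9)
        with pytest.raises(ValueError, match="share"):
            nv.ensemble([a, b], [e, e])


def consensus(species, freq):
    return nv.ConsensusSurface(np.asarray(freq, float), GRID, species, "points", "statistical", nv.CURRENT)


class TestRichnessMap:
    def test_expected_mode_sums_frequencies(self):
        layers = [
            consensus("a", np.full(16, 1.0)),
            consensus("b", np.full(16, 1.0)),
            consensus("c", np.full(16, 0.0)),
        ]
        rich = nv.richness_map(layers, "expected")
        np.testing.assert_allclose(rich.values, 2.0)

    def test_binary_mode_bounded_by_species_count(self):
        rng = np.random.default_rng(0)
        layers = [consensus(f"s{i}", rng.random(16)) for i in range(5)]
        rich = nv.richness_map(layers, "binary@0.5")
        assert np.all(rich.values <= 5)
        expected = sum((l.frequency >= 0.5).astype(int) for l in layers)
        np.testing.assert_array_equal(rich.values, expected)

    def test_duplicate_species_rejected(self):
        layers = [consensus("a", np.zeros(16)), consensus("a", np.zeros(16))]
        with pytest.raises(ValueError, match="duplicate"):
            nv.richness_map(layers)

    def test_empty_stack_with_grid_is_zero_map(self):
        rich = nv.richness_map([], "expected", grid=GRID)
        np.testing.assert_array_equal(rich.values, np.zeros(16))


class TestCompareModelFit:
    def toy(self, bump=0.0):
        rows = []
        for dt in ("points", "range_map"):
            for grp, base in (("envelope", 0.6), ("statistical", 0.6), ("machine_learning", 0.6)):
                for rep in range(3):
                    t = base + 0.01 * rep + (bump if grp == "statistical" else 0.0)
                    rows.append({"data_type": dt, "group": grp, "tss": t})
        return pd.DataFrame(rows)

    def test_group_means_match_hand_computation(self):
        df = pd.DataFrame(
            {
                "data_type": ["points"] * 4 + ["range_map"] * 4,
                "group": ["envelope", "envelope", "statistical", "statistical"] * 2,
                "tss": [0.5, 0.7, 0.9, 0.7, 0.4, 0.6, 0.8, 0.6],
            }
        )
        out = nv.compare_model_fit(df)
        s = out["group_summary"].set_index(["data_type", "group"])["mean"]
        assert s[("points", "envelope")] == pytest.approx(0.6)
        assert s[("range_map", "statistical")] == pytest.approx(0.7)

    def test_uniformly_better_group_yields_positive_contrast(self):
        out = nv.compare_model_fit(self.toy(bump=0.1))
        coefs = out["coefficients"]
        stat = [i for i in coefs.index if "group_statistical" in str(i) and ":" not in str(i)]
        assert coefs.loc[stat[0], "coef"] > 0

    def test_identical_groups_give_zero_contrasts(self):
        df = self.toy(0.0)
        df["tss"] = 0.6
        out = nv.compare_model_fit(df)
        coefs = out["coefficients"]
        non_intercept = [i for i in coefs.index if str(i) != "const"]
        assert np.allclose(coefs.loc[non_intercept, "coef"], 0.0, atol=1e-6)

    def test_single_observation_groups_rejected(self):
        df = pd.DataFrame(
            {"data_type": ["points", "points"], "group": ["a", "b"], "tss": [0.5, 0.6]}
        )
        with pytest.raises(ValueError, match="single-observation"):
            nv.compare_model_fit(df)
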