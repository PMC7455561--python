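import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sdmniche as sn
from sdmniche.evaluation import (auc, binarize_and_area, boyce_index,
                                 ensemble_combine, split_train_test,
                                 threshold_metrics, variable_importance)
from sdmniche.occurrences import OccurrenceSet
from sdmniche.raster import GEOGRAPHIC, GridTransform, RasterGrid, SuitabilityMap

scores = st.lists(st.floats(0, 1, allow_nan=False, width=32),
                  min_size=1, max_size=20)


def brute_force_auc(p, b):
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in p for y in b)
    return wins / (len(p) * len(b))


def brute_force_max_tss(p, b):
    best = None
    for t in sorted(set(p) | set(b)):
        sens = np.mean([x >= t for x in p])
        spec = np.mean([x < t for x in b])
        if best is None or sens + spec - 1 > best + 1e-12:
            best = sens + spec - 1
    return best


class TestSplit:
    def test_paper_style_counts(self):
        """45 records at an 80/20 split partition into 36 train / 9 test."""
        occ = OccurrenceSet(np.random.default_rng(0).random((45, 2)) * 10,
                            crs_kind=GEOGRAPHIC)
        train, test = split_train_test(occ, 0.8, rng_seed=1)
        assert (len(train), len(test)) == (36, 9)

    def test_same_seed_identical(self):
        occ = OccurrenceSet(np.random.default_rng(1).random((20, 2)),
                            crs_kind=GEOGRAPHIC)
        a = split_train_test(occ, 0.8, rng_seed=5)
        b = split_train_test(occ, 0.8, rng_seed=5)
        np.testing.assert_array_equal(a[0].xy, b[0].xy)

    def test_partition_is_disjoint_and_exhaustive(self):
        occ = OccurrenceSet(np.random.default_rng(2).random((31, 2)),
                            crs_kind=GEOGRAPHIC)
        train, test = split_train_test(occ, 0.7, rng_seed=3)
        both = np.vstack([train.xy, test.xy])
        assert len(both) == 31
        assert len(np.unique(both, axis=0)) == 31

    def test_empty_partition_rejected(self):
        occ = OccurrenceSet(np.random.default_rng(3).random((5, 2)),
                            crs_kind=GEOGRAPHIC)
        with pytest.raises(ValueError, match="empty"):
            split_train_test(occ, 0.99, rng_seed=0)


class TestAuc:
    @pytest.mark.parametrize("p,b,expected", [
        ([0.9, 0.8], [0.7, 0.4], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.9, 0.3], [0.5, 0.1], 0.75),
    ])
    def test_known_values(self, p, b, expected):
        assert auc(p, b) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, database=None)
    @given(scores, scores)
    def test_matches_pair_enumeration(self, p, b):
        assert auc(p, b) == pytest.approx(brute_force_auc(p, b))

    @settings(max_examples=30, derandomize=True, database=None)
    @given(scores, scores)
    def test_invariant_under_monotone_transform(self, p, b):
        f = lambda x: np.expm1(3 * np.asarray(x))   # strictly increasing
        assert auc(f(p), f(b)) == pytest.approx(auc(p, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestThresholdMetrics:
    def test_perfect_separation(self):
        t, sens, spec, tss = threshold_metrics([0.8, 0.9], [0.1, 0.2])
        assert (sens, spec, tss) == (1.0, 1.0, 1.0)

    def test_identical_distributions_give_zero_tss(self):
        _, _, _, tss = threshold_metrics([0.3, 0.7], [0.3, 0.7])
        assert tss == pytest.approx(0.0)
        _, _, _, tss = threshold_metrics([0.5] * 5, [0.5] * 5)
        assert tss == pytest.approx(0.0)

    def test_worked_example(self):
        t, sens, spec, tss = threshold_metrics([0.9, 0.6, 0.3], [0.5, 0.2])
        assert t == pytest.approx(0.6)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)
        assert tss == pytest.approx(2 / 3)

    @settings(max_examples=50, derandomize=True, database=None)
    @given(scores, scores)
    def test_matches_exhaustive_scan(self, p, b):
        _, _, _, tss = threshold_metrics(p, b)
        assert tss == pytest.approx(brute_force_max_tss(p, b))


class TestBoyceIndex:
    def test_monotone_profile_near_plus_one(self):
        """Presence density proportional to score: P/E rises monotonically."""
        rng = np.random.default_rng(0)
        land = rng.uniform(0, 1, 10000)
        pres = rng.choice(land, 2000, p=land / land.sum())
        assert boyce_index(pres, land) > 0.9

    def test_uniform_subsample_near_zero(self):
        """P/E is constant in expectation, so the index averages near 0."""
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            land = rng.uniform(0, 1, 10000)
            pres = rng.choice(land, 2000, replace=False)
            vals.append(boyce_index(pres, land))
        assert abs(np.mean(vals)) < 0.3

    def test_reversed_profile_near_minus_one(self):
        rng = np.random.default_rng(2)
        land = rng.uniform(0, 1, 10000)
        w = 1.0 - land
        pres = rng.choice(land, 2000, p=w / w.sum())
        assert boyce_index(pres, land) < -0.9

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        land = rng.uniform(0, 1, 5000)
        pres = land[land > 0.6][:300]
        a = boyce_index(pres, land)
        b = boyce_index(7 * pres + 3, 7 * land + 3)
        assert a == pytest.approx(b)

    def test_degenerate_scores_return_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert boyce_index([0.5] * 20, [0.5] * 200) == 0.0


class TestEnsembleCombine:
    def make_map(self, values, grid_factory):
        return SuitabilityMap(grid_factory(np.asarray(values, dtype=float)))

    def test_identical_members_fixed_point(self, grid_factory):
        m = self.make_map(np.full((5, 5), 0.42), grid_factory)
        out = ensemble_combine([m, m, m])
        np.testing.assert_allclose(out.grid.values, 0.42)

    def test_degenerate_weights_select_member(self, grid_factory):
        a = self.make_map(np.full((5, 5), 0.2), grid_factory)
        b = self.make_map(np.full((5, 5), 0.9), grid_factory)
        out = ensemble_combine([a, b], weights=[1.0, 0.0])
        np.testing.assert_allclose(out.grid.values, 0.2)

    def test_uniform_mean(self, grid_factory):
        a = self.make_map(np.full((5, 5), 0.2), grid_factory)
        b = self.make_map(np.full((5, 5), 0.6), grid_factory)
        out = ensemble_combine([a, b])
        np.testing.assert_allclose(out.grid.values, 0.4)

    def test_bounded_by_member_envelope(self, grid_factory):
        rng = np.random.default_rng(4)
        members = [self.make_map(rng.random((6, 6)), grid_factory)
                   for _ in range(4)]
        out = ensemble_combine(members)
        stackv = np.stack([m.grid.values for m in members])
        assert (out.grid.values >= stackv.min(axis=0) - 1e-12).all()
        assert (out.grid.values <= stackv.max(axis=0) + 1e-12).all()

    def test_misaligned_rejected(self, grid_factory):
        a = self.make_map(np.full((5, 5), 0.2), grid_factory)
        b = SuitabilityMap(grid_factory(np.full((6, 6), 0.2)))
        with pytest.raises(ValueError, match="aligned"):
            ensemble_combine([a, b])

    def test_zero_weights_rejected(self, grid_factory):
        a = self.make_map(np.full((5, 5), 0.2), grid_factory)
        with pytest.raises(ValueError, match="zero"):
            ensemble_combine([a], weights=[0.0])


class TestVariableImportance:
    def test_ignored_predictor_scores_zero(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.standard_normal((200, 2)),
                            columns=["used", "ignored"])
        fn = lambda t: 1 / (1 + np.exp(-t["used"].to_numpy()))
        imp = variable_importance(fn, data, n_repeats=5, rng_seed=1)
        assert imp.importance["ignored"] == 0.0
        assert imp.importance["used"] > 0.1

    def test_informative_predictor_always_ranks_first(self, training_tables):
        """The niche-defining predictor beats noise in every repeat."""
        m = sn.fit_model(sn.ModelSpec("glm"), training_tables["train"],
                         training_tables["background"])
        data = pd.concat([training_tables["train"],
                          training_tables["background"]], ignore_index=True)
        per_repeat_winners = []
        for rep in range(10):
            imp = variable_importance(m, data, n_repeats=1, rng_seed=100 + rep)
            ranked = imp.ranked()
            per_repeat_winners.append(ranked[0])
        assert all(w in ("bio12", "bio5") for w in per_repeat_winners)

    def test_constant_predictions_warn(self):
        data = pd.DataFrame(np.random.default_rng(6).random((40, 2)),
                            columns=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            imp = variable_importance(lambda t: np.full(len(t), 0.5), data)
        assert all(v == 0.0 for v in imp.importance.values())


class TestBinarizeAndArea:
    def test_counting_suitable_cells(self, grid_factory):
        vals = np.zeros((2, 5))
        vals[0, :4] = 0.9
        smap = SuitabilityMap(grid_factory(vals))
        binary, area = binarize_and_area(smap, 0.5)
        assert area == pytest.approx(4.0)          # four 1 km^2 cells
        assert binary.values[0, 0] == 1.0

    def test_threshold_zero_counts_everything_valid(self, grid_factory):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 0] = True
        smap = SuitabilityMap(grid_factory(np.full((3, 3), 0.1), mask=m))
        _, area = binarize_and_area(smap, 0.0)
        assert area == pytest.approx(8.0)

    def test_geographic_area_cosine_corrected(self):
        tr_eq = GridTransform(0.0, 0.5, 1.0)
        tr_60 = GridTransform(0.0, 60.5, 1.0)
        eq = SuitabilityMap(RasterGrid(np.ones((1, 1)), tr_eq, GEOGRAPHIC))
        hi = SuitabilityMap(RasterGrid(np.ones((1, 1)), tr_60, GEOGRAPHIC))
        _, a_eq = binarize_and_area(eq, 0.5)
        _, a_60 = binarize_and_area(hi, 0.5)
        assert a_60 / a_eq == pytest.approx(math.cos(math.radians(60)),
                                            rel=0.01)
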