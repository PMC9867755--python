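import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retorg.config import PipelineConfig
from retorg.datatypes import ValidationError
from retorg.dispersion import (
    euclid_2d,
    knn_mean_distance,
    simpson_same_type_probability,
    stage_diversity,
    trajectory_width,
)

from conftest import make_cell_table


class TestEuclid2D:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [((0, 0), (3, 4), 5.0), ((1, 1), (1, 1), 0.0),
         ((0, 0), (1, 1), np.sqrt(2))],
    )
    def test_known_distances(self, p1, p2, expected):
        assert euclid_2d(p1, p2) == pytest.approx(expected)


class TestKnnMeanDistance:
    def test_three_point_hand_enumeration(self):
        """Points (0,0), (3,4), (0,8): each point's nearest neighbor is at
        distance 5, so the n=1 mean is 5; per-point 2-NN means are 6.5, 5,
        6.5, so the n=2 mean is 6."""
        pts = np.array([[0, 0], [3, 4], [0, 8.0]])
        per_query = knn_mean_distance(pts, np.arange(3), n_max=2)
        assert per_query[:, 0].mean() == pytest.approx(5.0)
        assert per_query[:, 1].mean() == pytest.approx(6.0)

    def test_identical_points_zero_for_every_n(self):
        pts = np.zeros((6, 2))
        per_query = knn_mean_distance(pts, np.arange(6), n_max=4)
        np.testing.assert_allclose(per_query, 0.0)

    def test_n_max_too_large_rejected(self):
        with pytest.raises(ValidationError):
            knn_mean_distance(np.zeros((4, 2)), np.arange(4), n_max=4)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_curves_non_decreasing_in_n(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 2))
        per_query = knn_mean_distance(pts, np.arange(40), n_max=20)
        assert (np.diff(per_query, axis=1) >= -1e-12).all()


def two_condition_table(points_native, points_organoid):
    n, m = len(points_native), len(points_organoid)
    emb = np.vstack([points_native, points_organoid])
    stages = (["I"] * (n // 2) + ["II"] * (n - n // 2)
              + ["I"] * (m // 2) + ["II"] * (m - m // 2))
    return make_cell_table(
        np.ones((n + m, 1), dtype=int),
        condition=["native"] * n + ["organoid"] * m,
        stage=stages,
        embedding=emb,
    )


class TestTrajectoryWidth:
    def _cfg(self, seed=0, **kw):
        defaults = dict(n_cells_width=40, n_max=10, width_replicates=3,
                        rng_seed=seed)
        defaults.update(kw)
        return PipelineConfig(**defaults)

    def test_identical_point_sets_give_equal_curves(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(120, 2))
        table = two_condition_table(pts, pts.copy())
        curves = trajectory_width(table, self._cfg())
        np.testing.assert_allclose(
            curves.mean("native"), curves.mean("organoid"), rtol=0.15)

    def test_global_scaling_doubles_curves_exactly(self):
        """Scaling every coordinate by 2 doubles every per-replicate curve
        exactly when the same seed pairs the resampling draws."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2)) * 1.7
        t1 = two_condition_table(a, b)
        t2 = two_condition_table(2 * a, 2 * b)
        c1 = trajectory_width(t1, self._cfg(seed=5))
        c2 = trajectory_width(t2, self._cfg(seed=5))
        for cond in ("native", "organoid"):
            np.testing.assert_allclose(
                c2.curves[cond], 2 * c1.curves[cond], rtol=1e-12)

    def test_envelope_brackets_mean(self, synth_default, params):
        cells, _ = synth_default
        curves = trajectory_width(cells, params)
        for cond in ("native", "organoid"):
            assert (curves.lo(cond) <= curves.mean(cond) + 1e-12).all()
            assert (curves.mean(cond) <= curves.hi(cond) + 1e-12).all()
            assert (np.diff(curves.mean(cond)) >= -1e-12).all()

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(3)
        table = make_cell_table(
            np.ones((10, 1), dtype=int), embedding=rng.normal(size=(10, 2)))
        with pytest.raises(ValidationError, match="organoid"):
            trajectory_width(table, self._cfg())

    def test_seed_contract(self, synth_default):
        cells, _ = synth_default
        c1 = trajectory_width(cells, PipelineConfig(rng_seed=42))
        c2 = trajectory_width(cells, PipelineConfig(rng_seed=42))
        for cond in ("native", "organoid"):
            np.testing.assert_array_equal(c1.curves[cond], c2.curves[cond])


class TestStageDiversity:
    def _cfg(self, seed=0, **kw):
        defaults = dict(entropy_pairs=200, entropy_replicates=50, rng_seed=seed)
        defaults.update(kw)
        return PipelineConfig(**defaults)

    def _table(self, native_types, organoid_types):
        n, m = len(native_types), len(organoid_types)
        return make_cell_table(
            np.ones((n + m, 1), dtype=int),
            condition=["native"] * n + ["organoid"] * m,
            stage=["I"] * (n + m),
            cell_type=list(native_types) + list(organoid_types),
        )

    def test_single_type_stage_is_exactly_one(self):
        table = self._table(["NE"] * 6, ["NE"] * 6)
        est = stage_diversity(table, self._cfg())
        np.testing.assert_array_equal(est.samples[("native", "I")], 1.0)

    def test_two_by_two_composition_matches_exact_probability(self):
        """Composition {A: 2, B: 2}: P(same type) for two distinct cells is
        (2*1 + 2*1) / (4*3) = 1/3; the resampling mean must sit within
        3 SE of it."""
        table = self._table(["NE", "NE", "RGC", "RGC"],
                            ["NE", "NE", "RGC", "RGC"])
        cfg = self._cfg(entropy_pairs=1000, entropy_replicates=100)
        est = stage_diversity(table, cfg)
        samples = est.samples[("native", "I")]
        expected = 1.0 / 3.0
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - expected) <= 3 * max(se, 1e-4)

    @pytest.mark.parametrize(
        "composition",
        [{"NE": 3, "RGC": 5}, {"NE": 2, "RGC": 2, "PRP": 6}],
    )
    def test_convergence_to_simpson_formula(self, composition):
        types = [t for t, n in composition.items() for _ in range(n)]
        table = self._table(types, types)
        cfg = self._cfg(entropy_pairs=2000, entropy_replicates=100, seed=8)
        est = stage_diversity(table, cfg)
        samples = est.samples[("organoid", "I")]
        expected = simpson_same_type_probability(composition)
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - expected) <= 3 * max(se, 1e-4)

    def test_degenerate_stage_rejected(self):
        table = make_cell_table(
            np.ones((3, 1), dtype=int),
            condition=["native", "native", "organoid"],
            stage=["I", "I", "I"],
        )
        with pytest.raises(ValidationError, match="organoid"):
            stage_diversity(table, self._cfg())

    def test_samples_lie_in_unit_interval(self, synth_default):
        cells, _ = synth_default
        cfg = self._cfg(entropy_pairs=100, entropy_replicates=10)
        est = stage_diversity(cells, cfg)
        for vals in est.samples.values():
            assert ((0 <= vals) & (vals <= 1)).all()
        assert len(est.samples) == 8  # 2 conditions x 4 stages
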