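import math

import numpy as np
import pytest

from uncles.mn_selection import (MNPoint, build_mn_scatter, cluster_mse,
                                 iterative_select, m_metric, write_mn_table)
from uncles.uncles_engine import ClusterPool, ClusterRecord, UnclesConfig
from .conftest import make_dataset


def record(genes, spec_type="A", K=2, **kw):
    return ClusterRecord(genes=frozenset(genes), spec_type=spec_type, K=K, **kw)


def pool_of(records):
    return ClusterPool(list(records), UnclesConfig(k_list=(2,)), records[0].spec_type)


def point(distance, genes, N=None, K=2, index=0):
    rec = record(genes, K=K)
    return MNPoint(record=rec, M=0.0, N=N or len(rec.genes),
                   logN=math.log(N or len(rec.genes)),
                   corner_distance=distance, index=index)


class TestClusterMSE:
    def test_identical_profiles_score_zero(self):
        ds = make_dataset([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        assert cluster_mse(ds, {0, 1}) == 0.0

    def test_singleton_scores_zero(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]])
        assert cluster_mse(ds, {1}) == 0.0

    def test_hand_computed_value(self):
        # profiles (0,0) and (2,2): mean (1,1), total squared dev 4,
        # MSE = 4 / (D*N) = 4 / 4 = 1
        ds = make_dataset([[0.0, 0.0], [2.0, 2.0]])
        assert cluster_mse(ds, {0, 1}) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        ds = make_dataset([[0.0, 0.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            cluster_mse(ds, set())


class TestMMetric:
    def test_type_a_is_mean_over_datasets(self):
        # per-dataset MSEs engineered to 1 and 3
        d1 = make_dataset([[0.0, 0.0], [2.0, 2.0]], dataset_id="d1")
        a = 2.0 * math.sqrt(3.0)
        d2 = make_dataset([[0.0, 0.0], [a, a]], dataset_id="d2")
        rec = record({0, 1})
        assert m_metric(rec, [d1, d2]) == pytest.approx(2.0)

    def test_type_b_is_positive_minus_negative_mean(self):
        pos = make_dataset([[0.0, 0.0], [2.0, 2.0]], role="positive")
        neg = make_dataset([[0.0, 0.0], [2.0 * math.sqrt(3.0)] * 2],
                           role="negative")
        rec = record({0, 1}, spec_type="B")
        assert m_metric(rec, [pos, neg]) == pytest.approx(1.0 - 3.0)

    def test_type_b_needs_both_roles(self):
        pos = make_dataset([[0.0, 0.0], [2.0, 2.0]], role="positive")
        with pytest.raises(ValueError):
            m_metric(record({0, 1}, spec_type="B"), [pos])


class TestBuildScatter:
    def test_single_point_degenerate_scaling(self):
        ds = make_dataset(np.ones((4, 3)))
        pts = build_mn_scatter(pool_of([record({0, 1})]), [ds])
        assert pts[0].corner_distance == 0.0
        assert pts[0].scaled_M == 0.0 and pts[0].scaled_N == 1.0

    def test_dominating_cluster_is_closer(self):
        # cluster B: smaller M (tighter) and larger N than cluster A
        ds = make_dataset([[0.0, 0.0], [2.0, 2.0],
                           [5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        pts = build_mn_scatter(pool_of([record({0, 1}),
                                        record({2, 3, 4})]), [ds])
        assert pts[1].corner_distance < pts[0].corner_distance

    def test_hand_scaled_coordinates(self):
        # three clusters with M = 0, 1, 0 and N = 2, 2, 4: scaled points
        # (0,0), (1,0), (0,1) giving distances 1, sqrt(2), 0
        ds = make_dataset([[1.0, 1.0], [1.0, 1.0],
                           [0.0, 0.0], [2.0, 2.0],
                           [3.0, 3.0], [3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        pts = build_mn_scatter(
            pool_of([record({0, 1}), record({2, 3}),
                     record({4, 5, 6, 7})]), [ds])
        assert [p.corner_distance for p in pts] == pytest.approx(
            [1.0, math.sqrt(2.0), 0.0])

    def test_empty_records_excluded(self):
        ds = make_dataset(np.ones((3, 2)))
        pts = build_mn_scatter(pool_of([record(set()), record({0, 1})]), [ds])
        assert len(pts) == 1
        with pytest.raises(ValueError):
            build_mn_scatter(pool_of([record(set())]), [ds])

    def test_log_base_does_not_change_scaled_coordinates(self):
        # min-max scaling absorbs the log base (a linear rescaling)
        ds = make_dataset(np.random.default_rng(0).normal(size=(20, 3)))
        pts = build_mn_scatter(
            pool_of([record(set(range(i))) for i in (2, 5, 11)]), [ds])
        n10 = np.array([math.log10(p.N) for p in pts])
        rescaled = (n10 - n10.min()) / (n10.max() - n10.min())
        np.testing.assert_allclose([p.scaled_N for p in pts], rescaled,
                                   atol=1e-12)


class TestIterativeSelect:
    def test_disjoint_points_picked_in_distance_order(self):
        pts = [point(0.5, {0, 1}, index=0), point(0.1, {2, 3}, index=1),
               point(0.3, {4, 5}, index=2)]
        picks = iterative_select(pts, 3)
        assert [p.index for p, _ in picks] == [1, 2, 0]
        dists = [d for _, d in picks]
        assert dists == sorted(dists)

    def test_total_overlap_yields_single_pick(self):
        pts = [point(0.1, {0, 1}, index=0), point(0.2, {1, 2}, index=1),
               point(0.3, {0, 9}, index=2)]
        assert len(iterative_select(pts, 5)) == 1

    def test_hand_simulated_removal_sequence(self):
        # hand simulation: pick idx2 (d=.05), which removes idx0 and idx4
        # (shared genes 2 and 3); next best survivor idx1 (d=.15) removes
        # idx5 (shared gene 8); idx3 remains and is picked last
        pts = [point(0.10, {1, 2}, index=0),
               point(0.15, {7, 8}, index=1),
               point(0.05, {2, 3}, index=2),
               point(0.40, {10, 11}, index=3),
               point(0.30, {3, 4}, index=4),
               point(0.20, {8, 9}, index=5)]
        picks = iterative_select(pts, 10)
        assert [p.index for p, _ in picks] == [2, 1, 3]

    def test_selected_clusters_pairwise_disjoint(self):
        rng = np.random.default_rng(8)
        pts = [point(float(rng.random()),
                     set(rng.choice(30, size=5, replace=False).tolist()),
                     index=i)
               for i in range(40)]
        picks = iterative_select(pts, 10)
        chosen = [p.record.genes for p, _ in picks]
        for i, a in enumerate(chosen):
            for b in chosen[i + 1:]:
                assert not (a & b)

    def test_distance_ties_prefer_larger_clusters(self):
        pts = [point(0.2, {0, 1}, index=0),
               point(0.2, {5, 6, 7}, index=1)]
        assert iterative_select(pts, 1)[0][0].index == 1

    def test_bad_max_clusters_rejected(self):
        with pytest.raises(ValueError):
            iterative_select([point(0.1, {0})], 0)


def test_mn_plot_smoke(tmp_path):
    from uncles.mn_selection import plot_mn_scatter
    ds = make_dataset(np.random.default_rng(1).normal(size=(10, 3)))
    pts = build_mn_scatter(pool_of([record({0, 1}), record({2, 3, 4})]), [ds])
    out = tmp_path / "mn.png"
    plot_mn_scatter(pts, out, selected=iterative_select(pts, 1))
    assert out.stat().st_size > 0


def test_mn_table_export(tmp_path):
    ds = make_dataset(np.ones((4, 3)))
    pts = build_mn_scatter(pool_of([record({0, 1}), record({2, 3})]), [ds])
    picks = iterative_select(pts, 1)
    out = tmp_path / "mn.tsv"
    write_mn_table(pts, out, selected=picks)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("record_id\t")
    assert len(lines) == 3
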