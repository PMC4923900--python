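"""Profile feature construction, k-means behaviour, and optimal-k selection."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from timeclust import (ClusterConfig, InputError, cluster_contrast, cluster_report,
                       kmeans_cluster, profile_vectors, select_optimal_k)
from timeclust.clustering import ClusterResult


def ring_points(n_clusters, per_cluster, sd_deg, seed, radius=np.sqrt(5)):
    rng = np.random.default_rng(seed)
    centers = np.linspace(0, 2 * np.pi, n_clusters, endpoint=False)
    ang = np.repeat(centers, per_cluster) + rng.normal(0, np.radians(sd_deg),
                                                       n_clusters * per_cluster)
    pts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    return pd.DataFrame(pts, index=[f"p{i}" for i in range(len(pts))]), labels


class TestProfileVectors:
    def test_flat_difference_maps_to_zero_vector(self, planted_fit):
        fit, truth = planted_fit
        # a null probe that passed nothing still has NaN profiles; use a
        # constructed fit table instead: identical treated/control curves
        tbl = fit.table.copy()
        probe = fit.survivors()[0]
        for d in fit.day_grid:
            tbl.loc[probe, f"fit_ba_d{d:g}"] = tbl.loc[probe, f"fit_control_d{d:g}"]
        fit2 = type(fit)(contrast=fit.contrast, config=fit.config, table=tbl,
                         day_grid=fit.day_grid)
        v = profile_vectors(fit2, [probe])
        assert (v.to_numpy() == 0).all()

    def test_vectors_are_z_scored_and_scale_invariant(self, planted_fit):
        fit, _ = planted_fit
        probes = fit.survivors()[:10]
        v = profile_vectors(fit, probes)
        np.testing.assert_allclose(v.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(v.to_numpy().std(axis=1), 1, atol=1e-12)
        # scaling the raw fitted curves leaves standardized vectors unchanged
        tbl = fit.table.copy()
        cols = [c for c in tbl.columns if c.startswith("fit_")]
        tbl[cols] = tbl[cols] * 10
        fit10 = type(fit)(contrast=fit.contrast, config=fit.config, table=tbl,
                          day_grid=fit.day_grid)
        np.testing.assert_allclose(profile_vectors(fit10, probes).to_numpy(),
                                   v.to_numpy(), atol=1e-10)


class TestKmeans:
    def test_two_separated_blobs_fully_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))])
        labels, _ = kmeans_cluster(pts, 2, restarts=5, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_returns_total_ss(self, rng):
        pts = rng.normal(size=(20, 4))
        labels, inertia = kmeans_cluster(pts, 1, restarts=1, seed=0)
        assert set(labels) == {1}
        total_ss = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert inertia == pytest.approx(total_ss, rel=1e-9)

    def test_duplicated_points_are_co_clustered(self, rng):
        base = rng.normal(size=(5, 3))
        pts = np.vstack([base, base])
        labels, _ = kmeans_cluster(pts, 3, restarts=5, seed=1)
        assert (labels[:5] == labels[5:]).all()

    def test_k_beyond_distinct_vectors_is_an_error(self):
        pts = np.tile(np.arange(3.0), (4, 1)).T  # 3 distinct rows
        with pytest.raises(InputError, match="distinct"):
            kmeans_cluster(pts, 4, restarts=1, seed=0)


class TestSelectOptimalK:
    def test_too_few_probes_reports_zero_clusters(self):
        v = pd.DataFrame(np.eye(3))
        sel = select_optimal_k(v, ClusterConfig(min_probes=5))
        assert sel.k_star == 0 and sel.labels is None

    @pytest.mark.parametrize("k_true", [3, 6, 9])
    def test_recovers_planted_ring_clusters(self, k_true):
        v, truth = ring_points(k_true, 30, sd_deg=5, seed=k_true)
        sel = select_optimal_k(v, ClusterConfig(k_max=15, seed=k_true))
        assert sel.k_star == k_true
        assert adjusted_rand_score(truth, sel.labels.to_numpy()) >= 0.9

    def test_extreme_outlier_is_isolated_as_singleton(self, rng):
        blob = rng.normal(0, 0.2, (40, 5))
        outlier = np.full((1, 5), 30.0)
        v = pd.DataFrame(np.vstack([blob, outlier]),
                         index=[f"p{i}" for i in range(41)])
        sel = select_optimal_k(v, ClusterConfig(k_max=8, seed=3))
        counts = sel.labels.value_counts()
        assert counts.min() == 1
        assert sel.labels.iloc[-1] == counts.idxmin()

    def test_single_tight_blob_selects_one_cluster(self, rng):
        v = pd.DataFrame(rng.normal(0, 1.0, (60, 5)))
        sel = select_optimal_k(v, ClusterConfig(k_max=8, seed=5))
        assert sel.k_star == 1

    def test_deterministic_for_fixed_seed(self):
        v, _ = ring_points(5, 20, sd_deg=8, seed=11)
        a = select_optimal_k(v, ClusterConfig(k_max=10, seed=4))
        b = select_optimal_k(v, ClusterConfig(k_max=10, seed=4))
        assert a.k_star == b.k_star
        assert a.labels.equals(b.labels)


class TestClusterReport:
    def _result(self, contrast, label_map):
        labels = pd.Series(label_map) if label_map else None
        return ClusterResult(contrast=contrast, k=max(label_map.values()) if label_map else 0,
                             labels=labels, cluster_profiles=pd.DataFrame(),
                             selection_scores={})

    def test_shared_flags_mark_probes_clustered_in_both_contrasts(self):
        ann = pd.Series({"p1": "Psat1", "p2": "", "p3": "Fgf21"})
        rep = cluster_report(self._result("ba", {"p1": 1, "p2": 1}),
                             self._result("gh", {"p1": 1, "p3": 1}), ann)
        ba = rep["ba"].set_index("probe_id")
        assert bool(ba.loc["p1", "shared_flag"]) is True
        assert bool(ba.loc["p2", "shared_flag"]) is False
        assert ba.loc["p1", "gene"] == "Psat1"

    def test_zero_cluster_contrast_yields_empty_table(self):
        rep = cluster_report(self._result("ba", {"p1": 1}),
                             self._result("gh", {}), pd.Series(dtype=object))
        assert len(rep["gh"]) == 0
        assert list(rep["gh"].columns) == ["probe_id", "gene", "cluster", "shared_flag"]

    def test_multi_probe_gene_lands_in_one_cluster(self, planted_fit):
        """All probes planted on one template co-cluster, so a multi-probe
        gene's probes appear under a single cluster id."""
        fit, truth = planted_fit
        res = cluster_contrast(fit, ClusterConfig(k_max=8, seed=0))
        labels = truth.labels()
        for tpl in labels.loc[res.probe_ids()].unique():
            members = res.labels.loc[[p for p in res.probe_ids()
                                      if labels[p] == tpl]]
            assert members.nunique() == 1
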