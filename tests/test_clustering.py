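"""Profile matrices, agglomerative clustering, Newick export, heat maps."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from pcbrisk.clustering import (
    ClusterTree,
    build_profile_matrix,
    export_tree,
    hierarchical_cluster,
    render_heatmap,
)
from pcbrisk.congeners import CONGENERS
from pcbrisk.errors import DataError

NAMES = [c.value for c in CONGENERS]

# per-product survey means, used as a worked 6x3 profile
PRODUCT_MEANS = {
    "yogurt": [0.09, 0.14, 0.09, 0.50, 4.26, 9.58],
    "doogh": [0.06, 0.25, 0.08, 0.34, 3.33, 8.14],
    "kashk": [0.13, 0.17, 0.12, 0.61, 5.41, 12.21],
}


def _mean_records():
    rows = []
    for product, vals in PRODUCT_MEANS.items():
        rows.append({"sample_id": product, "product": product, "brand": "A",
                     **dict(zip(NAMES, vals))})
    return pd.DataFrame(rows)


def _cophenetic(tree: ClusterTree) -> dict[frozenset, float]:
    """Leaf-pair merge heights, reconstructed from the merge history."""
    n = len(tree.labels)
    members = {i: {tree.labels[i]} for i in range(n)}
    heights = {}
    for k, (l, r, h, _) in enumerate(tree.merges):
        for a in members[l]:
            for b in members[r]:
                heights[frozenset((a, b))] = h
        members[n + k] = members[l] | members[r]
    return heights


def _brute_force_agglomerate(points: np.ndarray, labels: list[str], linkage: str):
    """Oracle: recompute inter-cluster distances from raw members each step.

    single/complete/average linkage defined directly as min/max/mean over all
    member pairs; returns the sequence of (merged label-sets, height).
    """
    clusters = [frozenset([lbl]) for lbl in labels]
    pos = {lbl: points[i] for i, lbl in enumerate(labels)}
    agg = {"single": min, "complete": max, "average": lambda v: sum(v) / len(v)}[linkage]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            dists = [np.linalg.norm(pos[p] - pos[q]) for p in a for q in b]
            d = agg(dists)
            key = (d, min(a), min(b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((a | b, d))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


class TestProfileMatrix:
    def test_product_means_matrix(self):
        pm = build_profile_matrix(_mean_records(), group_by="product", scaling="none")
        assert pm.data.shape == (6, 3)
        assert list(pm.data.columns) == ["yogurt", "doogh", "kashk"]
        assert pm.data.loc["PCB180"].tolist() == pytest.approx([9.58, 8.14, 12.21])

    def test_z_scaled_rows_standardized(self, survey):
        pm = build_profile_matrix(survey, group_by="sample", scaling="row_z_score")
        for row in pm.data.index:
            assert pm.data.loc[row].mean() == pytest.approx(0.0, abs=1e-9)
            assert pm.data.loc[row].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_single_group_rejected(self):
        df = _mean_records().iloc[:1]
        with pytest.raises(DataError):
            build_profile_matrix(df, group_by="product")

    def test_constant_row_flagged_not_scaled(self):
        df = _mean_records()
        df[NAMES[0]] = 0.05
        pm = build_profile_matrix(df, group_by="product", scaling="row_unit_variance")
        assert NAMES[0] in pm.unscaled_rows
        assert (pm.data.loc[NAMES[0]] == 0.05).all()

    def test_zscore_distance_correlation_identity(self, survey):
        # for z-scored rows: d^2 = 2 (n-1) (1 - r)
        pm = build_profile_matrix(survey, group_by="sample", scaling="row_z_score")
        x, y = pm.data.iloc[0], pm.data.iloc[4]
        n = pm.data.shape[1]
        r = np.corrcoef(x, y)[0, 1]
        d2 = ((x - y) ** 2).sum()
        assert d2 == pytest.approx(2 * (n - 1) * (1 - r), rel=1e-9)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"])
        tree = hierarchical_cluster(m, linkage="single")
        assert tree.merges[0][:3] == (0, 1, 0.0)

    def test_three_point_single_linkage_hand_trace(self):
        # 1-D points 0, 1, 3: d(a,b)=1, d(b,c)=2, d(a,c)=3
        m = pd.DataFrame([[0.0], [1.0], [3.0]], index=["a", "b", "c"])
        tree = hierarchical_cluster(m, linkage="single")
        assert tree.merges[0] == (0, 1, 1.0, 2)
        assert tree.merges[1][2] == pytest.approx(2.0)  # min(2, 3)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_brute_force_oracle(self, linkage):
        rng = np.random.default_rng(42)
        for n in (3, 4, 5):
            for rep in range(4):
                x = rng.normal(size=(n, 3))
                labels = [f"L{i}" for i in range(n)]
                tree = hierarchical_cluster(
                    pd.DataFrame(x, index=labels), linkage=linkage
                )
                oracle = _brute_force_agglomerate(x, labels, linkage)
                members = {i: frozenset([labels[i]]) for i in range(n)}
                for k, (l, r, h, _) in enumerate(tree.merges):
                    merged = members[l] | members[r]
                    members[n + k] = merged
                    assert merged == oracle[k][0]
                    assert h == pytest.approx(oracle[k][1], rel=1e-9)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
    def test_matches_scipy_cophenetic(self, linkage):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 4))
        labels = [f"R{i}" for i in range(6)]
        tree = hierarchical_cluster(pd.DataFrame(x, index=labels), linkage=linkage)
        z = sch.linkage(x, method=linkage, metric="euclidean")
        coph = squareform(sch.cophenet(z))
        mine = _cophenetic(tree)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mine[frozenset((labels[i], labels[j]))] == pytest.approx(
                    coph[i, j], rel=1e-9
                )

    def test_column_permutation_invariance(self, survey):
        pm = build_profile_matrix(survey, group_by="sample")
        a = hierarchical_cluster(pm)
        shuffled = pm.data[list(pm.data.columns[::-1])]
        b = hierarchical_cluster(shuffled)
        for ma, mb in zip(a.merges, b.merges):
            assert ma[0] == mb[0] and ma[1] == mb[1] and ma[3] == mb[3]
            assert ma[2] == pytest.approx(mb[2], rel=1e-9)

    def test_merge_heights_nondecreasing(self, survey):
        pm = build_profile_matrix(survey, group_by="sample")
        for linkage in ("single", "complete", "average"):
            tree = hierarchical_cluster(pm, linkage=linkage)
            heights = [m[2] for m in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_leaf_order_is_permutation(self, survey):
        pm = build_profile_matrix(survey, group_by="product")
        tree = hierarchical_cluster(pm)
        assert sorted(tree.leaf_order) == sorted(NAMES)

    def test_non_finite_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(DataError):
            hierarchical_cluster(m)


class TestNewickExport:
    def test_two_leaf_midpoint_allocation(self):
        m = pd.DataFrame([[0.0], [3.0]], index=["A", "B"])
        tree = hierarchical_cluster(m)
        assert export_tree(tree) == "(A:1.5,B:1.5);"

    def test_round_trip_preserves_topology_and_heights(self, survey):
        import skbio

        pm = build_profile_matrix(survey, group_by="product")
        tree = hierarchical_cluster(pm)
        parsed = skbio.TreeNode.read(io.StringIO(export_tree(tree)))
        tips = sorted(t.name for t in parsed.tips())
        assert tips == sorted(NAMES)
        # tip-to-tip path length equals the merge height of the pair
        coph = _cophenetic(tree)
        for a, b in itertools.combinations(NAMES, 2):
            tip_a = parsed.find(a)
            assert tip_a.distance(parsed.find(b)) == pytest.approx(
                coph[frozenset((a, b))], rel=1e-9, abs=1e-9
            )

    def test_each_leaf_appears_once(self, survey):
        pm = build_profile_matrix(survey, group_by="product")
        nwk = export_tree(hierarchical_cluster(pm))
        for name in NAMES:
            assert nwk.count(name) == 1


class TestHeatmap:
    def test_renders_non_empty_file(self, tmp_path, survey):
        pm = build_profile_matrix(survey, group_by="product")
        tree = hierarchical_cluster(pm)
        out = tmp_path / "hm.png"
        render_heatmap(pm, str(out), row_tree=tree)
        assert out.exists() and out.stat().st_size > 0

    def test_svg_output(self, tmp_path):
        pm = build_profile_matrix(_mean_records(), group_by="product", scaling="none")
        out = tmp_path / "hm.svg"
        render_heatmap(pm, str(out))
        assert out.exists() and out.stat().st_size > 0
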