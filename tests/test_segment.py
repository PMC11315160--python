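import numpy as np
import pytest

from stisebs.grid import GridGeometry, LabelGrid
from stisebs.reduction import ComponentGrid
from stisebs.segment import (
    PatchGraph,
    build_patch_graph,
    kmeans_cluster,
    label_patches,
    minimum_spanning_tree,
    patch_means,
    skater_partition,
    assemble_superpixels,
)

from conftest import make_grid, make_labels


def scores_grid(arr):
    arr = np.asarray(arr, dtype=float)
    h, w = arr.shape[:2]
    mask = np.all(np.isfinite(arr), axis=2)
    return ComponentGrid(GridGeometry(height=h, width=w), mask, arr)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def flood_fill_patches(labels):
    """Independent 4-connected component labelling by BFS."""
    h, w = labels.shape
    out = np.full((h, w), -1, dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if labels[r0, c0] < 0 or out[r0, c0] >= 0:
                continue
            queue = [(r0, c0)]
            out[r0, c0] = nxt
            while queue:
                r, c = queue.pop()
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if 0 <= rr < h and 0 <= cc < w and out[rr, cc] < 0 and labels[rr, cc] == labels[r, c]:
                        out[rr, cc] = nxt
                        queue.append((rr, cc))
            nxt += 1
    return out


def kruskal_weight(n, edges, costs):
    """Total MST/forest weight by Kruskal with union-find."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    total = 0.0
    for idx in np.argsort(costs, kind="stable"):
        u, v = edges[idx]
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            total += costs[idx]
    return total


def part_ssd_direct(nodes, x):
    xs = x[list(nodes)]
    return float(((xs - xs.mean(axis=0)) ** 2).sum()) / len(nodes)


def skater_oracle(tree: PatchGraph, x, k):
    """Exhaustive greedy: at each step try every edge of every tree."""
    trees = []
    # connected components of the tree graph
    adj = tree.adjacency()
    seen = set()
    for s in range(tree.n_nodes):
        if s in seen:
            continue
        comp, stack = {s}, [s]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        edges = {eid for u in comp for _, eid in adj[u]}
        trees.append((comp, edges))
    steps = []
    while len(trees) < k:
        best = None
        for ti, (nodes, edges) in enumerate(trees):
            base = sum(part_ssd_direct(n, x) for n, _ in trees)
            for eid in sorted(edges):
                u, v = tree.edges[eid]
                # split by BFS avoiding eid
                side = {int(u)}
                stack = [int(u)]
                while stack:
                    a = stack.pop()
                    for b, e2 in adj[a]:
                        if e2 != eid and e2 in edges and b in nodes and b not in side:
                            side.add(b)
                            stack.append(b)
                other = nodes - side
                total = (
                    base
                    - part_ssd_direct(nodes, x)
                    + part_ssd_direct(side, x)
                    + part_ssd_direct(other, x)
                )
                cand = (total, eid, ti, side, other)
                if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
        total, eid, ti, side, other = best
        nodes, edges = trees.pop(ti)
        rem = edges - {eid}
        e_side = {e for e in rem if int(tree.edges[e][0]) in side and int(tree.edges[e][1]) in side}
        trees.append((side, e_side))
        trees.append((other, rem - e_side))
        steps.append((eid, total))
    return steps


def random_tree(n, rng):
    """Uniform random labelled tree via random attachment."""
    edges = []
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.append((min(u, v), max(u, v)))
    edges = sorted(edges)
    costs = rng.uniform(0.1, 2.0, size=len(edges))
    return PatchGraph(n_nodes=n, edges=np.array(edges), costs=costs)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


class TestKmeans:
    def test_k1_centroid_is_global_mean(self, rng):
        arr = rng.normal(size=(4, 4, 3))
        cg = scores_grid(arr)
        model = kmeans_cluster(cg, k=1, seed=0)
        flat = arr.reshape(-1, 3)
        np.testing.assert_allclose(model.centroids[0], flat.mean(axis=0), atol=1e-8)
        total_ss = ((flat - flat.mean(axis=0)) ** 2).sum()
        assert model.objective == pytest.approx(total_ss, rel=1e-8)

    def test_k_equals_n_zero_objective(self, rng):
        cg = scores_grid(rng.normal(size=(3, 3, 2)))
        model = kmeans_cluster(cg, k=9, seed=1)
        assert model.objective == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(model.label_grid.labels)) == 9

    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(scale=0.05, size=(16, 2))
        b = rng.normal(scale=0.05, size=(16, 2)) + 10.0
        arr = np.vstack([a, b]).reshape(4, 8, 2)
        model = kmeans_cluster(scores_grid(arr), k=2, seed=3)
        lab = model.label_grid.labels.ravel()
        assert len(set(lab[:16])) == 1 and len(set(lab[16:])) == 1
        assert lab[0] != lab[16]
        # per-point optimality: each point nearest its own centroid
        flat = arr.reshape(-1, 2)
        d = ((flat[:, None] - model.centroids[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(np.argmin(d, axis=1), lab)

    def test_k_out_of_range(self, rng):
        cg = scores_grid(rng.normal(size=(2, 2, 2)))
        with pytest.raises(ValueError):
            kmeans_cluster(cg, k=5, seed=0)
        with pytest.raises(ValueError):
            kmeans_cluster(cg, k=0, seed=0)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


class TestPatches:
    def test_constant_map_single_patch(self):
        lg, table = label_patches(make_labels(np.zeros((3, 3)), kind="cluster"))
        assert table.n_patches == 1
        assert table.sizes[0] == 9

    def test_diagonal_not_connected_rook(self):
        lg, table = label_patches(make_labels([[0, 1], [1, 0]], kind="cluster"))
        assert table.n_patches == 4
        lg8, table8 = label_patches(make_labels([[0, 1], [1, 0]], kind="cluster"), connectivity=8)
        assert table8.n_patches == 2

    def test_matches_flood_fill_oracle(self, rng):
        clusters = rng.integers(0, 2, size=(8, 8)).astype(np.int32)
        clusters[0, 0] = -1
        lg, table = label_patches(make_labels(clusters, kind="cluster"))
        oracle = flood_fill_patches(clusters)
        # same partition: bijection between label sets
        assert lg.labels[0, 0] == -1
        pairs = set(zip(lg.labels.ravel(), oracle.ravel()))
        valid_pairs = {p for p in pairs if p[0] >= 0}
        assert len(valid_pairs) == len({a for a, _ in valid_pairs})
        assert len(valid_pairs) == len({b for _, b in valid_pairs})
        # patches refine clusters
        for pid in range(table.n_patches):
            cl = np.unique(clusters[lg.labels == pid])
            assert len(cl) == 1 and cl[0] == table.cluster_id[pid]

    def test_patch_means_and_mass_conservation(self, rng):
        arr = rng.normal(size=(4, 4, 3))
        cg = scores_grid(arr)
        clusters = make_labels(rng.integers(0, 3, size=(4, 4)), kind="cluster")
        lg, table = label_patches(clusters)
        table = patch_means(table, cg)
        total = (table.sizes[:, None] * table.means).sum(axis=0)
        np.testing.assert_allclose(total, arr.reshape(-1, 3).sum(axis=0), atol=1e-8)
        # singleton patch mean equals its pixel's scores
        singles = np.nonzero(table.sizes == 1)[0]
        for pid in singles:
            r, c = [int(v[0]) for v in np.nonzero(lg.labels == pid)]
            np.testing.assert_allclose(table.means[pid], arr[r, c])


class TestPatchGraph:
    def test_two_patches_one_edge(self, rng):
        cg = scores_grid(rng.normal(size=(1, 2, 2)))
        lg, table = label_patches(make_labels([[0, 1]], kind="cluster"))
        table = patch_means(table, cg)
        g = build_patch_graph(lg, table)
        assert g.n_edges == 1
        np.testing.assert_array_equal(g.edges[0], [0, 1])
        expected = np.linalg.norm(cg.scores[0, 0] - cg.scores[0, 1])
        assert g.costs[0] == pytest.approx(expected)

    def test_equal_features_zero_cost(self):
        arr = np.ones((1, 2, 2))
        lg, table = label_patches(make_labels([[0, 1]], kind="cluster"))
        table = patch_means(table, scores_grid(arr))
        g = build_patch_graph(lg, table)
        assert g.costs[0] == 0.0

    def test_edges_match_pixel_pair_scan(self, rng):
        clusters = rng.integers(0, 4, size=(8, 8)).astype(np.int32)
        lg, table = label_patches(make_labels(clusters, kind="cluster"))
        table = patch_means(table, scores_grid(rng.normal(size=(8, 8, 2))))
        g = build_patch_graph(lg, table)
        # brute-force scan of all 4-neighbour pixel pairs
        expected = set()
        lab = lg.labels
        for r in range(8):
            for c in range(8):
                for rr, cc in ((r + 1, c), (r, c + 1)):
                    if rr < 8 and cc < 8 and lab[r, c] != lab[rr, cc]:
                        expected.add((min(lab[r, c], lab[rr, cc]), max(lab[r, c], lab[rr, cc])))
        assert {tuple(e) for e in g.edges} == expected


class TestMst:
    def test_triangle_drops_heaviest(self):
        g = PatchGraph(3, np.array([[0, 1], [0, 2], [1, 2]]), np.array([1.0, 3.0, 2.0]))
        t = minimum_spanning_tree(g)
        assert t.costs.sum() == pytest.approx(3.0)
        assert {tuple(e) for e in t.edges} == {(0, 1), (1, 2)}

    def test_path_graph_unchanged(self):
        g = PatchGraph(4, np.array([[0, 1], [1, 2], [2, 3]]), np.array([1.0, 1.0, 1.0]))
        t = minimum_spanning_tree(g)
        assert t.n_edges == 3

    def test_weight_matches_kruskal_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            full = [(u, v) for u in range(n) for v in range(u + 1, n)]
            m = int(rng.integers(n - 1, len(full) + 1))
            sel = rng.choice(len(full), size=m, replace=False)
            edges = np.array(sorted(full[i] for i in sel))
            costs = rng.uniform(0.1, 5.0, size=m).round(1)  # force some ties
            g = PatchGraph(n, edges, costs)
            t = minimum_spanning_tree(g)
            assert t.costs.sum() == pytest.approx(kruskal_weight(n, edges, costs))

    def test_disconnected_graph_gives_forest(self):
        g = PatchGraph(4, np.array([[0, 1], [2, 3]]), np.array([1.0, 2.0]))
        t = minimum_spanning_tree(g)
        assert t.n_edges == 2


class TestSkater:
    def chain(self, feats):
        feats = np.asarray(feats, dtype=float)
        n = len(feats)
        edges = np.array([[i, i + 1] for i in range(n - 1)])
        costs = np.linalg.norm(feats[edges[:, 0]] - feats[edges[:, 1]], axis=1)
        tree = PatchGraph(n, edges, costs)
        labels = make_labels(np.arange(n)[None, :], kind="patch")
        from stisebs.segment import PatchTable

        table = PatchTable(
            label_grid=labels,
            sizes=np.ones(n, dtype=np.int64),
            cluster_id=np.zeros(n, dtype=np.int64),
            means=feats,
        )
        return tree, table

    def test_chain_cuts_middle_edge(self):
        tree, table = self.chain([[0.0], [0.0], [10.0], [10.0]])
        sp = skater_partition(tree, table, k=2)
        assert sp.total_ssd == pytest.approx(0.0, abs=1e-12)
        lab = sp.label_grid.labels[0]
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]

    def test_k_equals_patches_all_singletons(self):
        tree, table = self.chain([[1.0], [2.0], [5.0]])
        sp = skater_partition(tree, table, k=3)
        assert sp.k == 3
        assert sp.total_ssd == pytest.approx(0.0)

    def test_greedy_steps_match_exhaustive_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 10))
            k = int(rng.integers(2, min(n, 4) + 1))
            tree = random_tree(n, rng)
            feats = rng.normal(size=(n, 2))
            labels = make_labels(np.arange(n)[None, :], kind="patch")
            from stisebs.segment import PatchTable

            table = PatchTable(
                label_grid=labels,
                sizes=np.ones(n, dtype=np.int64),
                cluster_id=np.zeros(n, dtype=np.int64),
                means=feats,
            )
            sp = skater_partition(tree, table, k=k, record_history=True)
            oracle = skater_oracle(tree, feats, k)
            assert len(sp.history) == len(oracle)
            for step, (eid, total) in zip(sp.history, oracle):
                assert step["edge_id"] == eid, f"trial {trial}"
                assert step["total_ssd"] == pytest.approx(total, abs=1e-9)

    def test_k_out_of_range(self):
        tree, table = self.chain([[1.0], [2.0]])
        with pytest.raises(ValueError):
            skater_partition(tree, table, k=3)
        with pytest.raises(ValueError):
            skater_partition(tree, table, k=0)


def bare_superpixels(lg):
    """Minimal SuperpixelSet over a label grid, series not yet attached."""
    from stisebs.segment import SuperpixelSet

    k = lg.n_labels
    counts = np.bincount(lg.labels[lg.valid_mask], minlength=k)
    return SuperpixelSet(
        k=k,
        label_grid=lg,
        patch_assignment=np.arange(k),
        n_patches=np.ones(k, dtype=np.int64),
        pixel_counts=counts.astype(np.int64),
        centroids=np.zeros((k, 1)),
        ssd=np.zeros(k),
    )


class TestAssemble:
    def test_mean_series_and_conservation(self):
        vals = np.array([[[0.2, 0.4], [0.4, 0.6]], [[0.0, 1.0], [0.5, 0.5]]])
        grid = make_grid(vals)
        sp = assemble_superpixels(bare_superpixels(make_labels([[0, 0], [1, 1]])), grid)
        np.testing.assert_allclose(sp.mean_series[0], [0.3, 0.5])
        # pixel-count-weighted mean of segment series = global mean
        global_mean = vals.reshape(-1, 2).mean(axis=0)
        weighted = (sp.pixel_counts[:, None] * sp.mean_series).sum(axis=0) / sp.pixel_counts.sum()
        np.testing.assert_allclose(weighted, global_mean, atol=1e-12)

    def test_singleton_superpixel_is_own_series(self, rng):
        vals = rng.uniform(-1, 1, (2, 2, 5))
        grid = make_grid(vals)
        sp = assemble_superpixels(bare_superpixels(make_labels(np.arange(4).reshape(2, 2))), grid)
        np.testing.assert_allclose(sp.mean_series, vals.reshape(4, 5))
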