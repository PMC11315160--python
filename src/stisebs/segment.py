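"""Superpixel segmentation core.

The pipeline turns per-pixel component scores into spatially contiguous
superpixels in four steps:

1. **k-means** on the component vectors (no spatial coordinates — this
   stage is deliberately non-spatially constrained, it only has to be
   fast and feature-faithful);
2. **patch dissolution** — maximal 4-connected sets of same-cluster
   pixels become patches, each carrying the mean component vector of
   its member pixels;
3. **patch graph + minimum spanning tree** — patches that share a
   pixel edge are connected, edge cost the Euclidean distance between
   patch feature vectors, reduced to an MST with Prim's algorithm;
4. **SKATER partition** — the MST is pruned edge by edge, each cut
   chosen greedily to minimize the total within-tree sum of squared
   deviations, until the requested number of superpixels exists.

The within-tree deviation of tree k with n_k member patches is

    SSD_k = (1/n_k) * sum_j ||x_j - x_k||^2

with x_k the unweighted mean of the member patch features.  The classic
SKATER objective (pixel-count-weighted means, unnormalized sums) is
available with ``weighted=True``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import GridGeometry, LabelGrid, TimeSeriesGrid
from .preprocess import PreprocessConfig, preprocess_stack
from .reduction import ComponentGrid, PCAModel, fit_pca, transform

__all__ = [
    "ClusterModel",
    "PatchTable",
    "PatchGraph",
    "SuperpixelSet",
    "StisebsResult",
    "kmeans_cluster",
    "label_patches",
    "patch_means",
    "build_patch_graph",
    "minimum_spanning_tree",
    "skater_partition",
    "assemble_superpixels",
    "run_stisebs",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Converged k-means state over the valid pixels."""

    k: int
    centroids: np.ndarray  # (k, C)
    label_grid: LabelGrid  # kind="cluster"
    objective: float  # within-cluster sum of squared distances
    seed: int
    n_iter: int


def kmeans_cluster(
    scores: ComponentGrid,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterModel:
    """Seeded k-means++ / Lloyd clustering of component vectors.

    A final assignment pass guarantees every pixel sits with its nearest
    centroid, so per-point optimality holds exactly at return.
    """
    from sklearn.cluster import KMeans

    pm = scores.matrix()
    n = pm.n_pixels
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} valid pixels")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
        algorithm="lloyd",
    ).fit(pm.data)
    centers = km.cluster_centers_
    # nearest-centroid reassignment wrt the *final* centers
    d2 = ((pm.data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2) if n * k <= 2_000_000 else None
    if d2 is not None:
        labels = np.argmin(d2, axis=1)
        objective = float(d2[np.arange(n), labels].sum())
    else:  # chunked for large problems
        labels = np.empty(n, dtype=np.int64)
        objective = 0.0
        step = max(1, 2_000_000 // k)
        for s in range(0, n, step):
            block = pm.data[s : s + step]
            dd = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            lb = np.argmin(dd, axis=1)
            labels[s : s + step] = lb
            objective += float(dd[np.arange(len(lb)), lb].sum())
    # relabel by first appearance (row-major) and permute centroids to
    # match, so label id i always indexes centroid row i
    uniq, first = np.unique(labels, return_index=True)
    order = uniq[np.argsort(first, kind="stable")]
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(len(order))
    labels = remap[labels]
    centers = centers[order]
    h, w = scores.geometry.shape
    lab = np.full((h, w), -1, dtype=np.int32)
    lab[pm.pixel_index[:, 0], pm.pixel_index[:, 1]] = labels
    lg = LabelGrid(scores.geometry, lab, kind="cluster")
    return ClusterModel(
        k=len(order),
        centroids=centers,
        label_grid=lg,
        objective=objective,
        seed=seed,
        n_iter=int(km.n_iter_),
    )


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


@dataclass
class PatchTable:
    """Per-patch membership and features.

    Patches partition the valid pixels; each patch is a maximal
    connected set of pixels sharing one cluster label.
    """

    label_grid: LabelGrid  # kind="patch"
    sizes: np.ndarray  # (J,) pixel counts
    cluster_id: np.ndarray  # (J,) source cluster per patch
    means: np.ndarray | None = None  # (J, C) mean component vectors

    @property
    def n_patches(self) -> int:
        return len(self.sizes)


def label_patches(clusters: LabelGrid, connectivity: int = 4) -> tuple[LabelGrid, PatchTable]:
    """Dissolve a cluster map into connected same-cluster patches."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT4 if connectivity == 4 else _STRUCT8
    labels = clusters.labels
    out = np.full(labels.shape, -1, dtype=np.int32)
    cluster_of = []
    offset = 0
    for cid in np.unique(labels[labels >= 0]):
        comp, n = ndimage.label(labels == cid, structure=struct)
        out[comp > 0] = comp[comp > 0] + offset - 1
        cluster_of.extend([int(cid)] * n)
        offset += n
    lg = LabelGrid(clusters.geometry, out, kind="patch")
    cluster_of = np.asarray(cluster_of, dtype=np.int64)
    # compact to row-major first-appearance order for determinism
    compacted = lg.compact()
    old = lg.labels[compacted.valid_mask]
    new = compacted.labels[compacted.valid_mask]
    remap = np.empty(offset, dtype=np.int64)
    remap[new] = old
    sizes = np.bincount(compacted.labels[compacted.valid_mask], minlength=offset)
    table = PatchTable(
        label_grid=compacted,
        sizes=sizes.astype(np.int64),
        cluster_id=cluster_of[remap],
    )
    return compacted, table


def _segment_means(labels_flat: np.ndarray, feats: np.ndarray, n_segments: int) -> np.ndarray:
    """Mean feature vector per segment id, via bincount per column."""
    counts = np.bincount(labels_flat, minlength=n_segments).astype(float)
    out = np.empty((n_segments, feats.shape[1]))
    for c in range(feats.shape[1]):
        out[:, c] = np.bincount(labels_flat, weights=feats[:, c], minlength=n_segments)
    out /= counts[:, None]
    return out


def patch_means(patches: PatchTable, scores: ComponentGrid) -> PatchTable:
    """Attach the unweighted mean score vector of each patch's pixels."""
    mask = patches.label_grid.valid_mask
    if not np.array_equal(mask, scores.valid_mask):
        raise ValueError("patch map and score grid have different masks")
    labels_flat = patches.label_grid.labels[mask]
    feats = scores.scores[mask]
    means = _segment_means(labels_flat, feats, patches.n_patches)
    return replace(patches, means=means)


# ---------------------------------------------------------------------------
# patch graph and MST
# ---------------------------------------------------------------------------


@dataclass
class PatchGraph:
    """Undirected patch adjacency with Euclidean feature costs.

    Edges are stored as (min_id, max_id) rows in lexicographic order;
    the row index is the edge id used for deterministic tie-breaking.
    """

    n_nodes: int
    edges: np.ndarray  # (E, 2) int
    costs: np.ndarray  # (E,) float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-node list of (neighbor, edge_id)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for eid, (u, v) in enumerate(self.edges):
            adj[u].append((int(v), eid))
            adj[v].append((int(u), eid))
        return adj


def adjacent_label_pairs(labels: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Unique (min, max) pairs of distinct labels sharing a pixel edge."""
    pairs = []
    shifts = [(0, 1), (1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1)]
    for dr, dc in shifts:
        if dc >= 0:
            a = labels[: labels.shape[0] - dr, : labels.shape[1] - dc]
            b = labels[dr:, dc:]
        else:
            a = labels[: labels.shape[0] - dr, -dc:]
            b = labels[dr:, : labels.shape[1] + dc]
        keep = (a >= 0) & (b >= 0) & (a != b)
        pairs.append(np.column_stack([a[keep], b[keep]]))
    allp = np.vstack(pairs)
    if len(allp) == 0:
        return np.empty((0, 2), dtype=np.int64)
    allp = np.sort(allp, axis=1)
    return np.unique(allp, axis=0).astype(np.int64)


def build_patch_graph(
    patches: LabelGrid | PatchTable,
    features: PatchTable | None = None,
    connectivity: int = 4,
) -> PatchGraph:
    """Adjacency graph of patches with Euclidean feature distances."""
    if isinstance(patches, PatchTable):
        features = features or patches
        patches = patches.label_grid
    if features is None or features.means is None:
        raise ValueError("patch features required; call patch_means first")
    pairs = adjacent_label_pairs(patches.labels, connectivity)
    diffs = features.means[pairs[:, 0]] - features.means[pairs[:, 1]]
    costs = np.sqrt((diffs ** 2).sum(axis=1))
    return PatchGraph(n_nodes=features.n_patches, edges=pairs, costs=costs)


def minimum_spanning_tree(g: PatchGraph) -> PatchGraph:
    """Prim's algorithm per connected component, deterministic ties.

    Candidate edges are ordered by the (cost, min node id, max node id)
    triple, so equal-cost alternatives always resolve the same way.
    Returns a forest when the input graph is disconnected.
    """
    adj = g.adjacency()
    visited = np.zeros(g.n_nodes, dtype=bool)
    chosen: list[int] = []
    for start in range(g.n_nodes):
        if visited[start]:
            continue
        visited[start] = True
        heap: list[tuple[float, int, int, int, int]] = []
        for nb, eid in adj[start]:
            u, v = g.edges[eid]
            heapq.heappush(heap, (g.costs[eid], int(u), int(v), eid, nb))
        while heap:
            _, _, _, eid, node = heapq.heappop(heap)
            if visited[node]:
                continue
            visited[node] = True
            chosen.append(eid)
            for nb, eid2 in adj[node]:
                if not visited[nb]:
                    u, v = g.edges[eid2]
                    heapq.heappush(heap, (g.costs[eid2], int(u), int(v), eid2, nb))
    chosen_arr = np.asarray(sorted(chosen), dtype=np.int64)
    return PatchGraph(
        n_nodes=g.n_nodes,
        edges=g.edges[chosen_arr],
        costs=g.costs[chosen_arr],
    )


# ---------------------------------------------------------------------------
# SKATER
# ---------------------------------------------------------------------------


@dataclass
class SuperpixelSet:
    """A spatially contiguous partition of the valid pixels.

    Superpixels are unions of whole patches; ``mean_series`` is filled
    by :func:`assemble_superpixels` (unweighted mean over member pixels
    of the index series).
    """

    k: int
    label_grid: LabelGrid  # kind="superpixel", pixel level
    patch_assignment: np.ndarray  # (J,) superpixel id per patch
    n_patches: np.ndarray  # (K,) member-patch counts n_k
    pixel_counts: np.ndarray  # (K,) member-pixel counts
    centroids: np.ndarray  # (K, C) mean patch feature vectors x_k
    ssd: np.ndarray  # (K,) within-tree squared deviation
    mean_series: np.ndarray | None = None  # (K, T)
    times: list[str] | None = None
    history: list[dict] = field(default_factory=list, repr=False)

    @property
    def total_ssd(self) -> float:
        return float(self.ssd.sum())


def _part_ssd(q: float, s: np.ndarray, n: float, weighted: bool) -> float:
    """Within-part squared deviation from aggregates.

    q = sum of (weighted) squared norms, s = (weighted) feature sum,
    n = element count (or total weight).  Literal form normalizes by n;
    the weighted/classic form is the raw within sum of squares.
    """
    wss = q - float(s @ s) / n
    wss = max(wss, 0.0)  # guard tiny negative round-off
    return wss / n if not weighted else wss


class _Tree:
    """One current tree of the pruning forest, with its best split cached."""

    __slots__ = ("nodes", "ssd", "best")

    def __init__(self, nodes, ssd, best):
        self.nodes = nodes  # list[int]
        self.ssd = ssd  # float
        self.best = best  # (delta, edge_id, child, parent) or None


def _evaluate_tree(nodes, adj, in_tree, x, w, q_node, weighted):
    """SSD of a tree and its best single-edge removal.

    Roots the tree at its minimum node, accumulates subtree aggregates
    bottom-up, then scores every edge removal from the aggregates.
    Returns (ssd, best) with best = (delta, edge_id, child, parent) or
    None for a singleton; delta = ssd_a + ssd_b - ssd_tree.
    """
    root = min(nodes)
    parent = {root: (-1, -1)}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v, eid in adj[u]:
            if in_tree[v] and v not in parent:
                parent[v] = (u, eid)
                order.append(v)
                stack.append(v)
    nw = {u: w[u] for u in order}
    ns = {u: w[u] * x[u] for u in order}
    nq = {u: q_node[u] for u in order}
    for u in reversed(order[1:]):
        p = parent[u][0]
        nw[p] += nw[u]
        ns[p] = ns[p] + ns[u]
        nq[p] += nq[u]
    tot_w, tot_s, tot_q = nw[root], ns[root], nq[root]
    ssd_tree = _part_ssd(tot_q, tot_s, tot_w, weighted)
    best = None
    for u in order[1:]:
        p, eid = parent[u]
        ssd_a = _part_ssd(nq[u], ns[u], nw[u], weighted)
        ssd_b = _part_ssd(tot_q - nq[u], tot_s - ns[u], tot_w - nw[u], weighted)
        delta = ssd_a + ssd_b - ssd_tree
        cand = (delta, eid, u, p)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    return ssd_tree, best


def skater_partition(
    tree: PatchGraph,
    patches: PatchTable,
    k: int,
    weighted: bool = False,
    record_history: bool = False,
) -> SuperpixelSet:
    """Prune an MST into k superpixels by greedy best-first edge removal.

    Every step evaluates every single-edge removal in every current tree
    (via rooted subtree aggregates, so a step is linear in tree size)
    and commits the one minimizing the total SSD; ties resolve to the
    lowest edge id.
    """
    if patches.means is None:
        raise ValueError("patch features required; call patch_means first")
    j = patches.n_patches
    if not (1 <= k <= j):
        raise ValueError(f"k={k} out of range [1, {j}]")
    x = patches.means
    w = np.ones(j) if not weighted else patches.sizes.astype(float)
    q_node = w * (x ** 2).sum(axis=1)
    adj = tree.adjacency()

    # initial forest: one tree per connected component of the MST
    comp = np.full(j, -1, dtype=np.int64)
    trees: list[_Tree] = []
    in_tree = np.zeros(j, dtype=bool)
    for start in range(j):
        if comp[start] >= 0:
            continue
        nodes = [start]
        comp[start] = len(trees)
        stack = [start]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if comp[v] < 0:
                    comp[v] = len(trees)
                    nodes.append(v)
                    stack.append(v)
        trees.append(_Tree(nodes, 0.0, None))
    if k < len(trees):
        raise ValueError(
            f"k={k} below the {len(trees)} disconnected components"
        )
    in_tree[:] = True
    for t in trees:
        flags = np.zeros(j, dtype=bool)
        flags[t.nodes] = True
        t.ssd, t.best = _evaluate_tree(t.nodes, adj, flags, x, w, q_node, weighted)

    history: list[dict] = []
    while len(trees) < k:
        best_ti, best_key = -1, None
        for ti, t in enumerate(trees):
            if t.best is None:
                continue
            # total after split = current total + delta, so the split with
            # the smallest delta minimizes the total SSD over all trees
            key = (t.best[0], t.best[1])
            if best_key is None or key < best_key:
                best_key, best_ti = key, ti
        if best_ti < 0:
            raise ValueError("no splittable tree left (k exceeds patch count?)")
        t = trees.pop(best_ti)
        _, eid, child, parent = t.best
        # collect the child-side nodes by DFS avoiding the removed edge
        member = np.zeros(j, dtype=bool)
        member[t.nodes] = True
        side = np.zeros(j, dtype=bool)
        stack = [child]
        side[child] = True
        while stack:
            u = stack.pop()
            for v, e2 in adj[u]:
                if e2 != eid and member[v] and not side[v]:
                    side[v] = True
                    stack.append(v)
        nodes_a = [u for u in t.nodes if side[u]]
        nodes_b = [u for u in t.nodes if not side[u]]
        for nodes in (nodes_a, nodes_b):
            flags = np.zeros(j, dtype=bool)
            flags[nodes] = True
            ssd, best = _evaluate_tree(nodes, adj, flags, x, w, q_node, weighted)
            trees.append(_Tree(nodes, ssd, best))
        if record_history:
            history.append(
                {
                    "edge_id": int(eid),
                    "n_trees": len(trees),
                    "total_ssd": float(sum(tt.ssd for tt in trees)),
                }
            )

    # deterministic superpixel ids: first appearance in row-major pixel scan
    assign = np.empty(j, dtype=np.int64)
    for ti, t in enumerate(trees):
        assign[t.nodes] = ti
    plab = patches.label_grid.labels
    sp_labels = np.full(plab.shape, -1, dtype=np.int32)
    valid = plab >= 0
    sp_labels[valid] = assign[plab[valid]]
    lg = LabelGrid(patches.label_grid.geometry, sp_labels, kind="superpixel").compact()
    # remap tree stats into compacted order
    new_of_old = np.full(len(trees), -1, dtype=np.int64)
    new_ids = lg.labels[valid]
    new_of_old[assign[plab[valid]]] = new_ids
    kk = len(trees)
    n_patches = np.zeros(kk, dtype=np.int64)
    ssd = np.zeros(kk)
    centroids = np.zeros((kk, x.shape[1]))
    final_assign = new_of_old[assign]
    for ti, t in enumerate(trees):
        sid = int(new_of_old[ti])
        n_patches[sid] = len(t.nodes)
        ssd[sid] = t.ssd
        centroids[sid] = (w[t.nodes, None] * x[t.nodes]).sum(axis=0) / w[t.nodes].sum()
    pixel_counts = np.zeros(kk, dtype=np.int64)
    np.add.at(pixel_counts, final_assign, patches.sizes)
    return SuperpixelSet(
        k=kk,
        label_grid=lg,
        patch_assignment=final_assign,
        n_patches=n_patches,
        pixel_counts=pixel_counts,
        centroids=centroids,
        ssd=ssd,
        history=history,
    )


def assemble_superpixels(sp: SuperpixelSet, ndvi: TimeSeriesGrid) -> SuperpixelSet:
    """Attach each superpixel's mean index series (mean over member pixels)."""
    mask = sp.label_grid.valid_mask
    if not np.array_equal(mask, ndvi.valid_mask):
        raise ValueError("superpixel map and series grid have different masks")
    labels_flat = sp.label_grid.labels[mask]
    series = ndvi.values[mask]
    means = _segment_means(labels_flat, series, sp.k)
    return replace(sp, mean_series=means, times=list(ndvi.times))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class StisebsResult:
    """All stage artifacts of one pipeline run."""

    labels: LabelGrid
    superpixels: SuperpixelSet
    pca: PCAModel
    clusters: ClusterModel
    patches: PatchTable
    graph: PatchGraph
    mst: PatchGraph
    preprocessed: TimeSeriesGrid


def run_stisebs(
    stack: TimeSeriesGrid,
    k_superpixels: int,
    k_clusters: int | None = None,
    variance_target: float = 0.99,
    max_components: int | None = 200,
    seed: int = 0,
    preprocess: bool | PreprocessConfig = False,
    connectivity: int = 4,
    weighted: bool = False,
    full: bool = False,
):
    """Run the full superpixel pipeline on a time-series grid.

    Returns ``(LabelGrid, SuperpixelSet)``, or a :class:`StisebsResult`
    with every stage artifact when ``full=True``.  ``k_clusters``
    defaults to ``k_superpixels``.  ``preprocess`` may be ``True`` (use
    defaults), a :class:`PreprocessConfig`, or ``False`` for series that
    are already clean.
    """
    if preprocess:
        cfg = preprocess if isinstance(preprocess, PreprocessConfig) else None
        clean = preprocess_stack(stack, cfg)
    else:
        clean = stack
    if k_clusters is None:
        k_clusters = k_superpixels
    from .grid import flatten

    pm = flatten(clean)
    pca = fit_pca(pm, variance_target=variance_target, max_components=max_components)
    scores = transform(pca, clean)
    clusters = kmeans_cluster(scores, k=k_clusters, seed=seed)
    patch_lg, patches = label_patches(clusters.label_grid, connectivity=connectivity)
    patches = patch_means(patches, scores)
    graph = build_patch_graph(patch_lg, patches, connectivity=connectivity)
    mst = minimum_spanning_tree(graph)
    k_eff = min(k_superpixels, patches.n_patches)
    sp = skater_partition(mst, patches, k=k_eff, weighted=weighted)
    sp = assemble_superpixels(sp, clean)
    if full:
        return StisebsResult(
            labels=sp.label_grid,
            superpixels=sp,
            pca=pca,
            clusters=clusters,
            patches=patches,
            graph=graph,
            mst=mst,
            preprocessed=clean,
        )
    return sp.label_grid, sp
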