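"""Segmentation quality assessment and comparison baselines.

A segmentation is judged by how well the original high-resolution (HR)
series are recovered after every pixel is replaced by its segment's
mean series ("disassembly to hypothetical HR pixels"):

* cumulative Euclidean error — sum over pixels of the L2 distance
  between the true and the broadcast series;
* inhomogeneity delta — mean pairwise series distance inside a segment
  (lower is better);
* isolation gamma — mean distance between a segment's mean series and
  those of its 4-adjacent neighbours (higher is better);
* land-cover agreement — each segment takes its modal class, the
  broadcast class map is scored against the true map with overall
  accuracy, Cohen's kappa and per-class precision / sensitivity / F1 /
  Matthews correlation from one-vs-rest confusion counts.

Two baselines put the numbers in context: coarse low-resolution blocks
(the naive aggregation a practitioner falls back to) and e-SLIC, SLIC
run on the first three principal components of the series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import LabelGrid, TimeSeriesGrid
from .reduction import fit_pca, transform
from .segment import SuperpixelSet, _segment_means, adjacent_label_pairs

__all__ = [
    "ClassMetrics",
    "binary_metrics",
    "broadcast_to_hr",
    "euclidean_error",
    "inhomogeneity",
    "isolation",
    "majority_label",
    "classification_metrics",
    "coarse_pixel_baseline",
    "eslic_baseline",
    "error_reduction_pct",
]


# ---------------------------------------------------------------------------
# disassembly and time-series deviation
# ---------------------------------------------------------------------------


def broadcast_to_hr(segments: LabelGrid, series) -> TimeSeriesGrid:
    """Give every HR pixel its segment's mean series.

    ``series`` is a :class:`SuperpixelSet` with ``mean_series`` filled,
    or a bare (K, T) array indexed by segment id.
    """
    if isinstance(series, SuperpixelSet):
        if series.mean_series is None:
            raise ValueError("superpixel set has no mean series; assemble first")
        table = series.mean_series
        times = series.times
    else:
        table = np.asarray(series, dtype=float)
        times = None
    mask = segments.valid_mask
    labels = segments.labels
    if labels[mask].max(initial=-1) >= len(table):
        raise ValueError("segment map references series beyond the table")
    h, w = segments.geometry.shape
    t = table.shape[1]
    values = np.full((h, w, t), np.nan)
    values[mask] = table[labels[mask]]
    if times is None:
        times = TimeSeriesGrid.default_times(t)
    return TimeSeriesGrid(segments.geometry, list(times), values, mask.copy())


def euclidean_error(
    truth: TimeSeriesGrid, estimate: TimeSeriesGrid, norm: str = "l2"
) -> tuple[float, np.ndarray]:
    """Cumulative per-pixel series deviation.

    Per-pixel error is the L2 (default) or L1 distance between the true
    and estimated series; the cumulative error is its sum over valid
    pixels.  Returns ``(cumulative, per_pixel)`` with ``per_pixel`` on
    the grid (NaN at masked pixels).
    """
    if truth.values.shape != estimate.values.shape:
        raise ValueError("grids have different shapes")
    if not np.array_equal(truth.valid_mask, estimate.valid_mask):
        raise ValueError("grids have different masks")
    diff = truth.values - estimate.values
    if norm == "l2":
        per_pixel = np.sqrt((diff ** 2).sum(axis=2))
    elif norm == "l1":
        per_pixel = np.abs(diff).sum(axis=2)
    else:
        raise ValueError("norm must be 'l2' or 'l1'")
    per_pixel = np.where(truth.valid_mask, per_pixel, np.nan)
    return float(np.nansum(per_pixel)), per_pixel


def error_reduction_pct(error_method: float, error_reference: float) -> float:
    """Percent reduction of ``error_method`` relative to a reference."""
    return 100.0 * (error_reference - error_method) / error_reference


# ---------------------------------------------------------------------------
# inhomogeneity / isolation
# ---------------------------------------------------------------------------


def inhomogeneity(
    segments: LabelGrid,
    ndvi: TimeSeriesGrid,
    max_exact: int = 2000,
    n_sample_pairs: int = 10000,
    seed: int = 0,
) -> dict:
    """Mean pairwise series distance inside each segment (delta).

    Exact over all unordered pixel pairs up to ``max_exact`` member
    pixels; above that an unbiased seeded random-pair estimate is used
    and flagged.  Singletons have delta 0.
    """
    from scipy.spatial.distance import pdist

    mask = segments.valid_mask
    labels_flat = segments.labels[mask]
    series = ndvi.values[mask]
    k = int(labels_flat.max()) + 1
    delta = np.zeros(k)
    sizes = np.bincount(labels_flat, minlength=k)
    approx = np.zeros(k, dtype=bool)
    rng = np.random.default_rng(seed)
    order = np.argsort(labels_flat, kind="stable")
    bounds = np.searchsorted(labels_flat[order], np.arange(k + 1))
    for s in range(k):
        members = order[bounds[s] : bounds[s + 1]]
        m = len(members)
        if m < 2:
            continue
        if m <= max_exact:
            delta[s] = float(pdist(series[members]).mean())
        else:
            i = rng.integers(0, m, size=n_sample_pairs)
            j = rng.integers(0, m - 1, size=n_sample_pairs)
            j = np.where(j >= i, j + 1, j)  # uniform over distinct pairs
            d = np.linalg.norm(series[members[i]] - series[members[j]], axis=1)
            delta[s] = float(d.mean())
            approx[s] = True
    weighted = float((delta * sizes).sum() / sizes.sum())
    return {
        "per_segment": delta,
        "sizes": sizes,
        "mean": float(delta.mean()),
        "weighted_mean": weighted,
        "approximate": approx,
    }


def isolation(
    segments: LabelGrid,
    mean_series: np.ndarray | SuperpixelSet,
    connectivity: int = 4,
) -> dict:
    """Mean distance between a segment and its adjacent segments (gamma).

    Segments with no neighbour (single-segment maps) are reported NaN
    and excluded from the mean.
    """
    if isinstance(mean_series, SuperpixelSet):
        if mean_series.mean_series is None:
            raise ValueError("superpixel set has no mean series; assemble first")
        mean_series = mean_series.mean_series
    mean_series = np.asarray(mean_series, dtype=float)
    k = mean_series.shape[0]
    pairs = adjacent_label_pairs(segments.labels, connectivity)
    gamma_sum = np.zeros(k)
    gamma_n = np.zeros(k)
    if len(pairs):
        d = np.linalg.norm(mean_series[pairs[:, 0]] - mean_series[pairs[:, 1]], axis=1)
        np.add.at(gamma_sum, pairs[:, 0], d)
        np.add.at(gamma_sum, pairs[:, 1], d)
        np.add.at(gamma_n, pairs[:, 0], 1)
        np.add.at(gamma_n, pairs[:, 1], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(gamma_n > 0, gamma_sum / gamma_n, np.nan)
    return {
        "per_segment": gamma,
        "mean": float(np.nanmean(gamma)) if np.isfinite(gamma).any() else float("nan"),
    }


# ---------------------------------------------------------------------------
# land-cover agreement
# ---------------------------------------------------------------------------


def majority_label(segments: LabelGrid, landcover: LabelGrid) -> LabelGrid:
    """Broadcast each segment's modal land-cover class to its pixels.

    Ties resolve to the smallest class id.
    """
    if segments.geometry.shape != landcover.geometry.shape:
        raise ValueError("segment and land-cover grids have different shapes")
    mask = segments.valid_mask & landcover.valid_mask
    seg = segments.labels[mask].astype(np.int64)
    cls = landcover.labels[mask].astype(np.int64)
    k = int(seg.max()) + 1
    n_cls = int(cls.max()) + 1
    counts = np.zeros((k, n_cls), dtype=np.int64)
    np.add.at(counts, (seg, cls), 1)
    modal = np.argmax(counts, axis=1)  # argmax takes the first (smallest id) on ties
    out = np.full(segments.labels.shape, -1, dtype=np.int32)
    out[mask] = modal[segments.labels[mask]]
    return LabelGrid(segments.geometry, out, kind="landcover")


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Per-class metrics from one-vs-rest confusion counts.

    Zero-denominator metrics are reported as 0 with ``degenerate=True``.
    MCC is computed in floats with pairwise products to stay exact for
    counts of realistic magnitude.
    """
    tp, fp, fn, tn = (float(v) for v in (tp, fp, fn, tn))
    degenerate = False

    def _safe(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp)
    sensitivity = _safe(tp, tp + fn)
    f1 = _safe(2 * precision * sensitivity, precision + sensitivity)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
        "mcc": float(mcc),
        "degenerate": degenerate,
    }


@dataclass
class ClassMetrics:
    """Confusion-matrix summary of a predicted vs true class map."""

    per_class: pd.DataFrame  # indexed by class id: tp fp fn tn + metrics
    overall_accuracy: float
    kappa: float
    n_pixels: int
    classes: np.ndarray

    def row_sums_ok(self) -> bool:
        s = self.per_class[["tp", "fp", "fn", "tn"]].sum(axis=1)
        return bool((s == self.n_pixels).all())


def classification_metrics(truth: LabelGrid, predicted: LabelGrid) -> ClassMetrics:
    """Score a predicted class map against the truth.

    Overall accuracy is the confusion-matrix trace over the pixel
    count; kappa uses the exact actual/predicted marginals (never a
    rounded accuracy); per-class metrics come from one-vs-rest counts.
    """
    if truth.geometry.shape != predicted.geometry.shape:
        raise ValueError("grids have different shapes")
    mask = truth.valid_mask & predicted.valid_mask
    yt = truth.labels[mask].astype(np.int64)
    yp = predicted.labels[mask].astype(np.int64)
    n = int(mask.sum())
    classes = np.unique(np.concatenate([yt, yp]))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(cm, (np.vectorize(idx.get)(yt), np.vectorize(idx.get)(yp)), 1)
    oa = float(np.trace(cm)) / n
    a = cm.sum(axis=1).astype(float)  # actual marginals a_l
    b = cm.sum(axis=0).astype(float)  # predicted marginals b_l
    chance = float((a * b).sum())
    denom = n * n - chance
    kappa = (n * n * oa - chance) / denom if denom != 0 else 0.0
    rows = []
    for i, c in enumerate(classes):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        tn = n - tp - fp - fn
        m = binary_metrics(tp, fp, fn, tn)
        rows.append({"class": int(c), "tp": tp, "fp": fp, "fn": fn, "tn": tn, **m})
    df = pd.DataFrame(rows).set_index("class")
    return ClassMetrics(
        per_class=df,
        overall_accuracy=oa,
        kappa=float(kappa),
        n_pixels=n,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def coarse_pixel_baseline(stack: TimeSeriesGrid, factor: int = 4) -> tuple[LabelGrid, SuperpixelSet]:
    """Aggregate to non-overlapping factor x factor blocks (LR pixels).

    Partial blocks at the grid edge are kept as smaller segments; fully
    masked blocks are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = stack.geometry.shape
    rows, cols = np.indices((h, w))
    block = (rows // factor) * (-(-w // factor)) + cols // factor
    labels = np.where(stack.valid_mask, block, -1).astype(np.int32)
    lg = LabelGrid(stack.geometry, labels, kind="superpixel").compact()
    sp = _segments_from_labels(lg, stack)
    return sp.label_grid, sp


def _segments_from_labels(lg: LabelGrid, stack: TimeSeriesGrid) -> SuperpixelSet:
    """Wrap an arbitrary contiguous label map as a SuperpixelSet."""
    mask = lg.valid_mask
    labels_flat = lg.labels[mask]
    k = int(labels_flat.max()) + 1
    pixel_counts = np.bincount(labels_flat, minlength=k)
    means = _segment_means(labels_flat, stack.values[mask], k)
    sp = SuperpixelSet(
        k=k,
        label_grid=lg,
        patch_assignment=np.arange(k),
        n_patches=np.ones(k, dtype=np.int64),
        pixel_counts=pixel_counts.astype(np.int64),
        centroids=means,
        ssd=np.zeros(k),
        mean_series=means,
        times=list(stack.times),
    )
    return sp


def _slic_labels(
    img: np.ndarray, valid: np.ndarray, k: int, compactness: float, max_iter: int
) -> np.ndarray:
    """Grid-seeded SLIC on an (H, W, C) feature image.

    Centers start on a near-square grid of ~k cells; each iteration
    assigns every pixel within a 2S x 2S neighbourhood of a center to
    the center minimizing

        D = sqrt(d_feat^2 + (d_xy / S)^2 * m^2),

    with S = sqrt(I / k) the expected superpixel spacing and m the
    compactness, then recomputes center features and positions.
    """
    h, w, _ = img.shape
    n_valid = int(valid.sum())
    s = float(np.sqrt(n_valid / k))
    ncols = max(1, int(np.ceil(np.sqrt(k * w / h))))
    nrows = max(1, int(np.ceil(k / ncols)))
    rr = (np.arange(nrows) + 0.5) * h / nrows
    cc = (np.arange(ncols) + 0.5) * w / ncols
    pos = np.array([(r, c) for r in rr for c in cc])  # (K0, 2)
    # snap centers to the nearest valid pixel
    vr, vc = np.nonzero(valid)
    vpos = np.column_stack([vr, vc]).astype(float)
    snap = np.argmin(
        ((vpos[None, :, :] - pos[:, None, :]) ** 2).sum(axis=2), axis=1
    )
    pos = vpos[snap]
    feat = img[pos[:, 0].astype(int), pos[:, 1].astype(int), :]
    rows, cols = np.indices((h, w))
    m2 = compactness**2
    labels = np.full((h, w), -1, dtype=np.int64)
    for _ in range(max_iter):
        best = np.full((h, w), np.inf)
        labels.fill(-1)
        for ci in range(len(pos)):
            r0, c0 = pos[ci]
            rlo, rhi = max(0, int(r0 - 2 * s)), min(h, int(r0 + 2 * s) + 1)
            clo, chi = max(0, int(c0 - 2 * s)), min(w, int(c0 + 2 * s) + 1)
            sub = np.s_[rlo:rhi, clo:chi]
            d_feat2 = ((img[sub] - feat[ci]) ** 2).sum(axis=2)
            d_xy2 = (rows[sub] - r0) ** 2 + (cols[sub] - c0) ** 2
            d = d_feat2 + d_xy2 / s**2 * m2
            better = (d < best[sub]) & valid[sub]
            best[sub][better] = d[better]
            np.place(labels[sub], better, ci)
            # np.place on a view works since sub is a basic slice
        # stranded valid pixels (outside every search window): nearest center
        stray = valid & (labels < 0)
        if stray.any():
            sr, sc = np.nonzero(stray)
            d2 = ((np.column_stack([sr, sc])[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            labels[sr, sc] = np.argmin(d2, axis=1)
        # update centers
        for ci in range(len(pos)):
            sel = labels == ci
            if not sel.any():
                continue
            feat[ci] = img[sel].mean(axis=0)
            pos[ci] = [rows[sel].mean(), cols[sel].mean()]
    return labels


def _merge_orphans(labels: np.ndarray, img: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Keep each label's largest component; merge the rest into the most
    feature-similar 4-adjacent segment."""
    from scipy import ndimage

    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    out = labels.copy()
    changed = True
    while changed:
        changed = False
        comp_id = np.full(out.shape, -1, dtype=np.int64)
        keep = {}
        nxt = 0
        for lab in np.unique(out[out >= 0]):
            comp, n = ndimage.label(out == lab, structure=struct)
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            main = int(np.argmax(sizes)) + 1
            for c in range(1, n + 1):
                comp_id[comp == c] = nxt
                keep[nxt] = c == main
                nxt += 1
        orphans = [cid for cid, ok in keep.items() if not ok]
        for cid in orphans:
            sel = comp_id == cid
            mean_f = img[sel].mean(axis=0)
            # 4-neighbour labels of this component
            grown = ndimage.binary_dilation(sel, structure=struct) & ~sel & valid
            nb_labels = np.unique(out[grown & (out >= 0)])
            nb_labels = nb_labels[nb_labels != out[sel][0]]
            if len(nb_labels) == 0:
                continue
            best_lab, best_d = -1, np.inf
            for nb in nb_labels:
                nb_mean = img[out == nb].mean(axis=0)
                d = float(np.linalg.norm(mean_f - nb_mean))
                if d < best_d or (d == best_d and nb < best_lab):
                    best_lab, best_d = int(nb), d
            out[sel] = best_lab
            changed = True
    return out


def eslic_baseline(
    stack: TimeSeriesGrid,
    k: int,
    compactness: float = 0.3,
    seed: int = 0,
    max_iter: int = 10,
) -> tuple[LabelGrid, SuperpixelSet]:
    """SLIC on the first three principal components of the series.

    The series are reduced to their top-3 component scores, each score
    min-max rescaled to [0, 1], and segmented with grid-seeded SLIC
    (combined feature + spacing-scaled spatial distance, 10 iterations)
    followed by connectivity enforcement: any region disconnected from
    its label's main body is merged into the most feature-similar
    4-adjacent segment.  The ``seed`` parameter is accepted for
    interface parity; the procedure itself is deterministic.
    """
    from .grid import flatten

    pm = flatten(stack)
    if k < 1 or k > pm.n_pixels:
        raise ValueError(f"k={k} out of range for {pm.n_pixels} pixels")
    pca = fit_pca(pm, variance_target=1.0, max_components=3)
    scores = transform(pca, stack)
    img = scores.scores.copy()
    for c in range(img.shape[2]):
        ch = img[:, :, c]
        finite = np.isfinite(ch)
        lo, hi = ch[finite].min(), ch[finite].max()
        img[:, :, c] = (ch - lo) / (hi - lo) if hi > lo else 0.0
    img = np.nan_to_num(img, nan=0.0)
    valid = stack.valid_mask
    labels = _slic_labels(img, valid, k, compactness, max_iter)
    labels = _merge_orphans(labels, img, valid)
    labels = np.where(valid, labels, -1).astype(np.int32)
    lg = LabelGrid(stack.geometry, labels, kind="superpixel").compact()
    sp = _segments_from_labels(lg, stack)
    return sp.label_grid, sp
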