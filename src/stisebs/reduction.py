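"""PCA reduction of per-pixel time series.

Each valid pixel is a point in T-dimensional period space.  The series
are centered (per-period mean subtracted) but not standardized — all
periods share the same index units — and projected on the leading
eigenvectors of the sample covariance, keeping the smallest number of
components whose cumulative explained-variance ratio reaches the target
(default 99 %), capped at ``max_components`` (default 200).

The decomposition runs through a thin SVD of the centered matrix, which
handles both the many-pixels (I >> T) and the long-series (T >> I)
regimes; the nonzero spectrum is the same either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridGeometry, PixelMatrix, TimeSeriesGrid, flatten

__all__ = ["PCAModel", "ComponentGrid", "fit_pca", "transform", "transform_matrix"]


@dataclass
class PCAModel:
    """Fitted principal-component basis for T-period series.

    loadings : (T, C) orthonormal columns, eigenvectors of the covariance.
    eigenvalues : (C,) descending sample variances along the loadings.
    mean : (T,) per-period mean removed before projection.
    explained_variance_ratio : (C,) eigenvalue shares of total variance.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    variance_target: float
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_periods(self) -> int:
        return self.loadings.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            loadings=self.loadings,
            eigenvalues=self.eigenvalues,
            mean=self.mean,
            explained_variance_ratio=self.explained_variance_ratio,
            variance_target=self.variance_target,
            n_samples=self.n_samples,
        )

    @classmethod
    def load(cls, path) -> "PCAModel":
        with np.load(path) as z:
            return cls(
                loadings=z["loadings"],
                eigenvalues=z["eigenvalues"],
                mean=z["mean"],
                explained_variance_ratio=z["explained_variance_ratio"],
                variance_target=float(z["variance_target"]),
                n_samples=int(z["n_samples"]),
            )


@dataclass
class ComponentGrid:
    """Per-pixel component scores over the source grid."""

    geometry: GridGeometry
    valid_mask: np.ndarray  # (H, W) bool
    scores: np.ndarray  # (H, W, C), NaN at masked pixels

    @property
    def n_components(self) -> int:
        return self.scores.shape[2]

    def matrix(self) -> PixelMatrix:
        """Valid-pixel score matrix in row-major ordinal order."""
        rows, cols = np.nonzero(self.valid_mask)
        return PixelMatrix(
            self.scores[rows, cols, :],
            np.column_stack([rows, cols]).astype(np.int64),
            self.geometry,
            self.valid_mask.copy(),
        )


def fit_pca(
    x: PixelMatrix | np.ndarray,
    variance_target: float = 0.99,
    max_components: int | None = 200,
) -> PCAModel:
    """Fit the principal-component basis of a pixel matrix.

    Retains the smallest C with cumulative explained-variance ratio >=
    ``variance_target`` (up to a 1e-9 numerical slack, so a spectrum
    hitting the target exactly is not over-counted), capped at
    ``max_components``.  A zero-variance (constant) matrix degenerates
    to a single component with ratio 1.
    """
    data = x.data if isinstance(x, PixelMatrix) else np.asarray(x, dtype=float)
    if data.ndim != 2:
        raise ValueError("input must be a 2-D (pixels x periods) matrix")
    n, t = data.shape
    if n < 2:
        raise ValueError("need at least 2 pixels to fit a covariance")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    mean = data.mean(axis=0)
    xc = data - mean
    # Thin SVD: sample covariance eigenvalues are s^2 / (n - 1).
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = (s ** 2) / (n - 1)
    total = eigvals.sum()
    if total <= 0.0:
        # constant input: one zero-variance component, ratio defined as 1
        loadings = _fix_signs(vt[:1].T)
        return PCAModel(
            loadings=loadings,
            eigenvalues=np.zeros(1),
            mean=mean,
            explained_variance_ratio=np.ones(1),
            variance_target=variance_target,
            n_samples=n,
        )
    ratio = eigvals / total
    cum = np.cumsum(ratio)
    c = int(np.searchsorted(cum, variance_target - 1e-9) + 1)
    c = min(c, len(eigvals))
    if max_components is not None:
        c = min(c, int(max_components))
    loadings = _fix_signs(vt[:c].T)
    return PCAModel(
        loadings=loadings,
        eigenvalues=eigvals[:c].copy(),
        mean=mean,
        explained_variance_ratio=ratio[:c].copy(),
        variance_target=variance_target,
        n_samples=n,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each loading's largest-magnitude element positive (sign is
    otherwise arbitrary and would break determinism)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def transform_matrix(model: PCAModel, data: np.ndarray) -> np.ndarray:
    """Project (n, T) series rows onto the retained components."""
    data = np.asarray(data, dtype=float)
    if data.shape[-1] != model.n_periods:
        raise ValueError(
            f"series length {data.shape[-1]} does not match the fitted {model.n_periods}"
        )
    return (data - model.mean) @ model.loadings


def transform(model: PCAModel, grid: TimeSeriesGrid) -> ComponentGrid:
    """Project every valid pixel's series; masked pixels stay NaN."""
    pm = flatten(grid)
    scores_flat = transform_matrix(model, pm.data)
    h, w = grid.geometry.shape
    scores = np.full((h, w, model.n_components), np.nan)
    scores[pm.pixel_index[:, 0], pm.pixel_index[:, 1], :] = scores_flat
    return ComponentGrid(grid.geometry, grid.valid_mask.copy(), scores)
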