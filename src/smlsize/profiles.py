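"""From localization tables to per-cluster line profiles.

Pipeline: density-based cluster detection, principal-axis determination by
covariance eigendecomposition, projection of member localizations onto the
axis, and uniform binning into a :class:`LineProfile` — the data vector all
fitting operates on.  Coordinates are continuous nanometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import DBSCAN

from .errors import DegenerateInputError, InvalidParameterError, SingleBinError

__all__ = [
    "LineProfile",
    "Cluster",
    "PrincipalAxis",
    "RasterImage",
    "find_clusters",
    "principal_axis",
    "extract_profile",
    "render_storm_image",
]

DEFAULT_BIN_WIDTH = 10.0  # nm; roughly half a typical localization precision
DEFAULT_MIN_CLUSTER_SIZE = 20


@dataclass
class LineProfile:
    """Binned localization counts along an axis.

    ``bin_centers`` are signed distances (nm) from ``origin`` along
    ``direction``; spacing must be uniform and equal to ``bin_width``.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    origin: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (1.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.shape != self.counts.shape:
            raise InvalidParameterError("bin_centers and counts must match in shape")
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be nonnegative")
        if self.bin_centers.size >= 2:
            spacing = np.diff(self.bin_centers)
            if np.any(spacing <= 0) or np.max(
                np.abs(spacing - self.bin_width)
            ) > 1e-9 * max(1.0, self.bin_width):
                raise InvalidParameterError(
                    "bin centers must increase uniformly by bin_width"
                )

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def span(self) -> float:
        return float(self.bin_centers[-1] - self.bin_centers[0] + self.bin_width)


class PrincipalAxis(NamedTuple):
    centroid: np.ndarray
    direction: np.ndarray
    tie: bool


@dataclass
class Cluster:
    """A detected localization cluster and its principal axis."""

    indices: np.ndarray
    centroid: tuple[float, float]
    principal_axis: tuple[float, float]
    axis_extent: float
    n_localizations: int
    axis_tie: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.principal_axis, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise InvalidParameterError("principal_axis must be a unit vector")


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # Nonnegative first component; if zero, nonnegative second.
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        return -v
    return v


def principal_axis(points) -> PrincipalAxis:
    """Centroid and leading covariance eigenvector of a 2D point set.

    Eigenvalue ties (isotropic clusters, relative gap < 1e-9) return
    direction ``(1, 0)`` with the ``tie`` flag set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateInputError("principal_axis requires >= 3 points of shape (n, 2)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    scale = max(evals[-1], np.finfo(float).tiny)
    if (evals[-1] - evals[0]) / scale < 1e-9:
        return PrincipalAxis(centroid, np.array([1.0, 0.0]), True)
    direction = _fix_sign(evecs[:, -1].copy())
    return PrincipalAxis(centroid, direction, False)


def find_clusters(
    table,
    eps: float = 100.0,
    min_pts: int = 10,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[Cluster]:
    """Density-based (DBSCAN) clustering of a localization table's (x, y).

    Noise points are excluded; clusters smaller than ``min_cluster_size``
    are dropped.  Deterministic given input order.  An empty table yields
    an empty list.
    """
    if eps <= 0:
        raise InvalidParameterError("eps must be > 0")
    x = np.asarray(table.x, dtype=float)
    y = np.asarray(table.y, dtype=float)
    if x.size == 0:
        return []
    xy = np.column_stack([x, y])
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)
    clusters: list[Cluster] = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_cluster_size:
            continue
        pts = xy[idx]
        if idx.size >= 3:
            axis = principal_axis(pts)
        else:  # pragma: no cover - min_cluster_size >= 3 in practice
            axis = PrincipalAxis(pts.mean(axis=0), np.array([1.0, 0.0]), True)
        proj = (pts - axis.centroid) @ axis.direction
        clusters.append(
            Cluster(
                indices=idx,
                centroid=(float(axis.centroid[0]), float(axis.centroid[1])),
                principal_axis=(float(axis.direction[0]), float(axis.direction[1])),
                axis_extent=float(proj.max() - proj.min()) if idx.size else 0.0,
                n_localizations=int(idx.size),
                axis_tie=axis.tie,
            )
        )
    return clusters


def extract_profile(
    cluster: Cluster,
    table,
    bin_width: float = DEFAULT_BIN_WIDTH,
    pad: float | None = None,
    axis: Sequence[float] | None = None,
) -> LineProfile:
    """Project cluster members onto an axis and bin into a line profile.

    Signed distances are measured from the cluster centroid along
    ``cluster.principal_axis`` (or ``axis`` if given, e.g. the perpendicular
    for a cylinder cross-section).  Bins are half-open ``[left, right)``
    over ``[-span/2 - pad, span/2 + pad]``; a point exactly on an edge falls
    in the right-hand bin.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    if pad is None:
        pad = 4.0 * bin_width
    direction = np.asarray(
        cluster.principal_axis if axis is None else axis, dtype=float
    )
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise InvalidParameterError("axis must be nonzero")
    direction = direction / norm
    x = np.asarray(table.x, dtype=float)[cluster.indices]
    y = np.asarray(table.y, dtype=float)[cluster.indices]
    cx, cy = cluster.centroid
    t = (x - cx) * direction[0] + (y - cy) * direction[1]
    span = float(t.max() - t.min()) if t.size else 0.0
    half = span / 2.0 + pad
    mid = float(t.max() + t.min()) / 2.0 if t.size else 0.0
    left = mid - half
    n_bins = int(np.ceil(2.0 * half / bin_width))
    if n_bins < 2:
        raise SingleBinError(
            f"bin_width {bin_width} does not resolve projected span {span}"
        )
    idx = np.floor((t - left) / bin_width).astype(int)
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins).astype(float)
    centers = left + (np.arange(n_bins) + 0.5) * bin_width
    return LineProfile(
        bin_centers=centers,
        counts=counts,
        bin_width=bin_width,
        origin=cluster.centroid,
        direction=(float(direction[0]), float(direction[1])),
    )


@dataclass
class RasterImage:
    """A rendered 2D localization histogram.

    Pixel ``(i, j)`` (row i = y, col j = x) has its center at
    ``origin + (j + 0.5, i + 0.5) * pixel_size``.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float]


def render_storm_image(
    table, pixel_size: float, blur_sigma: float = 0.0
) -> RasterImage:
    """2D histogram of localizations, optionally Gaussian-blurred for display.

    ``blur_sigma`` is in nm; the grid is padded by 4 blur sigmas so that the
    blur conserves total intensity.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    if blur_sigma < 0:
        raise InvalidParameterError("blur_sigma must be >= 0")
    x = np.asarray(table.x, dtype=float)
    y = np.asarray(table.y, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("cannot render an empty table")
    pad_px = int(np.ceil(4.0 * blur_sigma / pixel_size)) + 1 if blur_sigma > 0 else 0
    x0 = np.floor(x.min() / pixel_size) * pixel_size - pad_px * pixel_size
    y0 = np.floor(y.min() / pixel_size) * pixel_size - pad_px * pixel_size
    nx = int(np.floor((x.max() - x0) / pixel_size)) + 1 + pad_px
    ny = int(np.floor((y.max() - y0) / pixel_size)) + 1 + pad_px
    jj = np.floor((x - x0) / pixel_size).astype(int)
    ii = np.floor((y - y0) / pixel_size).astype(int)
    img = np.zeros((ny, nx), dtype=float)
    np.add.at(img, (ii, jj), 1.0)
    if blur_sigma > 0:
        img = gaussian_filter(img, sigma=blur_sigma / pixel_size, mode="constant")
    return RasterImage(pixels=img, pixel_size=float(pixel_size), origin=(float(x0), float(y0)))
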