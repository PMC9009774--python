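"""Cluster-based background subtraction for fluorescence frames.

Each frame is tiled into squares; every tile is summarized by six features
(median, population standard deviation, skewness, excess kurtosis of its
intensity histogram, and the two tile-local coordinates of the
intensity-weighted centroid).  After robust per-frame standardization, DBSCAN
with a Euclidean metric groups the tiles; the densest dim population — the
cluster with the lowest mean raw tile median — is taken as background.  The
background tiles' medians are then interpolated by a degree-2 surface over
the whole frame (shading estimate) and subtracted.

The moment features separate structured tiles from flat ones: a tile crossed
by a cell edge has inflated spread and skew, and its intensity-weighted
centroid sits off the geometric center, while pure-background tiles form a
tight cluster regardless of the smooth shading gradient (centroids are
tile-local precisely so that shading does not separate them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQBivariateSpline
from sklearn.cluster import DBSCAN

from .core_io import ImageStack, RunConfig

NOISE = -1

#: metric flag names set by per-frame background processing
FLAG_CLUSTER_FAIL = "cluster_fail"
FLAG_FEW_BG_TILES = "few_bg_tiles"


class BackgroundFailure(RuntimeError):
    """Per-frame failure of the background algorithm (reprocess with new eps)."""


@dataclass
class TileGrid:
    """Square tiling of a frame: ``n_rows x n_cols`` tiles of ``tile_size`` px.

    Tiles are indexed (row, col), 0-based, and cover the top-left
    ``n_rows*tile_size x n_cols*tile_size`` region; right/bottom remainder
    strips (when the frame is not an exact multiple) stay untiled but are
    still covered by surface evaluation.
    """

    frame: np.ndarray
    tile_size: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile(self, row: int, col: int) -> np.ndarray:
        ts = self.tile_size
        return self.frame[row * ts : (row + 1) * ts, col * ts : (col + 1) * ts]

    def tile_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Frame coordinates (x=cols, y=rows) of every tile center, row-major."""
        ts = self.tile_size
        cy = np.arange(self.n_rows) * ts + (ts - 1) / 2
        cx = np.arange(self.n_cols) * ts + (ts - 1) / 2
        yy, xx = np.meshgrid(cy, cx, indexing="ij")
        return xx.ravel(), yy.ravel()


def tile_image(frame: np.ndarray, window: int) -> TileGrid:
    """Tile ``frame`` into squares, ``window`` tiles along the width.

    ``tile_size = floor(width / window)``; the tile count along the height
    follows as ``floor(height / tile_size)``.  E.g. a 640x480 frame with
    window 40 gives 16x16-pixel tiles in a 30-row x 40-column grid.
    """
    height, width = frame.shape
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    tile_size = width // window
    if tile_size < 2:
        raise ValueError(
            f"window {window} too large for width {width}: tile size would be {tile_size} < 2"
        )
    n_rows = height // tile_size
    if n_rows < 1:
        raise ValueError(f"frame height {height} smaller than tile size {tile_size}")
    return TileGrid(frame=frame, tile_size=tile_size, n_rows=n_rows, n_cols=window)


def compute_tile_features(tile: np.ndarray) -> np.ndarray:
    """Six-feature summary of one tile.

    Returns ``[median, stdev, skewness, kurtosis, centroid_x, centroid_y]``
    where stdev is the population standard deviation, skewness/kurtosis the
    third/fourth standardized moments (kurtosis as excess), and the centroid
    is intensity-weighted in tile-local pixel coordinates.  Zero-variance
    tiles get skewness = kurtosis = 0; all-zero tiles get the geometric
    center as centroid.  These conventions keep degenerate tiles finite so
    they cluster with their flat neighbours instead of propagating NaN.
    """
    t = np.asarray(tile, dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty tile")
    med = float(np.median(t))
    mu = t.mean()
    var = ((t - mu) ** 2).mean()
    std = np.sqrt(var)
    if var > 0:
        skew = float((((t - mu) / std) ** 3).mean())
        kurt = float((((t - mu) / std) ** 4).mean() - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    total = t.sum()
    h, w = t.shape
    if total > 0:
        ys, xs = np.mgrid[0:h, 0:w]
        cx = float((xs * t).sum() / total)
        cy = float((ys * t).sum() / total)
    else:
        cx = (w - 1) / 2
        cy = (h - 1) / 2
    return np.array([med, std, skew, kurt, cx, cy])


def frame_features(grid: TileGrid) -> np.ndarray:
    """Feature matrix ``(n_tiles, 6)`` for every tile of the grid, row-major."""
    feats = np.empty((grid.n_tiles, 6))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            feats[r * grid.n_cols + c] = compute_tile_features(grid.tile(r, c))
    return feats


def normalize_features(features: np.ndarray) -> np.ndarray:
    """Robust per-dimension standardization: zero median, unit IQR.

    Makes one Euclidean eps meaningful across the six mixed-unit feature
    dimensions and across frames/channels.  Dimensions with zero spread map
    to all-zeros.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.shape[0] < 2:
        raise ValueError("need at least 2 tiles to normalize")
    med = np.median(F, axis=0)
    q75, q25 = np.percentile(F, [75, 25], axis=0)
    iqr = q75 - q25
    out = np.zeros_like(F)
    nz = iqr > 0
    out[:, nz] = (F[:, nz] - med[nz]) / iqr[nz]
    return out


@dataclass
class ClusterLabels:
    """DBSCAN tile labels plus the cluster designated as background."""

    labels: np.ndarray  # per-tile cluster id, NOISE = -1
    background_cluster: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == self.background_cluster

    @property
    def n_background_tiles(self) -> int:
        return int(self.background_mask.sum())


def cluster_tiles(
    normalized_features: np.ndarray,
    eps: float,
    min_samples: int = 5,
    raw_medians: np.ndarray | None = None,
) -> ClusterLabels:
    """Group tiles by DBSCAN (Euclidean) and designate the background cluster.

    ``eps`` is the maximum feature-space distance between two tiles placed in
    the same cluster.  Among the resulting clusters the one whose members
    have the lowest mean raw median intensity is designated background —
    background is the dimmest dense population in a fluorescence frame; NOISE
    tiles are always foreground.

    Raises
    ------
    BackgroundFailure
        If every tile is NOISE (no cluster found); the frame should be
        reprocessed with a different eps.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(normalized_features)
    ids = sorted(set(labels[labels != NOISE]))
    if not ids:
        raise BackgroundFailure("DBSCAN found no cluster (all tiles noise)")
    if raw_medians is None:
        raw_medians = normalized_features[:, 0]
    means = {cid: float(np.mean(raw_medians[labels == cid])) for cid in ids}
    background = min(means, key=lambda cid: (means[cid], cid))
    return ClusterLabels(labels=labels, background_cluster=background)


def estimate_background_surface(
    grid: TileGrid,
    background_mask: np.ndarray,
    tile_medians: np.ndarray,
    min_background_tiles: int = 6,
) -> np.ndarray:
    """Interpolate the shading surface from background-tile medians.

    Fits a degree-2 tensor-product least-squares spline (by default a single
    biquadratic patch, which contains every quadratic polynomial surface) to
    the scattered background tile centers and evaluates it at every pixel of
    the full frame, including untiled remainder strips, where the end
    polynomial pieces extend naturally.  With fewer than 9 background tiles
    (under-determined for the tensor patch) a 6-coefficient quadratic
    polynomial is fitted instead; below ``min_background_tiles`` the frame
    fails.

    Returns the full-resolution surface as a float array, finite everywhere.
    """
    bg = np.asarray(background_mask, dtype=bool).ravel()
    z = np.asarray(tile_medians, dtype=np.float64).ravel()
    n_bg = int(bg.sum())
    if n_bg < min_background_tiles:
        raise BackgroundFailure(
            f"only {n_bg} background tiles (< {min_background_tiles}); cannot fit surface"
        )
    xs, ys = grid.tile_centers()
    xs, ys, zs = xs[bg], ys[bg], z[bg]
    height, width = grid.frame.shape
    X = np.arange(width, dtype=np.float64)
    Y = np.arange(height, dtype=np.float64)

    surface = None
    if n_bg >= 9:
        try:
            spl = LSQBivariateSpline(
                xs, ys, zs, np.array([]), np.array([]),
                kx=2, ky=2, bbox=[0, width - 1, 0, height - 1],
            )
            surface = spl(X, Y, grid=True).T
        except Exception:
            surface = None  # degenerate geometry; fall through to polynomial
    if surface is None or not np.isfinite(surface).all():
        surface = _quadratic_poly_surface(xs, ys, zs, X, Y)
    if not np.isfinite(surface).all():
        raise BackgroundFailure("background surface fit produced non-finite values")
    return surface


def _quadratic_poly_surface(xs, ys, zs, X, Y) -> np.ndarray:
    """Global least-squares quadratic b(x,y) = a0+a1x+a2y+a3x^2+a4xy+a5y^2."""
    A = np.column_stack([np.ones_like(xs), xs, ys, xs**2, xs * ys, ys**2])
    coef, *_ = np.linalg.lstsq(A, zs, rcond=None)
    XX, YY = np.meshgrid(X, Y)
    return (
        coef[0] + coef[1] * XX + coef[2] * YY
        + coef[3] * XX**2 + coef[4] * XX * YY + coef[5] * YY**2
    )


def subtract_background(frame: np.ndarray, surface: np.ndarray, bit_depth: int) -> np.ndarray:
    """``round(frame - surface)`` clipped to the valid intensity range."""
    if frame.shape != surface.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs surface {surface.shape}")
    corrected = np.rint(frame.astype(np.float64) - surface)
    corrected = np.clip(corrected, 0, 2**bit_depth - 1)
    return corrected.astype(frame.dtype)


@dataclass
class FrameBackgroundResult:
    """Outcome of background subtraction for one frame."""

    frame_id: int
    corrected: np.ndarray
    eps: float
    n_clusters: int
    n_background_tiles: int
    flags: frozenset[str]
    surface: np.ndarray | None = None

    @property
    def failed(self) -> bool:
        return bool(self.flags & {FLAG_CLUSTER_FAIL, FLAG_FEW_BG_TILES})


def process_frame_background(
    frame: np.ndarray,
    frame_id: int,
    bit_depth: int,
    window: int,
    eps: float,
    min_samples: int = 5,
    keep_surface: bool = False,
) -> FrameBackgroundResult:
    """Full background pipeline for a single frame.

    A frame that fails (no cluster, or too few background tiles for the
    surface fit) is passed through uncorrected and flagged; the stack-level
    driver records it for reprocessing with a different eps.
    """
    grid = tile_image(frame, window)
    feats = frame_features(grid)
    medians = feats[:, 0]
    try:
        labels = cluster_tiles(normalize_features(feats), eps, min_samples, raw_medians=medians)
    except BackgroundFailure:
        return FrameBackgroundResult(
            frame_id, frame.copy(), eps, 0, 0, frozenset({FLAG_CLUSTER_FAIL})
        )
    try:
        surface = estimate_background_surface(grid, labels.background_mask, medians)
    except BackgroundFailure:
        return FrameBackgroundResult(
            frame_id, frame.copy(), eps, labels.n_clusters,
            labels.n_background_tiles, frozenset({FLAG_FEW_BG_TILES}),
        )
    corrected = subtract_background(frame, surface, bit_depth)
    return FrameBackgroundResult(
        frame_id, corrected, eps, labels.n_clusters, labels.n_background_tiles,
        frozenset(), surface=surface if keep_surface else None,
    )


def process_stack_background(
    stack: ImageStack,
    config: RunConfig,
    n_jobs: int = 1,
    logger=None,
) -> tuple[ImageStack, list[FrameBackgroundResult]]:
    """Background-subtract every frame of a stack.

    Frames are independent, so the result is identical for any worker count;
    per-frame eps is resolved from the config's frame ranges.  Failed frames
    are passed through unchanged, flagged in the results and logged.
    """
    tasks = [
        (stack.frames[i], int(stack.frame_ids[i]), config.eps_for_frame(int(stack.frame_ids[i])))
        for i in range(stack.n_frames)
    ]

    def work(frame, fid, eps):
        return process_frame_background(
            frame, fid, stack.bit_depth, config.window, eps, config.min_samples
        )

    if n_jobs == 1:
        results = [work(*t) for t in tasks]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(work)(*t) for t in tasks)

    corrected = np.stack([r.corrected for r in results])
    if logger is not None:
        for r in results:
            logger.info(
                "background frame=%d eps=%g clusters=%d bg_tiles=%d flags=%s",
                r.frame_id, r.eps, r.n_clusters, r.n_background_tiles,
                ",".join(sorted(r.flags)) or "-",
            )
    return stack.with_frames(corrected), list(results)
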