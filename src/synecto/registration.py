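"""Stage-drift estimation/correction and fiducial-based channel registration.

Drift is estimated by rendering the localization table in subsets of
frames (default 500), cross-correlating each subset image against the
first (reference) subset with sub-pixel precision, and interpolating the
per-subset displacements piecewise-linearly between subset centres
(constant extrapolation at the ends).

Channel registration maps the moving channel (488 nm) onto the reference
channel (640 nm) with a least-squares polynomial transform fitted to
matched fiducial bead positions.  Order 1 is affine (magnification,
rotation, shift); order 2 adds quadratic distortion terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .tables import LocalizationTable

DEFAULT_SUBSET_FRAMES = 500


@dataclass
class DriftTrajectory:
    """Displacement vs frame, anchored at zero on the reference segment."""

    knot_frames: np.ndarray        # subset-centre frames, strictly increasing
    displacement_nm: np.ndarray    # (n_knots, 2): dx, dy
    frame_range: tuple[int, int]   # frames the estimate covers (inclusive)
    flagged_knots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.knot_frames) <= 0):
            raise ValueError("knot frames must be strictly increasing")
        if np.any(np.abs(self.displacement_nm[0]) > 1e-9):
            raise ValueError("displacement at the reference segment must be zero")

    def at(self, frames) -> np.ndarray:
        frames = np.asarray(frames, float)
        dx = np.interp(frames, self.knot_frames, self.displacement_nm[:, 0])
        dy = np.interp(frames, self.knot_frames, self.displacement_nm[:, 1])
        return np.column_stack([dx, dy])


def _render_histogram(xy: np.ndarray, extent, bin_nm: float,
                      smooth_bins: float = 1.5) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    xmin, xmax, ymin, ymax = extent
    nx = max(int(np.ceil((xmax - xmin) / bin_nm)), 1)
    ny = max(int(np.ceil((ymax - ymin) / bin_nm)), 1)
    img, _, _ = np.histogram2d(xy[:, 1], xy[:, 0],
                               bins=(ny, nx),
                               range=((ymin, ymin + ny * bin_nm),
                                      (xmin, xmin + nx * bin_nm)))
    return gaussian_filter(img, smooth_bins) if smooth_bins > 0 else img


def estimate_drift(table: LocalizationTable,
                   subset_frames: int = DEFAULT_SUBSET_FRAMES,
                   render_bin_nm: float | None = None,
                   min_locs_per_subset: int = 10,
                   upsample_factor: int = 100) -> DriftTrajectory:
    """Estimate the drift trajectory from sub-stack image correlation.

    The rendering bin defaults to camera pixel / 5.  Subsets with fewer
    than ``min_locs_per_subset`` localizations are flagged and
    interpolated over.  Raises ``ValueError`` when the table spans fewer
    than two subsets.
    """
    df = table.df
    if df.empty:
        raise ValueError("empty localization table")
    frames = df["frame"].to_numpy(int)
    f_min, f_max = int(frames.min()), int(frames.max())
    n_subsets = (f_max - f_min) // subset_frames + 1
    if n_subsets < 2:
        raise ValueError("table spans fewer than two drift subsets")
    bin_nm = render_bin_nm or table.pixel_size_nm / 5.0
    xy = table.xy
    extent = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())

    centers, disps, flagged = [], [], []
    ref_img = None
    for s in range(n_subsets):
        lo = f_min + s * subset_frames
        hi = min(lo + subset_frames, f_max + 1)
        sel = (frames >= lo) & (frames < hi)
        center = (lo + hi - 1) / 2.0
        if sel.sum() < min_locs_per_subset:
            flagged.append(s)
            centers.append(center)
            disps.append((np.nan, np.nan))
            continue
        img = _render_histogram(xy[sel], extent, bin_nm)
        if ref_img is None:
            ref_img = img
            centers.append(center)
            disps.append((0.0, 0.0))
            continue
        shift, _, _ = phase_cross_correlation(ref_img, img,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        # shift registers the subset back onto the reference -> drift = -shift
        disps.append((-shift[1] * bin_nm, -shift[0] * bin_nm))
        centers.append(center)
    centers = np.asarray(centers, float)
    disps = np.asarray(disps, float)
    for ax in range(2):
        bad = np.isnan(disps[:, ax])
        if bad.any():
            disps[bad, ax] = np.interp(centers[bad], centers[~bad],
                                       disps[~bad, ax])
    return DriftTrajectory(centers, disps, (f_min, f_max), flagged)


def apply_drift_correction(table: LocalizationTable,
                           trajectory: DriftTrajectory) -> LocalizationTable:
    """Subtract the drift displacement from every localization."""
    frames = table.df["frame"].to_numpy(int)
    lo, hi = trajectory.frame_range
    if frames.size and (frames.min() < lo or frames.max() > hi):
        raise ValueError("table contains frames outside the drift trajectory")
    disp = trajectory.at(frames)
    df = table.df.copy()
    df["x_nm"] -= disp[:, 0]
    df["y_nm"] -= disp[:, 1]
    return table.with_df(df)


@dataclass
class FiducialPairSet:
    """Matched bead coordinates: moving channel vs reference channel."""

    moving_nm: np.ndarray    # (n, 2)
    reference_nm: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.moving_nm = np.asarray(self.moving_nm, float)
        self.reference_nm = np.asarray(self.reference_nm, float)
        if self.moving_nm.shape != self.reference_nm.shape:
            raise ValueError("pair arrays must have matching shapes")
        if len(np.unique(self.reference_nm, axis=0)) != len(self.reference_nm):
            raise ValueError("duplicate reference fiducial positions")

    def __len__(self) -> int:
        return len(self.moving_nm)


def _poly_features(xy: np.ndarray, order: int, scale: float) -> np.ndarray:
    x, y = xy[:, 0] / scale, xy[:, 1] / scale
    cols = [np.ones_like(x), x, y]
    if order >= 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


@dataclass
class PolynomialTransform:
    """(x, y) -> (x', y') polynomial map, nm in and out."""

    order: int
    coeffs: np.ndarray      # (n_features, 2)
    scale: float            # coordinate normalization used in the fit
    residual_rms_nm: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))
        return _poly_features(xy, self.order, self.scale) @ self.coeffs

    def inverse(self, bbox_nm: tuple[float, float, float, float],
                n_grid: int = 15) -> "PolynomialTransform":
        """Numerical inverse, fitted on a grid over ``bbox_nm``.

        Exact for affine maps; an approximation for order >= 2.
        """
        xmin, xmax, ymin, ymax = bbox_nm
        gx, gy = np.meshgrid(np.linspace(xmin, xmax, n_grid),
                             np.linspace(ymin, ymax, n_grid))
        src = np.column_stack([gx.ravel(), gy.ravel()])
        dst = self.apply(src)
        return fit_polynomial(dst, src, self.order)


def n_coefficients(order: int) -> int:
    return 3 if order == 1 else 6


def fit_polynomial(src: np.ndarray, dst: np.ndarray,
                   order: int = 1) -> PolynomialTransform:
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if order < 1 or order > 2:
        raise ValueError("polynomial order must be 1 or 2")
    ncoef = n_coefficients(order)
    if len(src) < ncoef:
        raise ValueError(f"need >= {ncoef} pairs for order {order}")
    scale = max(np.abs(src).max(), 1.0)
    X = _poly_features(src, order, scale)
    if np.linalg.matrix_rank(X) < ncoef:
        raise ValueError("degenerate fiducial geometry (rank-deficient fit)")
    coeffs, *_ = np.linalg.lstsq(X, dst, rcond=None)
    resid = X @ coeffs - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if len(src) else 0.0
    return PolynomialTransform(order, coeffs, scale, rms)


def fit_channel_transform(pairs: FiducialPairSet,
                          order: int = 1) -> PolynomialTransform:
    """Least-squares polynomial mapping moving -> reference channel."""
    return fit_polynomial(pairs.moving_nm, pairs.reference_nm, order)


def apply_transform(table: LocalizationTable,
                    transform: PolynomialTransform) -> LocalizationTable:
    """Map table coordinates through the channel transform."""
    mapped = transform.apply(table.xy)
    df = table.df.copy()
    df["x_nm"], df["y_nm"] = mapped[:, 0], mapped[:, 1]
    return table.with_df(df)


def fiducial_pairs_from_tables(moving: LocalizationTable,
                               reference: LocalizationTable,
                               eps_nm: float = 300.0,
                               min_samples: int = 10,
                               max_match_nm: float = 1000.0) -> FiducialPairSet:
    """Collapse always-on fiducial tracks to bead positions and match them.

    Beads are found by density clustering of each channel's fiducial
    localizations; cluster means in the moving channel are matched to the
    nearest reference-bead mean within ``max_match_nm``.
    """
    from scipy.spatial import cKDTree
    from sklearn.cluster import DBSCAN

    def bead_means(table: LocalizationTable) -> np.ndarray:
        xy = table.xy
        labels = DBSCAN(eps=eps_nm, min_samples=min_samples).fit_predict(xy)
        return np.array([xy[labels == k].mean(axis=0)
                         for k in sorted(set(labels)) if k >= 0])

    mv, ref = bead_means(moving), bead_means(reference)
    if len(mv) == 0 or len(ref) == 0:
        raise ValueError("no fiducial beads found in one of the channels")
    tree = cKDTree(ref)
    d, j = tree.query(mv)
    ok = d <= max_match_nm
    # enforce one-to-one: keep closest moving bead per reference bead
    best: dict[int, int] = {}
    for i in np.nonzero(ok)[0]:
        if j[i] not in best or d[i] < d[best[j[i]]]:
            best[j[i]] = i
    idx = sorted(best.items())
    return FiducialPairSet(np.array([mv[i] for _, i in idx]),
                           np.array([ref[jj] for jj, _ in idx]))
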