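"""Single-molecule localization: peak detection, Gaussian fitting, quality
filtering, blink merging, and Gaussian rendering.

The processing chain mirrors the standard dSTORM workflow: threshold-based
peak detection in each frame, least-squares fit of a symmetric 2-D Gaussian
for sub-pixel position and integrated photon count, inclusion only of
localizations with photon count >= 2000, merging of localizations that
re-appear within one camera pixel in consecutive frames into a single
photon-weighted localization, and rendering each localization as a
unit-mass Gaussian whose width is the estimated localization precision.

Precision is the first-order Thompson estimate sigma / sqrt(N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .tables import LocalizationTable

log = logging.getLogger(__name__)

DEFAULT_MIN_PHOTONS = 2000.0


@dataclass
class RenderedImage:
    """Super-resolution rendering: sum of unit-mass Gaussians."""

    data: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)


def read_stack(path) -> np.ndarray:
    """Read a (possibly multi-page) TIFF stack as (n_frames, ny, nx)."""
    import tifffile

    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack


def write_stack(path, stack: np.ndarray) -> None:
    """Write an image stack as multi-page TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, np.float32))


def detect_peaks(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Local maxima above ``threshold``, deduplicated in a 3x3 neighborhood.

    Returns an (n, 2) integer array of (row, col) candidates.
    """
    frame = np.asarray(frame, float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if frame.ndim != 2 or np.any(frame < 0):
        raise ValueError("frame must be a 2-D non-negative image")
    local_max = ndimage.maximum_filter(frame, size=3, mode="nearest")
    local_min = ndimage.minimum_filter(frame, size=3, mode="nearest")
    # strict local maxima only: constant plateaus are not peaks
    mask = (frame == local_max) & (frame > local_min) & (frame > threshold)
    rows, cols = np.nonzero(mask)
    # flat plateaus: keep one representative per 3x3 neighborhood
    keep = []
    taken = np.zeros_like(mask)
    for r, c in zip(rows, cols):
        if not taken[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].any():
            keep.append((r, c))
            taken[r, c] = True
    return np.asarray(keep, int).reshape(-1, 2)


def _gauss2d(coords, x0, y0, sigma, amplitude, offset):
    x, y = coords
    return (offset + amplitude
            * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))).ravel()


def fit_gaussian(frame: np.ndarray, candidate: tuple[int, int],
                 pixel_size_nm: float = 107.0, window: int = 7,
                 frame_index: int = 0, channel: str = "0") -> dict | None:
    """Fit a symmetric 2-D Gaussian in a window around a candidate pixel.

    Returns a localization record (dict of table columns) or None when the
    fit does not converge.  Raises ``ValueError`` when the fitting window
    is not fully inside the frame.
    """
    r, c = candidate
    half = window // 2
    if (r - half < 0 or c - half < 0
            or r + half >= frame.shape[0] or c + half >= frame.shape[1]):
        raise ValueError("fitting window out of frame bounds")
    patch = np.asarray(frame, float)[r - half:r + half + 1, c - half:c + half + 1]
    yy, xx = np.mgrid[r - half:r + half + 1, c - half:c + half + 1]
    p0 = (float(c), float(r), 1.3, float(patch.max() - patch.min()),
          float(patch.min()))
    try:
        popt, _ = curve_fit(
            _gauss2d, (xx, yy), patch.ravel(), p0=p0,
            bounds=([c - half, r - half, 0.3, 0.0, 0.0],
                    [c + half, r + half, float(window), np.inf, np.inf]),
            maxfev=2000)
    except (RuntimeError, ValueError):
        return None
    x0, y0, sigma, amplitude, _ = popt
    photons = 2.0 * np.pi * sigma**2 * amplitude  # integrated above background
    sigma_nm = sigma * pixel_size_nm
    precision = sigma_nm / np.sqrt(max(photons, 1.0))
    return {
        "frame": frame_index,
        "x_nm": x0 * pixel_size_nm, "y_nm": y0 * pixel_size_nm,
        "photons": photons, "sigma_nm": sigma_nm,
        "precision_nm": precision, "channel": channel,
    }


def localize_stack(stack: np.ndarray, threshold: float,
                   pixel_size_nm: float = 107.0, window: int = 7,
                   channel: str = "0") -> LocalizationTable:
    """Detect and fit every frame of a stack; failed fits are dropped."""
    records, dropped = [], 0
    for f, frame in enumerate(np.asarray(stack, float)):
        for cand in detect_peaks(frame, threshold):
            half = window // 2
            r, c = cand
            if (r - half < 0 or c - half < 0 or r + half >= frame.shape[0]
                    or c + half >= frame.shape[1]):
                continue
            rec = fit_gaussian(frame, tuple(cand), pixel_size_nm, window,
                               frame_index=f, channel=channel)
            if rec is None:
                dropped += 1
            else:
                records.append(rec)
    if dropped:
        log.info("dropped %d non-convergent fits", dropped)
    df = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["frame", "x_nm", "y_nm", "photons", "sigma_nm",
                 "precision_nm", "channel"])
    return LocalizationTable(df, pixel_size_nm, len(stack))


def filter_photons(table: LocalizationTable,
                   min_photons: float = DEFAULT_MIN_PHOTONS) -> LocalizationTable:
    """Keep only localizations with photon count >= ``min_photons``."""
    return table.with_df(table.df[table.df["photons"] >= min_photons])


def merge_consecutive(table: LocalizationTable, radius_px: float = 1.0,
                      max_run: int | None = None) -> LocalizationTable:
    """Merge re-blinking: chains of localizations in consecutive frames
    within ``radius_px`` camera pixels collapse to one photon-weighted
    localization (frame = first frame of the chain, photons summed).

    ``max_run`` caps chain length (None = unlimited); chains are built
    greedily in frame order, each localization linking to the nearest
    unconsumed successor in the next frame within the radius.
    """
    df = table.df
    if df.empty:
        return table.with_df(df)
    radius_nm = radius_px * table.pixel_size_nm
    out_frames = []
    merged_rows = []
    for channel, sub in df.groupby("channel", sort=False):
        sub = sub.sort_values("frame", kind="stable")
        idx = sub.index.to_numpy()
        frames = sub["frame"].to_numpy()
        xy = sub[["x_nm", "y_nm"]].to_numpy(float)
        photons = sub["photons"].to_numpy(float)
        consumed = np.zeros(len(sub), bool)
        by_frame: dict[int, list[int]] = {}
        for i, f in enumerate(frames):
            by_frame.setdefault(int(f), []).append(i)
        for i in range(len(sub)):
            if consumed[i]:
                continue
            chain = [i]
            consumed[i] = True
            cur = i
            while max_run is None or len(chain) < max_run:
                nxt_frame = int(frames[cur]) + 1
                cands = [j for j in by_frame.get(nxt_frame, []) if not consumed[j]]
                if not cands:
                    break
                d = np.linalg.norm(xy[cands] - xy[cur], axis=1)
                k = int(np.argmin(d))
                if d[k] > radius_nm:
                    break
                cur = cands[k]
                consumed[cur] = True
                chain.append(cur)
            w = photons[chain]
            wsum = w.sum()
            pos = (xy[chain] * w[:, None]).sum(axis=0) / wsum if wsum > 0 \
                else xy[chain].mean(axis=0)
            row = sub.loc[idx[chain[0]]].copy()
            row["x_nm"], row["y_nm"] = pos
            row["photons"] = wsum
            # averaging k re-blinks improves the position estimate
            if np.isfinite(row["precision_nm"]):
                row["precision_nm"] /= np.sqrt(len(chain))
            merged_rows.append(row)
            out_frames.append(frames[chain[0]])
    out = pd.DataFrame(merged_rows).reset_index(drop=True)
    return table.with_df(out)


def render(table: LocalizationTable, pixel_size_out_nm: float,
           extent_nm: tuple[float, float, float, float] | None = None,
           sigma_nm: float | None = None) -> RenderedImage:
    """Render localizations as unit-mass Gaussians at their precision.

    ``extent_nm`` = (xmin, xmax, ymin, ymax); default pads the data bounding
    box by 5 rendered widths.  ``sigma_nm`` overrides per-row precision.
    """
    if pixel_size_out_nm <= 0:
        raise ValueError("output pixel size must be positive")
    df = table.df
    xy = table.xy
    prec = (np.full(len(df), float(sigma_nm)) if sigma_nm is not None
            else df["precision_nm"].to_numpy(float))
    if np.any(~(prec > 0)):
        raise ValueError("all precisions must be positive for rendering")
    if extent_nm is None:
        pad = 6.0 * (prec.max() if len(prec) else pixel_size_out_nm)
        extent_nm = (xy[:, 0].min() - pad, xy[:, 0].max() + pad,
                     xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    xmin, xmax, ymin, ymax = extent_nm
    nx = max(int(np.ceil((xmax - xmin) / pixel_size_out_nm)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel_size_out_nm)), 1)
    img = np.zeros((ny, nx))
    from scipy.stats import norm

    xedges = xmin + pixel_size_out_nm * np.arange(nx + 1)
    yedges = ymin + pixel_size_out_nm * np.arange(ny + 1)
    for (x, y), s in zip(xy, prec):
        # integrate the Gaussian over pixels -> exact unit mass up to borders
        gx = np.diff(norm.cdf(xedges, loc=x, scale=s))
        gy = np.diff(norm.cdf(yedges, loc=y, scale=s))
        img += np.outer(gy, gx)
    return RenderedImage(img, pixel_size_out_nm, (xmin, ymin))
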