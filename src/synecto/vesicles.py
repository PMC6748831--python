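"""Vesicle (synaptic ectosome) segmentation, sizing and positivity classes.

Vesicles are segmented from the membrane-reference channel (WGA or CD81)
by density-based clustering (DBSCAN: radius ``eps``, minimum neighbor
count ``min_pts``).  The diameter of a cluster is the full width at half
maximum (FWHM) of the radially averaged rendered intensity profile about
its centroid, each member localization rendered as a Gaussian at its
precision — the same metric used for receptor microclusters.  Receptor
channels are then assigned to the nearest vesicle centroid and a vesicle
is "positive" for a channel when it carries at least ``min_locs``
assigned localizations, yielding the TCR-only / partner-only /
double-positive classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .tables import LocalizationTable

DEFAULT_EPS_NM = 50.0
DEFAULT_MIN_PTS = 5
DEFAULT_MIN_LOCS = 3


@dataclass
class VesicleCluster:
    id: int
    centroid_nm: np.ndarray
    member_indices: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    diameter_nm: float = np.nan
    diameter_flagged: bool = False
    cell_id: int = -1
    positivity: str | None = None

    @property
    def n_reference(self) -> int:
        ref = next(iter(self.member_indices.values()), np.empty(0))
        return len(ref)


# Microclusters share the vesicle data model (same size metric).
Microcluster = VesicleCluster


def segment_vesicles(reference_table: LocalizationTable,
                     eps_nm: float = DEFAULT_EPS_NM,
                     min_pts: int = DEFAULT_MIN_PTS,
                     channel_label: str = "reference") -> list[VesicleCluster]:
    """Density-cluster the membrane channel; noise points are discarded."""
    xy = reference_table.xy
    if len(xy) == 0:
        return []
    labels = DBSCAN(eps=eps_nm, min_samples=min_pts).fit_predict(xy)
    clusters = []
    for cid, k in enumerate(sorted(set(labels) - {-1})):
        members = np.nonzero(labels == k)[0]
        centroid = xy[members].mean(axis=0)
        clusters.append(VesicleCluster(
            id=cid, centroid_nm=centroid,
            member_indices={channel_label: members},
            counts={channel_label: len(members)}))
    # stable ordering: by centroid (x, then y)
    clusters.sort(key=lambda c: (c.centroid_nm[0], c.centroid_nm[1]))
    for new_id, c in enumerate(clusters):
        c.id = new_id
    return clusters


def radial_profile(xy: np.ndarray, precisions: np.ndarray,
                   center: np.ndarray, r_max_nm: float = 200.0,
                   r_step_nm: float = 1.0, n_angles: int = 48) -> tuple:
    """Radially averaged rendered intensity about ``center``.

    Each point contributes a unit-mass Gaussian of width = its precision;
    the profile is the mean intensity on rings of radius r.
    """
    radii = np.arange(0.0, r_max_nm + r_step_nm, r_step_nm)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (n_angles, 2)
    # sample points: (n_r, n_angles, 2)
    samples = center[None, None, :] + radii[:, None, None] * ring[None, :, :]
    flat = samples.reshape(-1, 2)
    intensity = np.zeros(len(flat))
    for (x, y), s in zip(xy, precisions):
        d2 = (flat[:, 0] - x) ** 2 + (flat[:, 1] - y) ** 2
        intensity += np.exp(-d2 / (2.0 * s * s)) / (2.0 * np.pi * s * s)
    profile = intensity.reshape(len(radii), n_angles).mean(axis=1)
    return radii, profile


def _half_crossing(radii: np.ndarray, profile: np.ndarray,
                   half: float) -> float:
    i_peak = int(np.argmax(profile))
    below = np.nonzero(profile[i_peak:] < half)[0]
    if len(below) == 0:
        return 2.0 * radii[-1]  # never falls below half within range
    j = i_peak + below[0]
    # linear interpolation between the bracketing samples
    r0, r1 = radii[j - 1], radii[j]
    p0, p1 = profile[j - 1], profile[j]
    r_half = r0 + (p0 - half) / (p0 - p1) * (r1 - r0) if p0 != p1 else r0
    return 2.0 * r_half


def fwhm_from_profile(radii: np.ndarray, profile: np.ndarray,
                      raw_profile: np.ndarray | None = None) -> float:
    """Full width at half maximum of a radial profile (diameter = 2 r_half).

    When ``raw_profile`` is given, the half level is refined in a second
    pass from the unsmoothed central plateau (mean of the raw profile
    inside half the first-pass half-max radius), which removes the upward
    bias of taking the maximum of a noisy profile.
    """
    fwhm = _half_crossing(radii, profile, profile.max() / 2.0)
    if raw_profile is None:
        return fwhm
    sel = radii <= max(fwhm / 4.0, radii[1])
    plateau = float(raw_profile[sel].mean())
    return _half_crossing(radii, profile, plateau / 2.0)


def _disk_profile_fwhm(diameter_nm: float, sigma_nm: float) -> float:
    """FWHM of a uniform disk convolved with an isotropic Gaussian.

    Radial profile of the convolution:
        I(r) = int_0^R s/sigma^2 exp(-(r-s)^2/2sigma^2) i0e(r s/sigma^2) ds
    (i0e is the exponentially scaled modified Bessel function).
    """
    from scipy.special import i0e

    R = diameter_nm / 2.0
    s = np.linspace(0.0, R, 200)
    r = np.linspace(0.0, R + 6.0 * sigma_nm, 400)
    rr, ss = np.meshgrid(r, s, indexing="ij")
    integrand = (ss / sigma_nm**2
                 * np.exp(-((rr - ss) ** 2) / (2.0 * sigma_nm**2))
                 * i0e(rr * ss / sigma_nm**2))
    profile = np.trapezoid(integrand, s, axis=1)
    return _half_crossing(r, profile, profile.max() / 2.0)


def deconvolved_diameter(fwhm_nm: float, sigma_nm: float) -> float:
    """Invert the disk-blur forward model: find D with model FWHM = observed.

    Returns NaN when the observed width is at or below the pure-Gaussian
    rendering floor (no disk size is resolvable).
    """
    from scipy.optimize import brentq

    floor = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_nm  # 2.355 sigma
    if fwhm_nm <= floor * 1.02:
        return np.nan
    hi = 2.0 * fwhm_nm
    while _disk_profile_fwhm(hi, sigma_nm) < fwhm_nm:
        hi *= 2.0
        if hi > 1e5:
            return np.nan
    return brentq(lambda d: _disk_profile_fwhm(d, sigma_nm) - fwhm_nm,
                  1e-3, hi, xtol=0.01)


def estimate_diameter(cluster: VesicleCluster, table: LocalizationTable,
                      precision_nm: float | None = None,
                      channel_label: str = "reference",
                      r_max_nm: float = 250.0,
                      deconvolve: bool = True) -> float:
    """FWHM diameter of the cluster's rendered radial profile (nm).

    The raw FWHM of a blurred disk underestimates the disk diameter (the
    blur rounds the convex rim); with ``deconvolve`` the observed FWHM is
    inverted through the disk (x) Gaussian forward model at the effective
    blur width (localization scatter plus rendering width in quadrature).
    ``precision_nm`` overrides per-row precisions.  Degenerate clusters
    (all points coincident, or width at the rendering floor) return the
    rendering-limited FWHM (2.355 x precision) and are flagged.
    """
    members = cluster.member_indices[channel_label]
    xy = table.xy[members]
    if precision_nm is not None:
        prec = np.full(len(xy), float(precision_nm))
    else:
        prec = table.df["precision_nm"].to_numpy(float)[members]
        prec = np.where(np.isfinite(prec) & (prec > 0), prec, 10.0)
    radii, profile = radial_profile(xy, prec, cluster.centroid_nm,
                                    r_max_nm=r_max_nm)
    # smooth over r at the rendering width: sampling noise in the profile
    # peak otherwise inflates the half-max threshold and shrinks the FWHM;
    # sparse clusters (< 10 points) render smoothly already and the kernel
    # would only broaden them
    from scipy.ndimage import gaussian_filter1d
    raw = profile
    smooth_nm = float(np.median(prec)) if len(xy) >= 10 else 0.0
    if smooth_nm > 0:
        profile = gaussian_filter1d(profile, smooth_nm / (radii[1] - radii[0]),
                                    mode="nearest")
    d = fwhm_from_profile(radii, profile, raw_profile=raw)
    degenerate = bool(np.allclose(xy, xy[0], atol=1e-9))
    if deconvolve and not degenerate:
        # each point carries scatter ~= its precision and is rendered with
        # a Gaussian of the same width -> effective blur sqrt(2) * precision
        sigma_eff = np.sqrt(2.0) * float(np.median(prec))
        d_corr = deconvolved_diameter(d, sigma_eff)
        if np.isfinite(d_corr):
            d = d_corr
        else:
            degenerate = True
    cluster.diameter_flagged = degenerate
    cluster.diameter_nm = float(d)
    return cluster.diameter_nm


def assign_channels(clusters: list[VesicleCluster],
                    other_tables: dict[str, LocalizationTable],
                    assign_radius_nm: float = 100.0) -> list[VesicleCluster]:
    """Assign each receptor localization to the nearest vesicle centroid.

    Localizations farther than ``assign_radius_nm`` from every centroid
    stay unassigned.  Exact distance ties go to the lower cluster id.
    """
    if not clusters:
        return clusters
    centroids = np.array([c.centroid_nm for c in clusters])
    ids = np.array([c.id for c in clusters])
    order = np.argsort(ids)
    tree = cKDTree(centroids[order])
    for channel, table in other_tables.items():
        for c in clusters:
            c.member_indices.setdefault(channel, np.empty(0, int))
            c.counts.setdefault(channel, 0)
        xy = table.xy
        if len(xy) == 0 or assign_radius_nm <= 0:
            continue
        k = min(2, len(clusters))
        d, j = tree.query(xy, k=k)
        d = np.atleast_2d(d.T).T if k == 1 else d
        j = np.atleast_2d(j.T).T if k == 1 else j
        assigned: dict[int, list[int]] = {}
        for i in range(len(xy)):
            if d[i, 0] > assign_radius_nm:
                continue
            pick = j[i, 0]
            if k == 2 and np.isfinite(d[i, 1]) and \
                    abs(d[i, 1] - d[i, 0]) <= 1e-9:
                pick = min(j[i, 0], j[i, 1])  # tie -> lower cluster id
            assigned.setdefault(int(pick), []).append(i)
        by_id = {c.id: c for c in clusters}
        for pos, rows in assigned.items():
            cluster = by_id[int(ids[order][pos])]
            cluster.member_indices[channel] = np.asarray(rows, int)
            cluster.counts[channel] = len(rows)
    return clusters


def classify_positivity(cluster: VesicleCluster, tcr_channel: str = "TCR",
                        partner_channel: str = "CD40L",
                        min_locs: int = DEFAULT_MIN_LOCS) -> str:
    """TCR-vs-partner positivity class from assigned localization counts."""
    tcr = cluster.counts.get(tcr_channel, 0) >= min_locs
    partner = cluster.counts.get(partner_channel, 0) >= min_locs
    if tcr and partner:
        cls = "double-positive"
    elif tcr:
        cls = "TCR-only"
    elif partner:
        cls = "partner-only"
    else:
        cls = "negative"
    cluster.positivity = cls
    return cls


def positivity_fractions(clusters: list[VesicleCluster],
                         tcr_channel: str = "TCR",
                         partner_channel: str = "CD40L",
                         min_locs: int = DEFAULT_MIN_LOCS) -> dict[str, float]:
    """Percentages of the three positive classes (sum to 100 exactly)."""
    classes = [classify_positivity(c, tcr_channel, partner_channel, min_locs)
               for c in clusters]
    positive = [c for c in classes if c != "negative"]
    n = len(positive)
    if n == 0:
        return {"TCR-only": 0.0, "partner-only": 0.0, "double-positive": 0.0}
    return {cls: 100.0 * positive.count(cls) / n
            for cls in ("TCR-only", "partner-only", "double-positive")}


def detect_microclusters(channel_table: LocalizationTable,
                         eps_nm: float = DEFAULT_EPS_NM,
                         min_pts: int = DEFAULT_MIN_PTS,
                         precision_nm: float | None = None,
                         channel_label: str = "receptor") -> list[Microcluster]:
    """Receptor microclusters: same machinery, same size metric."""
    clusters = segment_vesicles(channel_table, eps_nm, min_pts, channel_label)
    for c in clusters:
        estimate_diameter(c, channel_table, precision_nm, channel_label)
    return clusters


@dataclass
class PerCellStats:
    cell_id: int
    n_vesicles: int
    median_diameter_nm: float  # NaN when the cell has no vesicles


def per_cell_stats(clusters: list[VesicleCluster],
                   cell_centers_nm: np.ndarray,
                   cell_radii_um: np.ndarray,
                   guard_radius_um: float = 2.0) -> list[PerCellStats]:
    """Per-cell vesicle counts and median diameters.

    Clusters are assigned to the footprint containing their centroid, else
    to the nearest footprint within ``guard_radius_um`` of its rim;
    otherwise they are flagged (dropped from per-cell stats).
    """
    cell_centers_nm = np.asarray(cell_centers_nm, float)
    radii_nm = np.asarray(cell_radii_um, float) * 1000.0
    diam_by_cell: dict[int, list[float]] = {i: [] for i in
                                            range(len(cell_centers_nm))}
    for c in clusters:
        d = np.linalg.norm(cell_centers_nm - c.centroid_nm, axis=1)
        overshoot = d - radii_nm
        i = int(np.argmin(overshoot))
        if overshoot[i] <= guard_radius_um * 1000.0:
            c.cell_id = i
            diam_by_cell[i].append(c.diameter_nm)
        else:
            c.cell_id = -1
    return [PerCellStats(i, len(v),
                         float(np.median(v)) if v else np.nan)
            for i, v in sorted(diam_by_cell.items())]


def clusters_to_frame(clusters: list[VesicleCluster]) -> pd.DataFrame:
    """Tidy cluster table (one row per vesicle) for CSV export."""
    rows = []
    for c in clusters:
        row = {"id": c.id, "cell": c.cell_id,
               "x_nm": c.centroid_nm[0], "y_nm": c.centroid_nm[1],
               "diameter_nm": c.diameter_nm, "class": c.positivity}
        for ch, n in c.counts.items():
            row[f"n_{ch}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
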