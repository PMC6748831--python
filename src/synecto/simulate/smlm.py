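"""Forward model: ground-truth scenes to dSTORM localization tables / frames.

Each labelled molecule blinks stochastically (1 + Poisson extra blink
events, geometric on-time run lengths over consecutive frames), emitting
one localization per active frame at

    reported = true position + drift(frame) [+ channel warp] + N(0, sigma)

with log-normal photon counts.  Fiducial beads are always on, in every
channel and frame.  The raw-frame mode renders active emitters as 2-D
Gaussian PSFs on a Poisson background for exercising the peak-fitting
stage on small fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import LocalizationTable
from .scene import GroundTruthScene


@dataclass(frozen=True)
class BlinkModel:
    """Fluorophore photoswitching model.

    A labelled molecule produces ``1 + Poisson(mean_blinks_per_fluorophore - 1)``
    blink events; each event stays on for a geometric number of consecutive
    frames with mean ``mean_on_frames`` (mean 1 means always exactly one
    frame).  Photons per localization are log-normal with the stated linear
    mean; ``photon_cv`` is the coefficient of variation (0 = deterministic).
    """

    mean_blinks_per_fluorophore: float = 1.5
    mean_on_frames: float = 1.5
    photon_mean: float = 4000.0
    photon_cv: float = 0.3
    labeling_efficiency: float = 0.8

    def validate(self) -> None:
        if self.mean_blinks_per_fluorophore < 1:
            raise ValueError("mean_blinks_per_fluorophore must be >= 1")
        if self.mean_on_frames < 1:
            raise ValueError("mean_on_frames must be >= 1")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if self.photon_mean < 0 or self.photon_cv < 0:
            raise ValueError("photon parameters must be non-negative")

    def draw_photons(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.photon_cv == 0:
            return np.full(n, self.photon_mean)
        s2 = np.log1p(self.photon_cv**2)
        mu = np.log(self.photon_mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), size=n)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera / acquisition / aberration settings.

    ``drift_rate_nm_per_frame`` imposes linear stage drift; an explicit
    per-frame ``drift_nm`` trajectory (n_frames, 2) overrides it.  The
    inter-channel warp is an affine map (small rotation/scale plus shift)
    applied to the channels listed in ``warp_channels``, emulating the
    chromatic mismatch between optical detection paths that fiducial-based
    registration must undo.
    """

    pixel_size_nm: float = 107.0
    n_frames: int = 5000
    exposure_ms: float = 10.0
    localization_precision_nm: float = 10.0
    psf_sigma_nm: float = 150.0
    drift_rate_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    drift_nm: np.ndarray | None = None  # (n_frames, 2), overrides rate
    warp_channels: tuple[str, ...] = ("TCR",)
    warp_matrix: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.0), (0.0, 1.0))
    warp_shift_nm: tuple[float, float] = (0.0, 0.0)
    fiducial_photons: float = 50000.0

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.localization_precision_nm < 0:
            raise ValueError("localization precision must be >= 0")

    def drift_at(self, frames: np.ndarray) -> np.ndarray:
        if self.drift_nm is not None:
            return np.asarray(self.drift_nm)[np.asarray(frames, int)]
        rate = np.asarray(self.drift_rate_nm_per_frame)
        return np.asarray(frames, float)[:, None] * rate[None, :]

    def warp(self, xy: np.ndarray) -> np.ndarray:
        A = np.asarray(self.warp_matrix)
        return xy @ A.T + np.asarray(self.warp_shift_nm)


@dataclass
class SimulatedLocalizations:
    """Per-channel localization tables plus always-on fiducial tracks."""

    tables: dict[str, LocalizationTable]
    fiducial_tables: dict[str, LocalizationTable]
    scene: GroundTruthScene

    def table_with_fiducials(self, channel: str) -> LocalizationTable:
        """Channel table with its fiducial tracks appended (as acquired)."""
        t = self.tables[channel]
        f = self.fiducial_tables[channel]
        return t.with_df(pd.concat([t.df, f.df], ignore_index=True))


def _blink_schedule(rng: np.random.Generator, n_molecules: int,
                    blink: BlinkModel, n_frames: int):
    """Frame indices and molecule index for every emitted localization."""
    mol_idx, frames = [], []
    n_blinks = 1 + rng.poisson(blink.mean_blinks_per_fluorophore - 1.0,
                               size=n_molecules)
    for m in range(n_molecules):
        for _ in range(n_blinks[m]):
            start = rng.integers(0, n_frames)
            if blink.mean_on_frames == 1:
                run = 1
            else:
                run = rng.geometric(1.0 / blink.mean_on_frames)
            stop = min(start + run, n_frames)
            for f in range(start, stop):
                mol_idx.append(m)
                frames.append(f)
    return np.asarray(mol_idx, int), np.asarray(frames, int)


def simulate_localizations(scene: GroundTruthScene, blink: BlinkModel,
                           acq: AcquisitionConfig,
                           seed: int = 0) -> SimulatedLocalizations:
    """Emit per-channel localization tables from a ground-truth scene.

    Channels are labelled by species.  Deterministic in ``seed``.
    """
    blink.validate()
    acq.validate()
    rng = np.random.default_rng(seed)
    by_species = scene.molecules_by_species()

    tables: dict[str, LocalizationTable] = {}
    for species in sorted(by_species):
        pts = by_species[species]
        labeled = pts[rng.uniform(size=len(pts)) < blink.labeling_efficiency]
        mol_idx, frames = _blink_schedule(rng, len(labeled), blink, acq.n_frames)
        xy = labeled[mol_idx] if len(mol_idx) else np.empty((0, 2))
        xy = xy + acq.drift_at(frames)
        if species in acq.warp_channels:
            xy = acq.warp(xy)
        sig = acq.localization_precision_nm
        if sig > 0 and len(xy):
            xy = xy + rng.normal(scale=sig, size=xy.shape)
        photons = blink.draw_photons(rng, len(xy))
        df = pd.DataFrame({
            "frame": frames, "x_nm": xy[:, 0] if len(xy) else [],
            "y_nm": xy[:, 1] if len(xy) else [],
            "photons": photons, "sigma_nm": acq.psf_sigma_nm,
            "precision_nm": max(sig, 1e-9), "channel": species,
        })
        tables[species] = LocalizationTable(df, acq.pixel_size_nm, acq.n_frames)

    fiducial_tables: dict[str, LocalizationTable] = {}
    fid = scene.fiducials
    all_frames = np.repeat(np.arange(acq.n_frames), len(fid))
    fid_xy0 = np.tile(fid, (acq.n_frames, 1))
    for channel in sorted(set(tables) | {"CD81"}):
        xy = fid_xy0 + acq.drift_at(all_frames)
        if channel in acq.warp_channels:
            xy = acq.warp(xy)
        sig = acq.localization_precision_nm / 4.0  # bright beads localize better
        if sig > 0:
            xy = xy + rng.normal(scale=sig, size=xy.shape)
        df = pd.DataFrame({
            "frame": all_frames, "x_nm": xy[:, 0], "y_nm": xy[:, 1],
            "photons": acq.fiducial_photons, "sigma_nm": acq.psf_sigma_nm,
            "precision_nm": max(sig, 1e-9), "channel": channel,
        })
        fiducial_tables[channel] = LocalizationTable(df, acq.pixel_size_nm,
                                                     acq.n_frames)

    return SimulatedLocalizations(tables, fiducial_tables, scene)


@dataclass
class SimulatedFrames:
    stack: np.ndarray  # (n_frames, ny, nx) expected-photon images w/ Poisson noise
    truth: pd.DataFrame  # frame, x_nm, y_nm, photons of every active emitter
    pixel_size_nm: float


MAX_FIELD_PIXELS = 256 * 256


def simulate_frames(source, blink: BlinkModel,
                    acq: AcquisitionConfig, field_px: tuple[int, int],
                    background: float = 2.0, seed: int = 0,
                    poisson_noise: bool = True) -> SimulatedFrames:
    """Render raw camera frames for a small field.

    ``source`` is either a GroundTruthScene (all molecule positions pooled)
    or an (n, 2) array of molecule positions in nm.  Each active
    emitter is a 2-D Gaussian PSF integrated over pixels (photon-conserving
    up to border truncation), on a uniform Poisson background (photons per
    pixel per frame).  Raises ``ValueError`` when the field exceeds the
    memory budget.
    """
    blink.validate()
    acq.validate()
    ny, nx = field_px[1], field_px[0]
    if nx * ny > MAX_FIELD_PIXELS:
        raise ValueError(f"field {nx}x{ny} exceeds budget of "
                         f"{MAX_FIELD_PIXELS} pixels")
    rng = np.random.default_rng(seed)
    if isinstance(source, GroundTruthScene):
        chunks = list(source.molecule_positions.values())
        positions_nm = (np.concatenate(chunks) if chunks else np.empty((0, 2)))
    else:
        positions_nm = np.asarray(source, float)
    mol_idx, frames = _blink_schedule(rng, len(positions_nm), blink, acq.n_frames)
    photons = blink.draw_photons(rng, len(mol_idx))

    px = acq.pixel_size_nm
    sigma_px = acq.psf_sigma_nm / px
    stack = np.zeros((acq.n_frames, ny, nx))
    from scipy.stats import norm

    # pixel i spans [i - 0.5, i + 0.5): coordinates are pixel-centre indices
    xedges = np.arange(nx + 1) - 0.5
    yedges = np.arange(ny + 1) - 0.5
    for i, (m, f) in enumerate(zip(mol_idx, frames)):
        x_px, y_px = positions_nm[m] / px
        gx = np.diff(norm.cdf(xedges, loc=x_px, scale=sigma_px))
        gy = np.diff(norm.cdf(yedges, loc=y_px, scale=sigma_px))
        stack[f] += photons[i] * np.outer(gy, gx)
    stack += background
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)

    truth = pd.DataFrame({
        "frame": frames,
        "x_nm": positions_nm[mol_idx, 0] if len(mol_idx) else [],
        "y_nm": positions_nm[mol_idx, 1] if len(mol_idx) else [],
        "photons": photons,
    })
    return SimulatedFrames(stack, truth, px)
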