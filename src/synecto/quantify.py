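"""Flow-cytometry transfer quantification, SE surface geometry, and
cytokine-array normalization.

Transfer of a T-cell surface protein to the bead-supported lipid bilayer
(BSLB) is quantified from isotype-control-corrected geometric mean
fluorescence intensities (GMFI):

    percent transfer = 100 * GMFI_BSLB / (GMFI_BSLB + GMFI_Tcell)

Absolute molecule numbers come from a log-log-linear calibration against
MESF (molecules of equivalent soluble fluorochrome) bead ladders, divided
by the antibody dye ratio to report antibody-binding sites.

Surface geometry treats each synaptic ectosome as a sphere of diameter d:
total released membrane area = n * pi * d^2 (0.82 um^2 for d = 84 nm and
n = 37), from which site densities and the fraction of the T-cell surface
follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# MESF calibration

@dataclass
class MESFLadder:
    """Calibration beads: measured intensity vs assigned MESF molecules."""

    intensity: np.ndarray
    mesf: np.ndarray
    blank_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        self.mesf = np.asarray(self.mesf, float)
        if len(self.intensity) < 3:
            raise ValueError("MESF ladder needs at least 3 bead populations")
        if np.any(np.diff(self.mesf) <= 0):
            raise ValueError("MESF values must be strictly increasing")


@dataclass
class CalibrationCurve:
    """log10(intensity - blank) -> log10(MESF) linear fit."""

    slope: float
    intercept: float
    r_squared: float
    intensity_range: tuple[float, float]
    blank_intensity: float

    def to_mesf(self, intensity, warn_out_of_range: bool = True) -> np.ndarray:
        intensity = np.asarray(intensity, float)
        net = intensity - self.blank_intensity
        if np.any(net <= 0):
            raise ValueError("intensity at or below blank; cannot convert")
        lo, hi = self.intensity_range
        if warn_out_of_range and np.any((intensity < lo) | (intensity > hi)):
            log.warning("intensity outside calibrated range [%g, %g]", lo, hi)
        return 10.0 ** (self.slope * np.log10(net) + self.intercept)


def fit_mesf_curve(ladder: MESFLadder) -> CalibrationCurve:
    """Least-squares log-log fit after blank subtraction."""
    net = ladder.intensity - ladder.blank_intensity
    if np.any(net <= 0):
        raise ValueError("bead intensity at or below blank")
    if np.any(np.diff(ladder.intensity) <= 0):
        raise ValueError("bead intensities must increase with MESF")
    lx, ly = np.log10(net), np.log10(ladder.mesf)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationCurve(float(slope), float(intercept), r2,
                            (float(ladder.intensity.min()),
                             float(ladder.intensity.max())),
                            ladder.blank_intensity)


# --------------------------------------------------------------------------
# Transfer

def gmfi(intensities: np.ndarray) -> float:
    """Geometric mean over strictly positive events (others logged, dropped)."""
    x = np.asarray(intensities, float)
    pos = x[x > 0]
    if len(pos) < len(x):
        log.info("GMFI: dropped %d non-positive events", len(x) - len(pos))
    if len(pos) == 0:
        raise ValueError("no positive events for geometric mean")
    return float(np.exp(np.mean(np.log(pos))))


@dataclass
class TransferMeasurement:
    marker: str
    gmfi_bslb: float
    gmfi_tcell: float
    isotype_bslb: float = 0.0
    isotype_tcell: float = 0.0
    dye_ratio: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.gmfi_bslb, self.gmfi_tcell,
                  self.isotype_bslb, self.isotype_tcell):
            if v < 0:
                raise ValueError("GMFIs must be non-negative")
        if self.dye_ratio <= 0:
            raise ValueError("dye ratio must be positive")

    @property
    def corrected_bslb(self) -> float:
        # negative isotype-corrected signal clamps to zero (no transfer)
        return max(self.gmfi_bslb - self.isotype_bslb, 0.0)

    @property
    def corrected_tcell(self) -> float:
        return max(self.gmfi_tcell - self.isotype_tcell, 0.0)


def percent_transfer(m: TransferMeasurement) -> float:
    """100 * corrected GMFI_BSLB / (corrected GMFI_BSLB + GMFI_Tcell)."""
    b, t = m.corrected_bslb, m.corrected_tcell
    if b + t == 0:
        raise ValueError("both corrected GMFIs are zero; transfer undefined")
    return 100.0 * b / (b + t)


def molecules_from_panel(events: pd.DataFrame, curve: CalibrationCurve,
                         dye_ratio: float = 1.0) -> dict[str, float]:
    """Isotype-corrected absolute molecules per population.

    ``events`` columns: population, stain ('marker'/'isotype'), intensity.
    GMFIs are converted to MESF through the calibration curve, the isotype
    MESF subtracted (clamped at zero) and divided by the dye ratio.
    """
    out = {}
    for pop, sub in events.groupby("population"):
        marker = gmfi(sub.loc[sub["stain"] == "marker", "intensity"])
        iso = gmfi(sub.loc[sub["stain"] == "isotype", "intensity"])
        m = float(curve.to_mesf(marker, warn_out_of_range=False)[()])
        i = float(curve.to_mesf(iso, warn_out_of_range=False)[()])
        out[pop] = max(m - i, 0.0) / dye_ratio
    return out


def transfer_fraction_from_molecules(molecules: dict[str, float]) -> float:
    b, t = molecules["BSLB"], molecules["Tcell"]
    if b + t == 0:
        raise ValueError("no molecules detected in either population")
    return b / (b + t)


# --------------------------------------------------------------------------
# Surface geometry

def site_density(molecules: float, sphere_diameter_um: float) -> float:
    """Molecules per um^2 on a sphere of the given diameter (area pi d^2)."""
    if sphere_diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return molecules / (np.pi * sphere_diameter_um**2)


def se_total_area(diameter_nm: float, n_vesicles: int) -> float:
    """Total released SE membrane area in um^2 (spheres of diameter d)."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    if n_vesicles < 0:
        raise ValueError("vesicle count must be non-negative")
    return n_vesicles * np.pi * (diameter_nm / 1000.0) ** 2


def se_density(molecules: float, area_um2: float,
               per_trimer: int = 3) -> float:
    """Trimer (or monomer, per_trimer=1) density on the SE membrane."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return (molecules / per_trimer) / area_um2


def fraction_of_cell_surface(se_area_um2: float,
                             cell_area_um2: float) -> float:
    """SE area as a percentage of the T-cell surface area.

    The cell surface area is an explicit assumption supplied by the
    caller; it is not measured by this pipeline.
    """
    if cell_area_um2 <= 0:
        raise ValueError("cell area must be positive")
    return 100.0 * se_area_um2 / cell_area_um2


@dataclass
class SEGeometry:
    """Derived SE surface-geometry report."""

    diameter_nm: float
    n_vesicles: int
    molecules: float
    cell_area_um2: float = 410.0  # assumption, flagged in reports
    per_trimer: int = 3

    @property
    def total_area_um2(self) -> float:
        return se_total_area(self.diameter_nm, self.n_vesicles)

    @property
    def trimer_density_per_um2(self) -> float:
        return se_density(self.molecules, self.total_area_um2, self.per_trimer)

    @property
    def percent_of_cell_surface(self) -> float:
        return fraction_of_cell_surface(self.total_area_um2, self.cell_area_um2)

    def report(self) -> dict:
        return {
            "diameter_nm": self.diameter_nm,
            "n_vesicles": self.n_vesicles,
            "total_area_um2": self.total_area_um2,
            "molecules": self.molecules,
            "trimer_density_per_um2": self.trimer_density_per_um2,
            "percent_of_cell_surface": self.percent_of_cell_surface,
            "cell_area_um2_assumed": self.cell_area_um2,
        }


# --------------------------------------------------------------------------
# Cytokine array

def cytokine_fold_change(spots: pd.DataFrame,
                         control_condition: str) -> pd.DataFrame:
    """Duplicate-spot cytokine array fold changes over a control condition.

    ``spots`` columns: condition, analyte, intensity (two spot rows per
    analyte per condition) plus positive-control rows with analyte
    ``'positive'``.  Each analyte's mean duplicate intensity is divided by
    the array's mean positive-spot intensity (cancelling global scale
    differences between arrays); fold change is the ratio to the control
    condition.  Analytes missing a duplicate are flagged and excluded.
    """
    results = {}
    for cond, sub in spots.groupby("condition"):
        positives = sub.loc[sub["analyte"] == "positive", "intensity"]
        if positives.empty:
            raise ValueError(f"array {cond!r} has no positive control spots")
        pos_mean = positives.mean()
        vals = {}
        for analyte, rows in sub[sub["analyte"] != "positive"].groupby("analyte"):
            if len(rows) != 2:
                log.warning("analyte %r in %r: %d spots (need 2); excluded",
                            analyte, cond, len(rows))
                continue
            vals[analyte] = rows["intensity"].mean() / pos_mean
        results[cond] = vals
    if control_condition not in results:
        raise ValueError(f"control condition {control_condition!r} not present")
    control = results[control_condition]
    rows = []
    for cond, vals in results.items():
        for analyte, v in vals.items():
            if analyte in control and control[analyte] > 0:
                rows.append({"condition": cond, "analyte": analyte,
                             "fold_change": v / control[analyte]})
    return pd.DataFrame(rows)
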