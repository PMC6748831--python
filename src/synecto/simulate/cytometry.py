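"""Simulated flow-cytometry panels for transfer quantification round trips.

Emulates the bead-supported-lipid-bilayer (BSLB) transfer assay: after
synapse formation a marker's molecules are split between the BSLB
population and the T-cell population.  Fluorescence responds to molecule
number through a log-log-linear response (the same curve that generates
the MESF calibration-bead ladder), with log-normal event spread and an
additive isotype-control background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CytometryParams:
    """True molecule numbers and instrument response for one marker.

    ``transfer_fraction`` is the ground-truth fraction of the marker on the
    BSLB population.  The response is intensity = gain * molecules**slope
    (slope 1 = ideal linear instrument).  ``noise_cv`` is the log-normal
    coefficient of variation applied to event intensities and to ladder
    bead intensities.
    """

    marker: str = "CD40L"
    total_molecules: float = 20000.0
    transfer_fraction: float = 0.30
    gain: float = 0.05
    response_slope: float = 1.0
    noise_cv: float = 0.10
    isotype_molecules: float = 200.0
    n_events: int = 2000
    mesf_ladder: tuple[float, ...] = (2_500., 25_000., 250_000., 1_000_000.)
    blank_intensity: float = 5.0
    dye_ratio: float = 1.0  # AF647 dyes per antibody

    def validate(self) -> None:
        if not 0.0 <= self.transfer_fraction <= 1.0:
            raise ValueError("transfer_fraction must be in [0, 1]")
        if self.total_molecules < 0 or self.isotype_molecules < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if len(self.mesf_ladder) < 3 or np.any(np.diff(self.mesf_ladder) <= 0):
            raise ValueError("MESF ladder needs >= 3 strictly increasing values")


@dataclass
class SimulatedCytometryPanel:
    params: CytometryParams
    events: pd.DataFrame         # population, stain, intensity
    ladder: pd.DataFrame         # intensity, mesf
    blank_intensity: float
    true_molecules: dict[str, float]  # population -> true specific molecules


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    s2 = np.log1p(cv**2)
    return rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=n)


def simulate_cytometry(params: CytometryParams | None = None,
                       seed: int = 0) -> SimulatedCytometryPanel:
    """Generate event tables plus a MESF bead ladder. Deterministic in seed."""
    params = params or CytometryParams()
    params.validate()
    rng = np.random.default_rng(seed)

    def response(molecules: float) -> float:
        return params.gain * float(molecules) ** params.response_slope

    true = {
        "BSLB": params.total_molecules * params.transfer_fraction,
        "Tcell": params.total_molecules * (1.0 - params.transfer_fraction),
    }
    rows = []
    for pop, mol in true.items():
        for stain, m in (("marker", mol + params.isotype_molecules),
                         ("isotype", params.isotype_molecules)):
            base = response(max(m, 1e-12)) + params.blank_intensity
            inten = base * _lognormal_factor(rng, params.noise_cv, params.n_events)
            rows.append(pd.DataFrame({"population": pop, "stain": stain,
                                      "intensity": inten}))
    events = pd.concat(rows, ignore_index=True)

    ladder_int = np.array([response(m) for m in params.mesf_ladder])
    ladder_int = (ladder_int
                  * _lognormal_factor(rng, params.noise_cv / 4.0,
                                      len(ladder_int))
                  + params.blank_intensity)
    ladder = pd.DataFrame({"intensity": ladder_int,
                           "mesf": np.asarray(params.mesf_ladder, float)})

    return SimulatedCytometryPanel(params, events, ladder,
                                   params.blank_intensity, true)
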