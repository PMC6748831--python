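"""Simulated label-free proteomics (LFQ) tables with known enrichment truth.

Mimics a MaxQuant-style proteinGroups export from the BSLB sorting
experiment: LFQ intensities per protein for the +ligand and -ligand
conditions across independent experiments, zero-inflated (missing values
encoded as NaN), with a flagged subset of proteins truly enriched by a
configured linear fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ProteomeParams:
    n_proteins: int = 300
    fraction_enriched: float = 0.2
    effect_size: float = 6.0          # true linear fold change for enriched
    n_experiments: int = 2
    noise_cv: float = 0.2             # log-normal CV on intensities
    missing_rate: float = 0.05        # random dropout -> NaN
    base_intensity_mean_log10: float = 7.0
    base_intensity_sd_log10: float = 0.8

    def validate(self) -> None:
        if not 0.0 <= self.fraction_enriched <= 1.0:
            raise ValueError("fraction_enriched must be in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ValueError("need >= 1 protein and experiment")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulatedProteome:
    params: ProteomeParams
    table: pd.DataFrame          # protein, condition, experiment, lfq (NaN = missing)
    enriched: np.ndarray         # bool flags, length n_proteins
    protein_ids: np.ndarray


def simulate_proteome(params: ProteomeParams | None = None,
                      seed: int = 0) -> SimulatedProteome:
    """Deterministic in seed; missing values are explicit NaN, never zero."""
    params = params or ProteomeParams()
    params.validate()
    rng = np.random.default_rng(seed)

    ids = np.array([f"P{i:05d}" for i in range(params.n_proteins)])
    n_enriched = int(round(params.fraction_enriched * params.n_proteins))
    enriched = np.zeros(params.n_proteins, bool)
    enriched[rng.choice(params.n_proteins, size=n_enriched, replace=False)] = True

    base = 10.0 ** rng.normal(params.base_intensity_mean_log10,
                              params.base_intensity_sd_log10,
                              size=params.n_proteins)
    s2 = np.log1p(params.noise_cv**2)

    rows = []
    for exp in range(params.n_experiments):
        for cond in ("plus", "minus"):
            mean = base * np.where(enriched & (cond == "plus"),
                                   params.effect_size, 1.0)
            if params.noise_cv > 0:
                lfq = mean * rng.lognormal(-s2 / 2.0, np.sqrt(s2),
                                           size=params.n_proteins)
            else:
                lfq = mean.astype(float).copy()
            drop = rng.uniform(size=params.n_proteins) < params.missing_rate
            lfq[drop] = np.nan
            rows.append(pd.DataFrame({"protein": ids, "condition": cond,
                                      "experiment": exp, "lfq": lfq}))
    table = pd.concat(rows, ignore_index=True)
    return SimulatedProteome(params, table, enriched, ids)
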