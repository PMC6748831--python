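"""Localization tables: the tidy per-molecule record all stages exchange.

A localization table is a pandas DataFrame with columns

    frame      0-based acquisition frame index
    x_nm, y_nm fitted position, nanometres
    photons    integrated photon count of the fit
    sigma_nm   fitted PSF width
    precision_nm  estimated localization uncertainty (sigma/sqrt(N))
    channel    channel / species label (string)

wrapped with acquisition metadata (camera pixel size, frame count).
CSV round-trips use these names; ThunderSTORM-style headers
("x [nm]", "intensity [photon]", ...) are accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm", "precision_nm", "channel"]

_THUNDERSTORM_ALIASES = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "photons",
    "sigma [nm]": "sigma_nm",
    "uncertainty [nm]": "precision_nm",
    "uncertainty_xy [nm]": "precision_nm",
}


@dataclass
class LocalizationTable:
    """Ordered localization records plus acquisition metadata."""

    df: pd.DataFrame
    pixel_size_nm: float = 107.0
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        missing = [c for c in ("frame", "x_nm", "y_nm") if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        for col, default in (("photons", np.nan), ("sigma_nm", np.nan),
                             ("precision_nm", np.nan), ("channel", "0")):
            if col not in self.df.columns:
                self.df[col] = default
        self.df = (self.df[COLUMNS]
                   .sort_values("frame", kind="stable")
                   .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(float)

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df.copy(), self.pixel_size_nm, self.n_frames)

    def select_channel(self, channel: str) -> "LocalizationTable":
        return self.with_df(self.df[self.df["channel"] == channel])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_nm: float = 107.0,
                 n_frames: int | None = None) -> "LocalizationTable":
        df = pd.read_csv(path)
        df = df.rename(columns={c: _THUNDERSTORM_ALIASES.get(c.strip().strip('"'), c)
                                for c in df.columns})
        return cls(df, pixel_size_nm, n_frames)


def make_table(frame, x_nm, y_nm, photons=None, sigma_nm=None,
               precision_nm=None, channel="0",
               pixel_size_nm: float = 107.0,
               n_frames: int | None = None) -> LocalizationTable:
    """Convenience constructor from arrays."""
    n = len(np.atleast_1d(x_nm))
    df = pd.DataFrame({
        "frame": np.broadcast_to(np.asarray(frame), (n,)).astype(int),
        "x_nm": np.asarray(x_nm, float),
        "y_nm": np.asarray(y_nm, float),
        "photons": (np.full(n, np.nan) if photons is None
                    else np.broadcast_to(np.asarray(photons, float), (n,))),
        "sigma_nm": (np.full(n, np.nan) if sigma_nm is None
                     else np.broadcast_to(np.asarray(sigma_nm, float), (n,))),
        "precision_nm": (np.full(n, np.nan) if precision_nm is None
                         else np.broadcast_to(np.asarray(precision_nm, float), (n,))),
        "channel": np.broadcast_to(np.asarray(channel, object), (n,)),
    })
    return LocalizationTable(df, pixel_size_nm, n_frames)
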