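"""Per-site metadata: coordinates and environmental values.

A :class:`SiteTable` is a thin validated wrapper over a pandas DataFrame
indexed by site id, with ``lat``/``lon`` columns (WGS84 decimal degrees)
and any number of named environmental columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COORD_COLS = ("lat", "lon")
META_COLS = ("lat", "lon", "x_km", "y_km", "n_genotyped")


@dataclass
class SiteTable:
    df: pd.DataFrame
    env_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.df
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site ids: {dupes}")
        for c in COORD_COLS:
            if c not in df.columns:
                raise ValueError(f"SiteTable requires a '{c}' column")
        lat, lon = df["lat"].to_numpy(float), df["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude outside [-180, 180]")
        if not self.env_columns:
            self.env_columns = [c for c in df.columns if c not in META_COLS]

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.df.index]

    @property
    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of (lat, lon)."""
        return self.df[["lat", "lon"]].to_numpy(float)

    def env_values(self, columns: list[str] | None = None) -> pd.DataFrame:
        """Environmental values, validated complete for the requested columns."""
        cols = columns if columns is not None else self.env_columns
        sub = self.df[cols]
        if sub.isna().any().any():
            bad = [
                (str(site), col)
                for col in cols
                for site in sub.index[sub[col].isna()]
            ]
            raise ValueError(f"missing environmental values: {bad}")
        return sub.astype(float)

    @classmethod
    def from_csv(cls, path, env_columns: list[str] | None = None) -> "SiteTable":
        df = pd.read_csv(path, index_col="site_id")
        df.index = df.index.astype(str)
        return cls(df, env_columns or [])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="site_id")

    def __len__(self) -> int:
        return len(self.df)
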