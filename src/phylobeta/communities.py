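"""Site-by-species community tables and plot environment tables.

A :class:`CommunityTable` holds non-negative abundances of species (columns)
in plots (rows); it supplies presence sets and the relative abundances f_i
that the abundance-weighted beta-diversity metrics need.  An
:class:`EnvTable` holds one row of (latitude, longitude, altitude,
annual precipitation) per plot and yields the three between-plot
environmental distance matrices used as Mantel correlates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import PairwiseMatrix, PhyloTree

__all__ = [
    "CommunityTable",
    "EnvTable",
    "read_community",
    "read_env",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


class CommunityTable:
    """Plots x species abundance table.

    Parameters
    ----------
    df : pandas.DataFrame
        Rows are plots, columns species, values non-negative abundances
        (counts or densities).  Missing values are treated as 0.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        if df.index.duplicated().any():
            raise ValueError(
                f"duplicate plot ids: {sorted(df.index[df.index.duplicated()])}"
            )
        if df.columns.duplicated().any():
            raise ValueError("duplicate species ids")
        try:
            values = df.fillna(0.0).astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric abundance: {exc}") from exc
        if (values.values < 0).any():
            raise ValueError("negative abundances are not allowed")
        empty = values.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"plots with no individuals: {sorted(values.index[empty])}"
            )
        values.index.name = "plot"
        values.columns.name = None
        self.df = values

    @property
    def plots(self) -> list[str]:
        return list(self.df.index)

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    def abundances(self, plot: str) -> pd.Series:
        return self.df.loc[plot]

    def presence(self, plot: str) -> list[str]:
        """Species with abundance > 0 in the plot."""
        row = self.df.loc[plot]
        return list(row.index[row > 0])

    def relative_abundance(self, plot: str, mode: str = "abundance") -> pd.Series:
        """Relative abundances f_i over species present in the plot.

        ``mode="abundance"`` normalises observed abundances to sum to 1;
        ``mode="presence"`` assigns each present species f_i = 1/n, making
        presence-weighted metrics the equal-abundance special case.
        """
        row = self.df.loc[plot]
        present = row[row > 0]
        if present.empty:
            raise ValueError(f"plot {plot!r} is empty")
        if mode == "presence":
            return pd.Series(1.0 / len(present), index=present.index)
        if mode == "abundance":
            return present / present.sum()
        raise ValueError(f"unknown mode: {mode!r}")

    def check_against_tree(self, tree: PhyloTree) -> None:
        """Raise if any species in the table is missing from the tree."""
        missing = set(self.species) - set(tree.tip_labels)
        if missing:
            raise ValueError(
                f"species absent from the tree: {sorted(missing)[:10]}"
                + ("..." if len(missing) > 10 else "")
            )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="plot")

    def __repr__(self):
        return f"<CommunityTable {len(self.plots)} plots x {len(self.species)} species>"


def read_community(path_or_buf) -> CommunityTable:
    """Read a wide plots x species CSV (plot ids in the first column)."""
    df = pd.read_csv(path_or_buf, index_col=0)
    return CommunityTable(df)


_ENV_COLUMNS = ("lat", "lon", "alt_m", "precip_mm")


class EnvTable:
    """Per-plot environment: latitude, longitude, altitude, precipitation.

    Columns: ``lat`` and ``lon`` in decimal degrees, ``alt_m`` in metres,
    ``precip_mm`` in mm/yr; one row per plot.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.map(str)
        missing = [c for c in _ENV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"environment table missing columns: {missing}")
        if df.index.duplicated().any():
            raise ValueError("duplicate plot ids in environment table")
        df = df[list(_ENV_COLUMNS)].astype(float)
        if df.isna().any().any():
            raise ValueError("missing environment values are not allowed")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((df["lon"] < -180) | (df["lon"] > 360)).any():
            raise ValueError("longitude outside [-180, 360]")
        df.index.name = "plot"
        self.df = df

    @property
    def plots(self) -> list[str]:
        return list(self.df.index)

    def env_distances(self) -> dict[str, PairwiseMatrix]:
        """The three between-plot environmental distance matrices.

        Returns a dict with keys ``"geographic_km"`` (great-circle /
        haversine distance on a 6371 km sphere), ``"altitude_m"`` and
        ``"precip_mm"`` (absolute differences).
        """
        labels = self.plots
        lat = np.radians(self.df["lat"].values)
        lon = np.radians(self.df["lon"].values)
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        )
        geo = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
        np.fill_diagonal(geo, 0.0)
        out = {"geographic_km": PairwiseMatrix(labels, geo, metric_name="geographic_km")}
        for col, name in (("alt_m", "altitude_m"), ("precip_mm", "precip_mm")):
            v = self.df[col].values
            out[name] = PairwiseMatrix(
                labels, np.abs(v[:, None] - v[None, :]), metric_name=name
            )
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="plot")

    def __repr__(self):
        return f"<EnvTable {len(self.plots)} plots>"


def read_env(path_or_buf) -> EnvTable:
    """Read an environment CSV with columns plot,lat,lon,alt_m,precip_mm."""
    df = pd.read_csv(path_or_buf, index_col=0)
    return EnvTable(df)
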