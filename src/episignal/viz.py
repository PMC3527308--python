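"""Per-site parameter tables and the three geographic comparison products:
bubble map, parameter scatterplot, heat grid.

Every plotting function returns the numeric data it actually rendered
(marker sizes, colours, coordinates, the normalised matrix), so behaviour
can be asserted on data rather than pixels.  Figures are written as
PNG/SVG/PDF according to the destination extension; maps draw plain
lat/lon axes (no basemap download at run time).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import match_panel_geo  # noqa: E402
from .panel import GeoTable, TimeSeriesPanel  # noqa: E402

__all__ = ["SiteAnalysis", "build_parameter_table", "plot_map",
           "plot_scatter", "heat_grid", "PARAMETER_COLUMNS"]

#: stable column schema of the per-site parameter table; optional analyses
#: leave their columns empty rather than changing the schema
PARAMETER_COLUMNS = [
    "site", "latitude", "longitude", "group", "mean_level", "linear_trend",
    "peak_time_months", "relative_amplitude", "amplitude_flag",
    "secondary_peak_time_months", "secondary_relative_amplitude",
    "total_excess", "anomalies_above", "anomalies_below",
]


@dataclass
class SiteAnalysis:
    """Bundle of one site's analysis results feeding the parameter table."""

    mean_level: float | None = None
    linear_trend: float | None = None
    amplitudes: np.ndarray | None = None
    phases: np.ndarray | None = None
    frequencies: tuple | None = None
    peak_time_months: float | None = None
    relative_amplitude: float | None = None
    amplitude_flag: str = ""          # "", "undefined", "exceeds_1", "all_missing"
    secondary_peak_time_months: float | None = None
    secondary_relative_amplitude: float | None = None
    total_excess: float | None = None
    anomalies_above: int | None = None
    anomalies_below: int | None = None


def build_parameter_table(panel: TimeSeriesPanel, geo: GeoTable | None,
                          results: dict) -> pd.DataFrame:
    """Join per-site analysis results with geography into the export table.

    ``results`` maps site name -> :class:`SiteAnalysis`; all sites must
    have been analysed with identical options (same harmonic frequencies),
    which is checked.  Sites with undefined statistics carry an explicit
    flag instead of being silently dropped.
    """
    freq_sets = {tuple(r.frequencies) for r in results.values()
                 if r.frequencies is not None}
    if len(freq_sets) > 1:
        raise ValueError("sites were analysed with different harmonic "
                         f"frequency sets: {sorted(freq_sets)}")
    mapping = {}
    if geo is not None:
        mapping, _ = match_panel_geo(panel, geo)

    harm_cols = []
    if freq_sets:
        freqs = next(iter(freq_sets))
        for k in freqs:
            label = int(k) if float(k).is_integer() else k
            harm_cols += [f"amplitude_{label}cy", f"phase_{label}cy"]

    rows = []
    for name in panel.site_names:
        r = results.get(name, SiteAnalysis(amplitude_flag="all_missing"))
        lat, lon, group = mapping.get(name, (np.nan, np.nan, None))
        row = {
            "site": name, "latitude": lat, "longitude": lon,
            "group": group if group is not None else "",
            "mean_level": r.mean_level, "linear_trend": r.linear_trend,
            "peak_time_months": r.peak_time_months,
            "relative_amplitude": r.relative_amplitude,
            "amplitude_flag": r.amplitude_flag,
            "secondary_peak_time_months": r.secondary_peak_time_months,
            "secondary_relative_amplitude": r.secondary_relative_amplitude,
            "total_excess": r.total_excess,
            "anomalies_above": r.anomalies_above,
            "anomalies_below": r.anomalies_below,
        }
        for c in harm_cols:
            row[c] = np.nan
        if r.amplitudes is not None and freq_sets:
            for k, A, phi in zip(freqs, r.amplitudes, r.phases):
                label = int(k) if float(k).is_integer() else k
                row[f"amplitude_{label}cy"] = A
                row[f"phase_{label}cy"] = phi
        rows.append(row)
    cols = PARAMETER_COLUMNS[:6] + harm_cols + PARAMETER_COLUMNS[6:]
    cols = list(dict.fromkeys(cols))
    return pd.DataFrame(rows)[cols]


@dataclass
class RenderedPlot:
    """The numbers behind a figure, for data-level testing."""

    x: np.ndarray
    y: np.ndarray
    sizes: np.ndarray | None = None
    colors: np.ndarray | None = None
    labels: list | None = None
    matrix: np.ndarray | None = None
    row_order: list | None = None
    path: str | None = None


def _marker_areas(values: np.ndarray, min_area: float = 12.0,
                  max_area: float = 320.0) -> np.ndarray:
    """Marker areas proportional to the parameter (floored at min_area so
    near-zero values stay visible)."""
    v = np.asarray(values, dtype=float)
    vmax = np.nanmax(np.abs(v))
    if vmax == 0 or not np.isfinite(vmax):
        return np.full(v.shape, min_area)
    return np.maximum(max_area * np.abs(v) / vmax, min_area)


def _peak_time_colors(values: np.ndarray):
    """Cyclic 12-month colour scale: month 0 and month 12 share a colour."""
    cmap = plt.get_cmap("twilight")
    frac = (np.asarray(values, dtype=float) % 12.0) / 12.0
    return cmap(frac), cmap


def plot_map(table: pd.DataFrame, size_by: str = "relative_amplitude",
             color_by: str = "peak_time_months", dest=None) -> RenderedPlot:
    """Geographic bubble map: one marker per site at (lon, lat), area
    proportional to ``size_by``, colour from ``color_by`` (cyclic scale for
    peak timings, sequential otherwise)."""
    for col in ("latitude", "longitude", size_by, color_by):
        if col not in table.columns:
            raise ValueError(f"parameter {col!r} not in table; available: "
                             f"{', '.join(table.columns)}")
    ok = table["latitude"].notna() & table["longitude"].notna()
    sub = table[ok]
    if len(sub) == 0:
        raise ValueError("no geo-matched sites to map")
    sizes = _marker_areas(sub[size_by].to_numpy(dtype=float))
    cyclic = "peak_time" in color_by
    cvals = sub[color_by].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(7, 5))
    if cyclic:
        colors, cmap = _peak_time_colors(cvals)
        sc = ax.scatter(sub["longitude"], sub["latitude"], s=sizes,
                        c=cvals % 12.0, cmap=cmap, vmin=0, vmax=12,
                        edgecolors="k", linewidths=0.4)
        fig.colorbar(sc, ax=ax, label=f"{color_by} (cyclic, months)")
    else:
        sc = ax.scatter(sub["longitude"], sub["latitude"], s=sizes,
                        c=cvals, cmap="viridis", edgecolors="k",
                        linewidths=0.4)
        colors = sc.to_rgba(cvals)
        fig.colorbar(sc, ax=ax, label=color_by)
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    ax.set_title(f"size: {size_by}")
    path = None
    if dest is not None:
        fig.savefig(dest, bbox_inches="tight")
        path = str(dest)
    plt.close(fig)
    return RenderedPlot(x=sub["longitude"].to_numpy(),
                        y=sub["latitude"].to_numpy(),
                        sizes=sizes, colors=np.asarray(colors),
                        labels=sub["site"].tolist(), path=path)


def plot_scatter(table: pd.DataFrame, x: str = "latitude",
                 y: str = "peak_time_months", size_by: str | None = None,
                 color_by: str | None = "group", labels: bool = False,
                 dest=None) -> RenderedPlot:
    """Parameter-vs-parameter scatterplot (e.g. peak timing vs latitude),
    optionally sized by a third parameter, coloured by group, with per-site
    labels."""
    for col in (x, y) + ((size_by,) if size_by else ()):
        if col not in table.columns:
            raise ValueError(f"parameter {col!r} not in table; available: "
                             f"{', '.join(table.columns)}")
    xs = table[x].to_numpy(dtype=float)
    ys = table[y].to_numpy(dtype=float)
    sizes = _marker_areas(table[size_by].to_numpy(dtype=float)) \
        if size_by else np.full(len(table), 48.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if color_by and color_by in table.columns and \
            table[color_by].notna().any() and table[color_by].dtype == object:
        groups = table[color_by].fillna("").astype(str)
        for g in sorted(groups.unique()):
            m = (groups == g).to_numpy()
            ax.scatter(xs[m], ys[m], s=sizes[m], label=g or "(none)",
                       edgecolors="k", linewidths=0.3)
        ax.legend(title=color_by, fontsize=8)
    else:
        ax.scatter(xs, ys, s=sizes, edgecolors="k", linewidths=0.3)
    drawn_labels = None
    if labels:
        drawn_labels = table["site"].tolist()
        for xi, yi, name in zip(xs, ys, drawn_labels):
            if np.isfinite(xi) and np.isfinite(yi):
                ax.annotate(str(name), (xi, yi), fontsize=7,
                            xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    path = None
    if dest is not None:
        fig.savefig(dest, bbox_inches="tight")
        path = str(dest)
    plt.close(fig)
    return RenderedPlot(x=xs, y=ys, sizes=sizes, labels=drawn_labels,
                        path=path)


def heat_grid(panel: TimeSeriesPanel, geo: GeoTable | None = None,
              order_by: str = "latitude",
              normalize: str = "per_series_minmax",
              dest=None) -> RenderedPlot:
    """Sites-by-time heat grid: rows are series (latitude-descending or
    input order), columns are time, colour from the normalised value.

    Returns the exact matrix rendered.  Normalisations: ``none`` (raw
    values), ``per_series_minmax`` (each row to [0, 1] — the default, since
    cross-site magnitudes often differ by orders of magnitude),
    ``per_series_z`` (each row standardised).
    """
    if panel.n_sites < 2:
        raise ValueError("heat grid needs at least 2 series")
    if order_by == "latitude":
        if geo is None:
            raise ValueError("order_by='latitude' requires a geolocation "
                             "table")
        mapping, _ = match_panel_geo(panel, geo)
        order = sorted(mapping, key=lambda s: -mapping[s][0])
        missing_geo = [s for s in panel.site_names if s not in mapping]
        order += missing_geo
    elif order_by == "column_order":
        order = list(panel.site_names)
    else:
        raise ValueError(f"unknown order_by {order_by!r}")

    idx = [panel.site_names.index(s) for s in order]
    mat = panel.values[:, idx].T.astype(float).copy()
    if normalize == "per_series_minmax":
        for i in range(mat.shape[0]):
            row = mat[i]
            lo, hi = np.nanmin(row), np.nanmax(row)
            if hi > lo:
                mat[i] = (row - lo) / (hi - lo)
            else:
                mat[i] = np.zeros_like(row)
    elif normalize == "per_series_z":
        for i in range(mat.shape[0]):
            row = mat[i]
            sd = np.nanstd(row)
            mat[i] = (row - np.nanmean(row)) / sd if sd > 0 \
                else np.zeros_like(row)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")

    fig, ax = plt.subplots(figsize=(8, 0.35 * len(order) + 1.5))
    im = ax.imshow(mat, aspect="auto", interpolation="nearest",
                   cmap="inferno",
                   extent=(panel.time[0], panel.time[-1],
                           len(order) - 0.5, -0.5))
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=7)
    ax.set_xlabel("year")
    fig.colorbar(im, ax=ax, label=f"value ({normalize})")
    path = None
    if dest is not None:
        fig.savefig(dest, bbox_inches="tight")
        path = str(dest)
    plt.close(fig)
    return RenderedPlot(x=panel.time, y=np.arange(len(order)),
                        matrix=mat, row_order=order, path=path)
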