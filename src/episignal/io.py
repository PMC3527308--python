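"""Readers and writers for the two input layouts and the parameter export.

Time-series layout: one header row; column 1 = year, column 2 = within-year
unit, columns 3..N = one observation series per site/category.  Geolocation
layout: headerless, columns = site name, latitude, longitude[, group].  CSV
is the canonical dialect; .xlsx workbooks carry the same layout, with sheets
providing an optional third dimension (e.g. age groups).

The readers validate and *report* — they never reorder rows or fill gaps.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .panel import (GeoTable, PanelFormatError, TimeSeriesPanel,
                    ValidationReport, validate_calendar)

#: cell tokens accepted as a missing observation
MISSING_TOKENS = ("", "NaN", "nan", "NA", "na", "N/A")

_EXCEL_SUFFIXES = (".xlsx", ".xlsm", ".xls", ".ods")


def _is_workbook(source) -> bool:
    return isinstance(source, (str, os.PathLike)) and \
        str(source).lower().endswith(_EXCEL_SUFFIXES)


def _read_raw(source, sheet, header):
    kwargs = dict(header=header, dtype=object,
                  na_values=list(MISSING_TOKENS), keep_default_na=False)
    if _is_workbook(source):
        return pd.read_excel(source, sheet_name=sheet if sheet is not None else 0,
                             **kwargs)
    return pd.read_csv(source, skipinitialspace=True, **kwargs)


def _parse_int_column(col, colname: str, report: ValidationReport):
    out = np.zeros(len(col), dtype=int)
    for i, v in enumerate(col):
        try:
            f = float(v)
            if not float(f).is_integer():
                raise ValueError
            out[i] = int(f)
        except (TypeError, ValueError):
            report.add("error", f"row {i + 2}, column '{colname}'",
                       f"expected an integer, found {v!r}")
    return out


def scan_timeseries(source, sheet=None, periodicity_hint: int | None = None):
    """Parse and validate a time-series table.

    Returns ``(panel_or_None, ValidationReport)``; the panel is None when any
    error-severity issue was found.
    """
    report = ValidationReport()
    raw = _read_raw(source, sheet, header=0)
    if raw.shape[1] < 3:
        report.add("error", "header",
                   f"need >= 3 columns (year, subunit, series...), "
                   f"found {raw.shape[1]}")
        return None, report
    if raw.shape[0] == 0:
        report.add("error", "table", "no data rows")
        return None, report
    if raw.iloc[:, 0].isna().any() or raw.iloc[:, 1].isna().any():
        i = int(np.flatnonzero(raw.iloc[:, 0].isna() | raw.iloc[:, 1].isna())[0])
        report.add("error", f"row {i + 2}", "missing year or subunit value")
        return None, report
    years = _parse_int_column(raw.iloc[:, 0].tolist(), raw.columns[0], report)
    subunits = _parse_int_column(raw.iloc[:, 1].tolist(), raw.columns[1], report)
    if not report.ok:
        return None, report

    P = int(periodicity_hint) if periodicity_hint else int(subunits.max())
    if periodicity_hint and subunits.max() > periodicity_hint:
        report.add("error", "periodicity",
                   f"data contain subunit {subunits.max()} but the declared "
                   f"periodicity is {periodicity_hint}")
        return None, report
    if P >= 52 and (subunits == 53).any():
        report.add("warning", "calendar",
                   "week-53 rows present; they are kept and handled through "
                   "fractional-year time")

    validate_calendar(years, subunits, max(P, int(subunits.max())), report)
    if not report.ok:
        return None, report

    site_names = [str(c).strip() for c in raw.columns[2:]]
    values = np.full((len(raw), len(site_names)), np.nan)
    for j, col in enumerate(raw.columns[2:]):
        for i, v in enumerate(raw[col].tolist()):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                values[i, j] = float(v)
            except (TypeError, ValueError):
                report.add("error", f"row {i + 2}, column '{site_names[j]}'",
                           f"non-numeric cell {v!r}")
    if not report.ok:
        return None, report
    panel = TimeSeriesPanel(years=years, subunits=subunits, periodicity=P,
                            site_names=site_names, values=values,
                            sheet_label=str(sheet) if sheet is not None else None)
    return panel, report


def read_timeseries_table(source, sheet=None,
                          periodicity_hint: int | None = None) -> TimeSeriesPanel:
    """Read a time-series table, raising :class:`PanelFormatError` on any
    layout violation (non-ascending rows, calendar gaps, non-numeric cells,
    fewer than two complete years)."""
    panel, report = scan_timeseries(source, sheet=sheet,
                                    periodicity_hint=periodicity_hint)
    if panel is None:
        raise PanelFormatError(report.as_text())
    return panel


def read_geolocation_table(source) -> GeoTable:
    """Read a headerless geolocation table (site, lat, lon[, group])."""
    raw = _read_raw(source, sheet=None, header=None)
    if raw.shape[1] not in (3, 4):
        raise PanelFormatError(
            f"geolocation table must have 3 or 4 columns, found {raw.shape[1]}")
    names = [str(v).strip() for v in raw.iloc[:, 0].tolist()]

    def _floats(col, what):
        out = np.zeros(len(col))
        for i, v in enumerate(col):
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                raise PanelFormatError(
                    f"row {i + 1}: non-numeric {what} {v!r}") from None
        return out

    lats = _floats(raw.iloc[:, 1].tolist(), "latitude")
    lons = _floats(raw.iloc[:, 2].tolist(), "longitude")
    groups = None
    if raw.shape[1] == 4:
        groups = ["" if (g is None or (isinstance(g, float) and np.isnan(g)))
                  else str(g).strip() for g in raw.iloc[:, 3].tolist()]
    return GeoTable(site_names=names, latitudes=lats, longitudes=lons,
                    groups=groups)


def match_panel_geo(panel: TimeSeriesPanel, geo: GeoTable):
    """Join panel sites with geography by exact name match after trimming
    surrounding whitespace.

    Returns ``(mapping, report)``: mapping site name (as it appears in the
    panel) -> (lat, lon, group).  Panel sites absent from the geolocation
    table are a warning and are excluded from spatial outputs; zero matches
    is an error.
    """
    report = ValidationReport()
    geo_names = {n.strip(): i for i, n in enumerate(geo.site_names)}
    mapping: dict[str, tuple[float, float, str | None]] = {}
    for name in panel.site_names:
        key = name.strip()
        if key in geo_names:
            i = geo_names[key]
            group = geo.groups[i] if geo.groups is not None else None
            mapping[name] = (float(geo.latitudes[i]),
                             float(geo.longitudes[i]), group)
        else:
            report.add("warning", f"site '{name}'",
                       "no geolocation entry; excluded from spatial outputs")
    if not mapping:
        report.add("error", "geolocation", "no sites matched between the "
                   "time-series and geolocation tables")
        raise PanelFormatError(report.as_text())
    return mapping, report


def write_timeseries_table(panel: TimeSeriesPanel, dest) -> None:
    """Write a panel back to CSV in the canonical layout (round-trip safe)."""
    df = pd.DataFrame({"year": panel.years, panel_subunit_name(panel): panel.subunits})
    for j, name in enumerate(panel.site_names):
        df[name] = panel.values[:, j]
    df.to_csv(dest, index=False, float_format="%.12g", na_rep="NaN")


def panel_subunit_name(panel: TimeSeriesPanel) -> str:
    return {12: "month", 52: "week", 53: "week", 365: "day", 366: "day"}.get(
        panel.periodicity, "subunit")


def write_parameter_table(table: pd.DataFrame, dest) -> None:
    """Export a per-site parameter table as CSV, one row per site.

    Numeric values are written with enough digits (%.12g) that a read-back
    reproduces them to better than 1e-9 relative.
    """
    if table is None or len(table) == 0:
        raise ValueError("parameter table is empty; nothing to write")
    table.to_csv(dest, index=False, float_format="%.12g")


def read_parameter_table(source) -> pd.DataFrame:
    return pd.read_csv(source)
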