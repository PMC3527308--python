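"""Core data containers: the multi-site time-series panel and the geolocation table.

A panel is a rectangular block of observations indexed by a gap-free integer
calendar: one row per (year, within-year unit) pair, one column per site or
category.  The within-year unit runs 1..P where P is the periodicity (12 for
monthly data, 52 for weekly).  Missing observations are NaN; missing *rows*
are not allowed — the calendar must be contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PanelFormatError(ValueError):
    """Raised when an input table violates the panel layout contract."""


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    locus: str     # human-readable row/column location
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.locus}: {self.message}"


@dataclass
class ValidationReport:
    """Outcome of validating an input table: ok iff no error-severity issue."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, locus: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, locus, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def as_text(self) -> str:
        if not self.issues:
            return "OK: no issues found\n"
        return "\n".join(str(i) for i in self.issues) + "\n"


def fractional_year(years, subunits, periodicity: int) -> np.ndarray:
    """Map integer calendar to fractional-year time: year + (subunit - 0.5)/P.

    The half-unit offset places each observation at the centre of its
    within-year interval (mid-January for monthly subunit 1, etc.).
    """
    years = np.asarray(years, dtype=float)
    subunits = np.asarray(subunits, dtype=float)
    return years + (subunits - 0.5) / periodicity


@dataclass
class TimeSeriesPanel:
    """Multi-site observation matrix with its integer calendar.

    Parameters
    ----------
    years, subunits : integer vectors, one entry per row.
    periodicity : number of sub-year units per year (P).
    site_names : one name per value column.
    values : float matrix, shape (n_rows, n_sites); NaN marks missing.
    sheet_label : optional third-dimension category label (e.g. an age group).
    """

    years: np.ndarray
    subunits: np.ndarray
    periodicity: int
    site_names: list[str]
    values: np.ndarray
    sheet_label: str | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.subunits = np.asarray(self.subunits, dtype=int)
        self.site_names = [str(s) for s in self.site_names]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.years) != 1:
            self.values = self.values.T
        report = validate_calendar(self.years, self.subunits, self.periodicity)
        if self.values.shape != (len(self.years), len(self.site_names)):
            report.add("error", "values",
                       f"value matrix shape {self.values.shape} does not match "
                       f"{len(self.years)} rows x {len(self.site_names)} sites")
        if not report.ok:
            raise PanelFormatError(report.as_text())

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.years)

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def time(self) -> np.ndarray:
        """Fractional-year time axis (centre-of-interval convention)."""
        return fractional_year(self.years, self.subunits, self.periodicity)

    def series(self, site) -> np.ndarray:
        """One site's observation vector, selected by name or column index."""
        if isinstance(site, str):
            site = self.site_names.index(site)
        return self.values[:, site]

    def complete_years(self) -> np.ndarray:
        """Calendar years for which all P subunits are present."""
        out = []
        for y in np.unique(self.years):
            subs = self.subunits[self.years == y]
            if len(np.unique(subs)) >= self.periodicity:
                out.append(y)
        return np.asarray(out, dtype=int)

    def row_index(self, year: int, subunit: int) -> int:
        hits = np.flatnonzero((self.years == year) & (self.subunits == subunit))
        if len(hits) != 1:
            raise KeyError(f"({year}, {subunit}) not on the panel calendar")
        return int(hits[0])


def validate_calendar(years, subunits, periodicity: int,
                      report: ValidationReport | None = None) -> ValidationReport:
    """Check the calendar invariants: ascending, gap-free, subunits in 1..P,
    at least two complete years.  Issues are reported, never repaired."""
    rep = report if report is not None else ValidationReport()
    years = np.asarray(years, dtype=int)
    subunits = np.asarray(subunits, dtype=int)
    P = int(periodicity)
    if P < 2:
        rep.add("error", "periodicity", f"periodicity must be >= 2, got {P}")
        return rep
    bad = (subunits < 1) | (subunits > P)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rep.add("error", f"row {i + 1}",
                f"subunit {subunits[i]} outside 1..{P}")
        return rep
    # strictly ascending in (year, subunit)
    key = years * (P + 1) + subunits
    if len(key) > 1:
        diffs = np.diff(key)
        if (diffs <= 0).any():
            i = int(np.flatnonzero(diffs <= 0)[0]) + 1
            rep.add("error", f"row {i + 1}",
                    "rows not in ascending chronological order "
                    f"(({years[i]}, {subunits[i]}) follows "
                    f"({years[i - 1]}, {subunits[i - 1]}))")
            return rep
    # gap-free: every (year, subunit) between first and last present
    expect_y, expect_s = int(years[0]), int(subunits[0])
    for i in range(len(years)):
        if (years[i], subunits[i]) != (expect_y, expect_s):
            rep.add("error", f"row {i + 1}",
                    f"calendar gap: expected ({expect_y}, {expect_s}) "
                    f"but found ({years[i]}, {subunits[i]})")
            return rep
        expect_s += 1
        if expect_s > P:
            expect_s = 1
            expect_y += 1
    # at least 2 complete years
    n_complete = 0
    for y in np.unique(years):
        if (years == y).sum() >= P:
            n_complete += 1
    if n_complete < 2:
        rep.add("error", "calendar",
                f"at least 2 complete years required, found {n_complete}")
    return rep


@dataclass
class GeoTable:
    """Site coordinates (decimal degrees) with optional group labels."""

    site_names: list[str]
    latitudes: np.ndarray
    longitudes: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.site_names = [str(s).strip() for s in self.site_names]
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        if len(set(self.site_names)) != len(self.site_names):
            dupes = sorted({s for s in self.site_names
                            if self.site_names.count(s) > 1})
            raise PanelFormatError(f"duplicate site name(s) in geolocation "
                                   f"table: {', '.join(dupes)}")
        if not (len(self.site_names) == len(self.latitudes)
                == len(self.longitudes)):
            raise PanelFormatError("geolocation columns have unequal lengths")
        bad_lat = np.flatnonzero(np.abs(self.latitudes) > 90)
        if len(bad_lat):
            i = int(bad_lat[0])
            raise PanelFormatError(
                f"latitude {self.latitudes[i]} for site "
                f"'{self.site_names[i]}' outside [-90, 90]")
        bad_lon = np.flatnonzero(np.abs(self.longitudes) > 180)
        if len(bad_lon):
            i = int(bad_lon[0])
            raise PanelFormatError(
                f"longitude {self.longitudes[i]} for site "
                f"'{self.site_names[i]}' outside [-180, 180]")
        if self.groups is not None:
            self.groups = [str(g).strip() for g in self.groups]
            if len(self.groups) != len(self.site_names):
                raise PanelFormatError("group column length mismatch")

    def lookup(self, name: str):
        i = self.site_names.index(name.strip())
        group = self.groups[i] if self.groups is not None else None
        return float(self.latitudes[i]), float(self.longitudes[i]), group
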