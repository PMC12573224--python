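"""Reading, writing and validating multi-site tree-ring networks.

Ring widths travel in the Tucson (``.rwl``) decadal format or a long-format
CSV; site metadata (coordinates, SDM projection group, stand age) in a flat
CSV.  The in-memory containers are small dataclasses; a :class:`Network`
joins width series to site metadata and is the input of every downstream
stage.

Conventions
-----------
* Calendar years are CE integers; the ring formed in year ``t`` is indexed
  ``t`` (Schulman convention for the Northern Hemisphere).
* Widths are stored in millimetres.  Missing rings (encoded ``0`` in
  Tucson files) are stored as NaN and excluded from correlations; zero
  widths would break ratio detrending.
* Tucson values are integers whose unit is inferred per series from the
  stop marker: ``-9999`` (or a ``9990``-padded tail) means 0.01 mm,
  ``999`` means 0.001 mm.  An explicit ``units=`` override is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SDM_GROUPS = ("contraction", "persistence")

#: Minimum number of trees for a usable running-rbar window (see synchrony).
MIN_TREES_RBAR = 6

#: Minimum years of overlap with the climate record for correlations.
MIN_CLIMATE_OVERLAP = 20


class RwlParseError(ValueError):
    """Raised when a Tucson file cannot be decoded."""


@dataclass
class RingWidthSeries:
    """Ring widths of one tree (or core), on a contiguous year axis.

    ``widths[i]`` is the ring formed in calendar year ``first_year + i``,
    in mm; NaN marks a locally absent (missing) ring.
    """

    tree_id: str
    site_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValueError(f"{self.tree_id}: widths must be a non-empty 1-d array")
        finite = self.widths[np.isfinite(self.widths)]
        if finite.size and (finite <= 0).any():
            raise ValueError(f"{self.tree_id}: non-missing widths must be > 0 mm")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class SiteMeta:
    """Metadata of one study plot."""

    site_id: str
    latitude: float
    longitude: float
    sdm_group: str
    stand_age: float
    n_trees: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.site_id}: longitude {self.longitude} out of range")
        if self.sdm_group not in SDM_GROUPS:
            raise ValueError(
                f"{self.site_id}: unknown sdm_group {self.sdm_group!r}; "
                f"expected one of {SDM_GROUPS}"
            )
        if self.n_trees < 1:
            raise ValueError(f"{self.site_id}: n_trees must be >= 1")


@dataclass
class Network:
    """A multi-site tree-ring network: width series joined to site metadata."""

    series: list[RingWidthSeries]
    sites: dict[str, SiteMeta]

    def __post_init__(self) -> None:
        known = set(self.sites)
        for s in self.series:
            if s.site_id not in known:
                raise ValueError(f"series {s.tree_id}: unknown site {s.site_id!r}")
        populated = {s.site_id for s in self.series}
        empty = known - populated
        if empty:
            raise ValueError(f"sites without any series: {sorted(empty)}")

    def site_series(self, site_id: str) -> list[RingWidthSeries]:
        return [s for s in self.series if s.site_id == site_id]

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.sites)


@dataclass
class ValidationReport:
    n_series: int
    n_sites: int
    site_year_coverage: dict[str, tuple[int, int]]
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


# ---------------------------------------------------------------------------
# Tucson / .rwl
# ---------------------------------------------------------------------------

_STOP_001 = 999        # stop marker under the 0.001 mm dialect
_STOP_01 = -9999       # stop marker under the 0.01 mm dialect


def _detect_scale(values: list[int]) -> float:
    """Infer mm-per-unit from the stop marker convention of one series."""
    if values and values[-1] == _STOP_001:
        return 0.001
    # -9999 anywhere at the tail, or 9990-padded tail, signals 0.01 mm
    return 0.01


def read_rwl(
    path: str | Path,
    site_id: str | None = None,
    units: float | None = None,
) -> list[RingWidthSeries]:
    """Read a Tucson decadal file into :class:`RingWidthSeries`.

    Parameters
    ----------
    path
        Tucson file; each line ``<series-id> <decade-year> <v1> ... <v10>``.
    site_id
        Site assigned to every series; defaults to the file stem.
    units
        Override the per-series unit inference (mm per integer unit,
        e.g. ``0.01``); by default the stop marker decides.
    """
    path = Path(path)
    if site_id is None:
        site_id = path.stem
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise RwlParseError(f"{path}:{lineno}: too few fields")
            sid = tokens[0]
            try:
                year = int(tokens[1])
                vals = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise RwlParseError(f"{path}:{lineno}: malformed decade line: {exc}") from None
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((year, vals, lineno))

    out: list[RingWidthSeries] = []
    seen: set[str] = set()
    for sid in order:
        if sid in seen:
            raise RwlParseError(f"{path}: duplicate series id {sid!r}")
        seen.add(sid)
        chunks = sorted(raw[sid], key=lambda c: c[0])
        first_year = chunks[0][0]
        values: list[int] = []
        expect = first_year
        for year, vals, lineno in chunks:
            if year != expect:
                raise RwlParseError(
                    f"{path}:{lineno}: series {sid!r} expected decade starting "
                    f"{expect}, found {year}"
                )
            values.extend(vals)
            expect = year + len(vals)
        scale = units if units is not None else _detect_scale(values)
        # strip exactly one stop marker, then trailing 9990 padding
        if values and values[-1] in (_STOP_001, _STOP_01):
            values.pop()
        while values and values[-1] == 9990 and scale == 0.01:
            values.pop()
        widths = np.array(
            [np.nan if v == 0 else v * scale for v in values], dtype=float
        )
        finite = widths[np.isfinite(widths)]
        if finite.size and (finite <= 0).any():
            raise RwlParseError(f"{path}: series {sid!r} has non-positive widths")
        out.append(RingWidthSeries(sid, site_id, first_year, widths))
    return out


def write_rwl(
    series: Iterable[RingWidthSeries],
    path: str | Path,
    units: float = 0.01,
) -> None:
    """Write series to a Tucson decadal file (default dialect 0.01 mm,
    stop marker ``-9999``; ``units=0.001`` switches to the ``999`` dialect).
    """
    path = Path(path)
    stop = _STOP_001 if units == 0.001 else _STOP_01
    lines: list[str] = []
    for s in series:
        if len(s.tree_id) > 8:
            raise ValueError(f"series id {s.tree_id!r} exceeds 8 characters")
        ints: list[int] = []
        for w in s.widths:
            if np.isnan(w):
                ints.append(0)
                continue
            v = int(round(w / units))
            if v >= 100000 or w > 9999.0:
                raise ValueError(
                    f"{s.tree_id}: width {w} mm overflows the Tucson field"
                )
            ints.append(v)
        ints.append(stop)
        year = s.first_year
        i = 0
        while i < len(ints):
            # each line runs to the end of the calendar decade
            n = 10 - (year % 10) if i == 0 else 10
            chunk = ints[i : i + n]
            fields = "".join(f"{v:6d}" for v in chunk)
            lines.append(f"{s.tree_id:<8s}{year:4d}{fields}")
            year += len(chunk)
            i += len(chunk)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# CSV carriers
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["site_id", "lat", "lon", "sdm_group", "stand_age", "n_trees"]


def read_site_table(path: str | Path) -> dict[str, SiteMeta]:
    """Read the site metadata CSV (columns ``site_id, lat, lon, sdm_group,
    stand_age, n_trees``) into a dict keyed by site id."""
    df = pd.read_csv(path)
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"{path}: duplicate site_id {dups}")
    if df[["lat", "lon"]].isna().any().any():
        raise ValueError(f"{path}: missing latitude/longitude values")
    sites: dict[str, SiteMeta] = {}
    for row in df.itertuples(index=False):
        meta = SiteMeta(
            site_id=str(row.site_id),
            latitude=float(row.lat),
            longitude=float(row.lon),
            sdm_group=str(row.sdm_group),
            stand_age=float(row.stand_age),
            n_trees=int(row.n_trees),
        )
        sites[meta.site_id] = meta
    return sites


def write_site_table(sites: Mapping[str, SiteMeta], path: str | Path) -> None:
    rows = [
        {
            "site_id": m.site_id,
            "lat": m.latitude,
            "lon": m.longitude,
            "sdm_group": m.sdm_group,
            "stand_age": m.stand_age,
            "n_trees": m.n_trees,
        }
        for m in sites.values()
    ]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, index=False)


def read_long_csv(path: str | Path) -> list[RingWidthSeries]:
    """Read long-format ring widths (``site_id, tree_id, year, width_mm``).

    Years need not be contiguous in the file; interior gaps become missing
    rings (NaN).
    """
    df = pd.read_csv(path)
    required = ["site_id", "tree_id", "year", "width_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: list[RingWidthSeries] = []
    for (site, tree), grp in df.groupby(["site_id", "tree_id"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(np.unique(years)) != len(years):
            raise ValueError(f"{path}: duplicate year for tree {tree!r}")
        first, last = int(years[0]), int(years[-1])
        widths = np.full(last - first + 1, np.nan)
        widths[years - first] = grp["width_mm"].to_numpy(dtype=float)
        out.append(RingWidthSeries(str(tree), str(site), first, widths))
    return out


def write_long_csv(series: Iterable[RingWidthSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for year, w in zip(s.years, s.widths):
            if not math.isnan(w):
                rows.append(
                    {"site_id": s.site_id, "tree_id": s.tree_id,
                     "year": int(year), "width_mm": float(w)}
                )
    pd.DataFrame(rows, columns=["site_id", "tree_id", "year", "width_mm"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Network assembly and validation
# ---------------------------------------------------------------------------

def build_network(
    series: Sequence[RingWidthSeries], sites: Mapping[str, SiteMeta]
) -> Network:
    return Network(series=list(series), sites=dict(sites))


def validate_network(net: Network, climate_start: int | None = None) -> ValidationReport:
    """Sanity-check a network; never mutates the input.

    Flags series without usable overlap with the climate record (needed for
    any correlation) and sites too small for the running-rbar minimum.
    """
    coverage: dict[str, tuple[int, int]] = {}
    flags: list[str] = []
    for sid in net.site_ids:
        members = net.site_series(sid)
        first = min(s.first_year for s in members)
        last = max(s.last_year for s in members)
        coverage[sid] = (first, last)
        if len(members) < MIN_TREES_RBAR:
            flags.append(
                f"site {sid}: {len(members)} trees, below minimum for rbar "
                f"({MIN_TREES_RBAR})"
            )
    if climate_start is not None:
        for s in net.series:
            if s.last_year < climate_start:
                flags.append(f"series {s.tree_id}: no climate overlap")
            elif s.last_year - max(s.first_year, climate_start) + 1 < MIN_CLIMATE_OVERLAP:
                flags.append(
                    f"series {s.tree_id}: climate overlap below "
                    f"{MIN_CLIMATE_OVERLAP} years"
                )
    return ValidationReport(
        n_series=len(net.series),
        n_sites=len(net.sites),
        site_year_coverage=coverage,
        flags=flags,
    )
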