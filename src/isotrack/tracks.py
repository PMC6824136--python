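"""Geolocator track ingestion, filtering and utilisation surfaces.

Light-level geolocation fixes carry large errors (order 100 km) and two
known failure modes: latitudes are unusable around the equinoxes, and
single-fix jumps can imply impossible travel speeds.  This module removes
both, gates tracks on moult-season residency inside a study region, and
summarises populations of fixes as binned Gaussian kernel-density surfaces
that later serve as spatial priors.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .grid import GridSpec, GridSurface

__all__ = [
    "Fix",
    "Track",
    "MoultWindow",
    "RegionPolygon",
    "Residency",
    "DEFAULT_EQUINOX_WINDOWS",
    "DEFAULT_MOULT_WINDOWS",
    "NORTH_SEA_BBOX",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "filter_equinox",
    "filter_speed",
    "moult_residency",
    "nrd_bandwidth",
    "kde_surface",
    "scale_surface",
    "difference_surface",
    "overlap_percent",
]

EARTH_RADIUS_KM = 6371.0

#: Year-agnostic (month, day) windows during which latitude estimates from
#: day length are unreliable and fixes are discarded.
DEFAULT_EQUINOX_WINDOWS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((9, 10), (10, 18)),
    ((2, 20), (4, 2)),
)


@dataclass(frozen=True)
class Fix:
    individual_id: str
    date: dt.date
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


@dataclass
class Track:
    individual_id: str
    species: str
    winter: str
    fixes: list[Fix] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fix in self.fixes:
            if fix.individual_id != self.individual_id:
                raise ValueError(
                    f"fix individual {fix.individual_id!r} does not match "
                    f"track {self.individual_id!r}"
                )
        dates = [f.date for f in self.fixes]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("fix dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    def with_fixes(self, fixes: Sequence[Fix]) -> "Track":
        return replace(self, fixes=list(fixes))


@dataclass(frozen=True)
class MoultWindow:
    """Calendar months during which one feather type is grown."""

    species: str
    feather_type: str
    months: frozenset[int]

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("moult window needs at least one month")
        if not all(1 <= m <= 12 for m in self.months):
            raise ValueError("months must be in 1..12")


#: Post-breeding body moult (Jul-Sep) and pre-breeding cheek moult.
DEFAULT_MOULT_WINDOWS: dict[tuple[str, str], MoultWindow] = {
    ("puffin", "body"): MoultWindow("puffin", "body", frozenset({7, 8, 9})),
    ("puffin", "cheek"): MoultWindow("puffin", "cheek", frozenset({1, 2, 3})),
    ("razorbill", "body"): MoultWindow("razorbill", "body", frozenset({7, 8, 9})),
    ("razorbill", "cheek"): MoultWindow(
        "razorbill", "cheek", frozenset({12, 1, 2, 3})
    ),
}


class RegionPolygon:
    """Named closed polygon in lon/lat degrees (points on the edge count as
    inside; fixes over land are *not* excluded — coastal species bias)."""

    def __init__(self, name: str, vertices: Iterable[tuple[float, float]]):
        self.name = name
        self.polygon = Polygon(vertices)
        if not self.polygon.is_valid:
            raise ValueError(f"region {name!r}: polygon is invalid")

    @classmethod
    def bbox(
        cls, name: str, lon_min: float, lat_min: float, lon_max: float, lat_max: float
    ) -> "RegionPolygon":
        return cls(
            name,
            [
                (lon_min, lat_min),
                (lon_max, lat_min),
                (lon_max, lat_max),
                (lon_min, lat_max),
            ],
        )

    def contains(self, lon: float, lat: float) -> bool:
        pt = Point(lon, lat)
        return bool(self.polygon.contains(pt) or self.polygon.touches(pt))


#: Default study-region bounding box (configurable; the source region is
#: never defined as a formal polygon).
NORTH_SEA_BBOX = RegionPolygon.bbox("North Sea", -4.0, 51.0, 10.0, 62.0)


class Residency(Enum):
    RESIDENT = "resident"
    NON_RESIDENT = "non_resident"
    INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# filtering


def _in_window(
    date: dt.date, window: tuple[tuple[int, int], tuple[int, int]]
) -> bool:
    (m0, d0), (m1, d1) = window
    md = (date.month, date.day)
    if (m0, d0) <= (m1, d1):
        return (m0, d0) <= md <= (m1, d1)
    # window wraps the new year, e.g. (12, 20)-(1, 5)
    return md >= (m0, d0) or md <= (m1, d1)


def filter_equinox(
    track: Track,
    windows: Sequence[tuple[tuple[int, int], tuple[int, int]]] = DEFAULT_EQUINOX_WINDOWS,
) -> Track:
    """Drop fixes dated inside any of the year-agnostic (month, day) windows."""
    kept = [
        fix
        for fix in track.fixes
        if not any(_in_window(fix.date, w) for w in windows)
    ]
    return track.with_fixes(kept)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on a 6371 km sphere."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def filter_speed(track: Track, max_kmday: float = 500.0) -> Track:
    """Forward scan dropping fixes implying travel faster than ``max_kmday``.

    The first fix is always retained; each subsequent fix is compared against
    the last *retained* fix.  Automated, reproducible stand-in for visual
    outlier screening.
    """
    if max_kmday <= 0:
        raise ValueError("max_kmday must be > 0")
    if len(track.fixes) <= 1:
        return track.with_fixes(track.fixes)
    kept = [track.fixes[0]]
    for fix in track.fixes[1:]:
        prev = kept[-1]
        days = (fix.date - prev.date).days
        dist = haversine_km(prev.lon, prev.lat, fix.lon, fix.lat)
        if dist / max(days, 1) <= max_kmday:
            kept.append(fix)
    return track.with_fixes(kept)


def moult_residency(
    track: Track, window: MoultWindow, region: RegionPolygon
) -> Residency:
    """Whether every fix dated in the moult months lies inside ``region``.

    Returns ``Residency.INDETERMINATE`` when the track has no fixes in the
    window months (residency cannot be established either way).
    """
    if not track.fixes:
        raise ValueError("track is empty")
    in_window = [f for f in track.fixes if f.date.month in window.months]
    if not in_window:
        return Residency.INDETERMINATE
    if all(region.contains(f.lon, f.lat) for f in in_window):
        return Residency.RESIDENT
    return Residency.NON_RESIDENT


# ---------------------------------------------------------------------------
# kernel density


def nrd_bandwidth(values: Sequence[float]) -> float:
    """Normal-reference-distribution bandwidth.

    ``1.06 * min(sd, IQR / 1.34) * n ** (-1/5)`` with the sample standard
    deviation (ddof=1) and linear-interpolation quartiles.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        raise ValueError("degenerate spread: values have no usable dispersion")
    return 1.06 * spread * x.size ** (-1 / 5)


def _pooled_lonlat(tracks: Iterable[Track]) -> tuple[np.ndarray, np.ndarray]:
    lons, lats = [], []
    for track in tracks:
        for fix in track.fixes:
            lons.append(fix.lon)
            lats.append(fix.lat)
    return np.asarray(lons), np.asarray(lats)


def kde_surface(
    tracks: Sequence[Track],
    bandwidth: float,
    grid: GridSpec,
    chunk: int = 512,
) -> GridSurface:
    """Gaussian kernel density of all pooled fixes, evaluated at cell centres.

    A single scalar bandwidth (degrees) is shared by both axes.  The surface
    is a proper density per square degree: its discrete integral over the
    grid is ~1 when the kernels fall well inside the extent.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    lons, lats = _pooled_lonlat(tracks)
    if lons.size == 0:
        raise ValueError("empty population: no fixes to smooth")
    xs = grid.lon_centers()
    ys = grid.lat_centers()
    gx, gy = np.meshgrid(xs, ys)  # (nrow, ncol)
    acc = np.zeros(gx.shape)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for start in range(0, lons.size, chunk):
        dl = gx[..., None] - lons[start : start + chunk]
        dp = gy[..., None] - lats[start : start + chunk]
        acc += np.exp(-(dl**2 + dp**2) * inv2h2).sum(axis=-1)
    values = acc / (lons.size * 2.0 * np.pi * bandwidth**2)
    return GridSurface(grid.lon_min, grid.lat_min, grid.resolution, values)


def scale_surface(surface: GridSurface) -> GridSurface:
    """Min-max rescale to [0, 1]; NaN cells pass through untouched."""
    vmin = np.nanmin(surface.values)
    vmax = np.nanmax(surface.values)
    if not np.isfinite(vmin) or vmax == vmin:
        raise ValueError("degenerate scaling: surface is constant")
    return surface.with_values((surface.values - vmin) / (vmax - vmin))


def difference_surface(s_late: GridSurface, s_early: GridSurface) -> GridSurface:
    """Cellwise later-minus-earlier difference of two scaled surfaces.

    Positive cells mean more use in the later period.
    """
    s_late.require_aligned(s_early, "difference surfaces")
    return s_late.with_values(s_late.values - s_early.values)


def overlap_percent(
    s_a: GridSurface, s_ref: GridSurface, threshold: float = 0.4
) -> float:
    """Directional area overlap of supra-threshold regions, in percent.

    ``100 * |{s_a > t} ∩ {s_ref > t}| / |{s_ref > t}|`` — the denominator is
    the *reference* surface, so the measure is not symmetric.
    """
    s_a.require_aligned(s_ref, "overlap surfaces")
    with np.errstate(invalid="ignore"):
        in_a = s_a.values > threshold
        in_ref = s_ref.values > threshold
    n_ref = int(in_ref.sum())
    if n_ref == 0:
        raise ValueError("empty reference region at this threshold")
    return 100.0 * int((in_a & in_ref).sum()) / n_ref
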