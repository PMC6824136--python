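"""Comparison statistics and prey-context computations.

Small, self-contained implementations with exact small-sample behaviour:
a Yates-corrected 2x2 chi-squared, a Mann-Whitney rank test with exact
enumeration for pooled n <= 12, predator-prey isotopic spacing, and
catch-per-unit-effort gridding over ICES statistical rectangles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .grid import GridSurface
from .isoscape import Isoscape

__all__ = [
    "ContingencyTable2x2",
    "CPUERecord",
    "SpacingResult",
    "PREY_SIZE_LIMITS_MM",
    "yates_chisq",
    "mann_whitney_u",
    "isotopic_spacing",
    "decode_ices_rectangle",
    "cpue_grid",
]

#: Upper fork-length limits (mm) defining prey small enough to be swallowed;
#: applied upstream when CPUE records are assembled.
PREY_SIZE_LIMITS_MM = {"herring": 160, "sprat": 80, "sandeel": 120}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups (e.g. winters), columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")


@dataclass(frozen=True)
class CPUERecord:
    ices_rectangle: str
    species: str
    cpue_per_hr: float
    year: int | None = None
    quarter: int | None = None

    def __post_init__(self) -> None:
        if self.cpue_per_hr < 0:
            raise ValueError("CPUE must be >= 0")


@dataclass(frozen=True)
class SpacingResult:
    feather_d13C: float
    feather_d15N: float
    prey_d13C: float
    prey_d15N: float
    diff_d13C: float
    diff_d15N: float
    trophic_step: float
    consistent_with_consumption: bool


# ---------------------------------------------------------------------------


def yates_chisq(t: ContingencyTable2x2) -> tuple[float, float]:
    """Continuity-corrected chi-squared for a 2x2 table (df = 1).

    ``n * (max(|ad - bc| - n/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))``; the
    correction is always applied.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate margin: a row or column total is zero")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    stat = n * num / math.prod(margins)
    return stat, float(sps.chi2.sf(stat, df=1))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test of ``x`` relative to ``y``.

    Returns ``(W, p)`` where W is the rank-sum (U) statistic of ``x``.  For
    pooled sample size <= ``exact_max_n`` the p-value is computed exactly by
    enumerating every assignment of the pooled values to the two groups;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(pooled.size)
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for combo in itertools.combinations(idx, n1):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return u_obs, float(2.0 * sps.norm.sf(max(z, 0.0)))


def isotopic_spacing(
    feather_means: tuple[float, float],
    prey_iso: Isoscape,
    region: GridSurface,
    trophic_step: float = 3.5,
    step_window: float = 1.0,
) -> SpacingResult:
    """Feather-minus-prey isotopic differences within a foraging region.

    Prey means are unweighted averages of the prey isoscape cells inside the
    boolean ``region``.  The δ15N difference is flagged as consistent with
    direct consumption when it falls within ``trophic_step ± step_window``.
    """
    feather_c, feather_n = feather_means
    prey_iso.d13C.require_aligned(region, "spacing region")
    mask = region.values.astype(bool) & region.valid_mask()
    usable = mask & prey_iso.d13C.valid_mask() & prey_iso.d15N.valid_mask()
    if not usable.any():
        raise ValueError("empty foraging region")
    prey_c = float(prey_iso.d13C.values[usable].mean())
    prey_n = float(prey_iso.d15N.values[usable].mean())
    diff_c = feather_c - prey_c
    diff_n = feather_n - prey_n
    return SpacingResult(
        feather_d13C=feather_c,
        feather_d15N=feather_n,
        prey_d13C=prey_c,
        prey_d15N=prey_n,
        diff_d13C=diff_c,
        diff_d15N=diff_n,
        trophic_step=trophic_step,
        consistent_with_consumption=abs(diff_n - trophic_step) <= step_window,
    )


# ---------------------------------------------------------------------------
# ICES rectangles

_LON_LETTERS = "ABCDEFGHJKLM"  # no I, per the standard scheme


def decode_ices_rectangle(code: str) -> tuple[float, float, float, float]:
    """(lon_min, lat_min, lon_max, lat_max) of a 30' x 1 deg ICES rectangle.

    Row ``01`` starts at 36N; column ``A0`` starts at 44W with letter blocks
    of ten 1-degree columns (letter I unused).
    """
    code = code.strip().upper()
    if len(code) != 4 or not code[:2].isdigit() or not code[3].isdigit():
        raise ValueError(f"malformed ICES rectangle code {code!r}")
    row = int(code[:2])
    if row < 1 or row > 99:
        raise ValueError(f"ICES rectangle row out of range in {code!r}")
    letter = code[2]
    if letter not in _LON_LETTERS:
        raise ValueError(f"ICES rectangle column letter {letter!r} invalid in {code!r}")
    lat_min = 36.0 + (row - 1) * 0.5
    if letter == "A":
        digit = int(code[3])
        if digit > 3:
            raise ValueError(f"column {code[2:]!r} outside the A0-A3 block")
        lon_min = -44.0 + digit
    else:
        lon_min = -40.0 + (_LON_LETTERS.index(letter) - 1) * 10 + int(code[3])
    return lon_min, lat_min, lon_min + 1.0, lat_min + 0.5


def cpue_grid(
    records: Sequence[CPUERecord], resolution: float = 0.5
) -> GridSurface:
    """Rectangle-mean CPUE, log10(mean + 1), painted onto a lon/lat grid.

    The grid spans the union of the rectangles present; cells belonging to
    rectangles without records are nodata (NaN), not zero.  ``resolution``
    must evenly divide both 0.5 deg (lat) and 1 deg (lon).
    """
    if not records:
        raise ValueError("no CPUE records")
    if not math.isclose(0.5 / resolution, round(0.5 / resolution)):
        raise ValueError("resolution must evenly divide a 0.5 deg rectangle side")

    by_rect: dict[str, list[float]] = {}
    bounds: dict[str, tuple[float, float, float, float]] = {}
    for rec in records:
        try:
            bounds[rec.ices_rectangle] = decode_ices_rectangle(rec.ices_rectangle)
        except ValueError as err:
            raise ValueError(f"record {rec!r}: {err}") from err
        by_rect.setdefault(rec.ices_rectangle, []).append(rec.cpue_per_hr)

    lon_min = min(b[0] for b in bounds.values())
    lat_min = min(b[1] for b in bounds.values())
    lon_max = max(b[2] for b in bounds.values())
    lat_max = max(b[3] for b in bounds.values())
    ncol = round((lon_max - lon_min) / resolution)
    nrow = round((lat_max - lat_min) / resolution)
    values = np.full((nrow, ncol), np.nan)

    for rect, vals in sorted(by_rect.items()):
        rl0, rb0, rl1, rb1 = bounds[rect]
        cell = math.log10(float(np.mean(vals)) + 1.0)
        j0 = round((rl0 - lon_min) / resolution)
        j1 = round((rl1 - lon_min) / resolution)
        i0 = round((rb0 - lat_min) / resolution)
        i1 = round((rb1 - lat_min) / resolution)
        values[i0:i1, j0:j1] = cell

    return GridSurface(lon_min, lat_min, resolution, values)
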