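"""Dual-isotope reference surfaces, prey-tissue kriging and lipid correction.

An :class:`Isoscape` bundles a δ13C and a δ15N :class:`~isotrack.grid.GridSurface`
on a common grid, optionally with per-isotope prediction-uncertainty
surfaces.  Prey isoscapes are built from scattered tissue samples by
ordinary kriging against a weighted-least-squares-fitted semivariogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grid import GridSpec, GridSurface

__all__ = [
    "Isoscape",
    "TissueSample",
    "VariogramModel",
    "KILJUNEN_D",
    "KILJUNEN_I",
    "MIN_CN_RATIO",
    "lipid_correct_d13C",
    "empirical_semivariogram",
    "fit_variogram",
    "krige_points",
    "ordinary_krige",
    "extract_values",
]

IsotopeName = Literal["d13C", "d15N"]


@dataclass
class Isoscape:
    d13C: GridSurface
    d15N: GridSurface
    d13C_sd: GridSurface | None = None
    d15N_sd: GridSurface | None = None

    def __post_init__(self) -> None:
        self.d13C.require_aligned(self.d15N, "isoscape component grids")
        for sd in (self.d13C_sd, self.d15N_sd):
            if sd is not None:
                self.d13C.require_aligned(sd, "isoscape sd grids")

    def surface(self, isotope: IsotopeName) -> GridSurface:
        if isotope == "d13C":
            return self.d13C
        if isotope == "d15N":
            return self.d15N
        raise ValueError(f"unknown isotope {isotope!r}")

    @property
    def spec(self) -> GridSpec:
        return self.d13C.spec

    def sanity_check(self) -> None:
        """Loose plausibility bounds for marine tissue values."""
        c = self.d13C.values[np.isfinite(self.d13C.values)]
        n = self.d15N.values[np.isfinite(self.d15N.values)]
        if c.size and (c.min() < -40 or c.max() > 0):
            raise ValueError("d13C outside [-40, 0] permil")
        if n.size and (n.min() < 0 or n.max() > 30):
            raise ValueError("d15N outside [0, 30] permil")


@dataclass(frozen=True)
class TissueSample:
    lon: float
    lat: float
    d13C: float
    d15N: float
    cn_ratio: float | None = None
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.cn_ratio is not None and self.cn_ratio <= 0:
            raise ValueError("C:N ratio must be > 0 when present")

    def value(self, isotope: IsotopeName) -> float:
        return self.d13C if isotope == "d13C" else self.d15N


# ---------------------------------------------------------------------------
# lipid normalisation

KILJUNEN_D = 7.018
KILJUNEN_I = 0.048
#: C:N at which modelled lipid content reaches zero; below this the
#: correction is undefined.
MIN_CN_RATIO = 0.775 / 0.246


def lipid_correct_d13C(d13C: float, cn_ratio: float) -> float:
    """Arithmetic lipid normalisation of a bulk δ13C value.

    Lipid content is modelled from the mass C:N ratio,
    ``L = 93 / (1 + (0.246 * C:N - 0.775) ** -1)``, and the corrected value is
    ``d13C + D * (I + 3.90 / (1 + 287 / L))`` with D = 7.018, I = 0.048.
    The correction is non-negative (lipids are 13C-depleted) and increases
    with C:N.
    """
    if cn_ratio <= MIN_CN_RATIO:
        raise ValueError(
            f"C:N ratio {cn_ratio} at or below protein baseline "
            f"{MIN_CN_RATIO:.4f}; correction inapplicable"
        )
    lipid = 93.0 / (1.0 + 1.0 / (0.246 * cn_ratio - 0.775))
    return d13C + KILJUNEN_D * (KILJUNEN_I + 3.90 / (1.0 + 287.0 / lipid))


# ---------------------------------------------------------------------------
# variogram


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram in lon/lat degrees.

    ``range_`` is the distance at which the spherical model reaches the sill;
    for the exponential model it is the effective range (γ reaches ~95% of
    the sill).
    """

    model: Literal["spherical", "exponential"]
    nugget: float
    sill: float
    range_: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill <= self.nugget:
            raise ValueError("sill must exceed nugget")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """γ(h); γ(0) = 0 exactly (the nugget is a discontinuity)."""
        h = np.asarray(h, dtype=float)
        partial = self.sill - self.nugget
        if self.model == "spherical":
            hr = np.clip(h / self.range_, 0.0, 1.0)
            gamma = self.nugget + partial * (1.5 * hr - 0.5 * hr**3)
        elif self.model == "exponential":
            gamma = self.nugget + partial * (1.0 - np.exp(-3.0 * h / self.range_))
        else:  # pragma: no cover - guarded by type
            raise ValueError(f"unknown model {self.model!r}")
        return np.where(h > 0, gamma, 0.0)


def _sample_coords(samples: Sequence[TissueSample]) -> np.ndarray:
    return np.array([[s.lon, s.lat] for s in samples], dtype=float)


def empirical_semivariogram(
    samples: Sequence[TissueSample],
    isotope: IsotopeName,
    n_bins: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned classical (Matheron) semivariogram estimate.

    Returns (bin centre distances, γ estimates, pair counts); empty bins are
    dropped.  Lags run to half the maximum pairwise distance.
    """
    coords = _sample_coords(samples)
    z = np.array([s.value(isotope) for s in samples])
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    dist = d[iu]
    sqdiff = 0.5 * (z[:, None] - z[None, :])[iu] ** 2
    max_lag = dist.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist > lo) & (dist <= hi)
        if sel.any():
            centers.append(0.5 * (lo + hi))
            gammas.append(sqdiff[sel].mean())
            counts.append(int(sel.sum()))
    return np.asarray(centers), np.asarray(gammas), np.asarray(counts)


def fit_variogram(
    samples: Sequence[TissueSample],
    isotope: IsotopeName,
    model: Literal["spherical", "exponential"] = "spherical",
    n_bins: int = 12,
) -> VariogramModel:
    """WLS fit of the empirical semivariogram with Cressie weights N/γ²."""
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to fit a variogram")
    coords = _sample_coords(samples)
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("samples must span at least two distinct locations")
    z = np.array([s.value(isotope) for s in samples])
    var_z = float(np.var(z, ddof=1))
    flags: list[str] = []
    if var_z == 0.0:
        # all values identical: pure-nugget placeholder
        eps = 1e-9
        return VariogramModel(model, eps, 2 * eps, 1e-6, flags=("pure_nugget",))

    h, gamma, counts = empirical_semivariogram(samples, isotope, n_bins=n_bins)

    def residuals(theta: np.ndarray) -> np.ndarray:
        nugget, partial, rng = theta
        vm_gamma = _gamma_raw(h, model, nugget, nugget + partial, rng)
        w = np.sqrt(counts) / np.maximum(vm_gamma, 1e-12)
        return w * (gamma - vm_gamma)

    h_max = h.max()
    x0 = np.array([0.1 * var_z, max(var_z, 1e-9), h_max / 2.0])
    lb = np.array([0.0, 1e-12, h.min() / 10.0])
    ub = np.array([2.0 * var_z + 1e-9, 10.0 * var_z + 1e-6, 10.0 * h_max])
    fit = least_squares(residuals, x0, bounds=(lb, ub))
    nugget, partial, rng = fit.x
    if rng <= h.min() * 1.05:
        flags.append("range_at_minimum_lag")
    if nugget >= 0.8 * (nugget + partial):
        # essentially uncorrelated: nearly all variance sits in the nugget
        flags.append("no_spatial_structure")
    return VariogramModel(
        model, float(nugget), float(nugget + partial), float(rng), flags=tuple(flags)
    )


def _gamma_raw(
    h: np.ndarray, model: str, nugget: float, sill: float, range_: float
) -> np.ndarray:
    partial = sill - nugget
    if model == "spherical":
        hr = np.clip(h / range_, 0.0, 1.0)
        return nugget + partial * (1.5 * hr - 0.5 * hr**3)
    return nugget + partial * (1.0 - np.exp(-3.0 * h / range_))


# ---------------------------------------------------------------------------
# ordinary kriging


def krige_points(
    samples: Sequence[TissueSample],
    isotope: IsotopeName,
    coords: np.ndarray,
    variogram: VariogramModel,
    on_singular: Literal["error", "jitter"] = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions and standard deviations at ``coords``.

    Solves the classic (n+1) system with a Lagrange multiplier, so weights
    sum to one per prediction and, with zero nugget, the interpolator is
    exact at sample locations.
    """
    obs = _sample_coords(samples)
    z = np.array([s.value(isotope) for s in samples])
    n = len(samples)
    if n == 0:
        raise ValueError("no samples")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if n == 1:
        # degenerate: the OK mean is the single observation
        preds = np.full(coords.shape[0], z[0])
        return preds, np.zeros_like(preds)

    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram(cdist(obs, obs))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0

    try:
        lu = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        if on_singular == "jitter":
            jit = np.random.default_rng(0).normal(0.0, 1e-10, size=(n, n))
            a[:n, :n] += np.abs(jit) + np.abs(jit.T)
            lu = np.linalg.inv(a)
        else:
            raise ValueError(
                "singular kriging system (duplicate locations with zero "
                "nugget?); set on_singular='jitter' to perturb"
            )

    b = np.empty((coords.shape[0], n + 1))
    b[:, :n] = variogram(cdist(coords, obs))
    b[:, n] = 1.0
    w = b @ lu.T  # weights + multiplier per prediction point
    preds = w[:, :n] @ z
    var = np.einsum("ij,ij->i", w, b)
    return preds, np.sqrt(np.maximum(var, 0.0))


def ordinary_krige(
    samples: Sequence[TissueSample],
    isotope: IsotopeName,
    grid: GridSpec,
    variogram: VariogramModel,
    on_singular: Literal["error", "jitter"] = "error",
) -> tuple[GridSurface, GridSurface]:
    """Krige scattered samples onto a grid; returns (prediction, sd) surfaces."""
    xs, ys = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    preds, sds = krige_points(samples, isotope, coords, variogram, on_singular)
    shape = (grid.nrow, grid.ncol)
    return (
        GridSurface(grid.lon_min, grid.lat_min, grid.resolution, preds.reshape(shape)),
        GridSurface(grid.lon_min, grid.lat_min, grid.resolution, sds.reshape(shape)),
    )


# ---------------------------------------------------------------------------
# extraction


def extract_values(
    iso: Isoscape, mask: np.ndarray | GridSurface
) -> tuple[np.ndarray, np.ndarray]:
    """δ13C and δ15N values of all unmasked, data-bearing cells.

    Each cell contributes once (equal weight); cells that are nodata in
    either component are skipped.  Raises on an empty extraction region.
    """
    if isinstance(mask, GridSurface):
        iso.d13C.require_aligned(mask, "extraction mask")
        mask_arr = mask.values.astype(bool) & mask.valid_mask()
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != iso.d13C.values.shape:
            raise ValueError("mask shape does not match isoscape grid")
    usable = mask_arr & iso.d13C.valid_mask() & iso.d15N.valid_mask()
    if not usable.any():
        raise ValueError("empty extraction region")
    return iso.d13C.values[usable], iso.d15N.values[usable]
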