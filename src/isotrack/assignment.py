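"""Bayesian geographic assignment of feather isotope values.

The chain is: geolocator kernel density → cell mask → Monte-Carlo
calibration offset between feathers and the reference isoscape →
per-individual bivariate-normal likelihood surface → posterior
(prior × likelihood, renormalised) → top-mass likely region → summed
population surface → between-group region overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .grid import GridSurface
from .isoscape import Isoscape

__all__ = [
    "FeatherSample",
    "CalibrationOffset",
    "AssignmentConditions",
    "AssignmentResult",
    "kde_mask",
    "derive_offset",
    "likelihood_surface",
    "posterior_surface",
    "likely_region",
    "population_surface",
    "region_overlap",
]


@dataclass(frozen=True)
class FeatherSample:
    individual_id: str
    species: str
    feather_type: str
    winter: str
    d13C: float
    d15N: float


@dataclass(frozen=True)
class CalibrationOffset:
    """Feather-minus-reference offsets (trophic + tissue discrimination)."""

    delta13C_fj: float
    sd13C: float
    delta15N_fj: float
    sd15N: float
    n_draws: int = 1000

    def __post_init__(self) -> None:
        if self.sd13C < 0 or self.sd15N < 0:
            raise ValueError("offset standard deviations must be >= 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class AssignmentConditions:
    """Error budget and thresholds for one species/feather/winter group.

    ``odds_threshold`` is retained as metadata only: likely regions are
    defined by the top ``mass_quantile`` of posterior mass.
    """

    calibration: CalibrationOffset
    measurement_sd_d13C: float = 0.2
    measurement_sd_d15N: float = 0.2
    between_individual_var_d13C: float = 0.0
    between_individual_var_d15N: float = 0.0
    mass_quantile: float = 0.30
    odds_threshold: float = 1.42
    include_isoscape_sd: bool = False

    def __post_init__(self) -> None:
        if self.between_individual_var_d13C < 0 or self.between_individual_var_d15N < 0:
            raise ValueError("between-individual variances must be >= 0")
        if not 0.0 < self.mass_quantile < 1.0:
            raise ValueError("mass_quantile must be in (0, 1)")

    @property
    def total_var_d13C(self) -> float:
        return (
            self.measurement_sd_d13C**2
            + self.between_individual_var_d13C
            + self.calibration.sd13C**2
        )

    @property
    def total_var_d15N(self) -> float:
        return (
            self.measurement_sd_d15N**2
            + self.between_individual_var_d15N
            + self.calibration.sd15N**2
        )


@dataclass
class AssignmentResult:
    species: str
    feather_type: str
    winter: str
    calibration: CalibrationOffset
    posteriors: list[GridSurface] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    population: GridSurface | None = None
    likely: GridSurface | None = None


# ---------------------------------------------------------------------------


def kde_mask(kde: GridSurface, floor: float = 0.01) -> GridSurface:
    """Boolean surface marking cells with density strictly above ``floor``."""
    with np.errstate(invalid="ignore"):
        mask = kde.values > floor
    if not mask.any():
        raise ValueError(f"no kernel density cells above floor {floor}")
    return kde.with_values(mask.astype(float))


def derive_offset(
    iso_values: tuple[Sequence[float], Sequence[float]],
    feathers: Sequence[FeatherSample],
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CalibrationOffset:
    """Monte-Carlo calibration offset between feathers and isoscape cells.

    Per isotope, ``n_draws`` independent draws are taken from
    Normal(median, sd) of the feather population and of the isoscape values
    inside the kernel-density mask; the offset is the mean of the paired
    differences (feather minus isoscape) and the offset sd is the sd of
    those differences.  Zero-variance inputs degrade gracefully to point
    masses.
    """
    if len(feathers) < 2:
        raise ValueError("need at least two feather samples")
    iso_c, iso_n = (np.asarray(v, dtype=float) for v in iso_values)
    if iso_c.size < 2 or iso_n.size < 2:
        raise ValueError("need at least two isoscape cells")
    rng = np.random.default_rng(rng)

    out: dict[str, tuple[float, float]] = {}
    for key, feather_vals, iso_vals in (
        ("C", np.array([f.d13C for f in feathers]), iso_c),
        ("N", np.array([f.d15N for f in feathers]), iso_n),
    ):
        med_f = float(np.median(feather_vals))
        sd_f = float(np.std(feather_vals, ddof=1))
        med_j = float(np.median(iso_vals))
        sd_j = float(np.std(iso_vals, ddof=1))
        diffs = rng.normal(med_f, sd_f, n_draws) - rng.normal(med_j, sd_j, n_draws)
        sd = float(np.std(diffs, ddof=1)) if n_draws > 1 else 0.0
        out[key] = (float(np.mean(diffs)), sd)

    return CalibrationOffset(
        delta13C_fj=out["C"][0],
        sd13C=out["C"][1],
        delta15N_fj=out["N"][0],
        sd15N=out["N"][1],
        n_draws=n_draws,
    )


def likelihood_surface(
    feather: FeatherSample, iso: Isoscape, cond: AssignmentConditions
) -> GridSurface:
    """Per-cell bivariate-normal likelihood of the feather's isotope pair.

    Independent isotopes (diagonal covariance): each cell contributes
    ``phi(d13C; c_i + offset, var_C) * phi(d15N; n_i + offset, var_N)`` with
    the total variance summing measurement, between-individual and
    calibration terms.  Nodata cells get likelihood 0.
    """
    var_c = cond.total_var_d13C
    var_n = cond.total_var_d15N
    if cond.include_isoscape_sd:
        if iso.d13C_sd is None or iso.d15N_sd is None:
            raise ValueError("isoscape sd surfaces requested but absent")
        var_c = var_c + iso.d13C_sd.values**2
        var_n = var_n + iso.d15N_sd.values**2
    if np.any(np.asarray(var_c) <= 0) or np.any(np.asarray(var_n) <= 0):
        raise ValueError("total variance must be positive for both isotopes")

    mu_c = iso.d13C.values + cond.calibration.delta13C_fj
    mu_n = iso.d15N.values + cond.calibration.delta15N_fj
    lc = np.exp(-0.5 * (feather.d13C - mu_c) ** 2 / var_c) / np.sqrt(
        2.0 * math.pi * var_c
    )
    ln = np.exp(-0.5 * (feather.d15N - mu_n) ** 2 / var_n) / np.sqrt(
        2.0 * math.pi * var_n
    )
    values = np.nan_to_num(lc * ln, nan=0.0)
    return iso.d13C.with_values(values)


def posterior_surface(prior: GridSurface, likelihood: GridSurface) -> GridSurface:
    """Cellwise prior × likelihood, renormalised to sum 1.

    Zero-prior cells stay at exactly zero (hard prior support); nodata in
    either input is treated as zero.
    """
    prior.require_aligned(likelihood, "prior and likelihood")
    p = np.nan_to_num(prior.values, nan=0.0)
    l = np.nan_to_num(likelihood.values, nan=0.0)
    if np.any(p < 0) or np.any(l < 0):
        raise ValueError("prior and likelihood must be non-negative")
    product = p * l
    total = product.sum()
    if total <= 0:
        raise ValueError("prior and likelihood have disjoint support")
    return prior.with_values(product / total)


def likely_region(posterior: GridSurface, mass_quantile: float = 0.30) -> GridSurface:
    """Smallest set of highest-posterior cells holding >= the target mass.

    Ties are broken by ascending flat cell index, making the region
    deterministic.  The selected mass lies in
    [mass_quantile, mass_quantile + largest selected cell].
    """
    if not 0.0 < mass_quantile < 1.0:
        raise ValueError("mass_quantile must be in (0, 1)")
    flat = np.nan_to_num(posterior.values.ravel(), nan=0.0)
    total = flat.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("posterior must sum to 1")
    order = np.argsort(-flat, kind="stable")  # stable => ties by ascending index
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, mass_quantile - 1e-12)) + 1
    mask = np.zeros(flat.size, dtype=float)
    mask[order[:k]] = 1.0
    return posterior.with_values(mask.reshape(posterior.values.shape))


def population_surface(posteriors: Sequence[GridSurface]) -> GridSurface:
    """Normalised cellwise sum of individual posteriors."""
    if not posteriors:
        raise ValueError("no posteriors to combine")
    ref = posteriors[0]
    acc = np.zeros_like(ref.values)
    for p in posteriors:
        ref.require_aligned(p, "population posteriors")
        acc += np.nan_to_num(p.values, nan=0.0)
    return ref.with_values(acc / acc.sum())


def region_overlap(
    region_a: GridSurface,
    region_b: GridSurface,
    reference: Literal["a", "b"] = "a",
) -> float:
    """Percent overlap of two boolean regions relative to one of them."""
    region_a.require_aligned(region_b, "overlap regions")
    a = region_a.values.astype(bool)
    b = region_b.values.astype(bool)
    ref = a if reference == "a" else b
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("empty reference region")
    return 100.0 * int((a & b).sum()) / n_ref
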