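"""End-to-end assignment pipeline.

Chains the modules: speed/equinox filtering -> moult-residency gating ->
kernel-density prior -> density mask -> calibration offset -> per-feather
likelihood -> posterior -> likely region -> population surface, one run per
species x feather type x winter group found in the feather table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as iio
from .assignment import (
    AssignmentConditions,
    AssignmentResult,
    FeatherSample,
    derive_offset,
    kde_mask,
    likelihood_surface,
    likely_region,
    population_surface,
    posterior_surface,
    region_overlap,
)
from .grid import GridSurface, read_grid_csv, write_grid_csv
from .isoscape import Isoscape, extract_values
from .tracks import (
    DEFAULT_EQUINOX_WINDOWS,
    DEFAULT_MOULT_WINDOWS,
    NORTH_SEA_BBOX,
    MoultWindow,
    RegionPolygon,
    Residency,
    Track,
    filter_equinox,
    filter_speed,
    kde_surface,
    moult_residency,
    nrd_bandwidth,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    tracks: list[Track]
    feathers: list[FeatherSample]
    isoscape: Isoscape
    moult_windows: dict[tuple[str, str], MoultWindow] = field(
        default_factory=lambda: dict(DEFAULT_MOULT_WINDOWS)
    )
    region: RegionPolygon = field(default_factory=lambda: NORTH_SEA_BBOX)
    equinox_windows: Sequence = DEFAULT_EQUINOX_WINDOWS
    max_kmday: float = 500.0
    bandwidth: float | None = None  # None -> mean per-axis normal-reference value
    kde_floor: float = 0.01
    measurement_sd: float = 0.2
    mass_quantile: float = 0.30
    odds_threshold: float = 1.42
    n_draws: int = 1000
    seed: int = 0
    use_prior: bool = True
    out_dir: Path | None = None


def _group_key(f: FeatherSample) -> tuple[str, str, str]:
    return (f.species, f.feather_type, f.winter)


def _population_bandwidth(tracks: Sequence[Track]) -> float:
    lons = [f.lon for t in tracks for f in t.fixes]
    lats = [f.lat for t in tracks for f in t.fixes]
    return 0.5 * (nrd_bandwidth(lons) + nrd_bandwidth(lats))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every species x feather x winter group; returns results and a log.

    The returned dict holds ``results`` (group key -> AssignmentResult),
    ``log`` (parameters, seeds, per-group diagnostics) and ``overlaps``
    (between-winter likely-region overlap per species/feather, reference =
    earlier winter).
    """
    groups = sorted({_group_key(f) for f in config.feathers})
    if not groups:
        raise PipelineError("setup", "no feather samples supplied")
    rng = np.random.default_rng(config.seed)
    results: dict[tuple[str, str, str], AssignmentResult] = {}
    log: dict = {
        "seed": config.seed,
        "n_draws": config.n_draws,
        "measurement_sd": config.measurement_sd,
        "mass_quantile": config.mass_quantile,
        "odds_threshold_metadata": config.odds_threshold,
        "max_kmday": config.max_kmday,
        "kde_floor": config.kde_floor,
        "groups": {},
    }

    for species, feather_type, winter in groups:
        key = (species, feather_type, winter)
        label = f"{species}/{feather_type}/{winter}"
        feathers = [f for f in config.feathers if _group_key(f) == key]
        window = config.moult_windows.get((species, feather_type))
        if window is None:
            # fall back to any configured window for this feather type
            candidates = [
                w for (_, ft), w in config.moult_windows.items() if ft == feather_type
            ]
            if not candidates:
                raise PipelineError(
                    "setup", f"no moult window for {species}/{feather_type}"
                )
            window = MoultWindow(species, feather_type, candidates[0].months)

        # -- track filtering ------------------------------------------------
        try:
            tracks = [
                filter_speed(
                    filter_equinox(t, config.equinox_windows), config.max_kmday
                )
                for t in config.tracks
                if t.species == species and t.winter == winter and t.fixes
            ]
        except Exception as err:
            raise PipelineError("filter", f"{label}: {err}") from err
        if not tracks:
            raise PipelineError("filter", f"{label}: no tracks for this group")

        # -- residency gate -------------------------------------------------
        try:
            eligible = [
                t
                for t in tracks
                if moult_residency(t, window, config.region) is Residency.RESIDENT
            ]
        except Exception as err:
            raise PipelineError("residency", f"{label}: {err}") from err
        if not eligible:
            raise PipelineError(
                "residency", f"{label}: no individuals resident during moult"
            )

        # -- prior ----------------------------------------------------------
        try:
            season_tracks = [
                t.with_fixes([f for f in t.fixes if f.date.month in window.months])
                for t in eligible
            ]
            season_tracks = [t for t in season_tracks if t.fixes]
            bw = config.bandwidth or _population_bandwidth(season_tracks)
            kde = kde_surface(season_tracks, bw, config.isoscape.spec)
            prior = kde.with_values(kde.values / kde.values.sum())
            if not config.use_prior:
                flat = np.full_like(kde.values, 1.0 / kde.values.size)
                prior = kde.with_values(flat)
        except Exception as err:
            raise PipelineError("prior", f"{label}: {err}") from err

        # -- calibration offset ---------------------------------------------
        try:
            mask = kde_mask(kde, config.kde_floor)
            iso_values = extract_values(config.isoscape, mask)
            offset = derive_offset(
                iso_values, feathers, n_draws=config.n_draws, rng=rng
            )
        except Exception as err:
            raise PipelineError("offset", f"{label}: {err}") from err

        cond = AssignmentConditions(
            calibration=offset,
            measurement_sd_d13C=config.measurement_sd,
            measurement_sd_d15N=config.measurement_sd,
            between_individual_var_d13C=float(
                np.var([f.d13C for f in feathers], ddof=1)
            ),
            between_individual_var_d15N=float(
                np.var([f.d15N for f in feathers], ddof=1)
            ),
            mass_quantile=config.mass_quantile,
            odds_threshold=config.odds_threshold,
        )

        # -- assignment -------------------------------------------------------
        try:
            result = AssignmentResult(
                species=species,
                feather_type=feather_type,
                winter=winter,
                calibration=offset,
            )
            for feather in feathers:
                like = likelihood_surface(feather, config.isoscape, cond)
                post = posterior_surface(prior, like)
                result.posteriors.append(post)
                result.individual_ids.append(feather.individual_id)
            result.population = population_surface(result.posteriors)
            result.likely = likely_region(result.population, config.mass_quantile)
        except Exception as err:
            raise PipelineError("assignment", f"{label}: {err}") from err

        results[key] = result
        log["groups"]["/".join(key)] = {
            "n_feathers": len(feathers),
            "n_tracks": len(tracks),
            "n_eligible": len(eligible),
            "bandwidth": bw,
            "offset": {
                "delta13C_fj": offset.delta13C_fj,
                "sd13C": offset.sd13C,
                "delta15N_fj": offset.delta15N_fj,
                "sd15N": offset.sd15N,
            },
            "likely_region_cells": int(result.likely.values.sum()),
        }

    overlaps = _between_winter_overlaps(results)
    log["overlaps"] = overlaps

    if config.out_dir is not None:
        _write_outputs(config.out_dir, results, log)

    return {"results": results, "log": log, "overlaps": overlaps}


def _between_winter_overlaps(
    results: dict[tuple[str, str, str], AssignmentResult]
) -> dict[str, float]:
    """Likely-region overlap between winters, denominator = earlier winter."""
    overlaps: dict[str, float] = {}
    pairs: dict[tuple[str, str], list[str]] = {}
    for species, feather_type, winter in results:
        pairs.setdefault((species, feather_type), []).append(winter)
    for (species, feather_type), winters in pairs.items():
        if len(winters) < 2:
            continue
        winters = sorted(winters)
        early, late = winters[0], winters[-1]
        ra = results[(species, feather_type, late)].likely
        rb = results[(species, feather_type, early)].likely
        overlaps[f"{species}/{feather_type} {late} vs {early}"] = region_overlap(
            ra, rb, reference="b"
        )
    return overlaps


def _write_outputs(out_dir: Path, results: dict, log: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (species, feather_type, winter), res in results.items():
        stem = f"{species}_{feather_type}_{winter.replace('/', '-')}"
        write_grid_csv(res.population, out_dir / f"{stem}_population.csv")
        write_grid_csv(res.likely, out_dir / f"{stem}_likely.csv")
    with (out_dir / "run_log.json").open("w") as fh:
        json.dump(log, fh, indent=2)


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Expected sections: ``tracks`` (csv path), ``feathers`` (csv path),
    ``isoscape`` (``d13C``/``d15N`` grid-CSV paths), optional ``conditions``
    (measurement_sd, mass_quantile, n_draws, seed, bandwidth, max_kmday,
    kde_floor, use_prior), optional ``region`` (lon_min/lat_min/lon_max/
    lat_max) and ``output`` (dir).
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def respath(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    iso = Isoscape(
        d13C=read_grid_csv(respath(raw["isoscape"]["d13C"])),
        d15N=read_grid_csv(respath(raw["isoscape"]["d15N"])),
    )
    cfg = PipelineConfig(
        tracks=iio.read_tracks_csv(respath(raw["tracks"])),
        feathers=iio.read_feathers_csv(respath(raw["feathers"])),
        isoscape=iso,
    )
    cond = raw.get("conditions", {})
    for name in (
        "max_kmday",
        "bandwidth",
        "kde_floor",
        "measurement_sd",
        "mass_quantile",
        "odds_threshold",
        "n_draws",
        "seed",
        "use_prior",
    ):
        if name in cond:
            setattr(cfg, name, cond[name])
    if "region" in raw:
        r = raw["region"]
        cfg.region = RegionPolygon.bbox(
            r.get("name", "study region"),
            r["lon_min"],
            r["lat_min"],
            r["lon_max"],
            r["lat_max"],
        )
    if "output" in raw and raw["output"].get("dir"):
        cfg.out_dir = respath(raw["output"]["dir"])
    return cfg
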