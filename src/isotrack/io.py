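"""CSV readers and writers for the package's tabular interfaces.

Columns follow the documented dialects:

* fixes:    individual_id, species, winter, date (ISO 8601), lon, lat
* feathers: individual_id, species, feather_type, winter, d13C, d15N
* tissue:   lon, lat, d13C, d15N, cn_ratio, taxon
* CPUE:     ices_rectangle, species, year, quarter, cpue_per_hr

Grid surfaces use the plain-text dialect in :mod:`isotrack.grid`.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assignment import FeatherSample
from .isoscape import TissueSample
from .tracks import Fix, Track
from .trophic_stats import CPUERecord

__all__ = [
    "read_tracks_csv",
    "write_tracks_csv",
    "read_feathers_csv",
    "write_feathers_csv",
    "read_tissue_csv",
    "read_cpue_csv",
]


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path, dtype={"individual_id": str, "winter": str})
    required = {"individual_id", "species", "winter", "date", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for (ind, species, winter), sub in df.groupby(
        ["individual_id", "species", "winter"], sort=True
    ):
        sub = sub.sort_values("date")
        fixes = [
            Fix(
                individual_id=str(ind),
                date=dt.date.fromisoformat(str(row.date)),
                lon=float(row.lon),
                lat=float(row.lat),
            )
            for row in sub.itertuples()
        ]
        tracks.append(
            Track(individual_id=str(ind), species=species, winter=winter, fixes=fixes)
        )
    return tracks


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    rows = [
        {
            "individual_id": t.individual_id,
            "species": t.species,
            "winter": t.winter,
            "date": f.date.isoformat(),
            "lon": f.lon,
            "lat": f.lat,
        }
        for t in tracks
        for f in t.fixes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feathers_csv(path: str | Path) -> list[FeatherSample]:
    df = pd.read_csv(path, dtype={"individual_id": str, "winter": str})
    required = {"individual_id", "species", "feather_type", "winter", "d13C", "d15N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FeatherSample(
            individual_id=str(row.individual_id),
            species=row.species,
            feather_type=row.feather_type,
            winter=row.winter,
            d13C=float(row.d13C),
            d15N=float(row.d15N),
        )
        for row in df.itertuples()
    ]


def write_feathers_csv(feathers: Sequence[FeatherSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": f.individual_id,
                "species": f.species,
                "feather_type": f.feather_type,
                "winter": f.winter,
                "d13C": f.d13C,
                "d15N": f.d15N,
            }
            for f in feathers
        ]
    ).to_csv(path, index=False)


def read_tissue_csv(path: str | Path) -> list[TissueSample]:
    df = pd.read_csv(path)
    required = {"lon", "lat", "d13C", "d15N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for row in df.itertuples():
        cn = getattr(row, "cn_ratio", None)
        samples.append(
            TissueSample(
                lon=float(row.lon),
                lat=float(row.lat),
                d13C=float(row.d13C),
                d15N=float(row.d15N),
                cn_ratio=None if cn is None or pd.isna(cn) else float(cn),
                taxon=str(getattr(row, "taxon", "")),
            )
        )
    return samples


def read_cpue_csv(path: str | Path) -> list[CPUERecord]:
    df = pd.read_csv(path)
    required = {"ices_rectangle", "species", "cpue_per_hr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        year = getattr(row, "year", None)
        quarter = getattr(row, "quarter", None)
        records.append(
            CPUERecord(
                ices_rectangle=str(row.ices_rectangle),
                species=str(row.species),
                cpue_per_hr=float(row.cpue_per_hr),
                year=None if year is None or pd.isna(year) else int(year),
                quarter=None if quarter is None or pd.isna(quarter) else int(quarter),
            )
        )
    return records
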