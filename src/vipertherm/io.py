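"""Tabular input/output: sites, taxon traits, monthly climate, run config.

CSV is the canonical interchange format. Schemas:

* sites.csv    — site_id, taxon, lat, lon, elev_m
* traits.csv   — taxon, vtmax_c, mass_g, density_kg_m3, length_to_diameter,
                 absorptance, emissivity, diurnal
* climate.csv  — long format: site_id, scenario, month (1-12), tavg_c, dtr_c
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ectotherm import TaxonTraits
from .microclimate import MonthlyClimate

log = logging.getLogger(__name__)

SITE_COLUMNS = ["site_id", "taxon", "lat", "lon", "elev_m"]
TRAIT_COLUMNS = [
    "taxon", "vtmax_c", "mass_g", "density_kg_m3", "length_to_diameter",
    "absorptance", "emissivity", "diurnal",
]
CLIMATE_COLUMNS = ["site_id", "scenario", "month", "tavg_c", "dtr_c"]


class ValidationError(ValueError):
    """Malformed or out-of-range input data."""


@dataclass
class SiteCell:
    """One occurrence grid cell with its per-scenario monthly climate."""

    site_id: str
    taxon: str
    latitude: float
    longitude: float
    elevation: float
    climate: Dict[str, MonthlyClimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValidationError(f"site {self.site_id}: |lat| > 90 ({self.latitude})")
        if not -500 <= self.elevation <= 9000:
            raise ValidationError(
                f"site {self.site_id}: elevation out of range ({self.elevation} m)"
            )


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    sites_path: str
    traits_path: str
    climate_path: str
    output_dir: str
    scenarios: List[str]
    wind: float = 1.0
    solver_tolerance: float = 1e-6
    seed: int = 20250623
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if "current" not in self.scenarios:
            raise ValidationError("scenario list must contain 'current'")
        if self.solver_tolerance <= 0:
            raise ValidationError("solver tolerance must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "sites_path": self.sites_path,
            "traits_path": self.traits_path,
            "climate_path": self.climate_path,
            "output_dir": self.output_dir,
            "scenarios": list(self.scenarios),
            "wind": self.wind,
            "solver_tolerance": self.solver_tolerance,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_sites(path) -> List[SiteCell]:
    """Read and validate the site table; row numbers appear in errors."""
    df = pd.read_csv(path)
    _require_columns(df, SITE_COLUMNS, path)
    if df.empty:
        log.warning("%s: empty site table", path)
        return []
    sites: List[SiteCell] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            lat = float(row.lat)
            lon = float(row.lon)
            elev = float(row.elev_m)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {row_no}: non-numeric coordinate") from None
        try:
            sites.append(
                SiteCell(
                    site_id=str(row.site_id),
                    taxon=str(row.taxon),
                    latitude=lat,
                    longitude=lon,
                    elevation=elev,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from None
    return sites


def write_sites(sites: Sequence[SiteCell], path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "taxon": [s.taxon for s in sites],
            "lat": [s.latitude for s in sites],
            "lon": [s.longitude for s in sites],
            "elev_m": [s.elevation for s in sites],
        }
    )
    df.to_csv(path, index=False)


def read_traits(path) -> Dict[str, TaxonTraits]:
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, path)
    traits: Dict[str, TaxonTraits] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            traits[str(row.taxon)] = TaxonTraits(
                name=str(row.taxon),
                vtmax=float(row.vtmax_c),
                mass=float(row.mass_g),
                density=float(row.density_kg_m3),
                length_to_diameter=float(row.length_to_diameter),
                absorptance=float(row.absorptance),
                emissivity=float(row.emissivity),
                diurnal=bool(row.diurnal),
            )
        except ValueError as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from None
    return traits


def write_traits(taxa: Sequence[TaxonTraits], path) -> None:
    df = pd.DataFrame(
        {
            "taxon": [t.name for t in taxa],
            "vtmax_c": [t.vtmax for t in taxa],
            "mass_g": [t.mass for t in taxa],
            "density_kg_m3": [t.density for t in taxa],
            "length_to_diameter": [t.length_to_diameter for t in taxa],
            "absorptance": [t.absorptance for t in taxa],
            "emissivity": [t.emissivity for t in taxa],
            "diurnal": [t.diurnal for t in taxa],
        }
    )
    df.to_csv(path, index=False)


def read_climate(path, scenario_labels: Optional[Sequence[str]] = None) -> Dict[str, Dict[str, MonthlyClimate]]:
    """Read long-format monthly climate into site -> scenario -> MonthlyClimate.

    Every (site, scenario) pair must carry exactly the twelve months 1..12.
    """
    df = pd.read_csv(path)
    _require_columns(df, CLIMATE_COLUMNS, path)
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        bad = df.loc[(df["month"] < 1) | (df["month"] > 12)].iloc[0]
        raise ValidationError(
            f"{path}: month {bad['month']} out of 1..12 (site {bad['site_id']})"
        )
    dup = df.duplicated(subset=["site_id", "scenario", "month"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate record for site {bad['site_id']}, "
            f"scenario {bad['scenario']}, month {bad['month']}"
        )
    if scenario_labels is not None:
        df = df[df["scenario"].isin(scenario_labels)]

    out: Dict[str, Dict[str, MonthlyClimate]] = {}
    for (site_id, scenario), grp in df.groupby(["site_id", "scenario"], sort=True):
        if sorted(grp["month"]) != list(range(1, 13)):
            raise ValidationError(
                f"{path}: incomplete climate for site {site_id}, scenario {scenario}"
            )
        grp = grp.sort_values("month")
        out.setdefault(str(site_id), {})[str(scenario)] = MonthlyClimate(
            tavg=grp["tavg_c"].to_numpy(dtype=float),
            dtr=grp["dtr_c"].to_numpy(dtype=float),
        )
    return out


def write_climate(sites: Sequence[SiteCell], path) -> None:
    rows = []
    for s in sites:
        for scenario, clim in s.climate.items():
            for m in range(12):
                rows.append(
                    (s.site_id, scenario, m + 1, clim.tavg[m], clim.dtr[m])
                )
    pd.DataFrame(rows, columns=CLIMATE_COLUMNS).to_csv(path, index=False)


def attach_climate(sites: Sequence[SiteCell], mapping: Dict[str, Dict[str, MonthlyClimate]]) -> None:
    """Attach a climate mapping (from read_climate) to site objects in place."""
    for s in sites:
        if s.site_id not in mapping:
            raise ValidationError(f"no climate records for site {s.site_id}")
        s.climate = mapping[s.site_id]
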