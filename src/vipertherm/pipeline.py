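"""Pipeline orchestration: sites + traits + climates -> restriction analysis.

For every site x scenario the pipeline reconstructs the hourly environment,
solves the hourly operative temperature of the resident taxon, and counts
restriction hours (h_r). It then derives scenario comparisons (delta-h_r and
percent change against the current climate), per-taxon percentile summaries,
current-vs-future rank-sum tests, and the per-SSP regression of site-level
delta-h_r on latitude and elevation.

Pooling rules: within one SSP analogue, h_r values from the GCM analogues
are pooled (stacked, not averaged) for medians and rank-sum tests, while the
regression uses each site's mean delta-h_r across the SSP's GCMs (one row
per site per SSP). Both rules are echoed in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ectotherm import TaxonTraits, annual_operative_series
from .io import RunConfig, SiteCell, attach_climate, read_climate, read_sites, read_traits
from .microclimate import build_hourly_environment
from .restriction import RestrictionRecord, delta_hr, percent_change
from .stats import ols_two_predictor, rank_sum_test, summarize_taxon
from .synthetic import ssp_of

log = logging.getLogger(__name__)

ALL_TAXA = "ALL"


class PipelineError(RuntimeError):
    """A compute stage failed; message names the stage, site and scenario."""


def compute_restriction(
    sites: Sequence[SiteCell],
    traits: Dict[str, TaxonTraits],
    scenarios: Sequence[str],
    wind: float = 1.0,
) -> pd.DataFrame:
    """h_r for every site x scenario: columns site_id, taxon, scenario, h_r."""
    from .restriction import hours_of_restriction

    rows = []
    for i, site in enumerate(sites):
        if site.taxon not in traits:
            raise PipelineError(f"stage traits: no trait record for taxon {site.taxon!r}")
        tr = traits[site.taxon]
        for scenario in scenarios:
            try:
                env = build_hourly_environment(site, scenario, wind=wind)
                series = annual_operative_series(env, tr, site_id=site.site_id, scenario=scenario)
                h_r = hours_of_restriction(series, tr.vtmax)
            except Exception as exc:
                raise PipelineError(
                    f"stage te: site {site.site_id}, scenario {scenario}: {exc}"
                ) from exc
            rows.append((site.site_id, site.taxon, scenario, h_r))
        if (i + 1) % 100 == 0:
            log.info("restriction: %d/%d sites done", i + 1, len(sites))
    return pd.DataFrame(rows, columns=["site_id", "taxon", "scenario", "h_r"])


def compare_scenarios(restriction_df: pd.DataFrame) -> pd.DataFrame:
    """delta-h_r and percent change of every future scenario vs. current."""
    current = restriction_df[restriction_df["scenario"] == "current"].set_index("site_id")
    rows = []
    for row in restriction_df.itertuples(index=False):
        if row.scenario == "current":
            continue
        cur = current.loc[row.site_id]
        comp = delta_hr(
            RestrictionRecord(row.site_id, row.taxon, "current", int(cur["h_r"])),
            RestrictionRecord(row.site_id, row.taxon, row.scenario, int(row.h_r)),
        )
        rows.append(
            (row.site_id, row.taxon, row.scenario, comp.delta_hr, comp.percent_change)
        )
    return pd.DataFrame(
        rows, columns=["site_id", "taxon", "scenario", "delta_hr", "percent_change"]
    )


def _scenario_class(scenario: str) -> str:
    return "current" if scenario == "current" else ssp_of(scenario)


def summarize(restriction_df: pd.DataFrame) -> pd.DataFrame:
    """Percentile summaries per taxon (and pooled across taxa as 'ALL').

    Scenario classes pool the GCM analogues within each SSP.
    """
    df = restriction_df.copy()
    df["scenario_class"] = df["scenario"].map(_scenario_class)
    rows = []
    grouped = list(df.groupby(["taxon", "scenario_class"], sort=True))
    grouped += [((ALL_TAXA, cls), grp) for cls, grp in df.groupby("scenario_class", sort=True)]
    for (taxon, cls), grp in grouped:
        records = [
            RestrictionRecord(r.site_id, taxon, cls, int(r.h_r))
            for r in grp.itertuples(index=False)
        ]
        s = summarize_taxon(records)
        rows.append((taxon, cls, s.n_sites, s.median_hr, s.p5_hr, s.p95_hr))
    return pd.DataFrame(
        rows, columns=["taxon", "scenario_class", "n", "median_hr", "p5_hr", "p95_hr"]
    )


def rank_sum_tests(restriction_df: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney current vs. pooled-SSP h_r, per taxon and overall."""
    df = restriction_df.copy()
    df["scenario_class"] = df["scenario"].map(_scenario_class)
    ssps = sorted(c for c in df["scenario_class"].unique() if c != "current")
    rows = []
    taxa = sorted(df["taxon"].unique()) + [ALL_TAXA]
    for taxon in taxa:
        sub = df if taxon == ALL_TAXA else df[df["taxon"] == taxon]
        cur = sub.loc[sub["scenario_class"] == "current", "h_r"].to_numpy(float)
        for ssp in ssps:
            fut = sub.loc[sub["scenario_class"] == ssp, "h_r"].to_numpy(float)
            if len(cur) == 0 or len(fut) == 0:
                continue
            res = rank_sum_test(cur, fut)
            rows.append((taxon, ssp, res.u, res.z, res.p, res.method))
    return pd.DataFrame(rows, columns=["taxon", "ssp", "u", "z", "p", "method"])


def regressions(
    comparisons_df: pd.DataFrame, sites: Sequence[SiteCell]
) -> pd.DataFrame:
    """Per-SSP OLS of site-level delta-h_r (GCM-averaged) on latitude, elevation."""
    meta = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "lat": [s.latitude for s in sites],
            "elev": [s.elevation for s in sites],
        }
    ).set_index("site_id")
    df = comparisons_df.copy()
    df["ssp"] = df["scenario"].map(ssp_of)
    rows = []
    for ssp, grp in df.groupby("ssp", sort=True):
        per_site = grp.groupby("site_id")["delta_hr"].mean()
        lat = meta.loc[per_site.index, "lat"].to_numpy()
        elev = meta.loc[per_site.index, "elev"].to_numpy()
        res = ols_two_predictor(per_site.to_numpy(), lat, elev, scenario=ssp)
        for term, est in res.terms.items():
            rows.append((ssp, term, est.beta, est.se, est.t, est.p, res.df_resid))
    return pd.DataFrame(rows, columns=["ssp", "term", "beta", "se", "t", "p", "df_resid"])


def headline(summary_df: pd.DataFrame) -> Dict[str, Optional[float]]:
    """Cross-taxa medians per scenario class and percent change of medians."""
    overall = summary_df[summary_df["taxon"] == ALL_TAXA].set_index("scenario_class")
    out: Dict[str, Optional[float]] = {}
    cur = float(overall.loc["current", "median_hr"])
    out["median_hr_current"] = cur
    for cls in overall.index:
        if cls == "current":
            continue
        med = float(overall.loc[cls, "median_hr"])
        out[f"median_hr_{cls}"] = med
        out[f"percent_increase_{cls}"] = percent_change(cur, med)
    return out


def run_analysis(
    sites: Sequence[SiteCell],
    traits: Dict[str, TaxonTraits],
    scenarios: Sequence[str],
    wind: float = 1.0,
) -> Dict[str, object]:
    """Run every analysis stage in memory; returns a dict of DataFrames.

    Keys: restriction, comparisons, summary, tests, regression, headline.
    """
    restriction_df = compute_restriction(sites, traits, scenarios, wind=wind)
    comparisons_df = compare_scenarios(restriction_df)
    summary_df = summarize(restriction_df)
    tests_df = rank_sum_tests(restriction_df)
    regression_df = regressions(comparisons_df, sites)
    return {
        "restriction": restriction_df,
        "comparisons": comparisons_df,
        "summary": summary_df,
        "tests": tests_df,
        "regression": regression_df,
        "headline": headline(summary_df),
    }


def run_pipeline(cfg: RunConfig) -> Dict[str, Path]:
    """Full file-to-file run; returns the paths written.

    Outputs: restriction.csv, comparisons.csv, summary.csv, tests.csv,
    regression.csv, manifest.json (config echo, versions, seed, pooling
    rules) in cfg.output_dir.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    sites = read_sites(cfg.sites_path)
    traits = read_traits(cfg.traits_path)
    climate = read_climate(cfg.climate_path, cfg.scenarios)
    attach_climate(sites, climate)
    for site in sites:
        for scenario in cfg.scenarios:
            if scenario not in site.climate:
                raise PipelineError(
                    f"stage climate: site {site.site_id} lacks scenario {scenario}"
                )

    results = run_analysis(sites, traits, cfg.scenarios, wind=cfg.wind)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name in ("restriction", "comparisons", "summary", "tests", "regression"):
        path = outdir / f"{name}.csv"
        results[name].to_csv(path, index=False, float_format="%.10g")
        paths[name] = path

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "vipertherm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "pooling": {
            "medians_and_tests": "GCM analogues pooled within each SSP",
            "regression": "per-site mean delta_hr across GCMs within each SSP",
        },
        "headline": results["headline"],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
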