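"""Per-site floral abundance: floral units per 100 m^2 per week.

abundance(site, species) = mean weekly stem count at the site
                           x mean floral units per stem (study-wide).

The weekly stem value is the mean over the quadrats surveyed that week;
the weekly values are then averaged over the contiguous span of weeks
in which the species was recorded flowering at the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class AbundanceUndefined(ValueError):
    """Raised when a component mean cannot be computed from the data."""


@dataclass(frozen=True)
class FloralAbundance:
    site: str
    plant_id: str
    mean_stems: float
    mean_floral_units_per_stem: float
    abundance: float  # == mean_stems * mean_floral_units_per_stem
    n_weeks_observed: int
    n_stem_measurements: int


def mean_weekly_stems(stem_records: pd.DataFrame, site: str, plant_id: str,
                      span_zeros: str = "skip") -> tuple[float, int]:
    """Mean weekly stem count per 100 m^2 for one species at one site.

    The value for a week is the mean stem count over the quadrats (zones)
    surveyed at the site that week; a species absent from a surveyed
    quadrat's records contributes 0 for that quadrat. Weekly values are
    averaged over the contiguous span from the first to the last week the
    species was seen flowering (stems > 0). Weeks inside the span with no
    quadrat survey contribute nothing.

    Parameters
    ----------
    span_zeros
        ``"skip"`` (default) drops zero weeks inside the span from the
        average; ``"include"`` keeps them as true zeros.

    Returns
    -------
    (mean_stems, n_weeks) where n_weeks is the number of weekly values
    averaged.

    Raises
    ------
    AbundanceUndefined
        If the species was never recorded with stems > 0 at the site
        (signals the configured fallback).
    """
    if span_zeros not in ("skip", "include"):
        raise ValueError(f"span_zeros must be 'skip' or 'include', "
                         f"got {span_zeros!r}")
    at_site = stem_records[stem_records["site"] == site]
    if at_site.empty:
        raise AbundanceUndefined(f"no stem surveys at site {site!r}")

    weekly: dict[int, float] = {}
    for week, wk in at_site.groupby("week"):
        zones = wk["zone"].unique()
        sp = wk[wk["plant_id"] == plant_id]
        per_zone = sp.groupby("zone")["stems"].sum()
        # absent-from-records zones count 0 only when the zone was surveyed
        total = float(per_zone.reindex(zones, fill_value=0).sum())
        weekly[int(week)] = total / len(zones)

    weeks_positive = [w for w, v in weekly.items() if v > 0]
    if not weeks_positive:
        raise AbundanceUndefined(
            f"species {plant_id!r} never recorded flowering at {site!r}")
    lo, hi = min(weeks_positive), max(weeks_positive)
    span = {w: v for w, v in weekly.items() if lo <= w <= hi}
    if span_zeros == "skip":
        span = {w: v for w, v in span.items() if v > 0}
    values = list(span.values())
    return float(np.mean(values)), len(values)


def mean_floral_units_per_stem(floral_unit_records: pd.DataFrame,
                               plant_id: str) -> tuple[float, int]:
    """Study-wide mean floral units per stem for one species.

    Pools every stem measurement across sites and both data sources;
    one value per species for the whole study area.
    """
    sp = floral_unit_records[floral_unit_records["plant_id"] == plant_id]
    if sp.empty:
        raise AbundanceUndefined(
            f"no floral-unit data for species {plant_id!r}")
    vals = sp["floral_units_on_stem"].astype(float)
    return float(vals.mean()), int(len(vals))


def floral_abundance(stem_records: pd.DataFrame,
                     floral_unit_records: pd.DataFrame,
                     site: str, plant_id: str,
                     span_zeros: str = "skip") -> FloralAbundance:
    """Abundance estimate for one site x species (no fallback)."""
    mean_stems, n_weeks = mean_weekly_stems(stem_records, site, plant_id,
                                            span_zeros=span_zeros)
    mean_fu, n_meas = mean_floral_units_per_stem(floral_unit_records, plant_id)
    return FloralAbundance(
        site=site, plant_id=plant_id,
        mean_stems=mean_stems,
        mean_floral_units_per_stem=mean_fu,
        abundance=mean_stems * mean_fu,
        n_weeks_observed=n_weeks,
        n_stem_measurements=n_meas,
    )


def abundance_table(stem_records: pd.DataFrame,
                    floral_unit_records: pd.DataFrame,
                    span_zeros: str = "skip",
                    fallback: str = "species_mean") -> pd.DataFrame:
    """Abundance estimates for every site x species pair with any data.

    Fallback policy for missing components (``fallback``):

    * ``"species_mean"`` — use the species mean abundance across the
      other sites, else the smallest positive abundance study-wide,
      else drop;
    * ``"min_positive"`` — skip straight to the smallest positive value;
    * ``"drop"`` — drop the pair with a warning.
    """
    if fallback not in ("species_mean", "min_positive", "drop"):
        raise ValueError(f"unknown fallback {fallback!r}")
    sites = sorted(stem_records["site"].unique())
    plant_ids = sorted(
        set(stem_records["plant_id"]) | set(floral_unit_records["plant_id"])
    )
    rows: list[FloralAbundance] = []
    missing: list[tuple[str, str]] = []
    for site in sites:
        seen = set(stem_records.loc[stem_records["site"] == site, "plant_id"])
        for pid in plant_ids:
            if pid not in seen:
                continue
            try:
                rows.append(floral_abundance(stem_records, floral_unit_records,
                                             site, pid, span_zeros=span_zeros))
            except AbundanceUndefined:
                missing.append((site, pid))
    df = pd.DataFrame([vars(r) for r in rows])

    if missing and fallback != "drop" and not df.empty:
        min_positive = df.loc[df["abundance"] > 0, "abundance"].min()
        extra = []
        for site, pid in missing:
            sp = df[(df["plant_id"] == pid) & (df["abundance"] > 0)]
            if fallback == "species_mean" and not sp.empty:
                value = float(sp["abundance"].mean())
            elif np.isfinite(min_positive):
                value = float(min_positive)
            else:
                log.warning("dropping %s at %s: no abundance data and no "
                            "positive fallback", pid, site)
                continue
            extra.append({"site": site, "plant_id": pid,
                          "mean_stems": np.nan,
                          "mean_floral_units_per_stem": np.nan,
                          "abundance": value,
                          "n_weeks_observed": 0, "n_stem_measurements": 0})
        if extra:
            df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    elif missing:
        for site, pid in missing:
            log.warning("dropping %s at %s: abundance undefined", pid, site)
    return df.reset_index(drop=True)
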