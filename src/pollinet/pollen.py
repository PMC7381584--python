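"""Knapweed pollen proportions in bee bread and nectar, apiary-level
averages, and across-apiary summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATRICES = ("bee_bread", "nectar")


@dataclass(frozen=True)
class ApiarySummary:
    apiary_id: str
    matrix: str
    mean_percent: float
    n_rounds: int
    contains_knapweed: bool


def percent_knapweed(knapweed_grains, total_grains):
    """100 x knapweed / total grains. Vectorized; total 0 is an error."""
    k = np.asarray(knapweed_grains, dtype=float)
    t = np.asarray(total_grains, dtype=float)
    if np.any(t <= 0):
        raise ValueError("total_grains must be > 0")
    if np.any(k < 0) or np.any(k > t):
        raise ValueError("need 0 <= knapweed_grains <= total_grains")
    out = 100.0 * k / t
    return out if out.ndim else float(out)


def apiary_summaries(pollen: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apiary-level means and across-apiary statistics, per matrix.

    The apiary mean averages the per-sample percentages over rounds;
    across-apiary median/min/max are computed on the apiary means (not
    pooled samples). ``contains_knapweed`` is true when any round has
    knapweed grains > 0 — equivalent to mean_percent > 0.

    Returns ``(per_apiary, across)`` dataframes.
    """
    df = pollen.copy()
    df["percent"] = percent_knapweed(df["knapweed_grains"],
                                     df["total_grains"])
    per = (df.groupby(["apiary_id", "matrix"])
           .agg(mean_percent=("percent", "mean"),
                n_rounds=("percent", "size"),
                any_knapweed=("knapweed_grains", lambda s: bool((s > 0).any())))
           .reset_index()
           .rename(columns={"any_knapweed": "contains_knapweed"}))

    rows = []
    for matrix, grp in per.groupby("matrix"):
        means = grp["mean_percent"].to_numpy()
        rows.append({
            "matrix": matrix,
            "n_apiaries": len(grp),
            "median_percent": float(np.median(means)),
            "min_percent": float(means.min()),
            "max_percent": float(means.max()),
            "fraction_with_knapweed":
                float(grp["contains_knapweed"].mean()),
        })
    return per, pd.DataFrame(rows)
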