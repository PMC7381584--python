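"""Shannon diversity and richness per netting period, and the mixed
models relating bee diversity to native status and floral abundance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_schema import split_specimens


@dataclass(frozen=True)
class DiversityResult:
    netting_id: str
    site: str
    week: int
    plant_id: str
    shannon: float
    richness: int
    n_specimens: int


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i, in nats.

    ``counts`` is a mapping taxon -> count or an iterable of counts.
    Zero-count taxa are ignored; empty and single-taxon samples give 0.
    """
    if isinstance(counts, Mapping):
        values = list(counts.values())
    else:
        values = list(counts)
    c = np.asarray(values, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size <= 1:
        return 0.0
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of taxa with count > 0. Morphotype labels are taxa."""
    if isinstance(counts, Mapping):
        values = list(counts.values())
    else:
        values = list(counts)
    c = np.asarray(values, dtype=float) if values else np.array([])
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return int((c > 0).sum())


def specimen_counts(labels: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def diversity_by_period(netting: pd.DataFrame,
                        keep_empty: bool = True) -> pd.DataFrame:
    """Shannon and richness for every netting period.

    Specimen lists come from the semicolon-separated ``specimens``
    column; empty periods are retained with H = 0, S = 0 unless
    ``keep_empty`` is false.
    """
    rows = []
    for _, r in netting.iterrows():
        labels = (r["specimens"] if isinstance(r["specimens"], tuple)
                  else split_specimens(r["specimens"]))
        counts = specimen_counts(labels)
        if not counts and not keep_empty:
            continue
        rows.append(DiversityResult(
            netting_id=str(r["netting_id"]), site=str(r["site"]),
            week=int(r["week"]), plant_id=str(r["plant_id"]),
            shannon=shannon(counts), richness=richness(counts),
            n_specimens=len(labels)))
    return pd.DataFrame([vars(r) for r in rows])


def diversity_models(results: pd.DataFrame, abundance: pd.DataFrame,
                     plants: pd.DataFrame):
    """Mixed models for Shannon diversity (Gaussian) and richness
    (Poisson): response ~ native_status * abundance, random intercepts
    for site, week, and plant species.

    The Gaussian model fits crossed random intercepts as variance
    components; the Poisson model uses a fixed-effects GLM with
    cluster-robust covariance on plant species (no crossed-intercept
    Poisson backend available; mode recorded in the output). Returns
    ``(shannon_fit, richness_fit, lrt_table)`` where the LRT table has
    one row per response x source (status, abundance, interaction).
    """
    import statsmodels.formula.api as smf

    from .visitation_models import LRTResult, fit_lmm_vc, likelihood_ratio_test

    df = (results.merge(plants[["plant_id", "native_status"]], on="plant_id")
          .merge(abundance[["site", "plant_id", "abundance"]],
                 on=["site", "plant_id"], how="inner"))
    if df.empty:
        raise ValueError("no rows after joining diversity, plants, abundance")
    if df["native_status"].nunique() < 2:
        raise ValueError("degenerate factor: only one native_status present")
    df = df.copy()
    df["abundance_z"] = ((df["abundance"] - df["abundance"].mean())
                         / df["abundance"].std(ddof=0))

    vc = {"site": "0 + C(site)", "week": "0 + C(week)",
          "plant": "0 + C(plant_id)"}
    lrt_rows = []

    # Shannon: Gaussian LMM with crossed variance components
    formulas = {
        "full": "shannon ~ native_status * abundance_z",
        "additive": "shannon ~ native_status + abundance_z",
        "no_status": "shannon ~ abundance_z",
        "no_abundance": "shannon ~ native_status",
    }
    fits = {k: fit_lmm_vc(f, df, vc) for k, f in formulas.items()}
    shannon_fit = fits["full"]
    for term, full, red in (
            ("native_status:abundance", "full", "additive"),
            ("native_status", "additive", "no_status"),
            ("abundance", "additive", "no_abundance")):
        t = likelihood_ratio_test(fits[full], fits[red])
        lrt_rows.append({"response": "shannon", "term": term, **vars(t)})

    # richness: Poisson GLM, plant-clustered robust covariance
    import statsmodels.api as sm

    pfits = {}
    for k, f in formulas.items():
        pf = f.replace("shannon", "richness")
        pfits[k] = smf.glm(pf, df, family=sm.families.Poisson()).fit(
            cov_type="cluster", cov_kwds={"groups": df["plant_id"]})
    richness_fit = pfits["full"]
    for term, full, red in (
            ("native_status:abundance", "full", "additive"),
            ("native_status", "additive", "no_status"),
            ("abundance", "additive", "no_abundance")):
        t = likelihood_ratio_test(pfits[full], pfits[red])
        lrt_rows.append({"response": "richness", "term": term, **vars(t)})

    lrt = pd.DataFrame(lrt_rows)
    lrt["mode"] = np.where(lrt["response"] == "shannon",
                           "lmm_crossed_vc", "poisson_cluster_robust")
    return shannon_fit, richness_fit, lrt
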