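"""Visitation-rate models: negative-binomial regression with exposure
offsets, likelihood-ratio tests, slope and means contrasts with a
max-|t| (Tukey-style) adjustment, and the knapweed-vs-coflowering
contrast.

Backend note: the contract calls for crossed random intercepts
(observation period, site, week, plant species) in a negative-binomial
model. No pure-Python backend fits that family with crossed random
effects, so the documented approximation used here is a fixed-effects
NB2 fit with cluster-robust covariance (clustered on plant species by
default, the dominant grouping); every fit records which mode ran in
``RateModelFit.mode``. Gaussian responses (preference, Shannon
diversity) do get true crossed random intercepts via variance
components in a linear mixed model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

log = logging.getLogger(__name__)

TUKEY_MC_DRAWS = 200_000
TUKEY_MC_SEED = 20200617  # fixed: adjusted p-values must be reproducible


class DegenerateDesignError(ValueError):
    """The fixed-effects design is rank-deficient."""


class NonNestedError(ValueError):
    """The reduced model is not nested in the full model."""


@dataclass
class RateModelFit:
    """A fitted (approximate) NB2 rate model."""

    formula: str
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float  # theta of NB2: var = mu + mu^2 / theta
    llf: float
    converged: bool
    mode: str  # "nb_cluster_robust" — random effects approximated
    n_obs: int
    design_info: object = field(repr=False, default=None)
    result: object = field(repr=False, default=None)
    abundance_term: str | None = None

    @property
    def k_params(self) -> int:
        return len(self.params)


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    statistic: float
    p_adjusted: float
    adjustment: str  # "none" | "tukey-maxt"


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def visitation_rate(visits, floral_units, minutes):
    """Visits per floral unit per minute.

    Vectorized; zero exposure (floral_units < 1 or minutes <= 0) is an
    error because the rate denominator vanishes.
    """
    v = np.asarray(visits, dtype=float)
    fu = np.asarray(floral_units, dtype=float)
    m = np.asarray(minutes, dtype=float)
    if np.any(fu < 1) or np.any(m <= 0):
        raise ValueError("zero exposure: floral_units must be >= 1 and "
                         "minutes > 0")
    out = v / (fu * m)
    return out if out.ndim else float(out)


def long_rates_table(filtered_obs: pd.DataFrame) -> pd.DataFrame:
    """Reshape filtered observations to one row per period x pollinator
    type, with visits, exposure, and the rate."""
    rows = []
    for _, r in filtered_obs.iterrows():
        for ptype, col in (("honey_bee", "honey_bee_visits"),
                           ("wild", "wild_visits")):
            rows.append({
                "obs_id": r["obs_id"], "site": r["site"],
                "week": int(r["week"]), "plant_id": r["plant_id"],
                "pollinator_type": ptype,
                "visits": int(r[col]),
                "floral_units": int(r["floral_units"]),
                "minutes": float(r["minutes"]),
            })
    df = pd.DataFrame(rows)
    df["exposure"] = df["floral_units"] * df["minutes"]
    df["rate"] = visitation_rate(df["visits"], df["floral_units"],
                                 df["minutes"])
    return df


def _apply_transform(x: pd.Series, transform: str) -> pd.Series:
    if transform == "identity":
        return x
    if transform == "log1p":
        return np.log1p(x)
    if transform == "log":
        return np.log(x)
    raise ValueError(f"unknown abundance transform {transform!r}")


def fit_rate_model(table: pd.DataFrame,
                   fixed: str = "abundance_x * native_status * pollinator_type",
                   offset_col: str = "exposure",
                   cluster_col: str = "plant_id",
                   abundance_col: str = "abundance",
                   abundance_transform: str = "identity",
                   maxiter: int = 500) -> RateModelFit:
    """Fit the NB2 rate model with a log exposure offset.

    ``table`` is long-format (one row per observation period x
    pollinator type) with a ``visits`` count response. The offset is
    ``log(offset_col)`` (floral units x minutes). The abundance
    covariate enters as ``abundance_x`` after the configured transform
    (identity by default). Inference uses a cluster-robust covariance
    (``cluster_col``); non-convergence is flagged on the result rather
    than raised.
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    if abundance_col in df.columns:
        df["abundance_x"] = _apply_transform(df[abundance_col].astype(float),
                                             abundance_transform)
    offset = np.log(df[offset_col].astype(float))
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset log(exposure) must be finite and positive")

    formula = f"visits ~ {fixed}"
    for col in df.columns:
        if col in fixed and df[col].dtype == object \
                and df[col].nunique() < 2:
            raise DegenerateDesignError(
                f"rank-deficient design: factor {col!r} is constant")
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns; a factor "
            f"is constant or aliased in {list(X.columns)}")

    model = smf.negativebinomial(formula, df, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=maxiter, cov_type="cluster",
                            cov_kwds={"groups": df[cluster_col]})
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as e:  # keep the pipeline runnable
            log.warning("NB fit failed (%s); refitting with plain covariance",
                        e)
            res = model.fit(disp=0, maxiter=maxiter)
            converged = False

    alpha = float(res.params.get("alpha", np.nan))
    theta = 1.0 / alpha if alpha > 0 else np.inf
    return RateModelFit(
        formula=formula,
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                         columns=res.params.index),
        dispersion=theta,
        llf=float(res.llf),
        converged=converged,
        mode="nb_cluster_robust",
        n_obs=len(df),
        design_info=X.design_info,
        result=res,
        abundance_term="abundance_x" if abundance_col in table.columns else None,
    )


def fit_lmm_vc(formula: str, data: pd.DataFrame,
               vc_formula: dict[str, str]):
    """Gaussian linear mixed model with crossed random intercepts.

    Crossed intercepts are expressed as variance components over a
    single all-rows group; fitted by maximum likelihood so log
    likelihoods are comparable across nested mean structures.
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    df["_all"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups="_all",
                            vc_formula=vc_formula, re_formula="0")
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
    return res


def likelihood_ratio_test(fit_full, fit_reduced) -> LRTResult:
    """2(ll_full - ll_reduced) against chi-squared.

    Accepts any pair of fits exposing ``llf`` and ``params`` (our
    :class:`RateModelFit`, statsmodels results). Requires the reduced
    fixed-effect terms to be a subset of the full model's; the degrees
    of freedom are the parameter-count difference. The statistic is
    clamped at zero (boundary/optimizer noise).
    """
    def names(f):
        p = getattr(f, "params", None)
        if hasattr(p, "index"):
            return list(p.index)
        return [f"b{i}" for i in range(len(p))]

    full_names, red_names = names(fit_full), names(fit_reduced)
    # only compare mean-structure names when both carry labels
    if not set(red_names) <= set(full_names):
        extra = sorted(set(red_names) - set(full_names))
        raise NonNestedError(
            f"reduced model has terms absent from the full model: {extra}")
    df = len(full_names) - len(red_names)
    if df < 0:
        raise NonNestedError("reduced model has more parameters than full")
    chi2 = max(0.0, 2.0 * (float(fit_full.llf) - float(fit_reduced.llf)))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# contrasts


def _coef_and_cov(fit: RateModelFit) -> tuple[pd.Series, pd.DataFrame]:
    """Mean-structure coefficients, excluding the NB dispersion."""
    keep = [n for n in fit.params.index if n != "alpha"]
    return fit.params[keep], fit.cov.loc[keep, keep]


def tukey_maxt_pvalues(estimates: np.ndarray, cov: np.ndarray,
                       n_draws: int = TUKEY_MC_DRAWS,
                       seed: int = TUKEY_MC_SEED) -> np.ndarray:
    """Single-step max-|t| adjusted p-values for a set of contrasts.

    p_k = P(max_j |Z_j| >= |z_k|) with Z multivariate normal with the
    contrast correlation matrix — the Tukey-style family-wise
    adjustment. Exact for one contrast; Monte-Carlo integration with a
    fixed seed otherwise.
    """
    est = np.asarray(estimates, dtype=float)
    V = np.atleast_2d(np.asarray(cov, dtype=float))
    se = np.sqrt(np.diag(V))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
    if len(est) == 1:
        return np.array([2 * stats.norm.sf(abs(z[0]))])
    denom = np.outer(se, se)
    corr = np.where(denom > 0, V / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    # nearest PSD guard for MC sampling
    w, U = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    A = U * np.sqrt(w)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, len(est))) @ A.T
    maxabs = np.abs(draws).max(axis=1)
    return np.array([
        float(np.mean(maxabs >= abs(zk))) if np.isfinite(zk) else 0.0
        for zk in z
    ])


def _design_row(fit: RateModelFit, **factors) -> np.ndarray:
    new = pd.DataFrame([factors])
    (mat,) = patsy.build_design_matrices([fit.design_info], new)
    return np.asarray(mat)[0]


def _slope_vector(fit: RateModelFit, status: str, ptype: str) -> np.ndarray:
    """d(linear predictor)/d(abundance_x) for one status x type cell."""
    if fit.abundance_term is None:
        raise ValueError("model has no abundance covariate")
    base = dict(abundance_x=0.0, native_status=status, pollinator_type=ptype)
    x0 = _design_row(fit, **base)
    base["abundance_x"] = 1.0
    x1 = _design_row(fit, **base)
    return x1 - x0  # linear in abundance, so exact


def abundance_slopes(fit: RateModelFit,
                     statuses: Sequence[str] = ("native", "introduced"),
                     ptypes: Sequence[str] = ("honey_bee", "wild"),
                     ) -> tuple[list[ContrastResult], list[ContrastResult]]:
    """Abundance slopes per native_status x pollinator_type, plus the
    pairwise slope differences within each pollinator type.

    Returns ``(slopes, differences)``; slope tests are unadjusted Wald
    tests, differences carry the max-|t| adjustment within type.
    """
    beta, V = _coef_and_cov(fit)
    slope_vecs = {}
    for pt in ptypes:
        for st in statuses:
            L = _slope_vector(fit, st, pt)
            if len(L) != len(beta):
                raise ValueError("contrast length mismatch with coefficients")
            slope_vecs[(pt, st)] = L

    slopes: list[ContrastResult] = []
    for (pt, st), L in slope_vecs.items():
        est = float(L @ beta.to_numpy())
        var = float(L @ V.to_numpy() @ L)
        se = np.sqrt(var)
        zstat = est / se if se > 0 else np.inf
        slopes.append(ContrastResult(
            label=f"slope[{pt},{st}]", estimate=est, se=se, statistic=zstat,
            p_adjusted=float(2 * stats.norm.sf(abs(zstat))),
            adjustment="none"))

    diffs: list[ContrastResult] = []
    for pt in ptypes:
        pairs = [(a, b) for i, a in enumerate(statuses)
                 for b in statuses[i + 1:]]
        Ls = [slope_vecs[(pt, b)] - slope_vecs[(pt, a)] for a, b in pairs]
        ests = np.array([L @ beta.to_numpy() for L in Ls])
        covs = np.array([[Li @ V.to_numpy() @ Lj for Lj in Ls] for Li in Ls])
        padj = tukey_maxt_pvalues(ests, covs)
        for (a, b), est, var, p in zip(pairs, ests, np.diag(covs), padj):
            se = np.sqrt(var)
            diffs.append(ContrastResult(
                label=f"slope_diff[{pt}: {b} - {a}]", estimate=float(est),
                se=float(se), statistic=float(est / se) if se > 0 else np.inf,
                p_adjusted=float(p), adjustment="tukey-maxt"))
    return slopes, diffs


def status_main_effect(fit: RateModelFit, ptype: str,
                       at_abundance: float) -> ContrastResult:
    """Introduced-vs-native contrast of the linear predictor for one
    pollinator type, evaluated at a fixed abundance (used when the two
    slopes within the type do not differ)."""
    beta, V = _coef_and_cov(fit)
    xi = _design_row(fit, abundance_x=at_abundance,
                     native_status="introduced", pollinator_type=ptype)
    xn = _design_row(fit, abundance_x=at_abundance,
                     native_status="native", pollinator_type=ptype)
    L = xi - xn
    est = float(L @ beta.to_numpy())
    se = float(np.sqrt(L @ V.to_numpy() @ L))
    z = est / se if se > 0 else np.inf
    return ContrastResult(label=f"status[{ptype}] introduced - native",
                          estimate=est, se=se, statistic=z,
                          p_adjusted=float(2 * stats.norm.sf(abs(z))),
                          adjustment="none")


# ---------------------------------------------------------------------------
# knapweed contrast


@dataclass
class KnapweedContrast:
    fit: RateModelFit
    interaction_lrt: LRTResult
    means: pd.DataFrame            # rate-scale group means
    comparisons: list[ContrastResult]


def knapweed_contrast(table: pd.DataFrame,
                      knapweed_plants: Sequence[str],
                      cluster_col: str = "plant_id") -> KnapweedContrast:
    """Knapweed vs coflowering plants within the knapweed window.

    Fits visits ~ pollinator_type * plant_type with the exposure offset
    and NB2 family, then compares the four pollinator x plant-type
    means on the rate scale with max-|t| adjusted pairwise contrasts.
    """
    df = table.copy()
    knap = set(map(str, knapweed_plants))
    df["plant_type"] = np.where(df["plant_id"].astype(str).isin(knap),
                                "knapweed", "coflowering")
    if not (df["plant_type"] == "knapweed").any():
        raise ValueError("no knapweed rows in the supplied table")
    fit = fit_rate_model(df, fixed="pollinator_type * plant_type",
                         cluster_col=cluster_col, abundance_col="__none__")
    reduced = fit_rate_model(df, fixed="pollinator_type + plant_type",
                             cluster_col=cluster_col, abundance_col="__none__")
    lrt = likelihood_ratio_test(fit, reduced)

    beta, V = _coef_and_cov(fit)
    groups = [(pt, pl) for pt in ("honey_bee", "wild")
              for pl in ("knapweed", "coflowering")]
    rows = {g: _design_row(fit, pollinator_type=g[0], plant_type=g[1])
            for g in groups}
    means = []
    for g, x in rows.items():
        eta = float(x @ beta.to_numpy())
        se = float(np.sqrt(x @ V.to_numpy() @ x))
        means.append({"pollinator_type": g[0], "plant_type": g[1],
                      "rate": float(np.exp(eta)),
                      "rate_lo": float(np.exp(eta - 1.96 * se)),
                      "rate_hi": float(np.exp(eta + 1.96 * se))})
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    Ls = [rows[b] - rows[a] for a, b in pairs]
    ests = np.array([L @ beta.to_numpy() for L in Ls])
    covs = np.array([[Li @ V.to_numpy() @ Lj for Lj in Ls] for Li in Ls])
    padj = tukey_maxt_pvalues(ests, covs)
    comps = []
    for (a, b), est, var, p in zip(pairs, ests, np.diag(covs), padj):
        se = np.sqrt(var)
        comps.append(ContrastResult(
            label=f"{b[0]}/{b[1]} - {a[0]}/{a[1]}", estimate=float(est),
            se=float(se), statistic=float(est / se) if se > 0 else np.inf,
            p_adjusted=float(p), adjustment="tukey-maxt"))
    return KnapweedContrast(fit=fit, interaction_lrt=lrt,
                            means=pd.DataFrame(means), comparisons=comps)
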