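"""Null-model preference indices on site-week visitation matrices.

The observed matrix holds abundance-scaled visitation rates, rows =
pollinator types, columns = plant species observed that site-week.
Null matrices redistribute the rate mass at random while conserving the
row and column totals. Preference for a cell is the observed entry
minus the mean entry over the null ensemble: positive values indicate
preference, negative values avoidance.

The sampler core draws integer contingency tables from the multiple
hypergeometric distribution (the conditional distribution of
independent cells given both marginals) by sequential conditional
sampling — row by row, cell by cell, each cell a univariate
hypergeometric draw given what remains. Real-valued marginals are
handled by discretizing at a granularity ``g`` (largest-remainder
rounding so grand totals agree exactly), sampling the integer core, and
rescaling; marginal totals are then conserved to within ``1/g``.

With a single row the marginal constraints leave nothing random, so the
one-dimensional path drops the column constraints and allocates the row
total over cells by an equal-probability multinomial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_schema import POLLINATOR_TYPES

DEFAULT_GRANULARITY = 10_000
DEFAULT_N_REPLICATES = 1_000
#: auto-escalation cap for the discretization granularity
MAX_GRANULARITY = 10 ** 9


class MarginalError(ValueError):
    """Row and column totals are inconsistent or degenerate."""


# ---------------------------------------------------------------------------
# integer core


def _as_count_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x)
    if v.ndim != 1 or v.size == 0:
        raise MarginalError(f"{name} must be a non-empty 1-D vector")
    if np.any(v < 0):
        raise MarginalError(f"{name} must be non-negative")
    if not np.all(v == np.floor(v)):
        raise MarginalError(f"{name} must be integer-valued")
    return v.astype(np.int64)


def sample_integer_tables(row_sums, col_sums, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` integer tables with the given marginals.

    Sequential conditional (Patefield-style) sampling: filling row by
    row, the count for cell (i, j) given everything already placed is
    hypergeometric with ``ngood`` = remaining total of column j,
    ``nbad`` = remaining total of the later columns, and ``nsample`` =
    remaining total of row i. Marginals are conserved exactly in every
    replicate, and the table distribution is the multiple
    hypergeometric

        P(n) = (prod_i r_i!)(prod_j c_j!) / (N! prod_ij n_ij!).

    Vectorized over replicates; returns an array of shape
    ``(size, n_rows, n_cols)``.
    """
    r = _as_count_vector(row_sums, "row_sums")
    c = _as_count_vector(col_sums, "col_sums")
    if r.sum() != c.sum():
        raise MarginalError(
            f"marginal mismatch: sum(row_sums)={r.sum()} != "
            f"sum(col_sums)={c.sum()}")
    n_rows, n_cols = len(r), len(c)
    out = np.zeros((size, n_rows, n_cols), dtype=np.int64)
    col_rem = np.broadcast_to(c, (size, n_cols)).copy()
    for i in range(n_rows - 1):
        row_rem = np.full(size, r[i], dtype=np.int64)
        # totals of columns j+1..C-1, updated as cells are placed
        tail = col_rem[:, ::-1].cumsum(axis=1)[:, ::-1]
        for j in range(n_cols - 1):
            ngood = col_rem[:, j]
            nbad = tail[:, j + 1]
            draw = np.zeros(size, dtype=np.int64)
            active = row_rem > 0
            if np.any(active):
                draw[active] = rng.hypergeometric(
                    ngood[active], nbad[active], row_rem[active])
            out[:, i, j] = draw
            row_rem -= draw
            col_rem[:, j] -= draw
        out[:, i, n_cols - 1] = row_rem
        col_rem[:, n_cols - 1] -= row_rem
    out[:, n_rows - 1, :] = col_rem
    return out


def sample_integer_table(row_sums, col_sums,
                         rng: np.random.Generator) -> np.ndarray:
    """One integer table with the given marginals (see batch variant)."""
    return sample_integer_tables(row_sums, col_sums, 1, rng)[0]


def table_pmf(row_sums, col_sums) -> dict[bytes, float]:
    """Enumerate the multiple-hypergeometric pmf over all tables.

    Independent oracle for the sampler: exhaustive enumeration, with
    P(n) = (prod r_i!)(prod c_j!) / (N! prod n_ij!). Keys are the
    ``tobytes`` serialization of the int64 table. Only feasible for
    small grand totals.
    """
    from math import factorial

    r = _as_count_vector(row_sums, "row_sums")
    c = _as_count_vector(col_sums, "col_sums")
    if r.sum() != c.sum():
        raise MarginalError("marginal mismatch")
    n_rows, n_cols = len(r), len(c)
    tables: list[np.ndarray] = []

    def rec(i: int, col_rem: np.ndarray, acc: list[np.ndarray]) -> None:
        if i == n_rows:
            if np.all(col_rem == 0):
                tables.append(np.array(acc))
            return
        # enumerate compositions of r[i] bounded by col_rem
        def comp(j: int, rem: int, row: list[int]) -> None:
            if j == n_cols - 1:
                if rem <= col_rem[j]:
                    rec(i + 1, col_rem - np.array(row + [rem]),
                        acc + [np.array(row + [rem])])
                return
            for v in range(min(rem, col_rem[j]) + 1):
                comp(j + 1, rem - v, row + [v])

        comp(0, int(r[i]), [])

    rec(0, c.copy(), [])
    const = (np.prod([float(factorial(int(x))) for x in r])
             * np.prod([float(factorial(int(x))) for x in c])
             / factorial(int(r.sum())))
    pmf: dict[bytes, float] = {}
    for t in tables:
        denom = np.prod([float(factorial(int(x))) for x in t.ravel()])
        pmf[t.astype(np.int64).tobytes()] = const / denom
    total = sum(pmf.values())
    return {k: v / total for k, v in pmf.items()}


# ---------------------------------------------------------------------------
# decimal marginals


def round_preserving_sum(values, target_total: int) -> np.ndarray:
    """Largest-remainder rounding of non-negative reals to integers
    summing exactly to ``target_total``."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    base = np.floor(v).astype(np.int64)
    short = int(target_total - base.sum())
    if short < 0:
        # target below the floor sum: trim from the smallest remainders
        order = np.argsort(v - base, kind="stable")
        out = base.copy()
        for idx in order:
            if short == 0:
                break
            if out[idx] > 0:
                out[idx] -= 1
                short += 1
        if short != 0:
            raise ValueError("cannot round to target total")
        return out
    remainders = v - base
    order = np.argsort(-remainders, kind="stable")
    out = base.copy()
    out[order[:short]] += 1
    return out


def _discretize_marginals(row_sums, col_sums, g: int,
                          tolerance: float) -> tuple[np.ndarray, np.ndarray, int]:
    r = np.asarray(row_sums, dtype=float)
    c = np.asarray(col_sums, dtype=float)
    if np.any(r < 0) or np.any(c < 0):
        raise MarginalError("marginals must be non-negative")
    if abs(r.sum() - c.sum()) > tolerance * max(1.0, r.sum()):
        raise MarginalError(
            f"marginal mismatch beyond tolerance: {r.sum()} vs {c.sum()}")
    grand = 0.5 * (r.sum() + c.sum())
    while True:
        n = int(round(grand * g))
        ri = round_preserving_sum(r * g, n)
        ci = round_preserving_sum(c * g, n)
        bad = (np.any((r > 0) & (ri == 0)) or np.any((c > 0) & (ci == 0))
               or (grand > 0 and n == 0))
        if not bad:
            return ri, ci, g
        if g * 10 > MAX_GRANULARITY:
            raise MarginalError(
                f"positive marginal rounds to zero even at granularity "
                f"{g}; refusing to discretize")
        g *= 10


def sample_decimal_tables(row_sums, col_sums, size: int,
                          rng: np.random.Generator,
                          g: int = DEFAULT_GRANULARITY,
                          tolerance: float = 1e-9) -> np.ndarray:
    """Draw ``size`` real-valued tables conserving decimal marginals.

    Marginals are multiplied by ``g``, rounded with largest-remainder
    correction so the grand totals agree exactly, passed to the integer
    sampler, and divided back by ``g``. Row/column sums of the result
    differ from the targets by at most ``1/g`` per margin. ``g`` is
    auto-escalated x10 (up to a cap) if a positive marginal would round
    to zero.
    """
    if g < 100:
        raise ValueError("granularity g must be >= 100")
    ri, ci, g_used = _discretize_marginals(row_sums, col_sums, int(g),
                                           tolerance)
    tables = sample_integer_tables(ri, ci, size, rng)
    return tables.astype(float) / g_used


def sample_decimal_table(row_sums, col_sums, rng: np.random.Generator,
                         g: int = DEFAULT_GRANULARITY,
                         tolerance: float = 1e-9) -> np.ndarray:
    return sample_decimal_tables(row_sums, col_sums, 1, rng, g=g,
                                 tolerance=tolerance)[0]


def sample_one_dim(total: float, n_cells: int, rng: np.random.Generator,
                   g: int = DEFAULT_GRANULARITY,
                   size: int = 1) -> np.ndarray:
    """Allocate ``total`` over ``n_cells`` by equal-probability multinomial.

    The single-row degenerate case: fixing both marginals of a 1 x S
    matrix would leave nothing random, so the column constraints are
    dropped. Returns shape ``(size, n_cells)``; each row sums to
    ``total`` within ``1/g``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if total < 0:
        raise ValueError("total must be >= 0")
    m = int(round(total * g))
    draws = rng.multinomial(m, np.full(n_cells, 1.0 / n_cells), size=size)
    return draws.astype(float) * (total / m if m > 0 else 0.0)


# ---------------------------------------------------------------------------
# site-week matrices


def proportional_abundance(abundances: Mapping[str, float]) -> dict[str, float]:
    """Normalize the abundances of the plants observed in a site-week to
    shares summing to 1."""
    total = float(sum(abundances.values()))
    if any(v < 0 for v in abundances.values()):
        raise ValueError("abundances must be non-negative")
    if total <= 0:
        raise ValueError("all abundances are zero; shares undefined")
    return {k: float(v) / total for k, v in abundances.items()}


@dataclass
class SiteWeekMatrix:
    """Pollinator-type x plant matrix of (scaled) visitation rates."""

    site: str
    week: int
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray  # shape (len(row_labels), len(col_labels))
    scaling_mode: str = "multiply"
    one_dimensional: bool = False
    raw_rates: np.ndarray | None = None

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")
        assert np.allclose(self.values.sum(axis=1), self.row_sums, atol=atol)
        assert np.allclose(self.values.sum(axis=0), self.col_sums, atol=atol)


def build_site_week_matrix(rates: pd.DataFrame,
                           shares: Mapping[str, float],
                           scaling_mode: str = "multiply",
                           site: str | None = None,
                           week: int | None = None) -> SiteWeekMatrix:
    """Assemble one site-week matrix from long-format rates.

    ``rates`` has columns (pollinator_type, plant_id, rate), one row per
    type x plant observed that site-week. Scaling modes: ``multiply``
    (default; entry = rate x share), ``divide`` (rate / share; a plant
    with share 0 is dropped with a warning), ``none`` (raw rate).

    When every honey-bee rate is zero the honey-bee row is omitted and
    the matrix is flagged one-dimensional (no honey-bee preference is
    calculated for that site-week).
    """
    import warnings as _warnings

    if scaling_mode not in ("multiply", "divide", "none"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    plants = list(dict.fromkeys(rates["plant_id"]))
    if scaling_mode == "divide":
        dropped = [p for p in plants if shares.get(p, 0.0) == 0.0]
        if dropped:
            _warnings.warn(f"divide scaling: dropping plants with zero "
                           f"share: {dropped}", stacklevel=2)
            plants = [p for p in plants if p not in dropped]

    pivot = (rates.pivot_table(index="pollinator_type", columns="plant_id",
                               values="rate", aggfunc="mean")
             .reindex(index=list(POLLINATOR_TYPES), columns=plants)
             .fillna(0.0))
    raw = pivot.to_numpy(dtype=float)

    share_vec = np.array([shares[p] for p in plants], dtype=float)
    if scaling_mode == "multiply":
        values = raw * share_vec
    elif scaling_mode == "divide":
        values = raw / share_vec
    else:
        values = raw.copy()

    row_labels = list(POLLINATOR_TYPES)
    one_dim = False
    hb = row_labels.index("honey_bee")
    if np.all(values[hb] == 0):
        values = np.delete(values, hb, axis=0)
        raw = np.delete(raw, hb, axis=0)
        row_labels = [t for t in row_labels if t != "honey_bee"]
        one_dim = len(row_labels) == 1

    return SiteWeekMatrix(
        site=site if site is not None else str(rates.get("site", pd.Series(["?"])).iloc[0]),
        week=int(week) if week is not None else int(rates.get("week", pd.Series([0])).iloc[0]),
        row_labels=tuple(row_labels), col_labels=tuple(plants),
        values=values, scaling_mode=scaling_mode, one_dimensional=one_dim,
        raw_rates=raw,
    )


# ---------------------------------------------------------------------------
# preference


@dataclass
class NullEnsemble:
    """Per-cell summary of the null replicates for one matrix."""

    n_replicates: int
    mean: np.ndarray
    sd: np.ndarray
    seed: int | None = None

    @property
    def mc_se(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n_replicates)


def null_ensemble(matrix: SiteWeekMatrix, n_replicates: int,
                  rng: np.random.Generator,
                  g: int = DEFAULT_GRANULARITY) -> NullEnsemble:
    """Sample the null ensemble for a site-week matrix.

    Two-row matrices use the decimal marginal-conserving sampler; the
    one-dimensional path (honey bees absent) uses the equal-probability
    multinomial allocation of the single row total.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.values.shape[0] == 1:
        reps = sample_one_dim(float(matrix.values.sum()),
                              matrix.values.shape[1], rng, g=g,
                              size=n_replicates)[:, None, :]
    else:
        reps = sample_decimal_tables(matrix.row_sums, matrix.col_sums,
                                     n_replicates, rng, g=g)
    return NullEnsemble(n_replicates=n_replicates,
                        mean=reps.mean(axis=0),
                        sd=reps.std(axis=0, ddof=1) if n_replicates > 1
                        else np.zeros_like(reps[0]))


def preference_indices(matrix: SiteWeekMatrix,
                       n_replicates: int = DEFAULT_N_REPLICATES,
                       rng: np.random.Generator | None = None,
                       g: int = DEFAULT_GRANULARITY) -> pd.DataFrame:
    """Observed minus null-mean rate for every cell of one matrix.

    Returns a dataframe with one row per pollinator_type x plant:
    observed, expected (null mean), preference = observed - expected,
    and the Monte-Carlo standard error of the expected value.
    """
    if rng is None:
        rng = np.random.default_rng()
    ens = null_ensemble(matrix, n_replicates, rng, g=g)
    rows = []
    for i, ptype in enumerate(matrix.row_labels):
        for j, plant in enumerate(matrix.col_labels):
            obs = float(matrix.values[i, j])
            exp = float(ens.mean[i, j])
            rows.append({
                "site": matrix.site, "week": matrix.week,
                "plant_id": plant, "pollinator_type": ptype,
                "observed": obs, "expected": exp,
                "preference": obs - exp,
                "mc_se": float(ens.mc_se[i, j]),
                "one_dimensional": matrix.one_dimensional,
                "scaling_mode": matrix.scaling_mode,
            })
    return pd.DataFrame(rows)


def _siteweek_seed(master_seed: int, site: str, week: int) -> np.random.Generator:
    """Independent, order-invariant RNG stream for one site-week."""
    digest = hashlib.sha256(f"{site}|{week}".encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([master_seed, sub]))


def compute_preferences(rates: pd.DataFrame, abundance: pd.DataFrame,
                        n_replicates: int = DEFAULT_N_REPLICATES,
                        scaling_mode: str = "multiply",
                        g: int = DEFAULT_GRANULARITY,
                        seed: int = 0) -> pd.DataFrame:
    """Preference indices for every site-week in a long rates table.

    ``rates`` columns: site, week, plant_id, pollinator_type, rate.
    ``abundance`` columns: site, plant_id, abundance. Shares are the
    proportional abundances of the plants observed in each site-week.
    Each site-week draws from its own hashed RNG substream, so results
    do not depend on evaluation order.
    """
    ab = abundance.set_index(["site", "plant_id"])["abundance"]
    out = []
    for (site, week), grp in rates.groupby(["site", "week"], sort=True):
        plants = list(dict.fromkeys(grp["plant_id"]))
        raw = {}
        for p in plants:
            raw[p] = float(ab.get((site, p), np.nan))
        if any(np.isnan(v) for v in raw.values()):
            missing = [p for p, v in raw.items() if np.isnan(v)]
            raise KeyError(f"no abundance for {missing} at site {site!r}")
        shares = proportional_abundance(raw)
        m = build_site_week_matrix(grp, shares, scaling_mode=scaling_mode,
                                   site=str(site), week=int(week))
        rng = _siteweek_seed(seed, str(site), int(week))
        out.append(preference_indices(m, n_replicates=n_replicates,
                                      rng=rng, g=g))
    return pd.concat(out, ignore_index=True)


def aggregate_species_preference(results: pd.DataFrame) -> pd.DataFrame:
    """Mean preference per plant x pollinator type, with ranking.

    Unweighted mean over site-weeks; rank 1 is the most preferred
    species within each pollinator type.
    """
    agg = (results.groupby(["pollinator_type", "plant_id"])
           .agg(mean_preference=("preference", "mean"),
                n_site_weeks=("preference", "size"))
           .reset_index())
    agg["rank"] = (agg.groupby("pollinator_type")["mean_preference"]
                   .rank(ascending=False, method="min").astype(int))
    return agg.sort_values(["pollinator_type", "rank"]).reset_index(drop=True)


def preference_model(results: pd.DataFrame, plants: pd.DataFrame):
    """Linear mixed model: preference ~ native_status * pollinator_type.

    Random intercepts for observation cell (site-week-plant, pairing the
    honey-bee and wild rows), site, week, and plant species, fitted as
    crossed variance components by maximum likelihood. Likelihood-ratio
    tests for the interaction and both main effects, plus group means.
    """
    from .visitation_models import fit_lmm_vc, likelihood_ratio_test

    df = results.merge(plants[["plant_id", "native_status"]], on="plant_id",
                       how="inner")
    if df["pollinator_type"].nunique() < 2:
        raise ValueError("degenerate factor: only one pollinator_type "
                         "present; interaction model is unidentifiable")
    if df["native_status"].nunique() < 2:
        raise ValueError("degenerate factor: only one native_status present")
    df = df.copy()
    df["cell_id"] = (df["site"].astype(str) + ":" + df["week"].astype(str)
                     + ":" + df["plant_id"].astype(str))
    vc = {"cell": "0 + C(cell_id)", "site": "0 + C(site)",
          "week": "0 + C(week)", "plant": "0 + C(plant_id)"}
    full = fit_lmm_vc("preference ~ native_status * pollinator_type", df, vc)
    additive = fit_lmm_vc("preference ~ native_status + pollinator_type",
                          df, vc)
    no_status = fit_lmm_vc("preference ~ pollinator_type", df, vc)
    no_type = fit_lmm_vc("preference ~ native_status", df, vc)
    lrts = pd.DataFrame([
        {"term": "native_status:pollinator_type",
         **vars(likelihood_ratio_test(full, additive))},
        {"term": "native_status",
         **vars(likelihood_ratio_test(additive, no_status))},
        {"term": "pollinator_type",
         **vars(likelihood_ratio_test(additive, no_type))},
    ])
    means = (df.groupby(["pollinator_type", "native_status"])["preference"]
             .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
             .reset_index())
    return full, lrts, means
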