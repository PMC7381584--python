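"""Synthetic communities, observation designs, visit counts, netting
specimens, and pollen counts with recorded ground truth.

The default design mirrors the scale of a multi-site season: 3 sites x
18 weeks, 54 plant species (30 introduced / 24 native expected),
15-minute observation periods with >= 10 floral units. Visit counts are
drawn NB2 around

    mean = exposure x base_rate[type] x w[species, type]
                    x exp(beta[type, status] x centered log abundance)

so the abundance exponents beta, the species preference weights w, and
the dispersion theta are all recoverable estimands. All randomness
derives from one master seed via named substreams, so each product is
reproducible independently of generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_schema import POLLINATOR_TYPES, WILD_GROUPS


def _stream(master_seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([master_seed, sub]))


@dataclass
class GeneratorConfig:
    n_sites: int = 3
    n_weeks: int = 18
    n_plants: int = 54
    prop_introduced: float = 30 / 54
    # log-normal site x species floral abundance
    abundance_mu: float = 3.0
    abundance_sigma: float = 1.8
    # stems and floral-units-per-stem (abundance = product of the means)
    fu_per_stem_mu: float = 1.0
    fu_per_stem_sigma: float = 0.6
    n_quadrats: int = 3
    flowering_span: int = 6
    # visitation
    periods_per_site_week: int = 4
    plants_per_site_week: int = 6
    fixed_roster: bool = False  # observe the same plants every site-week
    floral_units_range: tuple[int, int] = (10, 50)
    minutes: float = 15.0
    base_rate: dict = field(default_factory=lambda: {
        "honey_bee": 0.02, "wild": 0.05})
    beta: dict = field(default_factory=lambda: {
        ("honey_bee", "native"): 0.0,
        ("honey_bee", "introduced"): 0.0,
        ("wild", "native"): -0.15,
        ("wild", "introduced"): -0.35,
    })
    weight_sigma: float = 0.2
    boosted_plant: str | None = None     # plant given extra visitation mass
    boosted_ptype: str | None = None     # boost one type only (None = both)
    boost_factor: float = 2.0
    theta: float = 3.0                   # NB2 dispersion (var = mu + mu^2/theta)
    # netting
    n_taxa: int = 20
    dirichlet_conc: float = 1.0
    mean_specimens: float = 6.0
    netting_per_site_week: int = 2
    # pollen
    n_apiaries: int = 22
    pollen_beta_a: float = 0.5
    pollen_beta_b: float = 4.0
    pollen_total: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_introduced <= 1.0:
            raise ValueError("prop_introduced must be in [0, 1]")
        for name in ("abundance_sigma", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class SyntheticTruth:
    """Generator parameters sufficient to compute every estimand."""

    statuses: dict              # plant_id -> native/introduced
    abundance: dict             # (site, plant_id) -> floral units/100m^2/wk
    log_abundance_center: float
    weights: dict               # (plant_id, pollinator_type) -> w
    beta: dict                  # (pollinator_type, status) -> exponent
    base_rate: dict
    theta: float
    realized_means: list = field(default_factory=list)

    def to_json(self) -> str:
        def keyed(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}
        payload = {
            "statuses": self.statuses,
            "abundance": keyed(self.abundance),
            "log_abundance_center": self.log_abundance_center,
            "weights": keyed(self.weights),
            "beta": keyed(self.beta),
            "base_rate": self.base_rate,
            "theta": self.theta,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _plant_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def generate_community(config: GeneratorConfig,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                  pd.DataFrame, SyntheticTruth]:
    """Plants, stem surveys, floral-unit counts, abundance, and truth.

    Abundances are log-normal per site x species; statuses are
    Bernoulli(prop_introduced). The stems and floral-units tables are
    constructed so that the abundance pipeline recovers the truth
    abundance exactly: weekly quadrat counts are constant over a
    flowering span and the per-stem counts are exact replicates of the
    species mean.
    """
    rng = _stream(config.seed, "community")
    plants = _plant_ids(config.n_plants)
    sites = [f"S{i}" for i in range(1, config.n_sites + 1)]
    status = np.where(rng.random(config.n_plants) < config.prop_introduced,
                      "introduced", "native")
    plants_df = pd.DataFrame({
        "plant_id": plants,
        "name": [f"Species {p}" for p in plants],
        "native_status": status,
    })

    # per-species floral units per stem; per site x species mean stems
    fu_per_stem = np.maximum(1.0, np.round(
        rng.lognormal(config.fu_per_stem_mu, config.fu_per_stem_sigma,
                      config.n_plants)))
    abundance_rows, stem_rows, fu_rows = [], [], []
    truth_abundance: dict = {}
    for si, site in enumerate(sites):
        mean_stems = np.maximum(1.0, np.round(
            rng.lognormal(config.abundance_mu, config.abundance_sigma,
                          config.n_plants) / fu_per_stem))
        start = rng.integers(1, max(2, config.n_weeks
                                    - config.flowering_span + 1),
                             config.n_plants)
        for pi, pid in enumerate(plants):
            stems_per_quadrat = mean_stems[pi]
            abundance = mean_stems[pi] * fu_per_stem[pi]
            truth_abundance[(site, pid)] = float(abundance)
            abundance_rows.append({
                "site": site, "plant_id": pid,
                "mean_stems": float(stems_per_quadrat),
                "mean_floral_units_per_stem": float(fu_per_stem[pi]),
                "abundance": float(abundance),
                "n_weeks_observed": config.flowering_span,
                "n_stem_measurements": 5,
            })
            for week in range(int(start[pi]),
                              int(start[pi]) + config.flowering_span):
                for q in range(config.n_quadrats):
                    stem_rows.append({
                        "site": site, "week": week, "zone": f"Z{q + 1}",
                        "plant_id": pid,
                        "stems": int(stems_per_quadrat),
                    })
        for pi, pid in enumerate(plants):
            for k in range(5):
                fu_rows.append({
                    "site": site, "date": f"2017-0{si + 5}-01",
                    "plant_id": pid, "stem_id": f"{site}-{pid}-{k}",
                    "floral_units_on_stem": int(fu_per_stem[pi]),
                })

    # species x type preference weights (log-normal, optionally boosted)
    weights: dict = {}
    for pid in plants:
        for ptype in POLLINATOR_TYPES:
            w = float(rng.lognormal(0.0, config.weight_sigma))
            if (config.boosted_plant == pid
                    and config.boosted_ptype in (None, ptype)):
                w *= config.boost_factor
            weights[(pid, ptype)] = w

    log_center = float(np.mean(np.log(list(truth_abundance.values()))))
    truth = SyntheticTruth(
        statuses=dict(zip(plants, map(str, status))),
        abundance=truth_abundance,
        log_abundance_center=log_center,
        weights=weights,
        beta=dict(config.beta),
        base_rate=dict(config.base_rate),
        theta=config.theta,
    )
    return (plants_df, pd.DataFrame(stem_rows), pd.DataFrame(fu_rows),
            pd.DataFrame(abundance_rows), truth)


def generate_observations(config: GeneratorConfig, plants_df: pd.DataFrame,
                          truth: SyntheticTruth) -> pd.DataFrame:
    """Observation periods with NB2 visit counts per visitor group.

    Honey-bee and wild means follow the generator's rate structure; the
    wild count is split over the wild visitor groups, and small
    ant/true-bug/outside-flower counts are added as filter fodder.
    """
    rng = _stream(config.seed, "observations")
    sites = sorted({s for s, _ in truth.abundance})
    status = truth.statuses
    rows = []
    obs_counter = 0
    lo, hi = config.floral_units_range
    for site in sites:
        for week in range(1, config.n_weeks + 1):
            if config.fixed_roster:
                chosen = plants_df["plant_id"].to_numpy()[
                    :config.plants_per_site_week]
            else:
                chosen = rng.choice(plants_df["plant_id"].to_numpy(),
                                    size=min(config.plants_per_site_week,
                                             len(plants_df)),
                                    replace=False)
            for k in range(config.periods_per_site_week):
                pid = str(chosen[k % len(chosen)])
                obs_counter += 1
                fu = int(rng.integers(lo, hi + 1))
                exposure = fu * config.minutes
                x = (np.log(truth.abundance[(site, pid)])
                     - truth.log_abundance_center)
                visits = {}
                for ptype in POLLINATOR_TYPES:
                    beta = truth.beta[(ptype, status[pid])]
                    mu = (exposure * truth.base_rate[ptype]
                          * truth.weights[(pid, ptype)] * np.exp(beta * x))
                    mu = min(mu, 1e6)  # overflow guard
                    visits[ptype] = int(rng.negative_binomial(
                        config.theta, config.theta / (config.theta + mu)))
                    truth.realized_means.append(
                        {"obs": obs_counter, "ptype": ptype, "mu": float(mu)})
                wild_split = rng.multinomial(
                    visits["wild"], [0.5, 0.35, 0.15])
                row = {
                    "obs_id": f"O{obs_counter:05d}", "site": site,
                    "week": week, "zone": f"Z{(k % 9) + 1}", "plant_id": pid,
                    "floral_units": fu, "minutes": config.minutes,
                    "visits_honey_bee": visits["honey_bee"],
                    "visits_ant": int(rng.poisson(0.3)),
                    "visits_true_bug": int(rng.poisson(0.1)),
                }
                for g, n in zip(WILD_GROUPS, wild_split):
                    row[f"visits_{g}"] = int(n)
                for g in ("honey_bee", *WILD_GROUPS, "ant", "true_bug"):
                    row[f"outside_{g}"] = int(rng.poisson(0.05))
                rows.append(row)
    return pd.DataFrame(rows)


def generate_netting(config: GeneratorConfig, plants_df: pd.DataFrame,
                     ) -> pd.DataFrame:
    """Netting periods with Dirichlet-multinomial specimen draws."""
    rng = _stream(config.seed, "netting")
    taxa = [f"taxon_{i:02d}" for i in range(1, config.n_taxa + 1)]
    rows = []
    nid = 0
    for site in [f"S{i}" for i in range(1, config.n_sites + 1)]:
        for week in range(1, config.n_weeks + 1):
            chosen = rng.choice(plants_df["plant_id"].to_numpy(),
                                size=min(config.netting_per_site_week,
                                         len(plants_df)), replace=False)
            for pid in chosen:
                nid += 1
                n = int(rng.poisson(config.mean_specimens))
                p = rng.dirichlet(np.full(config.n_taxa,
                                          config.dirichlet_conc))
                counts = rng.multinomial(n, p)
                specimens = [t for t, c in zip(taxa, counts)
                             for _ in range(c)]
                rows.append({
                    "netting_id": f"N{nid:05d}", "site": site, "week": week,
                    "zone": "Z1", "plant_id": str(pid),
                    "minutes": 15.0,
                    "specimens": ";".join(specimens),
                })
    return pd.DataFrame(rows)


def generate_pollen(config: GeneratorConfig) -> pd.DataFrame:
    """Two rounds of 300-grain counts per apiary; the knapweed share is
    Beta(a, b) per apiary, counts binomial."""
    rng = _stream(config.seed, "pollen")
    rows = []
    for i in range(1, config.n_apiaries + 1):
        for matrix in ("bee_bread", "nectar"):
            share = float(rng.beta(config.pollen_beta_a,
                                   config.pollen_beta_b))
            for rnd in (1, 2):
                rows.append({
                    "apiary_id": f"A{i:02d}", "round": rnd, "matrix": matrix,
                    "knapweed_grains": int(rng.binomial(config.pollen_total,
                                                        share)),
                    "total_grains": config.pollen_total,
                })
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    plants: pd.DataFrame
    observations: pd.DataFrame
    stems: pd.DataFrame
    floral_units: pd.DataFrame
    abundance: pd.DataFrame
    netting: pd.DataFrame
    pollen: pd.DataFrame
    truth: SyntheticTruth


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    plants, stems, fus, abund, truth = generate_community(config)
    obs = generate_observations(config, plants, truth)
    netting = generate_netting(config, plants)
    pollen = generate_pollen(config)
    return SyntheticDataset(plants=plants, observations=obs, stems=stems,
                            floral_units=fus, abundance=abund,
                            netting=netting, pollen=pollen, truth=truth)


def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("plants", "observations", "stems", "floral_units",
                 "netting", "pollen"):
        p = out / f"{name}.csv"
        getattr(data, name).to_csv(p, index=False)
        paths[name] = p
    (out / "truth.json").write_text(data.truth.to_json())
    paths["truth"] = out / "truth.json"
    return paths
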