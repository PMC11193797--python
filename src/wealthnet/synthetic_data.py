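"""Synthetic population generator.

Emulates the statistical structure the downstream analysis assumes, standing
in for restricted surveillance data: household-membership episodes over a
2000-2016 window whose shared-member ties form a sparse, long-tailed,
geographically clustered inter-household network (~10^4 households in 23
regions, mean degree ~1.72, global clustering ~0.21); two-wave binary asset
items driven by an autocorrelated latent wealth score; and binary outcome
vectors simulable from a known ALAAM parameter vector.

The tie-generating mechanism is a stand-in (the surveillance data records
membership flows, not their causes): each individual holds a primary
household membership; a configurable fraction acquire concurrent secondary
memberships in households chosen by geographic distance decay with a
triadic-closure shortcut (a two-hop contact of the primary household), and a
further fraction hold a third membership, which ties all three households
into a clique.  Multi-membership cliques and closure jointly produce the
clustering; a long-tailed household attractiveness weight produces the
degree tail.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from wealthnet.alaam_stats import AlaamModel, EffectSpec, OutcomeState
from wealthnet.network_build import (
    YEAR_MAX,
    YEAR_MIN,
    MultilevelNetwork,
    affiliate,
    build_ties,
)


class ConfigError(ValueError):
    pass


@dataclass
class WaveTransition:
    """Between-wave latent wealth dynamics.

    ``stay_prob`` is the target probability that a household keeps its latent
    wealth quintile between waves (sets the latent autocorrelation);
    ``contagion_strength`` adds a shift proportional to the mean baseline
    quintile (centred) of network neighbours.
    """

    stay_prob: float = 0.35
    contagion_strength: float = 0.0


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic population.

    Defaults emulate the observed surveillance population: ~11,834 households
    (~92,700 individuals) in 23 regions, a sparse shared-membership network
    with mean degree ~1.72 and global clustering ~0.21, ~28% non-resident
    members, 20 binary asset items per wave, and a majority of households
    changing wealth quintile between waves.
    """

    n_households: int = 11834
    n_regions: int = 23
    n_individuals: int | None = None  # default: 7.832 per household
    mean_degree_target: float = 1.72
    clustering_target: float = 0.21
    secondary_membership_rate: float = 0.0895
    distance_decay: float = 20.0
    triadic_closure_prob: float = 0.315
    extra_membership_prob: float = 0.15
    attractiveness_sigma: float = 0.8
    nonresident_rate: float = 0.28
    nonresident_dispersion: float = 0.5  # beta shape a; smaller = more clustered
    asset_items: int = 20
    item_loadings: np.ndarray | None = None
    item_noise: float = 0.6
    wave_transition: WaveTransition = field(default_factory=WaveTransition)
    attrition: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.wave_transition, dict):
            self.wave_transition = WaveTransition(**self.wave_transition)
        if self.n_individuals is None:
            self.n_individuals = int(round(7.832 * self.n_households))
        if self.item_loadings is None:
            self.item_loadings = np.linspace(0.6, 1.4, self.asset_items)
        self.item_loadings = np.asarray(self.item_loadings, dtype=float)
        self.validate()

    def validate(self):
        for name in (
            "secondary_membership_rate",
            "triadic_closure_prob",
            "extra_membership_prob",
            "nonresident_rate",
            "attrition",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.wave_transition.stay_prob <= 1.0:
            raise ConfigError("stay_prob outside [0, 1]")
        for name in ("n_households", "n_regions", "n_individuals", "asset_items"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_regions < 2:
            raise ConfigError("n_regions must be >= 2")
        if self.n_regions > self.n_households:
            raise ConfigError("more regions than households")
        if self.distance_decay <= 0:
            raise ConfigError("distance_decay must be positive")
        if len(self.item_loadings) != self.asset_items:
            raise ConfigError("item_loadings length must equal asset_items")
        if not np.isfinite(self.item_loadings).all():
            raise ConfigError("item_loadings must be finite")


@dataclass
class Geography:
    centroids: np.ndarray  # (n_regions, 2)
    coords: np.ndarray  # (n_households, 2)
    affiliation: dict  # household id -> region id
    region_ids: list


@dataclass
class SyntheticPopulation:
    episodes: pd.DataFrame
    affiliation: dict
    asset_wave1: pd.DataFrame
    asset_wave2: pd.DataFrame
    latent_wealth: pd.DataFrame  # columns z1, z2
    household_attributes: pd.DataFrame
    geography: Geography
    net: MultilevelNetwork
    config: GeneratorConfig
    true_theta: dict | None = None


def gen_geography(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    centroids: np.ndarray | None = None,
    coords: np.ndarray | None = None,
) -> Geography:
    """Region centroids, household coordinates and the affiliation map.

    Households are scattered around uniformly placed region centroids on the
    unit square and affiliated to the nearest centroid; empty regions are
    repaired by relocating the closest household onto the centroid, so no
    region is ever empty.  Explicit ``centroids``/``coords`` override the
    random placement (useful for controlled fixtures).
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if centroids is None:
        centroids = rng.uniform(0.05, 0.95, size=(cfg.n_regions, 2))
    centroids = np.asarray(centroids, dtype=float)
    if coords is None:
        scale = 0.5 / math.sqrt(cfg.n_regions)
        home = rng.integers(cfg.n_regions, size=cfg.n_households)
        coords = centroids[home] + rng.normal(0.0, scale, size=(cfg.n_households, 2))
    coords = np.asarray(coords, dtype=float)

    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    for r in range(len(centroids)):
        if not (assign == r).any():
            h = d2[:, r].argmin()
            coords[h] = centroids[r]
            assign[h] = r
    affiliation = {h: int(r) for h, r in enumerate(assign)}
    return Geography(
        centroids=centroids,
        coords=coords,
        affiliation=affiliation,
        region_ids=list(range(len(centroids))),
    )


def _episode_years(rng, n, p_full_start=0.5, p_full_end=0.8):
    """Start/end years of primary spells: most cover the whole window."""
    start = np.where(
        rng.random(n) < p_full_start,
        YEAR_MIN,
        rng.integers(YEAR_MIN, YEAR_MAX + 1, size=n),
    )
    end = np.where(
        rng.random(n) < p_full_end,
        YEAR_MAX,
        start + rng.integers(0, YEAR_MAX - YEAR_MIN + 1, size=n),
    )
    return start, np.minimum(end, YEAR_MAX)


def gen_membership(
    cfg: GeneratorConfig, geography: Geography, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Membership episodes whose shared members induce the household network.

    Every individual gets a primary episode; a ``secondary_membership_rate``
    fraction acquire one concurrent secondary membership -- chosen two-hop
    through the existing tie structure with probability
    ``triadic_closure_prob``, otherwise by region-level distance decay
    (weight proportional to region size x exp(-decay x centroid distance))
    and long-tailed household attractiveness within the region -- and an
    ``extra_membership_prob`` fraction of those acquire a second secondary
    membership, tying a three-household clique.  With a zero secondary rate
    the derived network has no ties, which is valid.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_h, n_ind = cfg.n_households, cfg.n_individuals

    primary = rng.integers(n_h, size=n_ind)
    # repair empty households: move one member from a multi-member household
    counts = np.bincount(primary, minlength=n_h)
    empties = np.where(counts == 0)[0]
    if len(empties):
        donors = np.argsort(-counts)
        order = np.argsort(primary, kind="stable")
        first_member = {}
        for d in donors[: len(empties) * 3]:
            lo = np.searchsorted(primary[order], d)
            first_member[d] = order[lo]
        di = 0
        for e in empties:
            while counts[donors[di]] <= 1:
                di += 1
            primary[first_member[donors[di]]] = e
            counts[donors[di]] -= 1
            di += 1

    start, end = _episode_years(rng, n_ind)
    # non-residency (circular labour migration) clusters within households:
    # a beta-distributed household propensity with marginal mean
    # nonresident_rate, so many households have no migrants while others have
    # several -- matching the observed 0-15+ spread of non-resident counts
    a = cfg.nonresident_dispersion
    b = a * (1.0 - cfg.nonresident_rate) / max(cfg.nonresident_rate, 1e-9)
    p_nonres = rng.beta(a, b, size=n_h)
    resident = rng.random(n_ind) >= p_nonres[primary]

    records = {
        "individual_id": list(range(n_ind)),
        "household_id": primary.tolist(),
        "start_year": start.tolist(),
        "end_year": end.tolist(),
        "resident_flag": resident.tolist(),
    }

    # region-choice machinery for distance-decay secondary memberships
    centroids = geography.centroids
    coords = geography.coords
    region_of = np.array([geography.affiliation[h] for h in range(n_h)])
    members_by_region = [np.where(region_of == r)[0] for r in range(cfg.n_regions)]
    attract = rng.lognormal(0.0, cfg.attractiveness_sigma, size=n_h)
    cum_by_region = []
    for mem in members_by_region:
        w = attract[mem]
        cum_by_region.append(np.cumsum(w) / w.sum())
    region_sizes = np.array([len(m) for m in members_by_region], dtype=float)

    n_sec = rng.binomial(n_ind, cfg.secondary_membership_rate)
    chosen = rng.choice(n_ind, size=n_sec, replace=False)

    adj: dict[int, set[int]] = {}

    def add_edge(a: int, b: int):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def pick_distance(h1: int) -> int:
        d = np.sqrt(((centroids - coords[h1]) ** 2).sum(axis=1))
        w = region_sizes * np.exp(-cfg.distance_decay * d)
        probs = w / w.sum()
        for _ in range(8):
            r = int(rng.choice(cfg.n_regions, p=probs))
            mem = members_by_region[r]
            h2 = int(mem[int(np.searchsorted(cum_by_region[r], rng.random()))])
            if h2 != h1:
                return h2
        return int((h1 + 1) % n_h)

    def pick_closure(h1: int) -> int | None:
        nbrs = adj.get(h1)
        if not nbrs:
            return None
        h2 = list(nbrs)[int(rng.integers(len(nbrs)))]
        cands = [c for c in adj.get(h2, ()) if c != h1]
        if not cands:
            return None
        return cands[int(rng.integers(len(cands)))]

    sec_records = []
    for i in chosen.tolist():
        h1 = int(primary[i])
        holdings = [h1]
        n_extra = 2 if rng.random() < cfg.extra_membership_prob else 1
        for _ in range(n_extra):
            h2 = None
            if rng.random() < cfg.triadic_closure_prob:
                h2 = pick_closure(h1)
            if h2 is None:
                h2 = pick_distance(h1)
            if h2 in holdings:
                continue
            s = int(rng.integers(YEAR_MIN, YEAR_MAX + 1))
            e = min(YEAR_MAX, s + int(rng.geometric(0.15)))
            sec_records.append((i, h2, s, e, True))
            for h in holdings:
                add_edge(h, h2)
            holdings.append(h2)

    if sec_records:
        sec = pd.DataFrame(
            sec_records,
            columns=["individual_id", "household_id", "start_year", "end_year", "resident_flag"],
        )
        episodes = pd.concat([pd.DataFrame(records), sec], ignore_index=True)
    else:
        episodes = pd.DataFrame(records)
    return episodes


@functools.lru_cache(maxsize=32)
def _rho_for_stay_prob(stay_prob: float) -> float:
    """Latent autocorrelation giving the target quintile-stay probability.

    For a standard bivariate normal with correlation rho and quintile cells,
    P(same quintile) rises monotonically from 0.2 (rho=0) to 1 (rho=1);
    solved by bisection on exact rectangle probabilities.
    """
    if stay_prob >= 1.0:
        return 1.0
    if stay_prob <= 0.2:
        return 0.0
    cuts = stats.norm.ppf(np.linspace(0, 1, 6))

    def stay(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        dist = stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True)

        def F(a, b):
            if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                return 0.0
            return float(dist.cdf([min(a, 8.0), min(b, 8.0)]))

        tot = 0.0
        for k in range(5):
            a, b = cuts[k], cuts[k + 1]
            tot += F(b, b) - 2 * F(a, b) + F(a, a)
        return tot

    lo, hi = 0.0, 0.9999
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if stay(mid) < stay_prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_assets(
    cfg: GeneratorConfig,
    net: MultilevelNetwork,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two waves of binary asset items driven by a latent wealth score.

    Wave-1 latent wealth is standard normal; wave-2 is an autocorrelated copy
    (autocorrelation set by ``wave_transition.stay_prob``) optionally shifted
    by the mean centred wave-1 quintile of tied neighbours
    (``contagion_strength``).  Item j is observed when
    loading_j x z + noise exceeds a per-item threshold; the measurement noise
    is drawn once per household-item and shared across waves, so with full
    persistence (stay_prob=1, no contagion) the two waves are identical.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    households = list(net.households)
    n = len(households)
    hpos = {h: i for i, h in enumerate(households)}

    z1 = rng.normal(size=n)
    rho = _rho_for_stay_prob(round(float(cfg.wave_transition.stay_prob), 6))
    innov = rng.normal(size=n) * math.sqrt(max(0.0, 1.0 - rho**2))

    shift = np.zeros(n)
    c = cfg.wave_transition.contagion_strength
    if c != 0.0:
        q1 = np.searchsorted(np.quantile(z1, [0.2, 0.4, 0.6, 0.8]), z1) + 1
        nbr_sum = np.zeros(n)
        nbr_cnt = np.zeros(n)
        for (a, b) in net.ties:
            ia, ib = hpos[a], hpos[b]
            nbr_sum[ia] += q1[ib] - 3
            nbr_sum[ib] += q1[ia] - 3
            nbr_cnt[ia] += 1
            nbr_cnt[ib] += 1
        has = nbr_cnt > 0
        shift[has] = c * nbr_sum[has] / (2.0 * nbr_cnt[has])
    z2 = rho * z1 + shift + innov

    lam = cfg.item_loadings
    tau = np.linspace(-1.5, 1.5, cfg.asset_items) * np.sqrt(1.0 + lam**2)
    noise = rng.logistic(size=(n, cfg.asset_items)) * cfg.item_noise
    cols = [f"item_{j + 1}" for j in range(cfg.asset_items)]
    idx = pd.Index(households, name="household_id")
    w1 = pd.DataFrame(
        (lam * z1[:, None] + noise > tau).astype(int), index=idx, columns=cols
    )
    w2 = pd.DataFrame(
        (lam * z2[:, None] + noise > tau).astype(int), index=idx, columns=cols
    )
    if cfg.attrition > 0:
        keep = rng.random(n) >= cfg.attrition
        w2 = w2.loc[keep]
    latent = pd.DataFrame({"z1": z1, "z2": z2}, index=idx)
    return w1, w2, latent


def gen_outcomes_from_model(
    net: MultilevelNetwork,
    spec: EffectSpec,
    covariates: pd.DataFrame | None = None,
    region_covariates: pd.DataFrame | None = None,
    n_burn: int = 200,
    seed: int | None = None,
) -> OutcomeState:
    """One draw from the ALAAM distribution at the spec's theta.

    Gibbs sampling from a uniform-random initial state with ``n_burn`` full
    sweeps; used for parameter-recovery studies where the generating theta is
    known.
    """
    from wealthnet.alaam_engine import gibbs_sample

    model = AlaamModel(net, spec, covariates=covariates, region_covariates=region_covariates)
    return gibbs_sample(model, n_burn=n_burn, n_draws=1, thin=0, seed=seed)[0]


def generate_population(cfg: GeneratorConfig) -> SyntheticPopulation:
    """Full synthetic population: geography, episodes, network, assets, attributes.

    All randomness flows from ``cfg.seed`` through per-stage child streams,
    so a fixed config reproduces byte-identical outputs.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    r_geo, r_mem, r_assets, r_attr = [np.random.default_rng(s) for s in ss.spawn(4)]
    geo = gen_geography(cfg, rng=r_geo)
    episodes = gen_membership(cfg, geo, rng=r_mem)
    net = build_ties(episodes)
    net = affiliate(net, geo.affiliation)
    w1, w2, latent = gen_assets(cfg, net, rng=r_assets)

    # household socio-demographic attributes
    idx = pd.Index(net.households, name="household_id")
    n = len(idx)
    ep_h = episodes.groupby("household_id")
    size = ep_h["individual_id"].nunique().reindex(idx).fillna(0).astype(int)
    nonres = (
        episodes[~episodes["resident_flag"].astype(bool)]
        .groupby("household_id")["individual_id"]
        .nunique()
        .reindex(idx)
        .fillna(0)
        .astype(int)
    )
    attrs = pd.DataFrame(
        {
            "head_female": (r_attr.random(n) < 0.55).astype(int),
            "pension_eligible": (r_attr.random(n) < 0.35).astype(int),
            "mortality_any": (r_attr.random(n) < 0.20).astype(int),
            "household_size": np.minimum(size.to_numpy(), 20),
            "n_nonresidents": np.minimum(nonres.to_numpy(), 15),
        },
        index=idx,
    )
    return SyntheticPopulation(
        episodes=episodes,
        affiliation=geo.affiliation,
        asset_wave1=w1,
        asset_wave2=w2,
        latent_wealth=latent,
        household_attributes=attrs,
        geography=geo,
        net=net,
        config=cfg,
    )


def write_population(pop: SyntheticPopulation, outdir: str | Path):
    """Write episodes/affiliations/asset CSVs (RFC 4180, UTF-8) and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop.episodes.to_csv(outdir / "episodes.csv", index=False)
    pd.DataFrame(
        {"household_id": list(pop.affiliation), "region_id": list(pop.affiliation.values())}
    ).to_csv(outdir / "affiliations.csv", index=False)
    pop.asset_wave1.to_csv(outdir / "assets_wave1.csv")
    pop.asset_wave2.to_csv(outdir / "assets_wave2.csv")
    pop.household_attributes.to_csv(outdir / "attributes.csv")
    truth = {
        "theta": pop.true_theta,
        "latent_wealth": {
            "z1": pop.latent_wealth["z1"].round(6).tolist(),
            "z2": pop.latent_wealth["z2"].round(6).tolist(),
        },
        "seed": pop.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
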