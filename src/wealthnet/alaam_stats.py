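"""Multilevel ALAAM configuration statistics and change statistics.

The model is an exponential-family distribution over the joint binary outcome
vector (y over households, Y over regions) conditional on the fixed multilevel
network:

    Pr(y, Y) = exp( sum_I theta_I z_I(y, Y) ) / kappa(theta)

Each effect I is a configuration count z_I.  Household-level effects combine
the outcome with degree, triangles, same-/cross-region ties, non-resident
members and nodal covariates; contagion effects count outcome-concordant tied
pairs; region-level effects combine the regional outcome with within- and
cross-region tie counts and meta-network contagion; cross-level effects couple
the two outcome layers (cross-level interaction and the micro-macro link).

``change_statistic`` gives the difference in z when one node's outcome flips
0 -> 1 with everything else held fixed -- the building block of the Gibbs
conditional logit P(outcome_i = 1 | rest) = theta . dz_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from wealthnet.network_build import MultilevelNetwork

HOUSEHOLD_STATIC_KINDS = (
    "density_household",
    "activity_household",
    "closure_household",
    "degree_same_region",
    "degree_cross_region",
    "household_covariate",
)
HOUSEHOLD_DYNAMIC_KINDS = (
    "contagion_same_region",
    "contagion_cross_region",
    "contagion_poorest",
)
REGION_STATIC_KINDS = (
    "density_region",
    "within_region_ties",
    "cross_region_ties",
    "region_covariate",
)
REGION_DYNAMIC_KINDS = ("contagion_region",)
CROSS_KINDS = ("cross_level_interaction", "micro_macro_link")

ALL_KINDS = (
    HOUSEHOLD_STATIC_KINDS
    + HOUSEHOLD_DYNAMIC_KINDS
    + REGION_STATIC_KINDS
    + REGION_DYNAMIC_KINDS
    + CROSS_KINDS
)


@dataclass(frozen=True)
class Effect:
    """One configuration statistic z_I with its parameter theta_I."""

    kind: str
    covariate: str | None = None
    theta: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind in ("household_covariate", "region_covariate") and not self.covariate:
            raise ValueError(f"effect kind {self.kind!r} requires a covariate name")
        if not self.name:
            default = self.kind if not self.covariate else f"{self.kind}:{self.covariate}"
            object.__setattr__(self, "name", default)

    @property
    def level(self) -> str:
        if self.kind in CROSS_KINDS:
            return "cross"
        if self.kind in REGION_STATIC_KINDS + REGION_DYNAMIC_KINDS:
            return "region"
        return "household"


@dataclass
class EffectSpec:
    """Ordered list of effects; the model's sufficient statistics."""

    effects: list[Effect] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError("effect names must be unique")

    def __len__(self):
        return len(self.effects)

    def __iter__(self):
        return iter(self.effects)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.effects]

    @property
    def theta(self) -> np.ndarray:
        return np.array([e.theta for e in self.effects], dtype=float)

    def with_theta(self, theta: Sequence[float]) -> "EffectSpec":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.effects),):
            raise ValueError("theta length does not match effect list")
        return EffectSpec([replace(e, theta=float(t)) for e, t in zip(self.effects, theta)])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no effect named {name!r}") from None

    def require_densities(self):
        """Estimation requires both density (intercept) effects, listed first."""
        kinds = [e.kind for e in self.effects[:2]]
        if "density_household" not in kinds or "density_region" not in kinds:
            raise ValueError(
                "effect list must start with density_household and density_region"
            )


def basic_spec(extra: Sequence[Effect] = ()) -> EffectSpec:
    """Density-only spec (both levels) plus optional extra effects."""
    return EffectSpec(
        [Effect("density_household"), Effect("density_region"), *extra]
    )


def full_effect_spec(
    covariate_names: Sequence[str] = (),
    region_covariate_names: Sequence[str] = (),
    include_poorest: bool = False,
) -> EffectSpec:
    """Every implemented configuration statistic (used for goodness of fit).

    The poorest-dyad contagion statistic requires the baseline-quintile
    covariate, so it is included only on request.
    """
    effects = [Effect("density_household"), Effect("density_region")]
    effects += [
        Effect(k)
        for k in (
            "activity_household",
            "closure_household",
            "degree_same_region",
            "degree_cross_region",
            "contagion_same_region",
            "contagion_cross_region",
            "within_region_ties",
            "cross_region_ties",
            "contagion_region",
            "cross_level_interaction",
            "micro_macro_link",
        )
    ]
    if include_poorest:
        effects.append(Effect("contagion_poorest"))
    effects += [Effect("household_covariate", covariate=c) for c in covariate_names]
    effects += [Effect("region_covariate", covariate=c) for c in region_covariate_names]
    return EffectSpec(effects)


@dataclass
class OutcomeState:
    """Joint binary outcome vectors with a household missingness mask."""

    y: np.ndarray  # int8, households (model node order)
    Y: np.ndarray  # int8, regions
    missing_mask: np.ndarray | None = None  # bool over households

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if not np.isin(self.y, (0, 1)).all() or not np.isin(self.Y, (0, 1)).all():
            raise ValueError("outcome entries must be 0/1")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.y), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.y.shape:
                raise ValueError("missing_mask shape mismatch")

    def copy(self) -> "OutcomeState":
        return OutcomeState(self.y.copy(), self.Y.copy(), self.missing_mask.copy())

    @property
    def n_nodes(self) -> int:
        return len(self.y) + len(self.Y)


class AlaamModel:
    """A MultilevelNetwork + covariates + EffectSpec compiled for computation.

    Precomputes node orderings, adjacency structures split by same/cross
    region, per-region tie counts, and the static part of every change
    statistic, so that full statistics, local change statistics and Gibbs
    sweeps share one representation.
    """

    def __init__(
        self,
        net: MultilevelNetwork,
        spec: EffectSpec,
        covariates: pd.DataFrame | None = None,
        region_covariates: pd.DataFrame | None = None,
        quintile_covariate: str = "baseline_quintile",
    ):
        if not net.affiliation:
            raise ValueError("network must be affiliated to regions first")
        self.net = net
        self.spec = spec
        self.h_ids = list(net.households)
        self.r_ids = list(net.regions)
        self.n_h = len(self.h_ids)
        self.n_r = len(self.r_ids)
        self._h_index = {h: i for i, h in enumerate(self.h_ids)}
        self._r_index = {r: i for i, r in enumerate(self.r_ids)}
        self.region_of = np.array(
            [self._r_index[net.affiliation[h]] for h in self.h_ids], dtype=np.int64
        )

        edges = np.array(
            [(self._h_index[a], self._h_index[b]) for a, b in net.ties], dtype=np.int64
        ).reshape(-1, 2)
        self.edge_u = edges[:, 0]
        self.edge_v = edges[:, 1]
        self.edge_same = self.region_of[self.edge_u] == self.region_of[self.edge_v]

        self.deg = np.bincount(
            np.concatenate([self.edge_u, self.edge_v]), minlength=self.n_h
        ).astype(float)
        su = self.edge_u[self.edge_same]
        sv = self.edge_v[self.edge_same]
        self.deg_same = np.bincount(
            np.concatenate([su, sv]), minlength=self.n_h
        ).astype(float)
        self.deg_cross = self.deg - self.deg_same

        # region-level tie counts: W_v within, C_v with exactly one endpoint in v
        self.W = np.bincount(self.region_of[su], minlength=self.n_r).astype(float)
        cu = self.edge_u[~self.edge_same]
        cv = self.edge_v[~self.edge_same]
        self.C = np.bincount(
            np.concatenate([self.region_of[cu], self.region_of[cv]]), minlength=self.n_r
        ).astype(float)

        # adjacency lists split by tie locality
        self.nbrs_same: list[list[int]] = [[] for _ in range(self.n_h)]
        self.nbrs_cross: list[list[int]] = [[] for _ in range(self.n_h)]
        for u, v, s in zip(self.edge_u, self.edge_v, self.edge_same):
            (self.nbrs_same if s else self.nbrs_cross)[u].append(int(v))
            (self.nbrs_same if s else self.nbrs_cross)[v].append(int(u))

        self.members: list[list[int]] = [[] for _ in range(self.n_r)]
        for h, r in enumerate(self.region_of):
            self.members[r].append(h)
        self.same_edges_by_region: list[list[tuple[int, int]]] = [
            [] for _ in range(self.n_r)
        ]
        for u, v in zip(su, sv):
            self.same_edges_by_region[self.region_of[u]].append((int(u), int(v)))
        self.meta_nbrs: list[list[int]] = [[] for _ in range(self.n_r)]
        self.meta_edges = np.array(
            [(self._r_index[a], self._r_index[b]) for a, b in net.meta_ties],
            dtype=np.int64,
        ).reshape(-1, 2)
        for a, b in self.meta_edges:
            self.meta_nbrs[a].append(int(b))
            self.meta_nbrs[b].append(int(a))

        self._tri: np.ndarray | None = None
        self.covariates = covariates
        self.region_covariates = region_covariates
        self.quintile_covariate = quintile_covariate

        # poorest-dyad support: neighbours with baseline quintile 1, empty
        # unless the household itself is in quintile 1
        self._poor_edge_mask: np.ndarray | None = None
        self.nbrs_poor: list[list[int]] = [[] for _ in range(self.n_h)]
        if any(e.kind == "contagion_poorest" for e in spec):
            q = self._covariate(quintile_covariate)
            poor = q == 1
            self._poor_edge_mask = poor[self.edge_u] & poor[self.edge_v]
            for u, v, p in zip(self.edge_u, self.edge_v, self._poor_edge_mask):
                if p:
                    self.nbrs_poor[u].append(int(v))
                    self.nbrs_poor[v].append(int(u))

        self._compile_static()

    # ----- helpers -------------------------------------------------------
    def household_index(self, h) -> int:
        return self._h_index[h]

    def region_index(self, r) -> int:
        return self._r_index[r]

    def _covariate(self, name: str) -> np.ndarray:
        if self.covariates is None or name not in self.covariates.columns:
            raise KeyError(f"household covariate {name!r} not provided")
        vals = self.covariates[name].reindex(self.h_ids)
        if vals.isna().any():
            missing = vals.index[vals.isna()][:5].tolist()
            raise KeyError(f"household covariate {name!r} missing for {missing}")
        return vals.to_numpy(dtype=float)

    def _region_covariate(self, name: str) -> np.ndarray:
        if self.region_covariates is None or name not in self.region_covariates.columns:
            raise KeyError(f"region covariate {name!r} not provided")
        vals = self.region_covariates[name].reindex(self.r_ids)
        if vals.isna().any():
            raise KeyError(f"region covariate {name!r} has missing regions")
        return vals.to_numpy(dtype=float)

    @property
    def triangles(self) -> np.ndarray:
        """Per-household triangle membership count (computed on demand)."""
        if self._tri is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_h))
            g.add_edges_from(zip(self.edge_u.tolist(), self.edge_v.tolist()))
            tri = nx.triangles(g)
            self._tri = np.array([tri[i] for i in range(self.n_h)], dtype=float)
        return self._tri

    # ----- compilation ---------------------------------------------------
    def _compile_static(self):
        """Static change-statistic matrices and dynamic channel weights.

        The change statistic of any implemented effect decomposes as a static
        per-node part plus a combination of a small number of dynamic
        channels: the outcome sums over same-/cross-region/poorest-dyad
        neighbours, the own region's outcome, the meta-neighbour outcome sum,
        and the within-region outcome aggregates.
        """
        K = len(self.spec)
        self.H_static = np.zeros((self.n_h, K))
        self.R_static = np.zeros((self.n_r, K))
        # dynamic channel weights per effect (household flip)
        self.w_same = np.zeros(K)  # x S_same(h)
        self.w_cross = np.zeros(K)  # x S_cross(h)
        self.w_poor = np.zeros(K)  # x S_poor(h)
        self.w_Yv = np.zeros(K)  # x Y_{v(h)}
        self.w_YvS = np.zeros(K)  # x Y_{v(h)} * S_same(h)
        # dynamic channel weights per effect (region flip)
        self.w_meta = np.zeros(K)  # x sum of Y over meta-neighbours
        self.w_ysum = np.zeros(K)  # x sum of y over member households
        self.w_tv = np.zeros(K)  # x count of y-concordant within-region ties

        for k, e in enumerate(self.spec):
            kind = e.kind
            if kind == "density_household":
                self.H_static[:, k] = 1.0
            elif kind == "activity_household":
                self.H_static[:, k] = self.deg
            elif kind == "closure_household":
                self.H_static[:, k] = self.triangles
            elif kind == "degree_same_region":
                self.H_static[:, k] = self.deg_same
            elif kind == "degree_cross_region":
                self.H_static[:, k] = self.deg_cross
            elif kind == "household_covariate":
                self.H_static[:, k] = self._covariate(e.covariate)
            elif kind == "contagion_same_region":
                self.w_same[k] = 1.0
            elif kind == "contagion_cross_region":
                self.w_cross[k] = 1.0
            elif kind == "contagion_poorest":
                self.w_poor[k] = 1.0
            elif kind == "density_region":
                self.R_static[:, k] = 1.0
            elif kind == "within_region_ties":
                self.R_static[:, k] = self.W
            elif kind == "cross_region_ties":
                self.R_static[:, k] = self.C
            elif kind == "region_covariate":
                self.R_static[:, k] = self._region_covariate(e.covariate)
            elif kind == "contagion_region":
                self.w_meta[k] = 1.0
            elif kind == "cross_level_interaction":
                self.w_Yv[k] = 1.0
                self.w_ysum[k] = 1.0
            elif kind == "micro_macro_link":
                self.w_YvS[k] = 1.0
                self.w_tv[k] = 1.0
            else:  # pragma: no cover
                raise AssertionError(kind)

    # ----- statistics -----------------------------------------------------
    def statistics(self, state: OutcomeState, exclude_masked: bool = False) -> np.ndarray:
        """Full statistic vector z(y, Y) for the model's effect list.

        With ``exclude_masked`` every term involving a masked household is
        explicitly dropped (the observed-margin statistics used when fitting
        with missing outcomes).
        """
        y = state.y.astype(float)
        if exclude_masked and state.missing_mask.any():
            y = y.copy()
            y[state.missing_mask] = 0.0
        Y = state.Y.astype(float)
        ey = y[self.edge_u] * y[self.edge_v]
        ysum_v = np.bincount(self.region_of, weights=y, minlength=self.n_r)
        t_v = np.bincount(
            self.region_of[self.edge_u[self.edge_same]],
            weights=ey[self.edge_same],
            minlength=self.n_r,
        )
        z = self.H_static.T @ y + self.R_static.T @ Y
        for k, e in enumerate(self.spec):
            kind = e.kind
            if kind == "contagion_same_region":
                z[k] = ey[self.edge_same].sum()
            elif kind == "contagion_cross_region":
                z[k] = ey[~self.edge_same].sum()
            elif kind == "contagion_poorest":
                z[k] = ey[self._poor_edge_mask].sum() if len(ey) else 0.0
            elif kind == "contagion_region":
                if len(self.meta_edges):
                    z[k] = (Y[self.meta_edges[:, 0]] * Y[self.meta_edges[:, 1]]).sum()
            elif kind == "cross_level_interaction":
                z[k] = float(Y @ ysum_v)
            elif kind == "micro_macro_link":
                z[k] = float(Y @ t_v)
        return z

    def statistics_batch(self, yb: np.ndarray, Yb: np.ndarray) -> np.ndarray:
        """Statistic vectors for a batch of states (rows of yb / Yb).

        Vectorised mirror of :meth:`statistics`; used by the exact
        enumeration oracle where every one of the 2^N outcome configurations
        is evaluated at once.
        """
        yb = np.asarray(yb, dtype=float)
        Yb = np.asarray(Yb, dtype=float)
        B = yb.shape[0]
        Z = yb @ self.H_static + Yb @ self.R_static
        ey = yb[:, self.edge_u] * yb[:, self.edge_v] if len(self.edge_u) else np.zeros((B, 0))
        onehot = np.zeros((self.n_h, self.n_r))
        onehot[np.arange(self.n_h), self.region_of] = 1.0
        ysum_v = yb @ onehot
        su = self.edge_u[self.edge_same]
        if len(su):
            edge_onehot = np.zeros((len(su), self.n_r))
            edge_onehot[np.arange(len(su)), self.region_of[su]] = 1.0
            t_v = ey[:, self.edge_same] @ edge_onehot
        else:
            t_v = np.zeros((B, self.n_r))
        for k, e in enumerate(self.spec):
            kind = e.kind
            if kind == "contagion_same_region":
                Z[:, k] = ey[:, self.edge_same].sum(axis=1)
            elif kind == "contagion_cross_region":
                Z[:, k] = ey[:, ~self.edge_same].sum(axis=1)
            elif kind == "contagion_poorest":
                Z[:, k] = ey[:, self._poor_edge_mask].sum(axis=1) if ey.shape[1] else 0.0
            elif kind == "contagion_region":
                if len(self.meta_edges):
                    Z[:, k] = (Yb[:, self.meta_edges[:, 0]] * Yb[:, self.meta_edges[:, 1]]).sum(axis=1)
            elif kind == "cross_level_interaction":
                Z[:, k] = (Yb * ysum_v).sum(axis=1)
            elif kind == "micro_macro_link":
                Z[:, k] = (Yb * t_v).sum(axis=1)
        return Z

    def change_statistic(self, state: OutcomeState, node: int, level: str) -> np.ndarray:
        """dz for flipping one node's outcome 0 -> 1, all else fixed.

        Computed locally from the node's incident ties and affiliations;
        exactly equals z(state with node=1) - z(state with node=0).
        """
        y = state.y
        Y = state.Y
        if level == "household":
            if state.missing_mask[node]:
                raise ValueError(f"household node {node} is masked")
            S_same = float(sum(y[j] for j in self.nbrs_same[node]))
            S_cross = float(sum(y[j] for j in self.nbrs_cross[node]))
            S_poor = float(sum(y[j] for j in self.nbrs_poor[node]))
            Yv = float(Y[self.region_of[node]])
            return (
                self.H_static[node]
                + self.w_same * S_same
                + self.w_cross * S_cross
                + self.w_poor * S_poor
                + self.w_Yv * Yv
                + self.w_YvS * (Yv * S_same)
            )
        elif level == "region":
            S_meta = float(sum(Y[w] for w in self.meta_nbrs[node]))
            ysum = float(sum(y[h] for h in self.members[node]))
            tv = float(sum(y[a] * y[b] for a, b in self.same_edges_by_region[node]))
            return (
                self.R_static[node]
                + self.w_meta * S_meta
                + self.w_ysum * ysum
                + self.w_tv * tv
            )
        raise ValueError(f"unknown level {level!r}")
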