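"""Simulation, estimation and model checking for the multilevel ALAAM.

Simulation is by Gibbs sampling over the joint (household, region) outcome
vector: one sweep visits every free node in a fresh random order and
resamples its outcome from the full conditional
logit P(outcome_i = 1 | rest) = theta . dz_i.

Estimation is three-phase Robbins-Monro stochastic approximation solving the
method-of-moments condition E_theta[z] = z_obs (the maximum-likelihood score
equation of the exponential family): phase 1 estimates a diagonal scaling
matrix from a short simulation, phase 2 runs gain-halving sub-phases of
updates theta <- theta - a D^-1 (z_sim - z_obs) with Polyak averaging, and
phase 3 draws a large thinned sample to compute convergence t-ratios,
standard errors from the inverse covariance of the simulated statistics, and
goodness-of-fit t-ratios.

An exact enumeration oracle (loglikelihood, normalising constant and full
outcome distribution) is available for networks with at most 20 total nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wealthnet.alaam_stats import AlaamModel, EffectSpec, OutcomeState, full_effect_spec

logger = logging.getLogger(__name__)

EXACT_NODE_LIMIT = 20
CONV_THRESHOLD = 0.1
GOF_THRESHOLD = 1.96


@dataclass
class EstimationSettings:
    """Sampler and Robbins-Monro settings.

    Sweeps are full passes over all free nodes.  Defaults follow the common
    three-phase stochastic-approximation convention (gain halved per
    sub-phase, diagonal derivative scaling, Polyak-averaged sub-phase
    estimates).
    """

    init_burn: int = 50
    p1_draws: int = 60
    p1_thin: int = 2
    subphases: int = 7
    p2_iters: int = 40
    p2_sweeps: int = 5
    a0: float = 0.5
    p3_burn: int = 50
    p3_draws: int = 600
    p3_thin: int = 2
    conv_threshold: float = CONV_THRESHOLD
    gof_threshold: float = GOF_THRESHOLD
    max_restarts: int = 2
    newton_polish: int = 1  # Fisher-scoring steps between phases 2 and 3
    polish_step_max: float = 0.5  # trust-region cap per component
    missing: str = "latent"  # or "clamp"


@dataclass
class FitResult:
    """Estimate, uncertainty and convergence diagnostics for one model fit."""

    effect_names: list[str]
    theta_hat: np.ndarray
    std_err: np.ndarray
    conv_t: np.ndarray
    converged: bool
    seed: int | None
    settings: EstimationSettings
    z_obs: np.ndarray | None = None
    info_matrix: np.ndarray | None = None
    gof_table: pd.DataFrame | None = None
    degenerate: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta_hat,
                "std_err": self.std_err,
                "odds_multiplier": np.exp(self.theta_hat),
                "conv_t": self.conv_t,
            },
            index=pd.Index(self.effect_names, name="effect"),
        )

    def to_dict(self) -> dict:
        return {
            "effects": self.effect_names,
            "theta": self.theta_hat.tolist(),
            "std_err": self.std_err.tolist(),
            "conv_t": self.conv_t.tolist(),
            "converged": bool(self.converged),
            "seed": self.seed,
            "settings": {
                k: getattr(self.settings, k) for k in self.settings.__dataclass_fields__
            },
        }


class GibbsSampler:
    """Sequential-scan Gibbs sampler over the joint outcome state.

    Keeps the outcome vectors as plain Python lists plus running per-region
    aggregates so that one node update costs O(degree).  Masked households are
    either updated like any other node (``missing='latent'``, imputation) or
    never touched (``missing='clamp'``).
    """

    def __init__(self, model: AlaamModel, state: OutcomeState, missing: str = "latent"):
        if missing not in ("latent", "clamp"):
            raise ValueError("missing must be 'latent' or 'clamp'")
        self.model = model
        self.missing = missing
        self.n_h = model.n_h
        self.n_r = model.n_r
        self.y = state.y.astype(int).tolist()
        self.Y = state.Y.astype(int).tolist()
        self.mask = state.missing_mask.copy()
        free_h = [h for h in range(self.n_h) if missing == "latent" or not self.mask[h]]
        self.nodes = free_h + [self.n_h + v for v in range(self.n_r)]
        self.region_of = model.region_of.tolist()
        self.ysum = [0] * self.n_r
        self.tv = [0] * self.n_r
        for h, yh in enumerate(self.y):
            if yh:
                self.ysum[self.region_of[h]] += 1
        for v, pairs in enumerate(model.same_edges_by_region):
            self.tv[v] = sum(self.y[a] * self.y[b] for a, b in pairs)
        self.set_theta(model.spec.theta)

    def set_theta(self, theta: np.ndarray):
        m = self.model
        theta = np.asarray(theta, dtype=float)
        self.theta = theta
        self.base_h = (m.H_static @ theta).tolist()
        self.base_r = (m.R_static @ theta).tolist()
        self.a_same = float(m.w_same @ theta)
        self.a_cross = float(m.w_cross @ theta)
        self.a_poor = float(m.w_poor @ theta)
        self.a_Yv = float(m.w_Yv @ theta)
        self.a_YvS = float(m.w_YvS @ theta)
        self.b_meta = float(m.w_meta @ theta)
        self.b_ysum = float(m.w_ysum @ theta)
        self.b_tv = float(m.w_tv @ theta)

    def sweep(self, rng: np.random.Generator, n_sweeps: int = 1):
        """Run full sweeps; each visits every free node in a fresh random order."""
        m = self.model
        y, Y = self.y, self.Y
        ysum, tv = self.ysum, self.tv
        reg = self.region_of
        ns, nc, npo = m.nbrs_same, m.nbrs_cross, m.nbrs_poor
        meta, base_h, base_r = m.meta_nbrs, self.base_h, self.base_r
        a_same, a_cross, a_poor = self.a_same, self.a_cross, self.a_poor
        a_Yv, a_YvS = self.a_Yv, self.a_YvS
        b_meta, b_ysum, b_tv = self.b_meta, self.b_ysum, self.b_tv
        use_poor = a_poor != 0.0
        n_h = self.n_h
        nodes = self.nodes
        n = len(nodes)
        exp = math.exp
        for _ in range(n_sweeps):
            order = rng.permutation(n)
            u = rng.random(n)
            for idx in order.tolist():
                i = nodes[idx]
                if i < n_h:
                    s_same = 0
                    for j in ns[i]:
                        s_same += y[j]
                    s_cross = 0
                    for j in nc[i]:
                        s_cross += y[j]
                    v = reg[i]
                    lam = base_h[i] + a_same * s_same + a_cross * s_cross
                    if use_poor:
                        s_poor = 0
                        for j in npo[i]:
                            s_poor += y[j]
                        lam += a_poor * s_poor
                    if Y[v]:
                        lam += a_Yv + a_YvS * s_same
                    if lam > 35.0:
                        new = 1
                    elif lam < -35.0:
                        new = 0
                    else:
                        new = 1 if u[idx] < 1.0 / (1.0 + exp(-lam)) else 0
                    old = y[i]
                    if new != old:
                        d = new - old
                        y[i] = new
                        ysum[v] += d
                        tv[v] += d * s_same
                else:
                    v = i - n_h
                    s_meta = 0
                    for w in meta[v]:
                        s_meta += Y[w]
                    lam = base_r[v] + b_meta * s_meta + b_ysum * ysum[v] + b_tv * tv[v]
                    if lam > 35.0:
                        Y[v] = 1
                    elif lam < -35.0:
                        Y[v] = 0
                    else:
                        Y[v] = 1 if u[idx] < 1.0 / (1.0 + exp(-lam)) else 0

    def state(self) -> OutcomeState:
        return OutcomeState(
            np.array(self.y, dtype=np.int8),
            np.array(self.Y, dtype=np.int8),
            self.mask.copy(),
        )


def _random_state(model: AlaamModel, rng: np.random.Generator) -> OutcomeState:
    return OutcomeState(
        (rng.random(model.n_h) < 0.5).astype(np.int8),
        (rng.random(model.n_r) < 0.5).astype(np.int8),
    )


def gibbs_sample(
    model: AlaamModel,
    theta: np.ndarray | None = None,
    state0: OutcomeState | None = None,
    n_burn: int = 0,
    n_draws: int = 1,
    thin: int = 1,
    seed: int | None = None,
    missing: str = "latent",
) -> list[OutcomeState]:
    """Draw outcome states from the ALAAM distribution by Gibbs sampling.

    ``n_burn`` full sweeps are applied before the first draw; consecutive
    draws are separated by ``thin`` sweeps.
    """
    rng = np.random.default_rng(seed)
    if state0 is None:
        state0 = _random_state(model, rng)
    if theta is not None:
        model = _with_theta(model, theta)
    sampler = GibbsSampler(model, state0, missing=missing)
    sampler.sweep(rng, n_burn)
    draws = []
    for _ in range(n_draws):
        sampler.sweep(rng, thin)
        draws.append(sampler.state())
    return draws


def _with_theta(model: AlaamModel, theta) -> AlaamModel:
    """Model view with a different theta (shares all compiled structure)."""
    import copy

    m = copy.copy(model)
    m.spec = model.spec.with_theta(theta)
    return m


# ---------------------------------------------------------------------------
# exact small-network oracle
# ---------------------------------------------------------------------------


def _enumerate_states(model: AlaamModel) -> tuple[np.ndarray, np.ndarray]:
    N = model.n_h + model.n_r
    if N > EXACT_NODE_LIMIT:
        raise ValueError(
            f"exact enumeration refused for {N} > {EXACT_NODE_LIMIT} nodes"
        )
    B = 1 << N
    bits = ((np.arange(B)[:, None] >> np.arange(N)[None, :]) & 1).astype(np.int8)
    return bits[:, : model.n_h], bits[:, model.n_h :]


def exact_distribution(model: AlaamModel, theta: np.ndarray | None = None) -> np.ndarray:
    """Exact probability of every outcome configuration (<= 20 nodes).

    State ``s`` encodes households in the low bits then regions, little
    endian: bit j of s is household j's outcome for j < n_h, else region
    (j - n_h)'s outcome.
    """
    if theta is None:
        theta = model.spec.theta
    yb, Yb = _enumerate_states(model)
    Z = model.statistics_batch(yb, Yb)
    logw = Z @ np.asarray(theta, dtype=float)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def exact_loglik(
    model: AlaamModel, state: OutcomeState, theta: np.ndarray | None = None
) -> tuple[float, float]:
    """Exact log-likelihood of ``state`` and the normalising constant kappa.

    Full enumeration over all 2^N outcome configurations; refuses networks
    with more than 20 total (household + region) nodes or masked outcomes.
    """
    if state.missing_mask.any():
        raise ValueError("exact likelihood requires fully observed outcomes")
    if theta is None:
        theta = model.spec.theta
    theta = np.asarray(theta, dtype=float)
    yb, Yb = _enumerate_states(model)
    Z = model.statistics_batch(yb, Yb)
    logw = Z @ theta
    M = logw.max()
    log_kappa = M + math.log(np.exp(logw - M).sum())
    z_obs = model.statistics(state)
    return float(z_obs @ theta - log_kappa), float(math.exp(log_kappa))


# ---------------------------------------------------------------------------
# Robbins-Monro estimation
# ---------------------------------------------------------------------------


def _simulate_stats(
    sampler: GibbsSampler,
    model: AlaamModel,
    rng: np.random.Generator,
    n_draws: int,
    thin: int,
    exclude_masked: bool,
) -> np.ndarray:
    out = np.empty((n_draws, len(model.spec)))
    for i in range(n_draws):
        sampler.sweep(rng, thin)
        out[i] = model.statistics(sampler.state(), exclude_masked=exclude_masked)
    return out


def _smart_init(model: AlaamModel, observed: OutcomeState) -> np.ndarray:
    """Density effects start at the logit of the observed prevalence."""
    theta = model.spec.theta.copy()
    if np.any(theta != 0):
        return theta
    obs_y = observed.y[~observed.missing_mask]
    for k, e in enumerate(model.spec):
        if e.kind == "density_household":
            p = float(np.clip(obs_y.mean() if len(obs_y) else 0.5, 0.02, 0.98))
            theta[k] = math.log(p / (1 - p))
        elif e.kind == "density_region":
            p = float(np.clip(observed.Y.mean(), 0.02, 0.98))
            theta[k] = math.log(p / (1 - p))
    return theta


def estimate_rm(
    model: AlaamModel,
    observed: OutcomeState,
    settings: EstimationSettings | None = None,
    seed: int | None = None,
) -> FitResult:
    """Robbins-Monro MCMC maximum-likelihood estimation.

    Solves E_theta[z] = z_obs by stochastic approximation (see module
    docstring).  Missing household outcomes are Gibbs-imputed as latent by
    default; statistics are then matched on the observed margin (terms
    involving masked nodes excluded on both sides).  Never raises on
    non-convergence: the returned ``FitResult`` carries ``converged=False``.
    """
    settings = settings or EstimationSettings()
    model.spec.require_densities()
    rng = np.random.default_rng(seed)
    has_missing = bool(observed.missing_mask.any())
    excl = has_missing
    z_obs = model.statistics(observed, exclude_masked=excl)
    K = len(model.spec)

    theta = _smart_init(model, observed)
    work = _with_theta(model, theta)
    state0 = observed.copy() if settings.missing == "clamp" else _random_state(model, rng)
    if settings.missing == "clamp" and has_missing:
        state0.y[state0.missing_mask] = 0
    sampler = GibbsSampler(work, state0, missing=settings.missing)
    sampler.sweep(rng, settings.init_burn)

    # phase 1: diagonal derivative scaling D ~ Var_theta0(z)
    z1 = _simulate_stats(sampler, work, rng, settings.p1_draws, settings.p1_thin, excl)
    D = z1.var(axis=0, ddof=1)
    floor = 1e-3 * (np.abs(z_obs) + 1.0)
    D = np.maximum(D, floor)

    def _phase3() -> tuple[np.ndarray, np.ndarray]:
        sampler.sweep(rng, settings.p3_burn)
        z3 = _simulate_stats(sampler, work, rng, settings.p3_draws, settings.p3_thin, excl)
        sd3 = z3.std(axis=0, ddof=1)
        deg = sd3 < 1e-12
        t = np.where(
            deg, np.where(np.abs(z3.mean(axis=0) - z_obs) < 1e-9, 0.0, np.inf),
            (z3.mean(axis=0) - z_obs) / np.where(deg, 1.0, sd3),
        )
        return z3, t

    def _newton_step(z3: np.ndarray) -> np.ndarray:
        """Damped Fisher-scoring step: dtheta = Cov(z)^-1 (z_obs - mean z)."""
        cov = np.atleast_2d(np.cov(z3.T))
        cov = cov + 1e-8 * np.eye(K)
        try:
            step = np.linalg.solve(cov, z_obs - z3.mean(axis=0))
        except np.linalg.LinAlgError:
            step = (z_obs - z3.mean(axis=0)) / np.maximum(np.diag(cov), floor)
        cap = settings.polish_step_max
        big = np.max(np.abs(step))
        if big > cap:
            step *= cap / big
        return step

    conv_t = np.full(K, np.inf)
    z3 = None
    for attempt in range(settings.max_restarts + 1):
        # phase 2: gain-halving sub-phases with Polyak averaging
        for sub in range(settings.subphases):
            a = settings.a0 / (2.0**sub)
            trail = np.zeros(K)
            for _ in range(settings.p2_iters):
                sampler.sweep(rng, settings.p2_sweeps)
                z_sim = model.statistics(sampler.state(), exclude_masked=excl)
                theta = theta - a * (z_sim - z_obs) / D
                sampler.set_theta(theta)
                trail += theta
            theta = trail / settings.p2_iters
            sampler.set_theta(theta)

        # Fisher-scoring polish with the full simulated covariance, then a
        # fresh phase 3 for the reported diagnostics
        for _ in range(settings.newton_polish):
            z3, conv_t = _phase3()
            if np.max(np.abs(conv_t)) < settings.conv_threshold:
                break
            theta = theta + _newton_step(z3)
            sampler.set_theta(theta)

        # phase 3: convergence check and uncertainty
        z3, conv_t = _phase3()
        if np.max(np.abs(conv_t)) < settings.conv_threshold:
            break
        if attempt < settings.max_restarts:
            logger.info(
                "estimate_rm: max |conv t| = %.3f, restarting phase 2",
                float(np.max(np.abs(conv_t))),
            )
            D = np.maximum(z3.var(axis=0, ddof=1), floor)

    # standard errors: inverse observed information = inverse cov of statistics
    cov = np.cov(z3.T) if K > 1 else np.array([[z3.var(ddof=1)]])
    cov = np.atleast_2d(cov)
    degenerate = np.diag(cov) < 1e-12
    std_err = np.full(K, np.inf)
    good = ~degenerate
    if good.any():
        sub = cov[np.ix_(good, good)]
        try:
            inv = np.linalg.inv(sub)
            std_err[good] = np.sqrt(np.maximum(np.diag(inv), 0.0))
        except np.linalg.LinAlgError:
            logger.warning("singular statistic covariance; SEs from diagonal only")
            std_err[good] = 1.0 / np.sqrt(np.diag(sub))
    if degenerate.any():
        logger.warning(
            "degenerate simulated variance for effects: %s",
            [model.spec.names[i] for i in np.where(degenerate)[0]],
        )

    converged = bool(np.max(np.abs(conv_t)) < settings.conv_threshold)
    return FitResult(
        effect_names=model.spec.names,
        theta_hat=theta,
        std_err=std_err,
        conv_t=conv_t,
        converged=converged,
        seed=seed,
        settings=settings,
        z_obs=z_obs,
        info_matrix=cov,
        degenerate=degenerate,
    )


def gof(
    fit: FitResult,
    model: AlaamModel,
    observed: OutcomeState,
    gof_spec: EffectSpec | None = None,
    n_draws: int = 500,
    thin: int = 2,
    burn: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit t-ratios at the fitted parameters.

    Simulates from the fitted model and reports, for every statistic in
    ``gof_spec`` (default: all implemented statistics), the t-ratio
    (simulated mean - observed) / simulated SD and an adequacy flag
    |t| < 1.96.  Statistics in the fitted model have |t| below the
    convergence threshold by construction when the fit converged.
    """
    if gof_spec is None:
        cov_names = list(model.covariates.columns) if model.covariates is not None else []
        rcov_names = (
            list(model.region_covariates.columns)
            if model.region_covariates is not None
            else []
        )
        gof_spec = full_effect_spec(
            cov_names, rcov_names, include_poorest=model.quintile_covariate in cov_names
        )
    gmodel = AlaamModel(
        model.net,
        gof_spec,
        covariates=model.covariates,
        region_covariates=model.region_covariates,
        quintile_covariate=model.quintile_covariate,
    )
    excl = bool(observed.missing_mask.any())
    z_obs = gmodel.statistics(observed, exclude_masked=excl)
    rng = np.random.default_rng(seed)
    fitted = _with_theta(model, fit.theta_hat)
    state0 = observed.copy()
    sampler = GibbsSampler(fitted, state0, missing=fit.settings.missing)
    sampler.sweep(rng, burn)
    sims = np.empty((n_draws, len(gof_spec)))
    for i in range(n_draws):
        sampler.sweep(rng, thin)
        sims[i] = gmodel.statistics(sampler.state(), exclude_masked=excl)
    mean, sd = sims.mean(axis=0), sims.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 1e-12, (mean - z_obs) / sd, np.where(np.abs(mean - z_obs) < 1e-9, 0.0, np.inf))
    in_model = [n in set(fit.effect_names) for n in gof_spec.names]
    return pd.DataFrame(
        {
            "observed": z_obs,
            "sim_mean": mean,
            "sim_sd": sd,
            "t_ratio": t,
            "adequate": np.abs(t) < GOF_THRESHOLD,
            "in_model": in_model,
        },
        index=pd.Index(gof_spec.names, name="statistic"),
    )
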