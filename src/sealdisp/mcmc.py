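"""Hierarchical Bayesian model of detection-corrected natal dispersal.

For one direction of movement (origin colony i to destination j) the data are
17 cohort rows: ``B_i`` females ever observed breeding and ``b_ij`` of them
first seen breeding at the opposite colony.  The observed ratio
``mu_ij = b_ij / B_i`` is biased when lifetime detection differs between
colonies; the corrected annual rate ``mu_hat`` satisfies

    mu_hat = b_ij / (b_ij + b_ii * Delta_ji),          (correction)
    b_ij   = B_i * mu_hat * Delta_ji
             / (1 - mu_hat * (1 - Delta_ji)),          (its exact inverse)

with ``Delta_ji = Delta_j / Delta_i`` the ratio of lifetime detection at the
two colonies.  The observed disperser count is modelled as Poisson with the
inverse formula's prediction as its mean, and the 17 annual rates share a
Normal hyper-distribution on the log-odds scale,
``logit(mu_hat) ~ Normal(theta, Sigma)`` (constant variant) or
``logit(mu_hat) ~ Normal(nu * t + eta, Sigma)`` with ``t`` the birth year
minus a centring year (trend variant).  The log-odds scale respects the (0,1)
support of the rates and lets the spread parameter mean the same thing for
rates near zero and near one half; the reported "mean dispersal" is the
posterior of ``expit(theta)``, back on the probability scale.

Sampling is a bespoke one-parameter-at-a-time Gaussian random-walk Metropolis
scheme.  The detection ratio is not a sampled parameter: at every sweep one
value is drawn uniformly from a stored prior sample (the Monte-Carlo detection
posterior), so detection uncertainty propagates into the dispersal posterior
but is never updated by the dispersal counts.  Flat priors on everything else,
subject only to ``mu_hat, theta, eta`` in (0, 1) and ``Sigma > 0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import CohortDispersalTable, InsufficientDataError

logger = logging.getLogger("sealdisp")

_LOG_2PI = math.log(2.0 * math.pi)

#: Year subtracted from birth years to centre the trend covariate.
YEAR_CENTER = 2002


@dataclass(frozen=True)
class DispersalModelConfig:
    """Settings for the Metropolis sampler."""

    n_steps: int = 6000
    burn_in: int = 2000
    proposal_sd: float = 0.05
    seed: int | None = None
    variant: str = "constant"  # or "trend"
    year_center: int = YEAR_CENTER
    hierarchical: bool = True  # False: flat prior on each rate (prob scale), no pooling
    adapt_window: int = 100  # burn-in adaptation block, targets ~0.3 acceptance

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must be < n_steps")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")
        if self.variant not in ("constant", "trend"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class DispersalPosterior:
    """Post-burn-in Metropolis chains for one direction of dispersal.

    ``mu`` holds the annual corrected rates on the probability scale.  In the
    constant variant ``hyper`` holds ``theta`` (the mean dispersal rate,
    ``expit`` of the log-odds hyper-mean), ``theta_logit`` and ``sigma`` (the
    log-odds hyper-mean and spread); the trend variant holds ``nu``, ``eta``
    and ``sigma``, all on the log-odds scale.
    """

    origin: str
    dest: str
    years: np.ndarray  # birth years, length n_cohorts
    mu: np.ndarray  # (n_kept, n_cohorts) annual corrected rates
    hyper: dict[str, np.ndarray]  # theta/sigma or nu/eta/sigma chains
    ratio_index: np.ndarray  # prior-draw index used at each kept step
    accept_rate: dict[str, float]
    config: DispersalModelConfig

    @property
    def variant(self) -> str:
        return self.config.variant

    def param_chains(self) -> dict[str, np.ndarray]:
        out = {f"mu_{y}": self.mu[:, k] for k, y in enumerate(self.years)}
        out.update(self.hyper)
        return out


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and central 95% interval per parameter."""

    table: pd.DataFrame  # index: parameter; columns: mean, ci_low, ci_high
    variant: str

    def __post_init__(self) -> None:
        t = self.table
        if ((t["ci_low"] > t["mean"]) | (t["mean"] > t["ci_high"])).any():
            raise ValueError("posterior mean outside its credible interval")

    def trend_excludes_zero(self) -> bool:
        """Whether the year-effect slope is credibly different from zero."""
        if self.variant != "trend":
            raise ValueError("trend test requires the trend variant")
        row = self.table.loc["nu"]
        return not (row["ci_low"] <= 0.0 <= row["ci_high"])


# ---------------------------------------------------------------------------
# Point formulas
# ---------------------------------------------------------------------------


def naive_dispersal(b_emigrant: float, b_resident: float) -> float:
    """Observed dispersal ratio b_ij / (b_ij + b_ii), uncorrected for detection."""
    total = b_emigrant + b_resident
    if total <= 0:
        raise InsufficientDataError("no observed breeders; dispersal ratio undefined")
    return b_emigrant / total


def corrected_dispersal_point(
    b_emigrant: float, b_resident: float, ratio: float
) -> float:
    """Detection-corrected dispersal b_ij / (b_ij + b_ii * Delta_ji)."""
    if ratio <= 0:
        raise ValueError("detection ratio must be positive")
    denom = b_emigrant + b_resident * ratio
    if denom <= 0:
        raise InsufficientDataError("no observed breeders; dispersal ratio undefined")
    return b_emigrant / denom


def predict_observed(B_obs: float, mu_hat: float, ratio: float) -> float:
    """Expected observed emigrant count given a corrected rate and detection ratio.

    Exact algebraic inverse of :func:`corrected_dispersal_point`: with
    ``b = predict_observed(B, mu, r)``, correcting ``(b, B - b)`` with ratio
    ``r`` returns ``mu``.
    """
    if not 0.0 <= mu_hat <= 1.0:
        raise ValueError("mu_hat must lie in [0, 1]")
    if ratio <= 0:
        raise ValueError("detection ratio must be positive")
    if B_obs < 0:
        raise ValueError("observed breeder total must be non-negative")
    denom = 1.0 - mu_hat * (1.0 - ratio)
    if denom <= 0:
        raise ValueError("degenerate prediction: 1 - mu*(1 - ratio) <= 0")
    return B_obs * mu_hat * ratio / denom


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def _poisson_logpmf(k: int, lam: float) -> float:
    if lam == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(lam) - lam - math.lgamma(k + 1.0)


def loglik_counts(b_obs: int, b_expected: float) -> float:
    """Poisson log-likelihood of an observed disperser count.

    By convention an expected count of exactly zero with zero observed
    contributes nothing (log-likelihood 0).
    """
    if b_obs < 0 or b_obs != int(b_obs):
        raise ValueError("observed count must be a non-negative integer")
    if b_expected < 0:
        raise ValueError("expected count must be non-negative")
    return _poisson_logpmf(int(b_obs), float(b_expected))


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def loglik_hyper(
    mu_hats: np.ndarray,
    theta: float = 0.0,
    sigma: float = 1.0,
    variant: str = "constant",
    nu: float = 0.0,
    eta: float = 0.0,
    years: np.ndarray | None = None,
    year_center: int = YEAR_CENTER,
) -> float:
    """Log-likelihood of the annual rates under the Normal hyper-distribution."""
    if sigma <= 0:
        return -math.inf
    mu_hats = np.asarray(mu_hats, dtype=float)
    if variant == "trend":
        if years is None:
            raise ValueError("trend variant needs cohort birth years")
        t = np.asarray(years, dtype=float) - year_center
        means = nu * t + eta
    elif variant == "constant":
        means = np.full_like(mu_hats, theta)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    z = (mu_hats - means) / sigma
    return float(
        -0.5 * np.dot(z, z) - mu_hats.size * (math.log(sigma) + 0.5 * _LOG_2PI)
    )


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def _direction_arrays(
    table: CohortDispersalTable, origin: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = table.direction(origin)
    years = sub.index.to_numpy(dtype=int)
    B = sub["breeding"].to_numpy(dtype=int)
    b = sub["emigrant"].to_numpy(dtype=int)
    if (B <= 0).any():
        # no observed breeders: the count likelihood is flat and the cohort's
        # rate is informed only by the hierarchy
        logger.warning(
            "cohort(s) %s from %r have no observed breeders; their annual "
            "rates are informed only by the hyper-distribution",
            list(years[B <= 0]),
            origin,
        )
    return years, B, b


def run_sampler(
    table: CohortDispersalTable,
    origin: str,
    ratio_draws: np.ndarray,
    config: DispersalModelConfig,
) -> DispersalPosterior:
    """Metropolis sampler for one direction of natal dispersal.

    Annual rates are sampled on the log-odds scale (the hyper-distribution's
    scale); the chain is initialised at the observed ratios (clipped inside
    (0, 1)).  Each sweep first refreshes the detection ratio by a uniform draw
    from ``ratio_draws``, then updates every parameter one at a time with a
    Gaussian random-walk proposal; per-parameter proposal scales adapt during
    burn-in toward ~0.3 acceptance and are frozen afterwards.  With
    ``hierarchical=False`` pooling is disabled: each rate is sampled directly
    on the probability scale under a flat prior on (0, 1).
    """
    years, B, b_obs = _direction_arrays(table, origin)
    dest = table.colonies[1] if origin == table.colonies[0] else table.colonies[0]
    ratio_draws = np.asarray(ratio_draws, dtype=float)
    if ratio_draws.size == 0:
        raise ValueError("empty detection-ratio prior sample")
    n = years.size
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    t_cov = years.astype(float) - cfg.year_center
    trend = cfg.variant == "trend"
    hier = cfg.hierarchical

    # parameter vector: n annual rates (log-odds when pooled), then hypers
    hyper_names = (["nu", "eta", "sigma"] if trend else ["theta", "sigma"]) if hier else []
    n_par = n + len(hyper_names)

    def to_prob(x_k: float) -> float:
        return 1.0 / (1.0 + math.exp(-x_k)) if hier else x_k

    naive = np.divide(
        b_obs, B, out=np.full(n, np.nan), where=B > 0, casting="unsafe"
    )
    fill = float(np.nanmean(naive)) if np.isfinite(np.nanmean(naive)) else 0.1
    naive = np.clip(np.nan_to_num(naive, nan=fill), 1e-3, 1.0 - 1e-3)
    x = np.log(naive / (1.0 - naive)) if hier else naive.copy()
    theta = float(x.mean())
    sigma = float(max(x.std(), 0.1 if hier else 0.02))
    nu, eta = 0.0, theta

    def hyper_mean(k: int) -> float:
        return nu * t_cov[k] + eta if trend else theta

    def pois_term(k: int, x_k: float, r: float) -> float:
        mu_k = to_prob(x_k)
        pred = B[k] * mu_k * r / (1.0 - mu_k * (1.0 - r))
        return _poisson_logpmf(int(b_obs[k]), pred)

    # initial likelihood check
    r0 = float(ratio_draws[rng.integers(ratio_draws.size)])
    for k in range(n):
        if not math.isfinite(pois_term(k, x[k], r0)):
            raise InsufficientDataError(
                f"non-finite initial likelihood for cohort {years[k]} "
                f"(B={B[k]}, b={b_obs[k]})"
            )

    n_keep = cfg.n_steps - cfg.burn_in
    mu_out = np.empty((n_keep, n))
    hyper_out = {name: np.empty(n_keep) for name in hyper_names}
    if hier and not trend:
        hyper_out["theta_logit"] = np.empty(n_keep)
    idx_out = np.empty(n_keep, dtype=int)

    scales = np.full(n_par, cfg.proposal_sd * (6.0 if hier else 1.0))
    acc = np.zeros(n_par)
    tries = np.zeros(n_par)
    acc_post = np.zeros(n_par)
    tries_post = np.zeros(n_par)

    # pre-generated randomness for speed
    z_all = rng.standard_normal((cfg.n_steps, n_par))
    logu_all = np.log(rng.random((cfg.n_steps, n_par)))
    ridx_all = rng.integers(ratio_draws.size, size=cfg.n_steps)

    pois = np.empty(n)
    norm = np.empty(n)

    for step in range(cfg.n_steps):
        r = float(ratio_draws[ridx_all[step]])
        for k in range(n):
            pois[k] = pois_term(k, x[k], r)
            if hier:
                norm[k] = _normal_logpdf(x[k], hyper_mean(k), sigma)
        burn = step < cfg.burn_in

        # annual rates
        for k in range(n):
            prop = x[k] + scales[k] * z_all[step, k]
            tries[k] += 1
            if not burn:
                tries_post[k] += 1
            if not hier and not 0.0 < prop < 1.0:
                continue
            new_pois = pois_term(k, prop, r)
            d = new_pois - pois[k]
            if hier:
                new_norm = _normal_logpdf(prop, hyper_mean(k), sigma)
                d += new_norm - norm[k]
            if d >= 0.0 or logu_all[step, k] < d:
                x[k] = prop
                pois[k] = new_pois
                if hier:
                    norm[k] = new_norm
                acc[k] += 1
                if not burn:
                    acc_post[k] += 1

        # hyper-parameters
        for j, name in enumerate(hyper_names):
            p = n + j
            tries[p] += 1
            if not burn:
                tries_post[p] += 1
            cur = {"theta": theta, "sigma": sigma, "nu": nu, "eta": eta}[name]
            prop = cur + scales[p] * z_all[step, p]
            if name == "sigma" and prop <= 0.0:
                continue
            trial = dict(theta=theta, sigma=sigma, nu=nu, eta=eta)
            trial[name] = prop
            if trend:
                means = trial["nu"] * t_cov + trial["eta"]
            else:
                means = np.full(n, trial["theta"])
            z = (x - means) / trial["sigma"]
            new_norm_sum = float(
                -0.5 * np.dot(z, z) - n * (math.log(trial["sigma"]) + 0.5 * _LOG_2PI)
            )
            d = new_norm_sum - float(norm.sum())
            if d >= 0.0 or logu_all[step, p] < d:
                theta, sigma, nu, eta = (
                    trial["theta"],
                    trial["sigma"],
                    trial["nu"],
                    trial["eta"],
                )
                for k in range(n):
                    norm[k] = _normal_logpdf(x[k], hyper_mean(k), sigma)
                acc[p] += 1
                if not burn:
                    acc_post[p] += 1

        # adapt proposal scales in blocks during burn-in only
        if burn and (step + 1) % cfg.adapt_window == 0:
            rates = acc / np.maximum(tries, 1)
            scales *= np.exp(rates - 0.3)
            np.clip(scales, 1e-4, 2.0, out=scales)
            acc[:] = 0.0
            tries[:] = 0.0

        if not burn:
            i = step - cfg.burn_in
            mu_out[i] = 1.0 / (1.0 + np.exp(-x)) if hier else x
            for j, name in enumerate(hyper_names):
                hyper_out[name][i] = {
                    "theta": 1.0 / (1.0 + math.exp(-theta)),  # dispersal scale
                    "sigma": sigma,
                    "nu": nu,
                    "eta": eta,
                }[name]
            if hier and not trend:
                hyper_out["theta_logit"][i] = theta
            idx_out[i] = ridx_all[step]

    names = [f"mu_{y}" for y in years] + hyper_names
    rates_post = {
        name: float(acc_post[p] / max(tries_post[p], 1)) for p, name in enumerate(names)
    }
    logger.info(
        "sampler %s->%s (%s): mean acceptance %.2f over %d kept steps",
        origin,
        dest,
        cfg.variant,
        float(np.mean(list(rates_post.values()))),
        n_keep,
    )
    return DispersalPosterior(
        origin=origin,
        dest=dest,
        years=years,
        mu=mu_out,
        hyper=hyper_out,
        ratio_index=idx_out,
        accept_rate=rates_post,
        config=cfg,
    )


def fit_dispersal(
    table: CohortDispersalTable,
    origin: str,
    ratio_draws: np.ndarray,
    config: DispersalModelConfig,
    n_chains: int = 1,
) -> DispersalPosterior:
    """Run one or more independent chains and pool their kept draws.

    Chains differ only by seed (derived from ``config.seed``); pooling kept
    draws across chains stabilises posterior means for reporting.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    seeds = np.random.SeedSequence(config.seed).spawn(n_chains)
    posts = [
        run_sampler(
            table,
            origin,
            ratio_draws,
            replace(config, seed=int(s.generate_state(1)[0] % (2**31))),
        )
        for s in seeds
    ]
    if n_chains == 1:
        return posts[0]
    pooled = posts[0]
    return DispersalPosterior(
        origin=pooled.origin,
        dest=pooled.dest,
        years=pooled.years,
        mu=np.concatenate([p.mu for p in posts]),
        hyper={
            k: np.concatenate([p.hyper[k] for p in posts]) for k in pooled.hyper
        },
        ratio_index=np.concatenate([p.ratio_index for p in posts]),
        accept_rate={
            k: float(np.mean([p.accept_rate[k] for p in posts]))
            for k in pooled.accept_rate
        },
        config=config,
    )


def summarize(posterior: DispersalPosterior) -> PosteriorSummary:
    """Posterior mean and central 95% credible interval for every parameter."""
    rows = {}
    for name, chain in posterior.param_chains().items():
        if chain.size == 0:
            raise ValueError("empty chain; nothing to summarize")
        lo, hi = np.percentile(chain, [2.5, 97.5])
        rows[name] = (float(chain.mean()), float(lo), float(hi))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "ci_low", "ci_high"]
    )
    table.index.name = "parameter"
    return PosteriorSummary(table=table, variant=posterior.variant)
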