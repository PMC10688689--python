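"""Detection probabilities from resight summaries.

The chain of estimates, per colony:

* reappearance ``pi`` — probability a female observed breeding in year t is
  observed at the same colony in year t+1; a binomial proportion with a Beta
  posterior,
* return rate ``tau`` — probability a tagged female is alive and still tagged
  a year later (survival x tag retention, only their product is identified);
  estimated from the decay of the pooled age distribution, log-linear OLS,
* annual detection ``delta = pi / tau``,
* lifetime detection ``Delta = delta / (1 - tau * (1 - delta))`` — probability
  a female who breeds at least once is ever observed.  The factor
  ``1 / (1 - tau * (1 - delta))`` is the expected number of seasons until
  first detection, so lifetime detection is annual detection times expected
  detection age.

Uncertainty is carried by Monte-Carlo draws: pi from its Beta posterior, tau
from a truncated Normal around the regression slope, and delta, Delta, and the
between-colony detection ratio Delta_ji = Delta_j / Delta_i propagated
element-wise.  The ratio draws become the prior sample the dispersal sampler
consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ingest import AgeCountTable, InsufficientDataError, ReappearanceTable

logger = logging.getLogger("sealdisp")

#: Default number of Monte-Carlo draws for detection posteriors.
DEFAULT_DRAWS = 100_000

#: Default age range for the return-rate regression (first-breeding ages are
#: noisy because age at first breeding varies over 3-4).
TAU_AGE_RANGE = (4, 14)


@dataclass(frozen=True)
class ReturnRateFit:
    """Log-linear regression of pooled age counts; ``exp(slope)`` estimates tau."""

    slope_mean: float
    slope_se: float
    age_range_used: tuple[int, int]
    n_points: int
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (0.0 < self.slope_mean < 1.0):
            raise ValueError("return rate estimate outside (0, 1) but marked valid")


@dataclass
class DetectionPosterior:
    """Monte-Carlo draws of pi, tau, delta, Delta per colony, plus ratio draws.

    ``draws[colony]`` maps each of ``"pi" | "tau" | "delta" | "Delta"`` to a
    vector of M draws.  ``ratio[(j, i)]`` holds draws of Delta_j / Delta_i; the
    opposite direction is the element-wise reciprocal.
    """

    colonies: tuple[str, str]
    draws: dict[str, dict[str, np.ndarray]]
    ratio: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def ratio_draws(self, dest: str, origin: str) -> np.ndarray:
        """Draws of the detection ratio Delta_dest / Delta_origin."""
        return self.ratio[(dest, origin)]

    def summary(self) -> pd.DataFrame:
        """Mean and central 95% interval of every stored quantity."""
        rows = []
        for colony, qs in self.draws.items():
            for name, v in qs.items():
                lo, hi = np.percentile(v, [2.5, 97.5])
                rows.append((colony, name, float(v.mean()), float(lo), float(hi)))
        for (j, i), v in self.ratio.items():
            lo, hi = np.percentile(v, [2.5, 97.5])
            rows.append((f"{j}/{i}", "ratio", float(v.mean()), float(lo), float(hi)))
        return pd.DataFrame(
            rows, columns=["colony", "quantity", "mean", "ci_low", "ci_high"]
        )


def posterior_pi(
    successes: int, trials: int, M: int = DEFAULT_DRAWS, seed=None
) -> np.ndarray:
    """Draws from the Beta posterior of the reappearance rate.

    Standard binomial posterior under a uniform prior:
    ``Beta(successes + 1, trials - successes + 1)``.
    """
    if trials <= 0:
        raise InsufficientDataError("no year-1 trials; reappearance rate undefined")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    rng = np.random.default_rng(seed)
    return rng.beta(successes + 1, trials - successes + 1, size=M)


def fit_return_rate(
    ages: AgeCountTable | pd.Series,
    colony: str | None = None,
    a_min: int = TAU_AGE_RANGE[0],
    a_max: int = TAU_AGE_RANGE[1],
) -> ReturnRateFit:
    """Estimate the return rate from the decay of the pooled age distribution.

    Ordinary least squares of ``log N_obs(a)`` on age ``a`` over
    ``[a_min, a_max]``; the annual return rate is ``exp(slope)`` and its
    standard error follows by the delta method.  Ages with zero counts inside
    the range are dropped with a warning (their log is undefined).
    """
    if isinstance(ages, AgeCountTable):
        if colony is None:
            raise ValueError("colony required when passing an AgeCountTable")
        series = ages.counts[colony]
    else:
        series = ages
    series = series[(series.index >= a_min) & (series.index <= a_max)]
    zero = series[series <= 0]
    if len(zero):
        logger.warning(
            "dropping %d zero-count age class(es) %s from return-rate fit",
            len(zero),
            list(zero.index),
        )
        series = series[series > 0]
    if len(series) < 3:
        raise InsufficientDataError(
            f"return-rate fit needs >=3 positive age classes in [{a_min}, {a_max}]"
        )
    x = sm.add_constant(series.index.to_numpy(dtype=float))
    fit = sm.OLS(np.log(series.to_numpy(dtype=float)), x).fit()
    slope, slope_se = fit.params[1], fit.bse[1]
    tau = math.exp(slope)
    tau_se = tau * slope_se  # delta method for tau = exp(slope)
    valid = 0.0 < tau < 1.0
    if not valid:
        logger.warning("return-rate fit at boundary: tau=%.4f flagged invalid", tau)
    return ReturnRateFit(
        slope_mean=tau,
        slope_se=float(tau_se) if np.isfinite(tau_se) else 0.0,
        age_range_used=(int(series.index.min()), int(series.index.max())),
        n_points=len(series),
        valid=valid,
    )


def posterior_tau(fit: ReturnRateFit, M: int = DEFAULT_DRAWS, seed=None) -> np.ndarray:
    """Normal draws around the return-rate estimate, truncated to (0, 1)."""
    if not fit.valid:
        raise ValueError("cannot draw from an invalid return-rate fit")
    s, se = fit.slope_mean, fit.slope_se
    if se <= 0:
        return np.full(M, s)
    mass = stats.norm.cdf(1.0, s, se) - stats.norm.cdf(0.0, s, se)
    if mass < 0.9:
        logger.warning(
            "truncating tau ~ Normal(%.3f, %.3f) to (0,1) discards %.0f%% of mass",
            s,
            se,
            100 * (1 - mass),
        )
    a, b = (0.0 - s) / se, (1.0 - s) / se
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=s, scale=se, size=M, random_state=rng)


def annual_detection(pi_draws: np.ndarray, tau_draws: np.ndarray) -> np.ndarray:
    """Annual detection delta = pi / tau, element-wise over paired draws."""
    pi_draws = np.asarray(pi_draws, dtype=float)
    tau_draws = np.asarray(tau_draws, dtype=float)
    if pi_draws.shape != tau_draws.shape:
        raise ValueError("pi and tau draw vectors must have equal length")
    if (tau_draws <= 0).any():
        raise ValueError("non-positive tau draw; detection undefined")
    delta = pi_draws / tau_draws
    n_over = int((delta >= 1.0).sum())
    if n_over:
        # reappearance cannot exceed return; keep draws, but flag loudly
        logger.warning(
            "%d delta draw(s) >= 1 (%.2f%%): pi posterior overlaps tau",
            n_over,
            100 * n_over / delta.size,
        )
    return delta


def lifetime_detection(
    delta_draws: np.ndarray, tau_draws: np.ndarray
) -> np.ndarray:
    """Lifetime detection Delta = delta / (1 - tau * (1 - delta)), element-wise.

    Compounds annual detection over a geometrically distributed breeding
    lifetime with annual persistence tau.
    """
    delta_draws = np.asarray(delta_draws, dtype=float)
    tau_draws = np.asarray(tau_draws, dtype=float)
    if ((delta_draws < 0) | (delta_draws > 1)).any():
        raise ValueError("delta draws must lie in [0, 1]")
    if ((tau_draws < 0) | (tau_draws >= 1)).any():
        raise ValueError("tau draws must lie in [0, 1)")
    return delta_draws / (1.0 - tau_draws * (1.0 - delta_draws))


def detection_ratio(
    delta_draws_j: np.ndarray, delta_draws_i: np.ndarray
) -> np.ndarray:
    """Element-wise ratio of lifetime-detection draws, Delta_ji = Delta_j / Delta_i."""
    j = np.asarray(delta_draws_j, dtype=float)
    i = np.asarray(delta_draws_i, dtype=float)
    if j.shape != i.shape:
        raise ValueError("draw vectors must have equal length")
    if (i <= 0).any():
        raise ValueError("non-positive lifetime detection in denominator")
    return j / i


def build_detection_posterior(
    reapp: ReappearanceTable,
    tau_fits: dict[str, ReturnRateFit],
    M: int = DEFAULT_DRAWS,
    seed=None,
) -> DetectionPosterior:
    """Run the whole detection chain for both colonies.

    Draws pi from each colony's reappearance counts and tau from its
    return-rate fit, propagates to delta and Delta, and stores both directions
    of the detection ratio.  The draw vectors are fixed once here; the
    dispersal sampler later resamples ratio draws uniformly, never updating
    them against the dispersal data.
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, dict[str, np.ndarray]] = {}
    for colony in reapp.colonies:
        successes, trials = reapp.pi_counts(colony)
        pi = posterior_pi(successes, trials, M=M, seed=rng)
        tau = posterior_tau(tau_fits[colony], M=M, seed=rng)
        delta = annual_detection(pi, tau)
        big_delta = lifetime_detection(np.clip(delta, 0.0, 1.0), tau)
        draws[colony] = {"pi": pi, "tau": tau, "delta": delta, "Delta": big_delta}
    c1, c2 = reapp.colonies
    r12 = detection_ratio(draws[c1]["Delta"], draws[c2]["Delta"])
    post = DetectionPosterior(colonies=reapp.colonies, draws=draws)
    post.ratio[(c1, c2)] = r12
    post.ratio[(c2, c1)] = 1.0 / r12
    return post
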