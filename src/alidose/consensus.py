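"""Hierarchical Bayesian consensus of per-plate viability measurements.

Plates run on different days disagree by more than the within-plate scatter,
so a single condition's viability is combined across plates with a
random-effects model:

    y_ij ~ Normal(theta_j, sigma_j^2)      insert i on plate j
    theta_j ~ Normal(mu, tau^2)            plate-level mean
    mu ~ Normal(m0, s0^2)                  diffuse prior on the consensus
    sigma_j, tau ~ Half-Cauchy(A)          weakly informative scale priors

The consensus value is the posterior of mu, reported with a central 95%
credible interval; a condition is called "significantly below control" when
more than 95% of the consensus posterior mass lies below 100%.  Sampling is
Metropolis-within-Gibbs: conjugate Gibbs updates for mu and theta_j,
adaptive log-scale random-walk Metropolis for sigma_j and tau.  When chains
fail the split-R-hat check, a frequentist random-effects combination of the
per-plate means (DerSimonian-Laird, as used by interlaboratory consensus
tools) stands in.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PosteriorSummary",
    "SignificanceCall",
    "HierarchicalConsensus",
    "fit_hierarchical_model",
    "significance_calls",
    "fallback_consensus",
    "convergence_check",
]

# numerical floor for sampled scales; keeps the degenerate zero-variance
# data case (all observations identical) finite
_LOG_SCALE_FLOOR = math.log(1e-6)
_Z95 = 1.959963984540054


@dataclass
class PosteriorSummary:
    condition: str
    plate_ids: list[str]
    per_plate_means: dict[str, float]
    per_plate_bounds: dict[str, tuple[float, float]]
    consensus_mean: float
    consensus_bounds: tuple[float, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    used_fallback: bool = False


@dataclass
class SignificanceCall:
    condition: str
    prob_below_reference: float
    flag_less_than_control: bool
    pairwise_equality: dict[tuple[str, str], bool] = field(default_factory=dict)


def _halfcauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log1p((x / scale) ** 2)


def _sample_condition(
    y_by_plate: list[np.ndarray],
    *,
    prior_mean_center: float,
    prior_mean_sd: float,
    hc_within: float,
    hc_between: float,
    n_chains: int,
    n_iterations: int,
    burn_in_fraction: float,
    thin: int,
    rng: np.random.Generator,
    sigma_fixed: float | None = None,
    tau_fixed: float | None = None,
) -> dict[str, np.ndarray]:
    """Run the Metropolis-within-Gibbs sampler for one condition.

    Returns post-burn-in draws shaped (chain, draw) for ``mu`` and ``tau``
    and (chain, draw, plate) for ``theta`` and ``sigma``.
    """
    J = len(y_by_plate)
    n_j = np.array([len(y) for y in y_by_plate], dtype=float)
    ybar_j = np.array([float(np.mean(y)) for y in y_by_plate])
    # within-plate sum of squares around theta is recomputed each sweep from
    # these sufficient statistics: SS_j(theta) = SS0_j + n_j (ybar_j-theta)^2
    ss0_j = np.array([float(np.sum((y - np.mean(y)) ** 2)) for y in y_by_plate])

    n_burn = int(n_iterations * burn_in_fraction)
    n_keep = max(0, (n_iterations - n_burn) // thin)
    mu_out = np.empty((n_chains, n_keep))
    tau_out = np.empty((n_chains, n_keep))
    theta_out = np.empty((n_chains, n_keep, J))
    sigma_out = np.empty((n_chains, n_keep, J))

    prior_prec = 1.0 / prior_mean_sd**2

    for c in range(n_chains):
        # dispersed initialization around the pooled mean
        pooled = float(np.average(ybar_j, weights=n_j))
        pooled_sd = max(float(np.std(np.concatenate(y_by_plate))), 1.0)
        mu = pooled + rng.normal(0.0, pooled_sd)
        theta = ybar_j + rng.normal(0.0, pooled_sd, size=J)
        log_sigma = np.full(J, math.log(pooled_sd)) + rng.normal(0.0, 0.3, size=J)
        log_tau = math.log(pooled_sd) + rng.normal(0.0, 0.3)
        if sigma_fixed is not None:
            log_sigma = np.full(J, math.log(sigma_fixed))
        tau_is_zero = tau_fixed is not None and tau_fixed == 0.0
        if tau_fixed is not None and not tau_is_zero:
            log_tau = math.log(tau_fixed)

        step_sigma = np.full(J, 0.5)
        step_tau = 0.5
        acc_sigma = np.zeros(J)
        acc_tau = 0.0
        adapt_block = 50

        k = 0
        for it in range(n_iterations):
            sigma = np.exp(log_sigma)
            sigma2 = sigma**2

            if tau_is_zero:
                # single-level reduction: theta_j == mu, conjugate update on
                # the full data
                prec = float(np.sum(n_j / sigma2)) + prior_prec
                mean = (float(np.sum(n_j * ybar_j / sigma2)) + prior_mean_center * prior_prec) / prec
                mu = rng.normal(mean, 1.0 / math.sqrt(prec))
                theta = np.full(J, mu)
                tau = 0.0
            else:
                tau = math.exp(log_tau)
                tau2 = tau**2
                # Gibbs: theta_j | rest
                prec_t = n_j / sigma2 + 1.0 / tau2
                mean_t = (n_j * ybar_j / sigma2 + mu / tau2) / prec_t
                theta = rng.normal(mean_t, 1.0 / np.sqrt(prec_t))
                # Gibbs: mu | rest
                prec_m = J / tau2 + prior_prec
                mean_m = (float(np.sum(theta)) / tau2 + prior_mean_center * prior_prec) / prec_m
                mu = rng.normal(mean_m, 1.0 / math.sqrt(prec_m))
                # Metropolis: log tau
                if tau_fixed is None:
                    ss_theta = float(np.sum((theta - mu) ** 2))
                    prop = log_tau + rng.normal(0.0, step_tau)
                    prop = max(prop, _LOG_SCALE_FLOOR)

                    def _lp_tau(lt: float) -> float:
                        t = math.exp(lt)
                        return (
                            -J * lt
                            - ss_theta / (2.0 * t * t)
                            + float(_halfcauchy_logpdf(np.array(t), hc_between))
                            + lt
                        )

                    if math.log(rng.uniform()) < _lp_tau(prop) - _lp_tau(log_tau):
                        log_tau = prop
                        acc_tau += 1.0

            # Metropolis: log sigma_j (vectorized over plates)
            if sigma_fixed is None:
                ss_j = ss0_j + n_j * (ybar_j - theta) ** 2
                prop = log_sigma + rng.normal(0.0, step_sigma, size=J)
                prop = np.maximum(prop, _LOG_SCALE_FLOOR)

                def _lp_sigma(ls: np.ndarray) -> np.ndarray:
                    s = np.exp(ls)
                    return (
                        -n_j * ls
                        - ss_j / (2.0 * s * s)
                        + _halfcauchy_logpdf(s, hc_within)
                        + ls
                    )

                accept = np.log(rng.uniform(size=J)) < _lp_sigma(prop) - _lp_sigma(log_sigma)
                log_sigma = np.where(accept, prop, log_sigma)
                acc_sigma += accept

            # step-size adaptation during burn-in, targeting ~44% acceptance
            if it < n_burn and (it + 1) % adapt_block == 0:
                rate_s = acc_sigma / adapt_block
                step_sigma *= np.exp((rate_s - 0.44))
                acc_sigma[:] = 0.0
                rate_t = acc_tau / adapt_block
                step_tau *= math.exp(rate_t - 0.44)
                acc_tau = 0.0

            if it >= n_burn and (it - n_burn) % thin == 0 and k < n_keep:
                mu_out[c, k] = mu
                tau_out[c, k] = 0.0 if tau_is_zero else math.exp(log_tau)
                theta_out[c, k] = theta
                sigma_out[c, k] = np.exp(log_sigma)
                k += 1

    return {"mu": mu_out, "tau": tau_out, "theta": theta_out, "sigma": sigma_out}


class HierarchicalConsensus(BaseEstimator):
    """Random-effects Bayesian consensus estimator for multi-plate assays.

    Parameters
    ----------
    prior_mean_center, prior_mean_sd : Gaussian prior on the consensus mean
        (percent-viability scale; the default N(100, 1000^2) is diffuse).
    halfcauchy_scale_within, halfcauchy_scale_between : Half-Cauchy scales for
        the within-plate sds and the between-plate sd.
    n_chains, n_iterations, burn_in_fraction, thin : MCMC schedule;
        ``n_iterations`` counts per-chain sweeps including burn-in.
    rhat_threshold : split-R-hat above which a condition is declared
        non-converged and the DerSimonian-Laird fallback is used.
    sigma_fixed, tau_fixed : pin a scale instead of sampling it (``tau_fixed=0``
        collapses the hierarchy to a single-level conjugate model); mainly for
        validation against closed-form posteriors.
    seed : base seed for the sampler.

    Attributes (after ``fit``)
    --------------------------
    summaries_ : dict of condition -> PosteriorSummary
    draws_ : dict of condition -> consensus (mu) draws, shape (chain, draw)
    conditions_ : fitted condition labels
    """

    def __init__(
        self,
        prior_mean_center: float = 100.0,
        prior_mean_sd: float = 1000.0,
        halfcauchy_scale_within: float = 25.0,
        halfcauchy_scale_between: float = 25.0,
        n_chains: int = 4,
        n_iterations: int = 10_000,
        burn_in_fraction: float = 0.5,
        thin: int = 1,
        rhat_threshold: float = 1.05,
        sigma_fixed: float | None = None,
        tau_fixed: float | None = None,
        seed: int | None = 0,
    ):
        self.prior_mean_center = prior_mean_center
        self.prior_mean_sd = prior_mean_sd
        self.halfcauchy_scale_within = halfcauchy_scale_within
        self.halfcauchy_scale_between = halfcauchy_scale_between
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in_fraction = burn_in_fraction
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.sigma_fixed = sigma_fixed
        self.tau_fixed = tau_fixed
        self.seed = seed

    def _validate(self) -> None:
        if self.halfcauchy_scale_within <= 0 or self.halfcauchy_scale_between <= 0:
            raise ValueError("Half-Cauchy scales must be > 0")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_iterations < 10:
            raise ValueError("n_iterations too small")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def fit(self, records: pd.DataFrame, y=None) -> "HierarchicalConsensus":
        """Fit the model to a viability table.

        ``records`` needs columns ``plate_id``, ``condition`` and
        ``viability_pct``; one posterior is sampled per condition.
        """
        self._validate()
        required = {"plate_id", "condition", "viability_pct"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records table is missing columns {sorted(missing)}")
        if len(records) == 0:
            raise ValueError("no viability records")

        rng = np.random.default_rng(self.seed)
        self.summaries_: dict[str, PosteriorSummary] = {}
        self.draws_: dict[str, np.ndarray] = {}
        self.conditions_ = sorted(records["condition"].unique())

        for condition in self.conditions_:
            sub = records[records["condition"] == condition]
            plate_ids = sorted(sub["plate_id"].unique())
            y_by_plate = [
                sub.loc[sub["plate_id"] == p, "viability_pct"].to_numpy(dtype=float)
                for p in plate_ids
            ]
            draws = _sample_condition(
                y_by_plate,
                prior_mean_center=self.prior_mean_center,
                prior_mean_sd=self.prior_mean_sd,
                hc_within=self.halfcauchy_scale_within,
                hc_between=self.halfcauchy_scale_between,
                n_chains=self.n_chains,
                n_iterations=self.n_iterations,
                burn_in_fraction=self.burn_in_fraction,
                thin=self.thin,
                rng=rng,
                sigma_fixed=self.sigma_fixed,
                tau_fixed=self.tau_fixed,
            )
            diag_params = {"mu": draws["mu"]}
            if self.tau_fixed is None:
                diag_params["tau"] = draws["tau"]
            diag = convergence_check(diag_params)
            converged = all(
                r <= self.rhat_threshold for r in diag["rhat"].values() if np.isfinite(r)
            )
            mu = draws["mu"]
            theta = draws["theta"]
            summary = PosteriorSummary(
                condition=condition,
                plate_ids=plate_ids,
                per_plate_means={
                    p: float(theta[:, :, j].mean()) for j, p in enumerate(plate_ids)
                },
                per_plate_bounds={
                    p: tuple(np.percentile(theta[:, :, j], [2.5, 97.5]))
                    for j, p in enumerate(plate_ids)
                },
                consensus_mean=float(mu.mean()),
                consensus_bounds=tuple(np.percentile(mu, [2.5, 97.5])),
                rhat=diag["rhat"],
                ess=diag["ess"],
                converged=converged,
            )
            if not converged:
                # fall back to the frequentist interlaboratory combination of
                # per-plate posterior means and sds
                means = np.array([theta[:, :, j].mean() for j in range(len(plate_ids))])
                sds = np.array([theta[:, :, j].std(ddof=1) for j in range(len(plate_ids))])
                fb_mean, fb_lo, fb_hi, _ = fallback_consensus(means, sds)
                summary.consensus_mean = fb_mean
                summary.consensus_bounds = (fb_lo, fb_hi)
                summary.used_fallback = True
            self.summaries_[condition] = summary
            self.draws_[condition] = mu
        return self

    def significance_calls(self, reference: float = 100.0) -> list[SignificanceCall]:
        if not hasattr(self, "draws_"):
            raise ValueError("estimator is not fitted")
        return significance_calls(self.draws_, reference=reference)

    def summary_frame(self) -> pd.DataFrame:
        """Per-condition consensus summary as a tidy DataFrame."""
        if not hasattr(self, "summaries_"):
            raise ValueError("estimator is not fitted")
        rows = []
        for cond, s in self.summaries_.items():
            rows.append(
                {
                    "condition": cond,
                    "consensus_mean": s.consensus_mean,
                    "ci_low": s.consensus_bounds[0],
                    "ci_high": s.consensus_bounds[1],
                    "converged": s.converged,
                    "used_fallback": s.used_fallback,
                }
            )
        return pd.DataFrame(rows)


def fit_hierarchical_model(records: pd.DataFrame, **params) -> HierarchicalConsensus:
    """Functional wrapper over :class:`HierarchicalConsensus`."""
    return HierarchicalConsensus(**params).fit(records)


def significance_calls(
    draws_by_condition: dict[str, np.ndarray],
    reference: float = 100.0,
    prob_threshold: float = 0.95,
) -> list[SignificanceCall]:
    """Below-control flags and pairwise-equality calls from posterior draws.

    A condition is flagged when more than ``prob_threshold`` of its consensus
    draws fall below ``reference``.  Two conditions are "statistically equal"
    when the central 95% interval of the difference of their consensus draws
    contains 0 (independent posteriors, draws paired after flattening).
    """
    calls: dict[str, SignificanceCall] = {}
    flat = {c: np.ravel(d) for c, d in draws_by_condition.items()}
    for cond, d in flat.items():
        p = float(np.mean(d < reference))
        calls[cond] = SignificanceCall(
            condition=cond,
            prob_below_reference=p,
            flag_less_than_control=bool(p > prob_threshold),
        )
    for a, b in itertools.combinations(sorted(flat), 2):
        n = min(flat[a].size, flat[b].size)
        diff = flat[a][:n] - flat[b][:n]
        lo, hi = np.percentile(diff, [2.5, 97.5])
        equal = bool(lo <= 0.0 <= hi)
        calls[a].pairwise_equality[(a, b)] = equal
        calls[b].pairwise_equality[(a, b)] = equal
    return [calls[c] for c in sorted(calls)]


def fallback_consensus(
    plate_means,
    plate_uncertainties,
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects combination of per-plate estimates.

    ``plate_uncertainties`` are standard uncertainties of the plate means.
    Returns ``(consensus, lo95, hi95, tau)`` where tau is the moment estimate
    of the between-plate sd (floored at 0) and the bounds use the normal
    quantile on the combined standard uncertainty.  With a single plate the
    plate's own mean and bounds are returned.
    """
    x = np.asarray(list(plate_means), dtype=float)
    u = np.asarray(list(plate_uncertainties), dtype=float)
    if x.shape != u.shape or x.ndim != 1:
        raise ValueError("means and uncertainties must be 1-D and equal length")
    if np.any(u < 0):
        raise ValueError("uncertainties must be >= 0")
    J = x.size
    if J == 0:
        raise ValueError("need at least one plate")
    if J == 1:
        return float(x[0]), float(x[0] - _Z95 * u[0]), float(x[0] + _Z95 * u[0]), 0.0

    if np.all(u == 0):
        # limit of the estimator as all u_j -> 0: tau^2 is the sample
        # variance of the plate means, weights become equal
        tau2 = float(x.var(ddof=1))
        consensus = float(x.mean())
        se = math.sqrt(tau2 / J)
    else:
        if np.any(u == 0):
            raise ValueError("mixed zero and non-zero uncertainties are not combinable")
        w = 1.0 / u**2
        xbar_w = float(np.sum(w * x) / np.sum(w))
        q = float(np.sum(w * (x - xbar_w) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (J - 1)) / c)
        w_star = 1.0 / (u**2 + tau2)
        consensus = float(np.sum(w_star * x) / np.sum(w_star))
        se = math.sqrt(1.0 / float(np.sum(w_star)))
    return consensus, consensus - _Z95 * se, consensus + _Z95 * se, math.sqrt(tau2)


def convergence_check(chains) -> dict[str, dict[str, float]]:
    """Split-R-hat and effective sample size per parameter.

    ``chains`` is either an array shaped (chain, draw) for a single parameter
    or a dict of name -> such arrays.  At least two chains are required.
    """
    if isinstance(chains, np.ndarray):
        chains = {"param": chains}
    arrays = {}
    for name, arr in chains.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim != 2:
            raise ValueError(f"{name}: chains must be shaped (chain, draw)")
        if a.shape[0] < 2:
            raise ValueError(f"{name}: need at least 2 chains")
        arrays[name] = a
    idata = az.from_dict(posterior=arrays)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    return {
        "rhat": {k: float(rhat_ds[k].values) for k in arrays},
        "ess": {k: float(ess_ds[k].values) for k in arrays},
    }
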