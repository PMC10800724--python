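"""Per-subject maximum a posteriori estimation of the seven learning traits.

The posterior is the session likelihood times independent priors:
Beta(2, 2) on each learning rate, Gamma(shape 2, scale 3) on beta, mu, nu
and lam, and a standard normal on phi. The optimizer searches transformed
coordinates (log / logit / identity) purely as a device to respect supports;
the objective remains the natural-space posterior density, with no Jacobian
correction, so the estimate is the MAP of the stated prior, not of a
reparametrized one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _core
from .bandit import BehavioralRecord
from .model import PARAM_NAMES, ModelParameters

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors over the seven traits.

    alpha_a, alpha_b : Beta shapes for alpha_pos and alpha_neg.
    gamma_shape, gamma_scale : Gamma prior for beta, mu, nu, lam.
    phi_mean, phi_sd : normal prior for phi.
    """

    alpha_a: float = 2.0
    alpha_b: float = 2.0
    gamma_shape: float = 2.0
    gamma_scale: float = 3.0
    phi_mean: float = 0.0
    phi_sd: float = 1.0

    def sample(self, rng: np.random.Generator) -> ModelParameters:
        """Draw one parameter vector from the prior (used for restarts)."""
        g = lambda: float(rng.gamma(self.gamma_shape, self.gamma_scale))
        b = lambda: float(rng.beta(self.alpha_a, self.alpha_b))
        return ModelParameters(
            beta=g(), mu=g(), nu=g(), alpha_pos=b(), alpha_neg=b(), lam=g(),
            phi=float(rng.normal(self.phi_mean, self.phi_sd)),
        )


DEFAULT_PRIORS = PriorSpec()


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the MAP search.

    n_starts restarts are drawn from the priors; each runs a quasi-Newton
    (L-BFGS-B) search in transformed coordinates with at most max_evals
    objective evaluations and objective tolerance tol. phi is searched within
    ±phi_bound to contain the additive-phi drift pathology; log-scale
    coordinates are boxed to [log_lo, log_hi] and logits to ±logit_bound.
    Fits whose optimum touches any box are flagged, not dropped.
    """

    n_starts: int = 10
    max_evals: int = 2000
    tol: float = 1e-6
    phi_bound: float = 50.0
    log_lo: float = -10.0
    log_hi: float = 5.0
    logit_bound: float = 15.0
    seed: int = 0


DEFAULT_FIT_CONFIG = FitConfig()


@dataclass
class FitResult:
    """MAP estimate with its objective values and convergence diagnostics."""

    params: ModelParameters | None
    log_likelihood: float
    log_posterior: float
    n_starts: int
    converged: bool
    best_start: int = -1
    bound_hit: bool = False
    subject_id: str | None = None
    message: str = ""


def log_likelihood(record: BehavioralRecord, params: ModelParameters) -> float:
    """Log probability of the observed choice sequence under the model."""
    if len(record) == 0:
        raise ValueError("empty record")
    value = float(_core.loglik(record.choices, record.rewards, *params.to_array()))
    if np.isnan(value):
        raise FloatingPointError("non-finite likelihood")
    return value


def log_prior(params: ModelParameters, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Joint log prior density; −inf outside the support (not an exception)."""
    lp = 0.0
    for name in ("alpha_pos", "alpha_neg"):
        lp += stats.beta.logpdf(getattr(params, name), priors.alpha_a, priors.alpha_b)
    for name in ("beta", "mu", "nu", "lam"):
        lp += stats.gamma.logpdf(
            getattr(params, name), priors.gamma_shape, scale=priors.gamma_scale
        )
    lp += stats.norm.logpdf(params.phi, priors.phi_mean, priors.phi_sd)
    return float(lp)


def log_posterior(
    record: BehavioralRecord,
    params: ModelParameters,
    priors: PriorSpec = DEFAULT_PRIORS,
) -> float:
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(record, params) + lp


# -- transformed coordinates ------------------------------------------------


def _to_transformed(params: ModelParameters) -> np.ndarray:
    b, m, n, ap, an, lam, phi = params.to_array()
    logit = lambda a: np.log(a / (1.0 - a))
    return np.array([np.log(b), np.log(m), np.log(n), logit(ap), logit(an), np.log(lam), phi])


def _from_transformed(x: np.ndarray) -> ModelParameters:
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    return ModelParameters(
        beta=float(np.exp(x[0])),
        mu=float(np.exp(x[1])),
        nu=float(np.exp(x[2])),
        alpha_pos=float(sig(x[3])),
        alpha_neg=float(sig(x[4])),
        lam=float(np.exp(x[5])),
        phi=float(x[6]),
    )


def _bounds(config: FitConfig) -> list[tuple[float, float]]:
    log_b = (config.log_lo, config.log_hi)
    logit_b = (-config.logit_bound, config.logit_bound)
    return [log_b, log_b, log_b, logit_b, logit_b, log_b, (-config.phi_bound, config.phi_bound)]


def fit_map(
    record: BehavioralRecord,
    priors: PriorSpec = DEFAULT_PRIORS,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> FitResult:
    """MAP estimate for one subject via multi-start bounded quasi-Newton.

    Restarts are drawn from the priors; the best final log posterior wins,
    ties broken by first found. Sessions shorter than two trials carry no
    usable sequential information and are rejected.
    """
    if len(record) < 2:
        raise ValueError("record must contain at least 2 trials")
    choices = np.ascontiguousarray(record.choices)
    rewards = np.ascontiguousarray(record.rewards)
    prior_args = (
        priors.alpha_a, priors.alpha_b, priors.gamma_shape, priors.gamma_scale,
        priors.phi_mean, priors.phi_sd,
    )

    def objective(x):
        return _core.neg_log_posterior_t(x, choices, rewards, *prior_args)

    bounds = _bounds(config)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    best = None
    best_fun = np.inf
    best_start = -1
    any_success = False
    for start in range(config.n_starts):
        x0 = np.clip(_to_transformed(priors.sample(rng)), lo + 1e-6, hi - 1e-6)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": config.max_evals, "ftol": config.tol},
        )
        if res.success:
            any_success = True
        if np.isfinite(res.fun) and res.fun < best_fun:
            best, best_fun, best_start = res, float(res.fun), start

    if best is None:
        return FitResult(
            params=None, log_likelihood=np.nan, log_posterior=np.nan,
            n_starts=config.n_starts, converged=False,
            subject_id=record.subject_id, message="all restarts failed",
        )

    params = _from_transformed(best.x)
    ll = log_likelihood(record, params)
    lp = ll + log_prior(params, priors)
    bound_hit = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    if bound_hit:
        logger.debug("subject %s: optimum at a search bound", record.subject_id)
    return FitResult(
        params=params,
        log_likelihood=ll,
        log_posterior=lp,
        n_starts=config.n_starts,
        converged=any_success,
        best_start=best_start,
        bound_hit=bound_hit,
        subject_id=record.subject_id,
    )


def fit_cohort(
    records: Sequence[BehavioralRecord],
    priors: PriorSpec = DEFAULT_PRIORS,
    config: FitConfig = DEFAULT_FIT_CONFIG,
) -> list[FitResult]:
    """Independent per-subject fits, order-stable and fully seeded.

    Each subject gets a deterministic child seed of ``config.seed``. Subjects
    whose records violate preconditions are returned as failed FitResults
    rather than raising, so one bad session never aborts a cohort.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to fit")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(records))
    results = []
    for rec, s in zip(records, seeds):
        sub_config = replace(config, seed=int(s) % (2**31))
        try:
            res = fit_map(rec, priors, sub_config)
        except ValueError as exc:
            res = FitResult(
                params=None, log_likelihood=np.nan, log_posterior=np.nan,
                n_starts=config.n_starts, converged=False,
                subject_id=rec.subject_id, message=str(exc),
            )
            logger.info("subject %s not fitted: %s", rec.subject_id, exc)
        results.append(res)
    n_bad = sum(not r.converged for r in results)
    logger.info("fitted %d subjects (%d flagged)", len(results), n_bad)
    return results


def fits_to_frame(results: Iterable[FitResult]) -> pd.DataFrame:
    """Fitted-parameter table: one row per subject plus diagnostics."""
    rows = []
    for r in results:
        row = {"subject_id": r.subject_id}
        if r.params is None:
            row.update({n: np.nan for n in PARAM_NAMES})
        else:
            row.update(dict(zip(PARAM_NAMES, r.params.to_array())))
        row.update(
            log_lik=r.log_likelihood,
            log_post=r.log_posterior,
            n_starts=r.n_starts,
            converged=r.converged,
            bound_hit=r.bound_hit,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(results: Iterable[FitResult], path) -> None:
    fits_to_frame(results).to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})
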