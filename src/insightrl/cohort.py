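"""Synthetic study cohorts: latent traits, bandit sessions, insight outcomes.

The generator emulates the study design end to end: a cohort of enrolled
participants with heterogeneous learning traits, one 100-trial bandit session
each, random administration order of the two spatial insight puzzles (the
8-coin and 9-dot problems), binary success outcomes produced through a probit
link on the traits and bandit performance with a cross-task transfer term,
and exclusion flags for incomplete participation and prior task experience.

Outcomes are generated at the level the analysis consumes — binary success
through a probit link — never by simulating puzzle solving itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import ndtr

from .bandit import BehavioralRecord, RewardSchedule, make_standard_schedule
from .fitting import DEFAULT_PRIORS, FitConfig, fit_cohort, fits_to_frame
from .model import PARAM_NAMES, ModelParameters, simulate_agent, tab_performance

logger = logging.getLogger(__name__)

#: Regressor order of the probit links (and of the analysis stage).
TRAIT_NAMES = PARAM_NAMES
LINK_KEYS = ("const",) + TRAIT_NAMES + ("tab_performance", "success_other")


@dataclass(frozen=True)
class TraitDistribution:
    """Truncated normal generating distribution for one latent trait."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass
class CohortConfig:
    """Everything the cohort generator needs, fully explicit and seedable.

    probit_8coin / probit_9dot map regressor names (LINK_KEYS) to link
    coefficients; ``success_other`` is the cross-task transfer coefficient,
    used only when the link conditions on the other task's outcome.

    transfer_structure:
      "by_order"    — the first-administered task is generated from traits
                      and bandit performance alone; the second adds the
                      transfer term times the first task's outcome.
      "directional" — 9-dot is generated from traits alone and 8-coin always
                      includes the transfer term; this makes the full-sample
                      8-coin regression correctly specified, which recovery
                      tests require.

    outcome_trait_source: "true" generates outcomes from the latent traits;
    "estimated" first fits the simulated sessions by MAP and feeds the
    estimates into the links (errors-in-variables switched off).
    """

    n_enrolled: int = 364
    n_incomplete: int = 7
    n_prior_experience: int = 32
    trait_distributions: dict[str, TraitDistribution] = field(default_factory=dict)
    probit_8coin: dict[str, float] = field(default_factory=dict)
    probit_9dot: dict[str, float] = field(default_factory=dict)
    order_probability: float = 0.5
    transfer_structure: str = "by_order"
    outcome_trait_source: str = "true"
    schedule: RewardSchedule = field(default_factory=make_standard_schedule)
    fit_config: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_enrolled < 1:
            raise ValueError("n_enrolled must be positive")
        if self.n_incomplete < 0 or self.n_prior_experience < 0:
            raise ValueError("exclusion counts must be non-negative")
        if self.n_incomplete + self.n_prior_experience > self.n_enrolled:
            raise ValueError("exclusions exceed enrollment")
        if not 0.0 <= self.order_probability <= 1.0:
            raise ValueError("order_probability must lie in [0, 1]")
        if self.transfer_structure not in ("by_order", "directional"):
            raise ValueError(f"unknown transfer_structure {self.transfer_structure!r}")
        if self.outcome_trait_source not in ("true", "estimated"):
            raise ValueError(f"unknown outcome_trait_source {self.outcome_trait_source!r}")
        missing = set(TRAIT_NAMES) - set(self.trait_distributions)
        if missing:
            raise ValueError(f"trait_distributions missing: {sorted(missing)}")
        for label, link in (("probit_8coin", self.probit_8coin), ("probit_9dot", self.probit_9dot)):
            unknown = set(link) - set(LINK_KEYS)
            if unknown:
                raise ValueError(f"{label} has unknown regressors: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_incomplete": self.n_incomplete,
            "n_prior_experience": self.n_prior_experience,
            "trait_distributions": {
                k: {"mean": d.mean, "sd": d.sd, "lower": d.lower, "upper": d.upper}
                for k, d in self.trait_distributions.items()
            },
            "probit_8coin": dict(self.probit_8coin),
            "probit_9dot": dict(self.probit_9dot),
            "order_probability": self.order_probability,
            "transfer_structure": self.transfer_structure,
            "outcome_trait_source": self.outcome_trait_source,
            "schedule": self.schedule.to_text(),
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        data = dict(data)
        known = {
            "n_enrolled", "n_incomplete", "n_prior_experience", "trait_distributions",
            "probit_8coin", "probit_9dot", "order_probability", "transfer_structure",
            "outcome_trait_source", "schedule", "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        config = default_study_config()
        if "trait_distributions" in data:
            config.trait_distributions = {
                k: TraitDistribution(
                    float(v["mean"]), float(v["sd"]),
                    float(v.get("lower", -np.inf)), float(v.get("upper", np.inf)),
                )
                for k, v in data.pop("trait_distributions").items()
            }
        if "schedule" in data:
            config.schedule = RewardSchedule.from_text(data.pop("schedule"))
        for key, value in data.items():
            setattr(config, key, value)
        config.probit_8coin = {k: float(v) for k, v in config.probit_8coin.items()}
        config.probit_9dot = {k: float(v) for k, v in config.probit_9dot.items()}
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_study_config(seed: int = 0) -> CohortConfig:
    """The study-design defaults: enrollment and exclusion counts, trait
    distributions matching the analyzed cohort's sample moments (truncated to
    supports), and probit links at the transfer-adjusted point estimates.

    phi is drawn from its standard-normal prior rather than from its fitted
    sample moments, whose huge spread reflects the additive-phi drift
    pathology rather than a plausible trait distribution (see methods note).
    """
    traits = {
        "beta": TraitDistribution(0.85, 1.06, lower=0.0),
        "mu": TraitDistribution(0.48, 0.28, lower=0.0),
        "nu": TraitDistribution(0.52, 0.30, lower=0.0),
        "alpha_pos": TraitDistribution(0.42, 0.27, lower=0.0, upper=1.0),
        "alpha_neg": TraitDistribution(0.59, 0.29, lower=0.0, upper=1.0),
        "lam": TraitDistribution(0.51, 0.28, lower=0.0),
        "phi": TraitDistribution(0.0, 1.0),
    }
    probit_8coin = {
        "const": -0.53, "beta": 0.00, "mu": -0.08, "nu": -0.09,
        "alpha_pos": 0.26, "alpha_neg": -0.69, "lam": -0.07, "phi": 0.00,
        "tab_performance": 0.00, "success_other": 0.59,
    }
    probit_9dot = {
        "const": 0.53, "beta": 0.00, "mu": -0.34, "nu": 0.23,
        "alpha_pos": 0.11, "alpha_neg": 0.31, "lam": -0.63, "phi": 0.01,
        "tab_performance": -0.01, "success_other": 0.59,
    }
    config = CohortConfig(
        trait_distributions=traits,
        probit_8coin=probit_8coin,
        probit_9dot=probit_9dot,
        seed=seed,
    )
    config.validate()
    return config


@dataclass
class CohortTable:
    """Per-subject cohort rows plus the underlying session records.

    ``table`` columns: subject_id, the seven true traits, tab_performance,
    task_order ("8coin_first" | "9dot_first"), excluded_reason ("none" |
    "incomplete" | "prior_experience"), success_8coin, success_9dot (NaN on
    excluded rows).
    """

    table: pd.DataFrame
    records: list[BehavioralRecord]

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["excluded_reason"] == "none"].reset_index(drop=True)


def _linear_predictor(link: Mapping[str, float], frame: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(frame), link.get("const", 0.0))
    for key, coef in link.items():
        if key in ("const", "success_other") or coef == 0.0:
            continue
        lp += coef * frame[key].to_numpy()
    return lp


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a full synthetic cohort under ``config``; bit-reproducible.

    The root seed is split into independent substreams for trait draws,
    per-subject sessions, task order, outcome draws, and exclusion flags, so
    changing one stage's consumption never perturbs another.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    trait_ss, session_ss, order_ss, outcome_ss, excl_ss = root.spawn(5)
    n = config.n_enrolled

    trait_rng = np.random.default_rng(trait_ss)
    traits = {
        name: config.trait_distributions[name].sample(trait_rng, n)
        for name in TRAIT_NAMES
    }

    records: list[BehavioralRecord] = []
    perf = np.empty(n)
    for i, child in enumerate(session_ss.spawn(n)):
        params = ModelParameters(**{k: float(traits[k][i]) for k in TRAIT_NAMES})
        rec, _ = simulate_agent(
            params, config.schedule, child, subject_id=f"s{i+1:04d}", collect_traces=False
        )
        records.append(rec)
        perf[i] = tab_performance(rec)

    order_rng = np.random.default_rng(order_ss)
    coin_first = order_rng.random(n) < config.order_probability
    task_order = np.where(coin_first, "8coin_first", "9dot_first")

    frame = pd.DataFrame({"subject_id": [r.subject_id for r in records]})
    for name in TRAIT_NAMES:
        frame[name] = traits[name]
    frame["tab_performance"] = perf
    frame["task_order"] = task_order

    link_frame = frame
    if config.outcome_trait_source == "estimated":
        fits = fits_to_frame(fit_cohort(records, DEFAULT_PRIORS, config.fit_config))
        link_frame = frame[["subject_id", "tab_performance"]].merge(
            fits[["subject_id", *TRAIT_NAMES]], on="subject_id"
        )

    outcome_rng = np.random.default_rng(outcome_ss)
    u8 = outcome_rng.random(n)
    u9 = outcome_rng.random(n)
    lp8 = _linear_predictor(config.probit_8coin, link_frame)
    lp9 = _linear_predictor(config.probit_9dot, link_frame)
    t8 = config.probit_8coin.get("success_other", 0.0)
    t9 = config.probit_9dot.get("success_other", 0.0)

    if config.transfer_structure == "directional":
        s9 = (u9 < ndtr(lp9)).astype(float)
        s8 = (u8 < ndtr(lp8 + t8 * s9)).astype(float)
    else:  # by_order: the second-administered task carries the transfer term
        s8 = np.where(coin_first, u8 < ndtr(lp8), 0.0)
        s9 = np.where(~coin_first, u9 < ndtr(lp9), 0.0)
        s8 = np.where(coin_first, s8, u8 < ndtr(lp8 + t8 * s9)).astype(float)
        s9 = np.where(~coin_first, s9, u9 < ndtr(lp9 + t9 * s8)).astype(float)

    excl_rng = np.random.default_rng(excl_ss)
    n_excl = config.n_incomplete + config.n_prior_experience
    flagged = excl_rng.choice(n, size=n_excl, replace=False)
    reason = np.full(n, "none", dtype=object)
    reason[flagged[: config.n_incomplete]] = "incomplete"
    reason[flagged[config.n_incomplete :]] = "prior_experience"

    frame["excluded_reason"] = reason
    frame["success_8coin"] = np.where(reason == "none", s8, np.nan)
    frame["success_9dot"] = np.where(reason == "none", s9, np.nan)
    return CohortTable(frame, records)


def apply_exclusions(cohort: CohortTable) -> CohortTable:
    """Drop flagged rows (and their session records), preserving order."""
    mask = (cohort.table["excluded_reason"] == "none").to_numpy()
    if not mask.any():
        warnings.warn("all subjects excluded; returning an empty cohort")
    dropped = {
        reason: int(count)
        for reason, count in cohort.table.loc[~mask, "excluded_reason"]
        .value_counts()
        .items()
    }
    if dropped:
        logger.info("excluded subjects: %s", dropped)
    table = cohort.table[mask].reset_index(drop=True)
    records = [r for r, keep in zip(cohort.records, mask) if keep]
    return CohortTable(table, records)
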