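"""Synthetic cohort generation for community-dwelling adults aged 60+.

The generator reproduces the baseline table of the simulated population:
marginal age (normal truncated at 60, shifted so the post-truncation mean
matches the target), sex, SES quartile and one-year falls-history shares, and
binary activity/care states. Frailty is the one modelled dependence: each
individual's 0-100 score is drawn from a lognormal whose natural-scale mean
and SD come from the (age band x sex x SES quartile x falls history) subgroup
table — 280 subgroups when fully populated, with sex-specific and pooled
fallbacks so sampling never fails.

Seeding: one master seed; individual i draws from the substream seeded by
(master_seed, i), so growing the cohort never reshuffles earlier individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .constants import (
    DEFAULT_AGE_BAND_EDGES,
    EQ5D_CEILING,
    EQ5D_FLOOR,
    FALL_CATEGORIES,
    N_AGE_BANDS,
    SES_QUARTILES,
    SEXES,
)
from .errors import ConfigurationError
from .frailty import categorize, rescale_from_model_scale

__all__ = [
    "IndividualState",
    "FrailtyDistributionConfig",
    "BaselineConfig",
    "generate_cohort",
    "sample_frailty",
    "age_group_of",
    "lognormal_log_params",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_SCHEMA_VERSION = 1

BINARY_STATES = (
    "high_physical_activity",
    "cognitive_impairment",
    "fear_of_falling",
    "abnormal_gait_balance",
    "paid_employment",
    "unpaid_work",
    "oop_care",
    "informal_care",
    "social_care",
)

HISTORY_CATEGORIES = FALL_CATEGORIES  # "none" means no falls history


@dataclass
class IndividualState:
    """Full state vector of one simulated person."""

    id: int
    age: float
    sex: str
    ses_quartile: int
    falls_history: str
    frailty: float
    high_physical_activity: bool = False
    cognitive_impairment: bool = False
    fear_of_falling: bool = False
    abnormal_gait_balance: bool = False
    paid_employment: bool = False
    unpaid_work: bool = False
    oop_care: bool = False
    informal_care: bool = False
    social_care: bool = False
    eq5d: float = 0.8
    alive: bool = True
    residence: str = "community"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.ses_quartile not in SES_QUARTILES:
            raise ConfigurationError(f"SES quartile must be 1-4, got {self.ses_quartile}")
        if self.falls_history not in HISTORY_CATEGORIES:
            raise ConfigurationError(f"unknown falls history {self.falls_history!r}")
        if not 0.0 <= self.frailty <= 100.0:
            raise ConfigurationError(f"frailty outside [0,100]: {self.frailty}")

    @property
    def frailty_category(self) -> str:
        return categorize(rescale_from_model_scale(self.frailty))

    def copy(self) -> "IndividualState":
        return replace(self)


def age_group_of(age: float, edges: tuple[float, ...] = DEFAULT_AGE_BAND_EDGES) -> int:
    """Map an age (>= 60) to one of 7 contiguous bands (1-based); last band open."""
    if age < edges[0]:
        raise ValueError(f"age below model entry minimum {edges[0]}: {age}")
    if len(edges) != N_AGE_BANDS:
        raise ConfigurationError(f"expected {N_AGE_BANDS} band edges, got {len(edges)}")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigurationError(f"age band edges must be strictly increasing: {edges}")
    for band in range(N_AGE_BANDS - 1, -1, -1):
        if age >= edges[band]:
            return band + 1
    raise AssertionError("unreachable")


def lognormal_log_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a natural-scale mean and SD.

    sigma_log^2 = ln(1 + (sd/mean)^2);  mu_log = ln(mean) - sigma_log^2 / 2.
    """
    if mean <= 0 or sd < 0:
        raise ConfigurationError(f"lognormal requires mean>0, sd>=0; got {mean}, {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


SubgroupKey = tuple[int, str, int, str]  # (age band, sex, SES quartile, falls history)


@dataclass
class FrailtyDistributionConfig:
    """Per-subgroup lognormal (natural-scale mean, SD) on the 0-100 frailty scale.

    Lookup falls back from the exact subgroup entry to a per-sex entry to the
    pooled entry; the pooled entry is mandatory so sampling never fails.
    """

    pooled: tuple[float, float]
    by_sex: dict[str, tuple[float, float]] = field(default_factory=dict)
    entries: dict[SubgroupKey, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (mean, sd) in self._all_items():
            if mean <= 0 or sd <= 0:
                raise ConfigurationError(
                    f"frailty distribution entry {label} must have mean>0 and sd>0, "
                    f"got mean={mean}, sd={sd}"
                )

    def _all_items(self):
        yield "pooled", self.pooled
        for sex, ms in self.by_sex.items():
            yield f"by_sex[{sex}]", ms
        for key, ms in self.entries.items():
            yield str(key), ms

    def lookup(self, key: SubgroupKey) -> tuple[float, float]:
        band, sex, ses, history = key
        if not (1 <= band <= N_AGE_BANDS and sex in SEXES and ses in SES_QUARTILES
                and history in HISTORY_CATEGORIES):
            raise ConfigurationError(f"invalid subgroup key {key}")
        if key in self.entries:
            return self.entries[key]
        if sex in self.by_sex:
            return self.by_sex[sex]
        return self.pooled

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def is_fully_populated(self) -> bool:
        return self.n_entries == N_AGE_BANDS * len(SEXES) * len(SES_QUARTILES) * len(
            HISTORY_CATEGORIES
        )  # 7 * 2 * 4 * 5 = 280


def sample_frailty(
    dist: FrailtyDistributionConfig, key: SubgroupKey, rng: np.random.Generator
) -> float:
    """One lognormal draw, moment-matched to the subgroup's mean/SD, clamped to [0,100]."""
    mean, sd = dist.lookup(key)
    mu, sigma = lognormal_log_params(mean, sd)
    draw = float(rng.lognormal(mu, sigma))
    return min(max(draw, 0.0), 100.0)


def _check_simplex(name: str, probs: Iterable[float], expected_len: int) -> list[float]:
    probs = [float(p) for p in probs]
    if len(probs) != expected_len:
        raise ConfigurationError(f"{name}: expected {expected_len} probabilities")
    if any(p < 0 or p > 1 for p in probs):
        raise ConfigurationError(f"{name}: probabilities must lie in [0,1]")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {sum(probs)}, not 1")
    return probs


@dataclass
class BaselineConfig:
    """Everything needed to generate a baseline cohort."""

    sample_size: int
    proportion_female: float
    age_mean: float
    age_sd: float
    age_min: float
    ses_quartile_probabilities: list[float]
    falls_history_probabilities: dict[str, float]
    binary_state_prevalences: dict[str, object]  # float, or dict by frailty category
    frailty_distributions: FrailtyDistributionConfig
    seed: int
    eq5d_intercept: float = 0.95
    eq5d_frailty_slope: float = -0.009
    eq5d_age_slope: float = -0.002
    eq5d_age_anchor: float = 70.0
    _age_loc: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sample_size < 0:
            raise ConfigurationError("sample_size must be >= 0")
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ConfigurationError("proportion_female must lie in [0,1]")
        if self.age_sd <= 0:
            raise ConfigurationError("age SD must be positive")
        self.ses_quartile_probabilities = _check_simplex(
            "ses_quartile_probabilities", self.ses_quartile_probabilities, 4
        )
        hist = [self.falls_history_probabilities.get(c, 0.0) for c in HISTORY_CATEGORIES]
        _check_simplex("falls_history_probabilities", hist, 5)
        for state, prev in self.binary_state_prevalences.items():
            if state not in BINARY_STATES:
                raise ConfigurationError(f"unknown binary state {state!r}")
            values = prev.values() if isinstance(prev, Mapping) else [prev]
            if any(not 0.0 <= float(v) <= 1.0 for v in values):
                raise ConfigurationError(f"prevalence for {state!r} outside [0,1]")
        self._ses_cumulative = np.cumsum(self.ses_quartile_probabilities)[:-1]
        self._history_cumulative = np.cumsum(hist)[:-1]

    @property
    def age_location(self) -> float:
        """Pre-truncation normal location solved so the truncated mean hits age_mean."""
        if self._age_loc is None:
            sd, lo, target = self.age_sd, self.age_min, self.age_mean

            def gap(loc: float) -> float:
                a = (lo - loc) / sd
                return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target

            self._age_loc = float(optimize.brentq(gap, target - 4 * sd, target + sd))
        return self._age_loc

    def state_prevalence(self, state: str, frailty_category: str) -> float:
        prev = self.binary_state_prevalences.get(state, 0.0)
        if isinstance(prev, Mapping):
            return float(prev[frailty_category])
        return float(prev)

    def baseline_eq5d(self, frailty: float, age: float) -> float:
        """Deterministic placeholder utility rule: linear in frailty and age."""
        value = (
            self.eq5d_intercept
            + self.eq5d_frailty_slope * frailty
            + self.eq5d_age_slope * (age - self.eq5d_age_anchor)
        )
        return min(max(value, EQ5D_FLOOR), EQ5D_CEILING)

    # -- YAML loading -------------------------------------------------------

    @classmethod
    def from_yaml(cls, source) -> "BaselineConfig":
        is_pathlike = isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source
        )
        if is_pathlike and Path(source).exists():
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = yaml.safe_load(str(source))
        try:
            frailty_raw = raw["frailty"]
            pooled = (float(frailty_raw["pooled"]["mean"]), float(frailty_raw["pooled"]["sd"]))
            by_sex = {
                sex: (float(ms["mean"]), float(ms["sd"]))
                for sex, ms in frailty_raw.get("by_sex", {}).items()
            }
            entries = {}
            for ent in frailty_raw.get("entries", []):
                key = (
                    int(ent["age_band"]),
                    str(ent["sex"]),
                    int(ent["ses_quartile"]),
                    str(ent["falls_history"]),
                )
                entries[key] = (float(ent["mean"]), float(ent["sd"]))
            dist = FrailtyDistributionConfig(pooled=pooled, by_sex=by_sex, entries=entries)
            eq5d = raw.get("baseline_eq5d", {})
            return cls(
                sample_size=int(raw["sample_size"]),
                proportion_female=float(raw["proportion_female"]),
                age_mean=float(raw["age"]["mean"]),
                age_sd=float(raw["age"]["sd"]),
                age_min=float(raw["age"].get("min", 60.0)),
                ses_quartile_probabilities=raw["ses_quartile_probabilities"],
                falls_history_probabilities=raw["falls_history_probabilities"],
                binary_state_prevalences=raw["binary_state_prevalences"],
                frailty_distributions=dist,
                seed=int(raw["seed"]),
                **{f"eq5d_{k}": float(v) for k, v in eq5d.items()},
            )
        except KeyError as exc:
            raise ConfigurationError(f"baseline config missing key: {exc}") from None


def load_baseline_config(name: str = "baseline_pooled") -> BaselineConfig:
    """Load a shipped baseline config by stem name (e.g. 'baseline_pooled')."""
    text = resources.files("frailsim.data").joinpath(f"{name}.yaml").read_text()
    return BaselineConfig.from_yaml(text)


def _generate_individual(i: int, config: BaselineConfig) -> IndividualState:
    rng = np.random.default_rng([config.seed, i])
    # Draw order is fixed so substreams are stable: age, sex, SES, history,
    # frailty, then the binary states in registry order.
    age = config.age_location + config.age_sd * rng.standard_normal()
    while age < config.age_min:
        age = config.age_location + config.age_sd * rng.standard_normal()
    sex = "female" if rng.random() < config.proportion_female else "male"
    ses = 1 + int(np.searchsorted(config._ses_cumulative, rng.random(), side="right"))
    ses = min(ses, 4)
    h = int(np.searchsorted(config._history_cumulative, rng.random(), side="right"))
    history = HISTORY_CATEGORIES[min(h, 4)]
    key = (age_group_of(age), sex, ses, history)
    frailty = sample_frailty(config.frailty_distributions, key, rng)
    category = categorize(rescale_from_model_scale(frailty))
    flags = {
        state: bool(rng.random() < config.state_prevalence(state, category))
        for state in BINARY_STATES
    }
    return IndividualState(
        id=i,
        age=float(age),
        sex=sex,
        ses_quartile=ses,
        falls_history=history,
        frailty=frailty,
        eq5d=config.baseline_eq5d(frailty, age),
        **flags,
    )


def generate_cohort(config: BaselineConfig) -> list[IndividualState]:
    """Generate exactly ``config.sample_size`` individuals, deterministically."""
    return [_generate_individual(i, config) for i in range(config.sample_size)]


# ---------------------------------------------------------------------------
# CSV round-tripping

_FRAME_COLUMNS = (
    ["id", "age", "sex", "ses_quartile", "falls_history", "frailty"]
    + list(BINARY_STATES)
    + ["eq5d", "alive", "residence"]
)


def cohort_to_frame(cohort: list[IndividualState]) -> pd.DataFrame:
    rows = [{c: getattr(ind, c) for c in _FRAME_COLUMNS} for ind in cohort]
    frame = pd.DataFrame(rows, columns=_FRAME_COLUMNS)
    frame.insert(0, "schema_version", COHORT_SCHEMA_VERSION)
    return frame


def frame_to_cohort(frame: pd.DataFrame) -> list[IndividualState]:
    if "schema_version" in frame.columns:
        versions = set(frame["schema_version"].unique())
        if versions != {COHORT_SCHEMA_VERSION}:
            raise ConfigurationError(f"unsupported cohort schema version(s): {versions}")
    cohort = []
    for _, row in frame.iterrows():
        kwargs = {c: row[c] for c in _FRAME_COLUMNS}
        kwargs["id"] = int(kwargs["id"])
        kwargs["ses_quartile"] = int(kwargs["ses_quartile"])
        for state in BINARY_STATES + ("alive",):
            kwargs[state] = bool(kwargs[state])
        cohort.append(IndividualState(**kwargs))
    return cohort


def write_cohort_csv(cohort: list[IndividualState], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[IndividualState]:
    return frame_to_cohort(pd.read_csv(path))
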