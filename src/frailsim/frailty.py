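"""Cumulative-deficit frailty index: construction, rescaling, categorisation.

The index counts health deficits present out of 52 measured items (chronic
diseases, sensory/physical impairments, a cognitive composite, subjective
symptoms, lifestyle risks, ADL/IADL limitations, polypharmacy, living alone)
and expresses the ratio on a 0-1 scale. Falls are deliberately not an index
item, so a fall can only raise frailty through the modelled associations,
never by construction.

Scores are categorised Fit / Mild / Moderate / Severe at the 50th, 85th and
97th percentile cutoffs of the source cohort (0.10, 0.23, 0.37 by default),
with each cutoff value itself belonging to the lower category. For use inside
the simulation the 0-1 score is multiplied by 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_CUTOFFS, FRAILTY_CATEGORIES, N_FRAILTY_ITEMS
from .errors import ConfigurationError, MissingDataError

__all__ = [
    "DeficitProfile",
    "compute_index",
    "categorize",
    "category_index",
    "rescale_to_model_scale",
    "rescale_from_model_scale",
    "empirical_cutoffs",
    "load_item_dictionary",
    "read_profiles_csv",
]


def load_item_dictionary() -> dict[str, list[str]]:
    """Load the versioned 52-item dictionary, grouped by deficit domain.

    Validates the total item count and that no falls item is present.
    """
    text = resources.files("frailsim.data").joinpath("frailty_items.yaml").read_text()
    raw = yaml.safe_load(text)
    groups: dict[str, list[str]] = raw["groups"]
    items = [name for group in groups.values() for name in group]
    if len(items) != N_FRAILTY_ITEMS:
        raise ConfigurationError(
            f"item dictionary must contain {N_FRAILTY_ITEMS} items, found {len(items)}"
        )
    if len(set(items)) != len(items):
        raise ConfigurationError("item dictionary contains duplicate item names")
    offenders = [name for name in items if "fall" in name.lower()]
    if offenders:
        raise ConfigurationError(
            f"falls must not be an index item (found {offenders}); falls raise "
            "frailty only via the modelled association"
        )
    return groups


def _item_names() -> tuple[str, ...]:
    groups = load_item_dictionary()
    return tuple(name for group in groups.values() for name in group)


@dataclass
class DeficitProfile:
    """Presence/absence flags for the 52 deficits, with per-item missingness."""

    flags: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    items: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.missing is None:
            self.missing = np.zeros_like(self.flags)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.flags.shape != self.missing.shape:
            raise ConfigurationError("flags and missing mask must have equal length")
        if self.flags.size != N_FRAILTY_ITEMS:
            raise ConfigurationError(
                f"a deficit profile has exactly {N_FRAILTY_ITEMS} items, "
                f"got {self.flags.size}"
            )


def compute_index(profile: DeficitProfile, min_completeness: float = 0.8) -> float:
    """Score a profile as deficits present / deficits measured.

    Missing items are removed from the denominator; profiles with fewer than
    ``min_completeness`` of items observed cannot be scored.
    """
    observed = ~profile.missing
    n_observed = int(observed.sum())
    if n_observed < min_completeness * profile.flags.size:
        raise MissingDataError(
            f"only {n_observed}/{profile.flags.size} items observed; "
            f"minimum completeness is {min_completeness:.0%}"
        )
    present = int((profile.flags & observed).sum())
    return present / n_observed


def categorize(score: float, cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS) -> str:
    """Map a 0-1 score to Fit/Mild/Moderate/Severe.

    Each cutoff value belongs to the lower category (0.10 is Fit, 0.37 is
    Moderate), matching the published ranges.
    """
    lo, mid, hi = cutoffs
    if not (0 < lo < mid < hi < 1):
        raise ConfigurationError(f"cutoffs must be strictly increasing in (0,1): {cutoffs}")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"frailty score outside [0, 1]: {score}")
    if score <= lo:
        return "Fit"
    if score <= mid:
        return "Mild"
    if score <= hi:
        return "Moderate"
    return "Severe"


def category_index(category: str) -> int:
    """Ordinal position of a category (Fit=0 ... Severe=3)."""
    return FRAILTY_CATEGORIES.index(category)


def rescale_to_model_scale(score: float) -> float:
    """0-1 index -> 0-100 model scale."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"frailty score outside [0, 1]: {score}")
    return score * 100.0


def rescale_from_model_scale(score: float) -> float:
    """0-100 model scale -> 0-1 index."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"model-scale frailty outside [0, 100]: {score}")
    return score / 100.0


def empirical_cutoffs(
    scores, percentiles: tuple[float, float, float] = (50.0, 85.0, 97.0)
) -> tuple[float, float, float]:
    """Category cutoffs as percentiles of an observed score distribution.

    Uses linear interpolation between order statistics (numpy's default
    definition). Requires at least 100 scores so the 97th percentile is
    meaningfully resolved.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise ValueError(f"need at least 100 scores to place cutoffs, got {scores.size}")
    q = np.percentile(scores, percentiles, method="linear")
    return (float(q[0]), float(q[1]), float(q[2]))


def read_profiles_csv(path) -> list[DeficitProfile]:
    """Read deficit profiles from CSV: one row per person, one 0/1/blank column per item."""
    names = _item_names()
    frame = pd.read_csv(path)
    missing_cols = [c for c in names if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(f"profile CSV lacks item columns: {missing_cols[:5]}...")
    profiles = []
    for _, row in frame[list(names)].iterrows():
        vals = row.to_numpy(dtype=float)
        missing = np.isnan(vals)
        flags = np.where(missing, False, vals > 0.5)
        profiles.append(DeficitProfile(flags=flags, missing=missing, items=names))
    return profiles
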