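"""Regression-equation evaluation for the simulation.

Each equation is a named coefficient table (logistic or linear family, fitted
over a two-year observation window) whose terms reference covariates of a
simulated individual or within-cycle derived quantities (current frailty
change, this cycle's fall category). A logistic linear predictor lp converts
to an event probability exp(lp)/(1+exp(lp)); two-year probabilities are
annualised by a constant-hazard transform 1-(1-p)^(1/2) and two-year linear
changes are halved for the one-year cycle.

Coefficient standard errors support probabilistic sensitivity analysis:
independent normal perturbation by default, multivariate normal when a full
variance-covariance matrix is supplied.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    CovariateResolutionError,
    RegistryError,
)

__all__ = [
    "Term",
    "CoefficientTable",
    "EquationRegistry",
    "linear_predictor",
    "event_probability",
    "annualize_probability",
    "annualize_change",
    "sample_coefficients",
    "coefficient_checksum",
    "load_equation_file",
    "load_default_registry",
]

# Guard before exponentiation: exp(709) is the float64 ceiling.
_LP_CLIP = 700.0

_TRANSFORMS = ("identity", "square")
_FAMILIES = ("logistic", "linear")


@dataclass(frozen=True)
class Term:
    """One regression term: covariate id, optional transform or categorical level."""

    covariate: str
    coefficient: float
    se: float = 0.0
    transform: str = "identity"
    level: str | None = None

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.se < 0:
            raise ConfigurationError(f"negative SE for {self.covariate}")
        if self.level is not None and self.transform != "identity":
            raise ConfigurationError(
                f"categorical term {self.covariate}={self.level} cannot carry a transform"
            )


@dataclass(frozen=True)
class CoefficientTable:
    """A named regression equation with point estimates and standard errors.

    Categorical covariates follow reference-level coding: the reference level
    carries no term and contributes zero.
    """

    name: str
    family: str
    constant: float
    constant_se: float = 0.0
    terms: tuple[Term, ...] = ()
    horizon: str = "two_year"
    source: str = ""
    # Optional covariate centering offsets (value - offset is fed to the
    # terms). All shipped tables use raw covariate values as printed; the
    # hook exists because the original covariate coding is not stated.
    offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"{self.name}: unknown family {self.family!r}")
        if self.horizon not in ("two_year", "one_year"):
            raise ConfigurationError(f"{self.name}: unknown horizon {self.horizon!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t.covariate for t in self.terms))


def _term_value(
    term: Term, cov: Mapping[str, object], table_name: str, offset: float
) -> float:
    try:
        raw = cov[term.covariate]
    except KeyError:
        raise CovariateResolutionError(
            f"equation {table_name!r}: covariate {term.covariate!r} not found "
            f"in the supplied covariate vector"
        ) from None
    if term.level is not None:
        return 1.0 if raw == term.level else 0.0
    x = float(raw) - offset  # type: ignore[arg-type]
    if term.transform == "square":
        x = x * x
    return x


def linear_predictor(table: CoefficientTable, cov: Mapping[str, object]) -> float:
    """constant + sum of coefficient * transformed covariate value."""
    lp = table.constant
    offsets = table.offsets
    for term in table.terms:
        lp += term.coefficient * _term_value(
            term, cov, table.name, offsets.get(term.covariate, 0.0)
        )
    return lp


# Largest double strictly below 1; keeps the logistic inside the open interval.
_ONE_MINUS = float(np.nextafter(1.0, 0.0))


def event_probability(lp: float) -> float:
    """Logistic transform exp(lp)/(1+exp(lp)), overflow-safe, strictly in (0,1)."""
    if not math.isfinite(lp):
        raise ValueError(f"non-finite linear predictor: {lp}")
    lp = min(max(lp, -_LP_CLIP), _LP_CLIP)
    if lp >= 0:
        p = 1.0 / (1.0 + math.exp(-lp))
    else:
        e = math.exp(lp)
        p = e / (1.0 + e)
    return min(p, _ONE_MINUS)


def annualize_probability(p_two_year: float, exponent: float = 0.5) -> float:
    """Two-year event probability -> annual, assuming a constant hazard.

    1 - (1-p)^exponent with exponent = cycle length / observation window
    (default 1/2).
    """
    if not 0.0 <= p_two_year < 1.0:
        raise ValueError(f"two-year probability must lie in [0,1): {p_two_year}")
    return 1.0 - (1.0 - p_two_year) ** exponent


def annualize_change(delta_two_year: float) -> float:
    """Two-year predicted change in a continuous outcome -> annual (halved)."""
    return delta_two_year / 2.0


def sample_coefficients(
    table: CoefficientTable,
    rng: np.random.Generator,
    vcov: np.ndarray | None = None,
) -> CoefficientTable:
    """Perturb a table's coefficients for probabilistic sensitivity analysis.

    Default: independent normal draws, one per coefficient, scaled by its SE
    (zero-SE coefficients are left untouched). If ``vcov`` is supplied it must
    be the full (k+1)x(k+1) variance-covariance matrix ordered constant-first,
    and a single multivariate normal draw is used instead.
    """
    means = np.array([table.constant] + [t.coefficient for t in table.terms])
    if vcov is not None:
        vcov = np.asarray(vcov, dtype=float)
        if vcov.shape != (means.size, means.size):
            raise ConfigurationError(
                f"{table.name}: vcov shape {vcov.shape} does not match "
                f"{means.size} coefficients"
            )
        eigvals = np.linalg.eigvalsh((vcov + vcov.T) / 2.0)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ConfigurationError(f"{table.name}: vcov is not positive semidefinite")
        draw = rng.multivariate_normal(means, vcov, method="svd")
    else:
        ses = np.array([table.constant_se] + [t.se for t in table.terms])
        draw = means + ses * rng.standard_normal(means.size)
    new_terms = tuple(
        replace(t, coefficient=float(c)) for t, c in zip(table.terms, draw[1:])
    )
    return replace(table, constant=float(draw[0]), terms=new_terms)


# ---------------------------------------------------------------------------
# Serialisation and transcription guard


def _canonical_payload(table: CoefficientTable) -> str:
    return json.dumps(
        {
            "name": table.name,
            "family": table.family,
            "horizon": table.horizon,
            "constant": [table.constant, table.constant_se],
            "offsets": sorted(table.offsets.items()),
            "terms": [
                [t.covariate, t.level, t.transform, t.coefficient, t.se]
                for t in table.terms
            ],
        },
        separators=(",", ":"),
    )


def coefficient_checksum(table: CoefficientTable) -> str:
    """sha256 over a canonical serialisation of every cell; guards transcription drift."""
    return hashlib.sha256(_canonical_payload(table).encode()).hexdigest()


def table_from_dict(raw: dict) -> CoefficientTable:
    terms = tuple(
        Term(
            covariate=t["covariate"],
            coefficient=float(t["coef"]),
            se=float(t.get("se", 0.0)),
            transform=t.get("transform", "identity"),
            level=t.get("level"),
        )
        for t in raw.get("terms", [])
    )
    const = raw["constant"]
    return CoefficientTable(
        name=raw["name"],
        family=raw["family"],
        constant=float(const["coef"]),
        constant_se=float(const.get("se", 0.0)),
        terms=terms,
        horizon=raw.get("horizon", "two_year"),
        source=raw.get("source", ""),
        offsets={k: float(v) for k, v in raw.get("centering_offsets", {}).items()},
    )


def load_equation_file(path_or_text) -> tuple[CoefficientTable, str | None]:
    """Parse one equation YAML; returns (table, embedded checksum or None)."""
    is_pathlike = isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str) and "\n" not in path_or_text
    )
    if is_pathlike and Path(path_or_text).exists():
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "name" not in raw:
        raise ConfigurationError("equation file must be a mapping with a 'name' key")
    return table_from_dict(raw), raw.get("checksum")


class EquationRegistry:
    """Dispatch table of named equations."""

    def __init__(self, tables: Mapping[str, CoefficientTable] | None = None) -> None:
        self._tables: dict[str, CoefficientTable] = dict(tables or {})

    def register(self, table: CoefficientTable) -> None:
        self._tables[table.name] = table

    def __contains__(self, name: str) -> bool:
        return name in self._tables

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self._tables))

    def get(self, name: str) -> CoefficientTable:
        try:
            return self._tables[name]
        except KeyError:
            raise RegistryError(
                f"equation {name!r} is not registered; available: {self.names()}"
            ) from None

    def evaluate(
        self,
        name: str,
        cov: Mapping[str, object],
        annualize: bool = True,
        annualization_exponent: float = 0.5,
    ) -> float:
        """Compose linear predictor, logistic transform and horizon conversion.

        Logistic family returns a probability (annualised when the equation is
        two-year and ``annualize`` is set); linear family returns the predicted
        change (halved under the same condition).
        """
        table = self.get(name)
        lp = linear_predictor(table, cov)
        if table.family == "logistic":
            p = event_probability(lp)
            if annualize and table.horizon == "two_year":
                p = annualize_probability(p, annualization_exponent)
            return p
        value = lp
        if annualize and table.horizon == "two_year":
            value = annualize_change(value)
        return value

    def perturbed(self, rng: np.random.Generator) -> "EquationRegistry":
        """A PSA copy with every table's coefficients independently perturbed."""
        return EquationRegistry(
            {name: sample_coefficients(t, rng) for name, t in self._tables.items()}
        )


# Shipped equation files. Tables transcribed from the source publication carry
# a "published" source tag; placeholder equations for quantities sourced from
# unavailable supplementary material are synthetic and say so in their files.
_EQUATION_FILES = (
    "falls_incidence.yaml",
    "frailty_change.yaml",
    "eq5d_change.yaml",
    "unpaid_work.yaml",
    "oop_care.yaml",
    "gp_access_synthetic.yaml",
    "exercise_demand_synthetic.yaml",
    "informal_care_synthetic.yaml",
    "paid_employment_synthetic.yaml",
)


def load_default_registry(verify: bool = True) -> EquationRegistry:
    """Load every shipped equation file, verifying embedded checksums."""
    registry = EquationRegistry()
    base = resources.files("frailsim.data").joinpath("equations")
    for fname in _EQUATION_FILES:
        table, checksum = load_equation_file(base.joinpath(fname).read_text())
        if verify:
            actual = coefficient_checksum(table)
            if checksum != actual:
                raise ConfigurationError(
                    f"{fname}: embedded checksum {checksum} does not match "
                    f"computed {actual}; coefficients may have drifted"
                )
        registry.register(table)
    return registry
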