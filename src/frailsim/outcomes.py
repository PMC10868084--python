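"""Aggregation of cycle ledgers into discounted QALYs, costs, incremental
cost-effectiveness statistics, and subgroup/equity tables.

Accounting identity (checked to 1e-9 in the test suite): total societal cost
equals public cost + out-of-pocket cost + informal-care cost (proxy-goods
valuation) + intervention time cost minus productivity offsets (human-capital
value of paid work, opportunity-cost value of unpaid work).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import LEDGER_COLUMNS, SimulationResult
from .errors import ConfigurationError

__all__ = [
    "discount",
    "discounted_totals",
    "societal_cost",
    "ComparisonSummary",
    "compare",
    "ceac",
    "subgroup_table",
    "equity_summary",
]

COST_COMPONENTS = ("public_cost", "oop_cost", "informal_care_cost",
                   "intervention_time_cost")


def discount(amount: float, cycle_index: int, rate: float) -> float:
    """Present value at the configured annual rate; cycle 0 is undiscounted."""
    if rate < 0:
        raise ConfigurationError(f"discount rate must be non-negative, got {rate}")
    return amount / (1.0 + rate) ** cycle_index


def _discount_frame(cycles: pd.DataFrame, rate: float) -> pd.DataFrame:
    factors = (1.0 + rate) ** (-cycles["cycle"].to_numpy(dtype=float))
    out = cycles.copy()
    for col in LEDGER_COLUMNS:
        out[col] = out[col] * factors
    return out


def societal_cost(frame: pd.DataFrame) -> pd.Series:
    """Net societal cost per row/individual: costs minus productivity offsets."""
    return sum(frame[c] for c in COST_COMPONENTS) - frame["productivity_value"]


def discounted_totals(result: SimulationResult, rate: float) -> pd.DataFrame:
    """Per-individual discounted horizon totals, with entry characteristics.

    Characteristics (sex, SES quartile, frailty category) are taken from the
    first simulated cycle of each individual.
    """
    disc = _discount_frame(result.cycles, rate)
    totals = disc.groupby("id")[list(LEDGER_COLUMNS)].sum()
    first = result.cycles.sort_values("cycle").groupby("id").first()
    totals["sex"] = first["sex"]
    totals["ses_quartile"] = first["ses_quartile"]
    totals["entry_frailty_category"] = first["frailty_category"]
    totals["societal_cost"] = societal_cost(totals)
    return totals


@dataclass
class ComparisonSummary:
    """Paired incremental summary of two strategies run under common random numbers."""

    label_a: str
    label_b: str
    mean_qaly: dict[str, float]
    mean_cost: dict[str, float]
    delta_qaly: float
    delta_cost: float
    icer: float | None
    nmb: float
    threshold: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        icer = "undefined (dQALY = 0)" if self.icer is None else f"{self.icer:,.0f}"
        return (
            f"{self.label_a} vs {self.label_b}: "
            f"dQALY={self.delta_qaly:.4f}, dCost={self.delta_cost:,.2f}, "
            f"ICER={icer}, NMB@{self.threshold:,.0f}={self.nmb:,.2f}"
        )


def compare(
    result_a: SimulationResult,
    result_b: SimulationResult,
    rate: float,
    threshold: float,
    cost_column: str = "societal_cost",
) -> ComparisonSummary:
    """Incremental statistics of strategy a relative to strategy b."""
    ta = discounted_totals(result_a, rate)
    tb = discounted_totals(result_b, rate)
    if not ta.index.equals(tb.index):
        raise ConfigurationError("comparison requires runs over the same cohort ids")
    dq = float(ta["qaly"].mean() - tb["qaly"].mean())
    dc = float(ta[cost_column].mean() - tb[cost_column].mean())
    icer = None if dq == 0 else dc / dq
    return ComparisonSummary(
        label_a=result_a.scenario_label,
        label_b=result_b.scenario_label,
        mean_qaly={result_a.scenario_label: float(ta["qaly"].mean()),
                   result_b.scenario_label: float(tb["qaly"].mean())},
        mean_cost={result_a.scenario_label: float(ta[cost_column].mean()),
                   result_b.scenario_label: float(tb[cost_column].mean())},
        delta_qaly=dq,
        delta_cost=dc,
        icer=icer,
        nmb=threshold * dq - dc,
        threshold=threshold,
    )


def ceac(psa_results: pd.DataFrame, thresholds) -> pd.Series:
    """Cost-effectiveness acceptability curve.

    ``psa_results`` holds one probabilistic-sensitivity-analysis draw per row
    with columns ``delta_qaly`` and ``delta_cost``; the curve is the fraction
    of draws with positive incremental net monetary benefit at each threshold.
    """
    if len(psa_results) < 2:
        raise ConfigurationError("CEAC needs at least 2 PSA draws")
    dq = psa_results["delta_qaly"].to_numpy(dtype=float)
    dc = psa_results["delta_cost"].to_numpy(dtype=float)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    probs = [(thr * dq - dc > 0).mean() for thr in thresholds]
    return pd.Series(probs, index=thresholds, name="probability_cost_effective")


def subgroup_table(
    totals: pd.DataFrame,
    by: str,
    outcome_columns: tuple[str, ...] = ("qaly", "public_cost", "societal_cost"),
) -> pd.DataFrame:
    """Per-group mean and standard error of the requested outcomes.

    ``totals`` is the output of :func:`discounted_totals` (or any frame with a
    grouping column). Groups of size one report an undefined (NaN) SE; empty
    groups are simply absent.
    """
    if by not in totals.columns:
        raise ConfigurationError(f"grouping column {by!r} not present")
    grouped = totals.groupby(by, observed=True)
    out = {}
    for col in outcome_columns:
        out[(col, "mean")] = grouped[col].mean()
        out[(col, "se")] = grouped[col].std(ddof=1) / np.sqrt(grouped[col].count())
    out[("n", "")] = grouped.size()
    return pd.DataFrame(out)


def equity_summary(
    totals_a: pd.DataFrame,
    totals_b: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Per-SES-quartile incremental net health benefit of strategy a vs b.

    INHB_q = mean(dQALY_q) - mean(dCost_q)/threshold, in QALY units; positive
    favours strategy a. The table carries a population-weighted overall row
    and the most-deprived (q4) minus most-privileged (q1) gap. Requires paired
    runs (identical individual ids, common random numbers).
    """
    if not totals_a.index.equals(totals_b.index):
        raise ConfigurationError("equity summary requires paired runs over the same ids")
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    dq = totals_a["qaly"] - totals_b["qaly"]
    dc = totals_a["societal_cost"] - totals_b["societal_cost"]
    ses = totals_a["ses_quartile"]
    rows = {}
    for q in (1, 2, 3, 4):
        mask = ses == q
        n = int(mask.sum())
        if n == 0:
            continue
        rows[f"q{q}"] = {
            "n": n,
            "delta_qaly": float(dq[mask].mean()),
            "delta_cost": float(dc[mask].mean()),
            "inhb": float(dq[mask].mean() - dc[mask].mean() / threshold),
        }
    overall = {
        "n": int(len(dq)),
        "delta_qaly": float(dq.mean()),
        "delta_cost": float(dc.mean()),
        "inhb": float(dq.mean() - dc.mean() / threshold),
    }
    rows["overall"] = overall
    table = pd.DataFrame(rows).T
    if "q4" in table.index and "q1" in table.index:
        table.loc["q4_minus_q1"] = table.loc["q4"] - table.loc["q1"]
        table.loc["q4_minus_q1", "n"] = np.nan
    return table
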