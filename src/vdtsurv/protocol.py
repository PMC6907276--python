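"""Influence-diagram cost-utility evaluation of surveillance protocol strategies.

A medical protocol is a set of diagnostic tests; each test carries a time
cost (minutes of specialist time per employee) and a monetary cost (USD per
employee, specialist salary folded in).  The protocol decision is modelled as
an influence diagram: a decision node over strategies, one probabilistic node
per test (whether the test is performed), a time- and a money-utility node
per test, and two additive linear aggregate utility nodes.  Because the
aggregates are additive and each test contributes ``perform_probability *
cost``, expected utilities are plain probability-weighted sums.

Total utility adds minutes and dollars on a common scale: the published
totals equal money (USD) + minutes numerically, i.e. an implicit valuation of
1 USD per minute.  ``minute_value`` exposes that valuation instead of
hard-coding it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class DiagnosticTest:
    """One protocol test with its specialist and per-employee costs."""

    name: str
    specialist: str  # "doctor" | "nurse"
    time_cost: float  # minutes per employee
    money_cost: float  # USD per employee
    perform_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.specialist not in ("doctor", "nurse"):
            raise ValueError(f"specialist must be doctor or nurse, got {self.specialist!r}")
        if self.time_cost < 0 or self.money_cost < 0:
            raise ValueError(f"costs must be non-negative for test {self.name!r}")
        if not 0.0 <= self.perform_probability <= 1.0:
            raise ValueError(
                f"perform_probability {self.perform_probability} outside [0, 1]"
            )


@dataclass(frozen=True)
class ProtocolStrategy:
    """A named subset of diagnostic tests."""

    id: str
    included_tests: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "included_tests", frozenset(self.included_tests))


@dataclass(frozen=True)
class UtilityReport:
    """Time, money and total utility of one strategy, plus reductions vs a reference."""

    strategy_id: str
    time_utility: float  # minutes
    money_utility: float  # USD
    total_utility: float  # USD (money + minute_value * time)
    reduction_total: float | None = None  # percent vs reference
    reduction_time: float | None = None  # percent vs reference


@dataclass
class InfluenceDiagram:
    """Decision (strategies) + probabilistic test nodes + additive utilities."""

    decision: list[ProtocolStrategy]
    test_nodes: list[DiagnosticTest]
    minute_value: float = 1.0

    def tests_by_name(self) -> dict[str, DiagnosticTest]:
        return {t.name: t for t in self.test_nodes}


def canonical_tests() -> list[DiagnosticTest]:
    """The ten published diagnostic tests with their specialists and costs."""
    rows = json.loads((_DATA / "protocol_tests.json").read_text())
    return [DiagnosticTest(**row) for row in rows]


def canonical_strategies() -> list[ProtocolStrategy]:
    """The six published strategies: extensive A, flexible B–E, optimized F."""
    payload = json.loads((_DATA / "protocol_strategies.json").read_text())
    return [
        ProtocolStrategy(id=sid, included_tests=frozenset(names))
        for sid, names in payload["strategies"].items()
    ]


def printed_total_utilities() -> dict[str, float]:
    """Published total-utility row, as printed (strategy B's cell is internally
    inconsistent with its own time and money cells; see :func:`table2_replica`)."""
    payload = json.loads((_DATA / "protocol_strategies.json").read_text())
    return {k: float(v) for k, v in payload["printed_total_utility"].items()}


def _resolve(strategy: ProtocolStrategy, tests: Sequence[DiagnosticTest]) -> list[DiagnosticTest]:
    by_name = {t.name: t for t in tests}
    unknown = strategy.included_tests - set(by_name)
    if unknown:
        raise KeyError(f"strategy {strategy.id!r} references unknown tests: {sorted(unknown)}")
    return [by_name[name] for name in sorted(strategy.included_tests)]


def evaluate_strategy(
    strategy: ProtocolStrategy,
    tests: Sequence[DiagnosticTest],
    minute_value: float = 1.0,
) -> UtilityReport:
    """Deterministic utilities: sums of the included tests' costs."""
    included = _resolve(strategy, tests)
    time = sum(t.time_cost for t in included)
    money = sum(t.money_cost for t in included)
    return UtilityReport(
        strategy_id=strategy.id,
        time_utility=time,
        money_utility=money,
        total_utility=money + minute_value * time,
    )


def expected_utility(diagram: InfluenceDiagram, strategy: ProtocolStrategy) -> UtilityReport:
    """Expected utilities under per-test perform probabilities.

    Each included test contributes ``perform_probability * cost`` to each
    axis; with all probabilities 1 this equals :func:`evaluate_strategy`.
    """
    included = _resolve(strategy, diagram.test_nodes)
    time = sum(t.perform_probability * t.time_cost for t in included)
    money = sum(t.perform_probability * t.money_cost for t in included)
    return UtilityReport(
        strategy_id=strategy.id,
        time_utility=time,
        money_utility=money,
        total_utility=money + diagram.minute_value * time,
    )


def reduction_report(
    strategies: Sequence[ProtocolStrategy],
    reference_id: str,
    tests: Sequence[DiagnosticTest],
    minute_value: float = 1.0,
) -> list[UtilityReport]:
    """Utilities plus percent reductions of each strategy versus a reference.

    ``reduction_total`` is on the total-utility axis, ``reduction_time`` on
    the time axis; both are reported because the published reduction row
    mixes the two (time-axis figures for the flexible strategies, total-axis
    for the optimized one).  Raw percentages are returned; round for display.
    """
    by_id = {s.id: s for s in strategies}
    if reference_id not in by_id:
        raise KeyError(f"reference strategy {reference_id!r} not among strategies")
    ref = evaluate_strategy(by_id[reference_id], tests, minute_value)
    if ref.total_utility == 0 or ref.time_utility == 0:
        raise ValueError("reference strategy has zero utility; reductions undefined")
    reports = []
    for s in strategies:
        r = evaluate_strategy(s, tests, minute_value)
        reports.append(
            UtilityReport(
                strategy_id=s.id,
                time_utility=r.time_utility,
                money_utility=r.money_utility,
                total_utility=r.total_utility,
                reduction_total=100.0 * (ref.total_utility - r.total_utility) / ref.total_utility,
                reduction_time=100.0 * (ref.time_utility - r.time_utility) / ref.time_utility,
            )
        )
    return reports


def table2_replica(
    tests: Sequence[DiagnosticTest] | None = None,
    strategies: Sequence[ProtocolStrategy] | None = None,
    minute_value: float = 1.0,
    reference_id: str = "A",
) -> pd.DataFrame:
    """Replica of the published strategy/cost table.

    Rows: one checkmark row per test, the three utility rows, both reduction
    rows, and a consistency flag comparing each computed total with the
    printed one (strategy B's printed total does not equal its own printed
    money + time cells; the flag row marks it).
    """
    tests = list(tests) if tests is not None else canonical_tests()
    strategies = list(strategies) if strategies is not None else canonical_strategies()
    printed = printed_total_utilities()
    reports = {
        r.strategy_id: r
        for r in reduction_report(strategies, reference_id, tests, minute_value)
    }
    cols = [s.id for s in strategies]
    rows: dict[str, list] = {}
    for t in tests:
        rows[t.name] = [
            "x" if t.name in s.included_tests else "" for s in strategies
        ]
    rows["time utility (min)"] = [reports[c].time_utility for c in cols]
    rows["money utility (USD)"] = [round(reports[c].money_utility, 4) for c in cols]
    rows["total utility (USD)"] = [round(reports[c].total_utility, 4) for c in cols]
    rows["total cost reduction (%)"] = [round(reports[c].reduction_total) for c in cols]
    rows["time cost reduction (%)"] = [round(reports[c].reduction_time) for c in cols]
    rows["printed total consistent"] = [
        "yes"
        if c not in printed or abs(printed[c] - reports[c].total_utility) < 5e-5
        else f"no (printed {printed[c]})"
        for c in cols
    ]
    return pd.DataFrame(rows, index=cols).T
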