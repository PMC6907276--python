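"""Seeded synthetic exam-record cohorts for administrative VDT employees.

The study population is described only through its disorder-class shares and
the class-conditional marginal frequency of each dichotomized clinical
attribute.  The generator therefore draws a disorder class per employee from
the class prior and then each attribute independently from its
class-conditional Bernoulli parameter — the maximum-entropy completion of the
published marginals, and exactly the conditional family a naive / augmented
naive Bayes classifier targets.

States per attribute are a fixed ordered pair; for each attribute one state
is the *tracked* state — the state whose frequency the source tabulation
reports (man, age >= 39 years, overweight BMI, variable sleep, physically
active, smoker, alcohol user).  All conditional parameters and all tabulated
profiles refer to the tracked state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Clinical attributes in canonical column order.
ATTRIBUTES: tuple[str, ...] = (
    "sex",
    "age_ge39",
    "bmi",
    "sleep",
    "activity",
    "smoker",
    "alcohol",
)

#: Ordered state pair per attribute (order is fixed; used for tie-breaking).
ATTRIBUTE_STATES: dict[str, tuple[str, str]] = {
    "sex": ("man", "woman"),
    "age_ge39": ("yes", "no"),
    "bmi": ("normal", "overweight"),
    "sleep": ("good", "variable"),
    "activity": ("yes", "no"),
    "smoker": ("yes", "no"),
    "alcohol": ("yes", "no"),
}

#: The state whose class-conditional frequency parameterizes the generator.
TRACKED_STATE: dict[str, str] = {
    "sex": "man",
    "age_ge39": "yes",
    "bmi": "overweight",
    "sleep": "variable",
    "activity": "yes",
    "smoker": "yes",
    "alcohol": "yes",
}

#: Disorder classes, in canonical (tie-breaking) order.
CLASS_LABELS: tuple[str, ...] = (
    "none",
    "musculoskeletal",
    "ophthalmological",
    "nervous",
    "cardiovascular",
    "other",
)

DISORDER_VARIABLE = "disorder"

_PAPER_SPEC_PATH = Path(__file__).parent / "data" / "paper_spec.json"


@dataclass(frozen=True)
class ExamRecord:
    """One employee's categorical health-surveillance exam outcome."""

    sex: str
    age_ge39: str
    bmi: str
    sleep: str
    activity: str
    smoker: str
    alcohol: str
    disorder: str

    def __post_init__(self) -> None:
        for attr in ATTRIBUTES:
            value = getattr(self, attr)
            if value not in ATTRIBUTE_STATES[attr]:
                raise ValueError(
                    f"invalid state {value!r} for attribute {attr!r}; "
                    f"expected one of {ATTRIBUTE_STATES[attr]}"
                )
        if self.disorder not in CLASS_LABELS:
            raise ValueError(
                f"invalid disorder class {self.disorder!r}; expected one of {CLASS_LABELS}"
            )


@dataclass
class PopulationSpec:
    """Generative parameters for a synthetic surveillance cohort.

    Parameters
    ----------
    n_records
        Default cohort size; the study analysed 2453 examinations.
    class_prior
        Probability of each disorder class; must cover :data:`CLASS_LABELS`
        exactly and sum to one.
    conditionals
        ``(class, attribute) -> P(attribute = tracked state | class)``.
    attribute_states
        Ordered state pair per attribute (defaults to the canonical pairs).
    """

    n_records: int = 2453
    class_prior: dict[str, float] = field(default_factory=dict)
    conditionals: dict[tuple[str, str], float] = field(default_factory=dict)
    attribute_states: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(ATTRIBUTE_STATES)
    )

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field, if any."""
        if self.n_records < 1:
            raise ValueError(f"n_records must be positive, got {self.n_records}")
        if set(self.class_prior) != set(CLASS_LABELS):
            raise ValueError(
                f"class_prior labels {sorted(self.class_prior)} != expected {sorted(CLASS_LABELS)}"
            )
        for label, p in self.class_prior.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class_prior[{label!r}] = {p} outside [0, 1]")
        total = sum(self.class_prior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_prior sums to {total!r}, not 1")
        for label in CLASS_LABELS:
            for attr in ATTRIBUTES:
                key = (label, attr)
                if key not in self.conditionals:
                    raise ValueError(f"conditionals missing entry for {key}")
                p = self.conditionals[key]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"conditionals[{key}] = {p} outside [0, 1]")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "n_records": self.n_records,
            "class_prior": self.class_prior,
            "conditionals": {
                label: {attr: self.conditionals[(label, attr)] for attr in ATTRIBUTES}
                for label in CLASS_LABELS
            },
            "attribute_states": {k: list(v) for k, v in self.attribute_states.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        payload = json.loads(text)
        spec = cls(
            n_records=payload["n_records"],
            class_prior={k: float(v) for k, v in payload["class_prior"].items()},
            conditionals={
                (label, attr): float(p)
                for label, row in payload["conditionals"].items()
                for attr, p in row.items()
            },
            attribute_states={
                k: tuple(v) for k, v in payload["attribute_states"].items()
            },
        )
        spec.validate()
        return spec


def default_paper_spec() -> PopulationSpec:
    """The population spec calibrated to the published study frequencies.

    1942 of 2453 employees had no disorder; within the disordered fraction the
    class shares are 29.08% musculoskeletal, 14.66% ophthalmological, 10.92%
    nervous and 9.97% cardiovascular, with the remainder pooled as "other".
    Class-conditional attribute frequencies are the published tracked-state
    percentages; the "other" pool, for which no breakdown is published,
    inherits the no-disorder column.
    """
    spec = PopulationSpec.from_json(_PAPER_SPEC_PATH.read_text())
    return spec


def generate_cohort(
    spec: PopulationSpec,
    n: int | None = None,
    seed: int = 0,
    coupling: tuple[str, str] | None = None,
) -> list[ExamRecord]:
    """Sample ``n`` independent exam records from ``spec``.

    Each record draws its disorder class from the class prior, then each
    attribute independently from its class-conditional Bernoulli parameter.
    The same ``(spec, n, seed)`` reproduces identical output.

    ``coupling=(a, b)`` is a hook for structure-learning tests: attribute
    ``b`` is overwritten with a deterministic copy of attribute ``a``'s
    tracked/non-tracked status, planting one feature-feature dependency in an
    otherwise class-conditionally independent cohort.
    """
    spec.validate()
    if n is None:
        n = spec.n_records
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if coupling is not None:
        for attr in coupling:
            if attr not in ATTRIBUTES:
                raise ValueError(f"unknown attribute {attr!r} in coupling")

    rng = np.random.default_rng(seed)
    prior = np.array([spec.class_prior[c] for c in CLASS_LABELS])
    class_idx = rng.choice(len(CLASS_LABELS), size=n, p=prior)

    # tracked-state indicator matrix, one column per attribute
    cond = np.array(
        [[spec.conditionals[(c, a)] for a in ATTRIBUTES] for c in CLASS_LABELS]
    )
    u = rng.random((n, len(ATTRIBUTES)))
    tracked = u < cond[class_idx]

    if coupling is not None:
        src, dst = coupling
        tracked[:, ATTRIBUTES.index(dst)] = tracked[:, ATTRIBUTES.index(src)]

    records: list[ExamRecord] = []
    for i in range(n):
        values = {}
        for j, attr in enumerate(ATTRIBUTES):
            states = spec.attribute_states[attr]
            tr = TRACKED_STATE[attr]
            other = states[1] if states[0] == tr else states[0]
            values[attr] = tr if tracked[i, j] else other
        records.append(ExamRecord(disorder=CLASS_LABELS[class_idx[i]], **values))
    return records


def tabulate_profile(
    records: Sequence[ExamRecord], class_label: str
) -> dict[str, float]:
    """Empirical tracked-state proportion of every attribute within a class.

    Raises ``ValueError`` if no record of ``class_label`` is present (an
    explicit empty-class error rather than a silent NaN).
    """
    subset = [r for r in records if r.disorder == class_label]
    if not subset:
        raise ValueError(f"no records with disorder class {class_label!r}")
    n = len(subset)
    return {
        attr: sum(getattr(r, attr) == TRACKED_STATE[attr] for r in subset) / n
        for attr in ATTRIBUTES
    }


def records_to_dataframe(records: Iterable[ExamRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with canonical column order."""
    columns = list(ATTRIBUTES) + [DISORDER_VARIABLE]
    data = {col: [getattr(r, col) for r in records] for col in columns}
    return pd.DataFrame(data, columns=columns)


def dataframe_to_records(frame: pd.DataFrame) -> list[ExamRecord]:
    """Inverse of :func:`records_to_dataframe`; validates every state token."""
    expected = list(ATTRIBUTES) + [DISORDER_VARIABLE]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                ExamRecord(**{col: getattr(row, col) for col in expected})
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 1}: {exc}") from exc
    return records
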