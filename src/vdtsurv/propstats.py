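"""Proportion-based significance screening of clinical risk factors.

For each clinical attribute, the tracked-state proportion in a disorder
class is compared against the no-disorder reference group with a pooled
two-sample z-test (two-sided, no continuity correction):

    z = (p1 - p2) / sqrt(p(1 - p)(1/n1 + 1/n2)),   p = (k1 + k2)/(n1 + n2)

No multiple-testing correction is applied by default; a Bonferroni option is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from vdtsurv.cohort import ATTRIBUTES, TRACKED_STATE, ExamRecord


@dataclass(frozen=True)
class ProportionTestResult:
    variable: str
    class_label: str
    statistic: float
    p_value: float
    significant: bool


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value.

    Degenerate case: when the pooled proportion is 0 or 1 both groups are
    necessarily identical, so the result is (0, 1).  A zero-variance case
    with unequal proportions cannot arise under pooling but is guarded with
    a signed infinite statistic.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError(f"group size must be >= 1, got {n}")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        if p1 == p2:
            return 0.0, 1.0
        return math.copysign(math.inf, p1 - p2), 0.0
    z = (p1 - p2) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def screen_risk_factors(
    records: Sequence[ExamRecord],
    class_label: str,
    reference_label: str = "none",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ProportionTestResult]:
    """Test every attribute's tracked-state proportion: class vs reference.

    Raises ``ValueError`` when either group is empty.  With ``bonferroni``
    the significance threshold is alpha divided by the number of attributes
    (p-values themselves are reported unadjusted).
    """
    cases = [r for r in records if r.disorder == class_label]
    controls = [r for r in records if r.disorder == reference_label]
    if not cases:
        raise ValueError(f"no records with disorder class {class_label!r}")
    if not controls:
        raise ValueError(f"no records with disorder class {reference_label!r}")
    threshold = alpha / len(ATTRIBUTES) if bonferroni else alpha
    results = []
    for attr in ATTRIBUTES:
        k1 = sum(getattr(r, attr) == TRACKED_STATE[attr] for r in cases)
        k2 = sum(getattr(r, attr) == TRACKED_STATE[attr] for r in controls)
        z, p = two_proportion_test(k1, len(cases), k2, len(controls))
        results.append(
            ProportionTestResult(
                variable=attr,
                class_label=class_label,
                statistic=z,
                p_value=p,
                significant=p <= threshold,
            )
        )
    return results


def results_to_dataframe(results: Sequence[ProportionTestResult]) -> pd.DataFrame:
    """CSV-ready table: class,variable,statistic,p_value,significant."""
    return pd.DataFrame(
        {
            "class": [r.class_label for r in results],
            "variable": [r.variable for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
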