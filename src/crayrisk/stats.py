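"""Descriptive and inferential statistics over concentration records.

Group summaries follow standard food-surveillance reporting: n, mean, SD
(n−1 denominator), median, range, and detection frequency (percent of
records above the limit of detection).  Records flagged below the LOD enter
the statistics at LOD/2, the conventional substitution for censored exposure
data.

Two-sample comparisons offer both the classical pooled-variance Student test
and the Welch test (Satterthwaite degrees of freedom); Welch is the default
because the compared groups have unequal sizes and visibly unequal variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConcentrationRecord, records_to_dataframe

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "two_sample_t",
    "pearson_correlation",
    "skewness_direction",
    "summaries_to_dataframe",
]

STRATA_KEYS = ("source", "region", "tissue")


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one stratum of records (μg/kg)."""

    labels: dict[str, str]
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    detection_frequency: float  # percent in [0, 100]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    group_ns: tuple[int, int]
    significant: bool  # at alpha = 0.05


def summarize(
    records: Sequence[ConcentrationRecord],
    by: Sequence[str] = ("source", "region"),
) -> list[GroupSummary]:
    """One summary per non-empty stratum of ``by`` keys, in stratum order.

    Empty input yields an empty list.  SD uses the n−1 denominator (0 for
    n = 1); detection frequency is 100 × (records above LOD) / n.
    """
    for key in by:
        if key not in STRATA_KEYS:
            raise KeyError(f"unknown stratification key {key!r}")
    if not records:
        return []
    df = records_to_dataframe(records)
    summaries: list[GroupSummary] = []
    for labels, group in df.groupby(list(by), sort=True, observed=True):
        if not isinstance(labels, tuple):
            labels = (labels,)
        values = group["effective_ug_kg"].to_numpy(dtype=float)
        n = values.size
        summaries.append(
            GroupSummary(
                labels=dict(zip(by, (str(label) for label in labels))),
                n=int(n),
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)) if n > 1 else 0.0,
                median=float(np.median(values)),
                min=float(np.min(values)),
                max=float(np.max(values)),
                detection_frequency=float(100.0 * (~group["below_lod"]).mean()),
            )
        )
    return summaries


def summaries_to_dataframe(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(s.labels)
        row.update(
            n=s.n, mean=s.mean, sd=s.sd, median=s.median,
            min=s.min, max=s.max, detection_frequency=s.detection_frequency,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_t(
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
    variant: Literal["pooled", "welch"] = "welch",
) -> TestResult:
    """Two-sided two-sample t-test at alpha = 0.05.

    ``pooled`` is the classical equal-variance Student test; ``welch`` uses
    the Satterthwaite degrees-of-freedom approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if variant == "pooled":
        if var_a == 0.0 and var_b == 0.0:
            raise ValueError("zero variance in both groups: statistic undefined")
        result = sps.ttest_ind(a, b, equal_var=True)
    elif variant == "welch":
        if var_a == 0.0 and var_b == 0.0:
            raise ValueError("zero variance in both groups: statistic undefined")
        result = sps.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = float(result.pvalue)
    return TestResult(
        statistic=float(result.statistic),
        p_value=p,
        group_ns=(int(a.size), int(b.size)),
        significant=bool(p < 0.05),
    )


def pearson_correlation(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float:
    """Product–moment correlation of two paired vectors (length ≥ 3)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.pearsonr(xv, yv).statistic)


def skewness_direction(
    values: Sequence[float] | np.ndarray,
) -> Literal["right_skewed", "left_skewed", "symmetric"]:
    """Classify skew by the mean–median relation.

    ``right_skewed`` when the mean exceeds the median beyond a relative
    tolerance of 1e-9 (the hallmark of positively skewed exposure data),
    ``left_skewed`` for the reverse, else ``symmetric``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(v))
    median = float(np.median(v))
    tolerance = 1e-9 * max(abs(mean), abs(median), 1.0)
    if mean - median > tolerance:
        return "right_skewed"
    if median - mean > tolerance:
        return "left_skewed"
    return "symmetric"
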