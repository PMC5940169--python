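"""Proportion, location and group-effect tests used in the retention analysis.

Implemented here:

* :func:`two_sample_prop_test` — Pearson chi-square on the 2x2
  retained/lost table, with the Yates continuity correction on by default.
  The correction subtracts ``N/2`` from ``|ad - bc|`` (equivalently 0.5
  from each ``|O - E|``), clipped at zero, so the corrected statistic can
  never exceed the uncorrected one and the corrected p-value is never
  smaller.
* :func:`one_sample_prop_vs_baseline` — score (chi-square) test of an
  observed retention count against a genome-wide baseline *range*, tested
  conservatively against the nearest bound of the range.
* :func:`welch_t_test` — unequal-variance t test with
  Welch-Satterthwaite degrees of freedom.
* :func:`wald_group_effect` — binomial regression of retention on a
  categorical grouping (reference coding, IRLS fit) with an overall Wald
  chi-square on the k-1 group coefficients; a likelihood-ratio p-value is
  carried along for robustness.

Chi-square tail probabilities come from :func:`scipy.stats.chi2.sf`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "BaselineRange",
    "DegenerateTableError",
    "SeparationError",
    "load_baselines",
    "two_sample_prop_test",
    "one_sample_prop_vs_baseline",
    "welch_t_test",
    "wald_group_effect",
]


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin or contradictory baseline."""


class SeparationError(ValueError):
    """A group's outcomes are all identical, so its effect is not estimable."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    inputs: Mapping[str, object]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.method != "welch_t" and self.statistic < -1e-12:
            raise ValueError("chi2-family statistics must be non-negative")


@dataclass(frozen=True)
class BaselineRange:
    """Genome-wide retention-rate range for one WGD, from published estimates."""

    event: str
    low: float
    high: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError("baseline range must satisfy 0 <= low <= high <= 1")


def load_baselines(path: str | Path) -> dict[str, BaselineRange]:
    """Read ``{"TSGD": {"low": .., "high": ..}, ...}`` JSON into ranges.

    Keys are WGD labels; ``VGD`` denotes the compound 1R/2R era.
    """
    data = json.loads(Path(path).read_text())
    allowed = {"VGD", "VGD1", "VGD2", "TSGD", "SSGD"}
    out = {}
    for key, val in data.items():
        if key not in allowed:
            raise ValueError(f"unknown baseline key {key!r}; allowed: {sorted(allowed)}")
        out[key] = BaselineRange(
            event=key,
            low=float(val["low"]),
            high=float(val["high"]),
            source_note=str(val.get("source_note", "")),
        )
    return out


def _counts(x) -> tuple[int, int]:
    """Accept a RetentionRate-like object or a (retained, total) pair."""
    if hasattr(x, "n_retained") and hasattr(x, "n_events"):
        return int(x.n_retained), int(x.n_events)
    k, n = x
    return int(k), int(n)


def two_sample_prop_test(a, b, continuity_correction: bool = True) -> TestResult:
    """Chi-square comparison of two retention proportions (df = 1).

    ``a`` and ``b`` are RetentionRate objects or (retained, total) pairs.
    Uses the closed form ``N (|ad-bc| - cN/2)^2 / (r1 r2 c1 c2)`` with
    ``c = 1`` under the Yates correction (clipped at zero) and ``c = 0``
    without.  A zero marginal total is a hard error: the asymptotic test is
    meaningless there and an exact test would be needed instead.
    """
    k1, n1 = _counts(a)
    k2, n2 = _counts(b)
    aa, bb = k1, n1 - k1
    cc, dd = k2, n2 - k2
    n = n1 + n2
    margins = (n1, n2, aa + cc, bb + dd)
    if any(m == 0 for m in margins):
        raise DegenerateTableError(
            "2x2 table has a zero marginal total; the chi-square approximation "
            "does not apply (an exact test would be required)"
        )
    disc = abs(aa * dd - bb * cc)
    if continuity_correction:
        disc = max(0.0, disc - n / 2.0)
    statistic = n * disc**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(
        statistic=float(statistic),
        df=1,
        p_value=p,
        method="yates_chi2" if continuity_correction else "pearson_chi2",
        inputs={"a": (k1, n1), "b": (k2, n2), "continuity_correction": continuity_correction},
    )


def one_sample_prop_vs_baseline(observed, baseline: BaselineRange) -> TestResult:
    """Score chi-square of an observed retention count against a baseline range.

    The observed rate is tested against the *nearest* bound of the range
    (the conservative choice: significance against the nearest endpoint
    implies significance against the whole range).  An observed rate lying
    inside the range is non-significant by construction and returns
    ``p = 1`` with a ``within_baseline_range`` marker.
    """
    k, n = _counts(observed)
    rate = k / n
    if baseline.low <= rate <= baseline.high:
        return TestResult(
            statistic=0.0,
            df=1,
            p_value=1.0,
            method="one_sample_prop",
            inputs={
                "observed": (k, n),
                "baseline": (baseline.low, baseline.high),
                "within_baseline_range": True,
            },
        )
    p0 = baseline.high if rate > baseline.high else baseline.low
    if p0 in (0.0, 1.0):
        raise DegenerateTableError(
            f"degenerate baseline bound p0={p0} contradicts the observation "
            f"{k}/{n}; the score test is undefined"
        )
    statistic = n * (rate - p0) ** 2 / (p0 * (1.0 - p0))
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(
        statistic=float(statistic),
        df=1,
        p_value=p,
        method="one_sample_prop",
        inputs={
            "observed": (k, n),
            "baseline": (baseline.low, baseline.high),
            "p0": p0,
            "within_baseline_range": False,
        },
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two values")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise ValueError("both samples have zero variance; the t statistic is undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method="welch_t",
        inputs={
            "n_x": int(len(x)),
            "n_y": int(len(y)),
            "mean_x": float(np.mean(x)),
            "mean_y": float(np.mean(y)),
        },
    )


def wald_group_effect(outcomes: Sequence, groups: Sequence[str]) -> TestResult:
    """Overall Wald test for a categorical group effect on retention.

    ``outcomes`` holds 0/1 retention indicators (RetentionEvent objects are
    accepted and their ``retained`` field used); ``groups`` holds the
    aligned category labels.  A binomial GLM with logit link and reference
    coding is fitted by IRLS, and the Wald statistic ``b' V^-1 b`` over the
    k-1 group coefficients is referred to chi-square with k-1 df.  A
    likelihood-ratio p-value against the intercept-only model is included
    in ``inputs`` for robustness reporting.

    A group whose outcomes are all 0 or all 1 causes complete separation of
    its coefficient; this is detected and raised as
    :class:`SeparationError` with advice to collapse categories.
    """
    y = np.asarray(
        [int(getattr(o, "retained", o)) for o in outcomes], dtype=float
    )
    labels = pd.Series([str(g) for g in groups])
    if len(y) != len(labels):
        raise ValueError("outcomes and groups must be aligned")
    if len(y) == 0:
        raise ValueError("no observations")
    counts = pd.DataFrame({"y": y, "g": labels}).groupby("g")["y"].agg(["sum", "count"])
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    degenerate = counts[(counts["sum"] == 0) | (counts["sum"] == counts["count"])]
    if len(degenerate):
        raise SeparationError(
            f"complete separation: group(s) {sorted(degenerate.index)} have "
            "all-lost or all-retained outcomes; consider collapsing categories"
        )
    dummies = pd.get_dummies(labels, drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    k = len(counts)
    contrast = np.zeros((k - 1, X.shape[1]))
    contrast[:, 1:] = np.eye(k - 1)
    wald = fit.wald_test(contrast, scalar=True)
    null_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    lr_stat = 2.0 * (fit.llf - null_fit.llf)
    lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=k - 1))
    return TestResult(
        statistic=float(wald.statistic),
        df=k - 1,
        p_value=float(wald.pvalue),
        method="wald_glm",
        inputs={
            "group_counts": {
                g: (int(row["sum"]), int(row["count"])) for g, row in counts.iterrows()
            },
            "lrt_p_value": lr_p,
        },
    )
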