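"""Comparison statistics for cumulative versus conventional metrics.

The analysis plan is deliberately nonparametric: a Shapiro-Wilk gate decides
whether distributions can be treated as normal (they essentially never are
for exposure counts), Spearman rank correlations relate point-in-time counts
to cumulative exposure, trajectory groups are described by order statistics,
and exposed/nonexposed contrasts are summarized by the difference of group
medians (d).  Correlations below |rs| = 0.3 are flagged as weak — the
conventional cut-off under which a single time-point measurement is judged
uninformative about whole-stay exposure.

Spearman's rs is the Pearson correlation of mid-ranks (average ranks on
ties); its two-sided P value uses the t approximation
``t = rs * sqrt((n-2)/(1-rs^2))`` on n-2 degrees of freedom, with an exact
permutation option for very small samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import DeterminantMetrics
from .records_io import ValidationError

logger = logging.getLogger("cdexposure")

__all__ = [
    "WEAK_THRESHOLD",
    "ShapiroGate",
    "CorrelationResult",
    "GroupDescriptives",
    "MedianDifference",
    "shapiro_wilk_gate",
    "spearman",
    "trajectory_descriptives",
    "median_difference",
    "correlation_table",
    "trajectory_table",
]

#: |rs| below this is reported as a weak correlation.
WEAK_THRESHOLD = 0.3


@dataclass(frozen=True)
class ShapiroGate:
    """Outcome of the Shapiro-Wilk normality gate.

    ``testable`` is False (statistic/p/normal are None) for samples outside
    the test's validity range (n < 3 or n > 5000) or with zero variance.
    """

    testable: bool
    statistic: float | None = None
    p_value: float | None = None
    normal: bool | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p_value: float
    n: int
    weak: bool


@dataclass(frozen=True)
class GroupDescriptives:
    group: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class MedianDifference:
    """Difference of group medians, exposed minus unexposed."""

    d: float
    n_exposed: int
    n_unexposed: int


def shapiro_wilk_gate(values: Sequence[float], alpha: float = 0.05) -> ShapiroGate:
    """Shapiro-Wilk test gating the parametric/nonparametric choice.

    ``normal`` is True when the test fails to reject at ``alpha`` (p >=
    alpha).  Degenerate samples (n outside [3, 5000], zero variance) are
    reported as not testable rather than raising.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000 or np.ptp(x) == 0.0:
        return ShapiroGate(testable=False)
    res = sps.shapiro(x)
    return ShapiroGate(
        testable=True,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normal=bool(res.pvalue >= alpha),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    weak_threshold: float = WEAK_THRESHOLD,
    exact: bool = False,
) -> CorrelationResult | None:
    """Spearman rank correlation with mid-ranks and t-approximation P value.

    Returns ``None`` (undefined correlation) when either vector has zero
    variance in ranks.  With ``exact=True`` and n <= 10 the two-sided P value
    is computed by full enumeration of rank permutations instead of the t
    approximation.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-d vectors")
    n = xa.size
    if n < 3:
        raise ValidationError(f"spearman needs n >= 3, got n={n}")
    rx, ry = _midranks(xa), _midranks(ya)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        return None
    rs = float(np.corrcoef(rx, ry)[0, 1])
    rs = max(-1.0, min(1.0, rs))
    if exact and n <= 10:
        p = _exact_permutation_p(rx, ry, rs)
    elif abs(rs) == 1.0:
        p = 0.0
    else:
        t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rs=rs, p_value=p, n=n, weak=abs(rs) < weak_threshold)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    """Two-sided exact P: share of permutations with |rs| >= |rs observed|."""
    n = rx.size
    sx, sy = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    obs = abs(rs_obs) - 1e-12  # tolerate float noise at the observed value
    hits = total = 0
    for perm in permutations(range(n)):
        rs_p = float(sx @ sy[list(perm)]) / denom
        hits += abs(rs_p) >= obs
        total += 1
    return hits / total


def trajectory_descriptives(
    metrics: Sequence[DeterminantMetrics],
    determinant: str,
    value: str = "cde",
) -> list[GroupDescriptives]:
    """Descriptive statistics of CDE or CDED per trajectory group.

    Quartiles use linear interpolation between order statistics.  Groups
    with no patients are omitted; non-applicable patients are excluded.
    """
    if value not in ("cde", "cded"):
        raise ValidationError(f"value must be 'cde' or 'cded', got {value!r}")
    groups: dict[str, list[float]] = {}
    for m in metrics:
        if m.determinant != determinant or not m.applicable:
            continue
        groups.setdefault(m.trajectory, []).append(float(getattr(m, value)))
    out: list[GroupDescriptives] = []
    for group in sorted(groups):
        vals = np.asarray(groups[group], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            GroupDescriptives(
                group=group,
                n=vals.size,
                mean=float(vals.mean()),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return out


def median_difference(
    values_exposed: Sequence[float], values_unexposed: Sequence[float]
) -> MedianDifference | None:
    """d = median(exposed) − median(unexposed); None when a group is empty."""
    exp = np.asarray(values_exposed, dtype=float)
    une = np.asarray(values_unexposed, dtype=float)
    if exp.size == 0 or une.size == 0:
        return None
    return MedianDifference(
        d=float(np.median(exp) - np.median(une)),
        n_exposed=int(exp.size),
        n_unexposed=int(une.size),
    )


# --------------------------------------------------------------------------
# Tabular drivers over a metrics table
# --------------------------------------------------------------------------


def correlation_table(metrics: Sequence[DeterminantMetrics]) -> pd.DataFrame:
    """Spearman correlations of admission/discharge counts with CDE and CDED.

    One row per determinant × time point × cumulative metric.  Rows with too
    few applicable patients (n < 3) or undefined correlations carry empty
    statistic columns.
    """
    by_det: dict[str, list[DeterminantMetrics]] = {}
    for m in metrics:
        if m.applicable:
            by_det.setdefault(m.determinant, []).append(m)
    rows = []
    for det, ms in sorted(by_det.items()):
        for timepoint, count_attr in (
            ("admission", "count_admission"),
            ("discharge", "count_discharge"),
        ):
            counts = [float(getattr(m, count_attr)) for m in ms]
            for metric in ("cde", "cded"):
                vals = [float(getattr(m, metric)) for m in ms]
                row = {
                    "determinant": det,
                    "timepoint": timepoint,
                    "metric": metric,
                    "rs": None,
                    "p_value": None,
                    "n": len(ms),
                    "weak": None,
                }
                if len(ms) >= 3:
                    res = spearman(counts, vals)
                    if res is not None:
                        row.update(
                            rs=res.rs, p_value=res.p_value, n=res.n, weak=res.weak
                        )
                    else:
                        logger.warning(
                            "Correlation undefined (zero rank variance): %s %s %s",
                            det,
                            timepoint,
                            metric,
                        )
                else:
                    logger.warning(
                        "Correlation not computable (n=%d < 3): %s %s %s",
                        len(ms),
                        det,
                        timepoint,
                        metric,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def trajectory_table(metrics: Sequence[DeterminantMetrics]) -> pd.DataFrame:
    """Trajectory-group descriptives of CDE and CDED, all determinants."""
    determinants = sorted({m.determinant for m in metrics if m.applicable})
    rows = []
    for det in determinants:
        for metric in ("cde", "cded"):
            for g in trajectory_descriptives(metrics, det, metric):
                rows.append(
                    {
                        "determinant": det,
                        "metric": metric,
                        "group": g.group,
                        "n": g.n,
                        "mean": g.mean,
                        "median": g.median,
                        "q1": g.q1,
                        "q3": g.q3,
                        "min": g.min,
                        "max": g.max,
                    }
                )
    return pd.DataFrame(rows)
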