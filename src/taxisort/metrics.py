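"""Sorting statistics: efficiencies, specificity, multi-round enrichment,
the logistic activity-decline model, and a summary-statistics t-test.

Definitions (counts refer to one sorting run):

* competent efficiency  eps_C = N_C_bottom / N_C_in   (true negatives),
* deficient efficiency  eps_D = N_D_top   / N_D_in    (true positives),
* specificity           S_p   = N_D_top / (N_D_top + N_C_top),

where "top" is the collection outlet enriched for taxis-deficient animals
and "bottom" the feed-line outlet enriched for competent ones.  Repeated
rounds are applied to the top-collected fraction, so the cumulative
recovery of competent worms after K rounds is ``1 - prod_k (1 - eps_k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InvalidInputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-run outlet counts for the two phenotype classes.

    ``bottom + top <= in`` per class; the remainder is unrecovered
    (timed out in the device or lost during handling).
    """

    n_competent_in: int = 0
    n_competent_bottom: int = 0
    n_competent_top: int = 0
    n_deficient_in: int = 0
    n_deficient_top: int = 0
    n_deficient_bottom: int = 0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if int(v) != v or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v}")
        if self.n_competent_bottom + self.n_competent_top > self.n_competent_in:
            raise InvalidInputError("competent outlet counts exceed input count")
        if self.n_deficient_bottom + self.n_deficient_top > self.n_deficient_in:
            raise InvalidInputError("deficient outlet counts exceed input count")


@dataclass(frozen=True)
class RoundSeries:
    """Per-round competent efficiencies for an iterative enrichment plan."""

    efficiencies: tuple[float, ...]
    counts: tuple[ConfusionCounts, ...] | None = None
    recovery_interval_min: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "efficiencies", tuple(float(e) for e in self.efficiencies))
        if len(self.efficiencies) < 1:
            raise InvalidInputError("a round series needs at least one round")
        for e in self.efficiencies:
            if not 0.0 <= e <= 1.0:
                raise InvalidInputError(f"efficiency {e} outside [0, 1]")


@dataclass(frozen=True)
class LogisticDecline:
    """Four-parameter logistic ``eps(t) = a / (1 + exp(-b (t - d))) + c``.

    With b < 0 this declines from the early plateau ``a + c`` to the late
    plateau ``c``; ``d`` (minutes) is the midpoint and ``|b|`` (1/min) the
    steepness.  ``form_id`` names the variant so alternative
    parameterisations stay distinguishable in serialised reports.
    """

    a: float
    b: float
    c: float
    d: float
    form_id: str = "offset-logistic"


@dataclass(frozen=True)
class GaitSummary:
    """Summary statistics of a gait-frequency sample (Hz)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidInputError("standard deviation must be >= 0")
        if self.n < 2:
            raise InvalidInputError("need n >= 2 per group")


@dataclass(frozen=True)
class LogisticFitReport:
    r_squared: float
    residuals: np.ndarray
    converged: bool
    degenerate: bool = False


def efficiency_competent(counts: ConfusionCounts) -> float:
    """Fraction of competent animals discharged at the bottom outlet."""
    if counts.n_competent_in == 0:
        raise InvalidInputError("no competent animals were introduced")
    return counts.n_competent_bottom / counts.n_competent_in


def efficiency_deficient(counts: ConfusionCounts) -> float:
    """Fraction of deficient animals discharged at the top outlet."""
    if counts.n_deficient_in == 0:
        raise InvalidInputError("no deficient animals were introduced")
    return counts.n_deficient_top / counts.n_deficient_in


def specificity(counts: ConfusionCounts) -> float:
    """Fraction of top-outlet animals that are truly taxis-deficient."""
    top_total = counts.n_deficient_top + counts.n_competent_top
    if top_total == 0:
        raise UndefinedMetricError(
            "specificity is undefined: no animals were collected at the top outlet"
        )
    return counts.n_deficient_top / top_total


def cumulative_efficiency(series: RoundSeries | Sequence[float]) -> float:
    """Cumulative competent recovery after K rounds, ``1 - prod(1 - eps_k)``.

    Each round re-sorts only the top-collected (false-positive) fraction of
    the previous round, so a worm is recovered at the bottom unless it is
    misclassified in every round.  Monotone non-decreasing in K.
    """
    effs = series.efficiencies if isinstance(series, RoundSeries) else tuple(series)
    if len(effs) == 0:
        raise InvalidInputError("empty round series")
    miss = 1.0
    for e in effs:
        if not 0.0 <= e <= 1.0:
            raise InvalidInputError(f"efficiency {e} outside [0, 1]")
        miss *= 1.0 - e
    return 1.0 - miss


def evaluate_logistic(model: LogisticDecline, t) -> np.ndarray | float:
    """Evaluate the decline curve at time(s) ``t`` (minutes)."""
    if model.form_id != "offset-logistic":
        raise InvalidInputError(f"unknown logistic form {model.form_id!r}")
    t = np.asarray(t, dtype=float)
    # overflow-safe logistic
    z = np.clip(model.b * (t - model.d), -700.0, 700.0)
    out = model.a / (1.0 + np.exp(-z)) + model.c
    return out if out.ndim else float(out)


def _logistic(t, a, b, c, d):
    z = np.clip(b * (t - d), -700.0, 700.0)
    return a / (1.0 + np.exp(-z)) + c


def fit_logistic_decline(
    times: Sequence[float],
    efficiencies: Sequence[float],
    initializer: tuple[float, float, float, float] | None = None,
) -> tuple[LogisticDecline, LogisticFitReport]:
    """Nonlinear least-squares fit of the four-parameter logistic.

    ``times`` in minutes, ``efficiencies`` in [0, 1], at least 5 points.
    Multi-start initialisation over midpoint candidates and both slope
    signs; the best converged start by SSE wins.  The curve is invariant
    under ``(a, b, c) -> (-a, -b, a + c)``, so the result is canonicalised
    to ``a >= 0`` (then ``b < 0`` always denotes a decline with late
    plateau ``c``).  Constant data yields the degenerate fit ``a = 0,
    c = mean`` with the ``degenerate`` flag set.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidInputError("times and efficiencies must be equal-length 1-D")
    if t.size < 5:
        raise InvalidInputError("need at least 5 points to fit 4 parameters")
    if np.any((y < 0) | (y > 1)):
        raise InvalidInputError("efficiencies must lie in [0, 1]")

    if np.ptp(y) < 1e-12:
        model = LogisticDecline(a=0.0, b=0.0, c=float(np.mean(y)), d=float(np.median(t)))
        rep = LogisticFitReport(
            r_squared=1.0, residuals=y - np.mean(y), converged=True, degenerate=True
        )
        return model, rep

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    span = float(np.ptp(t)) or 1.0

    starts: list[tuple[float, float, float, float]] = []
    if initializer is not None:
        starts.append(tuple(float(v) for v in initializer))
    amp = float(np.ptp(y))
    mid = 0.5 * (y.min() + y.max())
    # midpoint guess: time where y first crosses its mid-level
    cross = np.nonzero(np.diff(np.sign(y - mid)))[0]
    d0s = [float(t[c]) for c in cross[:2]] or [float(np.median(t))]
    for d0 in d0s:
        for mag in (2.0, 8.0, 32.0):
            for sign in (-1.0, 1.0):
                # either sign, the lower plateau is c and the amplitude a
                starts.append((amp, sign * mag / span, float(y.min()), d0))

    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _logistic(t, *p) - y, x0=np.array(p0), method="lm", max_nfev=5000
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise InvalidInputError("logistic fit failed from every start")
    sse, res = best
    a, b, c, d = (float(v) for v in res.x)
    # the form is invariant under (a, b, c) -> (-a, -b, a + c); canonicalise
    # to a >= 0 so that b < 0 always means a decline with late plateau c
    if a < 0:
        a, b, c = -a, -b, c + a
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    model = LogisticDecline(a=a, b=b, c=c, d=d)
    report = LogisticFitReport(
        r_squared=r2, residuals=_logistic(t, a, b, c, d) - y, converged=bool(res.success)
    )
    return model, report


def two_sample_t_from_summary(
    g1: GaitSummary,
    g2: GaitSummary,
    tails: int = 2,
    pooled: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Returns ``(t, df, p)``.  Default is Welch (unequal variances),
    two-tailed; ``pooled=True`` gives the classic equal-variance Student
    test.  ``t`` is signed as mean1 - mean2.
    """
    if tails not in (1, 2):
        raise InvalidInputError("tails must be 1 or 2")
    v1, v2 = g1.sd**2, g2.sd**2
    diff = g1.mean - g2.mean
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        return math.copysign(math.inf, diff), float(g1.n + g2.n - 2), 0.0
    if pooled:
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    else:
        q1, q2 = v1 / g1.n, v2 / g2.n
        se = math.sqrt(q1 + q2)
        df = (q1 + q2) ** 2 / (q1**2 / (g1.n - 1) + q2**2 / (g2.n - 1))
    t_stat = diff / se
    p = tails * float(stats.t.sf(abs(t_stat), df))
    return float(t_stat), float(df), min(p, 1.0)
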