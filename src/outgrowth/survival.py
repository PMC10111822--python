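"""Kaplan-Meier estimation, two-group logrank testing, caliper tumour area.

The product-limit estimator handles ties the standard way: deaths at a tied
time are processed together, and subjects censored at an event time are still
at risk for that event.  The two-group comparison reports the logrank
chi-square with the observed/expected hazard ratio

    HR = (O_A / E_A) / (O_B / E_B),     95% CI = exp(ln HR +/- 1.96 sqrt(1/E_A + 1/E_B))

and the median survival of each arm, reported as undefined when a curve
never drops to 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .errors import ValidationError

__all__ = [
    "SurvivalSample",
    "SurvivalCurve",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "tumour_area",
    "TwoGroupSurvivalModel",
    "SurvivalResults",
]


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: follow-up time, event flag (False = censored), group label."""

    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"survival time must be > 0, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with at-risk/event bookkeeping.

    ``event_times`` are the distinct times with at least one event;
    ``survival[i]`` is S(t) just after ``event_times[i]``.  ``se`` holds
    Greenwood standard errors of S at those times.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_subjects: int
    n_total_events: int

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the right-continuous step function S(t)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, or NaN when never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size == 0:
            return math.nan
        return float(self.event_times[below[0]])


def _as_arrays(
    samples: Iterable[SurvivalSample] | None = None,
    times: Sequence[float] | None = None,
    events: Sequence[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if samples is not None:
        samples = list(samples)
        times = [s.time for s in samples]
        events = [s.event for s in samples]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("no survival samples")
    if (t <= 0).any():
        raise ValidationError("survival times must be > 0")
    return t, e


def km_estimate(
    samples: Iterable[SurvivalSample] | None = None,
    *,
    times: Sequence[float] | None = None,
    events: Sequence[bool] | None = None,
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    t, e = _as_arrays(samples, times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    uniq = np.unique(t[e]) if e.any() else np.array([], dtype=float)
    n = t.size
    n_at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    for i, ti in enumerate(uniq):
        n_at_risk[i] = int((t >= ti).sum())  # censored at ti still at risk
        d[i] = int((e & (t == ti)).sum())
    frac = 1.0 - d / n_at_risk if uniq.size else np.array([])
    surv = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf))
        se = np.where(np.isfinite(gw), surv * np.sqrt(np.where(np.isfinite(gw), gw, 0.0)), 0.0)
    return SurvivalCurve(
        event_times=uniq,
        n_at_risk=n_at_risk,
        n_events=d,
        survival=surv,
        se=se,
        n_subjects=n,
        n_total_events=int(e.sum()),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    hazard_ratio: float  # (O_A/E_A)/(O_B/E_B), NaN when undefined
    ci95: tuple[float, float]
    groups: tuple[str, str]
    observed: tuple[float, float]
    expected: tuple[float, float]
    median_survival: dict[str, float]  # NaN = undefined (curve stays above 0.5)

    @property
    def hazard_ratio_inverse(self) -> float:
        return 1.0 / self.hazard_ratio if self.hazard_ratio > 0 else math.nan


def logrank_test(
    samples: Iterable[SurvivalSample] | None = None,
    *,
    times: Sequence[float] | None = None,
    events: Sequence[bool] | None = None,
    groups: Sequence[str] | None = None,
    group_order: Sequence[str] | None = None,
) -> LogrankResult:
    """Two-group logrank test with the O/E hazard ratio.

    ``group_order`` fixes which group is the HR numerator (defaults to first
    appearance order).  With zero events in both arms the statistic is 0,
    p = 1 and the HR undefined (NaN).
    """
    if samples is not None:
        samples = list(samples)
        times = [s.time for s in samples]
        events = [s.event for s in samples]
        groups = [s.group for s in samples]
    if groups is None:
        raise ValidationError("group labels are required")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray([str(x) for x in groups])
    if t.size == 0:
        raise ValidationError("no survival samples")
    if (t <= 0).any():
        raise ValidationError("survival times must be > 0")

    if group_order is None:
        seen: list[str] = []
        for x in g:
            if x not in seen:
                seen.append(x)
        group_order = seen
    labels = tuple(group_order)
    if len(labels) != 2 or len(set(labels)) != 2:
        raise ValidationError(f"exactly two groups required, got {labels}")
    mask_a = g == labels[0]
    mask_b = g == labels[1]
    if not mask_a.any() or not mask_b.any():
        raise ValidationError("each group must be non-empty")
    if mask_a.sum() + mask_b.sum() != t.size:
        extra = sorted(set(g) - set(labels))
        raise ValidationError(f"unknown group labels: {extra}")

    event_times = np.unique(t[e])
    o_a = e_a = var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n_i = at_risk.sum()
        n_ai = (at_risk & mask_a).sum()
        d_i = (e & (t == ti)).sum()
        d_ai = (e & (t == ti) & mask_a).sum()
        o_a += d_ai
        e_a += d_i * n_ai / n_i
        if n_i > 1:
            var += d_i * (n_i - d_i) * n_ai * (n_i - n_ai) / (n_i**2 * (n_i - 1))

    total_events = float(e.sum())
    o_b = total_events - o_a
    e_b = total_events - e_a
    if total_events == 0 or var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / var
        p = float(special.chdtrc(1, chi2))

    if e_a > 0 and e_b > 0 and o_a > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
        half = 1.96 * math.sqrt(1.0 / e_a + 1.0 / e_b)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    else:
        hr, ci = math.nan, (math.nan, math.nan)

    medians = {
        labels[0]: km_estimate(times=t[mask_a], events=e[mask_a]).median,
        labels[1]: km_estimate(times=t[mask_b], events=e[mask_b]).median,
    }
    return LogrankResult(
        chi2=float(chi2),
        p=float(p),
        hazard_ratio=float(hr),
        ci95=ci,
        groups=labels,
        observed=(float(o_a), float(o_b)),
        expected=(float(e_a), float(e_b)),
        median_survival=medians,
    )


def tumour_area(m1: float, m2: float) -> float:
    """Caliper tumour area = B x S (largest x smallest 2-D measurement, mm^2)."""
    if not (m1 > 0 and m2 > 0):
        raise ValidationError(f"caliper measurements must be > 0, got ({m1}, {m2})")
    b, s = max(m1, m2), min(m1, m2)
    return float(b) * float(s)


class TwoGroupSurvivalModel:
    """Survival comparison of two arms, statsmodels-style.

    Parameters are parallel arrays of follow-up time, event indicator and
    group label.  ``fit`` estimates a Kaplan-Meier curve per arm and, when
    exactly two arms are present, the logrank test and O/E hazard ratio.
    """

    def __init__(self, times, events, groups, group_order: Sequence[str] | None = None):
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        self.groups = np.asarray([str(g) for g in groups])
        self.group_order = list(group_order) if group_order else None

    @classmethod
    def from_dataframe(cls, df, time_col="time", event_col="event", group_col="group", **kw):
        return cls(df[time_col], df[event_col], df[group_col], **kw)

    def fit(self) -> "SurvivalResults":
        order = self.group_order
        if order is None:
            order = list(dict.fromkeys(self.groups))
        curves = {}
        for lbl in order:
            m = self.groups == lbl
            if not m.any():
                raise ValidationError(f"group {lbl!r} is empty")
            curves[lbl] = km_estimate(times=self.times[m], events=self.events[m])
        logrank = None
        if len(order) == 2:
            logrank = logrank_test(
                times=self.times, events=self.events, groups=self.groups, group_order=order
            )
        return SurvivalResults(self, curves, logrank)


class SurvivalResults:
    def __init__(self, model, curves: dict[str, SurvivalCurve], logrank: LogrankResult | None):
        self.model = model
        self.curves = curves
        self.logrank = logrank

    def survival_at(self, t: float) -> dict[str, float]:
        return {lbl: c.survival_at(t) for lbl, c in self.curves.items()}

    def summary(self) -> str:
        lines = ["Kaplan-Meier / logrank results", "=" * 50]
        for lbl, c in self.curves.items():
            med = c.median
            med_s = "undefined" if math.isnan(med) else f"{med:g}"
            lines.append(
                f"group {lbl!r}: n={c.n_subjects}, events={c.n_total_events}, median={med_s}"
            )
        lr = self.logrank
        if lr is not None:
            a, b = lr.groups
            hr_s = "undefined" if math.isnan(lr.hazard_ratio) else f"{lr.hazard_ratio:.4f}"
            lines += [
                f"logrank chi2={lr.chi2:.4f} (df=1), p={lr.p:.4g}",
                f"hazard ratio ({a} vs {b}): {hr_s} "
                f"(95% CI {lr.ci95[0]:.4f}-{lr.ci95[1]:.4f})"
                if not math.isnan(lr.hazard_ratio)
                else f"hazard ratio ({a} vs {b}): undefined",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Step plot of each arm's survival curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lbl, c in self.curves.items():
            x = np.concatenate([[0.0], c.event_times])
            y = np.concatenate([[1.0], c.survival])
            ax.step(x, y, where="post", label=str(lbl))
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax
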