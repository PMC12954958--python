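"""Validation statistics for assessed runs.

Assessed events are matched to ground-truth planting points by greedy
nearest-neighbour pairing within a tolerance radius; the result is a
five-status summary table (ground truth / assessed / correct / accuracy per
status plus totals), from which the overall accuracy, abnormality rate,
Wilson 95 % score interval and one-sided significance tests against a
baseline accuracy are computed.

Accuracy is ``100 · correct / ground_truth`` per status, with percentages
rounded half-up to two decimals for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .assessment import TransplantEvent, TransplantStatus
from .geodesy import PlanePoint, ProjectionConfig, lonlat_to_plane, plane_distance
from .simulator import GroundTruth

__all__ = [
    "StatusRow",
    "StatusSummary",
    "AccuracyInference",
    "match_events",
    "evaluate_run",
    "summary_accuracy",
    "wilson_interval",
    "accuracy_tests",
    "abnormality_rate",
]

STATUS_ORDER = [
    TransplantStatus.NORMAL,
    TransplantStatus.ROOT_EXPOSURE,
    TransplantStatus.SEEDLING_BURIAL,
    TransplantStatus.MISSED_PLANTING,
    TransplantStatus.DOUBLE_PLANTING,
]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation convention for percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class StatusRow:
    ground_truth: int = 0
    assessed: int = 0
    correct: int = 0

    @property
    def accuracy(self) -> Optional[float]:
        if self.ground_truth == 0:
            return None
        return _round2(100.0 * self.correct / self.ground_truth)


@dataclass
class StatusSummary:
    """Per-status counts plus totals, mirroring a field-validation table."""

    rows: Dict[TransplantStatus, StatusRow]

    @classmethod
    def from_counts(
        cls, counts: Dict[TransplantStatus, Tuple[int, int, int]]
    ) -> "StatusSummary":
        """Build a summary directly from (ground_truth, assessed, correct) triples."""
        rows = {}
        for status in STATUS_ORDER:
            gt, assessed, correct = counts.get(status, (0, 0, 0))
            if correct > min(gt, assessed):
                raise ValueError(f"correct > min(gt, assessed) for {status.value}")
            rows[status] = StatusRow(gt, assessed, correct)
        return cls(rows=rows)

    @property
    def total(self) -> StatusRow:
        return StatusRow(
            ground_truth=sum(r.ground_truth for r in self.rows.values()),
            assessed=sum(r.assessed for r in self.rows.values()),
            correct=sum(r.correct for r in self.rows.values()),
        )

    def as_dict(self) -> dict:
        out = {}
        for status in STATUS_ORDER:
            r = self.rows[status]
            out[status.value] = {
                "ground_truth": r.ground_truth,
                "assessed": r.assessed,
                "correct": r.correct,
                "accuracy": r.accuracy,
            }
        t = self.total
        out["total"] = {
            "ground_truth": t.ground_truth,
            "assessed": t.assessed,
            "correct": t.correct,
            "accuracy": t.accuracy,
        }
        return out


def match_events(
    assessed: Sequence[TransplantEvent],
    truth: Sequence[Tuple[TransplantStatus, PlanePoint]],
    tol: float,
) -> StatusSummary:
    """Greedy nearest-neighbour matching of events to truth points.

    Candidate pairs within ``tol`` metres are taken closest-first, each
    event and truth point matched at most once.  A matched pair is
    *correct* when the statuses agree.  Unmatched truth points count
    toward ground truth only; unmatched events toward assessed only.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    candidates = []
    for ti, (t_status, t_plane) in enumerate(truth):
        for ei, ev in enumerate(assessed):
            d = plane_distance(t_plane, ev.plane)
            if d <= tol:
                candidates.append((d, ti, ei))
    candidates.sort(key=lambda c: c[0])
    matched_t: dict[int, int] = {}
    matched_e: set[int] = set()
    for d, ti, ei in candidates:
        if ti in matched_t or ei in matched_e:
            continue
        matched_t[ti] = ei
        matched_e.add(ei)

    rows = {s: StatusRow() for s in STATUS_ORDER}
    for ti, (t_status, _) in enumerate(truth):
        rows[t_status].ground_truth += 1
        if ti in matched_t and assessed[matched_t[ti]].status is t_status:
            rows[t_status].correct += 1
    for ev in assessed:
        rows[ev.status].assessed += 1
    return StatusSummary(rows=rows)


def evaluate_run(
    assessed: Sequence[TransplantEvent],
    gt: GroundTruth,
    proj: ProjectionConfig,
    tol: Optional[float] = None,
) -> StatusSummary:
    """Match assessed events against a simulated ground truth.

    Default matching tolerance is ``0.3 · d_std``.
    """
    if tol is None:
        tol = 0.3 * gt.field_spec.d_std
    truth = [(tp.status, lonlat_to_plane(tp.geo, proj)) for tp in gt.points]
    return match_events(assessed, truth, tol)


def summary_accuracy(s: StatusSummary) -> Dict[str, Optional[float]]:
    """Per-status and overall accuracy in percent (2 decimals, half-up)."""
    if s.total.ground_truth == 0:
        raise ValueError("accuracy undefined: zero ground-truth points")
    out = {status.value: s.rows[status].accuracy for status in STATUS_ORDER}
    out["overall"] = s.total.accuracy
    return out


def wilson_interval(k: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent (2 dp)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 ≤ k ≤ n")
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return _round2(100.0 * low), _round2(100.0 * high)


@dataclass
class AccuracyInference:
    """Interval and significance tests for an observed accuracy k/n."""

    n: int
    k: int
    p_hat: float
    wilson_low: float  # percent
    wilson_high: float  # percent
    z_stat: float
    p_z: float
    p_binom: float
    baseline_p0: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "p_hat": self.p_hat,
            "wilson_low_pct": self.wilson_low,
            "wilson_high_pct": self.wilson_high,
            "z_stat": self.z_stat,
            "p_z": self.p_z,
            "p_binom": self.p_binom,
            "baseline_p0": self.baseline_p0,
        }


def accuracy_tests(k: int, n: int, p0: float = 0.85, conf: float = 0.95) -> AccuracyInference:
    """One-sided tests of accuracy k/n against a baseline proportion p0.

    z test: z = (k/n − p0) / √(p0 (1 − p0) / n), upper-tail p-value, no
    continuity correction.  Binomial test: exact upper tail P(X ≥ k | n, p0).
    """
    if not 0 < p0 < 1:
        raise ValueError("baseline p0 must be in (0, 1)")
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need n > 0 and 0 ≤ k ≤ n")
    p_hat = k / n
    z = (p_hat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p_z = float(stats.norm.sf(z))
    p_binom = float(stats.binom.sf(k - 1, n, p0))
    low, high = wilson_interval(k, n, conf)
    return AccuracyInference(
        n=n,
        k=k,
        p_hat=p_hat,
        wilson_low=low,
        wilson_high=high,
        z_stat=z,
        p_z=p_z,
        p_binom=p_binom,
        baseline_p0=p0,
    )


def abnormality_rate(s: StatusSummary) -> float:
    """Percent of assessed events that are non-normal."""
    total = s.total.assessed
    if total == 0:
        raise ValueError("abnormality rate undefined: no assessed events")
    abnormal = total - s.rows[TransplantStatus.NORMAL].assessed
    return 100.0 * abnormal / total


def plot_status_counts(s: StatusSummary, ax=None):
    """Bar chart of assessed counts per status (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = [st.value for st in STATUS_ORDER]
    ax.bar(labels, [s.rows[st].assessed for st in STATUS_ORDER])
    ax.set_ylabel("assessed events")
    ax.tick_params(axis="x", rotation=30)
    return ax


def plot_anomaly_scatter(events: Sequence[TransplantEvent], ax=None):
    """Spatial scatter of anomaly events in the spacing plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for status in STATUS_ORDER:
        if status is TransplantStatus.NORMAL:
            continue
        pts = [e.plane for e in events if e.status is status]
        if pts:
            ax.scatter([p.x for p in pts], [p.y for p in pts], label=status.value, s=12)
    ax.set_xlabel("x (m east)")
    ax.set_ylabel("y (m north)")
    ax.set_aspect("equal")
    ax.legend()
    return ax
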