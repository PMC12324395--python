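"""Shift classification, stabilization metrics, reset events and behavior score.

A cross-day field's shift class comes from comparing its COM-vs-run OLS slope
with a bootstrap built from every circular rotation of its COM-sorted run
fields: backward iff the slope is at or below the 10th percentile of that
distribution, forward iff at or above the 90th, else stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import TrackLayout
from .tracking import CrossDayField, LinkParams, RunField, fields_from_run_lists, ols_line

__all__ = [
    "ShiftClass",
    "DayField",
    "ResetEvent",
    "field_slope",
    "classify_shift",
    "shuffle_type_fractions",
    "split_day_fields",
    "stabilization_metrics",
    "classify_close_far",
    "gaussian_null_pass",
    "learning_change",
    "detect_reset_events",
    "reset_significance",
    "scaled_percentile",
    "behavior_score",
]

LABELS = ("backward", "forward", "stationary")


@dataclass
class ShiftClass:
    slope_cm_per_run: float
    bootstrap_slopes: np.ndarray
    label: str  # backward | forward | stationary


@dataclass
class DayField:
    """The within-one-day slice of a cross-day field (>= 3 runs)."""

    day: int
    run_fields: List[RunField]

    def __post_init__(self) -> None:
        if len(self.run_fields) < 3:
            raise ValueError("day fields need at least 3 runs")

    @property
    def runs(self) -> np.ndarray:
        return np.array([f.run_index for f in self.run_fields])

    @property
    def coms(self) -> np.ndarray:
        return np.array([f.com_cm for f in self.run_fields])

    @property
    def center_cm(self) -> float:
        return float(self.coms.mean())

    @property
    def median_com_cm(self) -> float:
        return float(np.median(self.coms))

    @property
    def slope(self) -> float:
        return ols_line(self.runs, self.coms)[0]

    @property
    def com_sd(self) -> float:
        return float(self.coms.std(ddof=0))


@dataclass
class ResetEvent:
    """A day-boundary field displacement (regression = forward, progression = backward)."""

    kind: str  # regression | progression
    magnitude_cm: float
    boundary_day: int  # event happens between boundary_day and boundary_day + 1
    significant: Optional[bool] = None


def field_slope(field: CrossDayField) -> float:
    """OLS slope (cm/run) of COM on global run index."""
    return ols_line(field.runs, field.coms)[0]


def classify_shift(field: CrossDayField) -> ShiftClass:
    """Shift class from the circular-rotation bootstrap of sorted COMs.

    COMs are sorted descending onto the field's run indices (the maximal
    backward arrangement); all ``n`` circular rotations of that sequence,
    with run indices fixed, give the bootstrap slope distribution.  The label
    follows the 10th/90th-percentile rule with linear-interpolation
    percentiles.  All-equal COMs yield a degenerate bootstrap and the field
    is stationary.
    """
    runs = field.runs.astype(float)
    coms = field.coms.astype(float)
    n = runs.size
    if n < 2:
        raise ValueError("need at least 2 run fields to classify")
    slope = field_slope(field)
    if np.ptp(coms) == 0:
        return ShiftClass(slope, np.zeros(n), "stationary")
    s = np.sort(coms)[::-1]
    # slopes of all circular rotations, vectorised via the OLS closed form
    idx = (np.arange(n)[None, :] + np.arange(n)[:, None]) % n
    rotated = s[idx]  # (n rotations, n)
    dx = runs - runs.mean()
    boot = (rotated - rotated.mean(axis=1, keepdims=True)) @ dx / float(dx @ dx)
    lo, hi = np.percentile(boot, [10, 90])
    if slope <= lo:
        label = "backward"
    elif slope >= hi:
        label = "forward"
    else:
        label = "stationary"
    return ShiftClass(slope, boot, label)


def _type_fractions(fields: Sequence[CrossDayField]) -> np.ndarray:
    labels = [classify_shift(f).label for f in fields]
    n = max(len(labels), 1)
    return np.array([labels.count(lab) / n for lab in LABELS])


def shuffle_type_fractions(
    cells: Dict[str, List[CrossDayField]],
    params: Optional[LinkParams] = None,
    n_shuffle: int = 100,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Observed vs within-field-shuffle baseline fractions of shift types.

    Each shuffle permutes the run fields within every detected cross-day
    field (each run field keeps its bins/COM but lands on another of the
    field's runs), re-runs linking Stages 2-4 on the permuted per-run field
    lists, reclassifies, and records the fraction of each type.  The observed
    fraction is significant when it reaches the 95th (or 5th) percentile of
    the ``n_shuffle`` baselines.
    """
    params = params or LinkParams()
    rng = np.random.default_rng(seed)
    observed = _type_fractions([f for fs in cells.values() for f in fs])
    baselines = np.empty((n_shuffle, 3))
    for k in range(n_shuffle):
        shuffled_fields: List[CrossDayField] = []
        for fs in cells.values():
            per_run: Dict[int, List[RunField]] = {}
            run_to_day: Dict[int, int] = {}
            for f in fs:
                for rf in f.run_fields:
                    run_to_day[rf.run_index] = rf.day
            for f in fs:
                runs = [rf.run_index for rf in f.run_fields]
                perm = rng.permutation(len(runs))
                for slot, j in enumerate(perm):
                    rf = f.run_fields[j]
                    new_run = runs[slot]
                    per_run.setdefault(new_run, []).append(
                        RunField(
                            run_index=new_run,
                            day=run_to_day[new_run],
                            start_bin=rf.start_bin,
                            end_bin=rf.end_bin,
                            com_cm=rf.com_cm,
                            mean_value=rf.mean_value,
                            width_cm=rf.width_cm,
                        )
                    )
            if not per_run:
                continue
            all_runs = sorted(per_run)
            lists = [sorted(per_run.get(r, []), key=lambda rf: rf.com_cm) for r in range(min(all_runs), max(all_runs) + 1)]
            shuffled_fields.extend(fields_from_run_lists(lists, params))
        baselines[k] = _type_fractions(shuffled_fields)
    lo, hi = np.percentile(baselines, [5, 95], axis=0)
    return {
        "observed": observed,
        "baselines": baselines,
        "significant_high": observed >= hi,
        "significant_low": observed <= lo,
        "labels": np.array(LABELS),
    }


# ---------------------------------------------------------------------------
# day fields and stabilization


def split_day_fields(field: CrossDayField, min_runs: int = 3) -> List[DayField]:
    """Slice a cross-day field into per-day day fields with >= ``min_runs`` runs."""
    by_day: Dict[int, List[RunField]] = {}
    for rf in field.run_fields:
        by_day.setdefault(rf.day, []).append(rf)
    return [DayField(day, rfs) for day, rfs in sorted(by_day.items()) if len(rfs) >= min_runs]


def stabilization_metrics(day_fields: Sequence[DayField]) -> Dict[str, Dict]:
    """Per-day slope, COM standard deviation, and adjacent-day centre distances."""
    slopes = {df.day: df.slope for df in day_fields}
    sds = {df.day: df.com_sd for df in day_fields}
    centers = {df.day: df.center_cm for df in day_fields}
    dists = {}
    days = sorted(centers)
    for a, b in zip(days[:-1], days[1:]):
        if b == a + 1:
            dists[(a, b)] = abs(centers[b] - centers[a])
    return {"slope": slopes, "com_sd": sds, "center_cm": centers, "adjacent_distance": dists}


def classify_close_far(
    field_location_cm: float,
    layout: TrackLayout,
    n_bins: int = 2,
) -> Tuple[str, bool]:
    """Close/far label of a field relative to its back landmark.

    The span between the adjacent anchor pair containing the field location
    (median of day-field centres) is split into ``n_bins`` equal parts;
    "close" is the part nearest the back anchor.  With 3 bins the labels are
    close / far1 / far2.  A location outside the span (field crossed its
    landmark) is assigned to the nearest part and flagged.
    """
    if n_bins not in (2, 3):
        raise ValueError("n_bins must be 2 or 3")
    anchors = np.asarray(layout.anchors_cm)
    k = int(np.searchsorted(anchors, field_location_cm, side="right")) - 1
    flagged = False
    if k < 0:
        k, flagged = 0, True
    if k >= anchors.size - 1:
        k, flagged = anchors.size - 2, True
    back, front = anchors[k], anchors[k + 1]
    rel = float(np.clip((field_location_cm - back) / (front - back), 0.0, 1.0))
    # a location exactly on a part boundary belongs to the part nearer the
    # back landmark
    part = 0 if rel == 0 else min(int(np.ceil(rel * n_bins)) - 1, n_bins - 1)
    labels = ("close", "far") if n_bins == 2 else ("close", "far1", "far2")
    return labels[part], flagged


def gaussian_null_pass(
    end_pcts: np.ndarray,
    n_sim: int = 20000,
    bin_pct: float = 20.0,
    seed: int = 0,
    mu: Optional[float] = None,
    sigma: Optional[float] = None,
) -> Dict[str, np.ndarray]:
    """Per-bin significance of the end-percentage-distance distribution.

    ``end_pcts`` are the signed relative distances (percent of the
    inter-landmark span) of late-learning field locations to their back
    landmark; negative values mean the field crossed it.  The null simulates
    ``n_sim`` same-size samples from a normal centred on the empirical PDF
    peak with sigma = range/6 (so +/- 3 sigma covers the range), binned
    identically; an observed bin count at or below the 5th / at or above the
    95th percentile of the simulated counts is flagged low / high.
    """
    end_pcts = np.asarray(end_pcts, dtype=float)
    if end_pcts.size < 2:
        raise ValueError("need at least two fields")
    rng = np.random.default_rng(seed)
    lo = np.floor(end_pcts.min() / bin_pct) * bin_pct
    hi = np.ceil(end_pcts.max() / bin_pct) * bin_pct
    if hi == lo:
        hi = lo + bin_pct
    edges = np.arange(lo, hi + bin_pct / 2, bin_pct)
    counts, _ = np.histogram(end_pcts, edges)
    centers = edges[:-1] + bin_pct / 2
    if mu is None:
        mu = centers[int(np.argmax(counts))]  # peak of the PDF envelope
    if sigma is None:
        sigma = float(np.ptp(end_pcts)) / 6.0  # +/- 3 sigma spans the range
    sims = rng.normal(mu, sigma, size=(n_sim, end_pcts.size))
    sim_counts = np.stack([np.histogram(s, edges)[0] for s in sims])
    lo_q, hi_q = np.percentile(sim_counts, [5, 95], axis=0)
    return {
        "bin_edges": edges,
        "observed": counts,
        "low": counts <= lo_q,
        "high": counts >= hi_q,
        "mu": np.array(mu),
        "sigma": np.array(sigma),
    }


def learning_change(
    metric_per_day: Dict[int, float],
    early_days: Sequence[int] = (1, 2, 3),
    late_days: Sequence[int] = (7, 8, 9, 10),
) -> Dict[int, float]:
    """Late-day metric values minus the early-window mean (one delta per late day)."""
    early = [metric_per_day[d] for d in early_days if d in metric_per_day]
    if not early:
        raise ValueError("empty early window")
    base = float(np.mean(early))
    return {d: metric_per_day[d] - base for d in late_days if d in metric_per_day}


# ---------------------------------------------------------------------------
# reset events


RESET_MIN_RUNS = {"dataset1": 6, "dataset2": 3, "simulated": 9}
RESET_PERCENTILE = {"dataset1": 70.0, "dataset2": 85.0, "simulated": 70.0}


def _day_first_last_runs(field: CrossDayField) -> Dict[int, Tuple[int, int]]:
    out: Dict[int, Tuple[int, int]] = {}
    for rf in field.run_fields:
        lo, hi = out.get(rf.day, (rf.run_index, rf.run_index))
        out[rf.day] = (min(lo, rf.run_index), max(hi, rf.run_index))
    return out


def detect_reset_events(
    field: CrossDayField,
    day_run_spans: Dict[int, Tuple[int, int]],
    min_runs_per_day: int = 6,
) -> List[ResetEvent]:
    """Day-boundary regression/progression events of one cross-day field.

    An event needs adjacent-day day fields where (a) the earlier one reaches
    the last run of its day, or (b) the later one starts at the first run of
    its day; both must have more than ``min_runs_per_day`` runs.  The kind
    follows the sign of the COM displacement across the boundary (forward =
    regression); the magnitude is |COM(first run field of day n+1) - COM(last
    run field of day n)|.
    """
    by_day: Dict[int, List[RunField]] = {}
    for rf in field.run_fields:
        by_day.setdefault(rf.day, []).append(rf)
    events: List[ResetEvent] = []
    days = sorted(by_day)
    for a, b in zip(days[:-1], days[1:]):
        if b != a + 1:
            continue
        fa, fb = by_day[a], by_day[b]
        if len(fa) <= min_runs_per_day or len(fb) <= min_runs_per_day:
            continue
        reaches_end = fa[-1].run_index == day_run_spans[a][1]
        starts_first = fb[0].run_index == day_run_spans[b][0]
        if not (reaches_end or starts_first):
            continue
        disp = fb[0].com_cm - fa[-1].com_cm
        if disp == 0:
            continue
        events.append(
            ResetEvent(
                kind="regression" if disp > 0 else "progression",
                magnitude_cm=abs(float(disp)),
                boundary_day=a,
            )
        )
    return events


def within_day_shifts(field: CrossDayField, days: Tuple[int, int], direction: str) -> np.ndarray:
    """Same-direction adjacent-run COM shifts inside the two participating day fields."""
    sign = 1.0 if direction == "regression" else -1.0
    shifts = []
    for day in days:
        rfs = [rf for rf in field.run_fields if rf.day == day]
        for u, v in zip(rfs[:-1], rfs[1:]):
            if v.run_index == u.run_index + 1:
                d = v.com_cm - u.com_cm
                if d * sign > 0:
                    shifts.append(abs(d))
    return np.asarray(shifts)


def reset_significance(
    event: ResetEvent,
    baseline_shifts: np.ndarray,
    percentile: float = 85.0,
) -> bool:
    """Event significance against within-day same-direction shift baseline.

    Significant iff the magnitude strictly exceeds the ``percentile``-th
    linear-interpolation percentile of the baseline.  An empty baseline
    means not significant (flagged by the caller).
    """
    baseline_shifts = np.asarray(baseline_shifts, dtype=float)
    if baseline_shifts.size == 0:
        return False
    return bool(event.magnitude_cm > np.percentile(baseline_shifts, percentile))


def scaled_percentile(reference_percentile: float, reference_magnitude: float, target_magnitude: float) -> float:
    """Magnitude-scaled significance percentile for a second dataset.

    The reference dataset's percentile threshold is scaled by the ratio of
    the two datasets' mean forward-reset magnitudes, e.g.
    ``85 * (9.503 / 10.984) = 73.539``, which motivates the 70th-percentile
    rule for datasets with smaller reset magnitudes.
    """
    if reference_magnitude <= 0:
        raise ValueError("reference magnitude must be positive")
    return reference_percentile * (target_magnitude / reference_magnitude)


# ---------------------------------------------------------------------------
# behavior


def behavior_score(pl_percent: float, ps_percentile: float, clamp: bool = True) -> float:
    """Composite learning score from predictive licking and slowing.

    ``PL/100 + (PS/100 - 0.5)/0.52``, clamped to [0, 1] for reporting.  PL is
    the percent of pre-reward licks; PS the percentile of pre-reward
    deceleration.
    """
    if not (0 <= pl_percent <= 100) or not (0 <= ps_percentile <= 100):
        raise ValueError("PL and PS must lie in [0, 100]")
    score = pl_percent / 100.0 + (ps_percentile / 100.0 - 0.5) / 0.52
    return float(np.clip(score, 0.0, 1.0)) if clamp else float(score)
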