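"""Run-by-run field detection and cross-day linking (Stages 1-4).

Stage 1 detects per-run fields against a circular-rotation shuffle null.
Stage 2 links fields in consecutive runs into segments by COM proximity.
Stage 3 joins segments across missed-field gaps (<= 7 runs) by end/start COMs.
Stage 4 merges fields whose linear COM-vs-run trends extrapolate onto each
other, catching day-boundary resets that break Stage-3 links.  Only fields
with more than ``min_runs`` (8) runs survive to downstream analysis.

Also here: within-day grid-cell classification on 5-cm day-averaged maps and
the landmark-template cue score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import RunActivityMap, TrackLayout

__all__ = [
    "RunField",
    "CrossDayField",
    "LinkParams",
    "detect_run_fields",
    "compute_com",
    "link_adjacent_runs",
    "link_segments",
    "merge_by_trend",
    "track_cell",
    "fields_from_run_lists",
    "normalized_run_field_count",
    "classify_grid_cell_day",
    "day_fields_from_trace",
    "cue_score",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class RunField:
    """One contiguous supra-threshold field in a single run."""

    run_index: int  # 1-based global run counter
    day: int
    start_bin: int
    end_bin: int  # inclusive
    com_cm: float
    mean_value: float
    width_cm: float

    @property
    def bins(self) -> range:
        return range(self.start_bin, self.end_bin + 1)

    def overlap(self, other: "RunField") -> int:
        lo = max(self.start_bin, other.start_bin)
        hi = min(self.end_bin, other.end_bin)
        return max(0, hi - lo + 1)


@dataclass
class CrossDayField:
    """An ordered chain of run fields spanning runs (and possibly days)."""

    run_fields: List[RunField]

    def __post_init__(self) -> None:
        runs = [f.run_index for f in self.run_fields]
        if any(b <= a for a, b in zip(runs, runs[1:])):
            raise ValueError("run fields must have strictly increasing run_index")

    @property
    def runs(self) -> np.ndarray:
        return np.array([f.run_index for f in self.run_fields])

    @property
    def coms(self) -> np.ndarray:
        return np.array([f.com_cm for f in self.run_fields])

    @property
    def n_runs(self) -> int:
        return len(self.run_fields)

    @property
    def first_run(self) -> int:
        return self.run_fields[0].run_index

    @property
    def last_run(self) -> int:
        return self.run_fields[-1].run_index

    @property
    def days(self) -> np.ndarray:
        return np.unique([f.day for f in self.run_fields])

    @property
    def coverage_cm(self) -> float:
        """Track coverage used in link tie-breaks: max COM - min COM."""
        c = self.coms
        return float(c.max() - c.min())

    def trend(self) -> Tuple[float, float]:
        """OLS (slope, intercept) of COM on global run index."""
        return ols_line(self.runs, self.coms)


@dataclass(frozen=True)
class LinkParams:
    """Distance thresholds (cm) and limits for the four linking stages."""

    d_run_cm: float = 10.0
    d_seg_cm: float = 10.0
    d_trend_cm: float = 10.0
    max_width_cm: float = np.inf
    max_gap_runs: int = 7
    min_runs: int = 8  # fields must have MORE than this many runs
    n_shuffles: int = 1000
    crit: float = 0.85
    min_field_bins: int = 3
    min_run_bins: int = 20

    def __post_init__(self) -> None:
        if min(self.d_run_cm, self.d_seg_cm, self.d_trend_cm) <= 0:
            raise ValueError("link distances must be positive")

    @classmethod
    def preset(cls, name: str) -> "LinkParams":
        presets = {
            "dataset1": dict(d_run_cm=28.0, d_seg_cm=28.0, d_trend_cm=28.0, max_width_cm=95.0),
            "dataset2": dict(d_run_cm=32.0, d_seg_cm=38.0, d_trend_cm=34.0, max_width_cm=150.0),
            "simulated": dict(d_run_cm=10.0, d_seg_cm=10.0, d_trend_cm=10.0, max_width_cm=np.inf),
        }
        if name not in presets:
            raise KeyError(f"unknown preset '{name}'; choose from {sorted(presets)}")
        return cls(**presets[name])


def ols_line(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Least-squares (slope, intercept) of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points for a slope")
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    if denom == 0.0:
        raise ValueError("degenerate x values")
    slope = float(dx @ (y - ym)) / denom
    return slope, ym - slope * xm


# ---------------------------------------------------------------------------
# Stage 1: per-run detection


def compute_com(field_values: np.ndarray, bin_centers_cm: np.ndarray) -> float:
    """Activity-weighted centre of mass, in cm at bin centres."""
    v = np.asarray(field_values, dtype=float)
    c = np.asarray(bin_centers_cm, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("COM undefined for all-zero values")
    return float((v * c).sum() / total)


def shuffle_pvalues(trace: np.ndarray, n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Per-bin ``1 - p`` against circular rotations of the same trace.

    Rotation offsets are drawn uniformly (with replacement) from
    ``[0.05 N, 0.95 N]`` samples; ``1 - p`` for a bin is the fraction of
    rotations whose value at that bin falls strictly below the observed one.
    """
    n = trace.size
    lo, hi = int(np.ceil(0.05 * n)), int(np.floor(0.95 * n))
    offsets = rng.integers(lo, hi + 1, size=n_shuffles)
    idx = (np.arange(n)[None, :] + offsets[:, None]) % n
    rotated = trace[idx]  # (n_shuffles, n)
    ge = (rotated >= trace[None, :]).mean(axis=0)
    return 1.0 - ge


def _fields_from_mask(
    sig: np.ndarray,
    trace: np.ndarray,
    run_index: int,
    day: int,
    bin_size: float,
    centers: np.ndarray,
    max_width_cm: float,
    min_bins: int,
) -> List[RunField]:
    labels, n = ndimage.label(sig)
    out: List[RunField] = []
    for lab in range(1, n + 1):
        bins = np.nonzero(labels == lab)[0]
        at_edge = bins[0] == 0 or bins[-1] == sig.size - 1
        need = max(2, min_bins - 1) if at_edge else min_bins
        if bins.size < need:
            continue
        width = bins.size * bin_size
        if width > max_width_cm:
            continue
        vals = trace[bins]
        if vals.sum() <= 0:
            continue
        out.append(
            RunField(
                run_index=run_index,
                day=day,
                start_bin=int(bins[0]),
                end_bin=int(bins[-1]),
                com_cm=compute_com(vals, centers[bins]),
                mean_value=float(vals.mean()),
                width_cm=float(width),
            )
        )
    return out


def detect_run_fields(
    amap: RunActivityMap,
    params: Optional[LinkParams] = None,
    seed: int = 0,
) -> List[List[RunField]]:
    """Stage 1: detect fields in every run of an activity map.

    Returns one (possibly empty) list of :class:`RunField` per run.  Runs with
    fewer than ``params.min_run_bins`` covered bins yield no fields;
    constant-valued runs beat none of their own rotations and also yield none.
    """
    params = params or LinkParams()
    rng = np.random.default_rng(seed)
    centers = amap.bin_centers_cm
    bin_size = amap.bin_size_cm
    out: List[List[RunField]] = []
    for r in range(amap.n_runs):
        trace = amap.values[r]
        covered = amap.coverage_mask[r]
        if covered.sum() < params.min_run_bins:
            out.append([])
            continue
        one_minus_p = shuffle_pvalues(trace, params.n_shuffles, rng)
        sig = (one_minus_p >= params.crit) & covered
        out.append(
            _fields_from_mask(
                sig,
                trace,
                int(amap.run_index[r]),
                int(amap.day_of_run[r]),
                bin_size,
                centers,
                params.max_width_cm,
                params.min_field_bins,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 2: consecutive-run linking


def _lex_best(candidates: List, keys) -> Optional[object]:
    """Lexicographic tie-break ladder; returns None when every level ties."""
    pool = list(candidates)
    for key in keys:
        best = min(key(c) for c in pool)
        pool = [c for c in pool if key(c) == best]
        if len(pool) == 1:
            return pool[0]
    return None


def link_adjacent_runs(
    run_fields: Sequence[List[RunField]],
    d_run_cm: float,
    run_order: Optional[Sequence[int]] = None,
) -> List[CrossDayField]:
    """Stage 2: link each run field to its closest next-run field.

    ``run_fields[i]`` holds the fields of the i-th run in temporal order.
    Forward choice: nearest COM within ``d_run_cm``; ties broken by largest
    bin overlap, then smallest width, then no link.  A next-run field claimed
    by several predecessors keeps the one with smallest COM distance, then
    largest overlap, then smallest width, else links nobody.  Unlinked fields
    are returned as single-run segments for Stage 3.
    """
    n_runs = len(run_fields)
    succ: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for i in range(n_runs - 1):
        cur, nxt = run_fields[i], run_fields[i + 1]
        if not cur or not nxt:
            continue
        claims: Dict[int, List[int]] = {}
        for a, fa in enumerate(cur):
            within = [(b, abs(nxt[b].com_cm - fa.com_cm)) for b in range(len(nxt)) if abs(nxt[b].com_cm - fa.com_cm) <= d_run_cm]
            if not within:
                continue
            dmin = min(d for _, d in within)
            closest = [b for b, d in within if d == dmin]
            if len(closest) > 1:
                pick = _lex_best(
                    closest,
                    [lambda b: -nxt[b].overlap(fa), lambda b: nxt[b].width_cm],
                )
            else:
                pick = closest[0]
            if pick is not None:
                claims.setdefault(pick, []).append(a)
        for b, claimers in claims.items():
            fb = nxt[b]
            if len(claimers) == 1:
                a = claimers[0]
            else:
                a = _lex_best(
                    claimers,
                    [
                        lambda a_: abs(cur[a_].com_cm - fb.com_cm),
                        lambda a_: -cur[a_].overlap(fb),
                        lambda a_: cur[a_].width_cm,
                    ],
                )
            if a is not None:
                succ[(i, a)] = (i + 1, b)

    # walk chains
    has_pred = set(succ.values())
    segments: List[CrossDayField] = []
    for i in range(n_runs):
        for a in range(len(run_fields[i])):
            if (i, a) in has_pred:
                continue
            chain = [run_fields[i][a]]
            node = (i, a)
            while node in succ:
                node = succ[node]
                chain.append(run_fields[node[0]][node[1]])
            segments.append(CrossDayField(chain))
    segments.sort(key=lambda s: (s.first_run, s.coms[0]))
    return segments


# ---------------------------------------------------------------------------
# Stages 3 & 4 share their conflict-resolution ladder


def _drop_skipped(
    segments: List[CrossDayField], cands: List[Tuple[int, float]]
) -> List[Tuple[int, float]]:
    """Drop candidates that lie temporally beyond another qualified candidate.

    Gap bridging exists to cross missed-field runs; a link must not skip over
    a segment that itself qualifies as the continuation, which with noisy
    COMs can otherwise split one trajectory into interleaved chains.
    """
    return [
        (j, d)
        for j, d in cands
        if not any(segments[j2].last_run < segments[j].first_run for j2, _ in cands if j2 != j)
    ]


def _resolve_pairs(
    segments: List[CrossDayField],
    qualified: Dict[int, List[Tuple[int, float]]],
) -> Dict[int, int]:
    """Resolve S1->S2 claims with the (runs, gap, coverage) ladder.

    ``qualified[i]`` lists ``(j, distance)`` candidates for segment ``i``.
    Returns a successor mapping i -> j.  Processing order is ascending
    first-run index; conflicts on a shared successor are resolved with the
    same ladder, greedily.
    """

    def ladder(cands: List[int], anchor: CrossDayField) -> Optional[int]:
        return _lex_best(
            cands,
            [
                lambda j: -segments[j].n_runs,
                lambda j: _gap(anchor, segments[j]),
                lambda j: segments[j].coverage_cm,
            ],
        )

    def _gap(a: CrossDayField, b: CrossDayField) -> int:
        first, second = (a, b) if a.first_run <= b.first_run else (b, a)
        return second.first_run - first.last_run - 1

    forward: Dict[int, int] = {}
    order = sorted(qualified, key=lambda i: (segments[i].first_run, segments[i].coms[0]))
    for i in order:
        cands = qualified[i]
        if not cands:
            continue
        dmin = min(d for _, d in cands)
        closest = [j for j, d in cands if d == dmin]
        pick = closest[0] if len(closest) == 1 else ladder(closest, segments[i])
        if pick is not None:
            forward[i] = pick

    # successor claimed by several predecessors
    claims: Dict[int, List[int]] = {}
    for i, j in forward.items():
        claims.setdefault(j, []).append(i)
    final: Dict[int, int] = {}
    for j, claimers in claims.items():
        if len(claimers) == 1:
            final[claimers[0]] = j
            continue
        pick = _lex_best(
            claimers,
            [
                lambda i_: -segments[i_].n_runs,
                lambda i_: segments[j].first_run - segments[i_].last_run - 1,
                lambda i_: segments[i_].coverage_cm,
            ],
        )
        if pick is not None:
            final[pick] = j
    return final


def _merge_chains(segments: List[CrossDayField], succ: Dict[int, int]) -> Tuple[List[CrossDayField], List[int]]:
    """Union successor links into merged fields; also report unlinked indices."""
    has_pred = set(succ.values())
    merged: List[CrossDayField] = []
    linked = set(succ) | has_pred
    for i, seg in enumerate(segments):
        if i in has_pred:
            continue
        chain = list(seg.run_fields)
        node = i
        while node in succ:
            node = succ[node]
            chain.extend(segments[node].run_fields)
        merged.append(CrossDayField(chain))
    unlinked = [i for i in range(len(segments)) if i not in linked]
    return merged, unlinked


def link_segments(
    segments: List[CrossDayField],
    d_seg_cm: float,
    max_gap: int = 7,
) -> Tuple[List[CrossDayField], List[CrossDayField]]:
    """Stage 3: join segments whose end/start mean COMs (last/first <=3 runs) match.

    Returns ``(putative cross-day fields, leftover multi-run segments)`` — the
    leftovers (unassigned segments with more than one run) feed Stage 4.
    """
    segments = sorted(segments, key=lambda s: (s.first_run, s.coms[0]))
    qualified: Dict[int, List[Tuple[int, float]]] = {}
    for i, s1 in enumerate(segments):
        cands = []
        end_com = s1.coms[-3:].mean()
        for j, s2 in enumerate(segments):
            if s2.first_run <= s1.last_run:
                continue
            gap = s2.first_run - s1.last_run - 1
            if gap > max_gap:
                continue
            dist = abs(end_com - s2.coms[:3].mean())
            if dist <= d_seg_cm:
                cands.append((j, dist))
        cands = _drop_skipped(segments, cands)
        if cands:
            qualified[i] = cands
    succ = _resolve_pairs(segments, qualified)
    merged, _ = _merge_chains(segments, succ)
    # anything that participated in a link is a putative cross-day field;
    # untouched multi-run segments go to Stage 4
    out_fields: List[CrossDayField] = []
    leftovers: List[CrossDayField] = []
    consumed = set(succ) | set(succ.values())
    for m in merged:
        root = next(i for i, s in enumerate(segments) if s.run_fields and s.run_fields[0] is m.run_fields[0])
        if root in consumed:
            out_fields.append(m)
        elif m.n_runs > 1:
            leftovers.append(m)
    return out_fields, leftovers


def merge_by_trend(
    fields: List[CrossDayField],
    d_trend_cm: float,
    max_gap: int = 7,
    min_runs: int = 8,
) -> List[CrossDayField]:
    """Stage 4: merge fields whose linear COM trends extrapolate onto each other.

    For candidate pair (F1 earlier, F2 later, no run overlap, gap <= 7), F1's
    fitted line is extended over F2's runs and vice versa; they merge when
    both mean absolute extension errors are <= ``d_trend_cm``.  Conflicts use
    the Stage-3 ladder.  Only fields with more than ``min_runs`` runs are
    returned.
    """
    fields = sorted(fields, key=lambda s: (s.first_run, s.coms[0]))
    qualified: Dict[int, List[Tuple[int, float]]] = {}
    for i, f1 in enumerate(fields):
        if f1.n_runs < 2:
            continue
        s1, b1 = f1.trend()
        cands = []
        for j, f2 in enumerate(fields):
            if f2.n_runs < 2 or f2.first_run <= f1.last_run:
                continue
            gap = f2.first_run - f1.last_run - 1
            if gap > max_gap:
                continue
            s2, b2 = f2.trend()
            err12 = np.abs(s1 * f2.runs + b1 - f2.coms).mean()
            err21 = np.abs(s2 * f1.runs + b2 - f1.coms).mean()
            if err12 <= d_trend_cm and err21 <= d_trend_cm:
                cands.append((j, float(max(err12, err21))))
        cands = _drop_skipped(fields, cands)
        if cands:
            qualified[i] = cands
    succ = _resolve_pairs(fields, qualified)
    merged, _ = _merge_chains(fields, succ)
    return [f for f in merged if f.n_runs > min_runs]


def track_cell(
    amap: RunActivityMap,
    params: Optional[LinkParams] = None,
    seed: int = 0,
) -> List[CrossDayField]:
    """Full Stage 1-4 pipeline for one cell."""
    params = params or LinkParams()
    per_run = detect_run_fields(amap, params, seed=seed)
    return fields_from_run_lists(per_run, params)


def fields_from_run_lists(per_run: Sequence[List[RunField]], params: LinkParams) -> List[CrossDayField]:
    """Stages 2-4 on already-detected per-run fields."""
    segments = link_adjacent_runs(per_run, params.d_run_cm)
    putative, leftovers = link_segments(segments, params.d_seg_cm, params.max_gap_runs)
    return merge_by_trend(putative + leftovers, params.d_trend_cm, params.max_gap_runs, params.min_runs)


# ---------------------------------------------------------------------------
# normalized run field count


def normalized_run_field_count(amap: RunActivityMap, run_fields: Sequence[List[RunField]]) -> np.ndarray:
    """Fields per cm of covered track, per run.

    First/last runs exclude their leading/trailing stretch of >= 3 consecutive
    uncovered bins (imaging started late / stopped early); middle runs divide
    by the full track length.  A fully uncovered run reports NaN.
    """
    n_runs = amap.n_runs
    counts = np.array([len(fs) for fs in run_fields], dtype=float)
    lengths = np.full(n_runs, amap.layout.length_cm)
    bs = amap.bin_size_cm
    for r, kind in ((0, "lead"), (n_runs - 1, "trail")):
        cov = amap.coverage_mask[r]
        if not cov.any():
            lengths[r] = np.nan
            continue
        if kind == "lead":
            k = int(np.argmax(cov))  # leading uncovered stretch
        else:
            k = int(np.argmax(cov[::-1]))
        if k >= 3:
            lengths[r] = amap.layout.length_cm - k * bs
    return counts / lengths


# ---------------------------------------------------------------------------
# day-level grid cell classification


def _smooth3(trace: np.ndarray) -> np.ndarray:
    from scipy.signal.windows import gaussian

    w = gaussian(3, std=1.0)
    w /= w.sum()
    return np.convolve(trace, w, mode="same")


@dataclass
class DayClassification:
    is_grid: bool
    fields: List[Tuple[int, int]]  # inclusive bin intervals
    field_coms_cm: List[float]
    reasons: Dict[str, bool]


def day_fields_from_trace(
    trace: np.ndarray,
    bin_size_cm: float,
    n_shuffles: int = 1000,
    crit: float = 0.8,
    seed: int = 0,
) -> Tuple[List[Tuple[int, int]], np.ndarray]:
    """Within-day fields on a (smoothed) day-averaged trace.

    Returns inclusive bin intervals (>= 3 bins, >= 2 at track ends) where
    ``1 - p >= crit`` against 1000 circular rotations, plus the per-bin
    ``1 - p`` itself.
    """
    rng = np.random.default_rng(seed)
    one_minus_p = shuffle_pvalues(trace, n_shuffles, rng)
    sig = one_minus_p >= crit
    labels, n = ndimage.label(sig)
    intervals = []
    for lab in range(1, n + 1):
        bins = np.nonzero(labels == lab)[0]
        at_edge = bins[0] == 0 or bins[-1] == trace.size - 1
        if bins.size >= (2 if at_edge else 3):
            intervals.append((int(bins[0]), int(bins[-1])))
    return intervals, one_minus_p


def classify_grid_cell_day(
    amap: RunActivityMap,
    day: int,
    n_shuffles: int = 1000,
    seed: int = 0,
    transient_threshold: float = 0.0,
) -> DayClassification:
    """Within-day grid-cell test on the run-averaged, 5-cm-binned, smoothed map.

    Criteria: >= 2 fields; more than L/(5w) in/out transitions (w = mean field
    width); widest field < 5w; >= 30% of bins assigned in- or out-of-field;
    in/out mean activity ratio >= 2; and >= 10% of runs showing a transient
    inside some field.
    """
    rows = amap.day_slice(day)
    values = amap.values[rows]
    trace5, runs5 = _rebin_to(values, amap.layout, 5.0)
    day_avg = _smooth3(trace5.mean(axis=0))
    intervals, one_minus_p = day_fields_from_trace(day_avg, 5.0, n_shuffles, 0.8, seed)

    centers = (np.arange(day_avg.size) + 0.5) * 5.0
    # runs with a transient inside any field
    if intervals:
        in_mask = np.zeros(day_avg.size, dtype=bool)
        for a, b in intervals:
            in_mask[a : b + 1] = True
        frac_active = float(np.mean(trace5[:, in_mask].max(axis=1) > transient_threshold))
        intervals = intervals if frac_active >= 0.10 else []
    coms = [compute_com(day_avg[a : b + 1], centers[a : b + 1]) for a, b in intervals]

    reasons: Dict[str, bool] = {}
    if not intervals:
        return DayClassification(False, [], [], {"has_fields": False})
    widths = np.array([(b - a + 1) * 5.0 for a, b in intervals])
    w = widths.mean()
    L = amap.layout.length_cm
    in_field = one_minus_p >= 0.8
    out_field = one_minus_p <= 0.2
    assigned = in_field | out_field
    labels = np.where(in_field, 1, np.where(out_field, -1, 0))
    seq = labels[labels != 0]
    transitions = int(np.sum(seq[1:] != seq[:-1]))
    reasons["two_fields"] = len(intervals) >= 2
    reasons["transitions"] = transitions > L / (5 * w)
    reasons["max_width"] = widths.max() < 5 * w
    reasons["assigned_bins"] = assigned.mean() >= 0.30
    out_mean = day_avg[out_field].mean() if out_field.any() else 0.0
    in_mean = day_avg[in_field].mean() if in_field.any() else 0.0
    reasons["contrast"] = out_mean > 0 and (in_mean / out_mean) >= 2.0 or (in_mean > 0 and out_mean == 0)
    return DayClassification(all(reasons.values()), intervals, coms, reasons)


def _rebin_to(values: np.ndarray, layout: TrackLayout, bin_size_cm: float) -> Tuple[np.ndarray, int]:
    """Average runs x bins activity into coarser bins (sizes must nest)."""
    n_runs, n_bins = values.shape
    cur = layout.length_cm / n_bins
    factor = bin_size_cm / cur
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("bin sizes do not nest")
    factor = int(round(factor))
    if factor == 1:
        return values, n_bins
    n_new = n_bins // factor
    return values[:, : n_new * factor].reshape(n_runs, n_new, factor).mean(axis=2), n_new


# ---------------------------------------------------------------------------
# cue score


def _zone_template(layout: TrackLayout, bin_size: float, landmark_width_cm: float, side: str) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    n_bins = int(round(layout.length_cm / bin_size))
    template = np.zeros(n_bins)
    zones: List[Tuple[int, int]] = []
    sides = layout.landmark_sides or tuple("B" * len(layout.landmark_edges_cm))
    half = landmark_width_cm / 2.0
    for edge, s in zip(layout.landmark_edges_cm, sides):
        if side != "both" and s != "B" and s.upper()[0] != side.upper()[0]:
            continue
        lm_lo, lm_hi = edge, edge + landmark_width_cm
        z_lo, z_hi = lm_lo - half, lm_hi + half
        b0 = max(0, int(np.floor(z_lo / bin_size)))
        b1 = min(n_bins - 1, int(np.ceil(z_hi / bin_size)) - 1)
        l0 = max(0, int(np.floor(lm_lo / bin_size)))
        l1 = min(n_bins - 1, int(np.ceil(lm_hi / bin_size)) - 1)
        template[l0 : l1 + 1] = 1.0
        zones.append((b0, b1))
    if not zones:
        raise ValueError(f"no landmarks of side '{side}' in layout")
    return template, zones


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0  # constant-trace convention
    return float(np.corrcoef(a, b)[0, 1])


def _score_against(activity: np.ndarray, template: np.ndarray, zones: List[Tuple[int, int]]) -> float:
    shifts = np.arange(activity.size)
    best, best_corr = 0, -np.inf
    for s in shifts:
        c = _safe_corr(np.roll(activity, s), template)
        if c > best_corr:
            best_corr, best = c, s
    shifted = np.roll(activity, best)
    per_zone = [_safe_corr(shifted[a : b + 1], template[a : b + 1]) for a, b in zones]
    return float(np.mean(per_zone))


def cue_score(
    day_trace: np.ndarray,
    layout: TrackLayout,
    side: str = "both",
    landmark_width_cm: float = 10.0,
    n_shuffles: int = 200,
    percentile: float = 80.0,
    seed: int = 0,
) -> Tuple[float, bool, np.ndarray]:
    """Cue-template match score and shuffle-based cue-cell call.

    The activity is circularly shifted to best match a 0/1 landmark template;
    the score is the mean correlation with the template inside each landmark
    zone (landmark +/- half its width).  Shuffles randomise landmark locations
    in the template; the cell is a cue cell when its score exceeds the
    ``percentile``-th percentile of the pooled shuffle scores.
    """
    rng = np.random.default_rng(seed)
    bin_size = layout.length_cm / day_trace.size
    template, zones = _zone_template(layout, bin_size, landmark_width_cm, side)
    score = _score_against(day_trace, template, zones)
    n_lm = len(zones)
    shuffles = np.empty(n_shuffles)
    for k in range(n_shuffles):
        edges = np.sort(rng.uniform(landmark_width_cm, layout.length_cm - 2 * landmark_width_cm, n_lm))
        fake = TrackLayout(layout.length_cm, tuple(edges), None, layout.bin_size_cm)
        t_k, z_k = _zone_template(fake, bin_size, landmark_width_cm, "both")
        shuffles[k] = _score_against(day_trace, t_k, z_k)
    return score, bool(score > np.percentile(shuffles, percentile)), shuffles
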