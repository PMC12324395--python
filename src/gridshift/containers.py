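"""Shared data containers for track geometry, activity maps and seeded randomness.

All track coordinates are centimetres from the track start.  Spatial bins are
half-open ``[k*bin, (k+1)*bin)`` and centres of mass are reported at bin
centres.  Runs are ordered by ``(day, within-day order)`` and carry a 1-based
global run counter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["TrackLayout", "RunActivityMap", "RngPolicy"]


@dataclass(frozen=True)
class TrackLayout:
    """Geometry of a 1D virtual track.

    Parameters
    ----------
    length_cm
        Total track length in cm.
    landmark_edges_cm
        Front-edge positions of the visual landmarks, strictly increasing and
        strictly inside ``(0, length_cm)``.  The start and end of the track
        count as landmarks as well; use :attr:`anchors_cm` for the full set.
    reward_span_cm
        Optional closed ``(lo, hi)`` interval containing the reward.
    bin_size_cm
        Width of the spatial bins; ``length_cm`` must be an integer multiple.
    landmark_sides
        Optional per-landmark side labels (``"L"``/``"R"``) used by the
        cue-cell analysis; ``None`` means sides are unknown/ignored.
    """

    length_cm: float
    landmark_edges_cm: Tuple[float, ...] = ()
    reward_span_cm: Optional[Tuple[float, float]] = None
    bin_size_cm: float = 2.5
    landmark_sides: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmark_edges_cm", tuple(float(x) for x in self.landmark_edges_cm))
        if self.length_cm <= 0:
            raise ValueError("length_cm must be positive")
        if self.bin_size_cm <= 0:
            raise ValueError("bin_size_cm must be positive")
        n = self.length_cm / self.bin_size_cm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"length_cm={self.length_cm} is not an integer multiple of bin_size_cm={self.bin_size_cm}"
            )
        edges = self.landmark_edges_cm
        if any(not (0.0 < e < self.length_cm) for e in edges):
            raise ValueError("landmark edges must lie strictly inside (0, length)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("landmark edges must be strictly increasing")
        if self.reward_span_cm is not None:
            lo, hi = self.reward_span_cm
            if not (0 <= lo <= hi <= self.length_cm):
                raise ValueError("reward span must be an ordered interval within the track")
        if self.landmark_sides is not None and len(self.landmark_sides) != len(edges):
            raise ValueError("landmark_sides must match landmark_edges_cm in length")

    @property
    def n_bins(self) -> int:
        return int(round(self.length_cm / self.bin_size_cm))

    @property
    def anchors_cm(self) -> Tuple[float, ...]:
        """Landmark anchor set including the track start and end."""
        return (0.0,) + self.landmark_edges_cm + (self.length_cm,)

    def bin_centers(self, bin_size_cm: Optional[float] = None) -> np.ndarray:
        """Bin-centre coordinates in cm, optionally for a different bin size."""
        b = self.bin_size_cm if bin_size_cm is None else float(bin_size_cm)
        n = self.length_cm / b
        if abs(n - round(n)) > 1e-9:
            raise ValueError("length_cm is not an integer multiple of the requested bin size")
        return (np.arange(int(round(n))) + 0.5) * b

    def with_bin_size(self, bin_size_cm: float) -> "TrackLayout":
        return TrackLayout(
            self.length_cm, self.landmark_edges_cm, self.reward_span_cm, bin_size_cm, self.landmark_sides
        )


@dataclass
class RunActivityMap:
    """Runs × track-bins activity of one cell, with per-run day labels.

    ``values`` holds non-negative, finite ΔF/F-like amplitudes.  Bins without
    data (e.g. imaging started mid-run) are marked ``False`` in
    ``coverage_mask``; their ``values`` entries are zero but are
    distinguishable from true zeros through the mask.
    """

    cell_id: str
    values: np.ndarray
    day_of_run: np.ndarray
    layout: TrackLayout
    run_index: Optional[np.ndarray] = None
    coverage_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a runs x bins matrix")
        n_runs, n_bins = self.values.shape
        self.day_of_run = np.asarray(self.day_of_run, dtype=int)
        if self.day_of_run.shape != (n_runs,):
            raise ValueError("day_of_run must have one entry per run")
        if np.any(self.day_of_run < 1):
            raise ValueError("days are 1-based positive integers")
        if np.any(np.diff(self.day_of_run) < 0):
            raise ValueError(f"cell {self.cell_id}: day_of_run must be non-decreasing")
        if self.run_index is None:
            self.run_index = np.arange(1, n_runs + 1)
        self.run_index = np.asarray(self.run_index, dtype=int)
        if self.run_index.shape != (n_runs,) or np.any(np.diff(self.run_index) <= 0):
            raise ValueError("run_index must be strictly increasing, one per run")
        if self.coverage_mask is None:
            self.coverage_mask = np.ones_like(self.values, dtype=bool)
        self.coverage_mask = np.asarray(self.coverage_mask, dtype=bool)
        if self.coverage_mask.shape != self.values.shape:
            raise ValueError("coverage_mask must match values in shape")
        bad = ~np.isfinite(self.values)
        if np.any(bad):
            runs, bins = np.nonzero(bad)
            locs = ", ".join(f"({self.cell_id}, run {self.run_index[r]}, bin {b})" for r, b in zip(runs[:5], bins[:5]))
            raise ValueError(f"non-finite values at {locs}")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")
        self.values = self.values.copy()
        self.values[~self.coverage_mask] = 0.0

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_size_cm(self) -> float:
        return self.layout.length_cm / self.n_bins

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size_cm

    @property
    def days(self) -> np.ndarray:
        return np.unique(self.day_of_run)

    def day_slice(self, day: int) -> np.ndarray:
        """Row indices of the runs belonging to ``day``."""
        return np.nonzero(self.day_of_run == day)[0]

    def day_average(self, day: Optional[int] = None) -> np.ndarray:
        rows = self.values if day is None else self.values[self.day_slice(day)]
        return rows.mean(axis=0)


class RngPolicy:
    """Deterministic named random streams derived from one master seed.

    Every stochastic stage draws its generator from ``stream(label)`` so that
    re-running the whole pipeline with the same master seed reproduces all
    outputs bit-for-bit, independently of execution order.
    """

    def __init__(self, master_seed: int):
        if not (0 <= int(master_seed) < 2**63):
            raise ValueError("master_seed must be a non-negative integer")
        self.master_seed = int(master_seed)

    def seed_for(self, label: str) -> int:
        return np.random.SeedSequence([self.master_seed, zlib.crc32(label.encode("utf-8"))]).generate_state(1)[0]

    def stream(self, label: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, zlib.crc32(label.encode("utf-8"))])
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngPolicy(master_seed={self.master_seed})"
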