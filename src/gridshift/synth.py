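"""Synthetic run-by-run activity with known ground truth.

Two generators cover the phenomenology the analysis pipeline is built for:

* :func:`generate_cell` plants one or more drifting Gaussian fields in a
  single cell — configurable backward slope (cm/run), landmark-anchored drift
  arrest, per-run COM jitter, per-run field misses, and a forward reset
  ("regression") applied at each day boundary.
* :func:`generate_module` builds a co-modular population as 1D slices of a
  shared 2D triangular lattice, so the spatial frequencies obey
  ``f3 = f1 + f2`` exactly and every cell rides one phase torus.  Population
  phase drifts and discontinuities ("jumps") at chosen track positions are
  shared by all cells, mimicking coherent low-dimensional dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import RunActivityMap, TrackLayout

__all__ = [
    "PlantedField",
    "ModuleSpec",
    "GroundTruth",
    "generate_cell",
    "generate_module",
    "default_layout",
]


def default_layout(bin_size_cm: float = 2.5) -> TrackLayout:
    """The study-condition track: 1000 cm, eight landmarks, reward near the end."""
    return TrackLayout(
        length_cm=1000.0,
        landmark_edges_cm=(100.0, 220.0, 340.0, 460.0, 580.0, 700.0, 800.0, 863.0),
        reward_span_cm=(863.0, 909.0),
        bin_size_cm=bin_size_cm,
    )


@dataclass
class PlantedField:
    """Ground-truth description of one drifting spatial field.

    ``slope_cm_per_run`` is the per-run COM drift (negative = backward).  When
    ``anchor`` names a landmark (index into ``layout.anchors_cm``), the drift
    decays linearly to zero within ``arrest_halfwidth_cm`` of that anchor, so
    the field stalls there instead of crossing it.  ``day_regression_cm`` is a
    forward reset applied at each day boundary.
    """

    com0_cm: float
    slope_cm_per_run: float = 0.0
    anchor: Optional[int] = None
    arrest_halfwidth_cm: float = 50.0
    width_cm: float = 30.0
    amplitude: float = 1.0
    com_jitter_sd_cm: float = 0.0
    miss_prob: float = 0.0
    day_regression_cm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob < 1.0):
            raise ValueError("miss_prob must be in [0, 1)")
        if self.width_cm <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")


@dataclass
class ModuleSpec:
    """A co-modular population sharing one triangular lattice.

    ``spacing_cm`` is the grid period of the underlying 2D lattice and
    ``slice_angle`` the angle of the 1D track cut through it, which together
    fix the slice frequencies ``f1 < f2 < f3 = f1 + f2``.  Per-cell phase
    offsets are fixed across runs and days; planted jumps and per-day drifts
    apply to the whole population.
    """

    n_cells: int = 12
    spacing_cm: float = 80.0
    slice_angle: float = 0.26  # radians off the lattice bisector; keeps f1, f2 resolvable
    phase_offsets: Optional[np.ndarray] = None  # (n_cells, 2) in radians
    planted_jumps: Sequence[Tuple[float, Tuple[float, float]]] = ()
    drift_per_day: Tuple[float, float] = (0.0, 0.0)  # phase offset added per day
    rotation_per_day: Tuple[float, float] = (0.0, 0.0)  # phase slope (rad/cm) added per day
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be positive")

    def slice_frequencies(self) -> Tuple[float, float, float]:
        """Spatial frequencies (cycles/cm) of the track slice.

        The lattice has wavevectors ``k_a``, ``k_b`` at 60 degrees with
        ``|k| = 4*pi/(sqrt(3)*spacing)``; the slice direction is rotated by
        ``slice_angle`` from the bisector.  Projections give three positive
        frequencies with ``f3 = f1 + f2`` exactly by construction.
        """
        k = 4 * math.pi / (math.sqrt(3) * self.spacing_cm)
        # wavevectors at +/-30 degrees around the slice bisector, plus angle
        a1 = math.pi / 6 + self.slice_angle
        a2 = -math.pi / 6 + self.slice_angle
        f1 = abs(k * math.cos(a1)) / (2 * math.pi)
        f2 = abs(k * math.cos(a2)) / (2 * math.pi)
        if min(f1, f2) < 1e-9:
            raise ValueError("degenerate slice: angle aligned with a lattice axis")
        lo, hi = sorted((f1, f2))
        return lo, hi, lo + hi


@dataclass
class GroundTruth:
    """Planted quantities, recoverable from the generator spec + RNG stream."""

    true_com_cm: Optional[np.ndarray] = None  # (n_fields, n_runs), NaN where missed
    present: Optional[np.ndarray] = None  # (n_fields, n_runs) bool
    warnings: List[str] = field(default_factory=list)
    # module-level truth
    frequencies: Optional[Tuple[float, float, float]] = None
    phase_offsets: Optional[np.ndarray] = None  # (n_cells, 3) planted FFT phases
    phase_drift: Optional[np.ndarray] = None  # (n_days, n_bins1cm, 3) population phase offsets
    jump_positions: Optional[np.ndarray] = None


def _runs_schedule(plan: Sequence[int]) -> np.ndarray:
    plan = np.asarray(plan, dtype=int)
    if plan.ndim != 1 or np.any(plan < 1):
        raise ValueError("plan must give a positive number of runs per day")
    return np.repeat(np.arange(1, len(plan) + 1), plan)


def _com_trajectory(f: PlantedField, day_of_run: np.ndarray, layout: TrackLayout) -> Tuple[np.ndarray, List[str]]:
    coms = np.empty(day_of_run.size)
    warns: List[str] = []
    com = float(f.com0_cm)
    anchor_pos = None if f.anchor is None else layout.anchors_cm[f.anchor]
    for t in range(day_of_run.size):
        if t > 0:
            if day_of_run[t] != day_of_run[t - 1] and f.day_regression_cm:
                com += f.day_regression_cm
            step = f.slope_cm_per_run
            if anchor_pos is not None and f.arrest_halfwidth_cm > 0:
                # drift decays linearly to zero within the arrest zone, so the
                # field approaches but never crosses its anchor
                dist = abs(com - anchor_pos)
                step *= min(1.0, dist / f.arrest_halfwidth_cm)
            com += step
        if not (0.0 <= com <= layout.length_cm):
            clipped = float(np.clip(com, 0.0, layout.length_cm))
            warns.append(f"run {t + 1}: COM {com:.1f} cm clipped to {clipped:.1f} cm")
            com = clipped
        coms[t] = com
    return coms, warns


def generate_cell(
    spec: Sequence[PlantedField],
    plan: Sequence[int],
    layout: Optional[TrackLayout] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    cell_id: str = "synth",
) -> Tuple[RunActivityMap, GroundTruth]:
    """Generate one cell's runs × bins activity from planted fields.

    Each present field is a Gaussian bump (sigma = width/4) at the drifted,
    jittered COM; additive Gaussian noise is truncated at zero.  The returned
    :class:`GroundTruth` records the noiseless COM trajectory per field and a
    presence mask (``miss_prob`` gates whole-run misses).
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    day_of_run = _runs_schedule(plan)
    n_runs = day_of_run.size
    centers = layout.bin_centers()
    values = np.zeros((n_runs, centers.size))

    fields = list(spec)
    for f in fields:
        if f.width_cm < 3 * layout.bin_size_cm:
            raise ValueError("planted width must span at least 3 bins for detectability")

    true_com = np.full((len(fields), n_runs), np.nan)
    present = np.ones((len(fields), n_runs), dtype=bool)
    gt = GroundTruth(true_com_cm=true_com, present=present)

    for i, f in enumerate(fields):
        coms, warns = _com_trajectory(f, day_of_run, layout)
        gt.warnings.extend(f"field {i}: {w}" for w in warns)
        miss = rng.random(n_runs) < f.miss_prob
        jitter = rng.normal(0.0, f.com_jitter_sd_cm, n_runs) if f.com_jitter_sd_cm else np.zeros(n_runs)
        present[i] = ~miss
        true_com[i] = np.where(miss, np.nan, coms)
        sigma = f.width_cm / 4.0
        obs = np.clip(coms + jitter, 0.0, layout.length_cm)
        bump = f.amplitude * np.exp(-((centers[None, :] - obs[:, None]) ** 2) / (2 * sigma**2))
        bump[miss] = 0.0
        values += bump

    if noise_sd > 0:
        values = np.maximum(values + rng.normal(0.0, noise_sd, values.shape), 0.0)
    amap = RunActivityMap(cell_id=cell_id, values=values, day_of_run=day_of_run, layout=layout)
    return amap, gt


def generate_module(
    mspec: ModuleSpec,
    plan: Sequence[int],
    layout: Optional[TrackLayout] = None,
    noise_sd: float = 0.05,
    noise_corr_cm: float = 3.0,
    seed: int = 0,
) -> Tuple[List[RunActivityMap], GroundTruth]:
    """Generate a co-modular population riding one 2D phase torus.

    Cell *i*'s noiseless rate on the 1-cm-binned track is::

        r_i(x) = A/2 * (1 + mean_j cos(2*pi*f_j*x + D_j(day, x) + phi_ij))

    with ``j in {1,2,3}``, per-cell phases satisfying ``phi_i3 = phi_i1 +
    phi_i2`` (one 2D torus), and population terms ``D_j`` holding per-day
    drifts/rotations and planted jumps, identical across cells.  The FFT phase
    a spectral analysis recovers at ``f_j`` equals ``phi_ij`` (plus the shared
    population term), which the ground truth records.
    """
    layout = layout or default_layout(bin_size_cm=1.0)
    if abs(layout.bin_size_cm - 1.0) > 1e-9:
        layout = layout.with_bin_size(1.0)
    rng = np.random.default_rng(seed)
    day_of_run = _runs_schedule(plan)
    n_days = int(day_of_run.max())
    x = layout.bin_centers()
    f1, f2, f3 = mspec.slice_frequencies()

    if mspec.phase_offsets is None:
        # Default: an exact product grid over the rhombus (randomly offset).
        # A uniform p x q grid makes every finite-population cross term of the
        # rate-weighted circular mean cancel identically, so the recovered
        # population phase is unbiased; non-factorable counts fall back to a
        # low-discrepancy spread.
        n = mspec.n_cells
        p = next((d for d in range(int(math.isqrt(n)), 0, -1) if n % d == 0), 1)
        u = rng.uniform(0, 1, size=2)
        if p > 1:
            q = n // p
            a, b = np.meshgrid(np.arange(q), np.arange(p))
            offsets = 2 * math.pi * np.column_stack([(a.ravel() / q + u[0]) % 1.0, (b.ravel() / p + u[1]) % 1.0])
        else:
            g = 1.32471795724474602596  # plastic constant
            k = np.arange(n)
            offsets = 2 * math.pi * np.column_stack([(k / g + u[0]) % 1.0, (k / g**2 + u[1]) % 1.0])
    else:
        offsets = np.asarray(mspec.phase_offsets, dtype=float)
        if offsets.shape != (mspec.n_cells, 2):
            raise ValueError("phase_offsets must be (n_cells, 2)")
    phi = np.column_stack([offsets[:, 0], offsets[:, 1], offsets[:, 0] + offsets[:, 1]])

    # population phase terms per day and position, shared by all cells
    drift = np.zeros((n_days, x.size, 3))
    for d in range(n_days):
        d0 = np.array([mspec.drift_per_day[0] * d, mspec.drift_per_day[1] * d])
        rot = np.array([mspec.rotation_per_day[0] * d, mspec.rotation_per_day[1] * d])
        comp12 = d0[None, :] + rot[None, :] * x[:, None]
        for pos, (j1, j2) in mspec.planted_jumps:
            step = (x >= pos).astype(float)
            comp12 = comp12 + step[:, None] * np.array([j1, j2])[None, :]
        drift[d, :, :2] = comp12
        drift[d, :, 2] = comp12.sum(axis=1)

    freqs = np.array([f1, f2, f3])
    maps: List[RunActivityMap] = []
    for i in range(mspec.n_cells):
        values = np.zeros((day_of_run.size, x.size))
        for t, day in enumerate(day_of_run):
            theta = 2 * math.pi * freqs[None, :] * x[:, None] + drift[day - 1] + phi[i][None, :]
            rate = mspec.amplitude * 0.5 * (1.0 + np.cos(theta).mean(axis=1))
            values[t] = rate
        if noise_sd > 0:
            # calcium-indicator dynamics smear noise along the track, so at
            # 1-cm binning the noise is spatially correlated, not i.i.d.
            noise = rng.normal(0.0, 1.0, values.shape)
            if noise_corr_cm > 0:
                sigma_bins = noise_corr_cm / layout.bin_size_cm
                noise = ndimage.gaussian_filter1d(noise, sigma_bins, axis=1, mode="wrap")
                noise /= noise.std()
            values = np.maximum(values + noise_sd * noise, 0.0)
        maps.append(
            RunActivityMap(cell_id=f"mod{i:03d}", values=values, day_of_run=day_of_run.copy(), layout=layout)
        )

    gt = GroundTruth(
        frequencies=(f1, f2, f3),
        phase_offsets=phi,
        phase_drift=drift,
        jump_positions=np.array([p for p, _ in mspec.planted_jumps]),
    )
    return maps, gt
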