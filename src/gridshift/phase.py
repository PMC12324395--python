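"""Toroidal population-phase analysis of co-modular grid cells.

Per-cell spatial spectra come from a Welch periodogram (Hamming 512, 2992-pt
transform, overlap 461, rate 1000 on 1-cm bins); the three largest detrended
peaks above 0.006 cycles/cm give the slice frequencies f1 < f2 < f3 and, via
the 2992-point FFT angle, the cell's phases.  A module qualifies when it has
more than 10 cells and |avg f1 + avg f2 - avg f3| < 8% of avg f3.  The
population phase trajectory is the rate-weighted circular mean of the cell
phases as a function of track position; distances, rotations, lateral shifts
and per-run phase jumps are measured in sheared (rhombus) coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .containers import TrackLayout

__all__ = [
    "SpectralPeaks",
    "PhaseTrajectory",
    "ModuleGroup",
    "cell_spectrum",
    "assign_modules",
    "qualify_module",
    "run_correlation",
    "field_trajectory_correlation",
    "shear",
    "shear_phases",
    "population_phase",
    "trajectory_distance",
    "trajectory_rotation",
    "lateral_shift",
    "phase_jumps",
    "influence_index",
]

FREQ_MIN = 0.006  # cycles/cm; lower peaks are low-frequency noise
DETREND_BAND = (0.001, 0.150)  # cycles/cm band for the linear PSD detrend
NFFT = 2992
NPERSEG = 512
NOVERLAP = 461
FS = 1000.0  # samples per track; 1 frequency unit = 0.001 cycles/cm


@dataclass(frozen=True)
class SpectralPeaks:
    """Top-three spectral peaks of a cell's day-averaged spatial activity."""

    freqs: Tuple[float, float, float]  # cycles/cm, ascending
    powers: Tuple[float, float, float]
    phases: Tuple[float, float, float]  # radians, from the 2992-pt FFT angle

    @property
    def f1(self) -> float:
        return self.freqs[0]

    @property
    def f2(self) -> float:
        return self.freqs[1]

    @property
    def f3(self) -> float:
        return self.freqs[2]


@dataclass
class PhaseTrajectory:
    """Unwrapped population phase (Psi1, Psi2) along the track."""

    x_cm: np.ndarray
    psi: np.ndarray  # (n_bins, 2), unwrapped radians
    flagged: np.ndarray = None  # bins where the resultant vanished
    source: str = "day-averaged"

    def __post_init__(self) -> None:
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.shape != (self.x_cm.size, 2):
            raise ValueError("psi must be (n_bins, 2)")
        if self.flagged is None:
            self.flagged = np.zeros(self.x_cm.size, dtype=bool)

    @property
    def start(self) -> np.ndarray:
        return self.psi[0]


@dataclass
class ModuleGroup:
    """Cells sharing one grid spacing (and hence one phase torus)."""

    cell_ids: List[str]
    spacings_cm: Dict[str, float]
    qualifying: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# spectra


def cell_spectrum(trace: np.ndarray) -> Optional[SpectralPeaks]:
    """Welch spectrum + FFT phases for one day-averaged 1-cm-binned trace.

    Returns ``None`` when fewer than three qualifying peaks exist (the cell is
    then excluded from phase analysis).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size != int(FS):
        raise ValueError(f"expected a {int(FS)}-sample (1-cm-binned) trace")
    f_hz, psd = signal.welch(
        trace,
        fs=FS,
        window=signal.windows.hamming(NPERSEG, sym=False),
        nperseg=NPERSEG,
        noverlap=NOVERLAP,
        nfft=NFFT,
        detrend="constant",
        scaling="density",
    )
    f_cm = f_hz / 1000.0  # cycles/cm
    band = (f_cm >= DETREND_BAND[0]) & (f_cm <= DETREND_BAND[1])
    det = psd.copy()
    det[band] = signal.detrend(psd[band], type="linear")

    # strict local maxima above the frequency floor, ranked by detrended power
    peaks, _ = signal.find_peaks(det)
    peaks = peaks[f_cm[peaks] > FREQ_MIN]
    if peaks.size < 3:
        return None
    top = peaks[np.argsort(det[peaks])[::-1][:3]]
    top = top[np.argsort(f_cm[top])]
    freqs = tuple(float(f) for f in f_cm[top])
    powers = tuple(float(p) for p in psd[top])

    spectrum = np.fft.fft(trace - trace.mean(), NFFT)
    phases = tuple(float(np.angle(spectrum[k])) for k in top)
    return SpectralPeaks(freqs=freqs, powers=powers, phases=phases)


def fft_phases(trace: np.ndarray, freqs_cm: Sequence[float]) -> Tuple[float, ...]:
    """FFT phases of a 1-cm-binned trace at the grid bins nearest ``freqs_cm``."""
    trace = np.asarray(trace, dtype=float)
    spectrum = np.fft.fft(trace - trace.mean(), NFFT)
    ks = [int(round(f * 1000.0 * NFFT / FS)) for f in freqs_cm]
    return tuple(float(np.angle(spectrum[k])) for k in ks)


def module_day_phases(traces: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Per-cell phases of one module-day at the module-average frequencies.

    Co-modular cells share the slice frequencies exactly, so per-cell peak
    positions differ only by estimation jitter; evaluating every cell's FFT
    angle at the same (module-averaged) frequency bins keeps the per-cell
    phases mutually consistent for the population circular mean.  Returns
    ``(freqs, phases (n_kept, 3), kept_indices)``; cells without three
    qualifying peaks are dropped.
    """
    peaks = [cell_spectrum(t) for t in traces]
    kept = [i for i, p in enumerate(peaks) if p is not None]
    if not kept:
        raise ValueError("no cell produced three qualifying spectral peaks")
    freqs = np.mean([peaks[i].freqs for i in kept], axis=0)
    phases = np.array([fft_phases(traces[i], freqs) for i in kept])
    return freqs, phases, kept


def qualify_module(per_day_peaks: Sequence[Sequence[SpectralPeaks]], min_cells: int = 10) -> Tuple[bool, Tuple[float, float, float]]:
    """Module-qualification test on per-day, per-cell spectral peaks.

    Averages f1..f3 over cells within each day, then over days; qualifies iff
    the member count exceeds ``min_cells`` and |avgf1 + avgf2 - avgf3| is
    within 8% of avgf3.
    """
    day_means = []
    n_cells = 0
    for day in per_day_peaks:
        fs = np.array([p.freqs for p in day if p is not None])
        if fs.size == 0:
            continue
        n_cells = max(n_cells, len(fs))
        day_means.append(fs.mean(axis=0))
    if not day_means:
        return False, (np.nan, np.nan, np.nan)
    avg = np.mean(day_means, axis=0)
    ok = n_cells > min_cells and abs(avg[0] + avg[1] - avg[2]) < 0.08 * avg[2]
    return bool(ok), (float(avg[0]), float(avg[1]), float(avg[2]))


# ---------------------------------------------------------------------------
# module assignment


def assign_modules(cell_spacings: Dict[str, float], bandwidth: Optional[float] = None) -> List[ModuleGroup]:
    """Group cells into modules from the peaks of their spacing density.

    A Gaussian kernel estimate of the pooled spacing distribution is scanned
    for peaks; the valleys between them split the cells into modules.  A
    unimodal density yields a single module.
    """
    if not cell_spacings:
        raise ValueError("no cell spacings given")
    ids = sorted(cell_spacings)
    vals = np.array([cell_spacings[c] for c in ids], dtype=float)
    if np.ptp(vals) < 1e-12:
        return [ModuleGroup(ids, dict(cell_spacings))]
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(vals.min() - 3 * vals.std(), vals.max() + 3 * vals.std(), 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens)
    if peaks.size <= 1:
        return [ModuleGroup(ids, dict(cell_spacings))]
    valleys = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        valleys.append(grid[a + int(np.argmin(dens[a:b]))])
    edges = [-np.inf, *valleys, np.inf]
    groups: List[ModuleGroup] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [c for c, v in zip(ids, vals) if lo < v <= hi]
        if members:
            groups.append(ModuleGroup(members, {c: cell_spacings[c] for c in members}))
    return groups


# ---------------------------------------------------------------------------
# population coherence


def run_correlation(
    activity: np.ndarray,
    run_pairs: Sequence[Tuple[int, int]],
    n_shuffle: int = 100,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Correlation of pairwise cell-cell correlation vectors between runs.

    ``activity`` is (n_cells, n_runs, n_bins).  For each run the pairwise
    Pearson correlations of all cell pairs form a vector; the run correlation
    of a pair of runs is the Pearson correlation between their vectors.  The
    shuffle control permutes cell identity in the second run of each pair.
    Constant cell traces have their pairs excluded.
    """
    n_cells = activity.shape[0]
    if n_cells < 6:
        raise ValueError("need at least 6 cells per module")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_cells, k=1)

    def pair_vector(run: int, order: Optional[np.ndarray] = None) -> np.ndarray:
        mat = activity[:, run, :]
        if order is not None:
            mat = mat[order]
        sd = mat.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.corrcoef(mat)
        cc[sd == 0, :] = np.nan
        cc[:, sd == 0] = np.nan
        return cc[iu]

    obs = np.empty(len(run_pairs))
    shuf = np.empty((len(run_pairs), n_shuffle))
    for k, (ra, rb) in enumerate(run_pairs):
        va, vb = pair_vector(ra), pair_vector(rb)
        good = np.isfinite(va) & np.isfinite(vb)
        obs[k] = np.corrcoef(va[good], vb[good])[0, 1] if good.sum() > 2 else np.nan
        for s in range(n_shuffle):
            vb_s = pair_vector(rb, rng.permutation(n_cells))
            good = np.isfinite(va) & np.isfinite(vb_s)
            shuf[k, s] = np.corrcoef(va[good], vb_s[good])[0, 1] if good.sum() > 2 else np.nan
    return obs, shuf


def field_trajectory_correlation(
    fields: Sequence,
    bin_cm: float = 20.0,
    min_overlap: int = 5,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """COM-trajectory correlation of field pairs vs their track distance.

    ``fields`` holds (cell_id, CrossDayField) pairs from co-modular cells.
    Pairs from different cells sharing >= ``min_overlap`` runs contribute a
    Pearson correlation over the shared runs; pair distance is the absolute
    difference of their median COMs.  Correlations are averaged in
    ``bin_cm``-wide distance bins; the Pearson trend across bin centres is
    returned as the third element.
    """
    dists, corrs = [], []
    for i in range(len(fields)):
        for j in range(i + 1, len(fields)):
            cid_a, fa = fields[i]
            cid_b, fb = fields[j]
            if cid_a == cid_b:
                continue
            runs_a = {f.run_index: f.com_cm for f in fa.run_fields}
            runs_b = {f.run_index: f.com_cm for f in fb.run_fields}
            common = sorted(set(runs_a) & set(runs_b))
            if len(common) < min_overlap:
                continue
            ca = np.array([runs_a[r] for r in common])
            cb = np.array([runs_b[r] for r in common])
            if ca.std() == 0 or cb.std() == 0:
                continue
            corrs.append(float(np.corrcoef(ca, cb)[0, 1]))
            dists.append(abs(float(np.median(ca)) - float(np.median(cb))))
    dists = np.asarray(dists)
    corrs = np.asarray(corrs)
    if dists.size == 0:
        return np.array([]), np.array([]), np.nan
    edges = np.arange(0, dists.max() + bin_cm, bin_cm)
    centers = edges[:-1] + bin_cm / 2
    means = np.array(
        [corrs[(dists >= lo) & (dists < hi)].mean() if np.any((dists >= lo) & (dists < hi)) else np.nan for lo, hi in zip(edges[:-1], edges[1:])]
    )
    good = np.isfinite(means)
    trend = float(np.corrcoef(centers[good], means[good])[0, 1]) if good.sum() > 2 else np.nan
    return centers, means, trend


# ---------------------------------------------------------------------------
# shearing and population phase


def shear(m: np.ndarray, n: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Shear integer rhombus bin coordinates: s1 = m + n/2, s2 = (sqrt3/2) m."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    return m + n / 2.0, (math.sqrt(3) / 2.0) * m


def shear_phases(psi: np.ndarray) -> np.ndarray:
    """Shear phase coordinates: Psi1' = Psi1 + Psi2/2, Psi2' = (sqrt3/2) Psi2."""
    psi = np.asarray(psi, dtype=float)
    out = np.empty_like(psi)
    out[..., 0] = psi[..., 0] + psi[..., 1] / 2.0
    out[..., 1] = (math.sqrt(3) / 2.0) * psi[..., 1]
    return out


def population_phase(
    phases: np.ndarray,
    rates: np.ndarray,
    x_cm: Optional[np.ndarray] = None,
    source: str = "day-averaged",
) -> PhaseTrajectory:
    """Rate-weighted circular mean of per-cell phases along the track.

    ``phases`` is (n_cells, >=2) with each cell's (phi1, phi2[, phi3]);
    ``rates`` is (n_cells, n_bins) of non-negative activity.  Per component,
    ``Psi_k(x) = atan2(sum_i sin(phi_ki) r_i(x), sum_i cos(phi_ki) r_i(x))``,
    unwrapped along x.  Bins where the resultant vanishes (zero total rate or
    antipodal cancellation) carry the previous value and are flagged.
    """
    phases = np.asarray(phases, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n_cells, n_bins = rates.shape
    if phases.shape[0] != n_cells:
        raise ValueError("phases and rates disagree on the number of cells")
    if x_cm is None:
        x_cm = np.arange(n_bins) + 0.5
    psi_raw = np.empty((n_bins, 2))
    flagged = np.zeros(n_bins, dtype=bool)
    eps = 1e-9 * max(rates.max(), 1.0)
    for k in range(2):
        s = np.sin(phases[:, k]) @ rates
        c = np.cos(phases[:, k]) @ rates
        resultant = np.hypot(s, c)
        ang = np.arctan2(s, c)
        bad = resultant <= eps
        flagged |= bad
        # carry the previous valid value through undefined bins
        for b in range(n_bins):
            if bad[b]:
                ang[b] = ang[b - 1] if b > 0 else 0.0
        psi_raw[:, k] = ang
    psi = np.unwrap(psi_raw, axis=0)
    return PhaseTrajectory(x_cm=x_cm, psi=psi, flagged=flagged, source=source)


# ---------------------------------------------------------------------------
# trajectory metrics


def _two_pi_correct(ta: PhaseTrajectory, tb: PhaseTrajectory) -> np.ndarray:
    """Shift all of Ta by multiples of 2*pi so its start offset to Tb is in (-pi, pi]."""
    psi = ta.psi.copy()
    for k in range(2):
        off = psi[0, k] - tb.psi[0, k]
        shift = -2 * math.pi * np.round(off / (2 * math.pi))
        psi[:, k] += shift
    return psi


def trajectory_distance(ta: PhaseTrajectory, tb: PhaseTrajectory) -> float:
    """Mean same-position Euclidean distance in sheared phase coordinates.

    Ta's start is first corrected by whole turns of 2*pi per component so the
    start offsets lie in (-pi, pi]; the same correction applies to all of Ta.
    """
    if ta.psi.shape != tb.psi.shape:
        raise ValueError("trajectories must share the same track binning")
    pa = shear_phases(_two_pi_correct(ta, tb))
    pb = shear_phases(tb.psi)
    return float(np.linalg.norm(pa - pb, axis=1).mean())


def trajectory_rotation(ta: PhaseTrajectory, tb: PhaseTrajectory) -> float:
    """Distance after removing each trajectory's own starting point."""
    if ta.psi.shape != tb.psi.shape:
        raise ValueError("trajectories must share the same track binning")
    pa = shear_phases(ta.psi - ta.psi[0])
    pb = shear_phases(tb.psi - tb.psi[0])
    return float(np.linalg.norm(pa - pb, axis=1).mean())


def lateral_shift(pairs: Sequence[Tuple[PhaseTrajectory, PhaseTrajectory]]) -> np.ndarray:
    """Sheared, 2*pi-corrected start-point distances, module-normalised.

    One value per adjacent-day pair, divided by the module's mean over all
    pairs (so a constant shift maps to all-ones).
    """
    raw = []
    for ta, tb in pairs:
        pa = shear_phases(_two_pi_correct(ta, tb)[0:1])[0]
        pb = shear_phases(tb.psi[0:1])[0]
        raw.append(float(np.linalg.norm(pa - pb)))
    raw = np.asarray(raw)
    mean = raw.mean()
    return raw / mean if mean > 0 else raw


# ---------------------------------------------------------------------------
# fragmentation


def _landmark_zones(layout: TrackLayout, expansion_cm: float) -> List[Tuple[float, float]]:
    return [(e - expansion_cm, e + expansion_cm) for e in layout.landmark_edges_cm]


def phase_jumps(
    traj: PhaseTrajectory,
    layout: TrackLayout,
    expansion_cm: float = 35.0,
    edge_exclusion_cm: float = 10.0,
    exclude_span: Optional[Tuple[float, float]] = (863.0, 909.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Within- vs between-landmark phase jumps of one per-run trajectory.

    The jump at x is the sheared Euclidean distance between the phase points
    at x and x+1 cm.  Jumps inside any symmetrically expanded landmark zone
    are "within"; the rest are "between".  The first/last
    ``edge_exclusion_cm`` of track and the reward span are dropped.
    """
    p = shear_phases(traj.psi)
    jumps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    xm = 0.5 * (traj.x_cm[:-1] + traj.x_cm[1:])  # jump midpoints
    valid = (xm >= edge_exclusion_cm) & (xm <= layout.length_cm - edge_exclusion_cm)
    if exclude_span is not None:
        valid &= ~((xm >= exclude_span[0]) & (xm <= exclude_span[1]))
    if traj.flagged is not None:
        fl = traj.flagged
        valid &= ~(fl[:-1] | fl[1:])
    within = np.zeros(xm.size, dtype=bool)
    for lo, hi in _landmark_zones(layout, expansion_cm):
        within |= (xm >= lo) & (xm <= hi)
    w = jumps[valid & within]
    b = jumps[valid & ~within]
    if b.size == 0:
        raise ValueError("no between-landmark bins left after exclusions")
    return w, b


def influence_index(
    run_trajs: Sequence[PhaseTrajectory],
    layout: TrackLayout,
    expansion_cm: float = 35.0,
    edge_exclusion_cm: float = 10.0,
    exclude_span: Optional[Tuple[float, float]] = (863.0, 909.0),
) -> np.ndarray:
    """Per-run landmark influence: within-jump mean minus the run-averaged between-jump mean."""
    within_means, between_means = [], []
    for t in run_trajs:
        w, b = phase_jumps(t, layout, expansion_cm, edge_exclusion_cm, exclude_span)
        within_means.append(w.mean() if w.size else np.nan)
        between_means.append(b.mean())
    baseline = float(np.nanmean(between_means))
    return np.asarray(within_means) - baseline
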