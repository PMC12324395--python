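"""Entorhinal-hippocampal attractor-network model of slow map learning.

Three coupled layers:

* a grid module — a 2D continuous-attractor sheet of rate neurons (n x n,
  four interleaved direction preferences, purely inhibitory centre-surround
  recurrence, feedforward drive modulated by a rotated, noisy velocity
  input), which path-integrates track velocity;
* a hippocampal layer ``h = ReLU(W_HG g + b)`` driven by a fixed Gaussian
  random projection of the grid sheet, with ``b`` setting sparsity;
* a sensory layer of fixed random landmark vectors (left/right subsets;
  track start and end drive both strongly) mapped into the hippocampus by a
  heteroassociatively learned ``W_HS``.

Every 20th timestep the grid state is replaced by ``W_GH h(t)`` and relaxed
back onto the attractor; simultaneously ``W_GH`` is updated by online
pseudoinverse (recursive-least-squares) learning that associates the
*delayed* hippocampal state ``h(t - tau)`` with the current grid state
``g(t)``.  Applying that map to the current ``h`` advances the grid phase
slightly each update, which expresses as a run-by-run backward shift of the
grid fields on the track.  A second, slow weight matrix trails the fast one
by ``tau_c`` runs; at each day boundary the fast weights reset to it,
producing the partial forward regression of fields between days.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import fft as sfft

from .containers import RunActivityMap, TrackLayout

__all__ = [
    "GridModule",
    "CircuitState",
    "SimConfig",
    "init_grid",
    "step_path_integration",
    "hippocampal_drive",
    "hexagonality",
    "pattern_shift",
    "run_experiment",
    "ExperimentResult",
]

log = logging.getLogger("gridshift.circuit")

LANDMARK_EDGES = (100.0, 220.0, 340.0, 460.0, 580.0, 700.0, 800.0, 863.0)


# ---------------------------------------------------------------------------
# grid attractor sheet


class GridModule:
    """Continuous-attractor grid sheet with four direction-preference groups.

    The recurrent kernel is the purely inhibitory centre-surround profile
    ``W0(d) = exp(-gamma |d|^2) - exp(-beta |d|^2)`` with ``beta = 3/lambda^2``
    and ``gamma = 1.05 beta`` (lattice period ``lambda`` in neurons); each
    neuron's outgoing kernel is displaced by ``ell`` neurons along its
    preferred direction, which makes the formed lattice flow with the
    direction-modulated feedforward drive ``B = A (1 + alpha e_i . v)``.
    """

    def __init__(
        self,
        n: int = 128,
        lam: float = 13.0,
        ell: float = 2.0,
        alpha: float = 1.0,
        w_amp: float = 4.0,
        dt_tau: float = 0.25,
        boundary: str = "periodic",
    ):
        self.n = int(n)
        self.lam = float(lam)
        self.ell = float(ell)
        self.alpha = float(alpha)
        self.w_amp = float(w_amp)
        self.dt_tau = float(dt_tau)
        self.boundary = boundary

        beta = 3.0 / lam**2
        gamma = 1.05 * beta
        # signed periodic displacement grid
        ax = np.arange(self.n)
        d = (ax + self.n / 2) % self.n - self.n / 2
        dx, dy = np.meshgrid(d, d, indexing="xy")

        # direction preference in interleaved 2x2 blocks: E, N, W, S
        self._dirs = np.array([(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)])
        ii, jj = np.meshgrid(ax, ax, indexing="ij")
        group = (ii % 2) * 2 + (jj % 2)
        self.group_masks = [(group == k) for k in range(4)]
        self.ex = sum(self._dirs[k][0] * m for k, m in enumerate(self.group_masks))
        self.ey = sum(self._dirs[k][1] * m for k, m in enumerate(self.group_masks))

        # per-group kernels: W0 displaced by ell * e_theta, FFT'd once.
        # A second set on a zero-padded 2n grid implements aperiodic
        # (non-wrapping) recurrence for the warm-up protocol.
        khat, khat_pad = [], []
        ax2 = np.arange(2 * self.n)
        d2 = (ax2 + self.n) % (2 * self.n) - self.n
        dx2, dy2 = np.meshgrid(d2, d2, indexing="xy")
        for k in range(4):
            ox, oy = ell * self._dirs[k]
            r2 = (dx - ox) ** 2 + (dy - oy) ** 2
            w0 = self.w_amp * (np.exp(-gamma * r2) - np.exp(-beta * r2))
            khat.append(np.fft.rfft2(w0))
            r2p = (dx2 - ox) ** 2 + (dy2 - oy) ** 2
            w0p = self.w_amp * (np.exp(-gamma * r2p) - np.exp(-beta * r2p))
            khat_pad.append(np.fft.rfft2(w0p))
        self._khat = np.stack(khat).astype(np.complex64)
        self._khat_pad = np.stack(khat_pad).astype(np.complex64)
        self._masks32 = np.stack(self.group_masks).astype(np.float32)
        # The 2x2 preference masks are checkerboard characters, so masking in
        # real space is a frequency translation by n/2: the whole four-group
        # convolution collapses to one FFT, four shifted coefficient
        # multiplies, and one inverse FFT.
        parity = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (a, b) per group index
        full_khat = []
        for k in range(4):
            ox, oy = ell * self._dirs[k]
            r2 = (dx - ox) ** 2 + (dy - oy) ** 2
            w0 = self.w_amp * (np.exp(-gamma * r2) - np.exp(-beta * r2))
            full_khat.append(np.fft.fft2(w0))
        self._coef = []
        for c1, c2 in parity:
            C = sum(
                full_khat[k] * 0.25 * (-1.0) ** (parity[k][0] * c1 + parity[k][1] * c2)
                for k in range(4)
            )
            self._coef.append(C.astype(np.complex64))

        # aperiodic warm-up uses an envelope that tapers the drive at the rim
        rho = np.hypot(ii - (self.n - 1) / 2, jj - (self.n - 1) / 2)
        R = self.n / 2.0
        dR = self.n / 8.0
        self.envelope = np.where(rho < R - dR, 1.0, np.exp(-4.0 * ((rho - R + dR) / dR) ** 2))

    def recurrent_input(self, r: np.ndarray, aperiodic: bool = False) -> np.ndarray:
        if aperiodic:
            padded = np.zeros((4, 2 * self.n, 2 * self.n))
            for k, m in enumerate(self.group_masks):
                padded[k, : self.n, : self.n] = r * m
            rhat = np.fft.rfft2(padded, axes=(-2, -1))
            tot = np.fft.irfft2((rhat * self._khat_pad).sum(axis=0), s=(2 * self.n, 2 * self.n))
            return tot[: self.n, : self.n]
        rhat = sfft.fft2(r)
        h = self.n // 2
        s0 = np.empty_like(rhat)  # shifted by h along axis 1
        s0[:, :h] = rhat[:, h:]
        s0[:, h:] = rhat[:, :h]
        s1 = np.empty_like(rhat)  # shifted by h along axis 0
        s1[:h] = rhat[h:]
        s1[h:] = rhat[:h]
        s2 = np.empty_like(rhat)  # shifted along both axes
        s2[:, :h] = s1[:, h:]
        s2[:, h:] = s1[:, :h]
        tot = self._coef[0] * rhat
        tot += self._coef[1] * s0
        tot += self._coef[2] * s1
        tot += self._coef[3] * s2
        return sfft.ifft2(tot).real

    def step(self, r: np.ndarray, v: Tuple[float, float] = (0.0, 0.0), aperiodic: bool = False) -> np.ndarray:
        """One Euler step of ``tau dr/dt = -r + ReLU(W r + B)``."""
        r = np.asarray(r, dtype=np.float32)
        A = self.envelope if aperiodic else 1.0
        B = A * (1.0 + self.alpha * (self.ex * v[0] + self.ey * v[1]))
        drive = np.maximum(self.recurrent_input(r, aperiodic) + B.astype(np.float32), 0.0)
        return r + np.float32(self.dt_tau) * (drive - r)

    def relax(self, r: np.ndarray, steps: int) -> np.ndarray:
        for _ in range(steps):
            r = self.step(r)
        return r


def init_grid(
    module: GridModule,
    seed: int = 0,
    warmup: int = 250,
    hex_threshold: float = 0.5,
    max_attempts: int = 6,
) -> np.ndarray:
    """Warm up the sheet: ``warmup`` aperiodic then ``warmup`` periodic steps.

    The aperiodic phase nucleates a triangular lattice; the periodic phase
    with a small unidirectional velocity anneals it into a stable pattern.
    The random initial condition gives each experiment a random grid phase.
    Occasionally a nucleation settles into a metastable defective state, so
    the protocol checks six-fold symmetry and re-nucleates from a fresh
    random state if needed.
    """
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for attempt in range(max_attempts):
        r = rng.uniform(0.0, 1.0, (module.n, module.n))
        for _ in range(warmup):
            r = module.step(r, aperiodic=True)
        for _ in range(warmup):
            r = module.step(r, v=(0.05, 0.0))
        if r.max() <= 0:
            raise RuntimeError("grid initialization collapsed to silence")
        r = module.relax(r, 60)  # settle the annealing transient
        # the envelope pins where the lattice nucleates, so translate by a
        # random offset to give each experiment a random grid phase
        r = np.roll(np.roll(r, int(rng.integers(module.n)), axis=0), int(rng.integers(module.n)), axis=1)
        score = hexagonality(r)
        if score > best_score:
            best, best_score = r, score
        if score >= hex_threshold:
            return r
        log.debug("init attempt %d: hexagonality %.2f below %.2f", attempt, score, hex_threshold)
    log.warning("grid init: best hexagonality %.2f after %d attempts", best_score, max_attempts)
    return best


def step_path_integration(module: GridModule, r: np.ndarray, v_sheet: Tuple[float, float]) -> np.ndarray:
    """Advance the attractor one step under a sheet-plane velocity input."""
    return module.step(r, v=v_sheet)


def hexagonality(r: np.ndarray) -> float:
    """Six-fold symmetry score of the sheet pattern's spatial autocorrelation.

    Mean autocorrelation at 60/120-degree rotations minus the mean at
    30/90/150 degrees (computed on the mean-subtracted pattern); stable
    triangular lattices score well above zero.
    """
    from scipy import ndimage

    a = r - r.mean()
    n = a.shape[0]
    f = np.fft.fft2(a)
    ac = np.fft.fftshift(np.fft.ifft2(f * np.conj(f)).real)
    ac /= ac.max()
    # mask an annulus around the first ring of peaks
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(yy - c, xx - c)
    ring = (rho > 4) & (rho < n / 2 - 2)

    def rot_corr(deg: float) -> float:
        rot = ndimage.rotate(ac, deg, reshape=False, order=1, mode="constant", cval=0.0)
        x, y = ac[ring], rot[ring]
        return float(np.corrcoef(x, y)[0, 1])

    pos = np.mean([rot_corr(60), rot_corr(120)])
    neg = np.mean([rot_corr(30), rot_corr(90), rot_corr(150)])
    return pos - neg


def lattice_orientation(r: np.ndarray, lam: float) -> float:
    """Orientation (radians) of the sheet lattice's first autocorrelation peak."""
    a = r - r.mean()
    f = np.fft.fft2(a)
    ac = np.fft.fftshift(np.fft.ifft2(f * np.conj(f)).real)
    n = r.shape[0]
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(yy - c, xx - c)
    ring = (rho > 0.6 * lam) & (rho < 1.4 * lam)
    masked = np.where(ring, ac, -np.inf)
    k = int(np.argmax(masked))
    iy, ix = divmod(k, n)
    return float(math.atan2(iy - c, ix - c))


def pattern_shift(r0: np.ndarray, r1: np.ndarray, max_shift: Optional[float] = None) -> Tuple[float, float]:
    """Best 2D translation (in neurons) aligning pattern ``r0`` to ``r1``.

    Sub-pixel estimate from the argmax of the periodic cross-correlation and
    a parabolic refinement.  For near-periodic patterns the correlation has
    lattice-displaced aliases; restrict the search with ``max_shift`` (less
    than half the lattice period) when the true shift is known to be small.
    """
    f0 = np.fft.fft2(r0 - r0.mean())
    f1 = np.fft.fft2(r1 - r1.mean())
    cc = np.fft.ifft2(np.conj(f0) * f1).real
    n = r0.shape[0]
    cc_search = cc
    if max_shift is not None:
        d = (np.arange(n) + n / 2) % n - n / 2
        dx, dy = np.meshgrid(d, d)
        cc_search = np.where(np.hypot(dx, dy) <= max_shift, cc, -np.inf)
    k = int(np.argmax(cc_search))
    iy, ix = divmod(k, n)

    def refine(cm1, c0, cp1):
        denom = cm1 - 2 * c0 + cp1
        return 0.0 if denom == 0 else 0.5 * (cm1 - cp1) / denom

    dy = refine(cc[(iy - 1) % n, ix], cc[iy, ix], cc[(iy + 1) % n, ix])
    dx = refine(cc[iy, (ix - 1) % n], cc[iy, ix], cc[iy, (ix + 1) % n])
    sy = (iy + dy + n / 2) % n - n / 2
    sx = (ix + dx + n / 2) % n - n / 2
    return float(sx), float(sy)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Circuit + protocol configuration.

    ``preset('full')`` matches the study conditions (128 x 128 sheet, 2000
    hippocampal cells, 200 sensory cells, 5000 steps/run, the 161-run/10-day
    schedule); ``preset('scaled')`` is a smaller configuration (48 x 48
    sheet, 500/100 cells, 1500 steps/run, 4 runs/day x 8 days) preserving the
    same dynamical regime for affordable replication runs.
    """

    n_sheet: int = 48
    n_hippo: int = 500
    n_sensory: int = 100
    track_cm: float = 1000.0
    landmarks: Tuple[float, ...] = LANDMARK_EDGES
    steps_per_run: int = 1500
    hippo_period: int = 20
    tau_steps: int = 16
    tau_c_runs: int = 1  # full scale: 4 of 16 runs/day; scaled keeps the 1:4 ratio
    gamma_s: float = 0.1
    gamma_boundary: float = 0.9  # start/end anchors are strong (pattern-completing) inputs
    gamma_h: float = 0.5  # weight of the hippocampal correction at schedule updates
    eta_hs: float = 0.05  # chase rate of the sensory->hippocampus associations
    relax_steps: int = 10
    post_blend_relax: bool = True
    slice_offset_rad: Optional[float] = 0.26  # None = fully random motion angle
    pretrain_runs: int = 4
    runs_per_day: Tuple[int, ...] = (4,) * 8
    velocity_gain: float = 0.09  # sheet velocity input per cm of track (pattern speed ~1.2x)
    velocity_noise_sd: float = 0.15  # cm/step, on the velocity input only
    sheet_noise_sd: float = 0.02  # isotropic sheet-velocity noise per step
    sensory_noise_sd: float = 0.1
    hippo_sparsity: float = 0.15  # target active fraction fixing the bias b
    plastic: bool = True
    sensory_plastic: bool = True
    novel_imprint: bool = True  # one-shot first-visit cue writes in the novel environment
    rls_delta: float = 1e2  # P initial scale (inverse regularisation)
    rls_forgetting: float = 1.0  # exponential forgetting; 1.0 = ordinary RLS
    n_tracking_cells: int = 36
    n_decoder_cells: int = 120
    grid_lambda: float = 13.0

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        if name == "scaled":
            cfg = cls()
        elif name == "full":
            cfg = cls(
                n_sheet=128,
                n_hippo=2000,
                n_sensory=200,
                steps_per_run=5000,
                relax_steps=30,
                pretrain_runs=20,
                tau_c_runs=4,
                slice_offset_rad=None,
                runs_per_day=(16, 16, 16, 16, 16, 16, 16, 17, 16, 16),
            )
        else:
            raise KeyError(f"unknown preset '{name}'")
        return replace(cfg, **overrides)

    @property
    def v_track(self) -> float:
        """Uniform track velocity, cm per step."""
        return self.track_cm / self.steps_per_run

    def layout(self) -> TrackLayout:
        return TrackLayout(
            length_cm=self.track_cm,
            landmark_edges_cm=self.landmarks,
            reward_span_cm=(863.0, 909.0),
            bin_size_cm=2.5,
        )


@dataclass
class CircuitState:
    """Mutable simulation state: layer activities and learned weights."""

    r: np.ndarray  # grid sheet (n, n)
    w_hg: np.ndarray  # grid -> hippocampus, fixed random
    b: float  # hippocampal bias (sparsity)
    w_gh_fast: np.ndarray  # hippocampus -> grid, RLS-learned
    p_rls: np.ndarray  # RLS inverse-correlation matrix
    w_hs: np.ndarray  # sensory -> hippocampus, heteroassociative
    snapshots: deque = dc_field(default_factory=deque)  # end-of-run (w, P) copies
    h_buffer: Dict[int, np.ndarray] = dc_field(default_factory=dict)
    boundary_cache: Dict[float, np.ndarray] = dc_field(default_factory=dict)
    rls_count: int = 0

    @property
    def g(self) -> np.ndarray:
        return self.r.ravel()


def hippocampal_drive(g: np.ndarray, w_hg: np.ndarray, b: float) -> np.ndarray:
    """``h = ReLU(W_HG g + b)``."""
    return np.maximum(w_hg @ np.asarray(g, dtype=w_hg.dtype) + np.asarray(b, dtype=w_hg.dtype), 0.0)


def _rls_update(state: CircuitState, h_in: np.ndarray, g_target: np.ndarray, lam: float = 1.0) -> None:
    """Online pseudoinverse (RLS) update associating ``h_in -> g_target``.

    ``lam`` is the exponential forgetting factor: with ``lam < 1`` the map
    keeps tracking a slowly drifting association instead of freezing once
    the inverse correlation has shrunk.
    """
    from scipy.linalg import blas

    h_in64 = np.asarray(h_in, dtype=np.float64)
    ph = state.p_rls @ h_in64
    denom = lam + float(h_in64 @ ph)
    if denom <= 1e-9 or not np.isfinite(denom):  # lost positive-definiteness
        log.warning("RLS inverse correlation degenerate (%.3g); resetting towards identity", denom)
        state.p_rls[:] = (state.p_rls + state.p_rls.T) / 2.0
        state.p_rls += np.eye(state.p_rls.shape[0]) * abs(denom)
        ph = state.p_rls @ h_in64
        denom = lam + float(h_in64 @ ph)
    k32 = (ph / denom).astype(np.float32)
    err = np.asarray(g_target, dtype=np.float32) - state.w_gh_fast @ np.asarray(h_in, dtype=np.float32)
    # in-place rank-1 BLAS updates; W stays float32/Fortran, P in float64
    state.w_gh_fast = blas.sger(1.0, err, k32, a=state.w_gh_fast, overwrite_a=1)
    state.p_rls = blas.dger(-1.0 / denom, ph, ph, a=state.p_rls, overwrite_a=1)
    if lam != 1.0:
        state.p_rls *= 1.0 / lam
    state.rls_count += 1
    if state.rls_count % 64 == 0:  # keep P symmetric against roundoff drift
        state.p_rls[:] = (state.p_rls + state.p_rls.T) / 2.0


# ---------------------------------------------------------------------------
# experiment


@dataclass
class ExperimentResult:
    """Per-run exports of one simulated experiment."""

    config: SimConfig
    day_of_run: np.ndarray
    rates_1cm: np.ndarray  # (n_runs, n_track_bins, n_tracking_cells)
    decoder_rates: np.ndarray  # (n_runs, n_track_bins, n_decoder_cells)
    weight_norms: np.ndarray  # Frobenius norm of W_GH_fast per run
    tracking_cell_sheet_idx: np.ndarray
    decoder_cell_sheet_idx: np.ndarray

    def activity_maps(self, bin_size_cm: float = 2.5) -> List[RunActivityMap]:
        """Tracking-cell activity as standard run x bin containers."""
        layout = self.config.layout().with_bin_size(bin_size_cm)
        factor = int(round(bin_size_cm / 1.0))
        n_bins = int(self.config.track_cm / bin_size_cm)
        maps = []
        vals = self.rates_1cm
        rebinned = vals[:, : n_bins * factor, :].reshape(vals.shape[0], n_bins, factor, -1).mean(axis=2)
        for c in range(rebinned.shape[-1]):
            maps.append(
                RunActivityMap(
                    cell_id=f"sim{c:03d}",
                    values=rebinned[:, :, c],
                    day_of_run=self.day_of_run,
                    layout=layout,
                )
            )
        return maps


def _even_sheet_sample(n: int, count: int) -> np.ndarray:
    """~``count`` flat indices forming an even subgrid of the n x n sheet."""
    side = max(1, int(round(math.sqrt(count))))
    xs = np.linspace(0, n - 1, side).round().astype(int)
    ii, jj = np.meshgrid(xs, xs, indexing="ij")
    flat = (ii * n + jj).ravel()
    return flat[:count]


def run_experiment(config: SimConfig, seed: int = 0) -> ExperimentResult:
    """Simulate pretraining plus the full run schedule and export activity.

    The model pretrains ``pretrain_runs`` runs in an environment with
    randomly drawn sensory cues (same track geometry), then runs the
    ``runs_per_day`` schedule in the novel environment.  Exports per-run
    1-cm-binned rates for a tracking-cell sample and a phase-even decoder
    sample, plus the Frobenius norm of the fast hippocampus-to-grid weights
    at the end of every run.
    """
    rng = np.random.default_rng(seed)
    n = config.n_sheet
    n_g = n * n
    module = GridModule(n=n, lam=config.grid_lambda)
    r = init_grid(module, seed=int(rng.integers(2**31)))

    # fixed random projections
    w_hg = (rng.normal(0.0, 1.0, (config.n_hippo, n_g)) / math.sqrt(n_g)).astype(np.float32)
    drive = w_hg @ r.ravel()
    b = -float(np.quantile(drive, 1.0 - config.hippo_sparsity))

    state = CircuitState(
        r=r,
        w_hg=w_hg,
        b=b,
        w_gh_fast=np.zeros((n_g, config.n_hippo), dtype=np.float32, order="F"),
        p_rls=np.asfortranarray(np.eye(config.n_hippo) * config.rls_delta),
        w_hs=np.zeros((config.n_hippo, config.n_sensory), dtype=np.float32),
    )

    # velocity rotation angle, fixed per experiment.  The base angle is
    # random; on the scaled sheet the motion direction is offset a fixed
    # 0.26 rad from the measured lattice axis so the 1D slice through the
    # lattice never degenerates (a near-axis slice makes the track tuning
    # stripe-like and untrackable on a small sheet).
    if config.slice_offset_rad is not None:
        axis = lattice_orientation(r, module.lam)
        sextant = float(rng.integers(6)) * math.pi / 3.0
        angle = axis + sextant + config.slice_offset_rad
    else:
        angle = rng.uniform(0.0, 2 * math.pi)
    rot = np.array([math.cos(angle), math.sin(angle)])

    def sensory_vectors(env_rng: np.random.Generator) -> Dict[float, np.ndarray]:
        half = config.n_sensory // 2
        vecs: Dict[float, np.ndarray] = {}
        for k, lm in enumerate(config.landmarks):
            v = np.zeros(config.n_sensory)
            if k % 2 == 0:  # alternate left/right cue populations
                v[:half] = env_rng.normal(0.0, 1.0, half)
            else:
                v[half:] = env_rng.normal(0.0, 1.0, config.n_sensory - half)
            vecs[lm] = v
        for edge_pos in (0.0, config.track_cm - 1e-6):  # boundaries drive both
            vecs[edge_pos] = 2.0 * env_rng.normal(0.0, 1.0, config.n_sensory)
        return vecs

    tau = config.tau_steps
    period = config.hippo_period
    # h must exist at steps == 0 (mod period) and at the lag partners == -tau
    h_phase = (-tau) % period

    n_track_bins = int(config.track_cm)  # 1-cm bins
    track_idx = _even_sheet_sample(n, config.n_tracking_cells)
    dec_idx = _even_sheet_sample(n, config.n_decoder_cells)

    sched_days = np.repeat(np.arange(1, len(config.runs_per_day) + 1), config.runs_per_day)
    n_runs = sched_days.size
    rates = np.zeros((n_runs, n_track_bins, track_idx.size), dtype=np.float32)
    dec_rates = np.zeros((n_runs, n_track_bins, dec_idx.size), dtype=np.float32)
    w_norms = np.zeros(n_runs)

    def one_run(
        vecs: Dict[float, np.ndarray], record: Optional[int], rls_on: bool, hs_on: bool, imprint: bool = True
    ) -> None:
        lm_sorted = sorted(vecs)
        next_lm = 0
        counts = np.zeros(n_track_bins, dtype=np.int32) if record is not None else None
        state.h_buffer.clear()
        pos = 0.0
        for t in range(config.steps_per_run):
            v_in = config.v_track + rng.normal(0.0, config.velocity_noise_sd)
            v_sheet = tuple(config.velocity_gain * v_in * rot + rng.normal(0.0, config.sheet_noise_sd, 2))
            state.r = module.step(state.r, v=v_sheet)
            pos = (t + 1) * config.v_track

            # sensory events fire at landmark crossings, off-schedule included
            while next_lm < len(lm_sorted) and pos >= lm_sorted[next_lm]:
                lm = lm_sorted[next_lm]
                is_boundary = lm in (0.0, lm_sorted[-1]) and lm not in config.landmarks
                s = (vecs[lm] + rng.normal(0.0, config.sensory_noise_sd, config.n_sensory)).astype(np.float32)
                g_prior = state.g
                h_pi = hippocampal_drive(g_prior, state.w_hg, state.b)
                # novelty-gated heteroassociation: an unlearned cue is
                # imprinted one-shot (this first write happens in every
                # condition — without it landmarks carry no information);
                # thereafter the association drifts slowly, and only when
                # sensory plasticity is on
                pred = state.w_hs @ s
                if imprint and np.linalg.norm(pred) < 0.3 * np.linalg.norm(h_pi):
                    state.w_hs += np.outer(h_pi - pred, s) / float(s @ s)
                elif hs_on:
                    state.w_hs += config.eta_hs * np.outer(h_pi - pred, s) / float(s @ s)
                h_s = state.w_hs @ s
                gamma = config.gamma_boundary if is_boundary else config.gamma_s
                g_new = (1.0 - gamma) * g_prior + gamma * (state.w_gh_fast @ h_s)
                state.r = np.maximum(g_new, 0.0).reshape(n, n)
                if is_boundary:
                    # a strong anchor may land slightly off the manifold
                    state.r = module.relax(state.r, config.relax_steps)
                if rls_on:
                    h_del = _delayed_h(state, t, tau)
                    if h_del is not None:
                        _rls_update(state, h_del, state.g, config.rls_forgetting)
                next_lm += 1

            phase = t % period
            if phase == h_phase or phase == 0:
                h_now = hippocampal_drive(state.g, state.w_hg, state.b)
                state.h_buffer[t] = h_now
                if phase == 0 and t > 0:
                    g_now = state.g
                    if rls_on:
                        h_del = _delayed_h(state, t, tau)
                        if h_del is not None:
                            _rls_update(state, h_del, g_now, config.rls_forgetting)
                    g_map = np.maximum(state.w_gh_fast @ h_now, 0.0)
                    if g_map.sum() > 0.1 * g_now.sum():
                        # blended correction keeps the phase continuous; the
                        # ongoing recurrent dynamics settle the mixture back
                        # onto the attractor without halting the flow (a
                        # zero-velocity relaxation here recentres the moving
                        # pattern's deformation and biases the phase)
                        mixed = (1.0 - config.gamma_h) * g_now + config.gamma_h * g_map
                        state.r = mixed.reshape(n, n)
                        if config.post_blend_relax:
                            state.r = module.relax(state.r, config.relax_steps)
                # drop stale buffer entries
                for key in [k for k in state.h_buffer if k < t - 2 * period - tau]:
                    del state.h_buffer[key]

            if record is not None:
                bin_i = min(int(pos), n_track_bins - 1)
                flat = state.r.ravel()
                rates[record, bin_i, :] += flat[track_idx]
                dec_rates[record, bin_i, :] += flat[dec_idx]
                counts[bin_i] += 1

        if record is not None:
            nz = counts > 0
            rates[record, nz, :] /= counts[nz, None]
            dec_rates[record, nz, :] /= counts[nz, None]

    # pretraining in a familiar environment: plasticity always on here — the
    # condition flags describe the novel environment only
    pre_vecs = sensory_vectors(np.random.default_rng(rng.integers(2**31)))
    for _ in range(config.pretrain_runs):
        one_run(pre_vecs, record=None, rls_on=True, hs_on=True, imprint=True)

    # novel environment: new cues, fresh boundary imprints
    vecs = sensory_vectors(np.random.default_rng(rng.integers(2**31)))
    state.snapshots.clear()
    state.boundary_cache.clear()
    for run in range(n_runs):
        one_run(vecs, record=run, rls_on=config.plastic, hs_on=config.sensory_plastic, imprint=config.novel_imprint)
        w_norms[run] = float(np.linalg.norm(state.w_gh_fast))
        state.snapshots.append((state.w_gh_fast.copy(), state.p_rls.copy()))
        if len(state.snapshots) > config.tau_c_runs + 1:
            state.snapshots.popleft()
        is_day_end = run + 1 < n_runs and sched_days[run + 1] != sched_days[run]
        if is_day_end and config.tau_c_runs > 0 and config.plastic:
            # consolidation: fast weights decay to their state tau_c runs ago
            w_old, p_old = state.snapshots[0]
            state.w_gh_fast = w_old.copy()
            state.p_rls = p_old.copy()

    return ExperimentResult(
        config=config,
        day_of_run=sched_days,
        rates_1cm=rates,
        decoder_rates=dec_rates,
        weight_norms=w_norms,
        tracking_cell_sheet_idx=track_idx,
        decoder_cell_sheet_idx=dec_idx,
    )


def _delayed_h(state: CircuitState, t: int, tau: int) -> Optional[np.ndarray]:
    """Most recent buffered hippocampal state at lag >= tau (exact for scheduled steps)."""
    want = t - tau
    keys = [k for k in state.h_buffer if k <= want]
    if not keys:
        return None
    return state.h_buffer[max(keys)]
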