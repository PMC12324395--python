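"""Spectral phase extraction, module grouping, trajectories, fragmentation."""

import numpy as np
import pytest
from scipy import stats

from gridshift.phase import (
    PhaseTrajectory,
    SpectralPeaks,
    assign_modules,
    cell_spectrum,
    field_trajectory_correlation,
    influence_index,
    lateral_shift,
    module_day_phases,
    phase_jumps,
    population_phase,
    qualify_module,
    run_correlation,
    shear,
    shear_phases,
    trajectory_distance,
    trajectory_rotation,
)
from gridshift.synth import ModuleSpec, default_layout, generate_module

GRID_STEP = 1000.0 / 2992.0 / 1000.0  # frequency-grid spacing in cycles/cm


def circdiff(a, b):
    return np.angle(np.exp(1j * (a - b)))


class TestCellSpectrum:
    def test_pure_cosine_peak_recovered(self):
        x = np.arange(1000) + 0.5
        # three tones so three peaks qualify; dominant at 0.02 cycles/cm
        trace = 1.0 + np.cos(2 * np.pi * 0.02 * x) + 0.4 * np.cos(2 * np.pi * 0.012 * x) + 0.3 * np.cos(2 * np.pi * 0.032 * x)
        p = cell_spectrum(trace)
        assert p is not None
        best = p.freqs[int(np.argmax(p.powers))]
        assert abs(best - 0.02) <= GRID_STEP

    def test_generator_slice_sum_rule(self, layout_1cm):
        maps, gt = generate_module(ModuleSpec(), plan=[2], layout=layout_1cm, noise_sd=0.0, seed=1)
        p = cell_spectrum(maps[0].day_average(1))
        assert abs(p.f3 - (p.f1 + p.f2)) <= 2 * GRID_STEP

    def test_phase_of_known_cosine(self):
        x = np.arange(1000) + 0.5
        # on-grid frequency so the FFT phase is exact
        f = 30 * 1000.0 / 2992.0 / 1000.0
        for phi0 in (0.3, -1.2, 2.8):
            trace = (
                1.0
                + np.cos(2 * np.pi * f * x + phi0)
                + 0.4 * np.cos(2 * np.pi * 2 * f * x)
                + 0.3 * np.cos(2 * np.pi * 3.5 * f * x)
            )
            p = cell_spectrum(trace)
            k = int(np.argmin(np.abs(np.array(p.freqs) - f)))
            # bin centres shift the reference by f*0.5 cm
            assert abs(circdiff(p.phases[k], phi0 + 2 * np.pi * f * 0.5)) < 0.1

    def test_noise_trace_excluded(self):
        # white noise has no three dominant peaks with stable ordering, but
        # find_peaks may still find maxima; a flat trace certainly fails
        assert cell_spectrum(np.ones(1000)) is None

    def test_per_cell_phases_match_planted_up_to_global_offset(self, layout_1cm):
        maps, gt = generate_module(ModuleSpec(n_cells=12), plan=[2], layout=layout_1cm, noise_sd=0.0, seed=7)
        freqs, phases, kept = module_day_phases([m.day_average(1) for m in maps])
        assert len(kept) == 12
        for comp in range(3):
            d = circdiff(phases[:, comp], gt.phase_offsets[:, comp])
            # residual spread about the circular mean is within grid slop
            resid = circdiff(d, np.angle(np.mean(np.exp(1j * d))))
            assert np.abs(resid).max() < 0.15


class TestModuleAssignment:
    def test_two_spacing_clusters_two_modules(self, rng):
        spacings = {}
        for i in range(40):
            spacings[f"a{i}"] = float(rng.normal(45.0, 1.5))
        for i in range(40):
            spacings[f"b{i}"] = float(rng.normal(90.0, 2.5))
        groups = assign_modules(spacings)
        assert len(groups) == 2
        members = sorted(groups, key=lambda g: np.mean(list(g.spacings_cm.values())))
        assert all(c.startswith("a") for c in members[0].cell_ids)
        assert all(c.startswith("b") for c in members[1].cell_ids)

    def test_identical_spacings_single_module(self):
        groups = assign_modules({f"c{i}": 60.0 for i in range(8)})
        assert len(groups) == 1 and groups[0].n_cells == 8

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            assign_modules({})


class TestQualifyModule:
    def _peaks(self, f1, f2, f3, n_cells):
        return [SpectralPeaks((f1, f2, f3), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))] * n_cells

    def test_generator_module_qualifies(self):
        ok, avg = qualify_module([self._peaks(0.010, 0.014, 0.024, 12)])
        assert ok

    @pytest.mark.parametrize("n_cells,expected", [(10, False), (11, True)])
    def test_member_count_rule_strictly_more_than_ten(self, n_cells, expected):
        ok, _ = qualify_module([self._peaks(0.010, 0.014, 0.024, n_cells)])
        assert ok is expected

    def test_ten_percent_mismatch_fails(self):
        ok, _ = qualify_module([self._peaks(0.010, 0.014, 0.0267, 12)])  # |f1+f2-f3| = 10% f3
        assert not ok


class TestRunCorrelation:
    def test_identical_runs_correlate_perfectly(self, rng):
        act = rng.random((8, 1, 100))
        act = np.repeat(act, 2, axis=1)
        obs, shuf = run_correlation(act, [(0, 1)], n_shuffle=20, seed=0)
        assert obs[0] == pytest.approx(1.0)

    def test_independent_runs_near_zero(self, rng):
        act = rng.standard_normal((10, 2, 400))
        obs, _ = run_correlation(act, [(0, 1)], n_shuffle=5, seed=0)
        n_pairs = 10 * 9 / 2
        assert abs(obs[0]) < 3 / np.sqrt(n_pairs)

    def test_shuffle_centred_at_zero_for_structured_data(self, rng):
        base = rng.random((12, 100))
        act = np.stack([base + 0.05 * rng.standard_normal((12, 100)) for _ in range(2)], axis=1)
        obs, shuf = run_correlation(act, [(0, 1)], n_shuffle=100, seed=1)
        assert obs[0] > 0.9
        assert abs(np.nanmean(shuf)) < 0.25

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            run_correlation(rng.random((4, 2, 50)), [(0, 1)])


class TestShear:
    @pytest.mark.parametrize("m,n,expected", [((0, 0), 0, (0.0, 0.0)), (2, 0, (2.0, np.sqrt(3))), (1, 1, (1.5, np.sqrt(3) / 2))])
    def test_bin_shear_formula(self, m, n, expected):
        if isinstance(m, tuple):
            m, n = m
        s1, s2 = shear(np.array(m), np.array(n))
        assert (s1, s2) == pytest.approx(expected)

    def test_phase_shear_formula(self):
        out = shear_phases(np.array([[2.0, 2.0]]))
        assert out[0] == pytest.approx([3.0, np.sqrt(3)])


class TestPopulationPhase:
    def test_shared_phase_recovered_everywhere(self, rng):
        phases = np.tile([0.7, -1.1], (5, 1))
        rates = rng.random((5, 50)) + 0.1
        traj = population_phase(phases, rates)
        assert np.allclose(np.angle(np.exp(1j * traj.psi[:, 0])), 0.7, atol=1e-9)
        assert np.allclose(np.angle(np.exp(1j * traj.psi[:, 1])), -1.1, atol=1e-9)

    def test_antipodal_cancellation_flagged(self):
        phases = np.array([[0.0, 0.0], [np.pi, np.pi]])
        rates = np.ones((2, 10))
        traj = population_phase(phases, rates)
        assert traj.flagged.all()

    def test_recovered_trajectory_matches_planted(self, layout_1cm):
        maps, gt = generate_module(ModuleSpec(n_cells=12), plan=[1], layout=layout_1cm, noise_sd=0.0, seed=2)
        freqs, phases, kept = module_day_phases([m.day_average(1) for m in maps])
        rates = np.array([maps[i].values[0] for i in kept])
        traj = population_phase(phases[:, :2], rates)
        x = layout_1cm.bin_centers()
        for kcomp in range(2):
            expect = -(2 * np.pi * gt.frequencies[kcomp] * x + gt.phase_drift[0][:, kcomp])
            resid = traj.psi[:, kcomp] - expect
            resid -= resid[0]
            assert np.sqrt(np.mean(resid**2)) < 0.1


class TestTrajectoryMetrics:
    def _traj(self, psi):
        return PhaseTrajectory(np.arange(psi.shape[0]) + 0.5, psi)

    def test_identity_distance_zero(self, rng):
        psi = np.cumsum(rng.random((50, 2)) * 0.1, axis=0)
        t = self._traj(psi)
        assert trajectory_distance(t, t) == 0.0
        assert trajectory_rotation(t, t) == 0.0

    def test_pure_sheared_translation(self, rng):
        psi = np.cumsum(rng.random((50, 2)) * 0.1, axis=0)
        delta = 0.8
        # translate by delta along sheared axis 1: psi1 += delta (psi2 fixed)
        t1 = self._traj(psi)
        t2 = self._traj(psi + np.array([delta, 0.0]))
        assert trajectory_distance(t2, t1) == pytest.approx(delta, abs=1e-9)
        assert trajectory_rotation(t2, t1) == pytest.approx(0.0, abs=1e-9)

    def test_two_pi_start_offset_corrected(self, rng):
        psi = np.cumsum(rng.random((30, 2)) * 0.05, axis=0)
        t1 = self._traj(psi)
        t2 = self._traj(psi + np.array([2 * np.pi, 0.0]))
        assert trajectory_distance(t2, t1) == pytest.approx(0.0, abs=1e-9)

    def test_scaling_about_start_grows_with_position(self):
        psi = np.linspace(0, 4, 40)[:, None] * np.array([1.0, 0.5])
        t1 = self._traj(psi)
        t2 = self._traj(psi * 1.1)
        assert trajectory_rotation(t2, t1) > 0

    def test_pseudometric_symmetry(self, rng):
        a = self._traj(np.cumsum(rng.random((30, 2)) * 0.1, axis=0))
        b = self._traj(np.cumsum(rng.random((30, 2)) * 0.1, axis=0))
        assert trajectory_distance(a, b) >= 0
        assert trajectory_distance(a, b) == pytest.approx(trajectory_distance(b, a), abs=1e-9)

    def test_length_mismatch_rejected(self, rng):
        a = self._traj(rng.random((30, 2)))
        b = self._traj(rng.random((20, 2)))
        with pytest.raises(ValueError):
            trajectory_distance(a, b)

    def test_lateral_shift_normalisation(self):
        base = np.zeros((10, 2))
        pairs = []
        for d in (1.0, 1.0, 2.0):  # one pair double the others
            pairs.append((self._traj(base + np.array([d, 0.0])), self._traj(base)))
        out = lateral_shift(pairs)
        n = 3
        assert out[-1] == pytest.approx(2 * n / (n + 1))
        assert np.allclose(out[:2], 1.0 * n / (n + 1) * 1.5 / 1.5 * np.array([1, 1]) * (3 / 4) / 0.75)


class TestPhaseJumps:
    def test_straight_line_zero_influence(self, layout_1cm):
        x = layout_1cm.bin_centers()
        psi = np.column_stack([0.05 * x, 0.03 * x])
        trajs = [PhaseTrajectory(x, psi, source="single-run")] * 5
        idx = influence_index(trajs, layout_1cm, expansion_cm=5.0)
        assert np.allclose(idx, 0.0, atol=1e-9)

    def test_planted_landmark_jumps_positive_index(self, layout_1cm):
        jumps = [(e, (0.4 * np.cos(k), 0.4 * np.sin(k))) for k, e in enumerate(layout_1cm.landmark_edges_cm)]
        maps, _ = generate_module(ModuleSpec(planted_jumps=jumps), plan=[30], layout=layout_1cm, noise_sd=0.1, seed=3)
        freqs, phases, kept = module_day_phases([m.day_average(1) for m in maps])
        trajs = [
            population_phase(phases[:, :2], np.array([maps[i].values[r] for i in kept]), source="single-run")
            for r in range(30)
        ]
        idx = influence_index(trajs, layout_1cm, expansion_cm=5.0)
        t, p = stats.ttest_1samp(idx, 0.0)
        assert idx.mean() > 0 and p < 0.05

    def test_mid_span_jumps_do_not_raise_index(self, layout_1cm):
        mids = [(160.0, (0.4, 0.0)), (280.0, (0.0, 0.4)), (400.0, (0.3, 0.3)), (520.0, (-0.4, 0.0))]
        maps, _ = generate_module(ModuleSpec(planted_jumps=mids), plan=[30], layout=layout_1cm, noise_sd=0.1, seed=1)
        freqs, phases, kept = module_day_phases([m.day_average(1) for m in maps])
        trajs = [
            population_phase(phases[:, :2], np.array([maps[i].values[r] for i in kept]), source="single-run")
            for r in range(30)
        ]
        idx = influence_index(trajs, layout_1cm, expansion_cm=5.0)
        assert idx.mean() < 0.01

    def test_everything_excluded_errors(self, layout_1cm):
        x = layout_1cm.bin_centers()
        traj = PhaseTrajectory(x, np.zeros((x.size, 2)))
        with pytest.raises(ValueError):
            phase_jumps(traj, layout_1cm, expansion_cm=500.0)


class TestFieldTrajectoryCorrelation:
    def _field(self, cell, coms, runs):
        from gridshift.tracking import CrossDayField, RunField

        rfs = [RunField(r, 1, 0, 3, float(c), 1.0, 10.0) for r, c in zip(runs, coms)]
        return (cell, CrossDayField(rfs))

    def test_copies_at_zero_distance_correlate(self, rng):
        coms = 100 + np.cumsum(rng.normal(-0.3, 1.0, 20))
        fields = [self._field("a", coms, range(1, 21)), self._field("b", coms + 0.01, range(1, 21))]
        centers, means, trend = field_trajectory_correlation(fields)
        assert means[np.isfinite(means)][0] == pytest.approx(1.0, abs=1e-6)

    def test_same_cell_pairs_skipped(self, rng):
        coms = 100 + np.arange(20.0)
        fields = [self._field("a", coms, range(1, 21)), self._field("a", coms, range(1, 21))]
        centers, means, trend = field_trajectory_correlation(fields)
        assert centers.size == 0

    def test_coherent_module_decays_with_distance(self, layout_1cm, rng):
        # shared drift + independent jitter: nearby fields correlate more
        shared = np.cumsum(rng.normal(-0.5, 1.5, 30))
        fields = []
        for i, offset in enumerate([0.0, 5.0, 200.0, 400.0]):
            coms = 100 + offset + shared + rng.normal(0, 0.5, 30)
            fields.append(self._field(f"c{i}", coms, range(1, 31)))
        centers, means, trend = field_trajectory_correlation(fields)
        good = np.isfinite(means)
        assert means[good][0] > 0.9
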