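"""Scaled replication study: canned conditions and pooled statistics.

These helpers run the scaled circuit model under the standard conditions
(delayed plasticity at several delays, and a frozen-weights control), push
the exported activity through the field-tracking / shift-classification /
phase / decoding pipelines, and pool statistics over seeds.  Both the test
suite and the reproduction script build on them so the numbers they report
come from identical computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circuit import ExperimentResult, SimConfig, run_experiment
from .decoder import sliding_window_mae
from .phase import influence_index, module_day_phases, population_phase
from .shifts import classify_shift, detect_reset_events, shuffle_type_fractions
from .tracking import CrossDayField, LinkParams, detect_run_fields, fields_from_run_lists

__all__ = ["Condition", "CONDITIONS", "run_condition", "FieldStats", "field_stats",
           "pooled_backward_test", "reset_balance", "model_influence_by_day", "decoding_curve"]


@dataclass(frozen=True)
class Condition:
    name: str
    plastic: bool = True
    sensory_plastic: bool = True
    novel_imprint: bool = True
    tau_steps: int = 16


CONDITIONS = {
    "plastic": Condition("plastic"),
    # the no-plasticity control learns nothing in the novel environment, not
    # even first-visit cue imprints
    "frozen": Condition("frozen", plastic=False, sensory_plastic=False, novel_imprint=False),
    "tau0": Condition("tau0", tau_steps=0),
    "tau4": Condition("tau4", tau_steps=4),
    "tau32": Condition("tau32", tau_steps=32),
}


def run_condition(cond: Condition, seed: int, **overrides) -> ExperimentResult:
    cfg = SimConfig.preset(
        "scaled",
        plastic=cond.plastic,
        sensory_plastic=cond.sensory_plastic,
        novel_imprint=cond.novel_imprint,
        tau_steps=cond.tau_steps,
        **overrides,
    )
    return run_experiment(cfg, seed=seed)


@dataclass
class FieldStats:
    """Tracked-field statistics of one simulated experiment."""

    cells: Dict[str, List[CrossDayField]] = field(default_factory=dict)
    labels: List[str] = field(default_factory=list)
    slopes: List[float] = field(default_factory=list)
    backward_slopes: List[float] = field(default_factory=list)
    n_regression: int = 0
    n_progression: int = 0
    weight_norms: Optional[np.ndarray] = None

    @property
    def n_fields(self) -> int:
        return len(self.labels)

    def fraction(self, label: str) -> float:
        return self.labels.count(label) / max(self.n_fields, 1)


def field_stats(res: ExperimentResult, seed: int, reset_min_runs: int = 2) -> FieldStats:
    """Track, classify and summarise all exported cells of one experiment."""
    params = LinkParams.preset("simulated")
    maps = res.activity_maps()
    out = FieldStats(weight_norms=res.weight_norms)
    day_spans: Dict[int, Tuple[int, int]] = {}
    for d in np.unique(maps[0].day_of_run):
        rows = np.nonzero(maps[0].day_of_run == d)[0]
        day_spans[int(d)] = (int(maps[0].run_index[rows[0]]), int(maps[0].run_index[rows[-1]]))
    for m in maps:
        per = detect_run_fields(m, params, seed=seed * 977 + int(m.cell_id[3:]))
        fields = fields_from_run_lists(per, params)
        if not fields:
            continue
        out.cells[m.cell_id] = fields
        for f in fields:
            sc = classify_shift(f)
            out.labels.append(sc.label)
            out.slopes.append(sc.slope_cm_per_run)
            if sc.label == "backward":
                out.backward_slopes.append(sc.slope_cm_per_run)
                for ev in detect_reset_events(f, day_spans, min_runs_per_day=reset_min_runs):
                    if ev.kind == "regression":
                        out.n_regression += 1
                    else:
                        out.n_progression += 1
    return out


def pooled_backward_test(stats: Sequence[FieldStats], n_shuffle: int = 100, seed: int = 0) -> Dict:
    """Backward-fraction significance against the within-field shuffle baseline.

    Pools the tracked fields of several seeds into one population, permutes
    run fields within each cross-day field, relinks and reclassifies.
    """
    cells: Dict[str, List[CrossDayField]] = {}
    for i, st in enumerate(stats):
        for cid, fs in st.cells.items():
            cells[f"s{i}/{cid}"] = fs
    return shuffle_type_fractions(cells, LinkParams.preset("simulated"), n_shuffle=n_shuffle, seed=seed)


def reset_balance(stats: Sequence[FieldStats]) -> Tuple[int, int]:
    """Pooled (regression, progression) event counts of backward fields."""
    return sum(s.n_regression for s in stats), sum(s.n_progression for s in stats)


def model_influence_by_day(
    res: ExperimentResult,
    expansion_cm: float = 5.0,
) -> Dict[int, np.ndarray]:
    """Per-day influence indices of the model module's phase trajectories.

    Per-cell phases come from the module-average spectral peaks of the
    day-averaged 1-cm traces (the same procedure applied to recorded
    modules); per-run trajectories use each run's instantaneous rates.
    """
    layout = res.config.layout().with_bin_size(1.0)
    rates = res.rates_1cm  # (runs, bins, cells)
    days = np.unique(res.day_of_run)
    out: Dict[int, np.ndarray] = {}
    for d in days:
        rows = np.nonzero(res.day_of_run == d)[0]
        day_avg = rates[rows].mean(axis=0)  # (bins, cells)
        try:
            freqs, phases, kept = module_day_phases([day_avg[:, c] for c in range(day_avg.shape[1])])
        except ValueError:
            continue
        trajs = [
            population_phase(phases[:, :2], rates[r][:, kept].T, source="single-run")
            for r in rows
        ]
        try:
            out[int(d)] = influence_index(trajs, layout, expansion_cm=expansion_cm)
        except ValueError:
            continue
    return out


def decoding_curve(res: ExperimentResult, block: int = 10, eval_runs: int = 10, step: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window KVM decoding MAE on the experiment's decoder sample."""
    n_runs = res.decoder_rates.shape[0]
    positions = np.arange(res.decoder_rates.shape[1]) + 0.5
    vectors = [res.decoder_rates[r] for r in range(n_runs)]
    pos = [positions.copy() for _ in range(n_runs)]
    return sliding_window_mae(vectors, pos, block=block, eval_runs=eval_runs, step=step)
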