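"""File formats: HDF5 activity containers, long CSV, and tabular results.

HDF5 layout::

    /cells/<id>/values        runs x bins float
    /cells/<id>/day_of_run    runs int
    /cells/<id>/coverage      runs x bins bool (optional; default all True)
    root attrs: bin_size_cm, length_cm, landmark_edges_cm, reward_span_cm

The long CSV dialect has columns ``cell,run,day,bin,value`` (UTF-8, comma,
'.' decimal, header mandatory).  Results tables are written as CSV with a JSON
sidecar recording the configuration hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import h5py
import numpy as np
import pandas as pd

from .containers import RunActivityMap, TrackLayout

__all__ = ["load_activity", "save_activity", "save_results", "config_hash"]

log = logging.getLogger("gridshift.io")


class SchemaError(ValueError):
    """Raised when an input file does not follow the documented layout."""


def _layout_to_attrs(layout: TrackLayout, attrs) -> None:
    attrs["length_cm"] = layout.length_cm
    attrs["bin_size_cm"] = layout.bin_size_cm
    attrs["landmark_edges_cm"] = np.asarray(layout.landmark_edges_cm, dtype=float)
    if layout.reward_span_cm is not None:
        attrs["reward_span_cm"] = np.asarray(layout.reward_span_cm, dtype=float)
    if layout.landmark_sides is not None:
        attrs["landmark_sides"] = [s.encode() for s in layout.landmark_sides]


def _layout_from_attrs(attrs) -> TrackLayout:
    for key in ("length_cm", "bin_size_cm"):
        if key not in attrs:
            raise SchemaError(f"missing required attribute '{key}'")
    sides = attrs.get("landmark_sides")
    if sides is not None:
        sides = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in sides)
    span = attrs.get("reward_span_cm")
    return TrackLayout(
        length_cm=float(attrs["length_cm"]),
        landmark_edges_cm=tuple(np.atleast_1d(attrs.get("landmark_edges_cm", ()))),
        reward_span_cm=None if span is None else (float(span[0]), float(span[1])),
        bin_size_cm=float(attrs["bin_size_cm"]),
        landmark_sides=sides,
    )


def save_activity(maps: List[RunActivityMap], path) -> None:
    """Write activity maps to the HDF5 container (all maps share one layout)."""
    path = Path(path)
    if not maps:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as f:
        _layout_to_attrs(maps[0].layout, f.attrs)
        grp = f.create_group("cells")
        for m in maps:
            g = grp.create_group(m.cell_id)
            g.create_dataset("values", data=m.values)
            g.create_dataset("day_of_run", data=m.day_of_run)
            g.create_dataset("run_index", data=m.run_index)
            if not m.coverage_mask.all():
                g.create_dataset("coverage", data=m.coverage_mask)


def load_activity(path) -> List[RunActivityMap]:
    """Load activity maps from HDF5 (``.h5``/``.hdf5``) or long CSV (``.csv``).

    The dialect is auto-detected by extension.  Invariants of
    :class:`RunActivityMap` are enforced on load; CSV rows out of
    ``(day, run)`` order are re-sorted with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_hdf5(path)
    if path.suffix.lower() == ".csv":
        return _load_csv(path)
    raise SchemaError(f"unrecognised activity container extension: {path.suffix}")


def _load_hdf5(path: Path) -> List[RunActivityMap]:
    out: List[RunActivityMap] = []
    with h5py.File(path, "r") as f:
        layout = _layout_from_attrs(f.attrs)
        if "cells" not in f:
            raise SchemaError("missing top-level 'cells' group")
        for cid, g in f["cells"].items():
            for ds in ("values", "day_of_run"):
                if ds not in g:
                    raise SchemaError(f"cell '{cid}': missing dataset '{ds}'")
            values = np.asarray(g["values"])
            _check_finite(values, cid)
            out.append(
                RunActivityMap(
                    cell_id=cid,
                    values=values,
                    day_of_run=np.asarray(g["day_of_run"]),
                    run_index=np.asarray(g["run_index"]) if "run_index" in g else None,
                    coverage_mask=np.asarray(g["coverage"]) if "coverage" in g else None,
                    layout=layout,
                )
            )
    out.sort(key=lambda m: m.cell_id)
    return out


def _check_finite(values: np.ndarray, cell: str) -> None:
    bad = ~np.isfinite(np.atleast_2d(values))
    if np.any(bad):
        runs, bins = np.nonzero(bad)
        where = ", ".join(f"({cell}, run {r + 1}, bin {b})" for r, b in zip(runs[:10], bins[:10]))
        raise ValueError(f"non-finite activity values at {where}")


def _load_csv(path: Path) -> List[RunActivityMap]:
    df = pd.read_csv(path)
    required = {"cell", "run", "day", "bin", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"long CSV is missing columns: {sorted(missing)}")
    # layout comes from a JSON sidecar if present, else inferred
    sidecar = path.with_suffix(".layout.json")
    if sidecar.exists():
        spec = json.loads(sidecar.read_text())
        layout = TrackLayout(
            length_cm=spec["length_cm"],
            landmark_edges_cm=tuple(spec.get("landmark_edges_cm", ())),
            reward_span_cm=tuple(spec["reward_span_cm"]) if spec.get("reward_span_cm") else None,
            bin_size_cm=spec.get("bin_size_cm", 2.5),
        )
    else:
        n_bins = int(df["bin"].max()) + 1
        layout = TrackLayout(length_cm=2.5 * n_bins, bin_size_cm=2.5)
        log.warning("no layout sidecar next to %s; assuming 2.5 cm bins", path)
    out = []
    for cid, sub in df.groupby("cell", sort=True):
        runs = sub[["day", "run"]].drop_duplicates()
        if not (runs.sort_values(["day", "run"]).values == runs.values).all():
            warnings.warn(f"cell {cid}: runs out of order in CSV; re-sorting by (day, run)")
        sub = sub.sort_values(["day", "run", "bin"])
        run_keys = sub[["day", "run"]].drop_duplicates().reset_index(drop=True)
        values = np.zeros((len(run_keys), layout.n_bins))
        for i, (_, rk) in enumerate(run_keys.iterrows()):
            rows = sub[(sub["day"] == rk["day"]) & (sub["run"] == rk["run"])]
            _check_finite(rows["value"].to_numpy(), str(cid))
            values[i, rows["bin"].to_numpy(dtype=int)] = rows["value"].to_numpy()
        out.append(
            RunActivityMap(
                cell_id=str(cid),
                values=values,
                day_of_run=run_keys["day"].to_numpy(dtype=int),
                run_index=run_keys["run"].to_numpy(dtype=int),
                layout=layout,
            )
        )
    return out


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_results(
    tables: Dict[str, pd.DataFrame],
    path,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write named tables as ``<path>/<name>.csv`` plus a JSON sidecar.

    The sidecar records the configuration hash, the seed and the package
    version so outputs can be traced back to the run that produced them.
    Empty tables produce header-only CSVs.
    """
    from . import __version__

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    sidecar = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "package_version": __version__,
        "tables": sorted(tables),
    }
    (outdir / "provenance.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
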