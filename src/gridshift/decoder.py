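"""Key-value-memory decoding of track position from grid population vectors.

The memory stores (population vector, position) pairs from a training block;
recall computes similarities between a query vector and all stored keys,
applies a softmax with a large inverse temperature (beta = 1000, effectively
an argmax), and — to suppress discontinuous predictions — restricts eligible
keys to those whose stored position lies within a 300 cm neighbourhood of
the ground-truth position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["KvmDecoder", "subsample_by_phase", "sliding_window_mae"]


def subsample_by_phase(phases: np.ndarray, count: int, seed: int = 0) -> np.ndarray:
    """Pick ``count`` cells evenly covering the (phi1, phi2) torus.

    Farthest-point sampling under the toroidal metric; deterministic given
    the seed (which selects the starting cell).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[0]
    if count >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    d2 = _torus_d2(phases, phases[chosen[0]])
    for _ in range(count - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, _torus_d2(phases, phases[nxt]))
    return np.array(sorted(chosen))


def _torus_d2(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    d = np.abs(pts - ref[None, :])
    d = np.minimum(d, 2 * np.pi - d)
    return (d**2).sum(axis=1)


@dataclass
class KvmDecoder:
    """Nearest-key position decoder with softmax recall.

    Parameters mirror the study's decoder: ``beta`` (inverse temperature)
    1000, ``neighborhood_cm`` 300, dot-product similarity by default with
    cosine as an option.  Follows the fit/predict convention: ``fit`` stores
    the key/value pairs, ``predict`` decodes queries.
    """

    beta: float = 1000.0
    neighborhood_cm: float = 300.0
    similarity: str = "dot"  # or "cosine"

    def fit(self, keys: np.ndarray, positions_cm: np.ndarray) -> "KvmDecoder":
        keys = np.asarray(keys, dtype=np.float32)
        positions_cm = np.asarray(positions_cm, dtype=float)
        if keys.shape[0] != positions_cm.shape[0]:
            raise ValueError("keys and positions must align")
        if keys.shape[0] == 0:
            raise ValueError("empty training block")
        self.keys_ = keys
        self.values_ = positions_cm
        if self.similarity == "cosine":
            norms = np.linalg.norm(keys, axis=1)
            norms[norms == 0] = 1.0
            self._keys_unit = keys / norms[:, None]
        return self

    def predict(self, queries: np.ndarray, true_positions_cm: np.ndarray) -> np.ndarray:
        """Decode positions; ``true_positions_cm`` gates the key neighbourhood.

        Softmax with ``beta`` over similarities is effectively an argmax; an
        exact similarity tie returns the smaller stored position.
        """
        if not hasattr(self, "keys_"):
            raise RuntimeError("decoder is not fitted")
        queries = np.asarray(queries, dtype=np.float32)
        true_positions_cm = np.asarray(true_positions_cm, dtype=float)
        # sort once so per-query ties resolve to the smallest position
        order = np.argsort(self.values_, kind="stable")
        vals = self.values_[order]
        if self.similarity == "cosine":
            kmat = self._keys_unit[order]
            qn = np.linalg.norm(queries, axis=1)
            qn[qn == 0] = 1.0
            sims = (queries / qn[:, None]) @ kmat.T
        else:
            sims = queries @ self.keys_[order].T
        # values are sorted, so each neighbourhood is a contiguous key slice
        lo = np.searchsorted(vals, true_positions_cm - self.neighborhood_cm, side="left")
        hi = np.searchsorted(vals, true_positions_cm + self.neighborhood_cm, side="right")
        out = np.empty(queries.shape[0])
        for i in range(queries.shape[0]):
            if hi[i] <= lo[i]:
                raise ValueError("empty key neighbourhood around the true position")
            s = sims[i, lo[i] : hi[i]]
            # beta-softmax recall; at beta=1000 this is an argmax, and the
            # first (smallest-position) key wins exact ties
            out[i] = vals[lo[i] + int(np.argmax(s))]
        return out


def sliding_window_mae(
    run_vectors: Sequence[np.ndarray],
    run_positions: Sequence[np.ndarray],
    block: int = 10,
    eval_runs: int = 10,
    step: int = 5,
    decoder: Optional[KvmDecoder] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window decoding error across learning.

    Every ``step`` runs, a decoder is trained on a ``block``-run window and
    tested on the following ``eval_runs`` runs; the mean absolute error over
    all test positions is reported per evaluation point.  Windows that do not
    fit are skipped.  Returns ``(evaluation start runs, MAE values)``.
    """
    n_runs = len(run_vectors)
    starts, maes = [], []
    for start in range(block, n_runs - eval_runs + 1, step):
        train_idx = range(start - block, start)
        test_idx = range(start, start + eval_runs)
        keys = np.concatenate([run_vectors[i] for i in train_idx])
        vals = np.concatenate([run_positions[i] for i in train_idx])
        dec = decoder or KvmDecoder()
        dec.fit(keys, vals)
        queries = np.concatenate([run_vectors[i] for i in test_idx])
        truth = np.concatenate([run_positions[i] for i in test_idx])
        pred = dec.predict(queries, truth)
        starts.append(start)
        maes.append(float(np.mean(np.abs(pred - truth))))
    return np.asarray(starts), np.asarray(maes)
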