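"""Re-matching refinement for cross-session cell-registration outputs.

Cross-session registration tools align spatial footprints against a
chosen reference session and emit an index map: sessions x registered
neurons, each entry the neuron's within-session index (0 = undetected).
Different reference sessions yield different maps.  The re-matcher
assembles, per registered neuron, a candidate matrix from all reference
maps, scores full assignments with a registered score

    RS(J; alpha) = alpha * (mean pairwise same-cell likelihood among
                   detected sessions) + (1 - alpha) * (fraction of
                   sessions with a detection)

and improves the main-reference assignment by greedy coordinate ascent
(at most 20 sweeps; only neurons detected in more than six sessions are
optimized).  Proposed changes are returned for review, never applied
blindly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "IndexMap", "RegisteredSolution", "extract_continuous_pieces",
    "registered_score", "build_candidates", "greedy_optimize",
    "synthetic_index_maps", "DEFAULT_REFERENCES",
]

DEFAULT_REFERENCES = {13: (1, 3, 7, 10, 13),
                      26: (1, 3, 7, 10, 13, 17, 20, 23, 26)}


@dataclass
class IndexMap:
    """S x Q matrix of per-session neuron indices (0 = undetected)."""

    indices: np.ndarray
    reference_session: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(self.indices < 0):
            raise ValueError("indices must be non-negative")

    @property
    def n_sessions(self):
        return self.indices.shape[0]

    @property
    def n_neurons(self):
        return self.indices.shape[1]


@dataclass
class RegisteredSolution:
    J: np.ndarray
    score: float
    initial_score: float
    iterations: int
    changed_sessions: np.ndarray      # proposed changes, for manual review
    score_trace: list = dc_field(default_factory=list)


def extract_continuous_pieces(column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of nonzero entries in one registered-neuron column,
    bounded by zeros or the column ends; (start, end) half-open pairs."""
    col = np.asarray(column)
    nz = col != 0
    pieces = []
    start = None
    for i, v in enumerate(nz):
        if v and start is None:
            start = i
        elif not v and start is not None:
            pieces.append((start, i))
            start = None
    if start is not None:
        pieces.append((start, len(col)))
    return pieces


def registered_score(J: np.ndarray, likelihood, alpha: float = 0.5) -> float:
    """RS(J; alpha) over a session assignment J (0 = undetected).

    ``likelihood(s_i, idx_i, s_j, idx_j)`` returns the pairwise same-cell
    likelihood in [0, 1] or NaN when unavailable; non-missing upper-
    triangle cells among detected sessions are averaged (0 when there are
    none), and the structural term is the detected-session fraction.
    """
    J = np.asarray(J, dtype=int)
    if J.size == 0:
        raise ValueError("empty assignment")
    S = len(J)
    det = np.flatnonzero(J > 0)
    vals = []
    for a in range(len(det)):
        for b in range(a + 1, len(det)):
            i, j = det[a], det[b]
            v = likelihood(i, J[i], j, J[j])
            if v is not None and np.isfinite(v):
                vals.append(v)
    pair_term = float(np.mean(vals)) if vals else 0.0
    return alpha * pair_term + (1.0 - alpha) * len(det) / S


def build_candidates(maps: list[IndexMap], main: int, neuron: int,
                     likelihood=None) -> np.ndarray:
    """Candidate matrix (S x n_maps) for one registered neuron of the main map.

    The corresponding column in every other map is the one sharing the
    most session-position entries with the main column (ties broken by
    higher mean pairwise likelihood when available); no new indices are
    invented.
    """
    main_col = maps[main].indices[:, neuron]
    S = len(main_col)
    cols = [main_col]
    for k, m in enumerate(maps):
        if k == main:
            continue
        agree = (m.indices == main_col[:, None]) & (main_col[:, None] > 0)
        scores = agree.sum(axis=0)
        best = np.flatnonzero(scores == scores.max())
        if len(best) > 1 and likelihood is not None:
            means = []
            for q in best:
                col = m.indices[:, q]
                det = np.flatnonzero(col > 0)
                vals = [likelihood(i, col[i], j, col[j])
                        for a, i in enumerate(det) for j in det[a + 1:]]
                vals = [v for v in vals if v is not None and np.isfinite(v)]
                means.append(np.mean(vals) if vals else 0.0)
            best = [best[int(np.argmax(means))]]
        cols.append(m.indices[:, best[0]])
    return np.column_stack(cols)


def greedy_optimize(candidates: np.ndarray, likelihood, alpha: float = 0.5,
                    max_iter: int = 20, min_detections: int = 6) -> RegisteredSolution:
    """Coordinate-ascent refinement of the main-reference assignment.

    Each sweep updates every session entry to the candidate maximizing
    the registered score with the other entries fixed; stops at
    convergence or ``max_iter`` sweeps.  Columns detected in at most
    ``min_detections`` sessions are returned unchanged (not optimized).
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("empty candidate set")
    J = candidates[:, 0].copy()
    initial = registered_score(J, likelihood, alpha)
    trace = [initial]
    if int((J > 0).sum()) <= min_detections:
        return RegisteredSolution(J=J, score=initial, initial_score=initial,
                                  iterations=0,
                                  changed_sessions=np.array([], int),
                                  score_trace=trace)
    S = candidates.shape[0]
    it = 0
    for it in range(1, max_iter + 1):
        changed = False
        for s in range(S):
            options = np.unique(candidates[s])
            best_v, best_score = J[s], registered_score(J, likelihood, alpha)
            for v in options:
                if v == J[s]:
                    continue
                J_try = J.copy()
                J_try[s] = v
                sc = registered_score(J_try, likelihood, alpha)
                if sc > best_score:
                    best_v, best_score = v, sc
            if best_v != J[s]:
                J[s] = best_v
                changed = True
            trace.append(best_score)
        if not changed:
            break
    final = registered_score(J, likelihood, alpha)
    return RegisteredSolution(J=J, score=final, initial_score=initial,
                              iterations=it,
                              changed_sessions=np.flatnonzero(J != candidates[:, 0]),
                              score_trace=trace)


def make_likelihood_lookup(P: dict):
    """Likelihood callable from a dict {((s_i, idx_i), (s_j, idx_j)): p}."""
    def lookup(si, ii, sj, jj):
        key = ((si, ii), (sj, jj)) if (si, ii) <= (sj, jj) else ((sj, jj), (si, ii))
        return P.get(key, np.nan)
    return lookup


def synthetic_index_maps(n_neurons: int = 30, n_sessions: int = 13,
                         n_references: int = 5, detect_prob: float = 0.9,
                         error_rate: float = 0.0, rng=None) -> dict:
    """CellReg-like index maps with planted ground truth.

    Every true neuron has a per-session index; each reference map
    reproduces the truth except that entries are undetected with
    probability 1 - detect_prob and, with ``error_rate``, swapped with
    another neuron's index for that session (a registration error).
    Pairwise likelihoods are high (0.9-1.0) for same-truth pairs and low
    (0.0-0.2) otherwise.  The ground-truth assignment rides along.
    """
    rng = np.random.default_rng() if rng is None else rng
    truth = np.arange(1, n_neurons + 1)[None, :].repeat(n_sessions, axis=0)
    maps = []
    for _ in range(n_references):
        m = truth.copy()
        undet = rng.random(m.shape) > detect_prob
        m[undet] = 0
        if error_rate > 0:
            for s in range(n_sessions):
                for q in range(n_neurons):
                    if m[s, q] > 0 and rng.random() < error_rate:
                        other = int(rng.integers(1, n_neurons + 1))
                        m[s, q] = other
        maps.append(IndexMap(indices=m, reference_session=0))
    P = {}
    for s_i in range(n_sessions):
        for s_j in range(s_i + 1, n_sessions):
            for a in range(1, n_neurons + 1):
                for b in range(1, n_neurons + 1):
                    same = a == b
                    p = rng.uniform(0.9, 1.0) if same else rng.uniform(0.0, 0.2)
                    P[((s_i, a), (s_j, b))] = p
    return {"maps": maps, "likelihood": make_likelihood_lookup(P),
            "truth": truth}
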