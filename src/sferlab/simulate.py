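"""Stochastic discrete dynamical system defined by the evolution rule.

Each simulated place field carries an observable state s_t and a hidden
re-expression probability P_t.  Per session: s_t ~ Bernoulli(P_t), then
P_{t+1} = f(P_t) after an active state or g(P_t) after an inactive one,
plus additive Gaussian step noise, clipped to [0, 1].  A field silent
for ``gate`` consecutive sessions is permanently withdrawn ("drifted");
the rest are "online".  With injection on, each newly drifted field is
replaced the same session by a fresh field (s = 1, P = P2), holding the
online total constant.

The two link functions generally each have a stable fixed point -- a
high one under f (super-stable fields) and a low one under g (almost-
drifted fields) -- which act as competing attractors and split the
population into dual fates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SimConfig", "FieldEnsembleState", "step_ensemble", "run_simulation",
    "drift_rate_curve", "pt_density", "find_fixed_points", "classify_peaks",
]


@dataclass
class SimConfig:
    f: callable                     # link after an active state
    g: callable                     # link after an inactive state
    initial_prob: float = 0.525
    n_fields: int = 10000
    n_sessions: int = 200
    gate: int = 8
    step_noise_sigma: float = 0.01
    injection: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.gate < 1:
            raise ValueError("gate must be >= 1")
        if not (0.0 <= self.initial_prob <= 1.0):
            raise ValueError("initial_prob must be a probability")


@dataclass
class FieldEnsembleState:
    P: np.ndarray
    s: np.ndarray                  # bool, current observable state
    silent_count: np.ndarray
    online: np.ndarray             # bool; drifted fields are ~online
    session: int = 1
    cum_drifted: int = 0
    injected: int = 0
    newly_drifted: int = 0

    @classmethod
    def initial(cls, config: SimConfig) -> "FieldEnsembleState":
        n = config.n_fields
        return cls(P=np.full(n, config.initial_prob),
                   s=np.ones(n, dtype=bool),
                   silent_count=np.zeros(n, dtype=int),
                   online=np.ones(n, dtype=bool))


def step_ensemble(state: FieldEnsembleState, config: SimConfig,
                  rng) -> FieldEnsembleState:
    """Advance one session in place and return the state."""
    online = state.online
    draw = rng.random(state.P.shape[0])
    s_new = (draw < state.P) & online
    state.silent_count = np.where(s_new, 0,
                                  state.silent_count + online.astype(int))
    drifted_now = online & (state.silent_count >= config.gate)
    state.newly_drifted = int(drifted_now.sum())
    state.cum_drifted += state.newly_drifted
    state.online = online & ~drifted_now

    P_next = np.where(s_new, config.f(state.P), config.g(state.P))
    if config.step_noise_sigma > 0:
        P_next = P_next + rng.normal(0.0, config.step_noise_sigma, P_next.shape)
    state.P = np.clip(P_next, 0.0, 1.0)
    state.s = s_new

    if config.injection and state.newly_drifted > 0:
        # replace each newly drifted field with a fresh one the same session
        k = state.newly_drifted
        state.P = np.concatenate([state.P, np.full(k, config.initial_prob)])
        state.s = np.concatenate([state.s, np.ones(k, bool)])
        state.silent_count = np.concatenate([state.silent_count, np.zeros(k, int)])
        state.online = np.concatenate([state.online, np.ones(k, bool)])
        state.injected += k
    state.session += 1
    return state


def run_simulation(config: SimConfig, n_bins: int = 40) -> dict:
    """Simulate the ensemble; per-session drift bookkeeping and P_t densities.

    Returns a trajectory dict with per-session arrays: ``newly_drifted``,
    ``online`` (online count at session end), ``cum_drifted``,
    ``injected`` and ``density`` (n_sessions x n_bins normalized P_t
    histograms over online fields, 40 bins within (0, 1]).
    """
    rng = np.random.default_rng(config.seed)
    state = FieldEnsembleState.initial(config)
    T = config.n_sessions
    newly = np.zeros(T, dtype=int)
    online_n = np.zeros(T, dtype=int)
    cum = np.zeros(T, dtype=int)
    injected = np.zeros(T, dtype=int)
    dens = np.zeros((T, n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    online_n[0] = int(state.online.sum())
    dens[0] = _density(state.P[state.online], edges)
    for t in range(1, T):
        step_ensemble(state, config, rng)
        newly[t] = state.newly_drifted
        online_n[t] = int(state.online.sum())
        cum[t] = state.cum_drifted
        injected[t] = state.injected
        dens[t] = _density(state.P[state.online], edges)
    return {"newly_drifted": newly, "online": online_n, "cum_drifted": cum,
            "injected": injected, "density": dens, "edges": edges,
            "n_fields": config.n_fields, "final_state": state}


def _density(P: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if len(P) == 0:
        return np.zeros(len(edges) - 1)
    h, _ = np.histogram(P, bins=edges)
    return h / h.sum()


def drift_rate_curve(trajectory: dict) -> dict:
    """Newly drifted fields as a fraction of online fields per session,
    plus the non-decreasing cumulative drifted count."""
    online = np.maximum(trajectory["online"], 1)
    return {"newly_fraction": trajectory["newly_drifted"] / online,
            "cumulative": trajectory["cum_drifted"]}


def plateau_drift_rate(trajectory: dict, last_fraction: float = 0.1) -> float:
    """Mean newly-drifted/online over the final fraction of sessions."""
    frac = drift_rate_curve(trajectory)["newly_fraction"]
    k = max(int(round(last_fraction * len(frac))), 1)
    return float(frac[-k:].mean())


def pt_density(trajectory: dict, session: int) -> np.ndarray:
    """Normalized 40-bin P_t density over online fields at a session."""
    d = trajectory["density"][session]
    if d.sum() == 0:
        raise ValueError(f"no online fields at session {session}")
    return d


def find_fixed_points(link, lo: float = 0.0, hi: float = 1.0,
                      n_grid: int = 2001, tol: float = 1e-10) -> list[dict]:
    """Roots of link(P) = P on [lo, hi] with stability labels.

    Bracketed bisection on a fine grid; a fixed point is stable when
    |link'(P)| < 1 (central difference).  An identity link is reported as
    a single degenerate entry.
    """
    grid = np.linspace(lo, hi, n_grid)
    h = np.asarray(link(grid), dtype=float) - grid
    if np.allclose(h, 0.0, atol=1e-12):
        return [{"P": None, "stable": None, "degenerate": True}]
    out = []
    for i in range(n_grid - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = h[i], h[i + 1]
        root = None
        if fa == 0.0:
            root = a
        elif fa * fb < 0:
            while b - a > tol:
                m = 0.5 * (a + b)
                fm = float(link(m)) - m
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            root = 0.5 * (a + b)
        if root is not None and not any(abs(root - o["P"]) < 1e-6 for o in out):
            eps = 1e-5
            x0, x1 = max(lo, root - eps), min(hi, root + eps)
            deriv = (float(link(x1)) - float(link(x0))) / (x1 - x0)
            out.append({"P": float(root), "stable": bool(abs(deriv) < 1.0),
                        "degenerate": False})
    if abs(h[-1]) == 0.0 and not any(abs(grid[-1] - o["P"]) < 1e-6 for o in out):
        out.append({"P": float(grid[-1]), "stable": None, "degenerate": False})
    return out


def classify_peaks(trajectory: dict, initial_prob: float | None = None,
                   min_prominence: float = 0.01) -> dict:
    """Track up to three density peaks across sessions.

    Peaks are local maxima of each session's P_t density; they are
    labeled "new" (nearest the initial probability), "low" and "high".
    Returns per-session peak positions and masses (NaN when a peak is
    absent); degenerate unimodal sessions simply populate fewer tracks.
    """
    dens = trajectory["density"]
    edges = trajectory["edges"]
    centers = 0.5 * (edges[:-1] + edges[1:])
    T = dens.shape[0]
    tracks = {lab: {"position": np.full(T, np.nan), "mass": np.full(T, np.nan)}
              for lab in ("new", "low", "high")}
    p2 = initial_prob if initial_prob is not None else float(
        centers[np.argmax(dens[0])])
    for t in range(T):
        d = dens[t]
        if d.sum() == 0:
            continue
        idx, props = find_peaks(np.concatenate([[0.0], d, [0.0]]),
                                prominence=min_prominence)
        idx = idx - 1
        peaks = [(centers[i], d[i]) for i in idx if 0 <= i < len(centers)]
        if not peaks:
            i = int(np.argmax(d))
            peaks = [(centers[i], d[i])]
        remaining = list(peaks)
        # "new" peak: nearest the initial probability
        new_pk = min(remaining, key=lambda p: abs(p[0] - p2))
        if abs(new_pk[0] - p2) <= 0.1:
            tracks["new"]["position"][t] = new_pk[0]
            tracks["new"]["mass"][t] = new_pk[1]
            remaining.remove(new_pk)
        if remaining:
            low_pk = min(remaining, key=lambda p: p[0])
            high_pk = max(remaining, key=lambda p: p[0])
            if low_pk[0] < p2:
                tracks["low"]["position"][t] = low_pk[0]
                tracks["low"]["mass"][t] = low_pk[1]
            if high_pk is not low_pk and high_pk[0] > p2:
                tracks["high"]["position"][t] = high_pk[0]
                tracks["high"]["mass"][t] = high_pk[1]
            elif high_pk is low_pk and high_pk[0] > p2:
                tracks["high"]["position"][t] = high_pk[0]
                tracks["high"]["mass"][t] = high_pk[1]
                tracks["low"]["position"][t] = np.nan
                tracks["low"]["mass"][t] = np.nan
    n_tracks = sum(1 for lab in tracks
                   if np.isfinite(tracks[lab]["mass"]).any())
    return {"tracks": tracks, "n_tracks": n_tracks}
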