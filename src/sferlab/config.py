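"""Generator configuration and hazard-curve calibration.

The synthetic cohorts emulate long-term tracking of hippocampal place
fields across recording sessions.  Each registered field contributes a
binary *field-state sequence* starting with 1 at its formation session.
Two empirical hazard curves summarize history dependence:

* retention: P(active next session | active for t_a consecutive sessions),
  an increasing reciprocal curve  r(t_a) = 1 - L1 / (t_a + b1);
* recovery:  P(active next session | silent for t_i consecutive sessions),
  a decreasing stretched-exponential (KWW) curve q(t_i) = a*exp(-(t_i/b)^c).

The default calibration pins both curves to reference values:
r(1) = 0.525, r(8) = 0.898 and q(1) = 0.297, q(8) = 0.035.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "GeneratorConfig",
    "reciprocal_retention",
    "kww_recovery",
    "solve_reciprocal_calibration",
    "solve_kww_calibration",
    "hazard_induced_links",
    "DEFAULT_RETENTION_POINTS",
    "DEFAULT_RECOVERY_POINTS",
]

# Reference retention / recovery probabilities at durations 1 and 8.
DEFAULT_RETENTION_POINTS = ((1, 0.525), (8, 0.898))
DEFAULT_RECOVERY_POINTS = ((1, 0.297), (8, 0.035))
DEFAULT_KWW_STRETCH = 0.8


def reciprocal_retention(t_a, L1: float, b1: float):
    """Retention curve r(t_a) = 1 - L1/(t_a + b1), clipped to [0, 1]."""
    t_a = np.asarray(t_a, dtype=float)
    return np.clip(1.0 - L1 / (t_a + b1), 0.0, 1.0)


def kww_recovery(t_i, a: float, b: float, c: float):
    """Recovery curve q(t_i) = a * exp(-(t_i/b)^c), clipped to [0, 1]."""
    t_i = np.asarray(t_i, dtype=float)
    return np.clip(a * np.exp(-((t_i / b) ** c)), 0.0, 1.0)


def solve_reciprocal_calibration(points=DEFAULT_RETENTION_POINTS):
    """Solve (L1, b1) so the reciprocal curve passes through two points.

    From 1 - L1/(t + b1) = p at (t1, p1) and (t2, p2):
    b1 = ((1-p2)*t2 - (1-p1)*t1) / ((1-p1) - (1-p2)), L1 = (1-p1)*(t1+b1).
    """
    (t1, p1), (t2, p2) = points
    u1, u2 = 1.0 - p1, 1.0 - p2
    if u1 == u2:
        raise ValueError("degenerate calibration points")
    b1 = (u2 * t2 - u1 * t1) / (u1 - u2)
    L1 = u1 * (t1 + b1)
    return float(L1), float(b1)


def solve_kww_calibration(points=DEFAULT_RECOVERY_POINTS, c: float = DEFAULT_KWW_STRETCH):
    """Solve (a, b) so the KWW curve with stretch exponent c hits two points.

    The two constraints leave one free parameter; the stretch exponent is
    held fixed (default 0.8, a typical stretched-exponential value) and
    a, b follow in closed form.
    """
    (t1, p1), (t2, p2) = points
    if not (p1 > p2 > 0):
        raise ValueError("recovery calibration must be decreasing and positive")
    ratio = math.log(p1 / p2)
    scale = (t2**c - t1**c) / ratio  # = b^c
    b = scale ** (1.0 / c)
    a = p1 * math.exp((t1 / b) ** c)
    return float(a), float(b), float(c)


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def hazard_induced_links(retention_params, recovery_params, degree: int = 1,
                         max_duration: int = 12):
    """Least-squares link functions (f, g) induced by the hazard calibration.

    Builds the one-step transition pairs implied by the duration-based
    hazards -- along an active run P moves r(t) -> r(t+1), along a silent
    run q(t) -> q(t+1), a recovery resets to r(1), a disappearance resets
    to q(1) -- and fits polynomial links f (after an active state) and g
    (after an inactive state) to those pairs.  Deterministic; used for the
    generator's default SFER-mode links.

    Returns (f_coeffs, g_coeffs) in increasing-power order.
    """
    L1, b1 = retention_params
    a, b, c = recovery_params
    t = np.arange(1, max_duration + 1, dtype=float)
    r = reciprocal_retention(t, L1, b1)
    q = kww_recovery(t, a, b, c)

    # pairs (previous P, next P) conditioned on the previous state
    f_x = np.concatenate([r[:-1], q])          # active run continues / recovery
    f_y = np.concatenate([r[1:], np.full_like(q, r[0])])
    g_x = np.concatenate([q[:-1], r])          # silence continues / disappearance
    g_y = np.concatenate([q[1:], np.full_like(r, q[0])])

    f_coef, *_ = np.linalg.lstsq(_poly_design(f_x, degree), f_y, rcond=None)
    g_coef, *_ = np.linalg.lstsq(_poly_design(g_x, degree), g_y, rcond=None)
    return f_coef, g_coef


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults describe the reference recording conditions: 500 neurons on a 9 m
    track, per-neuron field propensities lambda_i ~ Gamma(shape 5.3,
    rate 9.4) fields per meter, 26 tracked sessions, silent-session gate
    of 8, neuron-level day-to-day fluctuation sigma 0.1 and per-step
    simulation noise sigma 0.01.
    """

    n_neurons: int = 500
    track_length_m: float = 9.0
    gamma_shape: float = 5.3
    gamma_rate: float = 9.4
    n_sessions: int = 26
    initial_prob: float | None = None  # P2; default = calibrated r(1)
    retention_params: tuple = None
    recovery_params: tuple = None
    sfer_f: np.ndarray | None = None   # polynomial coefficients, increasing power
    sfer_g: np.ndarray | None = None
    fluct_sigma: float = 0.1
    step_noise_sigma: float = 0.01
    gate: int = 8
    missing_rate: float = 0.0
    seed: int | None = None
    retention_points: tuple = DEFAULT_RETENTION_POINTS
    recovery_points: tuple = DEFAULT_RECOVERY_POINTS

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        if self.track_length_m <= 0:
            raise ValueError("track length must be positive")
        if self.n_sessions < 2:
            raise ValueError("need at least 2 sessions")
        if self.gate < 1:
            raise ValueError("gate must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.retention_params is None:
            self.retention_params = solve_reciprocal_calibration(self.retention_points)
        if self.recovery_params is None:
            self.recovery_params = solve_kww_calibration(self.recovery_points)
        if self.sfer_f is None or self.sfer_g is None:
            f_coef, g_coef = hazard_induced_links(self.retention_params,
                                                  self.recovery_params)
            if self.sfer_f is None:
                self.sfer_f = f_coef
            if self.sfer_g is None:
                self.sfer_g = g_coef
        if self.initial_prob is None:
            L1, b1 = self.retention_params
            self.initial_prob = float(reciprocal_retention(1.0, L1, b1))
        if not (0.0 <= self.initial_prob <= 1.0):
            raise ValueError("initial_prob must be a probability")

    def retention_curve(self, t_a):
        return reciprocal_retention(t_a, *self.retention_params)

    def recovery_curve(self, t_i):
        return kww_recovery(t_i, *self.recovery_params)

    def f_link(self, p):
        return np.clip(np.polyval(self.sfer_f[::-1], p), 0.0, 1.0)

    def g_link(self, p):
        return np.clip(np.polyval(self.sfer_g[::-1], p), 0.0, 1.0)

    def rng(self):
        return np.random.default_rng(self.seed)
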