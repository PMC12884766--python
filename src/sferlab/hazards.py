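"""Duration-conditioned retention and recovery hazards and their fits.

The preliminary single-field evolution rule: the probability that a field
stays active grows with its retained duration t_a (reciprocal curve,
r(t_a) = 1 - L1/(t_a + b1)) and the probability that a silent field
recovers decays with its silent duration t_i (stretched-exponential KWW
curve, q(t_i) = a*exp(-(t_i/b)^c)).  Each position in a field-state
sequence with an observed successor contributes one sample at its current
run duration, so a long run contributes at every shorter duration too.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

from .config import reciprocal_retention, kww_recovery
from .sequences import FieldStateSequence

__all__ = [
    "HazardCurve",
    "ReciprocalFit",
    "KWWFit",
    "retention_probability",
    "recovery_probability",
    "cumulative_recovery",
    "fit_retention_reciprocal",
    "fit_recovery_kww",
    "stratified_hazards",
]


@dataclass
class HazardCurve:
    durations: np.ndarray      # positive ints
    probs: np.ndarray
    n_samples: np.ndarray
    ci: np.ndarray             # (len, 2) 95% Wilson intervals

    def prob_at(self, duration: int) -> float:
        idx = np.flatnonzero(self.durations == duration)
        if len(idx) == 0:
            raise KeyError(f"duration {duration} not in curve")
        return float(self.probs[idx[0]])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"duration": self.durations, "prob": self.probs,
                             "n": self.n_samples, "ci_lo": self.ci[:, 0],
                             "ci_hi": self.ci[:, 1]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReciprocalFit:
    L1: float
    b1: float
    rss: float
    alt_form: bool = False

    def __call__(self, t_a):
        if self.alt_form:
            return np.clip(1.0 - self.L1 / np.asarray(t_a, float) + self.b1, 0.0, 1.0)
        return reciprocal_retention(t_a, self.L1, self.b1)


@dataclass
class KWWFit:
    a: float
    b: float
    c: float
    rss: float

    def __call__(self, t_i):
        return kww_recovery(t_i, self.a, self.b, self.c)


def _states(seq) -> np.ndarray:
    return seq.states if isinstance(seq, FieldStateSequence) else np.asarray(seq)


def _collect_samples(sequences, kind: str):
    """(duration, outcome) samples for retention ('active' runs) or
    recovery ('silent' runs, only after the field has been active)."""
    samples = []
    for seq in sequences:
        s = _states(seq)
        run = 0
        for t in range(1, len(s)):
            prev = s[t - 1]
            if kind == "retention":
                run = run + 1 if prev == 1 else 0
            else:
                run = run + 1 if prev == 0 else 0
            if run > 0:
                samples.append((run, int(s[t])))
    return samples


def _curve_from_samples(samples, max_duration, min_samples):
    if not samples:
        return HazardCurve(durations=np.array([], int), probs=np.array([]),
                           n_samples=np.array([], int), ci=np.zeros((0, 2)))
    samples = np.asarray(samples)
    durations, probs, ns, cis = [], [], [], []
    top = samples[:, 0].max() if max_duration is None else max_duration
    for d in range(1, int(top) + 1):
        sel = samples[samples[:, 0] == d]
        if len(sel) < min_samples:
            continue
        k, n = int(sel[:, 1].sum()), len(sel)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        durations.append(d)
        probs.append(k / n)
        ns.append(n)
        cis.append((lo, hi))
    return HazardCurve(durations=np.array(durations, int), probs=np.array(probs),
                       n_samples=np.array(ns, int), ci=np.array(cis))


def retention_probability(sequences, max_duration: int | None = None,
                          min_samples: int = 5) -> HazardCurve:
    """P(stay active | active for t_a consecutive sessions).

    Every position with an observed successor contributes one sample at
    the length of the active run ending there; duration bins with fewer
    than ``min_samples`` samples (default 5) are excluded.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences")
    return _curve_from_samples(_collect_samples(sequences, "retention"),
                               max_duration, min_samples)


def recovery_probability(sequences, max_duration: int | None = None,
                         min_samples: int = 5) -> HazardCurve:
    """P(recover | silent for t_i consecutive sessions), same counting rule."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences")
    return _curve_from_samples(_collect_samples(sequences, "silent"),
                               max_duration, min_samples)


def cumulative_recovery(sequences, horizon: int = 5, chance_curve=None) -> float:
    """Fraction of disappearance events followed by recovery within
    ``horizon`` sessions, minus the same statistic on a chance recovery
    curve (per-silent-duration probabilities) when provided."""
    events = recovered = 0
    for seq in sequences:
        s = _states(seq)
        for t in range(1, len(s)):
            if s[t - 1] == 1 and s[t] == 0:
                events += 1
                # first recovery opportunity is the session after the
                # disappearance (silent duration 1)
                if np.any(s[t + 1:t + 1 + horizon] == 1):
                    recovered += 1
    if events == 0:
        raise ValueError("no disappearance events")
    frac = recovered / events
    chance = 0.0
    if chance_curve is not None:
        q = np.asarray(chance_curve, dtype=float)[:horizon]
        chance = 1.0 - np.prod(1.0 - q)
    return float(frac - chance)


def _check_curve(curve: HazardCurve):
    if len(curve.durations) < 3:
        raise ValueError("need at least 3 durations to fit")
    if np.allclose(curve.probs, curve.probs[0]) and curve.probs[0] in (0.0, 1.0):
        warnings.warn("degenerate constant hazard curve", stacklevel=3)


def fit_retention_reciprocal(curve: HazardCurve, alt_form: bool = False) -> ReciprocalFit:
    """Least-squares fit of r(t_a) = 1 - L1/(t_a + b1).

    ``alt_form`` fits the alternative reading 1 - L1/t_a + b1 instead.
    """
    _check_curve(curve)
    t, p = curve.durations.astype(float), curve.probs
    if alt_form:
        fun = lambda t, L1, b1: 1.0 - L1 / t + b1
        p0 = (0.5, 0.0)
    else:
        fun = lambda t, L1, b1: 1.0 - L1 / (t + b1)
        p0 = (0.5, 0.5)
    popt, _ = curve_fit(fun, t, p, p0=p0, maxfev=20000)
    rss = float(np.sum((fun(t, *popt) - p) ** 2))
    return ReciprocalFit(L1=float(popt[0]), b1=float(popt[1]), rss=rss,
                         alt_form=alt_form)


def fit_recovery_kww(curve: HazardCurve) -> KWWFit:
    """Least-squares fit of the stretched exponential q(t_i) = a*exp(-(t_i/b)^c)."""
    _check_curve(curve)
    t, p = curve.durations.astype(float), curve.probs
    fun = lambda t, a, b, c: a * np.exp(-((t / b) ** c))
    popt, _ = curve_fit(fun, t, p, p0=(max(p[0], 1e-3), 2.0, 0.9),
                        bounds=([0.0, 1e-6, 0.05], [1.5, 1e3, 5.0]), maxfev=20000)
    rss = float(np.sum((fun(t, *popt) - p) ** 2))
    return KWWFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), rss=rss)


def stratified_hazards(sequences, strata_labels, max_duration: int | None = None,
                       min_samples: int = 5) -> dict:
    """Retention/recovery curves per stratum (novelty, position, SNR...).

    ``strata_labels`` assigns one label per sequence; strata with no
    usable samples are omitted with a warning.
    """
    sequences = list(sequences)
    labels = np.asarray(strata_labels)
    if len(labels) != len(sequences):
        raise ValueError("one label per sequence required")
    out = {}
    for lab in np.unique(labels):
        group = [s for s, l in zip(sequences, labels) if l == lab]
        ret = retention_probability(group, max_duration, min_samples)
        rec = recovery_probability(group, max_duration, min_samples)
        if len(ret.durations) == 0 and len(rec.durations) == 0:
            warnings.warn(f"stratum {lab!r} has no usable samples; omitted",
                          stacklevel=2)
            continue
        out[lab] = {"retention": ret, "recovery": rec}
    return out
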