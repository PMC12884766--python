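"""Field registration and field-state sequence preparation.

Turns per-session place-field sets (or a registered field-activity table)
into analysis-ready binary field-state sequences: cross-session linking by
spatial overlap, missing-data handling (single flanked gaps in-filled,
remaining gaps split), lifespans, the initial re-expression probability,
and shuffle-based chance levels for the hazard curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FieldActivityTable

__all__ = [
    "FieldStateSequence",
    "SessionField",
    "register_fields",
    "prepare_sequences",
    "compute_lifespans",
    "estimate_initial_probability",
    "shuffle_chance_levels",
]


@dataclass
class FieldStateSequence:
    """Binary evolution trace of one registered field, starting at formation."""

    states: np.ndarray             # int8 vector, states[0] == 1
    field_id: int = -1
    formation_session: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or len(self.states) < 1:
            raise ValueError("states must be a non-empty 1-D vector")
        if self.states[0] != 1:
            raise ValueError("a field-state sequence must start with 1")

    def __len__(self):
        return len(self.states)


@dataclass
class SessionField:
    """One place field observed in one session: a bin mask with rates."""

    neuron: int
    mask: np.ndarray               # boolean over the common bin grid
    rates: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rates is None:
            self.rates = self.mask.astype(float)
        else:
            self.rates = np.asarray(self.rates, dtype=float)


def _overlap(a: np.ndarray, b: np.ndarray, denominator: str = "min") -> float:
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    if denominator == "min":
        denom = min(np.count_nonzero(a), np.count_nonzero(b))
    elif denominator == "max":
        denom = max(np.count_nonzero(a), np.count_nonzero(b))
    elif denominator == "union":
        denom = np.count_nonzero(a | b)
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return inter / denom


def _saddle_to_peak(profile: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Saddle-to-peak ratio of a 1-D summed rate profile between two fields.

    The saddle is the minimum of the profile on the gap between the two
    bin sets (or on the overlap if they touch); the peak is the lower of
    the two field peaks.
    """
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    peak = min(profile[ia].max(), profile[ib].max())
    if peak <= 0:
        return 0.0
    lo, hi = (ia.max(), ib.min()) if ia.max() < ib.min() else (ib.max(), ia.min())
    if lo >= hi:   # overlapping or adjacent fields: saddle on the overlap
        between = np.flatnonzero(mask_a & mask_b)
        if len(between) == 0:
            return 1.0
    else:
        between = np.arange(lo, hi + 1)
    return float(profile[between].min() / peak)


def register_fields(per_session_field_sets, n_sessions: int | None = None,
                    neurons_present=None, overlap_threshold: float = 0.75,
                    merge_threshold: float = 0.5,
                    overlap_denominator: str = "min") -> FieldActivityTable:
    """Link place fields across sessions into registered fields.

    Fields are chained greedily session by session: a field links to an
    existing registered field of the same neuron when their bin-mask
    overlap is at least ``overlap_threshold`` (default 75%, measured
    against the smaller field).  After linking, the per-field rates are
    normalized and summed across sessions, and same-neuron field pairs
    whose summed profile has a saddle-to-peak ratio above
    ``merge_threshold`` are merged; the rest stay distinct.  Sessions in
    which a field's neuron was not observed yield missing entries.
    """
    grids = {f.mask.shape for sess in per_session_field_sets for f in sess}
    if len(grids) > 1:
        raise ValueError("inconsistent grid dimensions across fields")
    S = n_sessions if n_sessions is not None else len(per_session_field_sets)

    registered = []   # dicts: neuron, mask, sessions {s: SessionField}
    for s, sess_fields in enumerate(per_session_field_sets):
        for f in sess_fields:
            best, best_ov = None, 0.0
            for reg in registered:
                if reg["neuron"] != f.neuron or s in reg["sessions"]:
                    continue
                ov = _overlap(reg["mask"], f.mask, overlap_denominator)
                if ov >= overlap_threshold and ov > best_ov:
                    best, best_ov = reg, ov
            if best is None:
                registered.append({"neuron": f.neuron, "mask": f.mask.copy(),
                                   "sessions": {s: f}})
            else:
                best["sessions"][s] = f
                best["mask"] = best["mask"] | f.mask

    # exception handling: merge same-neuron registered fields whose summed
    # normalized rate profiles are not separated by a deep enough saddle
    def summed_profile(reg):
        total = None
        for f in reg["sessions"].values():
            r = f.rates
            peak = r.max()
            norm = r / peak if peak > 0 else r
            total = norm if total is None else total + norm
        return total

    merged = True
    while merged:
        merged = False
        for i in range(len(registered)):
            for j in range(i + 1, len(registered)):
                a, b = registered[i], registered[j]
                if a["neuron"] != b["neuron"]:
                    continue
                profile = summed_profile(a) + summed_profile(b)
                if profile.ndim != 1:
                    continue  # saddle merging defined on linearized profiles
                ratio = _saddle_to_peak(profile, a["mask"], b["mask"])
                if ratio > merge_threshold:
                    a["mask"] = a["mask"] | b["mask"]
                    for s, f in b["sessions"].items():
                        a["sessions"].setdefault(s, f)
                    del registered[j]
                    merged = True
                    break
            if merged:
                break

    states = np.zeros((len(registered), S))
    neurons = np.array([reg["neuron"] for reg in registered], dtype=int)
    if neurons_present is not None:
        for s in range(S):
            present = set(neurons_present[s])
            absent = np.array([n not in present for n in neurons])
            states[absent, s] = np.nan
    for k, reg in enumerate(registered):
        for s in reg["sessions"]:
            states[k, s] = 1.0
    table = FieldActivityTable(states=states, neuron_of_field=neurons)
    table.masks = [reg["mask"] for reg in registered]
    return table


def _infill_single_gaps(row: np.ndarray) -> np.ndarray:
    """Set a single missing entry to 1 when flanked by active sessions.

    Runs of two or more consecutive missing entries are never in-filled.
    """
    out = row.copy()
    for t in range(1, len(row) - 1):
        if (np.isnan(row[t]) and not np.isnan(row[t - 1]) and not np.isnan(row[t + 1])
                and row[t - 1] == 1 and row[t + 1] == 1):
            out[t] = 1.0
    return out


def prepare_sequences(table, infill: bool = True) -> list[FieldStateSequence]:
    """Field-state sequences from an activity table.

    Single missing entries flanked by active states become 1; sequences
    are then split at remaining missing entries, and each emitted segment
    starts at its first active (formation) session.  All-zero rows emit
    nothing; a row may emit several sequences.
    """
    if isinstance(table, FieldActivityTable):
        states = table.states
    else:
        states = np.asarray(table, dtype=float)
    sequences = []
    for i, row in enumerate(states):
        if infill:
            row = _infill_single_gaps(row)
        # split at missing entries
        isnan = np.isnan(row)
        for seg_start, seg_end in _segments(~isnan):
            seg = row[seg_start:seg_end]
            ones = np.flatnonzero(seg == 1)
            if len(ones) == 0:
                continue
            f = ones[0]
            sequences.append(FieldStateSequence(states=seg[f:].astype(np.int8),
                                                field_id=i,
                                                formation_session=seg_start + f))
    return sequences


def _segments(mask: np.ndarray):
    """(start, end) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts, ends))


def compute_lifespans(sequences) -> list[int]:
    """Lifespan multiset: every maximal run of consecutive active sessions
    contributes its length (a dynamic field is counted multiple times)."""
    spans = []
    for seq in sequences:
        s = seq.states if isinstance(seq, FieldStateSequence) else np.asarray(seq)
        for a, b in _segments(s == 1):
            spans.append(int(b - a))
    return spans


def estimate_initial_probability(sequences) -> float:
    """P2: mean second state over all sequences of length >= 2."""
    vals = [int(seq.states[1]) for seq in sequences if len(seq) >= 2]
    if not vals:
        raise ValueError("no sequence with length >= 2")
    return float(np.mean(vals))


def shuffle_chance_levels(per_session_field_sets, n_shuffles: int = 100,
                          seed: int | None = None, max_duration: int = 8,
                          **register_kwargs):
    """Chance-level retention/recovery curves from randomized registration.

    Each shuffle relocates every field's bin mask uniformly within the
    grid (field count and size preserved per neuron), re-registers, and
    re-estimates the hazard curves; returns per-duration means with 95%
    bands across shuffles.
    """
    from .hazards import retention_probability, recovery_probability

    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng(seed)
    n_bins = per_session_field_sets[0][0].mask.shape[0] if \
        any(per_session_field_sets) and per_session_field_sets[0] else None
    for sess in per_session_field_sets:
        for f in sess:
            n_bins = f.mask.shape[0]
            break
        if n_bins is not None:
            break

    ret_curves, rec_curves = [], []
    for _ in range(n_shuffles):
        shuffled = []
        for sess in per_session_field_sets:
            new_sess = []
            for f in sess:
                size = int(np.count_nonzero(f.mask))
                start = rng.integers(0, max(n_bins - size, 0) + 1)
                mask = np.zeros(n_bins, dtype=bool)
                mask[start:start + size] = True
                rates = np.zeros(n_bins)
                rates[mask] = np.sort(f.rates[f.mask])[::-1][:size] if \
                    f.rates is not None else 1.0
                new_sess.append(SessionField(neuron=f.neuron, mask=mask, rates=rates))
            shuffled.append(new_sess)
        table = register_fields(shuffled, **register_kwargs)
        seqs = prepare_sequences(table)
        try:
            ret = retention_probability(seqs, max_duration=max_duration, min_samples=1)
            rec = recovery_probability(seqs, max_duration=max_duration, min_samples=1)
        except ValueError:
            continue
        ret_curves.append(_curve_to_vec(ret, max_duration))
        rec_curves.append(_curve_to_vec(rec, max_duration))

    def summarize(curves):
        arr = np.vstack(curves) if curves else np.full((1, max_duration), np.nan)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN durations
            return {"mean": np.nanmean(arr, axis=0),
                    "lo": np.nanpercentile(arr, 2.5, axis=0),
                    "hi": np.nanpercentile(arr, 97.5, axis=0)}

    return {"retention": summarize(ret_curves), "recovery": summarize(rec_curves),
            "durations": np.arange(1, max_duration + 1)}


def write_sequences_tsv(sequences, path) -> None:
    """Ragged TSV export: field_id, formation_session, states as 0/1 string."""
    import pandas as pd
    rows = [(s.field_id, s.formation_session,
             "".join(str(int(v)) for v in s.states)) for s in sequences]
    pd.DataFrame(rows, columns=["field_id", "formation_session", "states"]) \
        .to_csv(path, sep="\t", index=False)


def read_sequences_tsv(path) -> list[FieldStateSequence]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype={"states": str})
    return [FieldStateSequence(states=np.array([int(ch) for ch in r.states],
                                               dtype=np.int8),
                               field_id=int(r.field_id),
                               formation_session=int(r.formation_session))
            for r in df.itertuples(index=False)]


def _curve_to_vec(curve, max_duration):
    vec = np.full(max_duration, np.nan)
    for d, p in zip(curve.durations, curve.probs):
        if 1 <= d <= max_duration:
            vec[d - 1] = p
    return vec
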