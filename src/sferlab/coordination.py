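"""Inter-field coordination among sibling place fields.

Between consecutive sessions each tracked field undergoes one of three
evolutionary events: disappearance e1 = [1,0], formation e2 = [0,1] or
retention e3 = [1,1] ([0,0] pairs are excluded).  If fields evolved
independently, the pairwise joint probability of events would factorize
into the marginals; coordination is quantified by a chi-square statistic
over the 3x3 joint table and by the residual matrix R_ij = P(e_i, e_j) -
P_i P_j, whose diagonal captures synchronization of identical events.
Sibling pairs are fields of the same neuron separated by at least 50 cm
along the track.

The module also implements the two interaction mechanisms that restore
the observed synchronization in simulation: Gamma-Poisson field
assignment via per-neuron satiety, and neuron-level day-to-day
fluctuations shared by sibling fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .cohort import FieldActivityTable, SyntheticCohort

__all__ = [
    "EventPairTable", "CoordinationResult", "classify_transition_events",
    "chi_square_coordination", "permutation_null", "satiety",
    "multinomial_assignment", "simulate_interacting_sfer",
    "sibling_residuals",
]

EVENTS = {"disappearance": 0, "formation": 1, "retention": 2}
MIN_SIBLING_SEPARATION_CM = 50.0


@dataclass
class EventPairTable:
    """Per-field event labels for one consecutive-session pair, with
    sibling and non-sibling pair lists (index pairs into ``events``)."""

    events: np.ndarray            # event code per participating field
    field_ids: np.ndarray
    sibling_pairs: np.ndarray     # (n, 2)
    nonsibling_pairs: np.ndarray  # (n, 2)


def classify_transition_events(table: FieldActivityTable, session_pair,
                               min_separation_cm: float = MIN_SIBLING_SEPARATION_CM,
                               max_nonsibling: int | None = None,
                               rng=None) -> EventPairTable:
    """Label fields by their transition event between two sessions.

    Fields showing [0,0] or any missing entry in the pair are excluded.
    Sibling pairs are same-neuron pairs with center separation of at
    least ``min_separation_cm``; the non-sibling baseline is an
    equal-sized random sample of cross-neuron pairs (all of them when
    ``max_nonsibling`` is None and fewer exist).
    """
    t0, t1 = session_pair
    if not (0 <= t0 < table.n_sessions and 0 <= t1 < table.n_sessions):
        raise KeyError(f"unknown sessions {session_pair}")
    a = table.states[:, t0]
    b = table.states[:, t1]
    valid = ~np.isnan(a) & ~np.isnan(b) & ~((a == 0) & (b == 0))
    idx = np.flatnonzero(valid)
    code = np.where((a[idx] == 1) & (b[idx] == 0), 0,
                    np.where((a[idx] == 0) & (b[idx] == 1), 1, 2))
    neurons = table.neuron_of_field[idx]
    centers = table.centers_cm[idx] if table.centers_cm is not None else None

    sib, nonsib = [], []
    order = np.argsort(neurons, kind="stable")
    sorted_n = neurons[order]
    bounds = np.flatnonzero(np.diff(sorted_n)) + 1
    groups = np.split(order, bounds)
    for grp in groups:
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if centers is not None and \
                        abs(centers[grp[i]] - centers[grp[j]]) < min_separation_cm:
                    continue
                sib.append((grp[i], grp[j]))
    rng = np.random.default_rng() if rng is None else rng
    n_target = max_nonsibling if max_nonsibling is not None else len(sib)
    n_target = max(n_target, 1)
    tries = 0
    seen = set()
    while len(nonsib) < n_target and tries < 50 * n_target and len(idx) > 1:
        i, j = rng.integers(0, len(idx), 2)
        tries += 1
        if i == j or neurons[i] == neurons[j] or (min(i, j), max(i, j)) in seen:
            continue
        seen.add((min(i, j), max(i, j)))
        nonsib.append((i, j))
    return EventPairTable(events=code, field_ids=idx,
                          sibling_pairs=np.array(sib, int).reshape(-1, 2),
                          nonsibling_pairs=np.array(nonsib, int).reshape(-1, 2))


@dataclass
class CoordinationResult:
    marginals: np.ndarray         # P1, P2, P3
    joint: np.ndarray             # 3x3 symmetric
    chi2: float
    residuals: np.ndarray         # 3x3
    n_pairs: int


def chi_square_coordination(events: np.ndarray, pairs: np.ndarray,
                            expected_denominator: bool = False) -> CoordinationResult:
    """Chi-square coordination statistic over unordered event pairs.

    chi2 = N * sum_ij (P(e_i,e_j) - P_i P_j)^2 / P(e_i,e_j), with N the
    number of pairs; cells with zero joint probability are skipped.  The
    denominator is the observed joint probability;
    ``expected_denominator=True`` switches to the textbook P_i P_j.
    The residual matrix is R_ij = P(e_i,e_j) - P_i P_j.
    """
    pairs = np.asarray(pairs, int).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("no pairs")
    counts = np.bincount(events, minlength=3).astype(float)
    marg = counts / counts.sum()
    joint = np.zeros((3, 3))
    for i, j in pairs:
        a, b = events[i], events[j]
        joint[a, b] += 0.5
        joint[b, a] += 0.5
    N = len(pairs)
    joint = joint / N
    resid = joint - np.outer(marg, marg)
    chi2 = 0.0
    for a in range(3):
        for b in range(3):
            denom = np.outer(marg, marg)[a, b] if expected_denominator else joint[a, b]
            if denom > 0:
                chi2 += (joint[a, b] - marg[a] * marg[b]) ** 2 / denom
    chi2 *= N
    return CoordinationResult(marginals=marg, joint=joint, chi2=float(chi2),
                              residuals=resid, n_pairs=N)


def permutation_null(table: EventPairTable, neurons_of_events: np.ndarray,
                     n_perm: int = 1000, seed: int | None = None,
                     expected_denominator: bool = False) -> dict:
    """Permutation p-value for sibling coordination.

    Event labels are shuffled across fields (breaking the neuron
    structure) while the sibling pair topology is kept, giving a null
    distribution of the chi-square statistic.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    obs = chi_square_coordination(table.events, table.sibling_pairs,
                                  expected_denominator)
    null = np.empty(n_perm)
    ev = table.events.copy()
    for k in range(n_perm):
        rng.shuffle(ev)
        null[k] = chi_square_coordination(ev, table.sibling_pairs,
                                          expected_denominator).chi2
    p = (1 + np.sum(null >= obs.chi2)) / (1 + n_perm)
    return {"observed": obs, "null": null, "p_value": float(p)}


def satiety(field_count, propensity, track_length_m: float):
    """Per-neuron appetite for new fields: u = (1 - F(X; lambda*L)) * lambda,
    with F the Poisson CDF.  Strictly decreasing in the field count."""
    field_count = np.asarray(field_count)
    propensity = np.asarray(propensity, dtype=float)
    if np.any(field_count < 0):
        raise ValueError("field counts must be non-negative")
    if np.any(propensity <= 0):
        raise ValueError("propensities must be positive")
    return (1.0 - poisson.cdf(field_count, propensity * track_length_m)) * propensity


def multinomial_assignment(satieties, n_new: int, rng=None) -> np.ndarray:
    """Allocate n_new fields to neurons with probabilities u_i / sum(u)."""
    u = np.asarray(satieties, dtype=float)
    total = u.sum()
    if total <= 0:
        raise ValueError("all satieties are zero")
    rng = np.random.default_rng() if rng is None else rng
    return rng.multinomial(n_new, u / total)


def sibling_residuals(cohort: SyntheticCohort, session_pairs=None,
                      rng=None, fill_unobserved: bool = True) -> dict:
    """Mean diagonal residuals (disappearance, formation, retention) over
    sibling and non-sibling pairs, averaged across session pairs.

    In the synthetic cohorts every neuron is observed in every session,
    so a missing entry simply means the field did not exist (yet, or any
    more); for event classification those entries are inactive states.
    ``fill_unobserved=False`` keeps them missing, which hides formation
    events of newly assigned fields.
    """
    table = cohort.activity
    if fill_unobserved:
        states = np.nan_to_num(table.states, nan=0.0)
        table = FieldActivityTable(states=states,
                                   neuron_of_field=table.neuron_of_field,
                                   centers_cm=table.centers_cm,
                                   map_id=table.map_id)
    if session_pairs is None:
        session_pairs = [(t, t + 1) for t in range(table.n_sessions - 1)]
    rng = np.random.default_rng() if rng is None else rng
    sib_diag, non_diag, chi = [], [], []
    for pair in session_pairs:
        ev = classify_transition_events(table, pair, rng=rng)
        if len(ev.sibling_pairs) < 2 or len(ev.nonsibling_pairs) < 2:
            continue
        rs = chi_square_coordination(ev.events, ev.sibling_pairs)
        rn = chi_square_coordination(ev.events, ev.nonsibling_pairs)
        sib_diag.append(np.diag(rs.residuals))
        non_diag.append(np.diag(rn.residuals))
        chi.append(rs.chi2)
    if not sib_diag:
        raise ValueError("no session pair with enough sibling pairs")
    return {"sibling_diagonal": np.mean(sib_diag, axis=0),
            "nonsibling_diagonal": np.mean(non_diag, axis=0),
            "chi2_mean": float(np.mean(chi)),
            "n_session_pairs": len(sib_diag)}


def simulate_interacting_sfer(config, toggles=("assignment", "fluctuations"),
                              rng=None) -> dict:
    """Population simulation with selected interaction mechanisms.

    ``toggles`` is a subset of {"assignment", "fluctuations"}; with
    neither, sibling fields evolve independently and the diagonal
    residuals stay at chance.  Returns the cohort and its sibling /
    non-sibling diagonal residual summary.
    """
    from .cohort import generate_population_cohort

    toggles = set(toggles)
    unknown = toggles - {"assignment", "fluctuations"}
    if unknown:
        raise ValueError(f"unknown toggles {sorted(unknown)}")
    cohort = generate_population_cohort(
        config,
        assignment="assignment" in toggles,
        fluctuations="fluctuations" in toggles,
        injection=True,
        rng=rng)
    summary = sibling_residuals(cohort, rng=np.random.default_rng(config.seed))
    return {"cohort": cohort, "residuals": summary}
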