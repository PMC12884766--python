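"""Synthetic place-field cohorts.

Generates registered field x session activity tables with the statistical
structure the downstream analyses assume: sequences that begin with an
active state at formation, duration-dependent retention/recovery hazards
(or recursive SFER updates) governing later states, Gamma-Poisson
allocation of fields to neurons along a linear track, neuron-level
day-to-day fluctuations shared by sibling fields, and optional censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .config import GeneratorConfig

__all__ = [
    "FieldActivityTable",
    "SyntheticCohort",
    "sample_propensities",
    "sample_initial_fields",
    "generate_state_sequences",
    "generate_population_cohort",
    "generate_element_features",
    "generate_auxiliary_fixtures",
    "ELEMENT_FEATURES",
]

# The nine per-field-per-session covariates considered alongside field state.
ELEMENT_FEATURES = (
    "behavioral_progression",
    "n_training_sessions",
    "session_interval",
    "active_time_in_field",
    "peak_rate",
    "within_field_stability",
    "first_lap",
    "max_transient",
    "center_fluctuation",
)


@dataclass
class FieldActivityTable:
    """Registered fields x sessions matrix over {1, 0, missing(NaN)}."""

    states: np.ndarray                 # (n_fields, n_sessions) float, NaN = missing
    neuron_of_field: np.ndarray        # (n_fields,) int
    centers_cm: np.ndarray | None = None   # linearized field centers
    map_id: str = "synthetic"

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        self.neuron_of_field = np.asarray(self.neuron_of_field, dtype=int)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D (fields x sessions)")
        if len(self.neuron_of_field) != self.states.shape[0]:
            raise ValueError("neuron_of_field length mismatch")

    @property
    def n_fields(self) -> int:
        return self.states.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.states.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states,
                          columns=[f"s_{t+1}" for t in range(self.n_sessions)])
        df.insert(0, "map_id", self.map_id)
        df.insert(0, "neuron_id", self.neuron_of_field)
        df.insert(0, "field_id", np.arange(self.n_fields))
        if self.centers_cm is not None:
            df["center_cm"] = self.centers_cm
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "FieldActivityTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        state_cols = [c for c in df.columns if c.startswith("s_")]
        centers = df["center_cm"].to_numpy() if "center_cm" in df else None
        return cls(states=df[state_cols].to_numpy(dtype=float),
                   neuron_of_field=df["neuron_id"].to_numpy(dtype=int),
                   centers_cm=centers,
                   map_id=str(df["map_id"].iloc[0]) if len(df) else "synthetic")


@dataclass
class SyntheticCohort:
    activity: FieldActivityTable
    propensities: np.ndarray | None = None       # lambda_i, fields per meter
    truth: dict = dc_field(default_factory=dict)  # latent P trajectories etc.
    features: pd.DataFrame | None = None

    @property
    def neuron_of_field(self):
        return self.activity.neuron_of_field


def sample_propensities(config: GeneratorConfig, rng=None) -> np.ndarray:
    """Per-neuron field propensities lambda_i ~ Gamma(shape alpha, rate beta)."""
    if config.gamma_shape <= 0 or config.gamma_rate <= 0:
        raise ValueError("gamma parameters must be positive")
    rng = config.rng() if rng is None else rng
    return rng.gamma(shape=config.gamma_shape, scale=1.0 / config.gamma_rate,
                     size=config.n_neurons)


def sample_initial_fields(propensities, track_length_m: float, rng=None) -> np.ndarray:
    """Initial field count per neuron, X_i ~ Poisson(lambda_i * L)."""
    if track_length_m < 0:
        raise ValueError("track length must be non-negative")
    propensities = np.asarray(propensities, dtype=float)
    if np.any(propensities < 0):
        raise ValueError("propensities must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    return rng.poisson(propensities * track_length_m)


def _apply_missing(states: np.ndarray, formation: np.ndarray,
                   missing_rate: float, rng) -> np.ndarray:
    """Censor entries independently, never at the formation session."""
    if missing_rate <= 0:
        return states
    mask = rng.random(states.shape) < missing_rate
    mask[np.arange(states.shape[0]), formation] = False
    out = states.copy()
    out[mask] = np.nan
    return out


def generate_state_sequences(config: GeneratorConfig, n_fields: int,
                             mode: str = "hazard", rng=None,
                             formation=None) -> SyntheticCohort:
    """Generate field-state sequences that all begin with an active state.

    mode="hazard": state transitions follow the configured duration-based
    retention/recovery curves (semi-Markov in the run durations).
    mode="sfer": a latent re-expression probability P_t evolves by the
    recursive rule P_t = s_{t-1} f(P_{t-1}) + (1 - s_{t-1}) g(P_{t-1}),
    with additive per-step Gaussian noise, clipped to [0, 1].
    """
    if mode not in ("hazard", "sfer"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = config.rng() if rng is None else rng
    T = config.n_sessions
    states = np.zeros((n_fields, T), dtype=float)
    if formation is None:
        formation = np.zeros(n_fields, dtype=int)
    formation = np.asarray(formation, dtype=int)
    states[np.arange(n_fields), formation] = 1.0
    # entries before formation are missing (field did not exist yet)
    col = np.arange(T)[None, :]
    pre = col < formation[:, None]

    latent_P = np.full((n_fields, T), np.nan)

    if mode == "hazard":
        run_active = np.ones(n_fields, dtype=int)     # t_a counter
        run_silent = np.zeros(n_fields, dtype=int)    # t_i counter
        active = np.ones(n_fields, dtype=bool)
        for t in range(1, T):
            started = formation < t
            p = np.where(active, config.retention_curve(np.maximum(run_active, 1)),
                         config.recovery_curve(np.maximum(run_silent, 1)))
            latent_P[started, t] = p[started]
            s = rng.random(n_fields) < p
            # fields not yet formed keep their counters fresh
            newly = formation == t
            s[newly] = True
            states[started, t] = s[started].astype(float)
            run_active = np.where(s, np.where(active, run_active + 1, 1), 0)
            run_silent = np.where(~s, np.where(~active, run_silent + 1, 1), 0)
            run_active[newly] = 1
            run_silent[newly] = 0
            active = s
    else:
        P = np.full(n_fields, config.initial_prob)
        for t in range(1, T):
            started = formation < t
            latent_P[started, t] = P[started]
            s = rng.random(n_fields) < P
            newly = formation == t
            s[newly] = True
            states[started, t] = s[started].astype(float)
            P_next = np.where(s, config.f_link(P), config.g_link(P))
            if config.step_noise_sigma > 0:
                P_next = P_next + rng.normal(0.0, config.step_noise_sigma, n_fields)
            P = np.clip(P_next, 0.0, 1.0)
            P[newly] = config.initial_prob

    states[pre] = np.nan
    states = _apply_missing(states, formation, config.missing_rate, rng)
    table = FieldActivityTable(states=states,
                               neuron_of_field=np.zeros(n_fields, dtype=int))
    return SyntheticCohort(activity=table,
                           truth={"latent_P": latent_P, "mode": mode,
                                  "config": config, "formation": formation})


def generate_population_cohort(config: GeneratorConfig,
                               assignment: bool = True,
                               fluctuations: bool = True,
                               injection: bool = True,
                               rng=None) -> SyntheticCohort:
    """Full population cohort with Gamma-Poisson allocation and interactions.

    Fields are allocated to neurons (initially Poisson(lambda_i * L); later
    sessions via the satiety multinomial when ``assignment`` is on, else
    uniformly) so the total number of active fields stays at M0 when
    ``injection`` is on.  When ``fluctuations`` is on, a neuron-level
    Gaussian perturbation (sigma = fluct_sigma) is added each session to
    the latent P of all sibling fields, then clipped to [0, 1].
    """
    from .coordination import satiety as _satiety

    rng = config.rng() if rng is None else rng
    lam = sample_propensities(config, rng)
    counts0 = sample_initial_fields(lam, config.track_length_m, rng)
    M0 = int(counts0.sum())
    T = config.n_sessions

    nof = np.repeat(np.arange(config.n_neurons), counts0)
    centers = rng.uniform(0.0, config.track_length_m * 100.0, M0)
    formation = np.zeros(M0, dtype=int)
    S = np.full((M0, T), np.nan)
    Pmat = np.full((M0, T), np.nan)
    S[:, 0] = 1.0

    P = np.full(M0, config.initial_prob)
    silent = np.zeros(M0, dtype=int)
    online = np.ones(M0, dtype=bool)

    for t in range(1, T):
        # per-neuron fluctuation shared by sibling fields
        P_eff = P.copy()
        if fluctuations and config.fluct_sigma > 0:
            eps = rng.normal(0.0, config.fluct_sigma, config.n_neurons)
            P_eff = np.clip(P + eps[nof], 0.0, 1.0)
        s_new = (rng.random(P.shape[0]) < P_eff) & online
        S[online, t] = s_new[online].astype(float)
        Pmat[online, t] = P_eff[online]
        silent = np.where(s_new, 0, silent + online.astype(int))
        online = online & (silent < config.gate)
        # recursive SFER update
        P_next = np.where(s_new, config.f_link(P), config.g_link(P))
        if config.step_noise_sigma > 0:
            P_next = P_next + rng.normal(0.0, config.step_noise_sigma, P.shape[0])
        P = np.clip(P_next, 0.0, 1.0)

        if injection:
            n_active = int((s_new & online).sum())
            n_new = max(M0 - n_active, 0)
            if n_new > 0:
                active_counts = np.bincount(nof[s_new & online],
                                            minlength=config.n_neurons)
                if assignment:
                    u = _satiety(active_counts, lam, config.track_length_m)
                    probs = (u / u.sum() if u.sum() > 0
                             else np.full(config.n_neurons, 1.0 / config.n_neurons))
                else:
                    probs = np.full(config.n_neurons, 1.0 / config.n_neurons)
                alloc = rng.multinomial(n_new, probs)
                new_neurons = np.repeat(np.arange(config.n_neurons), alloc)
                k = len(new_neurons)
                S_new = np.full((k, T), np.nan)
                S_new[:, t] = 1.0
                S = np.vstack([S, S_new])
                Pmat = np.vstack([Pmat, np.full((k, T), np.nan)])
                nof = np.concatenate([nof, new_neurons])
                centers = np.concatenate(
                    [centers, rng.uniform(0.0, config.track_length_m * 100.0, k)])
                formation = np.concatenate([formation, np.full(k, t, dtype=int)])
                P = np.concatenate([P, np.full(k, config.initial_prob)])
                silent = np.concatenate([silent, np.zeros(k, int)])
                online = np.concatenate([online, np.ones(k, bool)])

    states = _apply_missing(S, formation, config.missing_rate, rng)
    table = FieldActivityTable(states=states, neuron_of_field=nof,
                               centers_cm=centers)
    return SyntheticCohort(activity=table, propensities=lam,
                           truth={"latent_P": Pmat, "M0": M0,
                                  "formation": np.asarray(formation),
                                  "config": config,
                                  "toggles": {"assignment": assignment,
                                              "fluctuations": fluctuations,
                                              "injection": injection}})


def generate_element_features(cohort: SyntheticCohort, coupling: dict | None = None,
                              rng=None, last_lap: float = 20.0) -> pd.DataFrame:
    """Nine standardized covariates per field-session.

    ``coupling`` maps feature names to coefficients linking the feature to
    the latent re-expression probability; uncoupled features are pure
    noise.  Inactive sessions receive the imputations used downstream:
    within-field stability -> 0, center fluctuation -> 0, first lap ->
    the last lap.
    """
    coupling = dict(coupling or {})
    unknown = set(coupling) - set(ELEMENT_FEATURES)
    if unknown:
        raise KeyError(f"unknown feature(s) in coupling: {sorted(unknown)}")
    rng = np.random.default_rng() if rng is None else rng

    states = cohort.activity.states
    latent = cohort.truth.get("latent_P")
    n_fields, T = states.shape
    rows = []
    for i in range(n_fields):
        for t in range(T):
            if np.isnan(states[i, t]):
                continue
            rows.append((i, t, states[i, t],
                         latent[i, t] if latent is not None and not np.isnan(latent[i, t])
                         else 0.5))
    idx = pd.DataFrame(rows, columns=["field_id", "session", "state", "latent_P"])
    n = len(idx)
    lat_z = (idx["latent_P"] - idx["latent_P"].mean())
    sd = idx["latent_P"].std()
    lat_z = lat_z / sd if sd > 0 else lat_z * 0.0

    feats = {}
    for name in ELEMENT_FEATURES:
        x = rng.normal(0.0, 1.0, n)
        if name in coupling and coupling[name] != 0:
            x = x + coupling[name] * lat_z.to_numpy()
        feats[name] = x

    df = pd.concat([idx, pd.DataFrame(feats)], axis=1)
    inactive = df["state"] == 0
    df.loc[inactive, "within_field_stability"] = 0.0
    df.loc[inactive, "center_fluctuation"] = 0.0
    df.loc[inactive, "first_lap"] = last_lap
    for name in ELEMENT_FEATURES:
        col = df[name]
        sd = col.std()
        df[name] = (col - col.mean()) / sd if sd > 0 else col * 0.0
    return df


def generate_auxiliary_fixtures(kind: str, config: GeneratorConfig | None = None,
                                rng=None, **kwargs):
    """Fixtures for the spatial toolkit ("scene") and re-matching ("index_maps")."""
    config = config if config is not None else GeneratorConfig()
    rng = config.rng() if rng is None else rng
    if kind == "scene":
        from .spatial import synthetic_scene
        return synthetic_scene(rng=rng, **kwargs)
    if kind == "index_maps":
        from .rematch import synthetic_index_maps
        return synthetic_index_maps(rng=rng, **kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}")
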