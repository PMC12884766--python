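"""The ten sequence-model families and their evaluation protocol.

Each model predicts P_t, the probability that a place field is active at
session t given its history, for binary field-state sequences starting
with an active state.  Families:

  I    state_equal_rate  -- constant rates conditioned on s_{t-1}
  II   preliminary_sfer  -- duration-based retention/recovery hazards
  III  hmm               -- HMM with a fixed emission ladder, Baum-Welch
  IV   sfer              -- recursive P_t = s f(P) + (1-s) g(P), link in
                            {linear, logistic, quadratic, cubic}
  V    gru               -- gated recurrent network (see gru module)
  VI   equal_rate        -- one constant
  VII  glm_all           -- logistic regression on nine element covariates
  VIII glm_state         -- VII + previous field state
  IX   glm_state_sfer    -- VIII + P_{t-1} from a cubic SFER model
  X    glm_single        -- logistic regression on one element

Evaluation is the negative log-likelihood at a given step over sequences
long enough to reach it, with repeated random 80/20 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .cohort import ELEMENT_FEATURES
from .gru import GRUModel, _pad, _sigmoid
from .hazards import (fit_recovery_kww, fit_retention_reciprocal,
                      recovery_probability, retention_probability)
from .sequences import FieldStateSequence, estimate_initial_probability

__all__ = [
    "ModelSpec", "EvalResult", "fit_model", "predict_reexpression",
    "nll_at_step", "evaluate_nll", "cross_validate", "transfer_validate",
    "update_monotonicity_audit", "hmm_emission_ladder",
    "HMMBinary", "SFERModel",
]

FAMILIES = ("equal_rate", "state_equal_rate", "preliminary_sfer", "hmm",
            "sfer", "gru", "glm_all", "glm_state", "glm_state_sfer",
            "glm_single")
SFER_LINKS = ("linear", "logistic", "quadratic", "cubic")
_EPS = 1e-6


@dataclass
class ModelSpec:
    family: str
    options: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "hmm" and self.options.get("n_states", 10) < 1:
            raise ValueError("hmm needs n_states >= 1")
        if self.family == "sfer" and \
                self.options.get("link", "linear") not in SFER_LINKS:
            raise ValueError(f"unknown sfer link {self.options.get('link')!r}")
        if self.family == "glm_single" and "element" not in self.options:
            raise ValueError("glm_single needs an 'element' option")


@dataclass
class EvalResult:
    fold_losses: np.ndarray
    mean_loss: float
    t: int


def _seq_states(seq):
    return np.asarray(getattr(seq, "states", seq), dtype=np.int8)


# ======================================================================
# Families I, VI
# ======================================================================

class EqualRateModel:
    """Model VI: a single constant re-expression probability."""

    family = "equal_rate"

    def fit(self, sequences, features=None):
        vals = [s for seq in sequences for s in _seq_states(seq)[1:]]
        if not vals:
            raise ValueError("no transitions to fit")
        self.p = float(np.mean(vals))
        return self

    def predict(self, history):
        return np.full(len(_seq_states(history)), self.p)

    def predict_batch(self, sequences, features=None):
        return [self.predict(s) for s in sequences]


class StateEqualRateModel:
    """Model I: constant rates conditioned on the previous field state."""

    family = "state_equal_rate"

    def fit(self, sequences, features=None):
        after = {0: [], 1: []}
        for seq in sequences:
            s = _seq_states(seq)
            for t in range(1, len(s)):
                after[int(s[t - 1])].append(int(s[t]))
        self.pa = float(np.mean(after[1])) if after[1] else 0.5
        self.pi = float(np.mean(after[0])) if after[0] else 0.5
        return self

    def predict(self, history):
        s = _seq_states(history)
        return np.where(s == 1, self.pa, self.pi).astype(float)

    def predict_batch(self, sequences, features=None):
        return [self.predict(s) for s in sequences]


# ======================================================================
# Family II: duration-based hazards
# ======================================================================

class PreliminarySFERModel:
    """Model II: P_t from fitted retention/recovery hazard curves.

    Durations beyond the range observed in training are handled by the
    fitted parametric curves themselves (extrapolation).
    """

    family = "preliminary_sfer"

    def fit(self, sequences, features=None):
        ret = retention_probability(sequences)
        rec = recovery_probability(sequences)
        self.retention = fit_retention_reciprocal(ret)
        self.recovery = fit_recovery_kww(rec)
        self.p2 = estimate_initial_probability(sequences)
        return self

    def predict(self, history):
        s = _seq_states(history)
        out = np.empty(len(s))
        run_a, run_i = 1, 0
        for t in range(len(s)):
            if t == 0:
                out[t] = float(self.retention(1))
            else:
                run_a = run_a + 1 if s[t] == 1 and s[t - 1] == 1 else (1 if s[t] == 1 else 0)
            if s[t] == 1:
                run_i = 0
                out[t] = float(self.retention(run_a))
            else:
                run_i = run_i + 1
                out[t] = float(self.recovery(run_i))
        return out

    def predict_batch(self, sequences, features=None):
        return [self.predict(s) for s in sequences]


# ======================================================================
# Family III: HMM with a fixed emission ladder
# ======================================================================

def hmm_emission_ladder(n_states: int) -> np.ndarray:
    """Emission matrix B (n_states x 2): active emission of hidden state i
    is (2i - 1) / (2N), i = 1..N; inactive emission is the complement."""
    if n_states < 1:
        raise ValueError("need at least one hidden state")
    i = np.arange(1, n_states + 1)
    active = (2 * i - 1) / (2 * n_states)
    return np.column_stack([1.0 - active, active])


class HMMBinary:
    """Model III: only the transition matrix is learned.

    The emission ladder is fixed by the state count; the initial hidden
    state is the ladder entry closest to the cohort's P2.  Baum-Welch
    runs on the observations s_2..s_l of every sequence.
    """

    family = "hmm"

    def __init__(self, n_states: int = 10, max_iter: int = 500, tol: float = 1e-6,
                 leak: float = 0.05):
        self.n = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.leak = leak

    def _init_A(self):
        n = self.n
        if n == 1:
            return np.ones((1, 1))
        A = np.full((n, n), self.leak / (n - 1))
        np.fill_diagonal(A, 1.0 - self.leak)
        return A

    def fit(self, sequences, features=None, p2: float | None = None):
        self.p2 = estimate_initial_probability(sequences) if p2 is None else p2
        self.B = hmm_emission_ladder(self.n)
        j = int(np.argmin(np.abs(self.B[:, 1] - self.p2)))
        self.pi = np.zeros(self.n)
        self.pi[j] = 1.0
        self.A = self._init_A()

        S, mask = _pad(sequences)
        obs = S[:, 1:].astype(int)            # s_2 .. s_l
        omask = mask[:, 1:]
        # emissions are fixed; precompute once for all EM iterations
        emit = self.B[:, 0][None, None, :] * (obs[:, :, None] == 0) + \
            self.B[:, 1][None, None, :] * (obs[:, :, None] == 1)
        emit = np.where(omask[:, :, None], emit, 1.0)
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            ll, xi_sum, gamma_sum = self._e_step(obs, omask, self.A, emit)
            with np.errstate(invalid="ignore", divide="ignore"):
                A_new = xi_sum / gamma_sum[:, None]
            A_new[gamma_sum <= 0] = self.A[gamma_sum <= 0]
            A_new = A_new / A_new.sum(axis=1, keepdims=True)
            self.A = A_new
            if abs(ll - prev_ll) < self.tol * max(abs(prev_ll), 1.0):
                self.converged_ = True
                break
            prev_ll = ll
        self.loglik_ = prev_ll
        self.n_iter_ = it + 1
        return self

    def _e_step(self, obs, omask, A, emit):
        Bn, K = obs.shape
        n = self.n
        alpha = np.zeros((Bn, K, n))
        beta = np.zeros((Bn, K, n))
        c = np.ones((Bn, K))

        a = self.pi[None, :] * emit[:, 0]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / np.maximum(c[:, 0], 1e-300)[:, None]
        for k in range(1, K):
            a = (alpha[:, k - 1] @ A) * emit[:, k]
            a = np.where(omask[:, k][:, None], a, alpha[:, k - 1])
            c[:, k] = np.where(omask[:, k], a.sum(axis=1), 1.0)
            alpha[:, k] = a / np.maximum(c[:, k], 1e-300)[:, None]

        beta[:, K - 1] = 1.0
        for k in range(K - 2, -1, -1):
            b = (beta[:, k + 1] * emit[:, k + 1]) @ A.T
            b = b / np.maximum(c[:, k + 1], 1e-300)[:, None]
            beta[:, k] = np.where(omask[:, k + 1][:, None], b, beta[:, k + 1])

        ll = float(np.sum(np.log(np.maximum(c[omask], 1e-300))))
        xi_sum = np.zeros((n, n))
        gamma_sum = np.zeros(n)
        for k in range(K - 1):
            valid = omask[:, k] & omask[:, k + 1]
            if not valid.any():
                continue
            al = alpha[valid, k]
            be = beta[valid, k + 1] * emit[valid, k + 1] / \
                np.maximum(c[valid, k + 1], 1e-300)[:, None]
            xi = np.einsum("bi,ij,bj->ij", al, A, be)
            xi_sum += xi
            gamma = alpha[valid, k] * beta[valid, k]
            gamma_sum += gamma.sum(axis=0)
        return ll, xi_sum, gamma_sum

    # forward filter -> predictive probabilities
    def predict(self, history):
        s = _seq_states(history)
        out = np.empty(len(s))
        filt = self.pi.copy()
        out[0] = float(filt @ self.B[:, 1])      # P_2
        for t in range(1, len(s)):
            o = int(s[t])
            post = filt * self.B[:, o]
            tot = post.sum()
            post = post / tot if tot > 0 else self.pi
            filt = post @ self.A
            out[t] = float(filt @ self.B[:, 1])  # P_{t+2} position t+1 (1-based)
        return out

    def predict_batch(self, sequences, features=None):
        return [self.predict(s) for s in sequences]


# ======================================================================
# Family IV: recursive SFER with parametric links
# ======================================================================

def _link_functions(link: str):
    """(f(P, theta_f), g(P, theta_g), n_params per link)."""
    if link == "linear":
        f = lambda P, th: th[0] * P + th[1]
        g = lambda P, th: th[0] * (1.0 - P) + th[1]
        return f, g, 2
    if link == "logistic":
        f = lambda P, th: _sigmoid(th[0] * P + th[1])
        g = lambda P, th: 1.0 - _sigmoid(th[0] * (1.0 - P) + th[1])
        return f, g, 2
    if link == "quadratic":
        f = lambda P, th: th[0] * P**2 + th[1] * P + th[2]
        g = lambda P, th: th[0] * (1 - P)**2 + th[1] * (1 - P) + th[2]
        return f, g, 3
    if link == "cubic":
        f = lambda P, th: th[0] * P**3 + th[1] * P**2 + th[2] * P + th[3]
        g = lambda P, th: th[0] * (1 - P)**3 + th[1] * (1 - P)**2 + th[2] * (1 - P) + th[3]
        return f, g, 4
    raise ValueError(f"unknown link {link!r}")


class SFERModel:
    """Model IV: P_t = s_{t-1} f(P_{t-1}) + (1 - s_{t-1}) g(P_{t-1}).

    The update is clipped to [0, 1]; the likelihood is non-convex in the
    link coefficients, so fitting uses bounded NLL minimization from
    several seeded starts.
    """

    family = "sfer"

    def __init__(self, link: str = "linear", n_starts: int = 8,
                 seed: int | None = None, maxiter: int = 2000):
        self.link = link
        self.n_starts = max(n_starts, 1)
        self.seed = seed
        self.maxiter = maxiter
        self._f, self._g, self._k = _link_functions(link)

    def set_params(self, theta_f, theta_g, p2: float = 0.5):
        self.theta_f = np.asarray(theta_f, float)
        self.theta_g = np.asarray(theta_g, float)
        self.p2 = p2
        return self

    def _nll_padded(self, theta, S, mask):
        th_f, th_g = theta[:self._k], theta[self._k:]
        B, T = S.shape
        P = np.full(B, self.p2)
        total, count = 0.0, 0
        for i in range(1, T):
            if i >= 2:
                m = mask[:, i]
                if m.any():
                    Pc = np.clip(P, _EPS, 1 - _EPS)
                    total -= np.sum(np.where(
                        m, S[:, i] * np.log(Pc) + (1 - S[:, i]) * np.log(1 - Pc), 0.0))
                    count += int(m.sum())
            P = np.where(S[:, i] == 1, self._f(P, th_f), self._g(P, th_g))
            P = np.clip(P, 0.0, 1.0)
        return total / max(count, 1)

    def fit(self, sequences, features=None, p2: float | None = None):
        self.p2 = estimate_initial_probability(sequences) if p2 is None else p2
        S, mask = _pad(sequences)
        S = S.astype(float)
        rng = np.random.default_rng(self.seed)
        best, best_val = None, np.inf
        for start in range(self.n_starts):
            if start == 0 and self.link in ("linear", "quadratic", "cubic"):
                # neutral start near the identity maps
                tf = np.zeros(self._k)
                tf[-2] = 1.0
                theta0 = np.concatenate([tf, tf])
            else:
                theta0 = rng.normal(0.0, 1.0, 2 * self._k)
            res = minimize(self._nll_padded, theta0, args=(S, mask),
                           method="Nelder-Mead",
                           options={"maxiter": self.maxiter, "xatol": 1e-5,
                                    "fatol": 1e-7})
            if res.fun < best_val:
                best, best_val = res, res.fun
        self.theta_f = best.x[:self._k]
        self.theta_g = best.x[self._k:]
        self.train_nll_ = float(best_val)
        return self

    def f(self, P):
        return np.clip(self._f(np.asarray(P, float), self.theta_f), 0.0, 1.0)

    def g(self, P):
        return np.clip(self._g(np.asarray(P, float), self.theta_g), 0.0, 1.0)

    def predict(self, history):
        s = _seq_states(history)
        out = np.empty(len(s))
        P = self.p2
        out[0] = P
        for t in range(1, len(s)):
            P = float(self.f(P)) if s[t] == 1 else float(self.g(P))
            out[t] = P
        return out

    def predict_batch(self, sequences, features=None):
        S, mask = _pad(sequences)
        B, T = S.shape
        out = np.full((B, T + 1), np.nan)
        P = np.full(B, self.p2)
        out[:, 1] = P
        for i in range(1, T):
            P = np.where(S[:, i] == 1, self.f(P), self.g(P))
            out[:, i + 1] = P
        return [out[b, 1:int(mask[b].sum()) + 1] for b in range(B)]


# ======================================================================
# Families VII-X: logistic regressions on element covariates
# ======================================================================

class GLMModel:
    """Logistic-regression families over the nine element covariates.

    variant: "all" (VII), "state" (VIII, adds s_{t-1}),
    "state_sfer" (IX, additionally adds P_{t-1} from a cubic SFER model),
    "single" (X, one named element).
    """

    def __init__(self, variant: str = "all", element: str | None = None,
                 seed: int | None = None):
        if variant not in ("all", "state", "state_sfer", "single"):
            raise ValueError(f"unknown GLM variant {variant!r}")
        if variant == "single" and element is None:
            raise ValueError("single-element GLM needs an element name")
        if element is not None and element not in ELEMENT_FEATURES:
            raise ValueError(f"unknown element {element!r}")
        self.variant = variant
        self.element = element
        self.seed = seed
        self.family = {"all": "glm_all", "state": "glm_state",
                       "state_sfer": "glm_state_sfer",
                       "single": "glm_single"}[variant]

    def _columns(self):
        if self.variant == "single":
            return [self.element]
        return list(ELEMENT_FEATURES)

    def _design(self, sequences, features: pd.DataFrame, sfer_model=None):
        lookup = {(int(r.field_id), int(r.session)): i
                  for i, r in enumerate(features.itertuples(index=False))}
        fmat = features[self._columns()].to_numpy()
        rows, ys = [], []
        sfer_preds = sfer_model.predict_batch(sequences) if sfer_model else None
        for j, seq in enumerate(sequences):
            s = _seq_states(seq)
            fid = getattr(seq, "field_id", -1)
            base = getattr(seq, "formation_session", 0)
            for t in range(1, len(s)):
                key = (fid, base + t - 1)
                if key not in lookup:
                    continue
                x = list(fmat[lookup[key]])
                if self.variant in ("state", "state_sfer"):
                    x.append(float(s[t - 1]))
                if self.variant == "state_sfer":
                    # P_{t-1}: the model-predicted probability for the
                    # previous step; formation (t=1) is certain, so 1.0
                    x.append(float(sfer_preds[j][t - 2]) if t >= 2 else 1.0)
                rows.append(x)
                ys.append(int(s[t]))
        if not rows:
            raise ValueError("no usable (sequence, feature) rows")
        X = sm.add_constant(np.asarray(rows, float), has_constant="add")
        return X, np.asarray(ys, float)

    def fit(self, sequences, features=None):
        if features is None:
            raise ValueError("GLM families need element features")
        self.sfer_ = None
        if self.variant == "state_sfer":
            self.sfer_ = SFERModel(link="cubic", seed=self.seed).fit(sequences)
        X, y = self._design(sequences, features, self.sfer_)
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            self.result_ = model.fit(maxiter=200)
        except Exception:
            self.result_ = model.fit_regularized(alpha=1e-4, maxiter=500)
        self.coef_ = np.asarray(self.result_.params)
        return self

    def predict_batch(self, sequences, features=None):
        if features is None:
            raise ValueError("GLM families need element features")
        preds = []
        lookup = {(int(r.field_id), int(r.session)): i
                  for i, r in enumerate(features.itertuples(index=False))}
        fmat = features[self._columns()].to_numpy()
        sfer_preds = self.sfer_.predict_batch(sequences) if self.sfer_ else None
        for j, seq in enumerate(sequences):
            s = _seq_states(seq)
            fid = getattr(seq, "field_id", -1)
            base = getattr(seq, "formation_session", 0)
            p = np.full(len(s), np.nan)
            for t in range(1, len(s) + 1):
                key = (fid, base + t - 1)
                if key not in lookup:
                    continue
                x = list(fmat[lookup[key]])
                if self.variant in ("state", "state_sfer"):
                    x.append(float(s[t - 1]))
                if self.variant == "state_sfer":
                    x.append(float(sfer_preds[j][t - 2]) if t >= 2 else 1.0)
                eta = self.coef_[0] + np.dot(self.coef_[1:], x)
                if t - 1 < len(p):
                    p[t - 1] = _sigmoid(eta)
            preds.append(p)
        return preds


# ======================================================================
# Fitting / prediction dispatch
# ======================================================================

def fit_model(spec: ModelSpec, sequences, features=None, seed: int | None = None):
    """Fit one model family on training sequences (80% split is the
    caller's responsibility)."""
    fam = spec.family
    opt = spec.options
    if fam == "equal_rate":
        return EqualRateModel().fit(sequences)
    if fam == "state_equal_rate":
        return StateEqualRateModel().fit(sequences)
    if fam == "preliminary_sfer":
        return PreliminarySFERModel().fit(sequences)
    if fam == "hmm":
        return HMMBinary(n_states=opt.get("n_states", 10)).fit(sequences)
    if fam == "sfer":
        return SFERModel(link=opt.get("link", "linear"),
                         n_starts=opt.get("n_starts", 8),
                         seed=seed).fit(sequences)
    if fam == "gru":
        model = GRUModel(hidden=opt.get("hidden", 16),
                         p2=estimate_initial_probability(sequences),
                         seed=seed,
                         batch_size=opt.get("batch_size", 2048),
                         max_epochs=opt.get("max_epochs", 1000),
                         patience=opt.get("patience", 100),
                         lr=opt.get("lr", 1e-3))
        model.family = "gru"
        return model.fit(sequences)
    if fam == "glm_all":
        return GLMModel("all", seed=seed).fit(sequences, features)
    if fam == "glm_state":
        return GLMModel("state", seed=seed).fit(sequences, features)
    if fam == "glm_state_sfer":
        return GLMModel("state_sfer", seed=seed).fit(sequences, features)
    if fam == "glm_single":
        return GLMModel("single", element=opt["element"],
                        seed=seed).fit(sequences, features)
    raise ValueError(fam)


def predict_reexpression(model, history) -> np.ndarray:
    """Recursive probabilities [P_2, ..., P_{l+1}] for one history."""
    s = _seq_states(history)
    if len(s) == 0:
        raise ValueError("empty history")
    if s[0] != 1:
        raise ValueError("history must start with an active state")
    if isinstance(model, GRUModel):
        return model.predict(s)
    if isinstance(model, SFERModel):
        return _sfer_traj(model, s)
    if isinstance(model, HMMBinary):
        return _hmm_traj(model, s)
    # constant / hazard families: one-step predictions at each history prefix
    if hasattr(model, "predict"):
        return np.asarray(model.predict(s), dtype=float)
    raise TypeError(f"cannot predict with {type(model).__name__}")


def _sfer_traj(model: SFERModel, s: np.ndarray) -> np.ndarray:
    out = np.empty(len(s))
    P = model.p2
    out[0] = P
    for t in range(1, len(s)):
        P = float(model.f(P)) if s[t] == 1 else float(model.g(P))
        out[t] = P
    return out


def _hmm_traj(model: HMMBinary, s: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(s), dtype=float)


def nll_at_step(predictions, sequences, t: int, eps: float = _EPS) -> float:
    """Mean NLL at step t over sequences with length >= t.

    ``predictions`` are per-sequence arrays [P_2 .. P_{l+1}] aligned with
    ``sequences``; P_t sits at index t - 2.
    """
    losses = []
    for p, seq in zip(predictions, sequences):
        s = _seq_states(seq)
        if len(s) < t:
            continue
        prob = float(np.clip(p[t - 2], eps, 1.0 - eps))
        y = int(s[t - 1])
        losses.append(-(y * np.log(prob) + (1 - y) * np.log(1.0 - prob)))
    if not losses:
        raise ValueError(f"no sequence reaches step {t}")
    return float(np.mean(losses))


def evaluate_nll(model, sequences, t: int, features=None) -> float:
    preds = model.predict_batch(sequences, features) \
        if isinstance(model, (GLMModel,)) else model.predict_batch(sequences)
    return nll_at_step(preds, sequences, t)


def cross_validate(spec: ModelSpec, sequences, t: int, k: int = 10,
                   seed: int | None = None, features=None,
                   train_fraction: float = 0.8) -> EvalResult:
    """k random 80/20 splits; mean test NLL at step t."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    sequences = list(sequences)
    rng = np.random.default_rng(seed)
    losses = []
    for fold in range(k):
        order = rng.permutation(len(sequences))
        n_train = int(round(train_fraction * len(sequences)))
        train = [sequences[i] for i in order[:n_train]]
        test = [sequences[i] for i in order[n_train:]]
        model = fit_model(spec, train, features=features,
                          seed=None if seed is None else seed + fold)
        losses.append(evaluate_nll(model, test, t, features=features))
    losses = np.asarray(losses)
    return EvalResult(fold_losses=losses, mean_loss=float(losses.mean()), t=t)


def transfer_validate(spec: ModelSpec, train_cohorts, test_cohorts, t: int,
                      seed: int | None = None, features=None) -> dict:
    """Fit on each training cohort, evaluate on each distinct test cohort.

    Returns the full loss matrix (NaN where train and test are the same
    cohort) and the mean off-diagonal loss.
    """
    mat = np.full((len(train_cohorts), len(test_cohorts)), np.nan)
    for i, train in enumerate(train_cohorts):
        model = fit_model(spec, train, features=features, seed=seed)
        for j, test in enumerate(test_cohorts):
            if train is test:
                continue
            mat[i, j] = evaluate_nll(model, test, t, features=features)
    if np.all(np.isnan(mat)):
        raise ValueError("train and test cohorts must differ")
    return {"matrix": mat, "mean_loss": float(np.nanmean(mat))}


def update_monotonicity_audit(model, sequences,
                              include_boundary: bool = False) -> float:
    """Fraction of prediction steps with a state-consistent update:
    P_t > P_{t-1} after an active state, P_t < P_{t-1} after an inactive
    one.  Ties count as violations.

    By default the audit covers updates the model's own dynamics produce
    (P_4 vs P_3 onward).  The very first update compares P_3 against the
    shared fixed initial probability P_2; for an HMM with a one-hot
    initial state that comparison is state-independent by construction (a
    degenerate posterior ignores its first observation), so it measures a
    boundary condition rather than the update rule.  Set
    ``include_boundary=True`` to count it anyway.
    """
    if not isinstance(model, (HMMBinary, SFERModel, GRUModel, PreliminarySFERModel)):
        raise TypeError("audit needs a model with recursive P_t")
    start = 1 if include_boundary else 2
    good = total = 0
    preds = model.predict_batch(sequences)
    for p, seq in zip(preds, sequences):
        s = _seq_states(seq)
        for t in range(start, len(p)):
            prev_state = s[t] if t < len(s) else s[-1]
            dp = p[t] - p[t - 1]
            total += 1
            if (prev_state == 1 and dp > 0) or (prev_state == 0 and dp < 0):
                good += 1
    if total == 0:
        raise ValueError("no prediction steps")
    return good / total
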