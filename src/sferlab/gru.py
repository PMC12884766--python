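"""Gated recurrent network for field-state sequences, in plain numpy.

A single GRU layer followed by a linear + sigmoid head predicts the
re-expression probability of a place field from its activity history.
At step t the input is x_t = [s_t, P_t] (the observed state and the
model's current probability); the head emits P_{t+1}.  Training
minimizes the negative log-likelihood with Adam and early stopping on a
held-out slice of the training sequences.  Gradients are computed by
hand with backpropagation through time; the probability fed back as an
input is treated as a constant (no gradient flows through it).
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUModel"]


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _init_params(hidden: int, n_in: int, rng) -> dict:
    k = 1.0 / np.sqrt(hidden)
    u = lambda shape: rng.uniform(-k, k, shape)
    return {
        "W": u((3 * hidden, n_in)), "U": u((3 * hidden, hidden)),
        "bi": u(3 * hidden), "bh": u(3 * hidden),
        "w_out": u(hidden), "b_out": np.zeros(1),
    }


class GRUModel:
    """Recurrent sequence model with a fixed initial probability P2.

    Default hyperparameters: hidden size in
    {8, 16, 32}, batch size 2048, at most 1000 epochs, early-stopping
    patience 100 epochs, learning rate 0.001.
    """

    def __init__(self, hidden: int = 16, p2: float = 0.5, seed: int | None = None,
                 batch_size: int = 2048, max_epochs: int = 1000,
                 patience: int = 100, lr: float = 1e-3, val_fraction: float = 0.1):
        self.hidden = hidden
        self.p2 = p2
        self.seed = seed
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr = lr
        self.val_fraction = val_fraction
        self.n_in = 2
        self.params = _init_params(hidden, self.n_in, np.random.default_rng(seed))
        self.history_: list[float] = []

    # ---------------------------------------------------------------- forward
    def _forward(self, S: np.ndarray, mask: np.ndarray, keep_cache: bool = False):
        """Run the recursion over a padded batch.

        S: (B, T) padded states; mask: (B, T) validity.  Returns
        P: (B, T+1) where P[:, i] is the model probability that the
        state at 0-based index i is active.  P[:, 1] is the fixed P2;
        P[:, i+1] for i >= 1 is computed from input [S[:, i], P[:, i]].
        For a sequence of length l, P[:, l] is its one-step-ahead
        prediction past the observed history (valid regardless of
        padding, since it only consumes inputs up to index l-1).
        """
        p = self.params
        B, T = S.shape
        H = self.hidden
        h = np.zeros((B, H))
        P = np.full((B, T + 1), np.nan)
        P[:, 1] = self.p2
        prob = np.full(B, self.p2)
        cache = []
        W, U, bi, bh = p["W"], p["U"], p["bi"], p["bh"]
        for i in range(1, T):
            x = np.stack([S[:, i], prob], axis=1)  # [s_t, P_t]
            gi = x @ W.T + bi
            gh = h @ U.T + bh
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
            hn = gh[:, 2 * H:]
            n = np.tanh(gi[:, 2 * H:] + r * hn)
            h_new = (1.0 - z) * n + z * h
            logit = h_new @ p["w_out"] + p["b_out"][0]
            prob_next = _sigmoid(logit)
            if keep_cache:
                cache.append((x, h.copy(), r, z, n, hn, h_new))
            P[:, i + 1] = prob_next
            h = h_new
            prob = prob_next
        return P, cache

    # --------------------------------------------------------------- backward
    def _backward(self, S, mask, P, cache):
        """Gradients of the mean NLL over supervised steps (index >= 2).

        cache[i-1] holds the intermediates of recursion step i (inputs at
        index i, output P[:, i+1]); the output at index i+1 is supervised
        when that position is observed.  The probability fed back as an
        input carries no gradient (stop-gradient convention).
        """
        p = self.params
        B, T = S.shape
        H = self.hidden
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        tgt = mask.copy()
        tgt[:, :2] = False  # indices 0 (always 1) and 1 (fixed P2) unsupervised
        denom = max(int(tgt.sum()), 1)

        dh_next = np.zeros((B, H))
        for i in range(T - 1, 0, -1):
            x, h_prev, r, z, n, hn, h_new = cache[i - 1]
            dh = dh_next
            if i + 1 < T:  # output P[:, i+1] has an observed target
                m = tgt[:, i + 1].astype(float)
                if m.any():
                    dlogit = (P[:, i + 1] - S[:, i + 1]) * m / denom
                    grads["w_out"] += h_new.T @ dlogit
                    grads["b_out"][0] += dlogit.sum()
                    dh = dh + np.outer(dlogit, p["w_out"])

            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n ** 2)
            dr = da_n * hn
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)

            grads["W"] += np.vstack([da_r.T @ x, da_z.T @ x, da_n.T @ x])
            grads["bi"] += np.concatenate([da_r.sum(0), da_z.sum(0), da_n.sum(0)])
            grads["U"] += np.vstack([da_r.T @ h_prev, da_z.T @ h_prev,
                                     (da_n * r).T @ h_prev])
            grads["bh"] += np.concatenate([da_r.sum(0), da_z.sum(0),
                                           (da_n * r).sum(0)])
            dh_next = dh_prev + da_r @ p["U"][:H] + da_z @ p["U"][H:2 * H] \
                + (da_n * r) @ p["U"][2 * H:]
        return grads

    # ------------------------------------------------------------------- loss
    @staticmethod
    def _nll(P, S, mask, eps=1e-6):
        """Mean NLL of P[:, i] vs S[:, i] over supervised indices i >= 2."""
        T = S.shape[1]
        Pc = np.clip(P[:, :T], eps, 1.0 - eps)
        m = mask.copy()
        m[:, :2] = False
        if m.sum() == 0:
            return np.nan
        ll = np.where(m, S * np.log(Pc) + (1.0 - S) * np.log(1.0 - Pc), 0.0)
        return float(-ll.sum() / m.sum())

    # -------------------------------------------------------------------- fit
    def fit(self, sequences, verbose: bool = False):
        """Train on a list of state sequences (each starting with 1)."""
        rng = np.random.default_rng(self.seed)
        S, mask = _pad(sequences)
        B = S.shape[0]
        n_val = max(int(round(self.val_fraction * B)), 1) if B > 10 else 0
        order = rng.permutation(B)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(tr_idx) == 0:
            tr_idx = order
        Sv, Mv = S[val_idx], mask[val_idx]
        St, Mt = S[tr_idx], mask[tr_idx]

        ms = {k: np.zeros_like(v) for k, v in self.params.items()}
        vs = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        wait = 0
        for epoch in range(self.max_epochs):
            perm = rng.permutation(len(St))
            for start in range(0, len(St), self.batch_size):
                idx = perm[start:start + self.batch_size]
                Sb, Mb = St[idx], Mt[idx]
                P, cache = self._forward(Sb, Mb, keep_cache=True)
                grads = self._backward(Sb, Mb, P, cache)
                step += 1
                for k in self.params:
                    g = grads[k]
                    ms[k] = beta1 * ms[k] + (1 - beta1) * g
                    vs[k] = beta2 * vs[k] + (1 - beta2) * g * g
                    mhat = ms[k] / (1 - beta1 ** step)
                    vhat = vs[k] / (1 - beta2 ** step)
                    self.params[k] = self.params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            monitor = Sv if n_val else St
            mmask = Mv if n_val else Mt
            Pm, _ = self._forward(monitor, mmask)
            loss = self._nll(Pm, monitor, mmask)
            self.history_.append(loss)
            if verbose and epoch % 50 == 0:
                print(f"epoch {epoch}: val NLL {loss:.5f}")
            if loss < best - 1e-6:
                best = loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        self.params = best_params
        return self

    # ---------------------------------------------------------------- predict
    def predict(self, history) -> np.ndarray:
        """[P_2, ..., P_{l+1}] for a single history s_1..s_l."""
        s = np.asarray(history, dtype=float)
        if len(s) == 0 or s[0] != 1:
            raise ValueError("history must start with an active state")
        P, _ = self._forward(s[None, :], np.ones((1, len(s)), bool))
        return P[0, 1:]

    def predict_batch(self, sequences) -> list[np.ndarray]:
        """Per-sequence [P_2 .. P_{l+1}] arrays (padding-safe)."""
        S, mask = _pad(sequences)
        P, _ = self._forward(S, mask)
        return [P[i, 1:int(mask[i].sum()) + 1] for i in range(len(P))]


def _pad(sequences):
    seqs = [np.asarray(getattr(s, "states", s), dtype=float) for s in sequences]
    T = max(len(s) for s in seqs)
    S = np.zeros((len(seqs), T))
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        S[i, :len(s)] = s
        mask[i, :len(s)] = True
    return S, mask
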