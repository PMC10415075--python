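"""Trainable guidance for the tree search: a small two-hidden-layer MLP
mapping an encoded interaction state to a probability distribution over
moves and a scalar value estimate in [0, 1].

States are encoded as one one-hot block per askable variable with an
explicit "unobserved" category, plus the normalized question count.  The
network is trained on (visit-distribution, realized-reward) targets from
self-play with a cross-entropy + squared-error loss, optimized by Adam.
Everything is plain numpy, seeded and deterministic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class GuidanceFunction:
    def __init__(
        self,
        askable: list[str],
        state_spaces: dict[str, list[str]],
        frames: list[str],
        max_questions: int = 6,
        hidden: int = 64,
        seed: int = 0,
        lr: float = 1e-3,
    ):
        self.askable = list(askable)
        self.state_spaces = {v: list(state_spaces[v]) for v in askable}
        self.frames = list(frames)
        self.max_questions = max_questions
        self.moves: list[tuple[str, str]] = [("ask", v) for v in self.askable] + [
            ("send", f) for f in self.frames
        ]
        self.move_index = {m: i for i, m in enumerate(self.moves)}
        self._offsets = {}
        d = 0
        for v in self.askable:
            self._offsets[v] = d
            d += len(self.state_spaces[v]) + 1  # + explicit "unobserved"
        self.input_dim = d + 1  # + question-count feature
        self.n_moves = len(self.moves)

        rng = np.random.default_rng(seed)
        h = hidden

        def init(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), (n_in, n_out))

        self.params = {
            "W1": init(self.input_dim, h), "b1": np.zeros(h),
            "W2": init(h, h), "b2": np.zeros(h),
            "Wp": init(h, self.n_moves), "bp": np.zeros(self.n_moves),
            "Wv": init(h, 1), "bv": np.zeros(1),
        }
        self.lr = lr
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    def encode(self, state) -> np.ndarray:
        """One-hot per askable variable (with unobserved category) plus the
        normalized number of questions asked."""
        x = np.zeros(self.input_dim)
        ev = dict(state.evidence)
        for v in self.askable:
            off = self._offsets[v]
            if v in ev:
                x[off + self.state_spaces[v].index(ev[v])] = 1.0
            else:
                x[off + len(self.state_spaces[v])] = 1.0
        x[-1] = state.questions_asked / max(self.max_questions, 1)
        return x

    def move_mask(self, legal_moves) -> np.ndarray:
        mask = np.zeros(self.n_moves, dtype=bool)
        for m in legal_moves:
            mask[self.move_index[m]] = True
        return mask

    def _forward(self, X: np.ndarray):
        h1 = np.tanh(X @ self.params["W1"] + self.params["b1"])
        h2 = np.tanh(h1 @ self.params["W2"] + self.params["b2"])
        logits = h2 @ self.params["Wp"] + self.params["bp"]
        s = h2 @ self.params["Wv"] + self.params["bv"]
        v = 1.0 / (1.0 + np.exp(-s))
        return h1, h2, logits, v

    @staticmethod
    def _masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
        z = np.where(mask, logits, -1e9)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z) * mask
        return e / e.sum(axis=-1, keepdims=True)

    def evaluate(self, state, legal_moves) -> tuple[dict, float]:
        """Prior probabilities over the legal moves (summing to one) and a
        bounded value estimate for ``state``."""
        x = self.encode(state)[None, :]
        _, _, logits, v = self._forward(x)
        mask = self.move_mask(legal_moves)[None, :]
        p = self._masked_softmax(logits, mask)[0]
        priors = {m: float(p[self.move_index[m]]) for m in legal_moves}
        return priors, float(v[0, 0])

    # ------------------------------------------------------------------
    def loss_on(self, X, Pi, Mask, Z) -> tuple[float, float]:
        """(policy cross-entropy, value MSE) without updating parameters."""
        _, _, logits, v = self._forward(X)
        p = self._masked_softmax(logits, Mask)
        ce = float(-np.mean(np.sum(Pi * np.log(np.clip(p, 1e-12, None)), axis=1)))
        mse = float(np.mean((v[:, 0] - Z) ** 2))
        return ce, mse

    def train_step(self, X, Pi, Mask, Z) -> float:
        B = X.shape[0]
        h1, h2, logits, v = self._forward(X)
        p = self._masked_softmax(logits, Mask)
        ce = -np.mean(np.sum(Pi * np.log(np.clip(p, 1e-12, None)), axis=1))
        mse = np.mean((v[:, 0] - Z) ** 2)
        loss = float(ce + mse)
        if not np.isfinite(loss):
            raise RuntimeError(
                "training loss diverged (NaN/inf); lower the learning rate "
                f"(current {self.lr}) or check the targets"
            )

        dlogits = (p - Pi) / B
        ds = (2.0 * (v[:, 0] - Z) * v[:, 0] * (1.0 - v[:, 0]) / B)[:, None]
        grads = {
            "Wp": h2.T @ dlogits, "bp": dlogits.sum(0),
            "Wv": h2.T @ ds, "bv": ds.sum(0),
        }
        dh2 = dlogits @ self.params["Wp"].T + ds @ self.params["Wv"].T
        dz2 = dh2 * (1.0 - h2 * h2)
        grads["W2"] = h1.T @ dz2
        grads["b2"] = dz2.sum(0)
        dh1 = dz2 @ self.params["W2"].T
        dz1 = dh1 * (1.0 - h1 * h1)
        grads["W1"] = X.T @ dz1
        grads["b1"] = dz1.sum(0)

        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def fit(
        self, X, Pi, Mask, Z, epochs: int = 20, batch_size: int = 64,
        rng: np.random.Generator | None = None, holdout: float = 0.1,
    ) -> list[dict]:
        """Minibatch training with a held-out split; returns the per-epoch
        loss log (train loss, held-out cross-entropy and value MSE)."""
        rng = rng or np.random.default_rng(0)
        n = X.shape[0]
        n_hold = max(1, int(holdout * n)) if n >= 10 else 0
        tr = slice(0, n - n_hold)
        ho = slice(n - n_hold, n) if n_hold else None
        log = []
        for epoch in range(epochs):
            order = rng.permutation(n - n_hold)
            losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(X[tr][idx], Pi[tr][idx], Mask[tr][idx], Z[tr][idx]))
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if ho is not None:
                ce, mse = self.loss_on(X[ho], Pi[ho], Mask[ho], Z[ho])
                entry["holdout_policy_ce"] = ce
                entry["holdout_value_mse"] = mse
            log.append(entry)
        return log

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "askable": self.askable,
            "frames": self.frames,
            "max_questions": self.max_questions,
            "state_spaces_flat": [f"{v}:{s}" for v in self.askable for s in self.state_spaces[v]],
        }
        np.savez(
            path,
            **self.params,
            _meta=np.array([repr(meta)], dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GuidanceFunction":
        import ast

        data = np.load(path, allow_pickle=True)
        meta = ast.literal_eval(str(data["_meta"][0]))
        spaces: dict[str, list[str]] = {v: [] for v in meta["askable"]}
        for entry in meta["state_spaces_flat"]:
            v, s = entry.split(":", 1)
            spaces[v].append(s)
        g = cls(meta["askable"], spaces, meta["frames"], meta["max_questions"],
                hidden=data["W2"].shape[0])
        for k in g.params:
            g.params[k] = data[k]
        return g
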