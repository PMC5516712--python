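"""Linear-chain conditional random field with L-BFGS training.

A compact CRF over string-valued observation features: state features are
(feature, label) weights, first-order label dependencies are a dense
transition matrix.  The negative log-likelihood with L2 penalty is minimized
with scipy's L-BFGS-B; the forward-backward recursions run batched over all
sentences (padded to the longest, with carry-forward masking), which keeps
training on a few thousand short sentences in the seconds range.

Training is deterministic given the data order; there is no randomness in
the objective or optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

from .resources import ContractError

FeatureSeq = Sequence[Sequence[str]]  # per-position lists of feature strings


@dataclass
class LinearChainCRF:
    labels: tuple[str, ...]
    vocab: dict[str, int]
    state_weights: np.ndarray  # (n_feats, n_labels)
    trans_weights: np.ndarray  # (n_labels, n_labels)
    meta: dict = field(default_factory=dict)

    # -- inference ---------------------------------------------------------
    def emissions(self, feats: FeatureSeq) -> np.ndarray:
        """Per-position label scores; unknown features are ignored."""
        n, L = len(feats), len(self.labels)
        E = np.zeros((n, L))
        for t, fs in enumerate(feats):
            for f in fs:
                j = self.vocab.get(f)
                if j is not None:
                    E[t] += self.state_weights[j]
        return E

    def decode(self, feats: FeatureSeq) -> tuple[str, ...]:
        """Viterbi-decode the most probable label sequence."""
        n = len(feats)
        if n == 0:
            return ()
        E = self.emissions(feats)
        L = len(self.labels)
        delta = E[0].copy()
        back = np.zeros((n, L), dtype=int)
        for t in range(1, n):
            scores = delta[:, None] + self.trans_weights  # (from, to)
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(L)] + E[t]
        path = [int(np.argmax(delta))]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return tuple(self.labels[i] for i in path)

    def decode_greedy(self, step_features) -> tuple[str, ...]:
        """Left-to-right greedy decode for label-history observation features.

        ``step_features(t, prev_labels)`` must return the feature strings for
        position ``t`` given the already-predicted label sequence.
        """
        preds: list[str] = []
        idx = {lab: i for i, lab in enumerate(self.labels)}
        t = 0
        while True:
            try:
                fs = step_features(t, tuple(preds))
            except IndexError:
                break
            if fs is None:
                break
            scores = np.zeros(len(self.labels))
            for f in fs:
                j = self.vocab.get(f)
                if j is not None:
                    scores += self.state_weights[j]
            if preds:
                scores += self.trans_weights[idx[preds[-1]]]
            preds.append(self.labels[int(np.argmax(scores))])
            t += 1
        return tuple(preds)

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ccmer-crf-v1",
            "labels": list(self.labels),
            "vocab": self.vocab,
            "state_weights": self.state_weights.tolist(),
            "trans_weights": self.trans_weights.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LinearChainCRF":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            labels=tuple(payload["labels"]),
            vocab={k: int(v) for k, v in payload["vocab"].items()},
            state_weights=np.array(payload["state_weights"]),
            trans_weights=np.array(payload["trans_weights"]),
            meta=payload.get("meta", {}),
        )


def train(
    sequences: Sequence[FeatureSeq],
    tag_sequences: Sequence[Sequence[str]],
    labels: tuple[str, ...],
    c2: float = 0.1,
    maxiter: int = 80,
    meta: dict | None = None,
) -> LinearChainCRF:
    """Fit CRF weights by penalized maximum likelihood (L-BFGS)."""
    seqs = [s for s in sequences if len(s) > 0]
    tags = [t for s, t in zip(sequences, tag_sequences) if len(s) > 0]
    if not seqs:
        raise ContractError("training set must contain at least one sequence")
    for s, t in zip(seqs, tags):
        if len(s) != len(t):
            raise ContractError("feature/tag length mismatch")

    L = len(labels)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    vocab: dict[str, int] = {}
    for s in seqs:
        for fs in s:
            for f in fs:
                if f not in vocab:
                    vocab[f] = len(vocab)
    F = len(vocab)
    S = len(seqs)
    maxT = max(len(s) for s in seqs)

    # sparse design matrix over padded (sentence, position) rows
    indptr = [0]
    indices: list[int] = []
    for s in seqs:
        for fs in s:
            indices.extend(vocab[f] for f in fs)
            indptr.append(len(indices))
        for _ in range(maxT - len(s)):
            indptr.append(len(indices))
    X = sparse.csr_matrix(
        (np.ones(len(indices)), np.array(indices), np.array(indptr)),
        shape=(S * maxT, F),
    )

    mask = np.zeros((S, maxT), dtype=bool)
    Y = np.zeros((S * maxT, L))
    emp_trans = np.zeros((L, L))
    y_ids = np.full((S, maxT), -1, dtype=int)
    for i, t in enumerate(tags):
        mask[i, : len(t)] = True
        ids = [lab_idx[lab] for lab in t]
        y_ids[i, : len(t)] = ids
        Y[i * maxT + np.arange(len(t)), ids] = 1.0
        for a, b in zip(ids, ids[1:]):
            emp_trans[a, b] += 1.0

    maskf = mask.astype(float)[:, :, None]

    def objective(theta: np.ndarray):
        W = theta[: F * L].reshape(F, L)
        T = theta[F * L :].reshape(L, L)
        E = (X @ W).reshape(S, maxT, L)

        # forward with carry-forward masking
        alpha = np.empty((S, maxT, L))
        alpha[:, 0] = E[:, 0]
        for t in range(1, maxT):
            nxt = logsumexp(alpha[:, t - 1][:, :, None] + T[None], axis=1) + E[:, t]
            alpha[:, t] = np.where(mask[:, t][:, None], nxt, alpha[:, t - 1])
        logZ = logsumexp(alpha[:, -1], axis=1)

        beta = np.zeros((S, maxT, L))
        for t in range(maxT - 2, -1, -1):
            nxt = logsumexp(
                T[None] + (E[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2
            )
            beta[:, t] = np.where(mask[:, t + 1][:, None], nxt, 0.0)

        post = np.exp(alpha + beta - logZ[:, None, None]) * maskf

        exp_trans = np.zeros((L, L))
        for t in range(1, maxT):
            act = mask[:, t]
            if not act.any():
                continue
            M = (
                alpha[:, t - 1][:, :, None]
                + T[None]
                + (E[:, t] + beta[:, t])[:, None, :]
                - logZ[:, None, None]
            )
            M = np.where(act[:, None, None], M, -np.inf)
            exp_trans += np.exp(M).sum(axis=0)

        gold_emit = float(np.sum(E.reshape(S * maxT, L) * Y))
        gold_trans = float(np.sum(emp_trans * T))
        nll = float(np.sum(logZ)) - gold_emit - gold_trans

        gW = X.T @ (post.reshape(S * maxT, L) - Y)
        gT = exp_trans - emp_trans

        nll += 0.5 * c2 * float(theta @ theta)
        grad = np.concatenate([np.asarray(gW).ravel(), gT.ravel()]) + c2 * theta
        return nll, grad

    theta0 = np.zeros(F * L + L * L)
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 4 * maxiter, "ftol": 1e-8},
    )
    theta = res.x
    model_meta = {"c2": c2, "maxiter": maxiter, "converged": bool(res.success)}
    if meta:
        model_meta.update(meta)
    return LinearChainCRF(
        labels=tuple(labels),
        vocab=vocab,
        state_weights=theta[: F * L].reshape(F, L).copy(),
        trans_weights=theta[F * L :].reshape(L, L).copy(),
        meta=model_meta,
    )
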