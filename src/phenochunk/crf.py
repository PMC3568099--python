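"""Linear-chain conditional random field for BIO tagging.

Maximum-likelihood training of a first-order linear-chain CRF with binary
indicator features, L2 regularization and L-BFGS optimization.  The
forward–backward recursions run in log space, batched over sequences
(padded to the longest sequence with carry-forward masking), so one
objective/gradient evaluation is a handful of dense (S, L, L) operations
plus two sparse matrix products.

Features are opaque strings (one indicator per distinct string); a shared
bias indicator is added to every token.  Feature strings unseen at training
time are ignored at prediction time.

The model is intentionally plain: no feature induction, dense weights for
every observed indicator, and a single regularization constant.  Transition
weights are unregularized state-to-state parameters shared across
positions, which is what makes the tagger a chunker rather than a per-token
classifier.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

_BIAS = "__bias__"


class LinearChainCRF:
    """First-order linear-chain CRF over a fixed label alphabet.

    Parameters
    ----------
    l2:
        L2 penalty coefficient on all weights (state, transition, initial).
    max_iter:
        L-BFGS iteration cap.
    tol:
        Projected-gradient tolerance passed to the optimizer.
    labels:
        Label alphabet; order fixes the parameterization.
    """

    def __init__(
        self,
        l2: float = 1.0,
        max_iter: int = 80,
        tol: float = 1e-4,
        labels: tuple[str, ...] = ("B", "I", "O"),
    ):
        self.l2 = float(l2)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.labels = tuple(labels)
        self._feat_index: dict[str, int] | None = None
        self.W_state: np.ndarray | None = None
        self.W_trans: np.ndarray | None = None
        self.W_init: np.ndarray | None = None

    # -- training ----------------------------------------------------------

    def fit(
        self,
        sequences: list[list[list[str]]],
        labels: list[list[str]],
    ) -> "LinearChainCRF":
        """Fit on tokenized sequences of feature-string lists.

        ``sequences[s][t]`` is the list of active feature strings for token
        t of sequence s; ``labels[s][t]`` its gold label.
        """
        if len(sequences) != len(labels):
            raise ValueError("sequences and labels differ in length")
        pairs = [
            (fs, ls) for fs, ls in zip(sequences, labels) if len(fs) > 0
        ]
        if not pairs:
            raise ValueError("no non-empty training sequences")
        for fs, ls in pairs:
            if len(fs) != len(ls):
                raise ValueError("feature/label length mismatch in a sequence")

        L = len(self.labels)
        lab_index = {lab: k for k, lab in enumerate(self.labels)}

        feat_index: dict[str, int] = {_BIAS: 0}
        rows, cols = [], []
        y: list[int] = []
        seq_lens: list[int] = []
        n = 0
        for fs, ls in pairs:
            seq_lens.append(len(fs))
            for feats, lab in zip(fs, ls):
                try:
                    y.append(lab_index[lab])
                except KeyError:
                    raise ValueError(f"label {lab!r} outside alphabet {self.labels}")
                for f in feats:
                    j = feat_index.setdefault(f, len(feat_index))
                    rows.append(n)
                    cols.append(j)
                rows.append(n)
                cols.append(0)  # bias
                n += 1

        F = len(feat_index)
        X = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, F)
        )
        y_arr = np.asarray(y)
        Y = np.zeros((n, L))
        Y[np.arange(n), y_arr] = 1.0

        lens = np.asarray(seq_lens)
        S, T = len(lens), int(lens.max())
        # flat-token index per padded slot; -1 marks padding
        pos = np.full((S, T), -1, dtype=np.int64)
        off = 0
        for s, ln in enumerate(lens):
            pos[s, :ln] = np.arange(off, off + ln)
            off += ln
        valid = pos >= 0

        # constant empirical counts
        gold_state = (X.T @ Y)  # (F, L)
        gold_trans = np.zeros((L, L))
        gold_init = np.zeros(L)
        off = 0
        for ln in lens:
            ys = y_arr[off : off + ln]
            gold_init[ys[0]] += 1
            np.add.at(gold_trans, (ys[:-1], ys[1:]), 1.0)
            off += ln

        nFL = F * L

        def unpack(theta):
            Ws = theta[:nFL].reshape(F, L)
            Wt = theta[nFL : nFL + L * L].reshape(L, L)
            Wi = theta[nFL + L * L :]
            return Ws, Wt, Wi

        def nll_grad(theta):
            Ws, Wt, Wi = unpack(theta)
            U = X @ Ws  # (n, L)
            Upad = np.zeros((S, T, L))
            Upad[valid] = U

            alpha = np.empty((S, T, L))
            alpha[:, 0] = Wi[None, :] + Upad[:, 0]
            for t in range(1, T):
                prev = alpha[:, t - 1]
                cand = logsumexp(
                    prev[:, :, None] + Wt[None, :, :], axis=1
                ) + Upad[:, t]
                m = valid[:, t][:, None]
                alpha[:, t] = np.where(m, cand, prev)
            logZ = logsumexp(alpha[:, T - 1], axis=1)

            beta = np.zeros((S, T, L))
            E_trans = np.zeros((L, L))
            for t in range(T - 2, -1, -1):
                nxt = Upad[:, t + 1] + beta[:, t + 1]  # (S, L)
                cand = logsumexp(Wt[None, :, :] + nxt[:, None, :], axis=2)
                m = valid[:, t + 1][:, None]
                beta[:, t] = np.where(m, cand, 0.0)
                # pairwise marginals for edge (t, t+1)
                lm = (
                    alpha[:, t, :, None]
                    + Wt[None, :, :]
                    + nxt[:, None, :]
                    - logZ[:, None, None]
                )
                pm = np.exp(lm)
                pm[~valid[:, t + 1]] = 0.0
                E_trans += pm.sum(axis=0)

            logP = alpha + beta - logZ[:, None, None]
            P = np.exp(logP)
            Pflat = P[valid]  # (n, L)
            E_state = X.T @ Pflat
            E_init = P[:, 0, :].sum(axis=0)

            gold_score = (
                float((Ws * gold_state).sum())
                + float((Wt * gold_trans).sum())
                + float(Wi @ gold_init)
            )
            nll = float(logZ.sum()) - gold_score
            nll += 0.5 * self.l2 * float(theta @ theta)

            grad = np.concatenate(
                [
                    (E_state - gold_state).ravel(),
                    (E_trans - gold_trans).ravel(),
                    E_init - gold_init,
                ]
            )
            grad += self.l2 * theta
            return nll, grad

        theta0 = np.zeros(nFL + L * L + L)
        res = scipy.optimize.minimize(
            nll_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol},
        )
        Ws, Wt, Wi = unpack(res.x)
        self._feat_index = feat_index
        self.W_state = np.ascontiguousarray(Ws)
        self.W_trans = np.ascontiguousarray(Wt)
        self.W_init = np.ascontiguousarray(Wi)
        return self

    # -- prediction --------------------------------------------------------

    @property
    def is_fitted(self) -> bool:
        return self.W_state is not None

    def predict(self, sequence: list[list[str]]) -> list[str]:
        """Viterbi decoding of one sequence of feature-string lists."""
        if not self.is_fitted:
            raise RuntimeError("CRF is not fitted")
        T = len(sequence)
        if T == 0:
            return []
        L = len(self.labels)
        U = np.zeros((T, L))
        fi = self._feat_index
        for t, feats in enumerate(sequence):
            U[t] = self.W_state[0]  # bias
            for f in feats:
                j = fi.get(f)
                if j is not None:
                    U[t] += self.W_state[j]

        delta = np.empty((T, L))
        back = np.zeros((T, L), dtype=np.int64)
        delta[0] = self.W_init + U[0]
        for t in range(1, T):
            scores = delta[t - 1][:, None] + self.W_trans
            back[t] = scores.argmax(axis=0)
            delta[t] = scores.max(axis=0) + U[t]
        path = [int(delta[T - 1].argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[k] for k in path]
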