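"""Minimal single-hidden-layer network trained with Adam.

The learner is deliberately small and self-contained because its objective
is not an off-the-shelf loss: it mixes weekly squared errors with
window-mean squared errors for period-mean (chamber) records, and adds a
sign-consistency penalty that pushes the model's finite-difference
sensitivities to agree in sign with the causal-graph link strengths. All
arithmetic is plain numpy and fully deterministic given the seed.

f(x) = w2 . tanh(W1 x + b1) + b2
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MLPParams:
    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def copy(self) -> "MLPParams":
        return MLPParams(self.W1.copy(), self.b1.copy(), self.w2.copy(), float(self.b2))

    def to_jsonable(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "MLPParams":
        return cls(
            np.asarray(d["W1"], dtype=float),
            np.asarray(d["b1"], dtype=float),
            np.asarray(d["w2"], dtype=float),
            float(d["b2"]),
        )


def init_params(n_in: int, hidden: int, seed) -> MLPParams:
    rng = np.random.default_rng(seed)
    return MLPParams(
        W1=rng.standard_normal((hidden, n_in)) / np.sqrt(max(n_in, 1)),
        b1=np.zeros(hidden),
        w2=rng.standard_normal(hidden) / np.sqrt(hidden),
        b2=0.0,
    )


def forward(p: MLPParams, X: np.ndarray) -> np.ndarray:
    H = np.tanh(X @ p.W1.T + p.b1)
    return H @ p.w2 + p.b2


def weighted_grads(p: MLPParams, X: np.ndarray, c: np.ndarray) -> MLPParams:
    """Gradients of sum_i c_i * f(x_i) with respect to the parameters."""
    H = np.tanh(X @ p.W1.T + p.b1)  # (n, hidden)
    gw2 = H.T @ c
    gb2 = float(c.sum())
    # df/dpre = w2 * (1 - H^2)
    pre = (1.0 - H**2) * p.w2  # (n, hidden)
    cpre = pre * c[:, None]
    gW1 = cpre.T @ X
    gb1 = cpre.sum(axis=0)
    return MLPParams(gW1, gb1, gw2, gb2)


def _axpy(acc: MLPParams, g: MLPParams, a: float = 1.0) -> None:
    acc.W1 += a * g.W1
    acc.b1 += a * g.b1
    acc.w2 += a * g.w2
    acc.b2 += a * g.b2


def sensitivities(p: MLPParams, probe: np.ndarray, h: float = 0.5) -> np.ndarray:
    """Mean central finite-difference sensitivity of f to each input column."""
    n, k = probe.shape
    out = np.empty(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        out[j] = float(np.mean(forward(p, probe + e) - forward(p, probe - e))) / (2.0 * h)
    return out


def guidance_penalty(p: MLPParams, probe: np.ndarray, signs: np.ndarray,
                     h: float = 0.5, skip: np.ndarray | None = None) -> float:
    """Hinge penalty only (no gradient); see guidance_penalty_and_grad."""
    S = sensitivities(p, probe, h)
    pen = 0.0
    for j in range(probe.shape[1]):
        if signs[j] == 0 or (skip is not None and skip[j]):
            continue
        pen += max(0.0, -signs[j] * S[j]) ** 2
    return pen


def guidance_penalty_and_grad(
    p: MLPParams, probe: np.ndarray, signs: np.ndarray, h: float = 0.5,
    skip: np.ndarray | None = None,
):
    """Sign-consistency hinge penalty and its parameter gradient.

    penalty = sum_j max(0, -sign_j * S_j)^2 over links j with sign_j != 0,
    where S_j is the mean finite-difference sensitivity over the probe rows.
    Columns flagged in ``skip`` (zero-variance probes) contribute nothing.
    """
    n, k = probe.shape
    S = sensitivities(p, probe, h)
    penalty = 0.0
    grad = MLPParams(np.zeros_like(p.W1), np.zeros_like(p.b1), np.zeros_like(p.w2), 0.0)
    for j in range(k):
        if signs[j] == 0 or (skip is not None and skip[j]):
            continue
        viol = max(0.0, -signs[j] * S[j])
        if viol <= 0.0:
            continue
        penalty += viol**2
        # d penalty/d theta = 2*viol * (-sign_j) * dS_j/dtheta
        e = np.zeros(k)
        e[j] = h
        coef = 2.0 * viol * (-signs[j]) / (2.0 * h * n)
        c = np.full(n, coef)
        _axpy(grad, weighted_grads(p, probe + e, c), 1.0)
        _axpy(grad, weighted_grads(p, probe - e, c), -1.0)
    return penalty, grad


@dataclass
class FitResult:
    params: MLPParams
    train_loss: float
    val_loss: float
    n_epochs: int


def fit(
    X_weekly: np.ndarray,
    y_weekly: np.ndarray,
    period_groups: list,  # list of (X_block, mean_target)
    X_val: np.ndarray,
    y_val: np.ndarray,
    val_groups: list,
    signs: np.ndarray,
    lam: float = 0.1,
    hidden: int = 16,
    seed=0,
    lr: float = 0.02,
    max_epochs: int = 1500,
    patience: int = 20,
    rtol: float = 1e-6,
    probe_cap: int = 256,
    min_epochs: int = 150,
) -> FitResult:
    """Full-batch Adam on the mixed-frequency + guidance objective.

    Targets are expected pre-standardized; features standardized. Early
    stopping monitors the validation data loss with ``patience`` epochs of
    < ``rtol`` relative improvement; a ``min_epochs`` warm-up keeps the
    noisy early epochs from triggering it. The best parameters are restored.
    """
    n_in = X_weekly.shape[1] if X_weekly.size else (
        period_groups[0][0].shape[1] if period_groups else 1
    )
    p = init_params(n_in, hidden, seed)
    m = MLPParams(np.zeros_like(p.W1), np.zeros_like(p.b1), np.zeros_like(p.w2), 0.0)
    v = MLPParams(np.zeros_like(p.W1), np.zeros_like(p.b1), np.zeros_like(p.w2), 0.0)
    b1m, b2m, eps = 0.9, 0.999, 1e-8

    n_terms = len(y_weekly) + len(period_groups)
    if n_terms == 0:
        raise ValueError("no training data")
    probe_src = X_weekly if X_weekly.size else np.vstack([g[0] for g in period_groups])
    stride = max(1, int(np.ceil(probe_src.shape[0] / probe_cap)))
    probe = probe_src[::stride]
    skip = probe.std(axis=0) <= 1e-12 if probe.shape[0] > 1 else np.zeros(n_in, bool)

    def data_loss_and_grad(params):
        grad = MLPParams(np.zeros_like(params.W1), np.zeros_like(params.b1),
                         np.zeros_like(params.w2), 0.0)
        loss = 0.0
        if len(y_weekly):
            r = forward(params, X_weekly) - y_weekly
            loss += float(r @ r)
            _axpy(grad, weighted_grads(params, X_weekly, 2.0 * r / n_terms))
        for Xg, ybar in period_groups:
            d = float(forward(params, Xg).mean() - ybar)
            loss += d * d
            c = np.full(Xg.shape[0], 2.0 * d / (n_terms * Xg.shape[0]))
            _axpy(grad, weighted_grads(params, Xg, c))
        return loss / n_terms, grad

    def val_loss(params):
        loss, n = 0.0, 0
        if len(y_val):
            r = forward(params, X_val) - y_val
            loss += float(r @ r)
            n += len(y_val)
        for Xg, ybar in val_groups:
            loss += (float(forward(params, Xg).mean() - ybar)) ** 2
            n += 1
        return loss / max(n, 1)

    best = p.copy()
    best_val = np.inf
    stale = 0
    t = 0
    n_epochs = 0
    for epoch in range(max_epochs):
        n_epochs = epoch + 1
        loss, grad = data_loss_and_grad(p)
        if lam > 0 and np.any(signs != 0):
            pen, pgrad = guidance_penalty_and_grad(p, probe, signs, skip=skip)
            loss += lam * pen
            _axpy(grad, pgrad, lam)
        t += 1
        for name in ("W1", "b1", "w2", "b2"):
            g = getattr(grad, name)
            mm = getattr(m, name)
            vv = getattr(v, name)
            mm = b1m * mm + (1 - b1m) * g
            vv = b2m * vv + (1 - b2m) * (g * g if name != "b2" else g**2)
            setattr(m, name, mm)
            setattr(v, name, vv)
            mhat = mm / (1 - b1m**t)
            vhat = vv / (1 - b2m**t)
            step = lr * mhat / (np.sqrt(vhat) + eps)
            setattr(p, name, getattr(p, name) - step)
        vl = val_loss(p)
        if lam > 0 and np.any(signs != 0):
            # selection must honour the full objective, or a sign-violating
            # fit with a slightly better data loss would always win
            vl += lam * guidance_penalty(p, probe, signs, skip=skip)
        if vl < best_val:
            best = p.copy()
        stale = 0 if vl < best_val * (1.0 - rtol) else stale + 1
        best_val = min(best_val, vl)
        if n_epochs >= min_epochs and stale >= patience:
            break
    final_train, _ = data_loss_and_grad(best)
    return FitResult(params=best, train_loss=final_train, val_loss=best_val, n_epochs=n_epochs)
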