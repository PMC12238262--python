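"""Naive reference implementations used as independent oracles in tests.

Deliberately written with explicit Python loops, index by index, so they
share no code path with the vectorized implementations they validate.
"""

from __future__ import annotations

import numpy as np


def oracle_cv(pos: np.ndarray, tau_max: int) -> np.ndarray:
    """Velocity autocorrelation by explicit loops."""
    v = np.diff(pos, axis=-1)
    n, _, m = v.shape
    denom, count = 0.0, 0
    for i in range(n):
        for t in range(m):
            denom += v[i, 0, t] ** 2 + v[i, 1, t] ** 2
            count += 1
    denom /= count
    out = np.zeros(tau_max + 1)
    for tau in range(tau_max + 1):
        if tau == 0:
            out[0] = 1.0
            continue
        acc, cnt = 0.0, 0
        for i in range(n):
            for t in range(m - tau):
                acc += v[i, 0, t] * v[i, 0, t + tau] + v[i, 1, t] * v[i, 1, t + tau]
                cnt += 1
        out[tau] = (acc / cnt) / denom
    return out


def oracle_cr(pos: np.ndarray, tau_max: int) -> np.ndarray:
    """Positional autocorrelation by explicit loops."""
    n, _, T = pos.shape
    denom, count = 0.0, 0
    for i in range(n):
        for t in range(T):
            denom += pos[i, 0, t] ** 2 + pos[i, 1, t] ** 2
            count += 1
    denom /= count
    out = np.zeros(tau_max + 1)
    for tau in range(tau_max + 1):
        if tau == 0:
            out[0] = 1.0
            continue
        acc, cnt = 0.0, 0
        for i in range(n):
            for t in range(T - tau):
                acc += (pos[i, 0, t] * pos[i, 0, t + tau]
                        + pos[i, 1, t] * pos[i, 1, t + tau])
                cnt += 1
        out[tau] = (acc / cnt) / denom
    return out


def oracle_moments(d: list[float]) -> dict[str, float]:
    """Population moments by accumulation loops."""
    n = len(d)
    mu = sum(d) / n
    var = sum((v - mu) ** 2 for v in d) / n
    if var == 0:
        return {"mean": mu, "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    sd = var ** 0.5
    return {"mean": mu, "variance": var,
            "skewness": sum((v - mu) ** 3 for v in d) / n / sd ** 3,
            "kurtosis": sum((v - mu) ** 4 for v in d) / n / var ** 2}


def oracle_xi(pos: np.ndarray, tau: int) -> dict[str, float]:
    """Non-Gaussianity by explicit pooling loops."""
    out = {}
    n, _, T = pos.shape
    for ci, comp in enumerate("xy"):
        m2, m4, cnt = 0.0, 0.0, 0
        for i in range(n):
            for t in range(T - tau):
                d = pos[i, ci, t + tau] - pos[i, ci, t]
                m2 += d ** 2
                m4 += d ** 4
                cnt += 1
        m2 /= cnt
        m4 /= cnt
        out[comp] = m4 / (3.0 * m2 ** 2) - 1.0
    return out


def oracle_msd(pos: np.ndarray, max_lag: int) -> np.ndarray:
    """Ensemble-and-time-averaged MSD by explicit loops."""
    n, _, T = pos.shape
    out = np.zeros(max_lag)
    for k, tau in enumerate(range(1, max_lag + 1)):
        acc, cnt = 0.0, 0
        for i in range(n):
            for t in range(T - tau):
                dx = pos[i, 0, t + tau] - pos[i, 0, t]
                dy = pos[i, 1, t + tau] - pos[i, 1, t]
                acc += dx ** 2 + dy ** 2
                cnt += 1
        out[k] = acc / cnt
    return out


def oracle_confusion_f1(pred: list[str], true: list[str]) -> float:
    """Weighted F1 from an explicit confusion matrix."""
    classes = sorted(set(true) | set(pred))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for p, t in zip(pred, true):
        conf[index[t], index[p]] += 1
    total = conf.sum()
    wf1 = 0.0
    for i in range(k):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        wf1 += (conf[i, :].sum() / total) * f1
    return float(wf1)
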