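"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal definitions — explicit loops,
explicit template counting, explicit confusion tallies — deliberately
sharing no code with the package so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def cheb(a, b) -> float:
    return max(abs(float(u) - float(v)) for u, v in zip(a, b))


def apen_brute(x, m: int, r: float) -> float:
    """Pincus approximate entropy by exhaustive template counting."""
    x = [float(v) for v in x]
    n = len(x)

    def phi(mm: int) -> float:
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = sum(1 for tj in templates if cheb(ti, tj) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_brute(x, m: int, r: float) -> float:
    """Sample entropy by exhaustive pairwise counting, self-matches excluded."""
    x = [float(v) for v in x]
    n = len(x)
    n_t = n - m  # equal numbers of m- and (m+1)-templates

    def count(mm: int) -> int:
        templates = [x[i : i + mm] for i in range(n_t)]
        c = 0
        for i in range(n_t):
            for j in range(i + 1, n_t):
                if cheb(templates[i], templates[j]) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def permen_brute(x, m: int, delay: int) -> float:
    """Permutation entropy via an explicit ordinal-pattern histogram.

    Ties ranked by temporal order of appearance (stable sort on value
    with index as tiebreak).
    """
    x = [float(v) for v in x]
    n_pat = len(x) - (m - 1) * delay
    patterns = []
    for i in range(n_pat):
        window = [x[i + k * delay] for k in range(m)]
        order = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        patterns.append(order)
    counts = Counter(patterns)
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def hos_brute(x) -> tuple[float, float, float, float]:
    """Literal-formula skewness, excess kurtosis, variance and sd.

    Skewness/kurtosis use the population (1/N) standard deviation in the
    denominator; variance uses 1/(N-1).
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sigma = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    skew = sum(((v - mean) / sigma) ** 3 for v in x) / n
    kurt = sum(((v - mean) / sigma) ** 4 for v in x) / n - 3.0
    variance = sum((v - mean) ** 2 for v in x) / (n - 1)
    return skew, kurt, variance, math.sqrt(variance)


def metrics_brute(y_true, y_pred, classes):
    """Confusion matrix, accuracy and macro P/R/F1 by explicit counting."""
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    accuracy = float(np.trace(cm)) / len(y_true)
    precisions, recalls, f1s = [], [], []
    for i in range(k):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return cm, accuracy, float(np.mean(precisions)), float(np.mean(recalls)), float(np.mean(f1s))


def laplacian_brute(data, labels, neighbor_table):
    """Per-channel neighbor-mean subtraction with explicit loops."""
    out = np.array(data, dtype=float, copy=True)
    for i, lab in enumerate(labels):
        nbrs = [n for n in sorted(neighbor_table[lab]) if n in labels]
        for t in range(data.shape[1]):
            mean = sum(data[labels.index(n), t] for n in nbrs) / len(nbrs)
            out[i, t] = data[i, t] - mean
    return out


def simulate_ar(phi, n: int, seed: int = 0, burn: int = 500) -> np.ndarray:
    """Self-simulated AR(p) series for parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    p = len(phi)
    x = np.zeros(n + burn)
    eps = rng.normal(size=n + burn)
    for t in range(p, n + burn):
        x[t] = sum(phi[i] * x[t - 1 - i] for i in range(p)) + eps[t]
    return x[burn:]
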