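"""Independent brute-force oracles shared across test modules."""

import itertools
import math

import numpy as np


def exact_shapley(predict_fn, x, background):
    """Exact Shapley values by full subset enumeration.

    Value function v(S) = mean over background rows of f(x_S, z_rest):
    features in S come from x, the rest from each background row in turn.
    Exponential in the number of features; intended for p <= ~8.
    """
    p = len(x)
    phi = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for subset in itertools.combinations(others, size):
                v_with = _value(predict_fn, x, background, list(subset) + [j])
                v_without = _value(predict_fn, x, background, list(subset))
                phi[j] += w * (v_with - v_without)
    return phi


def _value(predict_fn, x, background, subset):
    rows = np.array(background, dtype=float, copy=True)
    if subset:
        rows[:, subset] = x[subset]
    return float(np.mean(predict_fn(rows)))
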