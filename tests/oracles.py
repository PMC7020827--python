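"""Independent brute-force oracles used to validate the fast implementations.

Deliberately naive: explicit Python loops, exhaustive enumeration, no shared
code with the package.
"""

import math

import numpy as np


def sampen_bruteforce(x, m: int, r_frac: float) -> float:
    """Sample entropy by exhaustive template-pair counting (Chebyshev, no
    self-matches, N-m templates at both lengths, r = r_frac * SD)."""
    x = [float(v) for v in x]
    N = len(x)
    r = r_frac * float(np.std(x))
    n_t = N - m

    def matches(length):
        count = 0
        for i in range(n_t):
            for j in range(i + 1, n_t):
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    count += 1
        return count

    B = matches(m)
    A = matches(m + 1)
    if B == 0:
        return 0.0
    if A == 0:
        # same convention as the implementation: the finite ceiling that a
        # single match at length m+1 would produce
        return -math.log(2.0 / ((n_t - 1) * n_t))
    return -math.log(A / B)


def peen_bruteforce(x, m: int, tau: int) -> float:
    """Normalized permutation entropy by explicit pattern enumeration; ties
    ranked by order of occurrence."""
    x = [float(v) for v in x]
    n = len(x) - (m - 1) * tau
    counts: dict[tuple, int] = {}
    for i in range(n):
        v = [x[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (v[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    probs = [c / n for c in counts.values()]
    return -sum(p * math.log(p) for p in probs) / math.log(math.factorial(m))


def pk_bruteforce(x, y, tie_tol: float = 0.0) -> float:
    """Prediction probability by O(n^2) pair enumeration (no reflection)."""
    n = len(x)
    conc = disc = xtie = 0
    for i in range(n):
        for j in range(i + 1, n):
            dy = y[i] - y[j]
            if dy == 0:
                continue
            dx = x[i] - x[j]
            if abs(dx) <= tie_tol:
                xtie += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    return (conc + 0.5 * xtie) / (conc + disc + xtie)


def numerical_gradient(loss_fn, params: dict, eps: float = 1e-6) -> dict:
    """Central finite-difference gradient of ``loss_fn(params)`` per array."""
    grads = {}
    for key, value in params.items():
        g = np.zeros_like(value)
        flat = value.ravel()
        gflat = g.ravel()
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + eps
            hi = loss_fn(params)
            flat[idx] = orig - eps
            lo = loss_fn(params)
            flat[idx] = orig
            gflat[idx] = (hi - lo) / (2 * eps)
        grads[key] = g
    return grads
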