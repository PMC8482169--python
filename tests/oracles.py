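"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops, closed
forms, normal equations) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_match_counts(x, m, r):
    """O(n²) pair counts at template lengths m and m+1 (Chebyshev, no self-matches)."""
    x = list(map(float, x))
    n = len(x)
    nt = n - m  # same template range at both lengths
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def brute_sample_entropy(x, m, r):
    b, a = brute_match_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def brute_rcmse(x, m, r_factor, scales):
    """Refined composite MSE by naive coarse-graining + brute-force counts."""
    x = np.asarray(x, dtype=float)
    r = r_factor * float(np.std(x))
    entropies = []
    for tau in scales:
        b_tot = a_tot = 0
        for offset in range(tau):
            y = []
            start = offset
            while start + tau <= x.size:
                y.append(float(np.mean(x[start : start + tau])))
                start += tau
            b, a = brute_match_counts(y, m, r)
            b_tot += b
            a_tot += a
        entropies.append(-math.log(a_tot / b_tot) if a_tot and b_tot else float("nan"))
    return np.array(entropies)


def normal_equations_ols(y, X):
    """Closed-form OLS with intercept: estimates, SEs, R², adjusted R²."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    dof = n - p - 1
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / dof
    return beta, se, r2, adj


def pink_noise(n, rng):
    """1/f-type noise by spectral shaping of white noise."""
    f = np.fft.rfftfreq(n, 1.0)
    spec = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    spec[1:] = spec[1:] / np.sqrt(f[1:])
    spec[0] = 0.0
    return np.fft.irfft(spec, n)
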