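"""Independent brute-force transcriptions of every marker formula.

Deliberately naive (plain loops, direct formula evaluation) so they
share no code path with the package's vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np


def band_power(y):
    T = len(y)
    return sum(y[t] ** 2 for t in range(T)) / T


def relative_band_power(y_band, y_broad):
    return band_power(y_band) / band_power(y_broad)


def line_length(y):
    return sum(abs(y[t + 1] - y[t]) for t in range(len(y) - 1))


def _var(y):
    T = len(y)
    m = sum(y) / T
    return sum((v - m) ** 2 for v in y) / (T - 1)


def hjorth(y):
    d = [y[t + 1] - y[t] for t in range(len(y) - 1)]
    dd = [d[t + 1] - d[t] for t in range(len(d) - 1)]
    act = _var(y)
    mob = math.sqrt(_var(d) / act)
    mob_d = math.sqrt(_var(dd) / _var(d))
    return act, mob, mob_d / mob


def nonlinear_energy(y):
    T = len(y)
    return sum(y[t + 1] ** 2 - y[t] * y[t + 2] for t in range(T - 2)) / (T - 2)


def skewness(y):
    T = len(y)
    m = sum(y) / T
    sd = math.sqrt(_var(y))
    return sum((v - m) ** 3 for v in y) / ((T - 1) * sd**3)


def _cheb(y, p, q, m):
    return max(abs(y[p + v] - y[q + v]) for v in range(m))


def apen(y, r, m=2):
    """Template-count approximate entropy; d <= r, self-matches included."""
    T = len(y)
    out = []
    for mm in (m, m + 1):
        n = T - mm + 1
        logs = []
        for p in range(n):
            c = sum(1 for q in range(n) if _cheb(y, p, q, mm) <= r)
            logs.append(math.log(c / n))
        out.append(sum(logs) / n)
    return out[0] - out[1]


def sampen_counts(y, r, m=2):
    """(A, B) normalised match counts; d < r, p != q, both over T-m templates."""
    T = len(y)
    n = T - m
    A = B = 0
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _cheb(y, p, q, m) < r:
                B += 1
            if _cheb(y, p, q, m + 1) < r:
                A += 1
    norm = (T - m - 1) * (T - m)
    return A / norm, B / norm


def sampen(y, r, m=2):
    A, B = sampen_counts(y, r, m)
    return -math.log(A / B)


def pearson(x, y):
    T = len(x)
    mx, my = sum(x) / T, sum(y) / T
    cov = sum((x[t] - mx) * (y[t] - my) for t in range(T))
    sx = math.sqrt(sum((v - mx) ** 2 for v in x))
    sy = math.sqrt(sum((v - my) ** 2 for v in y))
    return cov / (sx * sy)


def plv(theta_m, theta_n):
    T = len(theta_m)
    acc = sum(np.exp(1j * (theta_m[t] - theta_n[t])) for t in range(T))
    return abs(acc) / T


def pac(a_m, theta_n):
    T = len(a_m)
    acc = sum(a_m[t] * np.exp(1j * theta_n[t]) for t in range(T))
    return abs(acc) / T


def coherence_band(G_mn, G_mm, G_nn):
    """Mean per-bin magnitude-squared coherency over the given bins."""
    vals = [abs(G_mn[f]) ** 2 / (G_mm[f] * G_nn[f]) for f in range(len(G_mn))
            if G_mm[f] > 0 and G_nn[f] > 0]
    return sum(vals) / len(vals)


def r2(y_true, y_pred):
    m = sum(y_true) / len(y_true)
    ss_tot = sum((v - m) ** 2 for v in y_true)
    ss_res = sum((a - b) ** 2 for a, b in zip(y_true, y_pred))
    return 1 - ss_res / ss_tot


def window_mean(series, start, length):
    return sum(series[start : start + length]) / length


def importance_triple_loop(phi):
    """imp_i = 1/(5NS) sum_s sum_f sum_n |phi[n,f,s,i]| on a dense tensor."""
    N, F, S, M = phi.shape
    out = np.zeros(M)
    for i in range(M):
        acc = 0.0
        for s in range(S):
            for f in range(F):
                for n in range(N):
                    acc += abs(phi[n, f, s, i])
        out[i] = acc / (F * N * S)
    return out
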