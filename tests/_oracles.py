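"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(exact rational arithmetic, explicit python loops, dense grids) so that
agreement is evidence of correctness rather than shared code.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def fisher_exact_oracle(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    row1 = tp + fp
    col1 = tp + fn
    n = tp + fp + fn + tn
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    denom = comb(n, row1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        x: Fraction(comb(col1, x) * comb(n - col1, row1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[tp]
    return float(sum(p for p in probs.values() if p <= p_obs))


def branch_crossings_oracle(angle, torque, direction, want_direction):
    """Zero-torque crossing of one direction branch by explicit pairwise scan.

    Walks every adjacent sample pair inside runs of constant direction,
    collects exact-zero hits and sign-change interpolations, and returns
    the median crossing (NaN when the branch never crosses)."""
    crossings = []
    i = 0
    n = len(angle)
    while i < n:
        j = i
        while j < n and direction[j] == direction[i]:
            j += 1
        if direction[i] == want_direction:
            for k in range(i, j):
                if torque[k] == 0.0:
                    crossings.append(angle[k])
            for k in range(i, j - 1):
                t0, t1 = torque[k], torque[k + 1]
                if t0 * t1 < 0:
                    a0, a1 = angle[k], angle[k + 1]
                    crossings.append(a0 + (a1 - a0) * (-t0) / (t1 - t0))
        i = j
    if not crossings:
        return float("nan")
    return float(np.median(crossings))


def dense_ls_slope_oracle(scale, shape, h, limit, d_total, fraction=0.10,
                          step=1e-3):
    """Discrete least-squares endpoint slope on a dense angle grid.

    Fits torque = scale*(exp(shape*x)-1)+h over the window of width
    fraction*d_total ending at the excursion; independent check of the
    analytic continuous-LS closed form."""
    d_max = np.log1p((limit - h) / scale) / shape
    w = fraction * d_total
    x = np.arange(d_max - w, d_max + step / 2, step)
    y = scale * np.expm1(shape * x) + h
    return float(np.polyfit(x, y, 1)[0])


def welch_t_oracle(a, b):
    """Textbook Welch two-sample t and two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def paired_t_oracle(a, b):
    """Textbook paired t and two-sided p."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)
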