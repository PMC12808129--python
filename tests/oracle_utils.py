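"""Brute-force oracles, independent of the library implementations."""

import math

import numpy as np


def average_ranks(a):
    """Average ranks (1-based) with ties sharing their mean rank."""
    a = np.asarray(a, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a))
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def bh_oracle(p):
    """Benjamini-Hochberg step-up by the textbook recipe.

    Sort ascending, scale p_(i) by m/i, take the running minimum from the
    largest p downwards, cap at 1, and restore the input order.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def paired_t_p_oracle(x, y):
    """Two-sided paired-t p-value from the t CDF (regularized beta form)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0 if np.all(d == 0) else 0.0
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    # survival function of |t| via the incomplete beta function
    from scipy.special import betainc

    p_one = 0.5 * betainc(df / 2.0, 0.5, df / (df + t * t))
    return 2.0 * p_one


def index_oracle(intensities, marker_rows):
    """Contamination index by explicit per-sample summation over a 2D array."""
    n_proteins, n_samples = intensities.shape
    out = []
    for j in range(n_samples):
        total = 0.0
        markers = 0.0
        for i in range(n_proteins):
            v = intensities[i, j]
            if not np.isnan(v):
                total += v
                if i in marker_rows:
                    markers += v
        out.append(markers / total if total > 0 else 0.0)
    return np.array(out)
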