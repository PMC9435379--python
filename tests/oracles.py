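"""Independent brute-force reference implementations used only by tests.

Each function re-derives a statistic from first principles (direct sums,
expected-count enumeration, normal equations) without calling the package,
so agreement checks are genuinely dual-route.
"""

import math

import numpy as np
from scipy import stats


def oracle_log_or(a, b, c, d):
    """Crude log-OR and Woolf SE, with +0.5 on every cell if any is zero."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a) + math.log(d) - math.log(b) - math.log(c), \
        math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def oracle_hwe_chi2(aa, ag, gg):
    """Chi-square HWE statistic via explicit expected-count enumeration."""
    n = aa + ag + gg
    n_a = 2 * aa + ag
    n_g = 2 * gg + ag
    if n_a == 0 or n_g == 0:
        return 0.0
    p = n_a / (n_a + n_g)
    expected = [n * p * p, n * 2 * p * (1 - p), n * (1 - p) * (1 - p)]
    return sum((o - e) ** 2 / e for o, e in zip((aa, ag, gg), expected))


def oracle_q(thetas, ses):
    """Cochran's Q by direct sum evaluation."""
    w = [1.0 / s**2 for s in ses]
    mu = sum(wi * t for wi, t in zip(w, thetas)) / sum(w)
    return sum(wi * (t - mu) ** 2 for wi, t in zip(w, thetas))


def oracle_mh(tables):
    """Mantel-Haenszel pooled log-OR and RBG SE from (a, b, c, d) tuples,
    spreadsheet-style: every per-table term computed and summed explicitly."""
    terms = []
    for a, b, c, d in tables:
        n = a + b + c + d
        raw_r, raw_s = a * d / n, b * c / n
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            n = a + b + c + d
        terms.append({
            "raw_r": raw_r, "raw_s": raw_s,
            "p": (a + d) / n, "q": (b + c) / n,
            "r": a * d / n, "s": b * c / n,
        })
    log_or = math.log(sum(t["raw_r"] for t in terms)
                      / sum(t["raw_s"] for t in terms))
    r = sum(t["r"] for t in terms)
    s = sum(t["s"] for t in terms)
    var = (sum(t["p"] * t["r"] for t in terms) / (2 * r * r)
           + sum(t["p"] * t["s"] + t["q"] * t["r"] for t in terms) / (2 * r * s)
           + sum(t["q"] * t["s"] for t in terms) / (2 * s * s))
    return log_or, math.sqrt(var)


def oracle_dl(thetas, ses):
    """DerSimonian-Laird tau2 and pooled log-OR by direct formula evaluation."""
    k = len(thetas)
    w = [1.0 / s**2 for s in ses]
    q = oracle_q(thetas, ses)
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = [1.0 / (s**2 + tau2) for s in ses]
    mu = sum(wi * t for wi, t in zip(w_star, thetas)) / sum(w_star)
    return tau2, mu, 1.0 / math.sqrt(sum(w_star))


def oracle_egger(thetas, ses):
    """Egger intercept, its SE and two-sided p via the normal equations."""
    x = np.array([1.0 / s for s in ses])
    y = np.array([t / s for t, s in zip(thetas, ses)])
    design = np.column_stack([np.ones_like(x), x])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    k = len(thetas)
    s2 = float(resid @ resid) / (k - 2)
    cov = s2 * np.linalg.inv(xtx)
    se_int = math.sqrt(cov[0, 0])
    t_stat = beta[0] / se_int
    return float(beta[0]), se_int, float(2 * stats.t.sf(abs(t_stat), k - 2))
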