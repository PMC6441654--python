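"""Independent brute-force oracles used to check the package's computations.

Everything here is written from the definitions (log-gamma sums, exhaustive
enumeration, exact rational combinatorics) without importing the package's
own numerical routines, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
from fractions import Fraction


def nb_logpmf(k: int, mean: float, phi: float) -> float:
    """log NB pmf with variance = mean + phi*mean^2 (Poisson at phi = 0)."""
    if mean == 0:
        return 0.0 if k == 0 else -math.inf
    if phi == 0:
        return k * math.log(mean) - mean - math.lgamma(k + 1)
    r = 1.0 / phi
    p = r / (r + mean)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log(1.0 - p)
    )


def exact_test_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided (by probability mass) exact-test p-value via full enumeration.

    Group sums are NB(n·mu_hat, phi/n) with mu_hat = total/(n_a+n_b); every
    split (k, total-k) with probability <= that of the observed split
    contributes, conditional on the total.
    """
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu_hat = total / (n_a + n_b)
    probs = [
        math.exp(nb_logpmf(k, n_a * mu_hat, phi / n_a) + nb_logpmf(total - k, n_b * mu_hat, phi / n_b))
        for k in range(total + 1)
    ]
    obs = probs[s_a]
    kept = sum(p for p in probs if p <= obs * (1 + 1e-10))
    return kept / sum(probs)


def bh_adjust(p_values):
    """Benjamini–Hochberg step-up by hand: sort, scale by m/rank, cummin from the top."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        adjusted[i] = min(running, 1.0)
    return adjusted


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via binomial coefficients."""
    denom = math.comb(N, n)
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return Fraction(num, denom)


def n50(lengths) -> int:
    """Length at which the descending cumulative sum first reaches half the total."""
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2
    cum = 0
    for l in ls:
        cum += l
        if cum >= half:
            return l
    raise AssertionError("unreachable for non-empty input")


def consistency_rule(calls_by_gene: dict[str, list[str]], min_support: int):
    """Literal application of the same-trend rule.

    calls_by_gene maps gene -> list of per-timepoint calls in
    {"up", "down", "none"}.  Returns {gene: (direction, support)} for genes
    with one coherent direction reaching min_support; genes reaching it in
    both directions are excluded.
    """
    out = {}
    for gene, calls in calls_by_gene.items():
        n_up = calls.count("up")
        n_down = calls.count("down")
        up_ok = n_up >= min_support
        down_ok = n_down >= min_support
        if up_ok and down_ok:
            continue
        if up_ok:
            out[gene] = ("up", n_up)
        elif down_ok:
            out[gene] = ("down", n_down)
    return out


def pearson(x, y) -> float:
    """Correlation from explicit covariance/sd sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def entropy_weights(columns: list[list[float]], conventional: bool = True):
    """Direct summation of the entropy-weight formulas over indicator columns."""
    n = len(columns[0])
    m = len(columns)
    hs = []
    for col in columns:
        s = sum(col)
        f = [v / s for v in col]
        h = sum(v * math.log(v) for v in f if v > 0) / math.log(n)
        hs.append(-h if conventional else h)
    denom = m - sum(hs)
    ws = [(1 - h) / denom for h in hs]
    return hs, ws
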