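"""Independent exact-arithmetic oracles used by the test suite.

These deliberately avoid the package's log-space code paths: everything
here is integer/rational arithmetic via :mod:`fractions` and
:func:`math.comb`.
"""

import math
from fractions import Fraction
from typing import Sequence


def exact_mvh_probability(m: Sequence[int], c: Sequence[int]) -> Fraction:
    """P(counts = c) under sampling sum(c) items without replacement from
    categories of sizes m: prod C(m_k, c_k) / C(sum m, sum c)."""
    num = 1
    for mk, ck in zip(m, c):
        num *= math.comb(mk, ck)
    return Fraction(num, math.comb(sum(m), sum(c)))


def exact_hypergeom_tail(big_n: int, big_k: int, n: int, x: int) -> Fraction:
    """P(X >= x) for X ~ Hypergeom(N, K, n), exact rational."""
    total = math.comb(big_n, n)
    acc = 0
    for i in range(x, min(n, big_k) + 1):
        if n - i > big_n - big_k:
            continue
        acc += math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
    return Fraction(acc, total)


def compositions(total: int, parts: int):
    """All weak compositions of ``total`` into ``parts`` non-negative ints."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in compositions(total - head, parts - 1):
            yield (head,) + tail


def bh_stepup(pvalues: Sequence[float], alpha: float) -> list:
    """Textbook step-up rule: reject the smallest k with
    p_(i) <= i*alpha/m for all i <= k (largest such k)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * alpha / m:
            k = rank
    reject = [False] * m
    for idx in order[:k]:
        reject[idx] = True
    return reject
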