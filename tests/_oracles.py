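"""Independent brute-force oracles used to freeze expected values."""

import math

import numpy as np


def log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(x: int) -> float:
        return math.exp(log_binom(r1, x) + log_binom(r2, c1 - x) - log_binom(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    total = sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-9))
    return min(total, 1.0)


def brute_force_union(interval_sets, lo: int, hi: int):
    """Per-bp membership union of interval sets on [lo, hi); returns merged list."""
    covered = np.zeros(hi - lo, dtype=bool)
    for ivals in interval_sets:
        for s, e in ivals:
            covered[max(s, lo) - lo : min(e, hi) - lo] = True
    merged = []
    i = 0
    n = len(covered)
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            merged.append((lo + i, lo + j))
            i = j
        else:
            i += 1
    return merged


def brute_force_dinuc_windows(seq: str):
    """All dinucleotide windows of a sequence, as a plain dict of 2-mers."""
    out: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        out[d] = out.get(d, 0) + 1
    return out
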