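"""Independent brute-force oracles used to pin the implementations.

Everything here is deliberately written from first principles (manual loops,
exact rational enumeration) and shares no code with the package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def oracle_scan_pg4(seq: str) -> list[tuple[int, int]]:
    """Brute-force canonical pG4 search.

    Enumerates all maximal G-runs >= 3 by manual iteration, then all
    4-tuples of consecutive runs with every inter-run gap in [1, 7], and
    applies the leftmost non-overlapping greedy policy. Returns (start, end)
    spans.
    """
    s = seq.upper()
    runs = []
    i = 0
    while i < len(s):
        if s[i] == "G":
            j = i
            while j < len(s) and s[j] == "G":
                j += 1
            if j - i >= 3:
                runs.append((i, j))
            i = j
        else:
            i += 1
    candidates = []
    for a in range(len(runs) - 3):
        quad = runs[a : a + 4]
        if all(1 <= quad[k + 1][0] - quad[k][1] <= 7 for k in range(3)):
            candidates.append((a, quad[0][0], quad[3][1]))
    chosen = []
    next_free = 0
    for a, s0, e0 in candidates:
        if a >= next_free:
            chosen.append((s0, e0))
            next_free = a + 4
    return chosen


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    if k < max(0, n - (N - K)) or k > min(K, n):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def fisher_two_sided_exact(table) -> float:
    """Two-sided Fisher p by exact enumeration of all tables with the
    observed margins (sum of probabilities <= the observed table's)."""
    (a, b), (c, d) = table
    r1, c1, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf_exact(a, N, c1, r1)
    total = Fraction(0)
    for x in range(max(0, r1 - (N - c1)), min(r1, c1) + 1):
        px = hypergeom_pmf_exact(x, N, c1, r1)
        if px <= p_obs:
            total += px
    return float(total)


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct tail summation."""
    return float(sum(hypergeom_pmf_exact(x, N, K, n) for x in range(k, min(K, n) + 1)))


def enumerate_label_assignments(n_isoforms: list[int], k_total: int):
    """All assignments of ``k_total`` pG4 labels to pooled transcripts with
    every gene getting >= 1, as per-gene count vectors with multiplicity.

    Yields (counts tuple, number of transcript-level assignments realising it).
    """
    transcripts = [(g, i) for g, n in enumerate(n_isoforms) for i in range(n)]
    from collections import Counter

    tally: Counter = Counter()
    for subset in combinations(range(len(transcripts)), k_total):
        counts = [0] * len(n_isoforms)
        for t in subset:
            counts[transcripts[t][0]] += 1
        if all(c >= 1 for c in counts):
            tally[tuple(counts)] += 1
    return dict(tally)


def alt_const_ratio_oracle(counts, totals) -> float:
    n_const = sum(1 for k, n in zip(counts, totals) if k == n)
    n_alt = sum(1 for k, n in zip(counts, totals) if 1 <= k < n)
    if n_const == 0:
        return float("inf") if n_alt else 0.0
    return n_alt / n_const


def exact_permutation_p(n_isoforms: list[int], k_obs: list[int]) -> float:
    """P(ratio >= observed) under the uniform constrained-assignment null."""
    tally = enumerate_label_assignments(n_isoforms, sum(k_obs))
    obs = alt_const_ratio_oracle(k_obs, n_isoforms)
    total = sum(tally.values())
    ge = sum(m for counts, m in tally.items()
             if alt_const_ratio_oracle(counts, n_isoforms) >= obs)
    return ge / total


def betabinom_logpmf_reference(k, n, rho, phi):
    """Alpha/beta-form beta-binomial log-pmf via scipy (moderate dispersion)."""
    from scipy.stats import betabinom

    a = rho * (1 - phi) / phi
    b = (1 - rho) * (1 - phi) / phi
    return betabinom.logpmf(k, n, a, b)
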