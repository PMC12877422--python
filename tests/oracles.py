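"""Independent reference implementations used only by the test suite.

Everything here is deliberately written from first principles (plain-Python
dynamic programming, exhaustive enumeration, hand pair-counting) and shares
no code with the package, so agreement between the two is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Alignment references
# ---------------------------------------------------------------------------


def _scorer(matrix_name: str = "BLOSUM62"):
    sub = substitution_matrices.load(matrix_name)
    alphabet = sub.alphabet

    def s(a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        return float(sub[alphabet.index(a), alphabet.index(b)])

    return s


def gotoh_global_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal global affine-gap score; a gap of length k costs open + k*extend.

    Terminal gaps are penalized like internal ones (true Needleman-Wunsch).
    """
    s = _scorer()
    first = gap_open + gap_extend  # cost of the first gap residue
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = s(a[i - 1], b[j - 1]) + diag
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
    return max(M[n][m], X[n][m], Y[n][m])


def smith_waterman_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal local affine-gap score (>= 0)."""
    s = _scorer()
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = s(a[i - 1], b[j - 1]) + diag
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def _chains(n: int, m: int):
    """All monotone chains of aligned index pairs in an n x m grid."""

    def extend(chain, i0, j0):
        yield chain
        for i in range(i0, n):
            for j in range(j0, m):
                yield from extend(chain + [(i, j)], i + 1, j + 1)

    yield from extend([], 0, 0)


def enumerate_optimal_stats(
    a: str, b: str, mode: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> tuple[float, set[tuple[int, int]]]:
    """Exhaustively enumerate alignments of tiny sequences.

    An alignment is identified by its chain of aligned residue pairs; for a
    fixed chain the cheapest gap arrangement puts one gap run per unaligned
    stretch.  Returns the optimal score and the set of
    (matches, aligned_columns) values realized by optimal alignments, where
    columns span first to last aligned pair (terminal gaps excluded).
    """
    s = _scorer()

    def gap_cost(k: int) -> float:
        return 0.0 if k == 0 else gap_open + k * gap_extend

    n, m = len(a), len(b)
    best_score = NEG_INF
    best_stats: set[tuple[int, int]] = set()
    for chain in _chains(n, m):
        if not chain:
            if mode == "local":
                score = 0.0
            else:  # both sequences fully gapped
                score = -(gap_cost(n) + gap_cost(m))
            stats = (0, 0)
        else:
            score = sum(s(a[i], b[j]) for i, j in chain)
            for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
                score -= gap_cost(i2 - i1 - 1) + gap_cost(j2 - j1 - 1)
            if mode == "global":
                lead_a, lead_b = chain[0]
                trail_a = n - 1 - chain[-1][0]
                trail_b = m - 1 - chain[-1][1]
                score -= (gap_cost(lead_a) + gap_cost(lead_b)
                          + gap_cost(trail_a) + gap_cost(trail_b))
            matches = sum(a[i] == b[j] for i, j in chain)
            a_span = chain[-1][0] - chain[0][0] + 1
            b_span = chain[-1][1] - chain[0][1] + 1
            columns = a_span + b_span - len(chain)
            stats = (matches, columns)
        if score > best_score + 1e-9:
            best_score = score
            best_stats = {stats}
        elif abs(score - best_score) <= 1e-9:
            best_stats.add(stats)
    return best_score, best_stats


# ---------------------------------------------------------------------------
# Partition agreement references
# ---------------------------------------------------------------------------


def pair_counting_ari(labels_a: list, labels_b: list) -> float:
    """Hubert-Arabie ARI by explicit enumeration of all element pairs."""
    n = len(labels_a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:  # degenerate: both trivial partitions
        return 1.0 if n10 == n01 == 0 else 0.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def entropy_nmi(labels_a: list, labels_b: list) -> float:
    """NMI normalized by the arithmetic mean of the two entropies."""
    n = len(labels_a)
    ca, cb = Counter(labels_a), Counter(labels_b)
    cab = Counter(zip(labels_a, labels_b))
    h_a = -sum(c / n * math.log(c / n) for c in ca.values())
    h_b = -sum(c / n * math.log(c / n) for c in cb.values())
    mi = 0.0
    for (la, lb), c in cab.items():
        p = c / n
        mi += p * math.log(p / (ca[la] / n * cb[lb] / n))
    if h_a + h_b == 0:
        return 1.0
    return mi / ((h_a + h_b) / 2)


def set_partitions(items: list):
    """All set partitions (as label lists) of ``items``."""
    if not items:
        yield []
        return
    if len(items) == 1:
        yield [0]
        return
    for sub in set_partitions(items[1:]):
        k = max(sub) + 1 if sub else 0
        for label in range(k + 1):
            yield [label] + sub


# ---------------------------------------------------------------------------
# Multiple testing reference
# ---------------------------------------------------------------------------


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up rule, computed by hand."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        q = min(1.0, p_values[i] * n / rank_from_top)
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return adjusted
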