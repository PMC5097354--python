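"""Independent brute-force oracles used by the tests.

Deliberately naive implementations: the full O(nm) Levenshtein table and
exhaustive enumeration over every possible corrupted index read.  They
share no code with the package paths they check.
"""

from __future__ import annotations

import itertools


def levenshtein_dp(a: str, b: str) -> int:
    """Unbanded dynamic-programming Levenshtein distance, unit costs.

    ``N`` mismatches everything, including ``N``.
    """
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (0 if match else 1),
            )
        prev = cur
    return prev[m]


def enumerate_misassignment_rate(
    p: float, true_index: str, wrong_index: str, k: int, condition_on_true_reject: bool = True
) -> float:
    """Exhaustive-enumeration probability that a read of ``true_index`` is
    accepted as ``wrong_index``.

    Sums, over all 4^L possible observed reads, the emission probability
    under independent per-base substitution (probability ``p``, uniform
    over the 3 alternatives) of reads within ``k`` mismatches of the wrong
    index (and, by default, more than ``k`` from the true index, mirroring
    unique-match acceptance).
    """
    assert len(true_index) == len(wrong_index)
    total = 0.0
    for obs in itertools.product("ACGT", repeat=len(true_index)):
        prob = 1.0
        for o, a in zip(obs, true_index):
            prob *= (1.0 - p) if o == a else p / 3.0
        d_wrong = sum(o != b for o, b in zip(obs, wrong_index))
        if d_wrong > k:
            continue
        if condition_on_true_reject:
            d_true = sum(o != a for o, a in zip(obs, true_index))
            if d_true <= k:
                continue
        total += prob
    return total


def index_at_distance(length: int, d: int) -> tuple[str, str]:
    """A canonical pair of equal-length indices at Hamming distance d."""
    a = "A" * length
    b = "C" * d + "A" * (length - d)
    return a, b
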