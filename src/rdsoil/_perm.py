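"""Shared label-permutation machinery for matrix-based group tests.

Null distributions permute group labels over samples with group sizes held
fixed.  Arrangements are counted as distinct orderings of the label multiset
(multinomial coefficient); duplicate orderings are not recounted.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterator, Sequence

DEFAULT_EXHAUSTIVE_CAP = 20_000


def n_distinct_arrangements(labels: Sequence) -> int:
    """Multinomial coefficient: distinct orderings of the label multiset."""
    counts = Counter(labels)
    total = math.factorial(sum(counts.values()))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def iter_distinct_arrangements(labels: Sequence) -> Iterator[tuple]:
    """Yield every distinct ordering of ``labels`` exactly once.

    Lexicographic next-permutation walk; the identity arrangement is one of
    the yielded orderings.
    """
    arr = sorted(labels)
    n = len(arr)
    while True:
        yield tuple(arr)
        i = n - 2
        while i >= 0 and not arr[i] < arr[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while not arr[i] < arr[j]:
            j -= 1
        arr[i], arr[j] = arr[j], arr[i]
        arr[i + 1 :] = reversed(arr[i + 1 :])
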