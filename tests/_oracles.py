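"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately reimplement, from first principles, the quantities
the package computes with faster or more structured algorithms.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Dict, List, Optional, Tuple


def brute_force_splits(contig: str, left_flank: str, right_flank: str) -> Optional[Tuple[int, int]]:
    """Try every split of contig into L + I + R.

    Requires flanks sized to the contig (each flank 2F with the breakend
    at the center and the contig carrying F retained bases per side, as
    the simulator renders them), so the contig's left end aligns with
    the left flank's start and its right end with the right flank's end.
    A split (i, j) with i <= j is valid when contig[:i] matches the left
    flank and contig[j:] the right flank at those aligned positions.
    Microhomology = number of valid empty-insertion splits - 1;
    insertion = |I| at the maximal-|L|+|R| split (ties toward smaller
    insertion).  Returns None when no split is valid.
    """
    n = len(contig)
    valid_i = [i for i in range(n + 1) if contig[:i] == left_flank[:i]]
    valid_j = [
        j
        for j in range(n + 1)
        if (n - j) <= len(right_flank) and contig[j:] == right_flank[len(right_flank) - (n - j):]
    ]
    if not valid_i or not valid_j:
        return None
    valid_j_set = set(valid_j)
    blunt = [i for i in valid_i if i in valid_j_set]
    if blunt:
        return (len(blunt) - 1, 0)
    best: Optional[Tuple[int, int]] = None
    best_score = -1
    for i in valid_i:
        k = bisect_left(valid_j, i)
        if k == len(valid_j):
            continue
        j = valid_j[k]
        score = i + (n - j)
        if score > best_score or (
            score == best_score and best is not None and (j - i) < (best[1] - best[0])
        ):
            best, best_score = (i, j), score
    if best is None:
        return None
    return (0, best[1] - best[0])


def brute_force_unique(calls_by_clone, parental_calls, threshold: float = 0.70) -> Dict[tuple, bool]:
    """O(n^2) uniqueness: a call is unique iff no comparator from another
    clone (or the parental line) covers it and is covered by it at
    ``threshold`` or more."""
    verdicts: Dict[tuple, bool] = {}
    for clone, calls in calls_by_clone.items():
        comparators = [
            c for other, cs in calls_by_clone.items() if other != clone for c in cs
        ]
        comparators += list(parental_calls)
        for c in calls:
            unique = True
            for o in comparators:
                if c.interval.chrom != o.interval.chrom:
                    continue
                ov = max(
                    0,
                    min(c.interval.end, o.interval.end)
                    - max(c.interval.start, o.interval.start),
                )
                if ov == 0:
                    continue
                if ov / c.interval.length >= threshold and ov / o.interval.length >= threshold:
                    unique = False
                    break
            verdicts[(clone, c.interval.chrom, c.interval.start, c.interval.end)] = unique
    return verdicts
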