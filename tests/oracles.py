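"""Independent brute-force oracles for the alignment scorers.

These enumerate *every* monotone alignment path (with affine gap states)
recursively instead of filling a DP table, so they share no machinery with
the implementation they check. Feasible only for tiny sequences.

Gap convention matches the package: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations


def enumerate_global_scores(a, b, sub, gap_open, gap_extend):
    """Yield the score of every global alignment of ``a`` and ``b``.

    ``a``/``b`` are index sequences, ``sub`` a nested mapping/array.
    ``last`` tracks the previous move so gap openings are charged once.
    """

    def rec(i, j, last):
        if i == len(a) and j == len(b):
            yield 0
            return
        if i < len(a) and j < len(b):
            s = sub[a[i]][b[j]]
            for rest in rec(i + 1, j + 1, "M"):
                yield s + rest
        if i < len(a):  # gap in b, consuming a
            cost = gap_extend + (gap_open if last != "A" else 0)
            for rest in rec(i + 1, j, "A"):
                yield cost + rest
        if j < len(b):  # gap in a, consuming b
            cost = gap_extend + (gap_open if last != "B" else 0)
            for rest in rec(i, j + 1, "B"):
                yield cost + rest

    yield from rec(0, 0, None)


def brute_global(a, b, sub, gap_open, gap_extend):
    """Optimal global affine score by exhaustive enumeration."""
    return max(enumerate_global_scores(a, b, sub, gap_open, gap_extend))


def brute_local(a, b, sub, gap_open, gap_extend):
    """Optimal local affine score: best global score over all substring
    pairs, floored at 0 (the empty alignment)."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    score = brute_global(
                        a[i0:i1], b[j0:j1], sub, gap_open, gap_extend
                    )
                    if score > best:
                        best = score
    return best
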