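"""Independent brute-force oracles for the founder-sampling probabilities.

A mutation with ``B`` bottlenecks above it experiences ``B + 1`` uniform
founder draws among ``m`` ASC lineages (``B`` lateral, then one terminal).
These oracles enumerate the outcome space exhaustively with exact rational
arithmetic and are deliberately independent of the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product


def enumerate_success_patterns(m: int, b: int):
    """Exhaustive enumeration over the m**(B+1) founder-index tuples,
    grouped by success pattern with exact multiplicities.

    A draw succeeds when the mutant lineage's index is chosen (1 of m ways);
    it fails in the other m - 1 ways, so a pattern with ``a`` successes and
    ``f`` failures covers exactly ``(m-1)**f`` founder tuples.

    Returns exact Fractions ``(q, p_det, expected_tips)``.
    """
    q = p = tips = Fraction(0)
    total = 0
    for pattern in product((0, 1), repeat=b + 1):
        fails = (b + 1) - sum(pattern)
        count = (m - 1) ** fails  # tuples realizing this pattern
        total += count
        lateral, terminal = pattern[:b], pattern[b]
        if any(lateral):
            q += count
        if any(pattern):
            p += count
        # lateral subtree at draw j holds 2**(b-j) tips; terminal adds 1
        ntips = sum(2 ** (b - j) for j, hit in enumerate(lateral, start=1) if hit) + terminal
        tips += count * ntips
    assert total == m ** (b + 1)
    denom = Fraction(m ** (b + 1))
    return q / denom, p / denom, tips / denom


def enumerate_founder_tuples(m: int, b: int):
    """Literal enumeration over founder-index tuples (mutant is index 0).

    Feasible only for small ``m**(B+1)``; used as a cross-check of
    :func:`enumerate_success_patterns`.
    """
    q = p = tips = Fraction(0)
    n = 0
    for tup in product(range(m), repeat=b + 1):
        n += 1
        lateral, terminal = tup[:b], tup[b]
        if any(x == 0 for x in lateral):
            q += 1
        if any(x == 0 for x in tup):
            p += 1
        tips += sum(2 ** (b - j) for j, x in enumerate(lateral, start=1) if x == 0)
        tips += int(terminal == 0)
    denom = Fraction(n)
    return q / denom, p / denom, tips / denom
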