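"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results through the slowest, most transparent
route available (full dynamic programming, exhaustive graph closure) and
share no code with the package's own implementations.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def smith_waterman_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Full Gotoh local-alignment DP, affine gaps.

    A gap of length L costs gap_open + (L - 1) * gap_extend (the first gap
    position carries the open penalty).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def smith_waterman_both_strands(a: str, b: str, **kw) -> float:
    return max(smith_waterman_score(a, b, **kw), smith_waterman_score(a, rc(b), **kw))


def connected_components_bruteforce(
    nodes: list[str], edges: list[tuple[str, str]]
) -> list[set[str]]:
    """Exhaustive transitive closure: repeatedly merge sets sharing an edge."""
    comps = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            cu = next(c for c in comps if u in c)
            cv = next(c for c in comps if v in c)
            if cu is not cv:
                comps.remove(cv)
                cu |= cv
                changed = True
    return sorted(comps, key=lambda c: min(c))


def shannon_direct(counts: list[float]) -> float:
    """-sum p ln p computed longhand."""
    import math

    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h
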