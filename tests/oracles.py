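"""Independent brute-force oracles used by the test suite.

Each oracle is written as plainly as possible and stays independent of the
implementation path it checks.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb


def binomial_two_sided_p(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-sided conditional-binomial p by direct tail enumeration."""
    n = x + y
    if n == 0:
        return 1.0
    q = Fraction(n2, n1 + n2)
    pmf = [comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    return min(1.0, float(2 * min(lower, upper)))


def binomial_tail_table(n: int, q: Fraction):
    """Exact pmf prefix sums of Binomial(n, q) for sweeping all (x, y) with x+y=n."""
    pmf = [Fraction(0)] * (n + 1)
    pmf[0] = (1 - q) ** n
    ratio = q / (1 - q)
    for k in range(n):
        pmf[k + 1] = pmf[k] * (n - k) * ratio / (k + 1)
    lower = [Fraction(0)] * (n + 1)
    acc = Fraction(0)
    for k in range(n + 1):
        acc += pmf[k]
        lower[k] = acc
    upper = [Fraction(0)] * (n + 1)
    acc = Fraction(0)
    for k in range(n, -1, -1):
        acc += pmf[k]
        upper[k] = acc
    return lower, upper


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for hypergeometric(N, K, n) by direct enumeration."""
    total = comb(N, n)
    s = Fraction(0)
    for i in range(k, min(K, n) + 1):
        s += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(s)


def bh_stepup(pvalues):
    """Hand Benjamini-Hochberg step-up, quadratic and explicit."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        best = min(
            pvalues[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)
        )
        q[i] = min(1.0, best)
    return q


def coverage_runs(depth, min_depth):
    """Per-base linear scan for maximal runs of depth >= min_depth."""
    runs = []
    start = None
    for i, d in enumerate(depth):
        if d >= min_depth and start is None:
            start = i
        elif d < min_depth and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    return runs


def cigar_reference_positions(pos: int, cigar: str):
    """Character-by-character CIGAR walk listing covered reference positions.

    M/=/X/D positions count as covered (deletions stay inside a block);
    N skips reference; I/S/H/P consume none.
    """
    covered = []
    cur = pos
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch in "M=XD":
            for _ in range(length):
                covered.append(cur)
                cur += 1
        elif ch == "N":
            cur += length
        elif ch in "ISHP":
            pass
        else:
            raise ValueError(ch)
    return covered


def positions_to_runs(positions):
    runs = []
    start = prev = None
    for p in positions:
        if start is None:
            start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            runs.append((start, prev + 1))
            start = prev = p
    if start is not None:
        runs.append((start, prev + 1))
    return runs


def mirna_match_oracle(tag: str, db: dict[str, str], max_mismatch: int = 2,
                       max_shift: int = 2):
    """Plain scan: best mature matches for a tag under substitutions + shift."""
    best_d = None
    best = []
    for mid, mat in db.items():
        a, b = tag.upper().replace("U", "T"), mat.upper().replace("U", "T")
        if abs(len(a) - len(b)) > max_shift:
            continue
        if len(a) > len(b):
            a, b = b, a
        d_here = None
        for off in range(min(max_shift, len(b) - len(a)) + 1):
            d = sum(1 for i in range(len(a)) if a[i] != b[off + i])
            if d_here is None or d < d_here:
                d_here = d
        if d_here is None or d_here > max_mismatch:
            continue
        if best_d is None or d_here < best_d:
            best_d, best = d_here, [mid]
        elif d_here == best_d:
            best.append(mid)
    return best_d, sorted(best)
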