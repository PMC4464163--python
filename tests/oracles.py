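"""Independent brute-force oracles used by the unit and acceptance tests."""

from fractions import Fraction
from math import comb

# same tie convention as the implementation (documented relative slack),
# evaluated here in exact rational arithmetic
TIE_SLACK = Fraction(1) + Fraction(1, 10**7)


def hypergeom_pmf_support(n: int, r: int, s: int) -> tuple[int, list[Fraction]]:
    """Exact pmf of the a-cell over its support; margins r (row) and s (col)."""
    lo, hi = max(0, r + s - n), min(r, s)
    denom = comb(n, s)
    pmf = [Fraction(comb(r, k) * comb(n - r, s - k), denom)
           for k in range(lo, hi + 1)]
    return lo, pmf

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Minimum-likelihood two-sided P by full enumeration in rationals."""
    n, r, s = a + b + c + d, a + b, a + c
    lo, pmf = hypergeom_pmf_support(n, r, s)
    threshold = pmf[a - lo] * TIE_SLACK
    return sum((q for q in pmf if q <= threshold), Fraction(0))
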