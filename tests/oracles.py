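"""Independent reference implementations used as test oracles.

These deliberately take different routes than the package code: the Wilson
bound is obtained by evaluating the continuity-corrected score equation at
p +/- 1/(2n), and diplotype concordance by exhaustive arrangement
enumeration.
"""

import itertools
import math

from pgxkit.cyp2d6 import Component, Diplotype, Haplotype


def wilson_cc_reference(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Continuity-corrected Wilson interval, textbook score-equation form."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - conf) / 2)

    def bound(p_adj: float, sign: int) -> float:
        centre = 2 * n * p_adj + z**2
        rad = z * math.sqrt(z**2 + 4 * n * p_adj * (1 - p_adj))
        return (centre + sign * rad) / (2 * (n + z**2))

    lo = 0.0 if x == 0 else bound((x - 0.5) / n, -1)
    hi = 1.0 if x == n else bound((x + 0.5) / n, +1)
    return max(0.0, lo), min(1.0, hi)


def brute_force_correct(call_alleles: list[str], cons_alleles: list[str]) -> bool:
    """Exhaustive arrangement enumeration: some ordering of the call's expanded
    alleles must align element-by-element with an ordering of the consensus."""
    if len(call_alleles) != len(cons_alleles):
        return False
    return any(list(p) == sorted(cons_alleles)
               for p in itertools.permutations(call_alleles))


def random_diplotype(rng, labels) -> Diplotype:
    """Random diplotype with 1-2 components per haplotype, 1-2 copies each."""
    def hap():
        k = rng.integers(1, 3)
        return Haplotype(tuple(
            Component(labels[rng.integers(len(labels))], int(rng.integers(1, 3)))
            for _ in range(k)))
    return Diplotype((hap(), hap()))
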