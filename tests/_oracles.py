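"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (exact rational arithmetic,
exhaustive enumeration) and shares no code path with the package.
"""

from fractions import Fraction
from itertools import combinations_with_replacement
from math import comb


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact HWE p-value by full enumeration with rational arithmetic.

    Conditional on the allele counts, the probability of observing ``het``
    heterozygotes among ``n`` diploids is

        P(het) = [ n! / (hom_a! het! hom_b!) * 2^het ] / [ (2n)! / (n_a! n_b!) ]

    The two-sided p sums P over all configurations with P <= P(observed).
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    denom = comb(2 * n, n_a)

    def prob(het: int) -> Fraction:
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        ways = (
            comb(n, hom_a) * comb(n - hom_a, het) * 2**het
        )  # multinomial n over (hom_a, het, hom_b)
        return Fraction(ways, denom)

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    p_obs = prob(n_ab)
    return sum(prob(h) for h in hets if prob(h) <= p_obs)


def hwe_genotype_probs(freqs) -> dict[tuple[int, int], float]:
    """HWE genotype distribution over unordered allele pairs."""
    out = {}
    for i, j in combinations_with_replacement(range(len(freqs)), 2):
        out[(i, j)] = (freqs[i] ** 2) if i == j else 2 * freqs[i] * freqs[j]
    return out


def pi_oracle(freqs) -> float:
    """P(two unrelated HWE individuals share a genotype), by enumeration."""
    return sum(f * f for f in hwe_genotype_probs(freqs).values())


def pisib_oracle(freqs) -> float:
    """P(two full sibs share a genotype): enumerate parents and transmissions."""
    genos = hwe_genotype_probs(freqs)
    total = 0.0
    for (f1, f2), pf in genos.items():
        for (m1, m2), pm in genos.items():
            # child genotype distribution given these parents
            child: dict[tuple[int, int], float] = {}
            for a in (f1, f2):
                for b in (m1, m2):
                    g = (min(a, b), max(a, b))
                    child[g] = child.get(g, 0.0) + 0.25
            total += pf * pm * sum(p * p for p in child.values())
    return total


def bh_oracle(pvals):
    """Step-up BH adjusted p-values, written from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
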