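"""Brute-force enumeration oracles for the identity statistics.

Kept separate from the package on purpose: these recompute the single-locus
match probabilities by exhaustive enumeration of genotype pairs (unrelated)
and of parental genotypes with Mendelian transmission (full sibs), sharing
no code with the closed-form implementations they check.
"""

from itertools import combinations_with_replacement

import numpy as np

from iisnp.identity_stats import pi_locus, pisib_locus


def _hwe_genotypes(freqs):
    out = {}
    for i, j in combinations_with_replacement(range(len(freqs)), 2):
        out[(i, j)] = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
    return out


def _pi_enum(freqs) -> float:
    return sum(f * f for f in _hwe_genotypes(freqs).values())


def _pisib_enum(freqs) -> float:
    genos = _hwe_genotypes(freqs)
    total = 0.0
    for (f1, f2), pf in genos.items():
        for (m1, m2), pm in genos.items():
            child: dict = {}
            for a in (f1, f2):
                for b in (m1, m2):
                    g = (min(a, b), max(a, b))
                    child[g] = child.get(g, 0.0) + 0.25
            total += pf * pm * sum(p * p for p in child.values())
    return total


def max_oracle_gap(n_vectors: int, seed: int) -> float:
    """Largest |closed form - enumeration| over random frequency vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        k = int(rng.integers(2, 5))
        w = rng.uniform(0.05, 1.0, size=k)
        freqs = w / w.sum()
        worst = max(worst, abs(pi_locus(freqs) - _pi_enum(freqs)))
        worst = max(worst, abs(pisib_locus(freqs) - _pisib_enum(freqs)))
    return worst
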