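"""Pairwise genotype r-squared and greedy LD pruning.

r-squared is the squared Pearson correlation of unphased alt-allele dosage
vectors (0/1/2) between two loci, computed over samples called at both —
the composite genotype correlation appropriate for unphased DNA/RNA calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from iisnp.genotype_io import GenotypeMatrix
from iisnp.locus_stats import LocusStats


@dataclass
class LdMatrix:
    """Upper-triangular pairwise r-squared over an ordered locus list.

    ``r2[i, j]`` (i < j) is NaN when undefined (zero dosage variance in
    the shared-call subset); ``n_used[i, j]`` counts samples called at
    both loci.
    """

    keys: list[tuple]
    r2: np.ndarray
    n_used: np.ndarray

    def pairs(self):
        """Yield (key_i, key_j, r2, n_used) for every unique pair."""
        L = len(self.keys)
        for i in range(L):
            for j in range(i + 1, L):
                yield self.keys[i], self.keys[j], self.r2[i, j], self.n_used[i, j]

    def to_table(self) -> str:
        lines = ["#locus_a\tlocus_b\tr2\tn_used"]
        for ka, kb, r2, n in self.pairs():
            lines.append(f"{_label(ka)}\t{_label(kb)}\t{r2:.6g}\t{n}")
        return "\n".join(lines) + "\n"


def _label(key) -> str:
    return ":".join(str(x) if not isinstance(x, tuple) else ",".join(x) for x in key)


def pairwise_r2(gm: GenotypeMatrix, loci=None) -> LdMatrix:
    """r-squared for all unique pairwise combinations of the given loci.

    Pairs where either dosage vector is constant among shared calls carry
    no linkage signal and get r2 = NaN (treated as 0 by the pruner).
    """
    keys = [loc.key for loc in gm.loci] if loci is None else list(loci)
    sub = gm.subset_loci(keys)
    d = sub.dosages()  # (n_samples, L), NaN where missing
    L = len(keys)
    r2 = np.full((L, L), np.nan)
    n_used = np.zeros((L, L), dtype=int)
    present = ~np.isnan(d)
    if present.all():
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(d, rowvar=False)
        r2[:] = c * c
        n_used[:] = d.shape[0]
    else:
        for i in range(L):
            for j in range(i + 1, L):
                m = present[:, i] & present[:, j]
                n = int(m.sum())
                n_used[i, j] = n_used[j, i] = n
                if n < 2:
                    continue
                x, y = d[m, i], d[m, j]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2[i, j] = r2[j, i] = r * r
    np.fill_diagonal(r2, np.nan)
    np.fill_diagonal(n_used, 0)
    return LdMatrix(keys, r2, n_used)


def prune_by_ld(
    ld: LdMatrix, stats: dict[tuple, LocusStats], threshold: float
) -> list[tuple]:
    """Greedy LD pruning: survivors have all pairwise r2 below ``threshold``.

    Pairs at or above the threshold are visited in descending r2 order;
    for each pair still intact, the less heterozygous locus is removed
    (ties: lower MAF, then lexicographically later key). Undefined r2
    counts as 0. Deterministic given the tie-break rules.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    flagged = [
        (ka, kb, r2)
        for ka, kb, r2, _ in ld.pairs()
        if np.isfinite(r2) and r2 >= threshold
    ]
    flagged.sort(key=lambda t: (-t[2], _label(t[0]), _label(t[1])))
    removed: set[tuple] = set()
    for ka, kb, _ in flagged:
        if ka in removed or kb in removed:
            continue
        removed.add(_pruning_loser(ka, kb, stats))
    return [k for k in ld.keys if k not in removed]


def _pruning_loser(ka: tuple, kb: tuple, stats: dict[tuple, LocusStats]) -> tuple:
    sa, sb = stats[ka], stats[kb]
    if (sa.ho, sa.maf) != (sb.ho, sb.maf):
        return ka if (sa.ho, sa.maf) < (sb.ho, sb.maf) else kb
    return max(ka, kb, key=_label)  # full tie: drop the later key
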