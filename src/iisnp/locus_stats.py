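"""Per-locus allele and genotype statistics.

Covers allele frequencies (AAF/MAF), call rate, observed/expected
heterozygosity, fixation index, the exact Hardy-Weinberg test conditional
on allele counts, Benjamini-Hochberg FDR adjustment, and AAF concordance
between two call sets.

All statistics use non-missing calls only; allele frequencies are obtained
by genotype counting (each diploid call contributes two alleles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from iisnp.genotype_io import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """A per-locus statistic is undefined (e.g. all calls missing)."""


@dataclass
class LocusStats:
    """Derived quantities for one locus.

    ``f`` (the fixation index (he - ho) / he) and the HWE p-value are NaN
    when undefined (monomorphic locus); ``hwe_q`` is filled in only after
    the whole table is FDR-adjusted.
    """

    key: tuple
    aaf: float
    maf: float
    call_rate: float
    n_genotype_classes: int
    n_alleles_observed: int
    ho: float
    he: float
    f: float
    hwe_p: float = np.nan
    hwe_q: float = np.nan


def _nonmissing(gt: np.ndarray) -> np.ndarray:
    gt = np.asarray(gt)
    return gt[gt[:, 0] != MISSING]


def allele_frequencies(gm: GenotypeMatrix, locus) -> tuple[float, float]:
    """Alternative and minor allele frequency at a locus.

    AAF counts all non-reference alleles over 2 x (non-missing calls);
    MAF is min(aaf, 1 - aaf). Missing calls are excluded from numerator
    and denominator.
    """
    gt = _nonmissing(gm.genotypes(locus))
    if len(gt) == 0:
        raise UndefinedStatisticError(f"locus {locus}: all calls missing")
    aaf = float((gt > 0).sum()) / (2 * len(gt))
    return aaf, min(aaf, 1.0 - aaf)


def call_rate(gm: GenotypeMatrix, locus) -> float:
    """Fraction of samples with a non-missing call at the locus."""
    gt = gm.genotypes(locus)
    return float((gt[:, 0] != MISSING).sum()) / len(gt)


def heterozygosities(gm: GenotypeMatrix, locus) -> tuple[float, float, float]:
    """Observed heterozygosity, expected heterozygosity and fixation index.

    ho = heterozygote fraction among non-missing calls; he = 1 - sum(p_i^2)
    over observed allele frequencies (2pq for a biallelic locus);
    f = (he - ho) / he, NaN when the locus is monomorphic (he == 0).
    """
    gt = _nonmissing(gm.genotypes(locus))
    if len(gt) == 0:
        raise UndefinedStatisticError(f"locus {locus}: all calls missing")
    ho = float((gt[:, 0] != gt[:, 1]).sum()) / len(gt)
    freqs = np.bincount(gt.ravel()) / (2 * len(gt))
    he = float(1.0 - (freqs**2).sum())
    f = (he - ho) / he if he > 0 else float("nan")
    return ho, he, f


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test on genotype counts of a biallelic locus.

    Conditions on the observed allele counts and enumerates every
    heterozygote count consistent with them; the two-sided p-value is the
    total conditional probability of configurations no more probable than
    the observed one (probability ordering). Returns p in (0, 1].
    """
    if n_aa < 0 or n_ab < 0 or n_bb < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype call required")
    n_a = 2 * n_aa + n_ab  # count of one allele; distribution is symmetric
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: single configuration
    hets = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    homa = (n_a - hets) // 2
    homb = (n_b - hets) // 2
    # log P(het | n_a, n) up to a shared constant: multinomial x 2^het
    logp = hets * np.log(2.0) - gammaln(homa + 1) - gammaln(hets + 1) - gammaln(homb + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_ab)[0][0]]
    # tolerance absorbs float ties between equiprobable configurations
    pval = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(pval, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aaf_concordance(aaf_a, aaf_b) -> tuple[float, float]:
    """Pearson correlation (and its square) between two matched AAF vectors."""
    a = np.asarray(aaf_a, dtype=float)
    b = np.asarray(aaf_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("AAF vectors must be matched and of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("zero variance in an AAF vector")
    r = float(pearsonr(a, b).statistic)
    return r, r * r


def compute_locus_stats(
    gm: GenotypeMatrix, loci=None, with_hwe: bool = True
) -> dict[tuple, LocusStats]:
    """Full per-locus statistics table for a matrix (or a locus subset).

    The HWE exact test is computed for biallelic-looking loci (at most two
    observed alleles); q-values are BH-adjusted across all tested loci.
    """
    keys = [loc.key for loc in gm.loci] if loci is None else list(loci)
    out: dict[tuple, LocusStats] = {}
    tested: list[tuple] = []
    pvals: list[float] = []
    for key in keys:
        gt = _nonmissing(gm.genotypes(key))
        cr = call_rate(gm, key)
        if len(gt) == 0:
            out[key] = LocusStats(key, np.nan, np.nan, cr, 0, 0, np.nan, np.nan, np.nan)
            continue
        aaf, maf = allele_frequencies(gm, key)
        ho, he, f = heterozygosities(gm, key)
        observed_alleles = np.unique(gt.ravel())
        n_classes = len({(a, b) for a, b in map(tuple, gt)})
        st = LocusStats(key, aaf, maf, cr, n_classes, len(observed_alleles), ho, he, f)
        if with_hwe and len(observed_alleles) <= 2:
            hi = observed_alleles.max()
            n_bb = int(((gt[:, 0] == hi) & (gt[:, 1] == hi)).sum())
            n_het = int((gt[:, 0] != gt[:, 1]).sum())
            st.hwe_p = hwe_exact_test(len(gt) - n_het - n_bb, n_het, n_bb)
            tested.append(key)
            pvals.append(st.hwe_p)
        out[key] = st
    if pvals:
        for key, q in zip(tested, bh_adjust(pvals)):
            out[key].hwe_q = float(q)
    return out


def stats_table(stats: dict[tuple, LocusStats]) -> str:
    """Tab-separated per-locus statistics table with a '#' header line."""
    cols = [
        "locus",
        "aaf",
        "maf",
        "call_rate",
        "n_genotype_classes",
        "n_alleles_observed",
        "ho",
        "he",
        "f",
        "hwe_p",
        "hwe_q",
    ]
    lines = ["#" + "\t".join(cols)]
    for key, st in stats.items():
        label = ":".join(str(x) if not isinstance(x, tuple) else ",".join(x) for x in key)
        lines.append(
            "\t".join(
                [label]
                + [
                    f"{v:.6g}" if isinstance(v, float) else str(v)
                    for v in (
                        st.aaf,
                        st.maf,
                        st.call_rate,
                        st.n_genotype_classes,
                        st.n_alleles_observed,
                        st.ho,
                        st.he,
                        st.f,
                        st.hwe_p,
                        st.hwe_q,
                    )
                ]
            )
        )
    return "\n".join(lines) + "\n"
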