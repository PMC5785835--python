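"""Probability of identity (PI) for unrelated individuals and full sibs.

PI at one locus is the probability that two unrelated individuals drawn
from a randomly mating population carry the same genotype: the sum over
genotypes of squared Hardy-Weinberg genotype frequencies,

    PI = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2.

For full sibs the match probability is the standard Evett-Weir form

    PIsib = 1/4 + (1/2) s2 + (1/2) s2^2 - (1/4) s4,

with s2 = sum p_i^2 and s4 = sum p_i^4. Multilocus values are products
across loci (independence is what the LD filter buys), accumulated in log
space to avoid underflow at panel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FREQ_TOL = 1e-9


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0 or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in (0, 1]")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"allele frequencies sum to {p.sum()!r}, not 1")
    return p


def pi_locus(freqs) -> float:
    """Single-locus probability of identity for unrelated individuals."""
    p = _check_freqs(freqs)
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    # sum_g f_g^2 over HWE genotype frequencies: homozygotes + heterozygotes
    return s4 + 2 * (s2**2 - s4)  # = 2*s2^2 - s4


def pisib_locus(freqs) -> float:
    """Single-locus match probability for full siblings (always >= PI)."""
    p = _check_freqs(freqs)
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


def multilocus_pi(per_locus) -> tuple[float, float]:
    """Product of per-locus identity probabilities: (linear, log10).

    Computed in log space; the linear value underflows to 0.0 only below
    ~1e-308, far beyond any realistic panel.
    """
    p = np.asarray(per_locus, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one per-locus probability")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("per-locus probabilities must lie in (0, 1]")
    log10 = float(np.log10(p).sum())
    return float(10.0**log10), log10


def cumulative_pi_curve(per_locus, order: str = "informative") -> np.ndarray:
    """Cumulative PI products for k = 1..L loci.

    ``order``: 'informative' sorts ascending per-locus PI (most
    discriminating first, the natural panel-accumulation order);
    'given' keeps the input order.
    """
    p = np.asarray(per_locus, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one per-locus probability")
    if order == "informative":
        p = np.sort(p)
    elif order != "given":
        raise ValueError(f"unknown ordering {order!r}")
    return np.exp(np.cumsum(np.log(p)))


@dataclass
class UniquenessResult:
    """Smallest panel prefix achieving uniqueness in a cohort of size n."""

    k: int | None
    threshold: float
    expected_collisions_at_k: float
    achieved: bool


def min_snps_for_uniqueness(cumulative, n_samples: int) -> UniquenessResult:
    """Minimum number of loci for uniqueness among ``n_samples`` individuals.

    Uniqueness criterion: the expected number of identical-genotype pairs,
    C(n, 2) * PI_k, drops below 1, i.e. cumulative PI < 1 / C(n, 2).
    """
    if n_samples < 2:
        raise ValueError("need a cohort of at least 2 samples")
    c = np.asarray(cumulative, dtype=float)
    if np.any(np.diff(c) > 1e-15):
        raise ValueError("cumulative PI must be non-increasing")
    n_pairs = n_samples * (n_samples - 1) / 2
    thr = 1.0 / n_pairs
    below = np.nonzero(c < thr)[0]
    if below.size == 0:
        return UniquenessResult(None, thr, float(c[-1] * n_pairs), False)
    k = int(below[0]) + 1
    return UniquenessResult(k, thr, float(c[k - 1] * n_pairs), True)


@dataclass
class IdentityReport:
    """Per-locus and cumulative identity statistics for a panel."""

    keys: list[tuple]
    freqs: list[np.ndarray]
    pi: np.ndarray
    pisib: np.ndarray
    order: np.ndarray  # indices into keys, accumulation order
    cumulative_pi: np.ndarray
    cumulative_pisib: np.ndarray
    multilocus_pi: float = field(init=False)
    multilocus_pisib: float = field(init=False)
    log10_pi: float = field(init=False)
    log10_pisib: float = field(init=False)
    uniqueness: UniquenessResult | None = None

    def __post_init__(self):
        self.multilocus_pi, self.log10_pi = multilocus_pi(self.pi)
        self.multilocus_pisib, self.log10_pisib = multilocus_pi(self.pisib)

    def to_table(self) -> str:
        lines = ["#rank\tlocus\tpi\tpisib\tcumulative_pi\tcumulative_pisib"]
        for rank, idx in enumerate(self.order):
            key = self.keys[idx]
            label = ":".join(
                str(x) if not isinstance(x, tuple) else ",".join(x) for x in key
            )
            lines.append(
                f"{rank + 1}\t{label}\t{self.pi[idx]:.6g}\t{self.pisib[idx]:.6g}"
                f"\t{self.cumulative_pi[rank]:.6g}\t{self.cumulative_pisib[rank]:.6g}"
            )
        return "\n".join(lines) + "\n"


def identity_report(
    gm, panel=None, n_samples: int | None = None
) -> IdentityReport:
    """Identity statistics for a panel using a matrix's allele frequencies.

    Frequencies are estimated from observed alleles at each panel locus.
    Loci are accumulated most-informative-first (ascending per-locus PI).
    When ``n_samples`` is given the uniqueness panel size is evaluated for
    a cohort of that size (default: the matrix's own sample count).
    """
    from iisnp.genotype_io import MISSING

    keys = [loc.key for loc in gm.loci] if panel is None else list(panel)
    freqs, pis, pisibs = [], [], []
    for key in keys:
        gt = gm.genotypes(key)
        alleles = gt[gt != MISSING]
        if alleles.size == 0:
            raise ValueError(f"locus {key}: all calls missing")
        p = np.bincount(alleles) / alleles.size
        p = p[p > 0]
        freqs.append(p)
        pis.append(pi_locus(p))
        pisibs.append(pisib_locus(p))
    pi = np.array(pis)
    pisib = np.array(pisibs)
    order = np.argsort(pi, kind="stable")
    cum_pi = np.exp(np.cumsum(np.log(pi[order])))
    cum_sib = np.exp(np.cumsum(np.log(pisib[order])))
    n = n_samples if n_samples is not None else gm.n_samples
    uniq = min_snps_for_uniqueness(cum_pi, n) if n >= 2 else None
    return IdentityReport(keys, freqs, pi, pisib, order, cum_pi, cum_sib, uniqueness=uniq)
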