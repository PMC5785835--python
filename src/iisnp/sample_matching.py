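"""Sample mix-up detection via allele-concordance matching.

For each query (RNA) sample and each reference (DNA/GWAS) sample, the
allele concordance score over the panel loci is the number of shared
alleles divided by the total number of compared alleles (2 per locus; 100
alleles for a complete 50-SNP panel). Shared alleles at one locus are the
multiset intersection of the two unordered allele pairs: AA/AA -> 2,
AA/AB -> 1, AB/AB -> 2, AA/BB -> 0. Loci where either call is missing are
excluded from numerator and denominator.

A query passes when its best-scoring references (at or above the score
threshold, 0.8 by default) include the expected reference from the sample
map; it fails when the best hits exclude every expected reference; it is
unsure when no reference reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from iisnp.genotype_io import MISSING, GenotypeMatrix, SampleMap


class MatchCategory(str, Enum):
    PASSED = "PASSED_MATCHING"
    FAILED = "FAILED_MATCHING"
    UNSURE = "UNSURE"


@dataclass
class ConcordanceScore:
    """Allele concordance between one query and one reference sample."""

    pair: tuple[str, str]
    shared_alleles: int
    total_alleles: int
    loci_compared: int
    identical_genotypes: int
    score: float

    def __post_init__(self):
        if not (self.shared_alleles <= self.total_alleles):
            raise ValueError("shared alleles exceed total alleles")


def _pair_stats(q: np.ndarray, r: np.ndarray) -> tuple[int, int, int]:
    """(shared alleles, loci compared, identical genotypes) for two call vectors.

    ``q`` and ``r`` have shape (L, 2) with allele indices sorted within
    each pair, MISSING for no-calls.
    """
    ok = (q[:, 0] != MISSING) & (r[:, 0] != MISSING)
    qa, ra = q[ok], r[ok]
    # multiset intersection of two sorted pairs = best of the two matchings
    m1 = (qa[:, 0] == ra[:, 0]).astype(np.int8) + (qa[:, 1] == ra[:, 1])
    m2 = (qa[:, 0] == ra[:, 1]).astype(np.int8) + (qa[:, 1] == ra[:, 0])
    shared = np.maximum(m1, m2)
    return int(shared.sum()), int(ok.sum()), int((shared == 2).sum())


def concordance_score(q: np.ndarray, r: np.ndarray, pair=("query", "ref")) -> ConcordanceScore:
    """Allele concordance score between two genotype vectors over a panel.

    Raises ``ValueError`` when no locus is comparable (score undefined;
    such queries are categorized UNSURE downstream).
    """
    q = np.asarray(q)
    r = np.asarray(r)
    if q.shape != r.shape:
        raise ValueError("genotype vectors must cover the same panel loci")
    shared, n_loci, identical = _pair_stats(q, r)
    if n_loci == 0:
        raise ValueError("no comparable loci (all calls missing)")
    return ConcordanceScore(
        pair=tuple(pair),
        shared_alleles=shared,
        total_alleles=2 * n_loci,
        loci_compared=n_loci,
        identical_genotypes=identical,
        score=shared / (2 * n_loci),
    )


def _score_matrix(
    queries: GenotypeMatrix, refs: GenotypeMatrix, panel
) -> tuple[np.ndarray, np.ndarray]:
    """All query x reference scores and identical-genotype counts.

    Returns (scores, identical) with NaN/-1 where no locus is comparable.
    """
    qm = queries.subset_loci(panel).calls  # (nq, L, 2)
    rm = refs.subset_loci(panel).calls  # (nr, L, 2)
    nq, nr = qm.shape[0], rm.shape[0]
    scores = np.full((nq, nr), np.nan)
    identical = np.full((nq, nr), -1, dtype=int)
    q_ok = qm[:, :, 0] != MISSING
    r_ok = rm[:, :, 0] != MISSING
    for i in range(nq):  # vectorize over references per query
        ok = q_ok[i][None, :] & r_ok  # (nr, L)
        q0, q1 = qm[i, :, 0][None, :], qm[i, :, 1][None, :]
        m1 = (q0 == rm[:, :, 0]).astype(np.int8) + (q1 == rm[:, :, 1])
        m2 = (q0 == rm[:, :, 1]).astype(np.int8) + (q1 == rm[:, :, 0])
        shared = np.where(ok, np.maximum(m1, m2), 0)
        n_loci = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = shared.sum(axis=1) / (2 * n_loci)
        scores[i] = np.where(n_loci > 0, s, np.nan)
        identical[i] = np.where(n_loci > 0, ((shared == 2) & ok).sum(axis=1), -1)
    return scores, identical


@dataclass
class MatchReport:
    """Best-hit assignments and pass/fail categories for every query."""

    queries: list[str]
    references: list[str]
    threshold: float
    best_hits: dict[str, set[str]]
    best_scores: dict[str, float]
    categories: dict[str, MatchCategory]
    counts: dict[MatchCategory, int] = field(default_factory=dict)
    scores: np.ndarray | None = None

    def __post_init__(self):
        if not self.counts:
            self.counts = {c: 0 for c in MatchCategory}
            for cat in self.categories.values():
                self.counts[cat] += 1

    def to_table(self) -> str:
        lines = [
            f"#threshold\t{self.threshold}",
            "#query\tcategory\tbest_score\tbest_hits",
        ]
        for q in self.queries:
            hits = ",".join(sorted(self.best_hits[q])) or "."
            score = self.best_scores[q]
            stxt = f"{score:.4f}" if np.isfinite(score) else "NA"
            lines.append(f"{q}\t{self.categories[q].value}\t{stxt}\t{hits}")
        lines.append(
            "#counts\t"
            + "\t".join(f"{c.value}={self.counts[c]}" for c in MatchCategory)
        )
        return "\n".join(lines) + "\n"


def match_samples(
    queries: GenotypeMatrix,
    refs: GenotypeMatrix,
    panel,
    expected: SampleMap,
    threshold: float = 0.8,
    unmapped_policy: str = "fail",
    keep_scores: bool = False,
) -> MatchReport:
    """Assign each query its best-matching references and categorize.

    Best hits are all references attaining the maximum score, provided it
    reaches ``threshold`` (several hits are legitimate: repeated reference
    measurements of one person). Categories: PASSED when an expected
    reference is among the best hits, FAILED when best hits exist but
    exclude every expected reference, UNSURE when no reference reaches the
    threshold. ``unmapped_policy``: 'fail' treats any confident hit for an
    unmapped query as FAILED; 'report' leaves such queries UNSURE.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if unmapped_policy not in ("fail", "report"):
        raise ValueError("unmapped_policy must be 'fail' or 'report'")
    scores, _ = _score_matrix(queries, refs, panel)
    best_hits: dict[str, set[str]] = {}
    best_scores: dict[str, float] = {}
    categories: dict[str, MatchCategory] = {}
    for i, q in enumerate(queries.samples):
        row = scores[i]
        finite = np.isfinite(row)
        best = float(np.nanmax(row)) if finite.any() else float("nan")
        hits = (
            {refs.samples[j] for j in np.nonzero(finite & (row >= best - 1e-12))[0]}
            if np.isfinite(best) and best >= threshold
            else set()
        )
        best_hits[q] = hits
        best_scores[q] = best
        exp = expected.expected(q)
        if not hits:
            categories[q] = MatchCategory.UNSURE
        elif exp & hits:
            categories[q] = MatchCategory.PASSED
        elif not exp and unmapped_policy == "report":
            categories[q] = MatchCategory.UNSURE
        else:
            categories[q] = MatchCategory.FAILED
    return MatchReport(
        list(queries.samples),
        list(refs.samples),
        threshold,
        best_hits,
        best_scores,
        categories,
        scores=scores if keep_scores else None,
    )


@dataclass
class ConcordanceDistributions:
    """Identical-genotype counts for expected pairs vs random non-pairs."""

    matched: np.ndarray
    unmatched: np.ndarray
    separation_gap: float  # min matched - max unmatched; > 0 means disjoint

    @property
    def disjoint(self) -> bool:
        return self.separation_gap > 0


def concordance_distributions(
    queries: GenotypeMatrix,
    refs: GenotypeMatrix,
    panel,
    expected: SampleMap,
    n_random: int = 1000,
    seed: int = 0,
) -> ConcordanceDistributions:
    """Identical-genotype-count distributions for matched and random pairs.

    For each expected (query, reference) pair, counts panel loci with fully
    identical genotypes; random non-matching pairs are drawn uniformly with
    replacement from pairs not in the expected map.
    """
    if not expected.pairs:
        raise ValueError("expected sample map is empty")
    _, identical = _score_matrix(queries, refs, panel)
    qidx = {s: i for i, s in enumerate(queries.samples)}
    ridx = {s: j for j, s in enumerate(refs.samples)}
    expected_set = set()
    matched = []
    for q, r in expected.pairs:
        if q in qidx and r in ridx:
            expected_set.add((qidx[q], ridx[r]))
            matched.append(identical[qidx[q], ridx[r]])
    rng = np.random.default_rng(seed)
    unmatched = []
    while len(unmatched) < n_random:
        i = int(rng.integers(queries.n_samples))
        j = int(rng.integers(refs.n_samples))
        if (i, j) in expected_set:
            continue
        unmatched.append(identical[i, j])
    matched_arr = np.array(matched)
    unmatched_arr = np.array(unmatched)
    gap = float(matched_arr.min() - unmatched_arr.max())
    return ConcordanceDistributions(matched_arr, unmatched_arr, gap)
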