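# Methods

This note documents the statistical models, the defaults and the design
choices behind `iisnp`, and what the synthetic-data generator does and does
not emulate.

## Genotype model and representation

Genotypes are unphased diploid calls stored as sorted pairs of allele
indices (REF = 0). Phase carries no information for any statistic computed
here — allele frequencies, heterozygosity, the exact HWE test, genotype r²
and allele concordance are all functions of the unordered genotype — so it
is discarded at read time. Half-calls (`0/.`) are treated as fully missing:
a lone allele cannot enter a genotype count, and keeping it would make the
call-rate and concordance denominators inconsistent. Coordinates keep the
VCF convention (1-based, closed) end to end; no 0-based conversion exists
anywhere in the package.

Multi-allelic records are preserved at read time and removed by the
biallelic filter, never silently split or dropped by the parser.

## Per-locus statistics

* **AAF / MAF** by genotype counting: alt-allele count over 2 × non-missing
  calls; MAF = min(AAF, 1 − AAF). Missing calls leave both numerator and
  denominator.
* **Heterozygosity**: observed Ho = heterozygote fraction; expected
  He = 1 − Σpᵢ² from the observed allele frequencies. He is the plain
  (uncorrected) form; the small-sample factor n/(n−1) is deliberately not
  applied — at the cohort sizes this package targets (hundreds to
  thousands) the correction is below the sampling noise, and the
  uncorrected form keeps He comparable across loci with different call
  rates.
* **Fixation index** F = (He − Ho)/He, undefined (NaN, flagged, never a
  crash) for monomorphic loci.
* **Exact HWE test**: conditional on the observed allele counts, the
  heterozygote count has distribution
  P(h) ∝ n! / (n_A! h! n_B!) · 2ʰ (all configurations with the same allele
  counts). The two-sided p-value sums the probabilities of all
  configurations no more probable than the observed one. This is the
  field-standard exact test for HWE; it is implemented with log-gamma
  arithmetic and verified in the tests against an exhaustive
  rational-arithmetic enumeration for every genotype triple with n ≤ 30.
  The test is conservative: attainable p-values are discrete, so the null
  rejection rate sits at or below the nominal level (checked by simulation
  at α = 0.01 and 0.05).
* **FDR**: Benjamini–Hochberg step-up adjustment (via
  `statsmodels.stats.multitest`), applied across all loci tested in one
  cascade run.

## The filtering cascade

Stage order: RNA call rate > 0.9 → biallelic (≤ 2 observed alleles, ≤ 3
genotype classes, evaluated on the RNA calls where miscalls create phantom
alleles) → MAF > 0.2 in both matrices (each matrix's own frequencies, not
pooled) → DNA/RNA intersection (same chrom/pos/ref and overlapping ALT
sets; REF conflicts are excluded and reported, not strand-corrected) →
HWE → HLA exclusion → LD pruning. HWE and HLA are independent predicates,
so their order cannot change the final set. An empty survivor set at any
stage is a valid result, not an error.

**HWE retention rule.** The operative cut is the FDR: a locus is retained
when its BH-adjusted value is ≥ 1%. An additional raw-p cut (`hwe_raw_p`,
default off) is available for users who want a fixed per-locus α as well.
The FDR-only default is deliberate: with m ≈ 50–100 loci in the cascade, a
raw per-locus cut at α = 0.01 removes at least one genuinely
equilibrium locus in roughly 1 − 0.99^m ≈ 40% of cohorts, which would make
the filter's output unstable for no gain in power; BH at 1% FDR controls
exactly the quantity that matters here (the fraction of wrongly discarded
loci) while rejecting strong violators with essentially the same power.

**HWE matrix.** The test runs on the DNA genotypes by default
(`hwe_on="dna"`), because RNA-derived calls carry extra genotype error that
inflates apparent HWE departures; configurable to RNA.

**LD pruning.** r² is the squared Pearson correlation of alt-dosage
vectors over samples called at both loci (composite genotype correlation —
the right quantity for unphased calls; no haplotype phasing is attempted).
Pairs with undefined r² (a constant dosage vector) carry no linkage signal
and are treated as r² = 0. Pruning is greedy in descending r²: for each
flagged pair still intact, the less heterozygous locus is removed, with
deterministic tie-breaks (lower MAF, then the lexicographically later
key). Survivors are re-checked to have max pairwise r² below threshold.

A caution on the default threshold: r² < 0.01 is *very* strict. For truly
unlinked loci, n·r² is approximately χ²₁, so the threshold is only
meaningful when n·0.01 is far in the χ² tail — around n = 2000,
P(spurious flag) ≈ 8×10⁻⁶ per pair. At a few hundred samples the same
threshold prunes heavily by chance; users with small cohorts should raise
`ld_r2` accordingly (the CLI config makes this a one-line change).

**Panel size.** The panel is whatever survives; no "top 50" is hard-coded.
An optional `max_panel_size` keeps the k loci with the lowest per-locus PI
(equivalently the highest heterozygosity) when a fixed size is required.

## Identity statistics

Per-locus PI is the probability two unrelated Hardy–Weinberg individuals
share a genotype, PI = Σpᵢ⁴ + Σᵢ<ⱼ(2pᵢpⱼ)² = 2(Σpᵢ²)² − Σpᵢ⁴. The full-sib
match probability uses the standard Evett–Weir form
PIsib = ¼ + ½Σpᵢ² + ½(Σpᵢ²)² − ¼Σpᵢ⁴. Both closed forms are checked to
1e-12 against exhaustive enumeration oracles (all genotype pairs; all
parental genotype pairs × Mendelian offspring distributions), including
3- and 4-allele frequency vectors, so the formula choice is verified rather
than trusted. PIsib ≥ PI always (sibs are harder to distinguish).

Multilocus values are products over loci — justified exactly by the LD
filter — computed in log10 space. Cumulative curves accumulate loci
most-informative-first (ascending per-locus PI) by default; the ordering is
configurable because any fixed panel ordering is equally valid, and the
informative-first curve answers the practical question "how few loci do I
need".

**Uniqueness criterion.** "Panel size sufficient for uniqueness in a cohort
of N" is operationalized as the smallest k with expected matching pairs
C(N,2)·PI_k < 1. This is a declared choice (a birthday-bound style
criterion); alternatives such as N·PI < 1 shift k by only 1–2 loci at
realistic N. Frequencies feeding PI default to the DNA matrix's estimates
over the final panel.

## Sample matching

The allele concordance score for a sample pair is Σ(shared alleles) /
(2 × compared loci), where shared alleles at a locus is the multiset
intersection of the two unordered allele pairs. Loci with a missing call on
either side leave both numerator and denominator — the score stays a
fraction of *compared* alleles, and the number of compared loci is reported
so a complete-panel interpretation (e.g. "out of 100 alleles") remains
recoverable. A pair with zero comparable loci has an undefined score and
the query is categorized UNSURE.

Best hits are all references attaining the maximum score, provided it
reaches the threshold (default 0.8); multiple hits are expected when the
reference set contains repeated measurements of one person, and a query
passes if *any* expected reference is among its best hits. A query with
confident best hits that exclude every expected reference is a flagged
mix-up. Queries absent from the expected map count as failures by default
(`unmapped_policy="fail"`); `"report"` downgrades them to UNSURE for
exploratory runs.

The threshold 0.8 sits in the wide gap between the two score populations:
true pairs score ≈ 1 − error rate (≈ 0.97 at 2% genotype error, since one
miscall usually changes one allele of two), while unrelated pairs at
MAF 0.2–0.5 score ≈ 0.55–0.65 in expectation. The matched/unmatched
distribution comparison uses identical-genotype counts (not scores), with
random non-matching pairs drawn with a recorded seed.

## The synthetic cohort generator

The generator reproduces the *statistical* structure the pipeline assumes:
biallelic HWE loci with configurable AAF spectrum (default uniform on
0.25–0.75, the high-MAF regime identification panels target), and planted
violations of exactly one filter each —

* low-MAF loci at a planted frequency (default 0.1),
* 3-allele loci (frequencies 0.45/0.35/0.20, high enough that the third
  allele is always observed at cohort scale),
* HWE violators with genotype probabilities p²+fpq, 2pq(1−f), q²+fpq
  (default f = 0.4: allele frequencies are untouched, so these loci fail
  only the HWE filter; at n = 2000 the exact test rejects them with
  essentially unit power),
* near-duplicate LD pairs: the duplicate copies its partner's genotypes
  with a small per-sample redraw probability (default 1%), giving r² ≈ 0.96
  — genotype copying is sufficient because the r² filter is genotype-based,
* loci placed inside the HLA interval,
* low call-rate loci (RNA call rate forced to ≈ 0.8).

The RNA matrix is the DNA matrix with independent symmetric genotype
miscalls (each error moves to a uniformly chosen different genotype;
default rate 2%, matching the >90% per-SNP DNA/RNA concordance regime a
blood panel operates in) plus independent missingness (default 1% per
call). Full-sib pairs come from two HWE parents with independent Mendelian
transmission per locus; sibs share no missingness correlation. Planted
swaps relabel RNA samples by one cyclic permutation over `n_swaps` chosen
non-sib samples, so `n_swaps` is exactly the number of mislabelled queries
(hence 0 or ≥ 2). Truth records every planted feature, the identity
expected map, the swap-resolved true map, and — because the LD survivor
depends on realized heterozygosity — the expected panel computed from the
generated matrices themselves.

**What the generator does not emulate**, and therefore what passing tests
do not establish about real data: allele-specific expression and
coverage-dependent RNA dropout (RNA errors here are symmetric and
locus-independent, whereas real RNA-Seq miscalls concentrate at low-coverage
and imbalanced loci), population structure and admixture (one panmictic
population), genuine haplotype LD (duplicates exercise the pruner but not
block structure), strand-flip representation mismatches between platforms
(conflicting REF alleles are excluded, not corrected), and SNP-specific
error hotspots. Results on real cohorts additionally depend on upstream
variant calling, which is out of scope here.

## Numerical choices and degenerate inputs

* HWE p-values compare configuration probabilities with a 1+1e-12 relative
  tolerance so equiprobable configurations (exact ties) aggregate correctly.
* Monomorphic loci: HWE p = 1, F undefined (flagged), r² undefined →
  treated as 0 by the pruner.
* All-missing loci raise a typed `UndefinedStatisticError` where a single
  statistic is requested, and produce NaN rows in bulk tables.
* Multilocus PI is accumulated in log10; the linear value is reported too
  and only underflows beyond ~10⁻³⁰⁸.
* Score ties in best-hit sets use a 1e-12 absolute tolerance.

## Problem sizes used in the bundled checks

The bundled verification (`scripts/acceptance.py` and the test suite) runs
at the scale the statistics demand rather than cohort scale: 2000 samples
for the planted-cohort recovery (the r² < 0.01 filter and the f = 0.4 HWE
power both need it — see above), 200 samples × 50 loci for swap detection,
10⁶ simulated pairs for the empirical PI/PIsib checks (3 standard errors at
10⁶ pairs resolves the third decimal), and 2000 null loci × 500 samples for
HWE calibration. These sizes were chosen so that every probabilistic
assertion has comfortable statistical margin; all complete in seconds.

## Known limitations

* No BCF or index support; only the GT field is interpreted.
* The concordance score uses hard calls; imputation dosages are not
  supported.
* No kinship classes beyond full sibs in the identity statistics, and no
  θ-correction for population substructure.
* "Close genetic distance" is not a separate pruning criterion; the r²
  threshold subsumes it. On real data with long-range LD this is a known
  deviation risk.
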