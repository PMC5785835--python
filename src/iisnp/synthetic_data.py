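"""Paired DNA/RNA cohort simulator with planted violations and known truth.

The generator emulates the study design behind DNA/RNA identification
panels: a cohort genotyped twice (once from DNA, once from RNA-derived
calls), where most loci are well-behaved biallelic SNPs in Hardy-Weinberg
equilibrium and a known subset violates exactly one panel-selection filter:

* low minor allele frequency,
* more than two alleles,
* Hardy-Weinberg departure (excess homozygosity with inbreeding-like
  coefficient ``f_plant``: genotype probabilities p^2+fpq, 2pq(1-f),
  q^2+fpq),
* near-duplicate locus pairs (strong LD),
* location inside the HLA/MHC interval,
* low genotype call rate.

The RNA matrix is the DNA matrix plus independent symmetric genotype
mis-calls and independent missingness; full-sib sample pairs come from two
simulated parents with Mendelian transmission; planted sample swaps
relabel RNA samples relative to the expected mapping. Everything is
deterministic given the seed, and every planted feature is recorded in a
:class:`SimulationTruth` so downstream stages can be tested against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from iisnp.genotype_io import (
    MISSING,
    GenotypeMatrix,
    HlaInterval,
    Locus,
    SampleMap,
)

#: Violation labels; each planted locus carries exactly one.
LABELS = ("none", "low_callrate", "multiallelic", "low_maf", "hwe", "ld_dup", "hla")


@dataclass
class SimulationConfig:
    """Cohort layout, allele-frequency spectrum, noise and planted features.

    ``n_loci`` is the total locus count including planted ones. Clean loci
    draw their alternative-allele frequency uniformly from ``aaf_range``
    (default 0.25-0.75, the high-MAF regime a panel targets); ``aafs``
    overrides with explicit per-locus frequencies for non-planted loci.
    ``n_swaps`` RNA samples are relabelled by one cyclic permutation, so
    each swapped query's data truly belongs to a different individual
    (0 or >= 2).
    """

    n_samples: int = 200
    n_loci: int = 60
    aaf_range: tuple[float, float] = (0.25, 0.75)
    aafs: list[float] | None = None
    missing_rate: float = 0.01
    rna_error_rate: float = 0.02
    n_multiallelic: int = 0
    n_low_maf: int = 0
    low_maf: float = 0.1
    n_hwe_violating: int = 0
    f_plant: float = 0.4
    n_ld_pairs: int = 0
    ld_flip_rate: float = 0.01
    n_hla: int = 0
    n_low_callrate: int = 0
    low_callrate: float = 0.8
    n_sib_pairs: int = 0
    n_swaps: int = 0
    seed: int = 0
    hla: HlaInterval = field(default_factory=HlaInterval)

    def validate(self) -> None:
        planted = (
            self.n_multiallelic
            + self.n_low_maf
            + self.n_hwe_violating
            + 2 * self.n_ld_pairs
            + self.n_hla
            + self.n_low_callrate
        )
        if min(
            self.n_samples,
            self.n_loci,
            self.n_multiallelic,
            self.n_low_maf,
            self.n_hwe_violating,
            self.n_ld_pairs,
            self.n_hla,
            self.n_low_callrate,
            self.n_sib_pairs,
            self.n_swaps,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if planted > self.n_loci:
            raise ValueError(
                f"planted loci ({planted}) exceed n_loci ({self.n_loci})"
            )
        for name in ("missing_rate", "rna_error_rate", "ld_flip_rate", "low_callrate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.f_plant <= 1:
            raise ValueError("f_plant must be in [0, 1]")
        if self.n_swaps == 1:
            raise ValueError("n_swaps must be 0 or >= 2 (a lone sample cannot swap)")
        if 2 * self.n_sib_pairs + self.n_swaps > self.n_samples:
            raise ValueError("not enough samples for sib pairs plus swaps")
        if self.aafs is not None and len(self.aafs) != self.n_loci:
            raise ValueError("explicit aafs must have length n_loci")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort."""

    labels: dict[tuple, str]  # locus key -> violation label
    planted_aaf: dict[tuple, tuple[float, ...]]  # allele freqs (ref first)
    clean_locus_keys: list[tuple]
    ld_pairs: list[tuple[tuple, tuple]]  # (original, near-duplicate)
    ld_survivors: list[tuple]  # more-heterozygous member of each pair (realized)
    sib_pairs: list[tuple[str, str]]
    swaps: list[tuple[str, str]]  # (query label, true donor label)
    expected_map: SampleMap  # the mapping a study would declare (identity)
    true_map: SampleMap  # actual donor of each RNA sample, swaps resolved
    expected_panel: list[tuple]  # clean loci + LD survivors, matrix order

    def to_table(self) -> str:
        lines = ["#locus\tlabel\tplanted_freqs"]
        for key, label in self.labels.items():
            loc = ":".join(
                str(x) if not isinstance(x, tuple) else ",".join(x) for x in key
            )
            freqs = ",".join(f"{p:.4f}" for p in self.planted_aaf[key])
            lines.append(f"{loc}\t{label}\t{freqs}")
        return "\n".join(lines) + "\n"


def _draw_hwe(rng, freqs: np.ndarray, n: int) -> np.ndarray:
    """n unordered genotype calls from HWE at the given allele frequencies."""
    a = rng.choice(len(freqs), size=(n, 2), p=freqs)
    return np.sort(a, axis=1).astype(np.int16)


def _draw_inbred(rng, aaf: float, f: float, n: int) -> np.ndarray:
    """Biallelic genotypes with inbreeding-like homozygote excess f."""
    p, q = 1.0 - aaf, aaf
    probs = [p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q]
    g = rng.choice(3, size=n, p=probs)
    out = np.zeros((n, 2), dtype=np.int16)
    out[g == 1, 1] = 1
    out[g == 2] = 1
    return out


def _sib_calls(rng, freqs: np.ndarray, n_pairs: int) -> np.ndarray:
    """Genotypes for n_pairs full-sib pairs: HWE parents, Mendelian children.

    Returns shape (2 * n_pairs, 2); rows 2k and 2k+1 are one sib pair.
    """
    father = rng.choice(len(freqs), size=(n_pairs, 2), p=freqs)
    mother = rng.choice(len(freqs), size=(n_pairs, 2), p=freqs)
    out = np.empty((2 * n_pairs, 2), dtype=np.int16)
    for s in range(2):
        fa = father[np.arange(n_pairs), rng.integers(2, size=n_pairs)]
        mo = mother[np.arange(n_pairs), rng.integers(2, size=n_pairs)]
        out[s::2] = np.sort(np.stack([fa, mo], axis=1), axis=1)
    return out


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, SimulationTruth]:
    """Generate paired DNA/RNA genotype matrices plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]

    # --- assign labels to locus slots, clean loci first, planted at the end
    labels: list[str] = ["none"] * (
        cfg.n_loci
        - cfg.n_low_callrate
        - cfg.n_multiallelic
        - cfg.n_low_maf
        - cfg.n_hwe_violating
        - 2 * cfg.n_ld_pairs
        - cfg.n_hla
    )
    labels += ["low_callrate"] * cfg.n_low_callrate
    labels += ["multiallelic"] * cfg.n_multiallelic
    labels += ["low_maf"] * cfg.n_low_maf
    labels += ["hwe"] * cfg.n_hwe_violating
    labels += ["ld_dup"] * (2 * cfg.n_ld_pairs)
    labels += ["hla"] * cfg.n_hla

    alleles = ("A", "C", "G", "T")
    loci: list[Locus] = []
    freq_list: list[tuple[float, ...]] = []
    pos_counter = 0
    hla_counter = 0
    for i, label in enumerate(labels):
        if label == "hla":
            chrom = cfg.hla.chrom
            pos = cfg.hla.start + 1000 * hla_counter
            hla_counter += 1
        else:
            chrom = "1"
            pos_counter += 1
            pos = 10_000 * pos_counter
        if label == "multiallelic":
            ref, alts = "A", ("C", "G")
            freqs = (0.45, 0.35, 0.20)
        else:
            ref, alts = "A", ("C",)
            if label == "low_maf":
                aaf = cfg.low_maf
            elif cfg.aafs is not None:
                aaf = float(cfg.aafs[i])
            else:
                aaf = float(rng.uniform(*cfg.aaf_range))
            freqs = (1.0 - aaf, aaf)
        loci.append(
            Locus(
                chrom=chrom,
                pos=pos,
                id=f"snp{i:05d}",
                ref_allele=ref,
                alt_alleles=alts,
                in_hla=cfg.hla.contains(chrom, pos),
            )
        )
        freq_list.append(freqs)

    # --- DNA genotypes
    n = cfg.n_samples
    n_sib_samples = 2 * cfg.n_sib_pairs
    calls = np.empty((n, cfg.n_loci, 2), dtype=np.int16)
    ld_partner_of: dict[int, int] = {}  # duplicate column -> source column
    ld_cols = [j for j, lab in enumerate(labels) if lab == "ld_dup"]
    for a, b in zip(ld_cols[0::2], ld_cols[1::2]):
        ld_partner_of[b] = a
    for j, label in enumerate(labels):
        freqs = np.asarray(freq_list[j])
        if j in ld_partner_of:
            src = ld_partner_of[j]
            col = calls[:, src, :].copy()
            flip = rng.random(n) < cfg.ld_flip_rate
            if flip.any():
                col[flip] = _draw_hwe(rng, np.asarray(freq_list[src]), int(flip.sum()))
            freq_list[j] = freq_list[src]
            calls[:, j, :] = col
            continue
        if label == "hwe":
            col = _draw_inbred(rng, freqs[1], cfg.f_plant, n)
        else:
            col = _draw_hwe(rng, freqs, n)
        if n_sib_samples:
            col[:n_sib_samples] = _sib_calls(rng, freqs, cfg.n_sib_pairs)
        calls[:, j, :] = col

    # --- RNA = DNA + symmetric genotype mis-calls
    rna_calls = calls.copy()
    if cfg.rna_error_rate > 0:
        err = rng.random((n, cfg.n_loci)) < cfg.rna_error_rate
        for i, j in zip(*np.nonzero(err)):
            k = loci[j].n_alleles
            gts = [(a, b) for a in range(k) for b in range(a, k)]
            cur = tuple(rna_calls[i, j])
            others = [g for g in gts if g != cur]
            rna_calls[i, j] = others[rng.integers(len(others))]

    # --- missingness, independent per matrix
    if cfg.missing_rate > 0:
        for arr in (calls, rna_calls):
            miss = rng.random((n, cfg.n_loci)) < cfg.missing_rate
            arr[miss] = MISSING
    for j, label in enumerate(labels):
        if label == "low_callrate":
            miss = rng.random(n) < (1.0 - cfg.low_callrate)
            rna_calls[miss, j, :] = MISSING

    # --- planted swaps: cyclic relabelling of RNA samples
    swaps: list[tuple[str, str]] = []
    if cfg.n_swaps:
        # swap among non-sib samples so the mislabelled data is unrelated
        pool = np.arange(n_sib_samples, n)
        chosen = np.sort(rng.choice(pool, size=cfg.n_swaps, replace=False))
        permuted = rna_calls.copy()
        for k, qi in enumerate(chosen):
            donor = chosen[(k + 1) % cfg.n_swaps]
            permuted[qi] = rna_calls[donor]
            swaps.append((samples[qi], samples[donor]))
        rna_calls = permuted

    dna = GenotypeMatrix(list(samples), loci, calls)
    rna = GenotypeMatrix(list(samples), list(loci), rna_calls)

    # --- truth, including the realized LD survivor (higher observed Ho)
    keys = [loc.key for loc in loci]
    label_map = dict(zip(keys, labels))
    ld_pairs = [
        (keys[a], keys[b]) for a, b in zip(ld_cols[0::2], ld_cols[1::2])
    ]
    survivors = []
    from iisnp.ld_pruning import _pruning_loser
    from iisnp.locus_stats import compute_locus_stats

    if ld_pairs:
        pair_keys = [k for ab in ld_pairs for k in ab]
        st = compute_locus_stats(dna, pair_keys, with_hwe=False)
        for ka, kb in ld_pairs:
            loser = _pruning_loser(ka, kb, st)
            survivors.append(kb if loser == ka else ka)
    clean = [k for k, lab in zip(keys, labels) if lab == "none"]
    panel = [k for k in keys if label_map[k] == "none" or k in set(survivors)]
    truth = SimulationTruth(
        labels=label_map,
        planted_aaf=dict(zip(keys, freq_list)),
        clean_locus_keys=clean,
        ld_pairs=ld_pairs,
        ld_survivors=survivors,
        sib_pairs=[(samples[2 * k], samples[2 * k + 1]) for k in range(cfg.n_sib_pairs)],
        swaps=swaps,
        expected_map=SampleMap([(s, s) for s in samples]),
        true_map=SampleMap([(s, dict(swaps).get(s, s)) for s in samples]),
        expected_panel=panel,
    )
    return dna, rna, truth


def _genotype_dosages(rng, aaf: float, n: int) -> np.ndarray:
    """Biallelic HWE genotypes as alt-allele dosage (0/1/2)."""
    return rng.binomial(1, aaf, size=n) + rng.binomial(1, aaf, size=n)


def simulate_unrelated_pairs(aafs, n_pairs: int, seed: int = 0) -> float:
    """Fraction of unrelated pairs with identical multilocus genotypes.

    Empirical counterpart of the multilocus PI: each pair is two
    independent HWE draws at every locus. Monomorphic frequencies (0 or 1)
    are allowed for degenerate checks.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    aafs = np.asarray(aafs, dtype=float)
    if np.any((aafs < 0) | (aafs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    match = np.ones(n_pairs, dtype=bool)
    for aaf in aafs:  # locus by locus keeps memory flat at n_pairs
        g1 = _genotype_dosages(rng, aaf, n_pairs)
        g2 = _genotype_dosages(rng, aaf, n_pairs)
        match &= g1 == g2
    return float(match.mean())


def simulate_sib_pairs(aafs, n_pairs: int, seed: int = 0) -> float:
    """Fraction of full-sib pairs with identical multilocus genotypes.

    Each pair descends from two HWE parents with independent Mendelian
    transmission per sib; the empirical counterpart of the PI-sibs product.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    aafs = np.asarray(aafs, dtype=float)
    if np.any((aafs < 0) | (aafs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    match = np.ones(n_pairs, dtype=bool)
    for aaf in aafs:
        father = rng.binomial(1, aaf, size=(n_pairs, 2))
        mother = rng.binomial(1, aaf, size=(n_pairs, 2))
        sib = []
        for _ in range(2):
            fa = father[np.arange(n_pairs), rng.integers(2, size=n_pairs)]
            mo = mother[np.arange(n_pairs), rng.integers(2, size=n_pairs)]
            sib.append(fa + mo)  # dosage identifies the unordered genotype
        match &= sib[0] == sib[1]
    return float(match.mean())


def write_cohort(dna, rna, truth, outdir, seed: int | None = None) -> dict:
    """Write DNA/RNA VCFs, the truth table and the expected sample map.

    Returns the paths written. The seed is recorded as a header comment in
    the truth table when provided.
    """
    import os

    from iisnp.genotype_io import write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "dna": os.path.join(outdir, "dna.vcf"),
        "rna": os.path.join(outdir, "rna.vcf"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "map": os.path.join(outdir, "expected_map.tsv"),
    }
    write_vcf(dna, paths["dna"])
    write_vcf(rna, paths["rna"])
    with open(paths["truth"], "w") as fh:
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        fh.write(truth.to_table())
    truth.expected_map.write(paths["map"])
    return paths
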