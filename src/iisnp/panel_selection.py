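"""The panel-selection filtering cascade with a per-stage audit trail.

Starting from paired DNA and RNA genotype matrices, the cascade keeps loci
that are: reliably called in RNA (call rate > 0.9), biallelic (at most two
observed alleles and three genotype classes), common (MAF > 0.2 in both
matrices), present in both call sets, in Hardy-Weinberg equilibrium at
FDR 1%, outside the HLA/MHC region, and mutually unlinked (pairwise
r-squared < 0.01, keeping the more heterozygous locus of each linked
pair). Whatever survives is the panel; an optional cap keeps the top-k
most informative loci (lowest per-locus probability of identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from iisnp.genotype_io import GenotypeMatrix, intersect_loci
from iisnp.identity_stats import pi_locus
from iisnp.ld_pruning import pairwise_r2, prune_by_ld
from iisnp.locus_stats import LocusStats, compute_locus_stats


@dataclass
class PanelParams:
    """Filter thresholds; defaults are the standard panel-selection values."""

    call_rate: float = 0.9  # RNA genotype call rate must exceed this
    maf: float = 0.2  # required in BOTH matrices
    hwe_fdr: float = 0.01  # BH-adjusted HWE cut: keep q >= hwe_fdr
    hwe_raw_p: float | None = None  # optional extra raw-p cut (keep p > value)
    ld_r2: float = 0.01  # pairwise r-squared ceiling
    hwe_on: str = "dna"  # matrix whose genotypes feed the HWE test
    max_panel_size: int | None = None  # optional top-k most-informative cap

    def validate(self) -> None:
        for name in ("call_rate", "maf"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.ld_r2 <= 1:
            raise ValueError("ld_r2 must be in (0, 1]")
        if not 0 < self.hwe_fdr <= 1:
            raise ValueError("hwe_fdr must be in (0, 1]")
        if self.hwe_on not in ("dna", "rna"):
            raise ValueError("hwe_on must be 'dna' or 'rna'")


@dataclass
class Stage:
    name: str
    criterion: str
    n_in: int
    n_out: int
    survivors: list[tuple]


@dataclass
class PanelSelectionResult:
    stages: list[Stage]
    final_panel: list[tuple]
    parameters: PanelParams
    conflicts: list[tuple] = field(default_factory=list)
    dna_stats: dict[tuple, LocusStats] | None = None
    rna_stats: dict[tuple, LocusStats] | None = None

    def stage_counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]


def select_panel(
    dna: GenotypeMatrix, rna: GenotypeMatrix, params: PanelParams | None = None
) -> PanelSelectionResult:
    """Run the full filtering cascade and return the surviving panel.

    Stage order: RNA call rate, biallelic, MAF in both, DNA/RNA
    intersection, HWE (on the DNA calls by default — the less error-prone
    genotypes), HLA exclusion, LD pruning. An empty survivor set at any
    stage yields a valid result with an empty panel, never an error.
    """
    params = params or PanelParams()
    params.validate()
    if dna.n_loci == 0 or rna.n_loci == 0 or dna.n_samples == 0 or rna.n_samples == 0:
        raise ValueError("both matrices must be non-empty")

    stages: list[Stage] = []
    rna_stats = compute_locus_stats(rna, with_hwe=False)

    def push(name: str, criterion: str, before: list[tuple], after: list[tuple]):
        stages.append(Stage(name, criterion, len(before), len(after), after))
        return after

    # (a) RNA genotype call rate
    current = [loc.key for loc in rna.loci]
    current = push(
        "call_rate",
        f"RNA call rate > {params.call_rate}",
        current,
        [k for k in current if rna_stats[k].call_rate > params.call_rate],
    )

    # (b) biallelic: <= 2 observed alleles and <= 3 genotype classes (RNA calls)
    current = push(
        "biallelic",
        "<= 2 observed alleles and <= 3 genotype classes",
        current,
        [
            k
            for k in current
            if rna_stats[k].n_alleles_observed <= 2
            and rna_stats[k].n_genotype_classes <= 3
        ],
    )

    # (c) MAF in both matrices (each matrix's own frequencies); loci absent
    # from DNA cannot fail the DNA half here — the intersection removes them
    inter = intersect_loci(rna, dna)
    dna_match = {}  # rna key -> matching dna key (same site, overlapping alts)
    dna_by_site = {loc.site: loc.key for loc in dna.loci}
    for k in inter.shared:
        site = (k[0], k[1], k[2])
        dna_match[k] = dna_by_site[site]
    dna_stats = compute_locus_stats(
        dna, [dna_match[k] for k in current if k in dna_match], with_hwe=False
    )
    current = push(
        "maf",
        f"MAF > {params.maf} in both DNA and RNA",
        current,
        [
            k
            for k in current
            if rna_stats[k].maf > params.maf
            and (k not in dna_match or dna_stats[dna_match[k]].maf > params.maf)
        ],
    )

    # (d) loci present in both call sets
    current = push(
        "intersection",
        "locus present in both DNA and RNA call sets",
        current,
        [k for k in current if k in dna_match],
    )

    # (e) Hardy-Weinberg: BH-adjusted exact test across surviving loci
    def in_dna(k):  # keys after (d) all have a DNA counterpart
        return dna_match[k]

    if params.hwe_on == "dna":
        hwe_stats = compute_locus_stats(dna, [in_dna(k) for k in current], with_hwe=True)
        hs = lambda k: hwe_stats[in_dna(k)]
    else:
        hwe_stats = compute_locus_stats(rna, current, with_hwe=True)
        hs = lambda k: hwe_stats[k]
    kept = [
        k
        for k in current
        if np.isfinite(hs(k).hwe_q)
        and hs(k).hwe_q >= params.hwe_fdr
        and (params.hwe_raw_p is None or hs(k).hwe_p > params.hwe_raw_p)
    ]
    crit = f"HWE exact test, BH q >= {params.hwe_fdr} ({params.hwe_on})"
    if params.hwe_raw_p is not None:
        crit += f" and raw p > {params.hwe_raw_p}"
    current = push("hwe", crit, current, kept)

    # (f) HLA exclusion
    rna_by_key = {loc.key: loc for loc in rna.loci}
    current = push(
        "hla",
        "locus outside the HLA/MHC interval",
        current,
        [k for k in current if not rna_by_key[k].in_hla],
    )

    # (g) LD pruning on DNA genotypes
    if len(current) >= 2:
        ld = pairwise_r2(dna, [in_dna(k) for k in current])
        prune_stats = compute_locus_stats(dna, [in_dna(k) for k in current], with_hwe=False)
        kept_dna = set(prune_by_ld(ld, prune_stats, params.ld_r2))
        survivors = [k for k in current if in_dna(k) in kept_dna]
    else:
        survivors = list(current)
    current = push("ld", f"pairwise r2 < {params.ld_r2}", current, survivors)

    # optional cap: keep the k most informative loci (lowest per-locus PI)
    if params.max_panel_size is not None and len(current) > params.max_panel_size:
        dna_panel_stats = compute_locus_stats(
            dna, [in_dna(k) for k in current], with_hwe=False
        )
        ranked = sorted(
            current,
            key=lambda k: pi_locus(
                [
                    1 - dna_panel_stats[in_dna(k)].aaf,
                    dna_panel_stats[in_dna(k)].aaf,
                ]
            ),
        )
        capped = [k for k in current if k in set(ranked[: params.max_panel_size])]
        current = push(
            "cap", f"top {params.max_panel_size} by per-locus PI", current, capped
        )

    return PanelSelectionResult(
        stages=stages,
        final_panel=current,
        parameters=params,
        conflicts=inter.conflicts,
        dna_stats=(
            compute_locus_stats(dna, [in_dna(k) for k in current], with_hwe=False)
            if current
            else {}
        ),
        rna_stats=rna_stats,
    )


def stage_table(result: PanelSelectionResult) -> str:
    """Tab-separated per-stage report of the filtering cascade."""
    p = result.parameters
    lines = [
        "#panel selection stage table",
        f"#thresholds\tcall_rate={p.call_rate}\tmaf={p.maf}\thwe_fdr={p.hwe_fdr}"
        f"\thwe_raw_p={p.hwe_raw_p}\tld_r2={p.ld_r2}\thwe_on={p.hwe_on}",
        "#stage\tcriterion\tn_in\tn_out",
    ]
    for s in result.stages:
        lines.append(f"{s.name}\t{s.criterion}\t{s.n_in}\t{s.n_out}")
    lines.append(f"final_panel\t\t\t{len(result.final_panel)}")
    return "\n".join(lines) + "\n"
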