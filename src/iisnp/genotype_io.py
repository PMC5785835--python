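"""Multi-sample genotype I/O: VCF reading/writing and the in-memory genotype matrix.

Genotypes are stored unphased as sorted pairs of allele indices per
(sample, locus); phase is irrelevant to every statistic downstream.
Coordinates follow the VCF convention (1-based, fully closed) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pysam

#: Sentinel allele index for a missing call. Half-calls (e.g. ``0/.``) are
#: treated as fully missing: no statistic here can use a lone allele.
MISSING: int = -1

#: Extended MHC on GRCh37. Genotype calls inside this interval are
#: artefact-prone in sequencing data and are excluded from panels.
DEFAULT_HLA_INTERVAL = ("6", 28_477_797, 33_448_354)


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class HlaInterval:
    """A chromosome interval flagged as HLA/MHC (1-based, closed)."""

    chrom: str = DEFAULT_HLA_INTERVAL[0]
    start: int = DEFAULT_HLA_INTERVAL[1]
    end: int = DEFAULT_HLA_INTERVAL[2]

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == _norm_chrom(self.chrom) and self.start <= pos <= self.end


@dataclass(frozen=True)
class Locus:
    """A variant site: chromosome, 1-based position, alleles, HLA flag.

    ``ref_allele`` has index 0; ``alt_alleles[i]`` has index ``i + 1``.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    in_hla: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError(f"locus {self.id}: empty REF allele")
        if not self.alt_alleles:
            raise ValueError(f"locus {self.id}: no ALT alleles")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"locus {self.id}: REF allele repeated in ALT")

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        """Unique locus key: (chrom, pos, ref, sorted alt-allele set)."""
        return (self.chrom, self.pos, self.ref_allele, tuple(sorted(self.alt_alleles)))

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def site(self) -> tuple[str, int, str]:
        """(chrom, pos, ref) — the join key used when intersecting call sets."""
        return (self.chrom, self.pos, self.ref_allele)

    def __str__(self) -> str:  # compact key for tables
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{','.join(self.alt_alleles)}"


class VcfParseError(ValueError):
    """Raised for malformed VCF input, naming the offending record."""


@dataclass
class GenotypeMatrix:
    """Samples x loci table of unphased diploid genotype calls.

    ``calls`` has shape (n_samples, n_loci, 2) and holds allele indices
    sorted within each pair; both entries are :data:`MISSING` for a
    missing call.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        keys = [loc.key for loc in self.loci]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate locus keys")
        # allele indices must be valid for each locus
        for j, loc in enumerate(self.loci):
            col = self.calls[:, j, :]
            if col.max(initial=MISSING) >= loc.n_alleles:
                raise ValueError(f"locus {loc}: allele index out of range")
        self._index = {k: j for j, k in enumerate(keys)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, key) -> int:
        """Index of a locus by full key, (chrom, pos, ref) site, or Locus."""
        if isinstance(key, Locus):
            key = key.key
        if key in self._index:
            return self._index[key]
        for j, loc in enumerate(self.loci):  # site-level fallback
            if loc.site == key:
                return j
        raise KeyError(f"locus {key!r} not in matrix")

    def genotypes(self, key) -> np.ndarray:
        """Calls at one locus: shape (n_samples, 2) of sorted allele indices."""
        return self.calls[:, self.locus_index(key), :]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_samples, n_loci), NaN where missing.

        Only meaningful for biallelic loci; at multi-allelic loci the value
        counts non-reference alleles.
        """
        d = (self.calls > 0).sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def subset_loci(self, keys: Iterable) -> "GenotypeMatrix":
        idx = [self.locus_index(k) for k in keys]
        return GenotypeMatrix(list(self.samples), [self.loci[j] for j in idx], self.calls[:, idx, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.loci), self.calls[idx, :, :])


@dataclass
class SampleMap:
    """Expected query -> reference sample pairing (many-to-one allowed)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        queries = [q for q, _ in self.pairs]
        if len(set(queries)) != len(queries):
            raise ValueError("duplicate query IDs in sample map")

    def expected(self, query: str) -> set[str]:
        """All references declared for a query (repeated measurements)."""
        return {r for q, r in self.pairs if q == query}

    @classmethod
    def read(cls, path) -> "SampleMap":
        pairs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
                pairs.append((fields[0], fields[1]))
        return cls(pairs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#query\treference\n")
            for q, r in self.pairs:
                fh.write(f"{q}\t{r}\n")


def read_vcf(path, hla: HlaInterval | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Every record becomes one locus; multi-allelic records are preserved
    (filtering happens downstream, never at read time). ``./.`` and
    half-calls become missing. ``in_hla`` is set from ``hla``
    (default: GRCh37 extended MHC).

    Raises :class:`VcfParseError` on malformed records or duplicate locus
    keys, naming the offending site.
    """
    hla = hla or HlaInterval()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # htslib warns about undeclared contigs
        try:
            vf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"{path}: cannot parse VCF: {exc}") from exc
        samples = list(vf.header.samples)
        loci: list[Locus] = []
        rows: list[np.ndarray] = []
        seen: set = set()
        for rec in vf:
            if rec.ref is None or not rec.alts:
                raise VcfParseError(f"{path}: record {rec.chrom}:{rec.pos} lacks REF/ALT")
            loc = Locus(
                chrom=rec.chrom,
                pos=rec.pos,
                id=rec.id or f"{rec.chrom}:{rec.pos}",
                ref_allele=rec.ref,
                alt_alleles=tuple(rec.alts),
                in_hla=hla.contains(rec.chrom, rec.pos),
            )
            if loc.key in seen:
                raise VcfParseError(f"{path}: duplicate locus {loc}")
            seen.add(loc.key)
            col = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    continue  # missing or half-call
                a, b = sorted(gt)
                col[i] = (a, b)
            loci.append(loc)
            rows.append(col)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(samples, loci, calls)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as minimal VCF 4.2 (GT only).

    Round-trips losslessly through :func:`read_vcf` for calls, sample
    order and locus keys. Missing calls are written ``./.``.
    """
    contigs = []
    for loc in gm.loci:
        if loc.chrom not in contigs:
            contigs.append(loc.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("".join(f"\t{s}" for s in gm.samples) + "\n")
        for j, loc in enumerate(gm.loci):
            fields = [
                loc.chrom,
                str(loc.pos),
                loc.id,
                loc.ref_allele,
                ",".join(loc.alt_alleles),
                ".",
                ".",
                ".",
                "GT",
            ]
            for i in range(gm.n_samples):
                a, b = gm.calls[i, j]
                fields.append("./." if a == MISSING else f"{a}/{b}")
            fh.write("\t".join(fields) + "\n")


class LocusIntersection(NamedTuple):
    """Shared locus keys plus sites excluded for REF-allele conflicts."""

    shared: list[tuple]
    conflicts: list[tuple]


def intersect_loci(a: GenotypeMatrix, b: GenotypeMatrix) -> LocusIntersection:
    """Locus keys present in both matrices, in matrix ``a`` order.

    Two loci match when (chrom, pos, ref) are identical and their ALT
    allele sets overlap. Sites sharing (chrom, pos) but disagreeing on REF
    are excluded and reported in ``conflicts`` rather than guessed at
    (no strand-flip reconciliation is attempted).
    """
    b_by_pos: dict[tuple[str, int], list[Locus]] = {}
    for loc in b.loci:
        b_by_pos.setdefault((loc.chrom, loc.pos), []).append(loc)
    shared, conflicts = [], []
    for loc in a.loci:
        candidates = b_by_pos.get((loc.chrom, loc.pos), [])
        if not candidates:
            continue
        same_ref = [c for c in candidates if c.ref_allele == loc.ref_allele]
        if not same_ref:
            conflicts.append((loc.chrom, loc.pos))
            continue
        if any(set(c.alt_alleles) & set(loc.alt_alleles) for c in same_ref):
            shared.append(loc.key)
    return LocusIntersection(shared, conflicts)
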