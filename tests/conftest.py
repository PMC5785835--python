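import numpy as np
import pytest

from iisnp.genotype_io import MISSING, GenotypeMatrix, Locus


def make_locus(i=0, chrom="1", pos=None, ref="A", alts=("C",), in_hla=False):
    return Locus(
        chrom=chrom,
        pos=pos if pos is not None else 1000 * (i + 1),
        id=f"snp{i}",
        ref_allele=ref,
        alt_alleles=tuple(alts),
        in_hla=in_hla,
    )


def gm_from_strings(columns, samples=None, loci=None):
    """Build a GenotypeMatrix from per-locus genotype-string columns.

    ``columns`` is a list of lists like ["0/0", "0/1", "./."]; every column
    is one locus, every entry one sample.
    """
    n_loci = len(columns)
    n_samples = len(columns[0])
    samples = samples or [f"S{i}" for i in range(n_samples)]
    if loci is None:
        n_alts = [
            max(
                (int(a) for col in (c,) for g in col for a in g.split("/") if a != "."),
                default=1,
            )
            for c in columns
        ]
        loci = [
            make_locus(i, alts=tuple("CGT"[: max(1, n_alts[i])])) for i in range(n_loci)
        ]
    calls = np.full((n_samples, n_loci, 2), MISSING, dtype=np.int16)
    for j, col in enumerate(columns):
        for i, g in enumerate(col):
            a, b = g.split("/")
            if a == "." or b == ".":
                continue
            calls[i, j] = sorted((int(a), int(b)))
    return GenotypeMatrix(samples, loci, calls)


@pytest.fixture
def small_gm():
    """Two loci, four samples, one missing call."""
    return gm_from_strings([["0/0", "0/0", "0/1", "1/1"], ["0/0", "./.", "1/1", "0/1"]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
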