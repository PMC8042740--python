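import numpy as np
import pytest

from pedcnv.io_formats import CNVSite, Genotype, Individual, Pedigree, SVType

SAMPLES = [f"s{i:02d}" for i in range(32)]


def make_site(
    site_id="siteX",
    svtype="DEL",
    chrom="chr1",
    start=10_000,
    length=500,
    qual=200.0,
    carriers=("s01",),
    hom_carriers=(),
    fc=None,
    samples=None,
    missing=(),
):
    """Construct a CNVSite with the given carriers and a single fold-change
    value shared by all carriers (non-carriers get 1.0).  ``fc`` defaults to
    a value that passes the depth-support rule for the type."""
    samples = list(samples) if samples is not None else list(SAMPLES)
    svtype = SVType(svtype)
    if fc is None:
        fc = 0.5 if svtype is SVType.DEL else 1.6
    genotypes = {}
    for s in samples:
        if s in missing:
            genotypes[s] = Genotype.MISSING
        elif s in hom_carriers:
            genotypes[s] = Genotype.HOM_ALT
        elif s in carriers:
            genotypes[s] = Genotype.HET
        else:
            genotypes[s] = Genotype.HOM_REF
    values = {s: (fc if genotypes[s].is_carrier else 1.0) for s in samples}
    return CNVSite(
        site_id=site_id,
        chrom=chrom,
        start=start,
        end=start + length - 1,
        svtype=svtype,
        qual=qual,
        genotypes=genotypes,
        fold_change_flank=dict(values),
        fold_change_gc=dict(values),
        length=length,
    )


@pytest.fixture
def flat_cohort_pedigree():
    """32 unrelated individuals named like SAMPLES (no trios)."""
    return Pedigree(individuals=[Individual(s, None, None, 1) for s in SAMPLES])


@pytest.fixture
def simple_trio_pedigree():
    """One trio (dad, mum -> kid) plus one unrelated individual."""
    return Pedigree(
        individuals=[
            Individual("dad", None, None, 1),
            Individual("mum", None, None, 2),
            Individual("kid", "dad", "mum", 1),
            Individual("other", None, None, 2),
        ],
        paternal_age={"kid": 8.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
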