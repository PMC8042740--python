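"""Readers and writers for the file formats the pipeline touches.

Formats: structural-variant VCF (SVTYPE=DEL/DUP with END/SVLEN and
per-sample depth fold-change FORMAT tags in the style written by depth
annotation of SV calls), whitespace-delimited pedigree (PED dialect with an
optional sire-age column), GTF gene annotation, and BED6 summaries.

One coordinate convention holds everywhere in memory: intervals are 1-based
and inclusive on both ends, the native convention of VCF and GTF.  BED is
0-based half-open; the conversion happens only at (de)serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import gffutils
import pandas as pd
import pysam

logger = logging.getLogger("pedcnv")

DEFAULT_FLANK_TAG = "DHFFC"  # variant depth / flanking depth
DEFAULT_GC_TAG = "DHBFC"  # variant depth / depth of similar-GC bins


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class CNVSite:
    """One copy-number variant record: an interval, a type, per-sample calls.

    ``start``/``end`` are 1-based inclusive.  ``length`` is SVLEN when the
    record carried one, otherwise ``end - start + 1``.  ``fold_change_flank``
    is the deletion depth metric (variant depth over flanking depth);
    ``fold_change_gc`` is the duplication metric (variant depth over depth in
    genome bins of similar GC content).  Missing per-sample annotations are
    simply absent from the maps.
    """

    site_id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    qual: float
    genotypes: dict[str, Genotype]
    fold_change_flank: dict[str, float] = field(default_factory=dict)
    fold_change_gc: dict[str, float] = field(default_factory=dict)
    length: int | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.site_id}: end {self.end} < start {self.start}")
        if self.length is None:
            self.length = self.end - self.start + 1
        if self.length < 1:
            raise ValueError(f"{self.site_id}: length {self.length} < 1")
        self.svtype = SVType(self.svtype)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def carriers(self) -> list[str]:
        """Samples with a non-reference genotype, in insertion order."""
        return [s for s, g in self.genotypes.items() if g.is_carrier]

    def events(self) -> list["Event"]:
        return [Event(self.site_id, s, self.genotypes[s]) for s in self.carriers()]


@dataclass(frozen=True)
class Event:
    """One non-reference genotype at one site in one sample."""

    site_id: str
    sample: str
    genotype: Genotype

    def __post_init__(self) -> None:
        if not self.genotype.is_carrier:
            raise ValueError("an event requires a non-reference genotype")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    iid: str
    sire: str | None
    dam: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    generation: int = 0


@dataclass(frozen=True)
class Trio:
    proband: str
    sire: str
    dam: str

    @property
    def trio_id(self) -> str:
        return self.proband


@dataclass
class Pedigree:
    """A validated pedigree: individuals with sire/dam links and sire ages.

    ``paternal_age`` maps a trio (keyed by proband id) to the sire's age at
    the proband's conception, in years.
    """

    individuals: list[Individual]
    paternal_age: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {ind.iid for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual ids in pedigree")
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in ids:
                    raise ValueError(f"unknown parent id {parent!r} for {ind.iid}")
        self._check_acyclic()
        self.individuals = [
            Individual(i.iid, i.sire, i.dam, i.sex, g)
            for i, g in zip(self.individuals, self._generations())
        ]

    def _parents_map(self) -> dict[str, tuple[str | None, str | None]]:
        return {i.iid: (i.sire, i.dam) for i in self.individuals}

    def _check_acyclic(self) -> None:
        parents = self._parents_map()
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ValueError(f"cyclic ancestry involving {node!r}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for p in parents[node]:
                if p is not None:
                    visit(p)
            state[node] = 2

        for iid in parents:
            visit(iid)

    def _generations(self) -> list[int]:
        parents = self._parents_map()
        gen: dict[str, int] = {}

        def depth(iid: str) -> int:
            if iid not in gen:
                ps = [p for p in parents[iid] if p is not None]
                gen[iid] = 0 if not ps else 1 + max(depth(p) for p in ps)
            return gen[iid]

        return [depth(i.iid) for i in self.individuals]

    @property
    def samples(self) -> list[str]:
        return [i.iid for i in self.individuals]

    @property
    def trios(self) -> list[Trio]:
        return [
            Trio(i.iid, i.sire, i.dam)
            for i in self.individuals
            if i.sire is not None and i.dam is not None
        ]

    def offspring_of(self, iid: str) -> list[str]:
        return [i.iid for i in self.individuals if iid in (i.sire, i.dam)]

    def is_founder(self, iid: str) -> bool:
        ind = next(i for i in self.individuals if i.iid == iid)
        return ind.sire is None and ind.dam is None


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Gene → transcript → exon hierarchy with strand.

    ``genes``: DataFrame[gene_id, chrom, start, end, strand];
    ``transcripts``: DataFrame[transcript_id, gene_id, chrom, start, end,
    biotype]; ``exons``: DataFrame[exon_id, transcript_id, chrom, start, end].
    Containment (exon within transcript within gene) is enforced at read
    time: violating features are dropped with a logged warning.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    @classmethod
    def empty(cls) -> "GeneModel":
        return cls(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"]),
            transcripts=pd.DataFrame(
                columns=["transcript_id", "gene_id", "chrom", "start", "end", "biotype"]
            ),
            exons=pd.DataFrame(columns=["exon_id", "transcript_id", "chrom", "start", "end"]),
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = (
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID={flank},Number=1,Type=Float,Description='
    '"Depth fold-change: variant vs flanking regions">',
    '##FORMAT=<ID={gc},Number=1,Type=Float,Description='
    '"Depth fold-change: variant vs bins of similar GC content">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
)


@dataclass
class VCFReadResult:
    """Sites parsed from an SV VCF plus counters for what was not kept."""

    sites: list[CNVSite]
    skipped_svtype: int = 0  # non-DEL/DUP records (e.g. INS, INV, BND)
    rejected: int = 0  # DEL/DUP records missing both END and SVLEN

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def _genotype_from_gt(gt: tuple | None) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    alleles = sorted(gt)
    if alleles == [0, 0]:
        return Genotype.HOM_REF
    if alleles == [0, 1]:
        return Genotype.HET
    if alleles == [1, 1]:
        return Genotype.HOM_ALT
    raise ValueError(f"unsupported genotype {gt!r} (multi-allelic SV records are rejected)")


def read_sv_vcf(
    path: str,
    cohort: list[str] | None = None,
    flank_tag: str = DEFAULT_FLANK_TAG,
    gc_tag: str = DEFAULT_GC_TAG,
) -> VCFReadResult:
    """Read DEL/DUP records from a structural-variant VCF.

    Records with other SVTYPEs are skipped and counted; records missing both
    END and SVLEN are rejected with a logged reason.  When ``cohort`` is
    given, the VCF sample columns must match it exactly (hard error
    otherwise).  Coordinates are kept 1-based inclusive as in the file.
    """
    result = VCFReadResult(sites=[])
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        if cohort is not None and set(vcf_samples) != set(cohort):
            raise ValueError(
                f"VCF samples do not match cohort: {sorted(set(vcf_samples) ^ set(cohort))}"
            )
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "DUP"):
                result.skipped_svtype += 1
                continue
            if rec.alts is not None and len(rec.alts) > 1:
                raise ValueError(f"multi-allelic SV record at {rec.chrom}:{rec.pos}")
            start = rec.pos
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            # htslib folds INFO/END into rec.stop and, when SVLEN is present,
            # recomputes stop from it — so SVLEN is authoritative for length
            # and END only a fallback; without either, stop of a 1-base
            # symbolic record equals POS and the record is rejected.
            if svlen is not None:
                length = abs(int(svlen))
            elif rec.stop > rec.pos:
                length = rec.stop - start + 1
            else:
                logger.warning(
                    "rejecting %s:%d (%s): neither END nor SVLEN present",
                    rec.chrom, rec.pos, svtype,
                )
                result.rejected += 1
                continue
            end = start + length - 1
            genotypes, fc_flank, fc_gc = {}, {}, {}
            for sample in vcf_samples:
                fmt = rec.samples[sample]
                genotypes[sample] = _genotype_from_gt(fmt.get("GT"))
                for tag, store in ((flank_tag, fc_flank), (gc_tag, fc_gc)):
                    val = fmt.get(tag)
                    if val is not None:
                        store[sample] = float(val)
            result.sites.append(
                CNVSite(
                    site_id=rec.id or f"{rec.chrom}_{rec.pos}_{svtype}",
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    svtype=SVType(svtype),
                    # htslib stores QUAL as float32; round back to printed precision
                    qual=round(float(rec.qual), 3) if rec.qual is not None else 0.0,
                    genotypes=genotypes,
                    fold_change_flank=fc_flank,
                    fold_change_gc=fc_gc,
                    length=length,
                )
            )
    return result


_GT_CODES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_sv_vcf(
    sites: list[CNVSite],
    path: str,
    samples: list[str],
    contigs: dict[str, int] | None = None,
    flank_tag: str = DEFAULT_FLANK_TAG,
    gc_tag: str = DEFAULT_GC_TAG,
) -> None:
    """Write a call-set as a VCF 4.2 with symbolic DEL/DUP alleles."""
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line.format(flank=flank_tag, gc=gc_tag))
    if contigs is None:
        contigs = {}
        for site in sites:
            contigs[site.chrom] = max(contigs.get(site.chrom, 0), site.end + 1)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sample in samples:
        header.add_sample(sample)
    ordered = sorted(sites, key=lambda s: (list(contigs).index(s.chrom), s.start, s.site_id))
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in ordered:
            rec = out.new_record(
                contig=site.chrom,
                start=site.start - 1,  # pysam is 0-based here
                stop=site.end,
                alleles=("N", f"<{site.svtype.value}>"),
                id=site.site_id,
                qual=site.qual,
            )
            rec.info["SVTYPE"] = site.svtype.value
            rec.info["SVLEN"] = int(site.length)
            for sample in samples:
                fmt = rec.samples[sample]
                fmt["GT"] = _GT_CODES[site.genotypes.get(sample, Genotype.MISSING)]
                if sample in site.fold_change_flank:
                    fmt[flank_tag] = round(float(site.fold_change_flank[sample]), 4)
                if sample in site.fold_change_gc:
                    fmt[gc_tag] = round(float(site.fold_change_gc[sample]), 4)
            out.write(rec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_pedigree(path: str) -> Pedigree:
    """Read a PED-dialect file: fam, iid, sire, dam, sex [, sire age].

    '0' denotes a missing parent.  The optional sixth column is the sire's
    age (years) at the individual's conception; '.'/'-9' mean absent.  Row
    order does not matter; links are validated on construction.
    """
    individuals: list[Individual] = []
    ages: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"PED row has {len(parts)} columns, expected >= 5: {line!r}")
            _fam, iid, sire, dam, sex = parts[:5]
            individuals.append(
                Individual(
                    iid=iid,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    sex=int(sex),
                )
            )
            if len(parts) >= 6 and parts[5] not in (".", "-9"):
                ages[iid] = float(parts[5])
    return Pedigree(individuals=individuals, paternal_age=ages)


def write_pedigree(pedigree: Pedigree, path: str, family_id: str = "FAM") -> None:
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            age = pedigree.paternal_age.get(ind.iid)
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.iid,
                        ind.sire or "0",
                        ind.dam or "0",
                        str(ind.sex),
                        "." if age is None else f"{age:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _attr_first(feature: gffutils.Feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gene_models(path: str) -> GeneModel:
    """Assemble a gene/transcript/exon hierarchy from a GTF (or GFF3) file.

    Rows with unparseable attribute blocks are skipped with a warning.
    Features violating containment (exon outside its transcript, transcript
    outside its gene) or referencing an unknown parent are dropped, also
    with a warning.
    """
    genes, transcripts, exons = [], [], []
    exon_serial = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # malformed row: skip, keep going
                logger.warning("skipping unparseable row %d of %s: %s", lineno, path, exc)
                continue
            ftype = feat.featuretype.lower()
            if ftype == "gene":
                genes.append(
                    dict(
                        gene_id=_attr_first(feat, "gene_id") or _attr_first(feat, "ID"),
                        chrom=feat.seqid, start=feat.start, end=feat.end,
                        strand=feat.strand,
                    )
                )
            elif ftype in ("transcript", "mrna"):
                transcripts.append(
                    dict(
                        transcript_id=_attr_first(feat, "transcript_id") or _attr_first(feat, "ID"),
                        gene_id=_attr_first(feat, "gene_id") or _attr_first(feat, "Parent"),
                        chrom=feat.seqid, start=feat.start, end=feat.end,
                        biotype=_attr_first(feat, "transcript_biotype") or "protein_coding",
                    )
                )
            elif ftype == "exon":
                exon_serial += 1
                exons.append(
                    dict(
                        exon_id=_attr_first(feat, "exon_id") or f"exon{exon_serial}",
                        transcript_id=_attr_first(feat, "transcript_id")
                        or _attr_first(feat, "Parent"),
                        chrom=feat.seqid, start=feat.start, end=feat.end,
                    )
                )
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    tx_df = pd.DataFrame(
        transcripts, columns=["transcript_id", "gene_id", "chrom", "start", "end", "biotype"]
    )
    ex_df = pd.DataFrame(exons, columns=["exon_id", "transcript_id", "chrom", "start", "end"])

    # containment enforcement: transcript within gene, exon within transcript
    if not tx_df.empty:
        gidx = gene_df.set_index("gene_id")
        keep = []
        for _, tx in tx_df.iterrows():
            if tx.gene_id not in gidx.index:
                logger.warning("dropping transcript %s: unknown gene %s", tx.transcript_id, tx.gene_id)
                keep.append(False)
                continue
            g = gidx.loc[tx.gene_id]
            ok = g.chrom == tx.chrom and g.start <= tx.start and tx.end <= g.end
            if not ok:
                logger.warning("dropping transcript %s: outside gene %s", tx.transcript_id, tx.gene_id)
            keep.append(bool(ok))
        tx_df = tx_df[keep].reset_index(drop=True)
    if not ex_df.empty:
        tidx = tx_df.set_index("transcript_id") if not tx_df.empty else pd.DataFrame()
        keep = []
        for _, ex in ex_df.iterrows():
            if tx_df.empty or ex.transcript_id not in tidx.index:
                logger.warning("dropping exon %s: unknown transcript %s", ex.exon_id, ex.transcript_id)
                keep.append(False)
                continue
            t = tidx.loc[ex.transcript_id]
            ok = t.chrom == ex.chrom and t.start <= ex.start and ex.end <= t.end
            if not ok:
                logger.warning("dropping exon %s: outside transcript %s", ex.exon_id, ex.transcript_id)
            keep.append(bool(ok))
        ex_df = ex_df[keep].reset_index(drop=True)
    return GeneModel(genes=gene_df, transcripts=tx_df, exons=ex_df)


def write_gene_models(model: GeneModel, path: str, source: str = "pedcnv") -> None:
    """Write a GeneModel as GTF 2.2 (gene, transcript, exon features)."""
    tx_by_gene = model.transcripts.groupby("gene_id") if not model.transcripts.empty else None
    ex_by_tx = model.exons.groupby("transcript_id") if not model.exons.empty else None
    with open(path, "w") as fh:
        for _, g in model.genes.iterrows():
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            if tx_by_gene is None or g.gene_id not in tx_by_gene.groups:
                continue
            for _, t in tx_by_gene.get_group(g.gene_id).iterrows():
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start}\t{t.end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";\n'
                )
                if ex_by_tx is None or t.transcript_id not in ex_by_tx.groups:
                    continue
                for _, e in ex_by_tx.get_group(t.transcript_id).iterrows():
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'exon_id "{e.exon_id}";\n'
                    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return bed_start + 1, bed_end


def write_bed(sites: list[CNVSite], path: str) -> None:
    """BED6 summary of a call-set; score is QUAL capped at 1000."""
    with open(path, "w") as fh:
        for site in sites:
            b0, b1 = to_bed_interval(site.start, site.end)
            score = int(min(site.qual, 1000))
            fh.write(f"{site.chrom}\t{b0}\t{b1}\t{site.site_id}\t{score}\t.\n")
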