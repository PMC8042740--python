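"""Synthetic pedigreed SV-cohort generator.

Emulates a 32-individual rhesus-macaque-style cohort containing 14
sire-dam-offspring trios (three multigenerational families plus one simple
two-trio family), with segregating deletions and duplications, injected de
novo CNVs, caller-style QUAL and per-sample depth fold-change annotations,
and the artifact classes the downstream filter cascade targets.  A truth
table records every simulated quantity so parameter recovery can be tested
end to end.

Defaults mirror the cohort the analysis assumes: 8,515 pre-filter sites, an
0.88 deletion fraction among segregating variants, log-normal lengths with
type-specific means near 3.2 kb (deletions) and 7.0 kb (duplications), and
0.57 expected de novo transmissions per trio (a haploid rate of 0.285 per
generation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import CNVSite, Genotype, GeneModel, Individual, Pedigree, SVType

_GT_FROM_DOSAGE = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}

#: site classes injected besides clean segregating variants
ARTIFACT_CLASSES = ("reference", "oversize", "low_quality", "alu")


@dataclass
class ArtifactRates:
    """Proportions of sites injected per artifact class.

    Defaults reproduce the pre-filter composition implied by per-rule site
    removals out of 8,515 call-set sites: reference-individual artifacts
    (carried by >= 31 of 32 samples), oversize (> 100 kb), low-quality
    (QUAL < 100), and Alu-window (275-325 bp) sites.
    """

    reference: float = 2615 / 8515
    oversize: float = 464 / 8515
    low_quality: float = 244 / 8515
    alu: float = 108 / 8515

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ARTIFACT_CLASSES}


@dataclass
class SimConfig:
    """Knobs of the cohort simulation; the defaults are the study conditions."""

    n_samples: int = 32
    n_sites: int = 8515
    deletion_fraction: float = 0.88
    # log-normal length parameters chosen so the untruncated means are the
    # observed per-type means (mean = exp(mu + sigma^2/2))
    del_length_sdlog: float = 1.2
    dup_length_sdlog: float = 1.2
    del_length_meanlog: float = math.log(3161) - 1.2**2 / 2
    dup_length_meanlog: float = math.log(6990) - 1.2**2 / 2
    length_min: int = 40
    length_max: int = 100_000
    # founder allele frequencies: uniform on (0, af_max]
    af_max: float = 0.5
    de_novo_rate: float = 0.57  # expected transmissions per trio (haploid rate x 2)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    depth_noise: float = 0.1  # sd of fold-change values around genotype means
    qual_range: tuple[float, float] = (100.0, 2500.0)
    sire_age_range: tuple[float, float] = (4.0, 12.0)  # years, skewed young
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 10_000_000 for i in range(1, 21)}
    )
    n_genes: int = 300
    n_terms: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        rates = self.artifact_rates.as_dict()
        if not all(0 <= v <= 1 for v in rates.values()) or sum(rates.values()) > 1:
            raise ValueError("artifact rates must be proportions summing to <= 1")
        if not 0 <= self.deletion_fraction <= 1:
            raise ValueError("deletion_fraction must be in [0, 1]")
        if self.length_min <= 0 or self.length_max <= self.length_min:
            raise ValueError("length bounds must satisfy 0 < min < max")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class DeNovoTruth:
    site_id: str
    trio_id: str  # proband id
    proband: str
    svtype: SVType
    transmitted_to: tuple[str, ...] = ()


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort.

    ``sites``: per-site class/type/frequency table; ``genotypes``: true allele
    dosages (rows = site_id, columns = samples); ``de_novo``: injected de novo
    events with their trio, carrier and any F1-to-offspring transmissions.
    """

    sites: pd.DataFrame
    genotypes: pd.DataFrame
    de_novo: list[DeNovoTruth]

    def de_novo_counts(self, pedigree: Pedigree) -> dict[str, int]:
        counts = {t.trio_id: 0 for t in pedigree.trios}
        for dn in self.de_novo:
            counts[dn.trio_id] += 1
        return counts


# ---------------------------------------------------------------------------
# Pedigree template
# ---------------------------------------------------------------------------


def default_pedigree(rng: np.random.Generator | None = None,
                     sire_age_range: tuple[float, float] = (4.0, 12.0)) -> Pedigree:
    """The 32-individual, 14-trio cohort template.

    Three multigenerational families (a sire with three dams and three
    offspring, the eldest offspring siring a grandchild with an unrelated
    dam: 9 individuals, 4 trios, one F1 proband) plus one simple family (a
    sire, two dams, two offspring: 5 individuals, 2 trios).  Sire ages at
    conception are drawn uniformly from ``sire_age_range``, a spread skewed
    young relative to the species' lifespan.
    """
    rng = rng or np.random.default_rng(0)
    individuals: list[Individual] = []
    ages: dict[str, float] = {}

    def founder(iid: str, sex: int) -> None:
        individuals.append(Individual(iid, None, None, sex))

    def child(iid: str, sire: str, dam: str, sex: int) -> None:
        individuals.append(Individual(iid, sire, dam, sex))
        ages[iid] = round(float(rng.uniform(*sire_age_range)), 1)

    for f in (1, 2, 3):
        s = f"F{f}_S1"
        founder(s, 1)
        for d in (1, 2, 3):
            founder(f"F{f}_D{d}", 2)
        founder(f"F{f}_D4", 2)  # mate of the F1 offspring
        child(f"F{f}_O1", s, f"F{f}_D1", 1)  # F1 proband, later a sire
        child(f"F{f}_O2", s, f"F{f}_D2", 2)
        child(f"F{f}_O3", s, f"F{f}_D3", int(rng.integers(1, 3)))
        child(f"F{f}_G1", f"F{f}_O1", f"F{f}_D4", int(rng.integers(1, 3)))
    founder("F4_S1", 1)
    founder("F4_D1", 2)
    founder("F4_D2", 2)
    child("F4_O1", "F4_S1", "F4_D1", int(rng.integers(1, 3)))
    child("F4_O2", "F4_S1", "F4_D2", int(rng.integers(1, 3)))
    return Pedigree(individuals=individuals, paternal_age=ages)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_lengths(rng: np.random.Generator, n: int, meanlog: float, sdlog: float,
                  lo: int, hi: int) -> np.ndarray:
    """Log-normal lengths truncated to [lo, hi] by rejection."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(meanlog, sdlog, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out).astype(np.int64)


def _mendelian_dosages(rng: np.random.Generator, pedigree: Pedigree,
                       founder_af: np.ndarray) -> np.ndarray:
    """True dosage matrix (n_sites x n_samples), Mendelian below founders."""
    samples = pedigree.samples
    col = {s: j for j, s in enumerate(samples)}
    n_sites = founder_af.size
    dosage = np.zeros((n_sites, len(samples)), dtype=np.int8)
    for ind in sorted(pedigree.individuals, key=lambda i: i.generation):
        j = col[ind.iid]
        if ind.sire is None and ind.dam is None:
            dosage[:, j] = rng.binomial(2, founder_af)
        else:
            for parent in (ind.sire, ind.dam):
                gamete = rng.random(n_sites) < dosage[:, col[parent]] / 2.0
                dosage[:, j] += gamete.astype(np.int8)
    return dosage


def _depth_means(svtype: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Expected depth fold-change by genotype: 1.0 for non-carriers, reduced
    for deletion carriers (0.5 het, 0.05 hom), elevated for duplication
    carriers (1.5 het, 2.0 hom)."""
    is_del = (svtype == "DEL")[:, None]
    means = np.ones_like(dosage, dtype=float)
    means[(dosage == 1) & is_del] = 0.5
    means[(dosage == 2) & is_del] = 0.05
    means[(dosage == 1) & ~is_del] = 1.5
    means[(dosage == 2) & ~is_del] = 2.0
    return means


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[CNVSite], Pedigree, TruthTable]:
    """Simulate a pedigreed CNV call-set with ground truth.

    Founder genotypes are Hardy-Weinberg draws from per-site allele
    frequencies; non-founder genotypes follow Mendelian transmission.  De
    novo CNVs are injected per trio at a Poisson rate of
    ``config.de_novo_rate`` transmissions, each appearing heterozygously in
    the proband only — except that an F1 proband's de novo events are passed
    to each of its own offspring with probability 1/2.  QUAL and per-sample
    depth fold-changes are generated conditional on the true genotype, with
    Gaussian noise truncated at zero.  Artifact sites (reference-individual,
    oversize, low-quality, Alu-window) are injected at the configured rates.
    """
    rng = np.random.default_rng(config.seed)
    pedigree = default_pedigree(rng, config.sire_age_range)
    if config.n_samples != len(pedigree.samples):
        raise ValueError(
            f"pedigree template yields {len(pedigree.samples)} samples, "
            f"config requests {config.n_samples}"
        )
    samples = pedigree.samples
    n = config.n_sites

    rates = config.artifact_rates.as_dict()
    classes = np.array(list(rates) + ["clean"])
    probs = np.array(list(rates.values()) + [1 - sum(rates.values())])
    site_class = rng.choice(classes, size=n, p=probs)
    svtype = np.where(rng.random(n) < config.deletion_fraction, "DEL", "DUP")

    lengths = np.empty(n, dtype=np.int64)
    for st, meanlog, sdlog in (
        ("DEL", config.del_length_meanlog, config.del_length_sdlog),
        ("DUP", config.dup_length_meanlog, config.dup_length_sdlog),
    ):
        mask = svtype == st
        lengths[mask] = _draw_lengths(
            rng, int(mask.sum()), meanlog, sdlog, config.length_min, config.length_max
        )
    alu_mask = site_class == "alu"
    lengths[alu_mask] = rng.integers(275, 326, int(alu_mask.sum()))
    over_mask = site_class == "oversize"
    lengths[over_mask] = rng.integers(
        config.length_max + 1, 4 * config.length_max, int(over_mask.sum())
    )

    chrom_names = list(config.chromosomes)
    chrom_sizes = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=chrom_sizes / chrom_sizes.sum())
    max_start = np.maximum(chrom_sizes[chrom_idx].astype(np.int64) - lengths, 1)
    starts = rng.integers(1, max_start + 1)

    qual = rng.uniform(*config.qual_range, n)
    lowq_mask = site_class == "low_quality"
    qual[lowq_mask] = rng.uniform(10, config.qual_range[0] - 0.1, int(lowq_mask.sum()))
    qual = np.round(qual, 1)

    af = rng.uniform(0, config.af_max, n) + 1e-9
    dosage = _mendelian_dosages(rng, pedigree, af)

    # resample monomorphic segregating sites: every call-set site is a call
    # in at least one sample
    for _ in range(1000):
        mono = np.flatnonzero((dosage.sum(axis=1) == 0) & (site_class != "reference"))
        if not mono.size:
            break
        dosage[mono] = _mendelian_dosages(rng, pedigree, af[mono])

    # reference-individual artifacts: carried by >= 31 of 32 samples
    ref_rows = np.flatnonzero(site_class == "reference")
    for i in ref_rows:
        n_car = int(rng.integers(config.n_samples - 1, config.n_samples + 1))
        carriers = rng.choice(config.n_samples, n_car, replace=False)
        dosage[i] = 0
        dosage[i, carriers] = np.where(rng.random(n_car) < 0.7, 1, 2)

    # de novo injection: new sites appended after the segregating ones
    dn_truth: list[DeNovoTruth] = []
    dn_rows: list[np.ndarray] = []
    dn_meta: list[tuple[str, int, int, float, str]] = []  # svtype, chrom_i, length, qual, class
    col = {s: j for j, s in enumerate(samples)}
    for trio in pedigree.trios:
        for _ in range(rng.poisson(config.de_novo_rate)):
            st = "DEL" if rng.random() < config.deletion_fraction else "DUP"
            meanlog, sdlog = (
                (config.del_length_meanlog, config.del_length_sdlog)
                if st == "DEL"
                else (config.dup_length_meanlog, config.dup_length_sdlog)
            )
            length = int(
                _draw_lengths(rng, 1, meanlog, sdlog, config.length_min, config.length_max)[0]
            )
            row = np.zeros(len(samples), dtype=np.int8)
            row[col[trio.proband]] = 1
            transmitted = []
            for kid in pedigree.offspring_of(trio.proband):
                if rng.random() < 0.5:
                    row[col[kid]] = 1
                    transmitted.append(kid)
            site_id = f"site{n + len(dn_rows):05d}"
            dn_truth.append(
                DeNovoTruth(site_id, trio.trio_id, trio.proband, SVType(st), tuple(transmitted))
            )
            dn_rows.append(row)
            ci = int(rng.integers(len(chrom_names)))
            dn_meta.append((st, ci, length, round(float(rng.uniform(*config.qual_range)), 1)))

    if dn_rows:
        dosage = np.vstack([dosage, np.array(dn_rows)])
        svtype = np.concatenate([svtype, [m[0] for m in dn_meta]])
        dn_chrom = np.array([m[1] for m in dn_meta])
        dn_len = np.array([m[2] for m in dn_meta], dtype=np.int64)
        chrom_idx = np.concatenate([chrom_idx, dn_chrom])
        lengths = np.concatenate([lengths, dn_len])
        dn_start = rng.integers(
            1, np.maximum(chrom_sizes[dn_chrom].astype(np.int64) - dn_len, 1) + 1
        )
        starts = np.concatenate([starts, dn_start])
        qual = np.concatenate([qual, [m[3] for m in dn_meta]])
        site_class = np.concatenate([site_class, ["de_novo"] * len(dn_rows)])
        af = np.concatenate([af, np.zeros(len(dn_rows))])

    total = dosage.shape[0]
    site_ids = np.array([f"site{i:05d}" for i in range(total)])

    means = _depth_means(svtype, dosage)
    fc_flank = np.maximum(rng.normal(means, config.depth_noise or 1e-12), 0.0)
    fc_gc = np.maximum(rng.normal(means, config.depth_noise or 1e-12), 0.0)

    sites: list[CNVSite] = []
    for i in range(total):
        genotypes = {s: _GT_FROM_DOSAGE[int(dosage[i, j])] for j, s in enumerate(samples)}
        sites.append(
            CNVSite(
                site_id=str(site_ids[i]),
                chrom=chrom_names[int(chrom_idx[i])],
                start=int(starts[i]),
                end=int(starts[i] + lengths[i] - 1),
                svtype=SVType(str(svtype[i])),
                qual=float(qual[i]),
                genotypes=genotypes,
                fold_change_flank={s: float(fc_flank[i, j]) for j, s in enumerate(samples)},
                fold_change_gc={s: float(fc_gc[i, j]) for j, s in enumerate(samples)},
                length=int(lengths[i]),
            )
        )

    truth_sites = pd.DataFrame(
        dict(
            site_id=site_ids,
            chrom=[chrom_names[int(c)] for c in chrom_idx],
            start=starts,
            length=lengths,
            svtype=svtype,
            site_class=site_class,
            allele_freq=af,
            qual=qual,
        )
    )
    truth = TruthTable(
        sites=truth_sites,
        genotypes=pd.DataFrame(dosage, index=site_ids, columns=samples),
        de_novo=dn_truth,
    )
    return sites, pedigree, truth


# ---------------------------------------------------------------------------
# Gene-model simulation
# ---------------------------------------------------------------------------


def simulate_gene_models(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GeneModel, pd.DataFrame]:
    """Simulate non-overlapping gene models plus a term-annotation table.

    Genes are placed without overlap on the configured chromosomes, each
    with 1-3 transcripts of 1-12 exons and a random strand.  The second
    return value maps invented functional terms to transcripts (columns
    ``term_id``, ``transcript_id``) for enrichment testing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chrom_names = list(config.chromosomes)
    genes, transcripts, exons = [], [], []
    n_per_chrom = np.bincount(
        rng.integers(0, len(chrom_names), config.n_genes), minlength=len(chrom_names)
    )
    tx_serial = ex_serial = 0
    for ci, chrom in enumerate(chrom_names):
        k = int(n_per_chrom[ci])
        if k == 0:
            continue
        L = config.chromosomes[chrom]
        gene_lens = rng.integers(2_000, 60_001, k)
        free = L - int(gene_lens.sum())
        if free <= k:
            raise ValueError(f"chromosome {chrom} too short for {k} non-overlapping genes")
        gaps = np.sort(rng.choice(free, k, replace=False))
        gstarts = gaps + np.concatenate([[0], np.cumsum(gene_lens[:-1])]) + 1
        for g in range(k):
            gid = f"gene_{chrom}_{g:04d}"
            gs, ge = int(gstarts[g]), int(gstarts[g] + gene_lens[g] - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(dict(gene_id=gid, chrom=chrom, start=gs, end=ge, strand=strand))
            for _ in range(int(rng.integers(1, 4))):
                tx_serial += 1
                tid = f"tx_{tx_serial:05d}"
                span = int(rng.integers(max((ge - gs) // 2, 200), ge - gs + 2))
                ts = int(rng.integers(gs, ge - span + 2))
                te = ts + span - 1
                transcripts.append(
                    dict(transcript_id=tid, gene_id=gid, chrom=chrom, start=ts, end=te,
                         biotype="protein_coding")
                )
                n_ex = int(rng.integers(1, 13))
                # 2*n_ex sorted breakpoints partition the transcript into
                # alternating exon/intron blocks starting and ending exonic
                cuts = np.sort(rng.choice(span, 2 * n_ex - 2, replace=False)) if n_ex > 1 else np.array([], int)
                bounds = np.concatenate([[0], cuts, [span - 1]])
                for x in range(n_ex):
                    ex_serial += 1
                    es = ts + int(bounds[2 * x])
                    ee = ts + int(bounds[2 * x + 1])
                    exons.append(
                        dict(exon_id=f"ex_{ex_serial:06d}", transcript_id=tid,
                             chrom=chrom, start=es, end=max(es, ee))
                    )
    model = GeneModel(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        transcripts=pd.DataFrame(
            transcripts,
            columns=["transcript_id", "gene_id", "chrom", "start", "end", "biotype"],
        ),
        exons=pd.DataFrame(exons, columns=["exon_id", "transcript_id", "chrom", "start", "end"]),
    )
    tx_ids = model.transcripts["transcript_id"].to_numpy()
    rows = []
    for t in range(config.n_terms if tx_ids.size else 0):
        size = 1 + rng.poisson(5)
        for tid in rng.choice(tx_ids, min(size, tx_ids.size), replace=False):
            rows.append(dict(term_id=f"term{t:03d}", transcript_id=str(tid)))
    terms = pd.DataFrame(rows, columns=["term_id", "transcript_id"])
    return model, terms


def write_truth_table(truth: TruthTable, path: str) -> None:
    """Tab-separated truth dump: site table, then genotypes, then de novos."""
    with open(path, "w") as fh:
        fh.write("#sites\n")
        truth.sites.to_csv(fh, sep="\t", index=False)
        fh.write("#genotypes\n")
        truth.genotypes.to_csv(fh, sep="\t", index_label="site_id")
        fh.write("#de_novo\n")
        fh.write("site_id\ttrio_id\tproband\tsvtype\ttransmitted_to\n")
        for dn in truth.de_novo:
            fh.write(
                f"{dn.site_id}\t{dn.trio_id}\t{dn.proband}\t{dn.svtype.value}\t"
                f"{','.join(dn.transmitted_to) or '.'}\n"
            )
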