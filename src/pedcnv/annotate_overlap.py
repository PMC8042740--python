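"""Interval-overlap accounting between CNVs and genic regions.

Three views of the same overlap relation are produced, mirroring the usual
reporting of genic impact in SV studies:

* region-centric — how many genes / transcripts / exons / 10 kb flanks are
  overlapped at least once, by CNV type and by overlap mode;
* CNV-centric — how many CNVs overlap at least one feature of each class;
* per-CNV averages — mean features hit per CNV, over all CNVs and
  conditional on hitting at least one.

Overlap modes: ``full`` means the feature is entirely contained within the
CNV interval; ``partial`` means the intersection is non-empty but not
containing.  For CNV-centric counts, a CNV's mode is ``full`` when it fully
contains at least one feature of the class.  For a feature overlapped by
several same-type CNVs in different modes, full takes precedence.  Overlap
requires at least one shared base; there is no reciprocal-overlap minimum.

In the absence of annotated regulatory regions, the 10 kb windows up- and
downstream of each gene (strand-aware) serve as regulatory proxies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CNVSite, GeneModel, SVType

FEATURE_CLASSES = ("gene", "transcript", "exon", "upstream10k", "downstream10k")
MODES = ("full", "partial")
DEFAULT_FLANK_BP = 10_000


@dataclass(frozen=True)
class OverlapRecord:
    site_id: str
    feature_id: str
    feature_class: str
    svtype: SVType
    mode: str  # 'full' | 'partial'


def classify_overlap(
    cnv: tuple[int, int],
    feature: tuple[int, int],
    cnv_chrom: str | None = None,
    feature_chrom: str | None = None,
) -> str:
    """'full' if feature within CNV, 'partial' if they share >= 1 base,
    else 'none'.  Intervals are 1-based inclusive; different chromosomes
    yield 'none'."""
    if cnv_chrom is not None and feature_chrom is not None and cnv_chrom != feature_chrom:
        return "none"
    cs, ce = cnv
    fs, fe = feature
    if fe < cs or fs > ce:
        return "none"
    if cs <= fs and fe <= ce:
        return "full"
    return "partial"


def flank_regions(
    gene_start: int,
    gene_end: int,
    strand: str,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_length: int | None = None,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """(upstream, downstream) windows of ``flank_bp`` adjacent to a gene.

    Upstream is 5' of the gene start respecting strand; windows are
    truncated at position 1 and at ``chrom_length`` and are ``None`` when
    fully truncated (gene abutting a chromosome end).
    """
    left = (max(1, gene_start - flank_bp), gene_start - 1) if gene_start > 1 else None
    right_end = gene_end + flank_bp if chrom_length is None else min(gene_end + flank_bp, chrom_length)
    right = (gene_end + 1, right_end) if right_end > gene_end else None
    if strand == "+":
        return left, right
    if strand == "-":
        return right, left
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def build_feature_table(
    model: GeneModel,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """All features as one table [feature_id, feature_class, chrom, start,
    end], with the two strand-aware flank proxies added per gene.
    Identifiers are deduplicated within each class."""
    frames = []
    for df, id_col, cls in (
        (model.genes, "gene_id", "gene"),
        (model.transcripts, "transcript_id", "transcript"),
        (model.exons, "exon_id", "exon"),
    ):
        if df.empty:
            continue
        sub = df.drop_duplicates(subset=id_col)[[id_col, "chrom", "start", "end"]].copy()
        sub.columns = ["feature_id", "chrom", "start", "end"]
        sub["feature_class"] = cls
        frames.append(sub)
    flank_rows = []
    for _, g in model.genes.drop_duplicates(subset="gene_id").iterrows():
        clen = (chrom_lengths or {}).get(g.chrom)
        up, down = flank_regions(int(g.start), int(g.end), g.strand, flank_bp, clen)
        if up is not None:
            flank_rows.append(
                dict(feature_id=f"{g.gene_id}:up", feature_class="upstream10k",
                     chrom=g.chrom, start=up[0], end=up[1])
            )
        if down is not None:
            flank_rows.append(
                dict(feature_id=f"{g.gene_id}:down", feature_class="downstream10k",
                     chrom=g.chrom, start=down[0], end=down[1])
            )
    if flank_rows:
        frames.append(pd.DataFrame(flank_rows))
    if not frames:
        return pd.DataFrame(columns=["feature_id", "feature_class", "chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)[
        ["feature_id", "feature_class", "chrom", "start", "end"]
    ]


@dataclass
class OverlapSummary:
    """The three tables plus the raw per-pair overlap records.

    ``region_centric`` and ``cnv_centric``: dict[(class, svtype, mode)] -> count.
    ``per_cnv_averages``: dict[(class, svtype, mode, scope)] -> mean, where
    mode includes 'all' (full+partial combined) and scope is 'all_cnvs' or
    'conditional' (CNVs with >= 1 overlap in that mode).
    """

    records: list[OverlapRecord]
    n_cnvs: dict[str, int]  # svtype -> number of CNVs in the call-set
    region_centric: dict = field(default_factory=dict)
    cnv_centric: dict = field(default_factory=dict)
    per_cnv_averages: dict = field(default_factory=dict)

    def table(self, which: str) -> pd.DataFrame:
        data = getattr(self, which)
        if which == "per_cnv_averages":
            rows = [
                dict(feature_class=k[0], svtype=k[1], mode=k[2], scope=k[3], mean=v)
                for k, v in sorted(data.items())
            ]
        else:
            rows = [
                dict(feature_class=k[0], svtype=k[1], mode=k[2], count=v)
                for k, v in sorted(data.items())
            ]
        return pd.DataFrame(rows)


def _collect_records(
    sites: list[CNVSite], features: pd.DataFrame
) -> list[OverlapRecord]:
    trees: dict[str, IntervalTree] = {}
    for row in features.itertuples(index=False):
        # half-open tree interval [start, end+1) encodes 1-based inclusive
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, (row.feature_id, row.feature_class, row.start, row.end)
        )
    records = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(site.start, site.end + 1):
            fid, fclass, fs, fe = hit.data
            mode = classify_overlap((site.start, site.end), (fs, fe))
            records.append(OverlapRecord(site.site_id, fid, fclass, site.svtype, mode))
    return records


def summarize_overlaps(
    sites: list[CNVSite],
    model: GeneModel,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: dict[str, int] | None = None,
    features: pd.DataFrame | None = None,
) -> OverlapSummary:
    """Compute all three overlap tables for a call-set against gene models.

    ``features`` may be passed directly (same columns as
    :func:`build_feature_table`) to annotate against an arbitrary region
    set.
    """
    if features is None:
        features = build_feature_table(model, flank_bp, chrom_lengths)
    records = _collect_records(sites, features)
    n_cnvs = {"DEL": 0, "DUP": 0}
    for s in sites:
        n_cnvs[s.svtype.value] += 1
    summary = OverlapSummary(records=records, n_cnvs=n_cnvs)

    # region-centric: one count per feature x svtype, full beats partial
    best_mode: dict[tuple[str, str, str], str] = {}
    for r in records:
        key = (r.feature_id, r.feature_class, r.svtype.value)
        if r.mode == "full" or key not in best_mode:
            best_mode[key] = r.mode
    for (fid, fclass, svt), mode in best_mode.items():
        k = (fclass, svt, mode)
        summary.region_centric[k] = summary.region_centric.get(k, 0) + 1

    # per-CNV per-class overlap counts by mode
    per_cnv: dict[tuple[str, str], dict[str, int]] = {}
    sv_of: dict[str, str] = {s.site_id: s.svtype.value for s in sites}
    for r in records:
        d = per_cnv.setdefault((r.site_id, r.feature_class), {"full": 0, "partial": 0})
        d[r.mode] += 1

    # cnv-centric: each CNV once per class; full if it contains >= 1 feature
    for (sid, fclass), d in per_cnv.items():
        mode = "full" if d["full"] > 0 else "partial"
        k = (fclass, sv_of[sid], mode)
        summary.cnv_centric[k] = summary.cnv_centric.get(k, 0) + 1

    # averages: over all CNVs of the type, and conditional on >= 1 overlap
    for fclass in FEATURE_CLASSES:
        for svt in ("DEL", "DUP"):
            counts = {
                mode: [
                    d["full"] + d["partial"] if mode == "all" else d[mode]
                    for (sid, fc), d in per_cnv.items()
                    if fc == fclass and sv_of[sid] == svt
                ]
                for mode in ("full", "partial", "all")
            }
            total = n_cnvs[svt]
            for mode, vals in counts.items():
                s = sum(vals)
                nonzero = [v for v in vals if v > 0]
                summary.per_cnv_averages[(fclass, svt, mode, "all_cnvs")] = (
                    s / total if total else math.nan
                )
                summary.per_cnv_averages[(fclass, svt, mode, "conditional")] = (
                    s / len(nonzero) if nonzero else math.nan
                )
    return summary


@dataclass
class RatioReport:
    """Deleted:duplicated ratios per feature class, region-centric.

    ``math.inf`` flags a class with zero duplicated features.  When a length
    cap is supplied, the same ratios restricted to CNVs no longer than the
    cap are included, along with the mean exons overlapped per
    exon-overlapping CNV under the cap.
    """

    ratios: dict[str, float]
    capped_ratios: dict[str, float] | None = None
    length_cap: int | None = None
    capped_mean_exons_per_cnv: float | None = None


def _region_ratios(summary: OverlapSummary) -> dict[str, float]:
    out = {}
    for fclass in FEATURE_CLASSES:
        dels = sum(summary.region_centric.get((fclass, "DEL", m), 0) for m in MODES)
        dups = sum(summary.region_centric.get((fclass, "DUP", m), 0) for m in MODES)
        out[fclass] = dels / dups if dups else (math.inf if dels else math.nan)
    return out


def exon_ratio_and_restrictions(
    sites: list[CNVSite],
    model: GeneModel,
    length_cap: int | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> RatioReport:
    """Region-centric del:dup ratios per class, optionally restricted to
    CNVs at most ``length_cap`` bp long (e.g. 25 kb, below which single-gene
    impact dominates)."""
    summary = summarize_overlaps(sites, model, flank_bp, chrom_lengths)
    report = RatioReport(ratios=_region_ratios(summary), length_cap=length_cap)
    if length_cap is not None:
        short = [s for s in sites if s.length <= length_cap]
        capped = summarize_overlaps(short, model, flank_bp, chrom_lengths)
        report.capped_ratios = _region_ratios(capped)
        # mean exons per exon-overlapping CNV under the cap
        per_cnv_ex: dict[str, int] = {}
        for r in capped.records:
            if r.feature_class == "exon":
                per_cnv_ex[r.site_id] = per_cnv_ex.get(r.site_id, 0) + 1
        report.capped_mean_exons_per_cnv = (
            sum(per_cnv_ex.values()) / len(per_cnv_ex) if per_cnv_ex else math.nan
        )
    return report
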