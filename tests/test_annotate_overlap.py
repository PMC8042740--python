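"""Overlap classification, flank geometry, and summary-table semantics,
including equivalence with an all-pairs brute-force scan."""

import math

import pandas as pd
import pytest

from pedcnv.annotate_overlap import (
    build_feature_table,
    classify_overlap,
    exon_ratio_and_restrictions,
    flank_regions,
    summarize_overlaps,
)
from pedcnv.io_formats import GeneModel
from pedcnv.simgen import SimConfig, simulate_cohort, simulate_gene_models

from conftest import make_site


class TestClassify:
    @pytest.mark.parametrize(
        "cnv,feat,expected",
        [
            ((100, 500), (200, 300), "full"),
            ((100, 500), (450, 600), "partial"),
            ((100, 500), (501, 600), "none"),  # inclusive coords do not touch
            ((100, 500), (100, 500), "full"),
            ((100, 500), (50, 600), "partial"),  # CNV inside feature
            ((100, 500), (500, 500), "full"),
            ((100, 500), (1, 99), "none"),
        ],
    )
    def test_modes(self, cnv, feat, expected):
        assert classify_overlap(cnv, feat) == expected

    def test_different_chromosomes_are_disjoint(self):
        assert classify_overlap((1, 10), (1, 10), "chr1", "chr2") == "none"


class TestFlanks:
    def test_plus_strand(self):
        up, down = flank_regions(10_000, 20_000, "+")
        assert up == (1, 9_999)  # truncated at chromosome start
        assert down == (20_001, 30_000)

    def test_minus_strand_mirror(self):
        up, down = flank_regions(10_000, 20_000, "-")
        assert up == (20_001, 30_000)
        assert down == (1, 9_999)

    def test_gene_at_chromosome_start(self):
        up, down = flank_regions(1, 5_000, "+")
        assert up is None
        assert down == (5_001, 15_000)

    def test_truncation_at_chromosome_end(self):
        up, down = flank_regions(90_000, 99_000, "+", chrom_length=100_000)
        assert down == (99_001, 100_000)

    def test_flank_strand_swap_on_callset(self):
        """Reversing a gene's strand swaps its upstream/downstream overlap
        counts on the same call-set."""
        def model_with_strand(strand):
            return GeneModel(
                genes=pd.DataFrame(
                    [dict(gene_id="g", chrom="chr1", start=50_000, end=60_000, strand=strand)]
                ),
                transcripts=GeneModel.empty().transcripts,
                exons=GeneModel.empty().exons,
            )

        # CNV engulfing the region left of the gene only
        site = make_site("left", start=39_000, length=12_001)  # ends at 51,000
        fwd = summarize_overlaps([site], model_with_strand("+"))
        rev = summarize_overlaps([site], model_with_strand("-"))
        assert fwd.region_centric.get(("upstream10k", "DEL", "full"), 0) == 1
        assert rev.region_centric.get(("downstream10k", "DEL", "full"), 0) == 1
        assert ("upstream10k", "DEL", "full") not in rev.region_centric
        assert ("downstream10k", "DEL", "full") not in fwd.region_centric


def _toy_model():
    """One gene, one transcript, two exons, all within one deletion."""
    return GeneModel(
        genes=pd.DataFrame(
            [dict(gene_id="g1", chrom="chr1", start=20_000, end=30_000, strand="+")]
        ),
        transcripts=pd.DataFrame(
            [dict(transcript_id="t1", gene_id="g1", chrom="chr1", start=20_000,
                  end=30_000, biotype="protein_coding")]
        ),
        exons=pd.DataFrame(
            [
                dict(exon_id="e1", transcript_id="t1", chrom="chr1", start=21_000, end=21_500),
                dict(exon_id="e2", transcript_id="t1", chrom="chr1", start=28_000, end=28_400),
            ]
        ),
    )


class TestSummaries:
    def test_full_containment_counts(self):
        cnv = make_site("big", "DEL", start=15_000, length=20_000)  # spans the gene
        s = summarize_overlaps([cnv], _toy_model())
        assert s.region_centric[("exon", "DEL", "full")] == 2
        assert s.cnv_centric[("exon", "DEL", "full")] == 1
        assert s.per_cnv_averages[("exon", "DEL", "all", "conditional")] == 2.0
        assert s.per_cnv_averages[("exon", "DEL", "all", "all_cnvs")] == 2.0

    def test_empty_callset_all_zero(self):
        s = summarize_overlaps([], _toy_model())
        assert s.region_centric == {} and s.cnv_centric == {}
        assert math.isnan(s.per_cnv_averages[("exon", "DEL", "all", "all_cnvs")])

    def test_full_precedence_over_partial_per_feature(self):
        """A feature hit fully by one DEL and partially by another counts
        once, under full."""
        model = _toy_model()
        full_cnv = make_site("f", "DEL", start=20_500, length=1_500)  # contains e1
        part_cnv = make_site("p", "DEL", start=21_300, length=300)  # partial e1
        s = summarize_overlaps([full_cnv, part_cnv], model)
        assert s.region_centric[("exon", "DEL", "full")] == 1
        assert ("exon", "DEL", "partial") not in s.region_centric
        # cnv-centric: each CNV counted under its own mode
        assert s.cnv_centric[("exon", "DEL", "full")] == 1
        assert s.cnv_centric[("exon", "DEL", "partial")] == 1

    def test_conditional_average_at_least_unconditional(self):
        sites, _, _ = simulate_cohort(SimConfig(seed=21, n_sites=150))
        model, _ = simulate_gene_models(SimConfig(seed=22, n_genes=120))
        s = summarize_overlaps(sites, model)
        for (fclass, svt, mode, scope), val in s.per_cnv_averages.items():
            if scope == "conditional" and not math.isnan(val):
                assert val >= s.per_cnv_averages[(fclass, svt, mode, "all_cnvs")]

    def test_count_bounds(self):
        sites, _, _ = simulate_cohort(SimConfig(seed=23, n_sites=150))
        model, _ = simulate_gene_models(SimConfig(seed=24, n_genes=120))
        s = summarize_overlaps(sites, model)
        n_cnvs = len(sites)
        features = build_feature_table(model)
        n_features = features.groupby("feature_class").size().to_dict()
        for fclass in n_features:
            cnv_total = sum(
                s.cnv_centric.get((fclass, svt, m), 0)
                for svt in ("DEL", "DUP") for m in ("full", "partial")
            )
            assert cnv_total <= n_cnvs
            region_total = sum(
                s.region_centric.get((fclass, svt, m), 0)
                for svt in ("DEL", "DUP") for m in ("full", "partial")
            )
            assert region_total <= 2 * n_features[fclass]


def brute_force_summary(sites, features):
    """Independent all-pairs recomputation of the three summary views."""
    records = {}
    for site in sites:
        for row in features.itertuples(index=False):
            mode = classify_overlap(
                (site.start, site.end), (row.start, row.end), site.chrom, row.chrom
            )
            if mode != "none":
                records[(site.site_id, row.feature_id, row.feature_class)] = (
                    site.svtype.value, mode,
                )
    region, cnvc = {}, {}
    best = {}
    for (sid, fid, fclass), (svt, mode) in records.items():
        k = (fid, fclass, svt)
        if best.get(k) != "full":
            best[k] = mode if k not in best or mode == "full" else best[k]
    for (fid, fclass, svt), mode in best.items():
        region[(fclass, svt, mode)] = region.get((fclass, svt, mode), 0) + 1
    per_cnv = {}
    for (sid, fid, fclass), (svt, mode) in records.items():
        d = per_cnv.setdefault((sid, fclass, svt), {"full": 0, "partial": 0})
        d[mode] += 1
    for (sid, fclass, svt), d in per_cnv.items():
        mode = "full" if d["full"] else "partial"
        cnvc[(fclass, svt, mode)] = cnvc.get((fclass, svt, mode), 0) + 1
    return region, cnvc, per_cnv


def test_indexed_summary_equals_brute_force():
    sites, _, _ = simulate_cohort(SimConfig(seed=31, n_sites=200))
    model, _ = simulate_gene_models(SimConfig(seed=32, n_genes=60))
    features = build_feature_table(model)
    s = summarize_overlaps(sites, model)
    region, cnvc, per_cnv = brute_force_summary(sites, features)
    assert s.region_centric == region
    assert s.cnv_centric == cnvc
    # averages: recompute one cell independently
    exon_del = [d["full"] + d["partial"] for (sid, fc, svt), d in per_cnv.items()
                if fc == "exon" and svt == "DEL"]
    n_del = sum(1 for x in sites if x.svtype.value == "DEL")
    if exon_del:
        assert s.per_cnv_averages[("exon", "DEL", "all", "all_cnvs")] == pytest.approx(
            sum(exon_del) / n_del
        )
        assert s.per_cnv_averages[("exon", "DEL", "all", "conditional")] == pytest.approx(
            sum(exon_del) / len(exon_del)
        )


class TestRatios:
    def test_all_deletion_callset_flagged_infinite(self):
        cnv = make_site("d", "DEL", start=15_000, length=20_000)
        report = exon_ratio_and_restrictions([cnv], _toy_model())
        assert math.isinf(report.ratios["exon"])

    def test_length_cap_restricts(self):
        model = _toy_model()
        long_cnv = make_site("long", "DEL", start=15_000, length=30_000)
        short_cnv = make_site("short", "DUP", start=21_100, length=200, fc=1.6)
        report = exon_ratio_and_restrictions([long_cnv, short_cnv], model, length_cap=25_000)
        # unrestricted: DEL hits 2 exons (region), DUP partially hits e1
        assert report.ratios["exon"] == pytest.approx(2 / 1)
        # capped: only the short DUP remains; its e1 overlap is partial
        assert report.capped_ratios["exon"] == 0.0
        assert report.capped_mean_exons_per_cnv == pytest.approx(1.0)
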