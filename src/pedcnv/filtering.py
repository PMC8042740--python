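"""The six-rule CNV filter cascade with event- and site-level accounting.

Rules are applied sequentially, in the order the call-set was curated:

1. ``carrier_count`` — remove sites present (non-reference genotype) in at
   least ``cohort_size - 1`` individuals: almost-universal calls are most
   likely variants carried by the reference individual, or misassemblies.
2. ``max_length`` — remove sites longer than 100 kb.
3. ``min_qual`` — remove sites with QUAL below 100.
4. ``del_foldchange`` — retain a deletion only if the carriers' depth
   fold-change versus the flanking regions is below 0.7.
5. ``dup_foldchange`` — retain a duplication only if the carriers' depth
   fold-change versus similar-GC bins is above 1.3.
6. ``alu_window`` — remove sites 275-325 bp long, the typical span of an
   Alu element, to purge unannotated mobile-element calls.

A site removed at a rule takes all of its remaining events with it; the
report reconciles exactly (input = output + removals, for events and sites
separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .io_formats import CNVSite, SVType

logger = logging.getLogger("pedcnv")

RULE_ORDER = (
    "carrier_count",
    "max_length",
    "min_qual",
    "del_foldchange",
    "dup_foldchange",
    "alu_window",
)


@dataclass
class FilterParams:
    """Thresholds of the cascade; defaults are the curated call-set's values.

    ``aggregate`` controls how per-carrier fold-change values become one
    site-level value for rules 4-5: ``median`` (default) or ``mean`` of the
    carriers, or ``all`` (every carrier must individually pass).
    ``missing_policy`` decides the fate of a site lacking the fold-change
    annotation its type's rule needs: ``remove`` (default, counted under
    that rule) or ``keep``.
    """

    max_carrier_samples: int | None = None  # default: cohort_size - 1
    max_length: int = 100_000
    min_qual: float = 100.0
    del_foldchange_max: float = 0.7
    dup_foldchange_min: float = 1.3
    alu_window: tuple[int, int] = (275, 325)
    aggregate: str = "median"
    missing_policy: str = "remove"

    def __post_init__(self) -> None:
        if self.alu_window[0] > self.alu_window[1]:
            raise ValueError("alu_window low bound exceeds high bound")
        if self.aggregate not in ("median", "mean", "all"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.missing_policy not in ("remove", "keep"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class FilterReport:
    """Per-rule removal accounting, in application order."""

    input_events: int
    input_sites: int
    removed: list[dict] = field(default_factory=list)  # rule, events, sites
    output_events: int = 0
    output_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = self.removed + [
            dict(rule="TOTAL_REMOVED",
                 events=sum(r["events"] for r in self.removed),
                 sites=sum(r["sites"] for r in self.removed)),
            dict(rule="RETAINED", events=self.output_events, sites=self.output_sites),
        ]
        return pd.DataFrame(rows, columns=["rule", "events", "sites"])

    def is_conserved(self) -> bool:
        return (
            self.input_events == self.output_events + sum(r["events"] for r in self.removed)
            and self.input_sites == self.output_sites + sum(r["sites"] for r in self.removed)
        )


def count_events_sites(sites: list[CNVSite]) -> tuple[int, int]:
    """(n_events, n_sites): an event is one non-reference genotype at one
    site in one sample; a site is one record."""
    return sum(len(s.carriers()) for s in sites), len(sites)


def _site_foldchange_fails(site: CNVSite, params: FilterParams) -> bool:
    """True if the depth-support retention criterion for the site's type
    does not hold (the site should be removed)."""
    values_map = (
        site.fold_change_flank if site.svtype is SVType.DEL else site.fold_change_gc
    )
    vals = [values_map[s] for s in site.carriers() if s in values_map]
    if not vals:
        return params.missing_policy == "remove"

    def passes(v: float) -> bool:
        if site.svtype is SVType.DEL:
            return v < params.del_foldchange_max
        return v > params.dup_foldchange_min

    if params.aggregate == "all":
        return not all(passes(v) for v in vals)
    agg = median(vals) if params.aggregate == "median" else sum(vals) / len(vals)
    return not passes(agg)


def _rule_predicate(rule: str, site: CNVSite, params: FilterParams, max_carriers: int) -> bool:
    """True if ``rule`` removes ``site``."""
    if rule == "carrier_count":
        return len(site.carriers()) >= max_carriers
    if rule == "max_length":
        return site.length > params.max_length
    if rule == "min_qual":
        return site.qual < params.min_qual
    if rule == "del_foldchange":
        return site.svtype is SVType.DEL and _site_foldchange_fails(site, params)
    if rule == "dup_foldchange":
        return site.svtype is SVType.DUP and _site_foldchange_fails(site, params)
    if rule == "alu_window":
        return params.alu_window[0] <= site.length <= params.alu_window[1]
    raise ValueError(f"unknown filter rule {rule!r}")


def apply_filter_cascade(
    sites: list[CNVSite],
    cohort_size: int,
    params: FilterParams | None = None,
    order: tuple[str, ...] = RULE_ORDER,
) -> tuple[list[CNVSite], FilterReport]:
    """Run the cascade; returns (retained sites, per-rule report).

    ``order`` may permute the rules (every rule name must appear exactly
    once) to measure order sensitivity; the default is the curated order.
    """
    params = params or FilterParams()
    if sorted(order) != sorted(RULE_ORDER):
        raise ValueError(f"order must be a permutation of {RULE_ORDER}")
    max_carriers = (
        params.max_carrier_samples
        if params.max_carrier_samples is not None
        else cohort_size - 1
    )
    n_events, n_sites = count_events_sites(sites)
    report = FilterReport(input_events=n_events, input_sites=n_sites)
    current = list(sites)
    for rule in order:
        kept, dropped_events, dropped_sites = [], 0, 0
        for site in current:
            if _rule_predicate(rule, site, params, max_carriers):
                dropped_sites += 1
                dropped_events += len(site.carriers())
            else:
                kept.append(site)
        report.removed.append(dict(rule=rule, events=dropped_events, sites=dropped_sites))
        current = kept
    report.output_events, report.output_sites = count_events_sites(current)
    logger.info(
        "filter cascade: %d events at %d sites -> %d events at %d sites",
        n_events, n_sites, report.output_events, report.output_sites,
    )
    return current, report


def prune_nearby_sites(sites: list[CNVSite], window: int = 100) -> list[CNVSite]:
    """Optional pre-cascade pruning: among sites whose start positions fall
    within ``window`` bp of each other on a chromosome (transitively
    chained), keep only the highest-QUAL site; QUAL ties break to the
    leftmost start, then lexicographic id.  Output preserves input order."""
    by_chrom: dict[str, list[CNVSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    keep_ids: set[str] = set()
    for chrom_sites in by_chrom.values():
        ordered = sorted(chrom_sites, key=lambda s: (s.start, s.site_id))
        cluster: list[CNVSite] = []
        for s in ordered:
            if cluster and s.start - cluster[-1].start > window:
                best = max(cluster, key=lambda c: (c.qual, -c.start, c.site_id))
                keep_ids.add(best.site_id)
                cluster = []
            cluster.append(s)
        if cluster:
            best = max(cluster, key=lambda c: (c.qual, -c.start, c.site_id))
            keep_ids.add(best.site_id)
    return [s for s in sites if s.site_id in keep_ids]
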