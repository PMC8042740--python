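"""Trio-based de novo CNV identification and mutation-rate estimation.

A de novo call requires the proband heterozygous, both parents homozygous
reference, and every other cohort member homozygous reference — with one
exception: an F1 proband (an offspring that is itself a parent) transmits
each of its de novo variants to its own offspring with probability 1/2, so
the proband's own children are allowed to carry the variant.

The per-generation haploid mutation rate is the mean number of de novo
transmissions across trios divided by two; its 95% confidence interval uses
the normal critical value 1.96 on the standard error of the per-trio counts
(sample standard deviation over the square root of the number of trios),
scaled to the haploid rate the same way and floored at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import CNVSite, Genotype, Pedigree, SVType

logger = logging.getLogger("pedcnv")

POLICIES = ("strict", "parent-missing-tolerant")


@dataclass(frozen=True)
class DeNovoCall:
    """One de novo CNV in one trio's proband.

    ``passed_f1_check`` is True when the uniqueness requirement was
    satisfied only through the F1 allowance, i.e. at least one of the
    proband's own offspring carries the variant.
    """

    site_id: str
    trio_id: str
    proband: str
    svtype: SVType
    passed_f1_check: bool = False


@dataclass
class RateEstimate:
    """Haploid per-generation de novo CNV rate with a 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    per_trio_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("confidence interval must contain the point estimate")


def find_denovo(
    sites: list[CNVSite],
    pedigree: Pedigree,
    policy: str = "strict",
) -> list[DeNovoCall]:
    """Scan a (filtered) call-set for de novo CNVs across all trios.

    Under the default ``strict`` policy a site with a missing genotype in
    any trio member is skipped for that trio; under
    ``parent-missing-tolerant`` a missing parental genotype is treated as
    compatible with homozygous reference (the proband must still be a
    called heterozygote).  Cohort members outside the trio disqualify a
    candidate only by carrying the variant; a missing genotype elsewhere is
    not evidence of carriage.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    calls: list[DeNovoCall] = []
    trios = pedigree.trios
    offspring = {t.proband: set(pedigree.offspring_of(t.proband)) for t in trios}
    for site in sites:
        carriers = set(site.carriers())
        if not carriers:
            continue
        for trio in trios:
            gt_child = site.genotypes.get(trio.proband, Genotype.MISSING)
            gt_sire = site.genotypes.get(trio.sire, Genotype.MISSING)
            gt_dam = site.genotypes.get(trio.dam, Genotype.MISSING)
            if gt_child is not Genotype.HET:  # hom-alt probands excluded
                continue
            if policy == "strict":
                if Genotype.MISSING in (gt_sire, gt_dam):
                    continue
                if gt_sire is not Genotype.HOM_REF or gt_dam is not Genotype.HOM_REF:
                    continue
            else:
                if any(g.is_carrier for g in (gt_sire, gt_dam)):
                    continue
            others = carriers - {trio.proband}
            allowed = offspring[trio.proband]
            if others - allowed:
                continue
            calls.append(
                DeNovoCall(
                    site_id=site.site_id,
                    trio_id=trio.trio_id,
                    proband=trio.proband,
                    svtype=site.svtype,
                    passed_f1_check=bool(others),
                )
            )
    logger.info("de novo scan: %d calls across %d trios", len(calls), len(trios))
    return calls


def per_trio_counts(calls: list[DeNovoCall], pedigree: Pedigree) -> dict[str, int]:
    """De novo transmissions per trio, including zero-count trios."""
    counts = {t.trio_id: 0 for t in pedigree.trios}
    for call in calls:
        counts[call.trio_id] += 1
    return counts


def estimate_rate(counts: dict[str, int] | list[int]) -> RateEstimate:
    """Haploid per-generation rate from per-trio transmission counts.

    rate = mean(counts) / 2; 95% CI = rate +/- 1.96 * sd(counts) / sqrt(n) / 2
    with the sample (n-1) standard deviation, lower bound floored at zero.
    Raises on fewer than two trios (the interval is undefined).
    """
    if isinstance(counts, dict):
        mapping = dict(counts)
    else:
        mapping = {f"trio{i}": c for i, c in enumerate(counts)}
    values = np.asarray(list(mapping.values()), dtype=float)
    if values.size < 2:
        raise ValueError("rate CI requires at least two trios")
    rate = float(values.mean()) / 2.0
    half_width = 1.96 * float(values.std(ddof=1)) / math.sqrt(values.size) / 2.0
    return RateEstimate(
        rate=rate,
        ci_low=max(rate - half_width, 0.0),
        ci_high=rate + half_width,
        per_trio_counts={k: int(v) for k, v in mapping.items()},
    )
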