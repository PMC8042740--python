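"""Ratio and distribution statistics for CNV call-sets.

Covers the deletion/duplication ratio at any scope, the 2x2 chi-squared
contrast with Yates continuity correction, the two-sample
Kolmogorov-Smirnov comparison of length distributions (with the Alu-length
window excluded by default), Fisher exact term enrichment with
Benjamini-Hochberg FDR control, and the contrast of polymorphic
deletion/duplication counts against fixed gene loss/gain counts between
species.

The continuity-corrected statistic is the classic

    chi2 = n * (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))

with the correction clamped to zero when |ad - bc| < n/2, and the p-value
from the upper tail of chi-squared with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CNVSite, SVType

DEFAULT_ALU_WINDOW = (275, 325)


@dataclass
class ContingencyResult:
    table: tuple[tuple[float, float], tuple[float, float]]
    chi2: float
    df: int
    p_value: float


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


def yates_chi2(table, correction: bool = True) -> ContingencyResult:
    """2x2 chi-squared test, with Yates continuity correction by default.

    Raises on a zero row or column margin (the statistic is undefined).
    Without correction this reduces to the classic Pearson formula.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    (a, b), (c, d) = t
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-squared undefined")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / math.prod(margins)
    return ContingencyResult(
        table=((a, b), (c, d)),
        chi2=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


def del_dup_ratio(n_del: float, n_dup: float) -> float:
    """Deletions over duplications; ``inf`` flags zero duplications."""
    if n_dup == 0:
        return math.inf if n_del > 0 else math.nan
    return n_del / n_dup


def callset_del_dup_counts(sites: list[CNVSite]) -> tuple[int, int]:
    """(n_del_sites, n_dup_sites) of a call-set."""
    n_del = sum(1 for s in sites if s.svtype is SVType.DEL)
    return n_del, len(sites) - n_del


def deletion_fraction(sites: list[CNVSite]) -> float:
    n_del, n_dup = callset_del_dup_counts(sites)
    if n_del + n_dup == 0:
        return math.nan
    return n_del / (n_del + n_dup)


def ks_length_test(
    lengths_a,
    lengths_b,
    exclusion_window: tuple[int, int] | None = DEFAULT_ALU_WINDOW,
) -> KSResult:
    """Two-sample KS comparison of CNV length distributions.

    Lengths inside ``exclusion_window`` (default the 275-325 bp Alu span)
    are dropped from both samples first; pass ``None`` to compare the raw
    sets.  Raises if either sample is empty after exclusion.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if exclusion_window is not None:
        lo, hi = exclusion_window
        a = a[(a < lo) | (a > hi)]
        b = b[(b < lo) | (b > hi)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample after applying the exclusion window")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=a.size,
        n2=b.size,
    )


@dataclass
class EnrichmentResult:
    """Per-term Fisher results; ``table`` columns: term_id, n_overlap_term,
    n_overlap_other, n_rest_term, n_rest_other, odds_ratio, p_value,
    q_value, significant."""

    table: pd.DataFrame
    fdr: float

    @property
    def significant_terms(self) -> list[str]:
        return self.table.loc[self.table.significant, "term_id"].tolist()


def fisher_enrichment(
    term_annotations: pd.DataFrame,
    overlapped: set[str],
    universe: set[str],
    fdr: float = 0.01,
) -> EnrichmentResult:
    """Term enrichment among CNV-overlapped transcripts.

    ``term_annotations`` has columns ``term_id`` and ``transcript_id``.
    Each term gets a two-sided Fisher exact test on the 2x2 of
    {overlapped, not-overlapped} x {annotated, not-annotated} over the
    ``universe``, then Benjamini-Hochberg adjustment; terms with q <= fdr
    are flagged.
    """
    if not universe:
        raise ValueError("empty transcript universe")
    if not overlapped <= universe:
        raise ValueError("overlapped set must be a subset of the universe")
    rows = []
    by_term = term_annotations.groupby("term_id")["transcript_id"]
    for term, members in by_term:
        mem = set(members) & universe
        if not mem:
            continue
        a = len(mem & overlapped)
        b = len(overlapped) - a
        c = len(mem) - a
        d = len(universe) - len(overlapped) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            dict(term_id=term, n_overlap_term=a, n_overlap_other=b,
                 n_rest_term=c, n_rest_other=d, odds_ratio=odds, p_value=p)
        )
    df = pd.DataFrame(
        rows,
        columns=["term_id", "n_overlap_term", "n_overlap_other", "n_rest_term",
                 "n_rest_other", "odds_ratio", "p_value"],
    )
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return EnrichmentResult(table=df, fdr=fdr)
    reject, q, _, _ = multipletests(df.p_value.to_numpy(), alpha=fdr, method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df.q_value <= fdr
    return EnrichmentResult(table=df.sort_values("q_value", ignore_index=True), fdr=fdr)


@dataclass
class PolymorphicFixedResult:
    """Contrast of within-species polymorphic del/dup counts against
    between-species fixed gene loss/gain counts."""

    polymorphic_ratio: float  # del : dup among segregating CNVs
    fixed_ratio: float  # loss : gain among fixed changes
    contingency: ContingencyResult


def polymorphic_vs_fixed(
    poly_del: int, poly_dup: int, fixed_loss: int, fixed_gain: int
) -> PolymorphicFixedResult:
    """Both ratios plus the Yates chi-squared on the 2x2
    [[poly_del, poly_dup], [fixed_loss, fixed_gain]]."""
    if min(poly_del, poly_dup, fixed_loss, fixed_gain) < 0:
        raise ValueError("counts must be non-negative")
    result = yates_chi2([[poly_del, poly_dup], [fixed_loss, fixed_gain]])
    return PolymorphicFixedResult(
        polymorphic_ratio=del_dup_ratio(poly_del, poly_dup),
        fixed_ratio=del_dup_ratio(fixed_loss, fixed_gain),
        contingency=result,
    )
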