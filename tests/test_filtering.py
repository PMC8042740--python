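"""Filter cascade: engineered per-rule fixture, conservation, idempotence,
rule ordering, and the optional nearby-site pruning."""

import pytest
from hypothesis import given, settings, strategies as st

from pedcnv.filtering import (
    FilterParams,
    RULE_ORDER,
    apply_filter_cascade,
    count_events_sites,
    prune_nearby_sites,
)
from pedcnv.simgen import SimConfig, simulate_cohort

from conftest import SAMPLES, make_site


def engineered_callset():
    """10 sites: one designed violation per rule, four clean."""
    many = tuple(SAMPLES[:31])
    return [
        make_site("clean_del1", "DEL", length=500, qual=200, carriers=("s01", "s02")),
        make_site("viol_carrier", "DEL", length=500, qual=200, carriers=many),
        make_site("viol_length", "DEL", length=150_000, qual=200, carriers=("s01",)),
        make_site("clean_dup1", "DUP", length=2_000, qual=300, carriers=("s03",)),
        make_site("viol_qual", "DEL", length=500, qual=50, carriers=("s01",)),
        make_site("viol_delfc", "DEL", length=500, qual=200, carriers=("s02",), fc=0.9),
        make_site("clean_del2", "DEL", length=5_000, qual=150, carriers=("s04", "s05")),
        make_site("viol_dupfc", "DUP", length=2_000, qual=300, carriers=("s06",), fc=1.1),
        make_site("viol_alu", "DEL", length=300, qual=250, carriers=("s07",), fc=0.4),
        make_site("clean_dup2", "DUP", length=900, qual=500, carriers=("s08", "s09")),
    ]


class TestCascadeFixture:
    def test_one_removal_per_rule_four_survivors(self):
        kept, report = apply_filter_cascade(engineered_callset(), cohort_size=32)
        assert {s.site_id for s in kept} == {
            "clean_del1", "clean_dup1", "clean_del2", "clean_dup2"
        }
        assert [r["sites"] for r in report.removed] == [1, 1, 1, 1, 1, 1]
        assert [r["rule"] for r in report.removed] == list(RULE_ORDER)
        assert report.is_conserved()

    def test_site_carried_by_31_of_32_removed_by_rule1(self):
        site = make_site("near_universal", "DEL", carriers=tuple(SAMPLES[:20]),
                         hom_carriers=tuple(SAMPLES[20:31]))
        kept, report = apply_filter_cascade([site], cohort_size=32)
        assert kept == []
        assert report.removed[0] == dict(rule="carrier_count", events=31, sites=1)

    def test_alu_window_removes_otherwise_clean_site(self):
        """A 300 bp deletion passing every depth/quality rule still falls to
        the Alu-window rule."""
        site = make_site("alu300", "DEL", length=300, qual=250, carriers=("s01",), fc=0.4)
        kept, report = apply_filter_cascade([site], cohort_size=32)
        assert kept == []
        removals = {r["rule"]: r["sites"] for r in report.removed}
        assert removals["alu_window"] == 1
        assert sum(removals.values()) == 1

    def test_alu_window_bounds_inclusive(self):
        for length, removed in [(274, False), (275, True), (325, True), (326, False)]:
            site = make_site(f"len{length}", "DEL", length=length, qual=250, carriers=("s01",))
            kept, _ = apply_filter_cascade([site], cohort_size=32)
            assert (kept == []) is removed


class TestCascadeProperties:
    def test_conservation_and_idempotence_on_synthetic_cohort(self):
        sites, pedigree, _ = simulate_cohort(SimConfig(seed=13, n_sites=1000))
        kept, report = apply_filter_cascade(sites, len(pedigree.samples))
        assert report.is_conserved()
        ev_in, si_in = count_events_sites(sites)
        assert (report.input_events, report.input_sites) == (ev_in, si_in)
        # idempotence: the cascade removes nothing from its own output
        again, report2 = apply_filter_cascade(kept, len(pedigree.samples))
        assert [s.site_id for s in again] == [s.site_id for s in kept]
        assert all(r["sites"] == 0 and r["events"] == 0 for r in report2.removed)

    def test_any_rule_order_conserves(self):
        callset = engineered_callset()
        order = ("alu_window", "dup_foldchange", "del_foldchange", "min_qual",
                 "max_length", "carrier_count")
        kept, report = apply_filter_cascade(callset, 32, order=order)
        assert report.is_conserved()
        assert [r["rule"] for r in report.removed] == list(order)
        # the engineered violations are disjoint, so survivors are identical
        assert {s.site_id for s in kept} == {
            "clean_del1", "clean_dup1", "clean_del2", "clean_dup2"
        }

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError):
            apply_filter_cascade([], 32, order=("min_qual",))

    def test_missing_foldchange_policy(self):
        site = make_site("nofc", "DEL", length=500, qual=200, carriers=("s01",))
        site.fold_change_flank = {}
        kept, report = apply_filter_cascade([site], 32)
        assert kept == []  # default: remove, counted under the DEL rule
        assert report.removed[3]["sites"] == 1
        kept, _ = apply_filter_cascade(
            [site], 32, FilterParams(missing_policy="keep")
        )
        assert len(kept) == 1

    def test_aggregate_modes(self):
        site = make_site("mixed", "DEL", length=500, qual=200, carriers=("s01", "s02", "s03"))
        site.fold_change_flank.update({"s01": 0.2, "s02": 0.3, "s03": 0.9})
        kept, _ = apply_filter_cascade([site], 32, FilterParams(aggregate="median"))
        assert len(kept) == 1  # median 0.3 < 0.7
        kept, _ = apply_filter_cascade([site], 32, FilterParams(aggregate="all"))
        assert kept == []  # s03 fails individually


@given(
    n_carriers=st.integers(0, 32),
    length=st.integers(40, 200_000),
    qual=st.floats(0, 3000, allow_nan=False),
    is_del=st.booleans(),
    fc=st.floats(0, 3, allow_nan=False),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_event_site_conservation_is_universal(n_carriers, length, qual, is_del, fc):
    site = make_site(
        "h", "DEL" if is_del else "DUP", length=length, qual=qual,
        carriers=tuple(SAMPLES[:n_carriers]), fc=fc,
    )
    kept, report = apply_filter_cascade([site], 32)
    assert report.is_conserved()
    assert report.input_sites == 1
    assert len(kept) in (0, 1)


class TestCounting:
    def test_two_sites_three_hets_each(self):
        sites = [
            make_site("a", carriers=("s01", "s02", "s03")),
            make_site("b", carriers=("s04", "s05", "s06")),
        ]
        assert count_events_sites(sites) == (6, 2)

    def test_empty(self):
        assert count_events_sites([]) == (0, 0)

    def test_hom_alt_counts_one_event(self):
        site = make_site("a", carriers=(), hom_carriers=("s01",))
        assert count_events_sites([site]) == (1, 1)


class TestPruneNearby:
    def test_keeps_highest_quality_within_window(self):
        sites = [
            make_site("low", start=1000, qual=100),
            make_site("high", start=1050, qual=900),
            make_site("far", start=5000, qual=50),
        ]
        kept = prune_nearby_sites(sites, window=100)
        assert {s.site_id for s in kept} == {"high", "far"}

    def test_quality_tie_breaks_leftmost(self):
        sites = [
            make_site("right", start=1080, qual=500),
            make_site("left", start=1000, qual=500),
        ]
        kept = prune_nearby_sites(sites, window=100)
        assert [s.site_id for s in kept] == ["left"]

    def test_chaining_across_cluster(self):
        # starts 1000, 1090, 1180: pairwise gaps 90 chain into one cluster
        sites = [
            make_site("a", start=1000, qual=10),
            make_site("b", start=1090, qual=20),
            make_site("c", start=1180, qual=30),
        ]
        kept = prune_nearby_sites(sites, window=100)
        assert [s.site_id for s in kept] == ["c"]

    def test_different_chromosomes_not_clustered(self):
        sites = [
            make_site("a", chrom="chr1", start=1000, qual=10),
            make_site("b", chrom="chr2", start=1000, qual=20),
        ]
        assert len(prune_nearby_sites(sites)) == 2
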