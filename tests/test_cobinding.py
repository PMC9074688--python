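import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfcobind.cobinding import (
    GROUP1,
    GROUP2,
    GROUP3,
    CobindParams,
    annotate_switches,
    cobind_fraction_recovery,
    detect_switch,
    group_summits,
)
from tfcobind.genomic_io import GenomicInterval

from conftest import make_gene, make_peak


def summit_peak(summit, factor="A", chrom="chr1", name=""):
    return make_peak(
        chrom=chrom, start=max(0, summit - 150), end=summit + 150, summit=summit,
        factor=factor, name=name or f"{factor}{summit}",
    )


def brute_force_groups(peaks_a, peaks_b, maxd):
    """O(n^2) oracle: group labels and co-bound counts by direct distance scan."""
    a_groups = []
    for pa in peaks_a:
        ds = [abs(pa.summit - pb.summit) for pb in peaks_b if pb.chrom == pa.chrom]
        a_groups.append(GROUP1 if ds and min(ds) <= maxd else GROUP2)
    b_groups = []
    for pb in peaks_b:
        ds = [abs(pa.summit - pb.summit) for pa in peaks_a if pa.chrom == pb.chrom]
        b_groups.append(GROUP3 if not ds or min(ds) > maxd else None)
    return a_groups, b_groups


class TestGroupSummits:
    def test_inclusive_boundary_at_threshold(self):
        a = [summit_peak(1000, "A")]
        assigns, summary = group_summits(a, [summit_peak(1050, "B")])
        assert assigns[0].group == GROUP1
        assert assigns[0].distance == 50
        assert summary.fraction_a_cobound == 1.0

    def test_exclusion_one_bp_past_threshold(self):
        a = [summit_peak(1000, "A")]
        assigns, summary = group_summits(a, [summit_peak(1051, "B")])
        assert assigns[0].group == GROUP2
        assert summary.n_group3 == 1  # the B peak is unpartnered

    def test_fraction_from_direct_count(self):
        a = [summit_peak(i * 100 + 10_000, "A", name=f"a{i}") for i in range(10)]
        b = [summit_peak(i * 100 + 10_000, "B", name=f"b{i}") for i in range(7)]
        _assigns, summary = group_summits(a, b)
        assert summary.fraction_a_cobound == pytest.approx(0.70)
        assert summary.n_group1 == 7 and summary.n_group2 == 3 and summary.n_group3 == 0

    def test_tie_break_prefers_lower_coordinate(self):
        a = [summit_peak(1000, "A")]
        b = [summit_peak(1050, "B", name="hi"), summit_peak(950, "B", name="lo")]
        assigns, _ = group_summits(a, b, CobindParams(tie_break="lower_coordinate"))
        assert assigns[0].partner.summit == 950
        assigns, _ = group_summits(a, b, CobindParams(tie_break="first_listed"))
        assert assigns[0].partner.name == "hi"

    def test_different_chromosome_never_partners(self):
        a = [summit_peak(1000, "A", chrom="chr1")]
        b = [summit_peak(1000, "B", chrom="chr2")]
        assigns, summary = group_summits(a, b)
        assert assigns[0].group == GROUP2
        assert summary.n_group3 == 1

    def test_conservation_group1_plus_group2_is_a(self, default_dataset):
        ds = default_dataset
        _a, summary = group_summits(ds.peaks["SOX4"]["tnf"], ds.peaks["RELA"]["tnf"])
        assert summary.n_group1 + summary.n_group2 == summary.n_a
        assert summary.n_group3 <= summary.n_b

    def test_symmetry_audit_swapped_arguments(self, default_dataset):
        """Swapping arguments reports the B-perspective co-bound count."""
        ds = default_dataset
        _x, s_ab = group_summits(ds.peaks["SOX4"]["tnf"], ds.peaks["RELA"]["tnf"])
        _y, s_ba = group_summits(ds.peaks["RELA"]["tnf"], ds.peaks["SOX4"]["tnf"])
        assert s_ba.n_a == s_ab.n_b
        # jitter-free pairs: each partner is mutual, so counts agree here
        assert s_ba.n_group1 == s_ab.n_group1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(100):
            maxd = int(rng.integers(0, 120))
            n_a = int(rng.integers(1, 200))
            n_b = int(rng.integers(1, 200))
            chroms = ["chr1", "chr2"]
            a = [
                summit_peak(int(rng.integers(300, 50_000)), "A", chrom=chroms[int(rng.integers(2))], name=f"a{i}")
                for i in range(n_a)
            ]
            b = [
                summit_peak(int(rng.integers(300, 50_000)), "B", chrom=chroms[int(rng.integers(2))], name=f"b{i}")
                for i in range(n_b)
            ]
            assigns, summary = group_summits(a, b, CobindParams(max_summit_distance=maxd))
            oracle_a, oracle_b = brute_force_groups(a, b, maxd)
            got_a = [x.group for x in assigns[:n_a]]
            assert got_a == oracle_a, f"trial {trial}"
            assert summary.n_group3 == sum(1 for g in oracle_b if g == GROUP3)
            for x in assigns[:n_a]:
                if x.group == GROUP1:
                    ds = [abs(x.peak.summit - pb.summit) for pb in b if pb.chrom == x.peak.chrom]
                    assert x.distance == min(ds)

    def test_peak_without_summit_impossible_but_empty_ok(self):
        assigns, summary = group_summits([], [])
        assert assigns == [] and summary.fraction_a_cobound == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        a_summits=st.lists(st.integers(300, 20_000), min_size=1, max_size=60),
        b_summits=st.lists(st.integers(300, 20_000), min_size=1, max_size=60),
        maxd=st.integers(0, 200),
    )
    def test_grouping_equals_brute_force_for_generated_summits(self, a_summits, b_summits, maxd):
        a = [summit_peak(s, "A", name=f"a{i}") for i, s in enumerate(a_summits)]
        b = [summit_peak(s, "B", name=f"b{i}") for i, s in enumerate(b_summits)]
        assigns, summary = group_summits(a, b, CobindParams(max_summit_distance=maxd))
        oracle_a, oracle_b = brute_force_groups(a, b, maxd)
        assert [x.group for x in assigns[: len(a)]] == oracle_a
        assert summary.n_group1 + summary.n_group2 == len(a)
        assert summary.n_group3 == sum(1 for g in oracle_b if g == GROUP3)


class TestFractionRecovery:
    @pytest.mark.parametrize("frac", [0.0, 0.5, 1.0])
    def test_noise_free_recovery_is_exact(self, frac):
        assert cobind_fraction_recovery(500, frac, seed=9) == pytest.approx(round(frac * 500) / 500)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            cobind_fraction_recovery(0, 0.5, seed=1)


class TestDetectSwitch:
    def _maps(self, a_basal, a_induced, b_basal, b_induced):
        return (
            {"untreated": a_basal, "tnf": a_induced},
            {"untreated": b_basal, "tnf": b_induced},
        )

    def test_canonical_switch_pattern(self):
        a_b = [make_peak(start=100, end=300, name="rela_basal")]
        b_i = [make_peak(start=150, end=350, name="sox4_gained")]
        fa, fb = self._maps(a_b, [], [], b_i)
        calls = detect_switch(fa, fb, basal="untreated", induced="tnf")
        assert len(calls) == 1
        assert calls[0].basal_peak_factor_a.name == "rela_basal"
        assert calls[0].gained_peak_factor_b.name == "sox4_gained"
        assert all(calls[0].evidence.values())

    def test_persistent_factor_a_blocks_call(self):
        a_b = [make_peak(start=100, end=300)]
        a_i = [make_peak(start=120, end=280)]
        b_i = [make_peak(start=150, end=350)]
        fa, fb = self._maps(a_b, a_i, [], b_i)
        assert detect_switch(fa, fb, basal="untreated", induced="tnf") == []

    def test_gain_on_other_chromosome_blocks_call(self):
        a_b = [make_peak(start=100, end=300)]
        b_i = [make_peak(chrom="chr2", start=150, end=350)]
        fa, fb = self._maps(a_b, [], [], b_i)
        assert detect_switch(fa, fb, basal="untreated", induced="tnf") == []

    def test_preexisting_factor_b_blocks_call(self):
        a_b = [make_peak(start=100, end=300)]
        b_b = [make_peak(start=110, end=290)]
        b_i = [make_peak(start=150, end=350)]
        fa, fb = self._maps(a_b, [], b_b, b_i)
        assert detect_switch(fa, fb, basal="untreated", induced="tnf") == []

    def test_missing_condition_key_raises(self):
        with pytest.raises(KeyError):
            detect_switch({"untreated": []}, {"untreated": [], "tnf": []}, "untreated", "tnf")

    def test_planted_switches_and_only_those_recovered(self, default_dataset):
        ds = default_dataset
        calls = detect_switch(
            {"untreated": ds.peaks["RELA"]["untreated"], "tnf": ds.peaks["RELA"]["tnf"]},
            {"untreated": ds.peaks["SOX4"]["untreated"], "tnf": ds.peaks["SOX4"]["tnf"]},
            basal="untreated",
            induced="tnf",
        )
        planted = {(s["chrom"], s["start"], s["end"]) for s in ds.manifest.switch_loci}
        got = {(c.locus.chrom, c.locus.start, c.locus.end) for c in calls}
        assert got == planted


class TestAnnotateSwitches:
    def test_utr3_flag_and_gene_assignment(self):
        gene = make_gene(
            gene_id="gS",
            start=10_000,
            end=20_000,
            strand="+",
            exons=((10_000, 11_000), (19_000, 20_000)),
            cds=(10_100, 19_400),
            utr3=GenomicInterval("chr1", 19_400, 20_000, "+"),
        )
        basal = make_peak(start=19_400, end=19_800, summit=19_600, name="b")
        gained = make_peak(start=19_500, end=19_900, summit=19_700, name="g")
        fa = {"u": [basal], "t": []}
        fb = {"u": [], "t": [gained]}
        calls = detect_switch(fa, fb, basal="u", induced="t")
        (ann,) = annotate_switches(calls, [gene])
        assert ann.gene == "gS" and ann.utr3_overlap

    def test_intronic_switch_flagged_false(self):
        gene = make_gene(
            gene_id="gS",
            start=10_000,
            end=20_000,
            strand="+",
            exons=((10_000, 11_000), (19_000, 20_000)),
            utr3=GenomicInterval("chr1", 19_400, 20_000, "+"),
        )
        basal = make_peak(start=14_000, end=14_400, summit=14_200)
        gained = make_peak(start=14_100, end=14_500, summit=14_300)
        calls = detect_switch({"u": [basal], "t": []}, {"u": [], "t": [gained]}, "u", "t")
        (ann,) = annotate_switches(calls, [gene])
        assert ann.gene == "gS" and not ann.utr3_overlap

    def test_intergenic_switch_has_no_gene(self):
        gene = make_gene(gene_id="gS", start=500_000, end=520_000)
        basal = make_peak(start=100, end=500, summit=300)
        gained = make_peak(start=200, end=600, summit=400)
        calls = detect_switch({"u": [basal], "t": []}, {"u": [], "t": [gained]}, "u", "t")
        (ann,) = annotate_switches(calls, [gene])
        assert ann.gene is None and not ann.utr3_overlap
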