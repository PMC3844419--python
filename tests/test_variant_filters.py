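import numpy as np
import pytest

from rnasomatic.coverage import CoverageTrack
from rnasomatic.variant_filters import (
    CascadeThresholds,
    FilterReport,
    SamplePair,
    VariantCall,
    filter1_quality,
    filter2_paired_coverage,
    filter3_somatic_subtraction,
    run_cascade,
)

T = CascadeThresholds()


def track(sample_id, depths):
    return CoverageTrack(sample_id=sample_id, depths={k: np.asarray(v) for k, v in depths.items()})


class TestVariantCall:
    def test_support_must_not_exceed_depth(self, make_variant):
        with pytest.raises(ValueError, match="alt support"):
            make_variant(depth=5, alt_support=6)

    def test_ref_must_differ_from_alt(self, make_variant):
        with pytest.raises(ValueError, match="ref == alt"):
            make_variant(ref="A", alt="A")

    def test_indel_flag_derived(self, make_variant):
        assert make_variant(ref="A", alt="AT").is_indel
        assert not make_variant(ref="A", alt="G").is_indel


class TestFilter1:
    def test_qual_boundary(self, make_variant):
        low = make_variant(qual=19.9, alt_support=5, depth=50)
        edge = make_variant(qual=20.0, alt_support=2, depth=3)
        assert filter1_quality([low], T) == []
        assert filter1_quality([edge], T) == [edge]

    def test_single_read_support_removed(self, make_variant):
        v = make_variant(qual=60, alt_support=1, depth=50)
        assert filter1_quality([v], T) == []

    def test_depth_window(self, make_variant):
        too_deep = make_variant(qual=60, alt_support=100, depth=501)
        too_shallow = make_variant(qual=60, alt_support=2, depth=2)
        at_max = make_variant(qual=60, alt_support=100, depth=500)
        assert filter1_quality([too_deep, too_shallow, at_max], T) == [at_max]

    def test_order_preserved_and_empty_ok(self, make_variant):
        vs = [make_variant(pos=p, qual=60, alt_support=5, depth=30) for p in range(5)]
        assert filter1_quality(vs, T) == vs
        assert filter1_quality([], T) == []

    def test_idempotent(self, make_variant):
        vs = [
            make_variant(pos=p, qual=q, alt_support=s, depth=d)
            for p, q, s, d in [(0, 60, 5, 30), (1, 10, 5, 30), (2, 60, 1, 30), (3, 60, 9, 900)]
        ]
        once = filter1_quality(vs, T)
        assert filter1_quality(once, T) == once


class TestFilter2:
    def test_mate_uncovered_removed(self, make_variant):
        v = make_variant(chrom="c", pos=0)
        own = track("s1", {"c": [10]})
        mate = track("s2", {"c": [0]})
        assert filter2_paired_coverage([v], own, mate, T) == []

    def test_min_depth_boundary_kept(self, make_variant):
        v = make_variant(chrom="c", pos=0)
        own = track("s1", {"c": [3]})
        mate = track("s2", {"c": [3]})
        assert filter2_paired_coverage([v], own, mate, T) == [v]

    def test_missing_track_errors(self, make_variant):
        with pytest.raises(ValueError):
            filter2_paired_coverage([make_variant()], None, track("s2", {}), T)

    def test_brute_force_positional_oracle(self, make_variant):
        rng = np.random.default_rng(3)
        own = track("s1", {"c": rng.integers(0, 30, size=50)})
        mate_depths = rng.integers(0, 30, size=50)
        mate_depths[rng.choice(50, size=20, replace=False)] = 0
        mate = track("s2", {"c": mate_depths})
        vs = [make_variant(chrom="c", pos=int(p)) for p in rng.choice(50, 10, replace=False)]
        kept = filter2_paired_coverage(vs, own, mate, T)
        expected = [
            v for v in vs if own.depth("c", v.pos) >= 3 and mate.depth("c", v.pos) >= 3
        ]
        assert kept == expected


class TestFilter3:
    def test_shared_variant_dropped_from_both(self, make_variant):
        n = make_variant(sample_id="n", pos=5)
        t = make_variant(sample_id="t", pos=5)
        ns, ts = filter3_somatic_subtraction([n], [t])
        assert ns == [] and ts == []

    def test_blacklisted_tumor_variant_removed(self, make_variant):
        t = make_variant(sample_id="t", pos=7, ref="C", alt="T")
        _, ts = filter3_somatic_subtraction([], [t], blacklist={("toy.1", 7, "C", "T")})
        assert ts == []

    def test_positional_blacklist_entry_matches(self, make_variant):
        t = make_variant(sample_id="t", pos=7, ref="C", alt="T")
        _, ts = filter3_somatic_subtraction([], [t], blacklist={("toy.1", 7)})
        assert ts == []

    def test_set_difference_oracle(self, make_variant):
        n = [make_variant(sample_id="n", pos=5, ref="A", alt="G")]
        t = [
            make_variant(sample_id="t", pos=5, ref="A", alt="G"),
            make_variant(sample_id="t", pos=9, ref="C", alt="T"),
        ]
        ns, ts = filter3_somatic_subtraction(n, t)
        assert ns == []
        assert [v.key for v in ts] == [("toy.1", 9, "C", "T")]

    def test_allele_vs_positional_matching(self, make_variant):
        n = [make_variant(sample_id="n", pos=5, ref="A", alt="G")]
        t = [make_variant(sample_id="t", pos=5, ref="A", alt="C")]
        _, ts_allele = filter3_somatic_subtraction(n, t, match_alleles=True)
        _, ts_pos = filter3_somatic_subtraction(n, t, match_alleles=False)
        assert len(ts_allele) == 1 and ts_pos == []

    def test_symmetry(self, make_variant):
        n = [make_variant(sample_id="n", pos=p) for p in (1, 2, 3)]
        t = [make_variant(sample_id="t", pos=p) for p in (2, 3, 4)]
        ns, ts = filter3_somatic_subtraction(n, t)
        ts2, ns2 = filter3_somatic_subtraction(t, n)
        assert [v.key for v in ns] == [v.key for v in ns2]
        assert [v.key for v in ts] == [v.key for v in ts2]

    def test_idempotent(self, make_variant):
        n = [make_variant(sample_id="n", pos=p) for p in (1, 2)]
        t = [make_variant(sample_id="t", pos=p) for p in (2, 5)]
        ns, ts = filter3_somatic_subtraction(n, t)
        ns2, ts2 = filter3_somatic_subtraction(ns, ts)
        assert ns2 == ns and ts2 == ts


class TestFilterReport:
    def test_row_sum_arithmetic(self):
        report = FilterReport.from_counts(
            {"a": {"raw": 10, "after_filter1": 5}, "b": {"raw": 7, "after_filter1": 3}}
        )
        df = report.to_frame()
        assert df.loc["Raw", "Sum"] == 17
        assert df.loc["After filter 1", "Sum"] == 8

    def test_monotonicity_enforced(self):
        report = FilterReport.from_counts({"a": {"raw": 5, "after_filter1": 9}})
        with pytest.raises(ValueError, match="non-monotone"):
            report.validate()


class TestRunCascade:
    def test_empty_inputs_all_zero(self):
        pair = SamplePair(
            normal_id="n",
            tumor_id="t",
            normal_variants=[],
            tumor_variants=[],
            normal_cov=track("n", {}),
            tumor_cov=track("t", {}),
        )
        somatic, report = run_cascade([pair])
        assert somatic == {"n": [], "t": []}
        assert (report.to_frame().to_numpy() == 0).all()

    def test_mismatched_pairing_errors(self, make_variant):
        with pytest.raises(ValueError, match="do not match"):
            SamplePair(
                normal_id="n",
                tumor_id="t",
                normal_variants=[],
                tumor_variants=[],
                normal_cov=track("x", {}),
                tumor_cov=track("t", {}),
            )

    def test_monotone_attrition_on_cohort(self, default_cohort):
        _, report = run_cascade(default_cohort.sample_pairs(), blacklist=default_cohort.blacklist)
        report.validate()
        for sid in report.sample_order:
            seq = [report.get(sid, s) for s in ("raw", "after_filter1", "after_filter2", "after_filter3")]
            assert seq == sorted(seq, reverse=True)


def brute_force_cascade(pair, blacklist, t=T):
    """Independent re-implementation of the cascade with plain set logic."""

    def f1(vs):
        return [
            v for v in vs
            if v.qual >= t.min_qual and v.alt_support >= t.min_support
            and t.min_depth <= v.depth <= t.max_depth
        ]

    def covered(v):
        a = pair.normal_cov.depths.get(v.chrom)
        b = pair.tumor_cov.depths.get(v.chrom)
        da = a[v.pos] if a is not None and v.pos < len(a) else 0
        db = b[v.pos] if b is not None and v.pos < len(b) else 0
        return da >= t.min_depth and db >= t.min_depth

    n = [v for v in f1(pair.normal_variants) if covered(v)]
    tm = [v for v in f1(pair.tumor_variants) if covered(v)]
    shared = {(v.chrom, v.pos, v.ref, v.alt) for v in n} & {
        (v.chrom, v.pos, v.ref, v.alt) for v in tm
    }
    bad = shared | set(blacklist)
    n3 = [v for v in n if (v.chrom, v.pos, v.ref, v.alt) not in bad and (v.chrom, v.pos) not in bad]
    t3 = [v for v in tm if (v.chrom, v.pos, v.ref, v.alt) not in bad and (v.chrom, v.pos) not in bad]
    return len(n), len(tm), n3, t3


def test_cascade_matches_brute_force_oracle(default_cohort):
    somatic, report = run_cascade(
        default_cohort.sample_pairs(), blacklist=default_cohort.blacklist
    )
    for pair in default_cohort.sample_pairs():
        n2, t2, n3, t3 = brute_force_cascade(pair, default_cohort.blacklist)
        assert report.get(pair.normal_id, "after_filter2") == n2
        assert report.get(pair.tumor_id, "after_filter2") == t2
        assert [v.key for v in somatic[pair.normal_id]] == [v.key for v in n3]
        assert [v.key for v in somatic[pair.tumor_id]] == [v.key for v in t3]
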