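import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wheatrec.io_formats import PARENT_A, PARENT_B, UNDETERMINED, VariantTable
from wheatrec.skim_caller import (
    MarkerTrack,
    SkimConfig,
    build_parental_snps,
    classify_event_lengths,
    classify_line_positions,
    conservation_filter,
    normalize_gc_by_informative_sites,
    segment_marker_track,
    validate_shifts_with_readpairs,
)
from oracles import segmentation_oracle

A, B = PARENT_A, PARENT_B


def vt(rows):
    return VariantTable.from_records(rows)


def make_track(positions, labels, line="l", chrom="c1"):
    return MarkerTrack(
        line=line,
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        labels={chrom: np.asarray(labels, dtype=np.int8)},
    )


class TestParentalSNPBuild:
    def base(self, pos, qual=60.0, depth=10, alt=10):
        return ("c1", pos, "C", "T", qual, depth, alt, 60.0)

    def test_quality_29_excluded(self):
        snps = build_parental_snps(vt([self.base(100, qual=29.0)]))
        assert len(snps) == 0

    def test_fraction_exactly_080_excluded(self):
        snps = build_parental_snps(vt([self.base(100, depth=10, alt=8)]))
        assert len(snps) == 0

    def test_depth_below_3_excluded(self):
        snps = build_parental_snps(vt([("c1", 100, "C", "T", 60.0, 2, 2, 60.0)]))
        assert len(snps) == 0

    def test_three_snps_in_10bp_span_all_removed(self):
        snps = build_parental_snps(vt([self.base(100), self.base(104), self.base(108)]))
        assert len(snps) == 0

    def test_spread_snps_kept(self):
        snps = build_parental_snps(vt([self.base(100), self.base(104), self.base(120)]))
        assert len(snps) == 3

    def test_fourth_snp_in_dense_span_also_removed(self):
        snps = build_parental_snps(
            vt([self.base(100), self.base(101), self.base(102), self.base(109)])
        )
        assert len(snps) == 0

    def test_empty_input(self):
        assert len(build_parental_snps(vt([]))) == 0


class TestClassifyLinePositions:
    @pytest.fixture
    def snps(self):
        return build_parental_snps(
            vt([("c1", p, "C", "T", 60.0, 10, 10, 60.0) for p in (100, 500, 900, 1300)])
        )

    def cov(self, depths):
        return pd.DataFrame(
            {"chrom": "c1", "pos": [100, 500, 900, 1300], "depth": depths}
        )

    def test_matching_alt_allele_is_parent_a(self, snps):
        track = classify_line_positions(
            vt([("c1", 100, "C", "T", 60.0, 10, 9, 60.0)]), self.cov([10, 0, 0, 0]),
            snps,
        )
        assert track.labels["c1"][0] == PARENT_A

    def test_low_fraction_undetermined(self, snps):
        track = classify_line_positions(
            vt([("c1", 100, "C", "T", 60.0, 10, 6, 60.0)]), self.cov([10, 0, 0, 0]),
            snps,
        )
        assert track.labels["c1"][0] == UNDETERMINED

    def test_wrong_allele_undetermined(self, snps):
        track = classify_line_positions(
            vt([("c1", 100, "C", "G", 60.0, 10, 9, 60.0)]), self.cov([10, 0, 0, 0]),
            snps,
        )
        assert track.labels["c1"][0] == UNDETERMINED

    def test_no_snp_no_coverage_undetermined(self, snps):
        track = classify_line_positions(vt([]), self.cov([0, 0, 0, 0]), snps)
        assert (track.labels["c1"] == UNDETERMINED).all()

    def test_no_snp_with_coverage_is_parent_b(self, snps):
        track = classify_line_positions(vt([]), self.cov([5, 5, 5, 5]), snps)
        assert (track.labels["c1"] == PARENT_B).all()

    def test_low_quality_snp_ignored(self, snps):
        # a qual-19 call is discarded; with coverage the site falls through
        # to reference confirmation
        track = classify_line_positions(
            vt([("c1", 100, "C", "T", 19.0, 10, 9, 60.0)]), self.cov([5, 0, 0, 0]),
            snps,
        )
        assert track.labels["c1"][0] == PARENT_B

    def test_missing_coverage_rows_count_as_zero(self, snps):
        cov = pd.DataFrame({"chrom": ["c1"], "pos": [100], "depth": [5]})
        track = classify_line_positions(vt([]), cov, snps)
        assert track.labels["c1"][0] == PARENT_B
        assert (track.labels["c1"][1:] == UNDETERMINED).all()


class TestSegmentation:
    def test_two_marker_break_discarded(self):
        labels = [A] * 10 + [B] * 2 + [A] * 10
        evs = segment_marker_track(make_track(range(1, 23), labels))
        assert [e.kind for e in evs] == ["SHIFT"]  # one merged terminal run
        assert evs[0].support == 20

    def test_three_marker_event_emitted(self):
        pos = [1000, 2000, 3000, 4000, 5000, 10_400, 10_900, 11_300,
               20_000, 21_000, 22_000, 23_000, 24_000]
        labels = [A] * 5 + [B] * 3 + [A] * 5
        evs = segment_marker_track(make_track(pos, labels))
        gc = [e for e in evs if e.kind == "GC"]
        assert len(gc) == 1
        assert (gc[0].start, gc[0].end, gc[0].span, gc[0].support) == (
            10_400, 11_300, 901, 3)
        assert gc[0].donor == B

    def test_uniform_track_no_events(self):
        evs = segment_marker_track(make_track(range(1, 11), [A] * 10))
        assert [e.kind for e in evs] == ["SHIFT"]

    def test_undetermined_removed_before_segmentation(self):
        labels = [A] * 5 + [UNDETERMINED] * 4 + [B] * 3 + [A] * 5
        evs = segment_marker_track(make_track(range(1, 18), labels))
        assert sum(e.kind == "GC" for e in evs) == 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 60))
            labels = rng.choice([A, B, UNDETERMINED], size=n, p=[0.4, 0.4, 0.2])
            pos = np.sort(rng.choice(10**6, size=n, replace=False)) + 1
            evs = segment_marker_track(make_track(pos, labels))
            expected = segmentation_oracle(pos, labels)
            got = [
                (e.donor if e.kind == "GC" else "TERM", e.start, e.end, e.support)
                for e in evs
            ]
            assert got == expected

    def test_idempotent_on_induced_labels(self, rng):
        """Re-segmenting the label string induced by the called runs
        reproduces the same events."""
        for _ in range(50):
            n = int(rng.integers(10, 80))
            labels = rng.choice([A, B], size=n, p=[0.6, 0.4])
            pos = np.arange(1, n + 1) * 100
            evs = segment_marker_track(make_track(pos, labels))
            pos2, lab2 = [], []
            for e in sorted(evs, key=lambda e: e.start):
                step = max((e.end - e.start) // max(e.support - 1, 1), 1)
                for k in range(e.support):
                    pos2.append(e.start + k * step if k < e.support - 1 else e.end)
                    lab2.append(e.donor)
            evs2 = segment_marker_track(make_track(pos2, lab2))
            assert [
                (e.kind, e.donor, e.start, e.end, e.support) for e in evs
            ] == [(e.kind, e.donor, e.start, e.end, e.support) for e in evs2]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([A, B]), min_size=4, max_size=60), st.data())
    def test_deleting_marker_from_long_run_never_creates_events(self, labels, data):
        pos = [(i + 1) * 100 for i in range(len(labels))]
        evs = segment_marker_track(make_track(pos, labels))
        long_runs = [e for e in evs if e.support >= 4]
        if not long_runs:
            return
        e = data.draw(st.sampled_from(long_runs))
        inside = [i for i, p in enumerate(pos) if e.start <= p <= e.end]
        kill = data.draw(st.sampled_from(inside))
        pos2 = [p for i, p in enumerate(pos) if i != kill]
        lab2 = [l for i, l in enumerate(labels) if i != kill]
        evs2 = segment_marker_track(make_track(pos2, lab2))
        assert len([x for x in evs2 if x.kind == "GC"]) <= len(
            [x for x in evs if x.kind == "GC"]
        )

    def test_events_sorted_nonoverlapping_min_support(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 100))
            labels = rng.choice([A, B], size=n)
            pos = np.sort(rng.choice(10**7, size=n, replace=False)) + 1
            evs = segment_marker_track(make_track(pos, labels))
            assert all(e.support >= 3 for e in evs)
            starts = [e.start for e in evs]
            assert starts == sorted(starts)
            for e1, e2 in zip(evs, evs[1:]):
                assert e1.end < e2.start


class TestLengthClasses:
    def ev(self, span):
        from wheatrec.io_formats import RecombinationEvent

        return RecombinationEvent(line="l", chrom="c1", start=1000,
                                  end=1000 + span - 1, donor=A, kind="GC",
                                  support=3)

    @pytest.mark.parametrize(
        "span,expected",
        [
            (10, "SUB_MINIMUM"),
            (20, "20bp-2kbp"),
            (1500, "20bp-2kbp"),
            (2000, "2-10kbp"),
            (9999, "2-10kbp"),
            (10_000, "10-500kbp"),
            (500_000, ">500kbp"),
            (45_000_000, ">500kbp"),
        ],
    )
    def test_half_open_bins(self, span, expected):
        e = classify_event_lengths([self.ev(span)])[0]
        assert e.length_class == expected

    def test_co_proxy_flags(self):
        e = classify_event_lengths([self.ev(45_000_000)])[0]
        assert e.co20_flag and e.co40_flag
        e = classify_event_lengths([self.ev(25_000_000)])[0]
        assert e.co20_flag and not e.co40_flag

    def test_class_partition_is_total(self, rng):
        evs = [self.ev(int(s)) for s in rng.integers(1, 10**8, size=100)]
        classify_event_lengths(evs)
        assert all(e.length_class is not None for e in evs)


class TestConservation:
    def ev(self, line, start, end, donor=A):
        from wheatrec.io_formats import RecombinationEvent

        return RecombinationEvent(line=line, chrom="c1", start=start, end=end,
                                  donor=donor, kind="GC", support=3)

    def test_unique_and_sv_flags(self):
        by_line = {f"l{i}": [self.ev(f"l{i}", 100, 200)] for i in range(7)}
        by_line["l7"] = [self.ev("l7", 10_000, 10_100)]
        for i in range(8, 12):
            by_line[f"l{i}"] = []
        census = conservation_filter(by_line, n_lines=12)
        shared = by_line["l0"][0]
        assert shared.sharing_count == 7
        assert shared.sv_flagged  # 7/12 > 0.5
        unique = by_line["l7"][0]
        assert unique.unique_to_line and not unique.sv_flagged
        assert census["fraction_unique"] == pytest.approx(1 / 8)

    def test_different_donor_not_shared(self):
        by_line = {
            "l0": [self.ev("l0", 100, 200, donor=A)],
            "l1": [self.ev("l1", 150, 250, donor=B)],
        }
        conservation_filter(by_line)
        assert by_line["l0"][0].sharing_count == 1

    def test_matches_allpairs_oracle(self, rng):
        from oracles import sharing_census_oracle

        for _ in range(30):
            by_line = {}
            raw = {}
            for li in range(3):
                evs = []
                tuples = []
                last = 0
                for _ in range(5):
                    s = last + int(rng.integers(1, 500))
                    e = s + int(rng.integers(0, 400))
                    last = e + 1
                    d = int(rng.integers(0, 2))
                    evs.append(self.ev(f"l{li}", s, e, donor=d))
                    tuples.append(("c1", s, e, d))
                by_line[f"l{li}"] = evs
                raw[f"l{li}"] = tuples
            conservation_filter(by_line)
            expected = sharing_census_oracle(raw)
            for line, evs in by_line.items():
                for i, e in enumerate(evs):
                    assert e.sharing_count == expected[(line, i)]


class TestReadPairValidation:
    def test_concordant_site_supported(self):
        res = validate_shifts_with_readpairs(
            [[("C", "T")] * 3], [("C", "T")]
        )
        assert res == {"n_assessable": 1, "n_supported": 1, "accuracy": 1.0}

    def test_undercovered_site_excluded(self):
        res = validate_shifts_with_readpairs(
            [[("C", "T")] * 2, [("C", "T")] * 3], [("C", "T"), ("C", "T")]
        )
        assert res["n_assessable"] == 1

    def test_discordant_site_counts_as_false_positive(self):
        res = validate_shifts_with_readpairs(
            [[("C", "C")] * 3], [("C", "T")]
        )
        assert res["accuracy"] == 0.0

    def test_no_assessable_sites_is_error(self):
        with pytest.raises(ValueError):
            validate_shifts_with_readpairs([[("C", "T")]], [("C", "T")])


class TestNormalization:
    def test_exact_value(self):
        assert normalize_gc_by_informative_sites(10_000, 25_000_000, 31_327_143) == (
            pytest.approx(12_530.8572)
        )

    def test_identity(self):
        assert normalize_gc_by_informative_sites(42, 1000, 1000) == 42.0

    def test_halving_informative_doubles_output(self, rng):
        for _ in range(20):
            gc = int(rng.integers(1, 10**4))
            inf = int(rng.integers(2, 10**6)) * 2
            ref = int(rng.integers(1, 10**7))
            assert normalize_gc_by_informative_sites(gc, inf // 2, ref) == (
                pytest.approx(2 * normalize_gc_by_informative_sites(gc, inf, ref))
            )

    def test_zero_informative_is_error(self):
        with pytest.raises(ValueError):
            normalize_gc_by_informative_sites(1, 0, 10)
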