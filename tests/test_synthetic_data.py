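import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatrec.io_formats import HET, PARENT_A, PARENT_B, UNDETERMINED
from wheatrec.skim_caller import classify_line_positions, build_parental_snps
from wheatrec.synthetic_data import (
    LineTruth,
    SimConfig,
    SimTruth,
    Tract,
    constant_mosaic,
    emit_array_genotypes,
    emit_parental_variants,
    emit_skim_observations,
    evaluate_calls_against_truth,
    het_fraction,
    sample_array_markers,
    sample_discrimination_sites,
    simulate_meiosis,
    simulate_ssd_population,
    state_at,
    zygosity_mosaic,
)


class TestMeiosis:
    def test_obligate_crossover(self, small_config):
        rng = np.random.default_rng(0)
        L = small_config.chrom_length
        h0 = constant_mosaic(L, PARENT_A)
        h1 = constant_mosaic(L, PARENT_B)
        for _ in range(300):
            _, cos, _, _ = simulate_meiosis(h0, h1, L, small_config, rng)
            assert len(cos) >= 1

    def test_same_seed_same_gamete(self, small_config):
        L = small_config.chrom_length
        h0 = constant_mosaic(L, PARENT_A)
        h1 = constant_mosaic(L, PARENT_B)
        g1, c1, t1, _ = simulate_meiosis(h0, h1, L, small_config,
                                         np.random.default_rng(5))
        g2, c2, t2, _ = simulate_meiosis(h0, h1, L, small_config,
                                         np.random.default_rng(5))
        assert np.array_equal(g1[0], g2[0]) and np.array_equal(g1[1], g2[1])
        assert c1 == c2 and t1 == t2

    def test_unbiased_positions_are_uniform(self):
        cfg = SimConfig(distal_bias=0.0, mean_cos_per_chrom=3.0,
                        obligate_co=False, seed=0)
        rng = np.random.default_rng(17)
        L = cfg.chrom_length
        h0 = constant_mosaic(L, PARENT_A)
        h1 = constant_mosaic(L, PARENT_B)
        pos = []
        while len(pos) < 2000:
            _, cos, _, _ = simulate_meiosis(h0, h1, L, cfg, rng)
            pos.extend(cos)
        _, p = stats.kstest(np.array(pos) / L, "uniform")
        assert p > 0.01

    def test_distal_bias_shifts_mass_to_ends(self):
        cfg = SimConfig(distal_bias=1.0, seed=0)
        rng = np.random.default_rng(23)
        L = cfg.chrom_length
        h0 = constant_mosaic(L, PARENT_A)
        h1 = constant_mosaic(L, PARENT_B)
        pos = []
        while len(pos) < 1000:
            _, cos, _, _ = simulate_meiosis(h0, h1, L, cfg, rng)
            pos.extend(cos)
        arm = np.minimum(np.array(pos), L - np.array(pos)) / (L / 2)
        assert np.mean(arm) < 0.4  # telomere-proximal


class TestSsdPopulation:
    def test_mosaics_tile_chromosomes(self, small_truth, small_config):
        for lt in small_truth.lines:
            for c, (ends, states) in lt.final.items():
                assert ends[-1] == small_config.chrom_length
                assert (np.diff(ends) > 0).all()
                assert (states[1:] != states[:-1]).all()  # simplified

    def test_generation_one_is_fully_heterozygous(self):
        cfg = SimConfig(generations=1, n_lines=2, n_chroms=1,
                        chrom_length=10_000_000, seed=3)
        truth = simulate_ssd_population(cfg)
        assert all(lt.het_fraction == 1.0 for lt in truth.lines)

    def test_f8_heterozygosity_near_closed_form(self, small_truth):
        mean_het = np.mean([lt.het_fraction for lt in small_truth.lines])
        assert mean_het == pytest.approx(0.5 ** 7, abs=0.01)

    def test_determinism_byte_for_byte(self, small_config):
        t1 = simulate_ssd_population(small_config)
        t2 = simulate_ssd_population(small_config)
        for a, b in zip(t1.lines, t2.lines):
            assert a.planted_cos == b.planted_cos
            assert a.co_positions == b.co_positions
            for c in a.final:
                assert np.array_equal(a.final[c][0], b.final[c][0])
                assert np.array_equal(a.final[c][1], b.final[c][1])

    def test_detectability_halves_per_planting_generation(self):
        """Tracts planted later survive to F8 as homozygous islands about
        half as often per generation."""
        cfg = SimConfig(seed=11, n_lines=300)
        truth = simulate_ssd_population(cfg)
        gens = np.arange(1, 6)
        mean = np.array([
            np.mean([
                sum(t.detectable for t in lt.tracts if t.generation == g)
                for lt in truth.lines
            ])
            for g in gens
        ])
        slope = np.polyfit(gens, np.log(mean), 1)[0]
        assert abs(slope + np.log(2)) < 0.3


class TestArrayEmission:
    def test_markers_read_off_mosaic(self, small_truth, small_config):
        rng = np.random.default_rng(4)
        markers = sample_array_markers(small_config, rng)
        gm = emit_array_genotypes(small_truth, markers, small_config, rng)
        lt = small_truth.lines[0]
        col = gm.line_calls(lt.line)
        for i in range(0, len(markers), 7):
            c, p = markers.iloc[i]["chrom"], markers.iloc[i]["pos"]
            assert col[i] == state_at(lt.final[c], p)

    def test_no_missing_without_missing_rate(self, small_truth, small_config):
        rng = np.random.default_rng(4)
        markers = sample_array_markers(small_config, rng)
        gm = emit_array_genotypes(small_truth, markers, small_config, rng)
        assert (gm.calls != 3).all()

    def test_marker_count_matches_config(self, small_config):
        rng = np.random.default_rng(4)
        markers = sample_array_markers(small_config, rng)
        assert len(markers) == pytest.approx(small_config.array_markers, abs=3)


class TestSkimEmission:
    def test_site_spacing_matches_config(self, small_config):
        rng = np.random.default_rng(8)
        sites = sample_discrimination_sites(small_config, rng)
        c0 = sites[sites["chrom"] == "chr1"]["pos"].to_numpy()
        gaps = np.diff(c0)
        assert abs(gaps.mean() - 540) < 20

    def test_noisefree_parent_a_site_has_fraction_one(self):
        cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, label_noise=0.0,
                        coverage_mean=8.0, seed=1)
        lt = LineTruth(
            line="l", final={"chr1": constant_mosaic(1_000_000, PARENT_A)},
            shadow={"chr1": constant_mosaic(1_000_000, PARENT_A)},
            planted_cos=[], tracts=[],
        )
        rng = np.random.default_rng(2)
        sites = sample_discrimination_sites(cfg, rng)
        vt, cov = emit_skim_observations(lt, sites, cfg, rng)
        covered = cov[cov["depth"] > 0]
        assert len(vt) == len(covered)
        assert (vt.alt_fraction == 1.0).all()

    def test_zero_depth_site_undetermined_after_classification(self):
        cfg = SimConfig(n_chroms=1, chrom_length=500_000, label_noise=0.0,
                        coverage_mean=3.0, seed=1)
        lt = LineTruth(
            line="l", final={"chr1": constant_mosaic(500_000, PARENT_A)},
            shadow={"chr1": constant_mosaic(500_000, PARENT_A)},
            planted_cos=[], tracts=[],
        )
        rng = np.random.default_rng(9)
        sites = sample_discrimination_sites(cfg, rng)
        parental = emit_parental_variants(sites, cfg, rng)
        snps = build_parental_snps(parental)
        vt, cov = emit_skim_observations(lt, snps.df, cfg, rng)
        track = classify_line_positions(vt, cov, snps, line="l")
        depth = cov.set_index("pos")["depth"]
        lab = track.labels["chr1"]
        pos = track.positions["chr1"]
        zero = depth.loc[pos].to_numpy() == 0
        assert (lab[zero] == UNDETERMINED).all()


class TestEvaluationHarness:
    def make_truth(self):
        L = 10_000_000
        ends = np.array([4_000_000, 4_050_000, L])
        states = np.array([PARENT_A, PARENT_B, PARENT_A], dtype=np.int8)
        tract = Tract(1, "c1", 4_000_001, 4_050_000, PARENT_B,
                      detectable=True, n_markers=5)
        lt = LineTruth(
            line="l", final={"c1": (ends, states)}, shadow={"c1": (ends, states)},
            planted_cos=[], tracts=[tract],
            co_positions=[("c1", 7_000_000)],
        )
        cfg = SimConfig(n_chroms=1, chrom_length=L, seed=0)
        return SimTruth(config=cfg, lines=[lt])

    def ev(self, start, end, donor, kind="GC"):
        from wheatrec.io_formats import RecombinationEvent

        return RecombinationEvent(line="l", chrom="c1", start=start, end=end,
                                  donor=donor, kind=kind, support=3)

    def test_gc_recall_and_precision(self):
        truth = self.make_truth()
        calls = {"l": [self.ev(4_010_000, 4_040_000, PARENT_B)]}
        res = evaluate_calls_against_truth(calls, truth, kind="GC")
        assert res["recall"] == 1.0 and res["precision"] == 1.0

    def test_wrong_donor_not_recovered(self):
        truth = self.make_truth()
        calls = {"l": [self.ev(4_010_000, 4_040_000, PARENT_A)]}
        res = evaluate_calls_against_truth(calls, truth, kind="GC")
        assert res["recall"] == 0.0

    def test_call_straddling_junction_is_false_positive(self):
        truth = self.make_truth()
        calls = {"l": [self.ev(3_900_000, 4_040_000, PARENT_B)]}
        res = evaluate_calls_against_truth(calls, truth, kind="GC")
        assert res["precision"] == 0.0

    def test_empty_calls(self):
        truth = self.make_truth()
        res = evaluate_calls_against_truth({"l": []}, truth, kind="GC")
        assert res["recall"] == 0.0 and np.isnan(res["precision"])

    def test_co_matching_within_tolerance(self):
        truth = self.make_truth()
        calls = {"l": [self.ev(6_000_001, 6_000_001, PARENT_B, kind="CO")]}
        res = evaluate_calls_against_truth(calls, truth, kind="CO",
                                           co_tolerance=2_000_000)
        assert res["recall"] == 1.0 and res["precision"] == 1.0
        assert res["median_error"] == 999_999
        res = evaluate_calls_against_truth(calls, truth, kind="CO",
                                           co_tolerance=500_000)
        assert res["recall"] == 0.0 and res["precision"] == 0.0

    def test_unknown_line_rejected(self):
        truth = self.make_truth()
        with pytest.raises(ValueError):
            evaluate_calls_against_truth({"ghost": []}, truth)

    def test_recall_matches_bruteforce_overlap_matrix(self, rng):
        truth = self.make_truth()
        lt = truth.lines[0]
        lt.tracts = []
        for k in range(6):
            s = int(rng.integers(1, 9_000_000))
            e = s + int(rng.integers(10, 100_000))
            lt.tracts.append(Tract(1, "c1", s, e, PARENT_B, detectable=True,
                                   n_markers=4))
        calls = {
            "l": [
                self.ev(int(s), int(s) + int(rng.integers(10, 120_000)), PARENT_B)
                for s in sorted(rng.integers(1, 9_000_000, size=5))
            ]
        }
        res = evaluate_calls_against_truth(calls, truth, kind="GC")
        expected = sum(
            any(c.start <= t.end and c.end >= t.start for c in calls["l"])
            for t in lt.tracts
        ) / len(lt.tracts)
        assert res["recall"] == pytest.approx(expected)


def test_zygosity_mosaic_combines_homologs():
    h0 = (np.array([50, 100]), np.array([PARENT_A, PARENT_B], dtype=np.int8))
    h1 = (np.array([30, 100]), np.array([PARENT_A, PARENT_B], dtype=np.int8))
    z = zygosity_mosaic(h0, h1)
    assert state_at(z, 10) == PARENT_A
    assert state_at(z, 40) == HET
    assert state_at(z, 80) == PARENT_B
    assert het_fraction(z) == pytest.approx(0.2)
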