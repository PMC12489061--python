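"""Exposure closed form, interval arithmetic, parsing and the per-base oracle."""

import numpy as np
import pandas as pd
import pytest

from paralogrisk import (
    GenomeAnnotation,
    ResectionParams,
    co_risk_fraction,
    exposure_intervals,
    merge_intervals,
    parse_annotation,
    per_base_co_oracle,
    per_base_oracle,
    repeat_coverage,
    resection_risk_fraction,
    risk_profile,
)
from paralogrisk.resection_risk import at_risk_intervals

from conftest import make_annotation, random_annotation


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_bed_is_half_open(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chrII\t100\t200\tgeneA\t0\t+\n")
        sizes = tmp_path / "chrom.sizes"
        sizes.write_text("chrII\t1000\n")
        ann = parse_annotation(bed, sizes)
        row = ann.intervals.iloc[0]
        assert (row.chrom, row.start, row.end, row["name"], row.strand) == \
            ("chrII", 100, 200, "geneA", "+")

    def test_gff3_converts_to_half_open(self, tmp_path):
        gff = tmp_path / "x.gff3"
        gff.write_text("##gff-version 3\nchr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=geneB\n")
        sizes = tmp_path / "chrom.sizes"
        sizes.write_text("chr1\t1000\n")
        ann = parse_annotation(gff, sizes)
        row = ann.intervals.iloc[0]
        assert (row.start, row.end, row["name"], row.strand) == (100, 200, "geneB", "-")

    @pytest.mark.parametrize("line, msg", [
        ("chr1\t200\t100\tg\n", "line 1"),          # end < start
        ("chrX\t10\t20\tg\n", "unknown chromosome"),
        ("chr1\tnot_an_int\t20\tg\n", "malformed"),
    ])
    def test_bad_lines_name_the_line(self, tmp_path, line, msg):
        bed = tmp_path / "bad.bed"
        bed.write_text(line)
        sizes = tmp_path / "chrom.sizes"
        sizes.write_text("chr1\t1000\n")
        with pytest.raises(ValueError, match=msg):
            parse_annotation(bed, sizes)


# ---------------------------------------------------------------------------
# Interval merge
# ---------------------------------------------------------------------------

class TestMerge:
    def test_overlap(self):
        m = merge_intervals([("c", 0, 10), ("c", 5, 15)])
        assert m.values.tolist() == [["c", 0, 15]]

    def test_halfopen_adjacency_merges(self):
        m = merge_intervals([("c", 0, 10), ("c", 10, 20)])
        assert m.values.tolist() == [["c", 0, 20]]

    def test_chromosomes_kept_separate(self):
        m = merge_intervals([("c1", 0, 10), ("c2", 0, 10)])
        assert len(m) == 2

    def test_total_bp_equals_position_set_union(self, rng):
        """Conservation: merged bp equals the exact cardinality of the union."""
        for _ in range(30):
            ivs = []
            positions = set()
            for _ in range(int(rng.integers(1, 12))):
                chrom = f"c{rng.integers(0, 2)}"
                s = int(rng.integers(0, 500))
                e = s + int(rng.integers(1, 80))
                ivs.append((chrom, s, e))
                positions.update((chrom, p) for p in range(s, e))
            m = merge_intervals(ivs)
            assert int((m["end"] - m["start"]).sum()) == len(positions)


# ---------------------------------------------------------------------------
# Exposure geometry
# ---------------------------------------------------------------------------

class TestExposureIntervals:
    def test_long_repeat_single_coalesced_interval(self):
        # 1-kb gene, L=4 kb, E=300: oracle-verified single interval
        assert exposure_intervals(10_000, 11_000, 4_000, 300, 100_000) == \
            [(6_300, 14_701)]

    def test_short_repeat_central_band_excluded(self):
        # 400-bp gene with L=1 kb: two arms; the central band is not at risk
        arms = exposure_intervals(1_000, 1_400, 1_000, 300, 1_000_000)
        assert arms == [(300, 1_101), (1_300, 2_101)]

    def test_tract_below_minimum_exposure_is_empty(self):
        assert exposure_intervals(1_000, 2_000, 200, 300, 10_000) == []

    def test_repeat_shorter_than_minimum_is_empty(self):
        assert exposure_intervals(1_000, 1_200, 5_000, 300, 10_000) == []

    def test_clipped_to_chromosome(self):
        arms = exposure_intervals(100, 1_400, 4_000, 300, 2_000)
        assert arms == [(0, 2_000)]

    def test_matches_per_base_scan(self, rng):
        """Per-repeat closed form equals a direct per-position scan."""
        for _ in range(50):
            size = int(rng.integers(2_000, 20_000))
            s = int(rng.integers(0, size - 100))
            e = s + int(rng.integers(50, min(5_000, size - s)))
            L = int(rng.integers(0, 6_000))
            E = int(rng.integers(1, 800))
            ann = make_annotation({"c": size}, [("c", s, e)])
            closed = at_risk_intervals(ann, L, E)
            bp = int((closed["end"] - closed["start"]).sum()) if len(closed) else 0
            assert bp / size == per_base_oracle(ann, L, E)


# ---------------------------------------------------------------------------
# CO geometry
# ---------------------------------------------------------------------------

class TestCoRisk:
    def test_one_kb_repeat(self):
        ann = make_annotation({"c": 10_000}, [("c", 2_000, 3_000)])
        assert co_risk_fraction(ann, margin=300) == 0.04

    def test_repeat_no_longer_than_twice_margin_contributes_zero(self):
        ann = make_annotation({"c": 10_000}, [("c", 2_000, 2_600)])
        assert co_risk_fraction(ann, margin=300) == 0.0

    def test_empty_annotation(self):
        ann = make_annotation({"c": 10_000}, [])
        assert co_risk_fraction(ann, margin=300) == 0.0

    def test_overlapping_zones_merged(self):
        ann = make_annotation({"c": 100_000}, [("c", 0, 10_000), ("c", 5_000, 15_000)])
        # zones [300, 9700) and [5300, 14700) merge to [300, 14700)
        assert co_risk_fraction(ann, margin=300) == pytest.approx(14_400 / 100_000)

    def test_matches_per_base_enumeration(self, rng):
        for _ in range(40):
            ann = random_annotation(rng, max_chrom=20_000)
            margin = int(rng.integers(0, 600))
            assert co_risk_fraction(ann, margin=margin) == \
                per_base_co_oracle(ann, margin)

    def test_negative_margin_rejected(self):
        ann = make_annotation({"c": 10_000}, [("c", 0, 1_000)])
        with pytest.raises(ValueError):
            co_risk_fraction(ann, margin=-1)


# ---------------------------------------------------------------------------
# Genome-wide resection risk
# ---------------------------------------------------------------------------

class TestResectionRisk:
    def test_time_zero_is_zero(self):
        ann = make_annotation({"c": 100_000}, [("c", 10_000, 11_000)])
        assert resection_risk_fraction(ann, ResectionParams(), 0.0) == 0.0

    def test_single_gene_one_hour(self):
        ann = make_annotation({"c": 100_000}, [("c", 10_000, 11_000)])
        frac = resection_risk_fraction(ann, ResectionParams(), 1.0)
        assert frac == per_base_oracle(ann, 4_000, 300)
        assert frac == pytest.approx(0.084, rel=1e-2)

    def test_oracle_equivalence_randomized(self, rng):
        """Closed form equals the brute-force scan exactly on random genomes
        with tandem, overlapping and edge-clipped repeats."""
        params_grid = [(4_000, 300), (1_000, 300), (500, 100), (300, 300)]
        for i in range(40):
            ann = random_annotation(rng)
            L, E = params_grid[i % len(params_grid)]
            t = L / 4_000
            p = ResectionParams(min_exposure_bp=E, times_hr=[t])
            assert resection_risk_fraction(ann, p, t) == per_base_oracle(ann, L, E)

    def test_both_ends_mode_matches_oracle(self, rng):
        for _ in range(15):
            ann = random_annotation(rng)
            p = ResectionParams(both_ends=True, times_hr=[1.0])
            assert resection_risk_fraction(ann, p, 1.0) == \
                per_base_oracle(ann, 4_000, 300, both_ends=True)

    def test_both_ends_is_stricter(self, rng):
        for _ in range(10):
            ann = random_annotation(rng)
            loose = ResectionParams(times_hr=[1.0])
            strict = ResectionParams(both_ends=True, times_hr=[1.0])
            assert resection_risk_fraction(ann, strict, 1.0) <= \
                resection_risk_fraction(ann, loose, 1.0)

    def test_naive_extend_is_plain_extension(self):
        ann = make_annotation({"c": 100_000}, [("c", 10_000, 11_000)])
        p = ResectionParams(naive_extend=True, times_hr=[1.0])
        # [10000-4000, 11000+4000) = 9000 bp
        assert resection_risk_fraction(ann, p, 1.0) == 9_000 / 100_000
        # at t=0 the naive mode covers exactly the repeat body
        assert resection_risk_fraction(ann, p, 0.0) == 1_000 / 100_000

    def test_monotone_in_time_and_repeat_count(self, rng):
        ann1 = random_annotation(rng)
        params = ResectionParams(times_hr=np.linspace(0, 4, 17))
        prof = risk_profile(ann1, params)
        f = prof.table["genome_fraction"].to_numpy()
        assert (np.diff(f) >= 0).all()
        # adding a repeat never decreases the fraction
        chrom = next(iter(ann1.chrom_sizes))
        size = ann1.chrom_sizes[chrom]
        extra = pd.DataFrame([(chrom, 0, min(2_000, size), "extra", "+")],
                             columns=["chrom", "start", "end", "name", "strand"])
        ann2 = GenomeAnnotation(ann1.chrom_sizes,
                                pd.concat([ann1.intervals, extra], ignore_index=True))
        for t in (0.5, 1.0, 4.0):
            assert resection_risk_fraction(ann2, params, t) >= \
                resection_risk_fraction(ann1, params, t)

    def test_saturates_to_one(self):
        """f(t) -> 1 when every chromosome carries a long-enough repeat."""
        ann = make_annotation({"a": 50_000, "b": 30_000},
                              [("a", 10_000, 11_000), ("b", 5_000, 5_800)])
        params = ResectionParams(times_hr=[100.0])
        assert resection_risk_fraction(ann, params, 100.0) == 1.0

    def test_ordering_co_coverage_resection(self, rng):
        """CO-eligible <= static repeat coverage <= resection fraction
        (repeats >= 2*E_min, tract >= 2*E_min)."""
        for _ in range(10):
            ann = random_annotation(rng)
            long_enough = ann.intervals[(ann.intervals.end - ann.intervals.start) >= 600]
            ann = GenomeAnnotation(ann.chrom_sizes, long_enough.reset_index(drop=True))
            co = co_risk_fraction(ann, margin=300)
            cov_bp, _ = repeat_coverage(ann)
            cov = cov_bp / ann.genome_bp
            res = resection_risk_fraction(ann, ResectionParams(times_hr=[1.0]), 1.0)
            assert co <= cov <= res or (co == cov == res == 0.0)


class TestRiskProfile:
    def test_empty_annotation_all_zero(self):
        ann = make_annotation({"c": 10_000}, [])
        prof = risk_profile(ann)
        assert (prof.table["genome_fraction"] == 0).all()
        assert prof.repeat_coverage_bp == 0

    def test_single_gene_closed_form_curve(self):
        """One repeat on one chromosome: at-risk bp is exactly
        min(len + 2L - 2E + 1, C) once L >= E (clipping aside), else 0."""
        C, s, e, E = 200_000, 90_000, 91_000, 300
        ann = make_annotation({"c": C}, [("c", s, e)])
        times = np.arange(0, 4.01, 0.25)
        prof = risk_profile(ann, ResectionParams(times_hr=times))
        for _, row in prof.table.iterrows():
            L = row["L_bp"]
            expect = 0 if L < E else min((e - s) + 2 * L - 2 * E + 1, C)
            assert row["at_risk_bp"] == expect

    def test_reports_static_coverage(self):
        ann = make_annotation({"c": 100_000}, [("c", 0, 1_000), ("c", 500, 2_000)])
        prof = risk_profile(ann, ResectionParams(times_hr=[1.0]))
        assert prof.repeat_coverage_bp == 2_000          # merged
        assert prof.repeat_coverage_bp_unmerged == 2_500
        assert prof.repeat_coverage_fraction == 0.02

    def test_empty_time_grid_rejected(self):
        ann = make_annotation({"c": 10_000}, [])
        with pytest.raises(ValueError):
            risk_profile(ann, ResectionParams(times_hr=[]))


def test_per_base_oracle_refuses_large_genomes():
    ann = make_annotation({"c": 20_000_000}, [])
    with pytest.raises(ValueError, match="closed form"):
        per_base_oracle(ann, 4_000, 300)


def test_annotation_validation():
    with pytest.raises(ValueError, match="outside"):
        make_annotation({"c": 1_000}, [("c", 500, 2_000)])
    with pytest.raises(ValueError, match="unknown chromosome"):
        make_annotation({"c": 1_000}, [("d", 0, 100)])
    with pytest.raises(ValueError, match="duplicate"):
        make_annotation({"c": 1_000}, [("c", 0, 100, "g"), ("c", 200, 300, "g")])
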