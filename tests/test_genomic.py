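"""Interval operations against hand arithmetic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from coregdep import (
    GeneAnnotation,
    PeakSet,
    assign_peaks_to_tss,
    categorize_peak_locations,
    extend_peaks,
    nominate_targets,
    overlap_fraction,
)


def _peaks(rows):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _annotation(tss_rows):
    """Minimal annotation: (gene_id, chrom, strand, tss) tuples, 1-exon genes."""
    df = pd.DataFrame(
        {
            "chrom": [r[1] for r in tss_rows],
            "strand": [r[2] for r in tss_rows],
            "tss": [(r[3],) if isinstance(r[3], int) else tuple(r[3]) for r in tss_rows],
            "exons": [((min(r[3] if not isinstance(r[3], int) else [r[3]]),
                        min(r[3] if not isinstance(r[3], int) else [r[3]]) + 1000),)
                      for r in tss_rows],
        },
        index=pd.Index([r[0] for r in tss_rows], name="gene_id"),
    )
    return GeneAnnotation(df)


class TestAssignPeaksToTss:
    def test_midpoint_distance_rule(self):
        ann = _annotation([("g1", "chr1", "+", 400_000)])
        peaks = _peaks([("chr1", 140_000, 160_000)])
        out = assign_peaks_to_tss(peaks, ann, window=300_000)
        assert len(out) == 1
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["distance"] == -250_000

    def test_window_boundary_inclusive(self):
        ann = _annotation([("g1", "chr1", "+", 400_000)])
        peaks = _peaks([("chr1", 99_990, 100_010)])  # midpoint exactly 100 000
        out = assign_peaks_to_tss(peaks, ann, window=300_000)
        assert len(out) == 1

    def test_strand_orients_distance(self):
        ann = _annotation([("g1", "chr1", "-", 400_000)])
        peaks = _peaks([("chr1", 140_000, 160_000)])
        out = assign_peaks_to_tss(peaks, ann, window=300_000)
        # upstream on the minus strand = larger coordinate; this peak is
        # downstream of transcription, distance +250 kb
        assert out.iloc[0]["distance"] == 250_000

    def test_missing_chromosome_skipped(self, caplog):
        ann = _annotation([("g1", "chr1", "+", 400_000)])
        peaks = _peaks([("chrUn", 100, 300)])
        with caplog.at_level("WARNING"):
            out = assign_peaks_to_tss(peaks, ann)
        assert out.empty
        assert "chrUn" in caplog.text

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        n_peaks, n_genes, window = 200, 40, 250_000
        starts = rng.integers(0, 5_000_000, size=n_peaks)
        peaks = _peaks([("chr1", int(s), int(s) + 400) for s in starts])
        tss = rng.integers(0, 5_000_000, size=n_genes)
        ann = _annotation([(f"g{i}", "chr1", "+", int(t)) for i, t in enumerate(tss)])

        got = assign_peaks_to_tss(peaks, ann, window=window)
        got_pairs = set(zip(got["peak_id"], got["gene_id"], got["distance"]))

        expected = set()
        for i, s in enumerate(starts):
            mid = (int(s) + int(s) + 400) // 2
            for j, t in enumerate(tss):
                if abs(mid - int(t)) <= window:
                    expected.add((f"peak_{i}", f"g{j}", mid - int(t)))
        assert got_pairs == expected

    def test_invariant_under_input_reordering(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 2_000_000, size=50)
        rows = [("chr1", int(s), int(s) + 200) for s in starts]
        ann = _annotation(
            [(f"g{i}", "chr1", "+", int(t)) for i, t in enumerate(rng.integers(0, 2_000_000, 10))]
        )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"] = [f"p{i}" for i in range(len(df))]
        a = assign_peaks_to_tss(PeakSet(df), ann)
        b = assign_peaks_to_tss(PeakSet(df.sample(frac=1, random_state=0)), ann)
        key = ["peak_id", "gene_id", "tss"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestNominateTargets:
    ASSIGN = pd.DataFrame(
        {"peak_id": ["p1", "p2", "p3"], "gene_id": ["g1", "g2", "g3"],
         "tss": [0, 0, 0], "distance": [0, 0, 0]}
    )

    def test_min_lists_one(self):
        got = nominate_targets(self.ASSIGN, [{"g2", "g3"}, {"g3"}], min_lists=1)
        assert got == {"g2", "g3"}

    def test_min_lists_two(self):
        got = nominate_targets(self.ASSIGN, [{"g2", "g3"}, {"g3"}], min_lists=2)
        assert got == {"g3"}

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="cross-match"):
            nominate_targets(self.ASSIGN, [])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(100)]
        assigned = rng.choice(genes, size=60, replace=False)
        assign = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(60)], "gene_id": assigned,
             "tss": 0, "distance": 0}
        )
        lists = [set(rng.choice(genes, size=30, replace=False)) for _ in range(5)]
        for min_lists in (1, 2, 3):
            got = nominate_targets(assign, lists, min_lists)
            expected = {
                g for g in assigned if sum(g in lst for lst in lists) >= min_lists
            }
            assert got == expected


class TestCategorizePeaks:
    def test_exon_beats_intron_and_intergenic(self, small_annotation):
        peaks = _peaks([("chr1", 105_500, 105_600)])  # inside gA exon 2
        out = categorize_peak_locations(peaks, small_annotation)
        assert list(out.labels) == ["exon"]

    def test_far_upstream_is_intergenic(self, small_annotation):
        peaks = _peaks([("chr1", 10_000, 10_100)])
        out = categorize_peak_locations(peaks, small_annotation)
        assert list(out.labels) == ["intergenic"]

    def test_promoter_strand_orientation(self, small_annotation):
        # gB is on the minus strand at 400 000: its promoter extends upstream
        # toward larger coordinates
        peaks = _peaks([("chr1", 402_000, 402_010)])
        out = categorize_peak_locations(peaks, small_annotation)
        assert list(out.labels) == ["promoter"]

    def test_counts_partition_peaks(self, small_annotation):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 500_000, 50)]
        out = categorize_peak_locations(_peaks(rows), small_annotation)
        assert sum(out.counts.values()) == 50

    def test_matches_per_position_oracle(self, small_annotation):
        rng = np.random.default_rng(5)
        rows = [
            (c, int(s), int(s) + 200)
            for c, s in zip(
                rng.choice(["chr1", "chr2"], 40), rng.integers(0, 500_000, 40)
            )
        ]
        peaks = _peaks(rows)
        got = list(categorize_peak_locations(peaks, small_annotation).labels)

        def oracle(chrom, mid):
            ann = small_annotation.df
            for _, row in ann[ann["chrom"] == chrom].iterrows():
                for t in row["tss"]:
                    lo, hi = (t - 3000, t + 500) if row["strand"] == "+" else (t - 500, t + 3000)
                    if lo <= mid <= hi:
                        return "promoter"
            for _, row in ann[ann["chrom"] == chrom].iterrows():
                if any(s <= mid < e for s, e in row["exons"]):
                    return "exon"
            for _, row in ann[ann["chrom"] == chrom].iterrows():
                if row["exons"][0][0] <= mid < row["exons"][-1][1]:
                    return "intron"
            return "intergenic"

        expected = [
            oracle(r[0], (r[1] + r[2]) // 2) for r in rows
        ]
        assert got == expected


class TestOverlapFraction:
    def test_identity_and_disjoint(self):
        a = _peaks([("chr1", 0, 100), ("chr1", 200, 300)])
        b = _peaks([("chr1", 1000, 1100)])
        assert overlap_fraction(a, a) == 1.0
        assert overlap_fraction(a, b) == 0.0

    def test_two_of_three(self):
        a = _peaks([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 500, 600)])
        b = _peaks([("chr1", 250, 260), ("chr1", 590, 700)])
        assert overlap_fraction(a, b) == pytest.approx(2 / 3)

    def test_empty_a_warns_and_returns_zero(self):
        a = PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        b = _peaks([("chr1", 0, 100)])
        with pytest.warns(UserWarning):
            assert overlap_fraction(a, b) == 0.0

    def test_invariant_to_shuffle_and_split(self):
        rng = np.random.default_rng(9)
        rows_a = [("chr1", int(s), int(s) + 150) for s in rng.integers(0, 100_000, 30)]
        rows_b = [("chr1", int(s), int(s) + 400) for s in rng.integers(0, 100_000, 20)]
        a, b = _peaks(rows_a), _peaks(rows_b)
        base = overlap_fraction(a, b)
        shuffled = _peaks([rows_b[i] for i in rng.permutation(len(rows_b))])
        assert overlap_fraction(a, shuffled) == base
        # split every B interval into two adjacent halves
        split_rows = []
        for c, s, e in rows_b:
            m = (s + e) // 2
            split_rows += [(c, s, m), (c, m, e)]
        assert overlap_fraction(a, _peaks(split_rows)) == base

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        rows_a = [("chr1", int(s), int(s) + 120) for s in rng.integers(0, 50_000, 400)]
        rows_b = [("chr1", int(s), int(s) + 80) for s in rng.integers(0, 50_000, 300)]
        got = overlap_fraction(_peaks(rows_a), _peaks(rows_b))
        hit = sum(
            1
            for _, sa, ea in rows_a
            if any(sa < eb and sb < ea for _, sb, eb in rows_b)
        )
        assert got == pytest.approx(hit / len(rows_a))


class TestExtendPeaks:
    def test_basic_pad(self):
        out = extend_peaks(_peaks([("chr1", 5000, 6000)]), 1000, {"chr1": 10**6})
        assert (out.df.loc[0, "start"], out.df.loc[0, "end"]) == (4000, 7000)

    def test_left_clip_at_zero(self):
        out = extend_peaks(_peaks([("chr1", 300, 500)]), 1000, {"chr1": 10**6})
        assert (out.df.loc[0, "start"], out.df.loc[0, "end"]) == (0, 1500)

    def test_right_clip_at_chrom_end(self):
        out = extend_peaks(_peaks([("chr1", 900, 950)]), 1000, {"chr1": 1000})
        assert (out.df.loc[0, "start"], out.df.loc[0, "end"]) == (0, 1000)

    def test_zero_pad_identity(self):
        peaks = _peaks([("chr1", 300, 500)])
        out = extend_peaks(peaks, 0)
        pd.testing.assert_frame_equal(out.df, peaks.df)

    def test_missing_chrom_size_errors(self):
        with pytest.raises(KeyError, match="chr1"):
            extend_peaks(_peaks([("chr1", 300, 500)]), 10, {"chr2": 1000})


class TestPeakSetIO:
    def test_bed_round_trip(self, tmp_path):
        peaks = PeakSet(
            pd.DataFrame(
                {"chrom": ["chr1", "chr2"], "start": [10, 20], "end": [100, 200],
                 "name": ["a", "b"], "score": [1.0, 2.5], "strand": ["+", "-"]}
            )
        )
        path = tmp_path / "p.bed"
        peaks.write_bed(path)
        back = PeakSet.read_bed(path)
        pd.testing.assert_frame_equal(back.df, peaks.df)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start < end"):
            _peaks([("chr1", 100, 100)])
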