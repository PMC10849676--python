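"""Cross-lane joining, significance filter, gene association, enhancer
intersection (incl. bedtools oracle) and PWM scanning (incl. Biopython
oracle)."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmptargets.annotate import (
    GeneModel,
    JoinedPeak,
    associate_genes,
    filter_significant,
    intersect_enhancers,
    join_peaks,
    read_bed,
    read_gff3_genes,
    scan_motif,
    write_gff3_genes,
)
from bmptargets.peakcall import Peak


def peak(summit, lane, h=100.0, e=12.0, d=1.0, chrom="chr1"):
    return Peak(
        chrom=chrom, start=summit - 150, end=summit + 150, summit=summit,
        height=h, enrichment=e, dist_score=d, score=h * d, lane_id=lane,
    )


def joined(summit=500, e=12.0, s=100.0, chrom="chr1", start=None, end=None):
    return JoinedPeak(
        chrom=chrom, consensus_summit=summit, members=[], n_lanes=2,
        mean_height=s, mean_enrichment=e, mean_score=s,
        start=start if start is not None else summit - 150,
        end=end if end is not None else summit + 150,
    )


class TestJoinPeaks:
    def test_gap_rule_100bp(self):
        one = join_peaks({"A": [peak(1000, "A")], "B": [peak(1090, "B")]})
        assert len(one) == 1
        assert one[0].consensus_summit == 1045
        two = join_peaks({"A": [peak(1000, "A")], "B": [peak(1110, "B")]}, min_lanes=1)
        assert len(two) == 2

    def test_single_lane_passthrough(self):
        res = join_peaks({"A": [peak(100, "A"), peak(900, "A")]}, min_lanes=1)
        assert [j.consensus_summit for j in res] == [100, 900]

    def test_single_linkage_chain(self):
        res = join_peaks(
            {"A": [peak(200, "A"), peak(380, "A")], "B": [peak(290, "B")]}, min_lanes=1
        )
        assert len(res) == 1  # consecutive gaps of 90 <= 100 chain up

    def test_min_lanes_drops_unreplicated(self):
        res = join_peaks({"A": [peak(1000, "A")], "B": [peak(5000, "B")]}, min_lanes=2)
        assert res == []

    def test_lane_relabeling_and_order_invariance(self):
        lanes1 = {"A": [peak(1000, "A"), peak(3000, "A")], "B": [peak(1050, "B")]}
        lanes2 = {"X": [peak(1050, "X")], "Y": [peak(3000, "Y"), peak(1000, "Y")]}
        r1 = join_peaks(lanes1, min_lanes=1)
        r2 = join_peaks(lanes2, min_lanes=1)
        assert [j.consensus_summit for j in r1] == [j.consensus_summit for j in r2]

    def test_empty_input(self):
        assert join_peaks({}) == []


class TestFilterSignificant:
    @pytest.mark.parametrize(
        "e, s, kept",
        [
            (10.0, 80.0, True),  # thresholds are inclusive ("at least")
            (9.99, 200.0, False),
            (200.0, 79.99, False),
            (10.01, 80.01, True),
        ],
    )
    def test_boundary_inclusive(self, e, s, kept):
        assert (len(filter_significant([joined(e=e, s=s)])) == 1) is kept

    def test_enumeration(self):
        peaks = [
            joined(e=11, s=90),
            joined(e=5, s=90),
            joined(e=11, s=30),
            joined(e=15, s=200),
            joined(e=1, s=1),
        ]
        assert len(filter_significant(peaks)) == 2

    @given(st.floats(0, 50), st.floats(0, 300))
    def test_monotone_in_thresholds(self, min_e, min_s):
        peaks = [joined(e=e, s=s) for e in (1, 5, 12, 30) for s in (10, 85, 120)]
        loose = filter_significant(peaks, 0, 0)
        tight = filter_significant(peaks, min_e, min_s)
        assert len(tight) <= len(loose)
        assert all(p in loose for p in tight)


class TestAssociateGenes:
    genes = [
        GeneModel("geneA", "chr1", "+", 10_000, (10_000, 15_000)),
        GeneModel("geneB", "chr1", "+", 18_000, (18_000, 23_000)),
        GeneModel("geneC", "chr1", "-", 49_999, (45_000, 50_000)),
    ]

    def test_nearest_tss_wins(self):
        res = associate_genes([joined(summit=13_000)], self.genes)
        assert res[0].gene_id == "geneA"  # inside geneA and 3 kb < 5 kb

    def test_upstream_distance_sign(self):
        res = associate_genes([joined(summit=9000)], self.genes)
        assert res[0].gene_id == "geneA"
        assert res[0].distance_to_tss == -1000  # 1 kb upstream on + strand
        res = associate_genes([joined(summit=52_000)], self.genes)
        assert res[0].gene_id == "geneC"
        assert res[0].distance_to_tss == -2001  # upstream of a - strand TSS

    def test_out_of_range_unassigned(self):
        res = associate_genes([joined(summit=9000)], self.genes, max_assoc_dist=500)
        assert res[0].gene_id is None

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [
            GeneModel("geneB", "chr1", "+", 12_000, (12_000, 13_000)),
            GeneModel("geneA", "chr1", "+", 8_000, (8_000, 9_000)),
        ]
        res = associate_genes([joined(summit=10_000)], genes)
        assert res[0].gene_id == "geneA"

    def test_tss_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "chr1", "+", 99, (100, 200))

    def test_target_counts_bounded_by_peak_count(self):
        peaks = [joined(summit=s) for s in (9000, 9500, 13_000, 40_000)]
        res = associate_genes(peaks, self.genes)
        assert len(res) == len(peaks)
        distinct = {t.gene_id for t in res if t.gene_id}
        assert len(distinct) <= len(res)


class TestIntersectEnhancers:
    def test_one_bp_overlap_counts(self):
        assert intersect_enhancers(
            [joined(start=100, end=200)], [("chr1", 199, 300)]
        ) == [True]

    def test_halfopen_abutment_does_not(self):
        assert intersect_enhancers(
            [joined(start=100, end=200)], [("chr1", 200, 300)]
        ) == [False]

    def test_containment_counts(self):
        assert intersect_enhancers(
            [joined(start=100, end=200)], [("chr1", 0, 1000)]
        ) == [True]

    def test_agrees_with_exhaustive_check(self, rng):
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 10_000))
            peaks.append(joined(summit=s + 50, start=s, end=s + int(rng.integers(1, 400))))
        enh = [
            ("chr1", int(s), int(s) + int(rng.integers(1, 300)))
            for s in rng.integers(0, 10_000, 40)
        ]
        expected = [
            any(p.start < e2 and e1 < p.end for c, e1, e2 in enh) for p in peaks
        ]
        assert intersect_enhancers(peaks, enh) == expected

    def test_agrees_with_bedtools(self, rng, tmp_path):
        assert shutil.which("bedtools"), "bedtools expected on PATH"
        peaks = []
        for i in range(40):
            s = int(rng.integers(0, 5000))
            peaks.append(joined(summit=s + 10, start=s, end=s + int(rng.integers(1, 200))))
        enh = [
            ("chr1", int(s), int(s) + int(rng.integers(1, 150)))
            for s in rng.integers(0, 5000, 25)
        ]
        a = tmp_path / "peaks.bed"
        b = tmp_path / "enh.bed"
        a.write_text("".join(f"chr1\t{p.start}\t{p.end}\tp{i}\n" for i, p in enumerate(peaks)))
        b.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in sorted(enh)))
        out = subprocess.run(
            ["bedtools", "intersect", "-u", "-a", str(a), "-b", str(b)],
            capture_output=True, text=True, check=True,
        ).stdout
        hit_names = {line.split("\t")[3] for line in out.strip().splitlines() if line}
        expected = [f"p{i}" in hit_names for i in range(len(peaks))]
        assert intersect_enhancers(peaks, enh) == expected

    def test_malformed_bed_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t20\nchr1\tx\t30\n")
        with pytest.raises(ValueError, match="2"):
            read_bed(p)


BRE_LIKE_PFM = np.array(
    [
        # consensus GGCGCC
        [0, 0, 1, 0, 0, 1],
        [1, 0, 8, 0, 10, 8],
        [9, 10, 0, 10, 0, 0],
        [0, 0, 1, 0, 0, 1],
    ],
    dtype=float,
)


class TestScanMotif:
    def test_consensus_scores_column_maxima(self):
        with np.errstate(divide="ignore"):
            logodds = np.log2((BRE_LIKE_PFM / BRE_LIKE_PFM.sum(0)) / 0.25)
        expected = logodds.max(axis=0).sum()
        hit = scan_motif("GGCGCC", BRE_LIKE_PFM, threshold=0.0)
        assert hit.score == pytest.approx(expected)
        assert hit.has_motif and hit.position == 0 and hit.strand == "+"

    def test_reverse_strand_site_found(self):
        # revcomp of GGCGCC is GGCGCC (palindrome-ish); use asymmetric motif
        pfm = np.array(
            [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0], [0, 0, 0, 10]], dtype=float
        )  # consensus ACGT; revcomp ACGT -> ACGT is palindromic too. Use AACG:
        pfm = np.array(
            [[10, 10, 0, 0], [0, 0, 10, 0], [0, 0, 0, 10], [0, 0, 0, 0]], dtype=float
        )  # consensus AACG; revcomp = CGTT
        hit = scan_motif("TTTCGTTTTT", pfm, threshold=5.0)
        assert hit.has_motif and hit.strand == "-" and hit.position == 3

    def test_matches_bruteforce_rescoring(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        pfm = rng.integers(0, 10, (4, 7)).astype(float) + 1
        with np.errstate(divide="ignore"):
            lo = np.log2((pfm / pfm.sum(0)) / 0.25)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(seq))
        best = -np.inf
        L = pfm.shape[1]
        for i in range(len(seq) - L + 1):
            f = sum(lo["ACGT".index(seq[i + j]), j] for j in range(L))
            r = sum(lo["ACGT".index(rc[i + j]), j] for j in range(L))
            best = max(best, f, r)
        hit = scan_motif(seq, pfm, threshold=np.inf)
        assert hit.score == pytest.approx(best)

    def test_matches_biopython_pssm(self):
        from Bio import motifs
        from Bio.Seq import Seq

        instances = [Seq("GGCGCC"), Seq("GGCGCC"), Seq("GACGTC"), Seq("GGAGCC")]
        m = motifs.create(instances)
        pssm = m.counts.normalize().log_odds()
        seq = "TTGGCGCCATGACGTCTTACGTGGA"
        fwd = np.asarray(pssm.calculate(Seq(seq)), dtype=float)
        rev = np.asarray(pssm.calculate(Seq(seq).reverse_complement()), dtype=float)[::-1]
        expected = np.nanmax(np.maximum(fwd, rev))
        pfm = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        hit = scan_motif(seq, pfm, threshold=0.0)
        assert hit.score == pytest.approx(expected, abs=1e-5)

    def test_n_scores_zero_bits(self):
        pfm = np.full((4, 3), 5.0)
        hit = scan_motif("NNN", pfm, threshold=0.0)
        assert hit.score == pytest.approx(0.0)

    def test_zero_column_sum_rejected(self):
        pfm = BRE_LIKE_PFM.copy()
        pfm[:, 2] = 0
        with pytest.raises(ValueError):
            scan_motif("GGCGCC", pfm, threshold=0.0)


class TestGff3RoundTrip:
    def test_roundtrip(self, tmp_path):
        genes = [
            GeneModel("g1", "chr1", "+", 100, (100, 500)),
            GeneModel("g2", "chr2", "-", 899, (300, 900)),
        ]
        p = tmp_path / "genes.gff3"
        write_gff3_genes(genes, p)
        assert p.read_text().startswith("##gff-version 3\n")
        back = read_gff3_genes(p)
        assert [(g.gene_id, g.chrom, g.strand, g.tss, g.span) for g in back] == [
            (g.gene_id, g.chrom, g.strand, g.tss, g.span) for g in genes
        ]
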