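"""FPKM/TE arithmetic, consensus-peak pairing, segment assignment."""
import numpy as np
import pandas as pd
import pytest

from trilayer.io import GeneModel, PeakRecord, SampleMeta
from trilayer.quantify import (
    ConsensusPeak,
    annotate_peaks,
    assign_segment,
    compute_fpkm,
    compute_te,
    consensus_peaks,
    expressed_filter,
    gene_m6a_level,
    segment_distribution,
)
from conftest import make_matrix


def simple_models(lengths: dict[str, int]):
    out = {}
    pos = 0
    for gid, L in lengths.items():
        out[gid] = GeneModel(gid, "chr1", "+", [(pos, pos + L)], pos + 10, pos + L - 10)
        pos += L + 1000
    return out


class TestFpkm:
    def test_direct_formula(self):
        metas = [SampleMeta("s1", "P1", "mrna_input", 1)]
        m = make_matrix({"s1": np.array([100, 999_900])}, metas, genes=["gA", "gB"])
        models = simple_models({"gA": 2000, "gB": 1000})
        f = compute_fpkm(m, models)
        # count 100, length 2000 nt, library 1e6 -> 50
        assert f.loc["gA", "s1"] == pytest.approx(50.0)

    def test_zero_count_gives_zero(self):
        metas = [SampleMeta("s1", "P1", "mrna_input", 1)]
        m = make_matrix({"s1": np.array([0, 10])}, metas, genes=["gA", "gB"])
        f = compute_fpkm(m, simple_models({"gA": 500, "gB": 500}))
        assert f.loc["gA", "s1"] == 0.0

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, 50)
        metas = [SampleMeta("s1", "P1", "mrna_input", 1), SampleMeta("s2", "P1", "mrna_input", 2)]
        m = make_matrix({"s1": counts, "s2": counts * 2}, metas)
        models = simple_models({f"g{i}": 100 * (i + 1) for i in range(50)})
        f = compute_fpkm(m, models)
        np.testing.assert_allclose(f["s1"], f["s2"])

    def test_count_proportional_to_length_gives_equal_fpkm(self):
        lengths = np.array([100, 200, 400, 800])
        metas = [SampleMeta("s1", "P1", "mrna_input", 1)]
        m = make_matrix({"s1": lengths * 3}, metas, genes=[f"g{i}" for i in range(4)])
        models = simple_models({f"g{i}": int(l) for i, l in enumerate(lengths)})
        f = compute_fpkm(m, models)
        assert f["s1"].nunique() == 1

    def test_zero_library_hard_error(self):
        metas = [SampleMeta("s1", "P1", "mrna_input", 1)]
        m = make_matrix({"s1": np.array([0, 0])}, metas, genes=["gA", "gB"])
        with pytest.raises(ValueError, match="zero total"):
            compute_fpkm(m, simple_models({"gA": 100, "gB": 100}))


class TestExpressedAndTe:
    def _matrix(self):
        metas = [
            SampleMeta("i1", "P1", "mrna_input", 1),
            SampleMeta("i2", "P1", "mrna_input", 2),
            SampleMeta("p1", "P1", "polysome", 1),
            SampleMeta("p2", "P1", "polysome", 2),
        ]
        return metas

    def test_mean_replicate_rule(self):
        metas = self._matrix()
        fpkm = pd.DataFrame(
            {"i1": [0.8, 0.0], "i2": [1.4, 0.0], "p1": [1.0, 1.0], "p2": [1.0, 1.0]},
            index=["gA", "gB"],
        )
        m = make_matrix({k: np.array([1, 1]) for k in ["i1", "i2", "p1", "p2"]}, metas, genes=["gA", "gB"])
        ex = expressed_filter(fpkm, m, 1.0)
        assert "gA" in ex[("P1", "mrna_input")]  # mean 1.1 >= 1
        assert "gB" not in ex[("P1", "mrna_input")]

    def test_threshold_zero_admits_all(self):
        metas = self._matrix()
        fpkm = pd.DataFrame({k: [0.0, 0.5] for k in ["i1", "i2", "p1", "p2"]}, index=["gA", "gB"])
        m = make_matrix({k: np.array([0, 1]) for k in ["i1", "i2", "p1", "p2"]}, metas, genes=["gA", "gB"])
        ex = expressed_filter(fpkm, m, 0.0)
        assert ex[("P1", "mrna_input")] == {"gA", "gB"}

    def test_te_ratio_and_undefined(self):
        metas = self._matrix()
        fpkm = pd.DataFrame(
            {"i1": [10.0, 0.4, 5.0], "i2": [10.0, 0.4, 5.0],
             "p1": [20.0, 9.0, 0.0], "p2": [20.0, 9.0, 0.0]},
            index=["gA", "gB", "gC"],
        )
        m = make_matrix({k: np.array([1, 1, 1]) for k in ["i1", "i2", "p1", "p2"]}, metas,
                        genes=["gA", "gB", "gC"])
        ex = expressed_filter(fpkm, m, 1.0)
        te = compute_te(fpkm, m, ex)
        assert te.loc["gA", "P1"] == pytest.approx(2.0)   # poly 20 / input 10
        assert np.isnan(te.loc["gB", "P1"])                # input below floor
        assert te.loc["gC", "P1"] == 0.0                   # poly 0, input 5


def pk(start, end, fe, rep, summit=None, chrom="chr1", name=""):
    return PeakRecord(chrom, start, end, summit if summit is not None else (start + end) // 2,
                      fe, 1e-5, rep, name)


class TestConsensusPeaks:
    def test_identical_peaks_give_identity(self):
        (c,) = consensus_peaks([pk(100, 300, 4.0, 1)], [pk(100, 300, 6.0, 2)])
        assert (c.start, c.end) == (100, 300)
        assert c.m6a_level == pytest.approx(5.0)

    def test_union_interval(self):
        (c,) = consensus_peaks([pk(100, 300, 4.0, 1)], [pk(250, 400, 2.0, 2)])
        assert (c.start, c.end) == (100, 400)

    def test_summit_from_higher_enrichment_replicate(self):
        (c,) = consensus_peaks([pk(100, 300, 4.0, 1, summit=120)],
                               [pk(100, 300, 6.0, 2, summit=280)])
        assert c.summit == 280

    def test_disjoint_peaks_give_nothing(self):
        assert consensus_peaks([pk(100, 200, 4.0, 1)], [pk(300, 400, 2.0, 2)]) == []

    def test_multi_partner_prefers_largest_overlap_each_used_once(self):
        r1 = [pk(100, 300, 4.0, 1, name="a"), pk(290, 500, 3.0, 1, name="b")]
        r2 = [pk(250, 480, 5.0, 2, name="c")]
        out = consensus_peaks(r1, r2)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (250, 500)  # b+c (overlap 190 > a+c 50)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        r1, r2 = [], []
        pos = 0
        for i in range(50):
            pos += int(rng.integers(200, 500))
            w = int(rng.integers(80, 200))
            r1.append(pk(pos, pos + w, float(rng.uniform(2, 9)), 1))
            if rng.random() < 0.7:
                s = pos + int(rng.integers(-60, 60))
                r2.append(pk(s, s + w, float(rng.uniform(2, 9)), 2))
        r2.sort(key=lambda p: (p.chrom, p.start))
        fwd = consensus_peaks(r1, r2)
        rev = consensus_peaks(r2, r1)
        key = lambda c: (c.chrom, c.start, c.end, round(c.m6a_level, 9), c.summit)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))


class TestSegmentAssignment:
    def brute_force_expected(self, gm, window):
        """Independent oracle: build per-segment transcript position sets from
        the exon/CDS intervals, then apply window overrides."""
        half = window // 2
        exonic = list(range(gm.mature_length))
        # CDS membership from genomic CDS interval
        cds_pos = {
            t for t in exonic
            if gm.cds_start <= gm.from_transcript(t) < gm.cds_end
        }
        # orient via genomic position of extreme CDS bases
        tpos_of = {gm.from_transcript(t): t for t in exonic}
        if gm.strand == "+":
            start_c, stop_c = tpos_of[gm.cds_start], tpos_of[gm.cds_end - 1]
        else:
            start_c, stop_c = tpos_of[gm.cds_end - 1], tpos_of[gm.cds_start]
        expected = {}
        for t in exonic:
            if abs(t - start_c) <= half:
                expected[t] = "start"
            elif abs(t - stop_c) <= half:
                expected[t] = "stop"
            elif t in cds_pos:
                expected[t] = "cds"
            elif t < start_c:
                expected[t] = "utr5"
            else:
                expected[t] = "utr3"
        return expected

    @pytest.mark.parametrize("which", ["gene_plus", "gene_minus"])
    def test_agrees_with_brute_force_scan(self, which, request):
        gm = request.getfixturevalue(which)
        expected = self.brute_force_expected(gm, 200)
        for t, want in expected.items():
            assert assign_segment(t, gm, 200) == want, f"t={t}"

    def test_stop_window_inside_utr3(self, gene_plus):
        # 80 nt downstream of the stop codon, inside the 3'UTR
        _, stop_c = gene_plus.transcript_landmarks()
        assert assign_segment(stop_c + 80, gene_plus, 200) == "stop"

    def test_outside_window_is_utr3(self, gene_plus):
        _, stop_c = gene_plus.transcript_landmarks()
        assert assign_segment(stop_c + 150, gene_plus, 200) == "utr3"

    def test_window_boundary_inclusive(self, gene_plus):
        _, stop_c = gene_plus.transcript_landmarks()
        assert assign_segment(stop_c + 100, gene_plus, 200) == "stop"
        assert assign_segment(stop_c + 101, gene_plus, 200) == "utr3"

    def test_intron_and_intergenic_via_annotate(self, gene_plus):
        peaks = [
            ConsensusPeak("chr1", 1250, 1350, 1300, 5.0),   # intron
            ConsensusPeak("chr1", 5000, 5100, 5050, 5.0),   # outside any gene
        ]
        out = annotate_peaks(peaks, [gene_plus], 200)
        assert out[0].segment == "intron" and out[0].gene_id == "gplus"
        assert out[1].segment == "intergenic" and out[1].gene_id is None


class TestGeneLevelAndDistribution:
    def test_level_is_max_over_peaks(self):
        peaks = [
            ConsensusPeak("chr1", 0, 10, 5, 3.0, gene_id="gA", segment="utr3"),
            ConsensusPeak("chr1", 20, 30, 25, 7.0, gene_id="gA", segment="stop"),
            ConsensusPeak("chr1", 0, 10, 5, 5.0, gene_id="gB", segment="utr3"),
        ]
        lv = gene_m6a_level(peaks)
        assert lv["gA"] == 7.0 and lv["gB"] == 5.0
        assert "gC" not in lv

    def test_single_peak_mean_of_replicates(self):
        (c,) = consensus_peaks([pk(0, 100, 4.0, 1)], [pk(0, 100, 6.0, 2)])
        c.gene_id = "gA"
        assert gene_m6a_level([c])["gA"] == pytest.approx(5.0)

    def test_distribution_sums_to_one(self):
        peaks = [ConsensusPeak("c", 0, 1, 0, 1.0, gene_id="g", segment=s)
                 for s in ["utr3"] * 7 + ["stop"] * 2 + ["cds"]]
        d = segment_distribution(peaks)
        assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)
        assert d["utr3"] == pytest.approx(0.7)

    def test_all_one_segment(self):
        peaks = [ConsensusPeak("c", 0, 1, 0, 1.0, gene_id="g", segment="utr3")] * 10
        assert segment_distribution(peaks)["utr3"] == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            segment_distribution([])
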