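import numpy as np
import pandas as pd
import pytest

from exprnet import genomic
from exprnet.genomic import (
    AnnotationParseError,
    GeneAnnotation,
    MissingMethylationError,
    PromoterRegion,
    TFPeak,
    aggregate_methylation,
    derive_regions,
    map_tf_candidates,
    methylation_matrix,
    read_annotation,
)

GTF = """\
chr1\tsrc\ttranscript\t1001\t5000\t.\t+\t.\tgene_id "GA"; gene_name "GA"; transcript_id "GA.1";
chr1\tsrc\ttranscript\t1001\t5000\t.\t-\t.\tgene_id "GB"; gene_name "GB"; transcript_id "GB.1";
chr1\tsrc\ttranscript\t1001\t7000\t.\t+\t.\tgene_id "GA"; gene_name "GA"; transcript_id "GA.2";
chr1\tsrc\ttranscript\t9001\t9500\t.\t+\t.\tgene_id "GA"; gene_name "GA"; transcript_id "GA.3";
"""


class TestReadAnnotation:
    def test_gtf_tss_conventions_and_dedup(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        genes = {g.gene_symbol: g for g in read_annotation(p, "gtf")}
        # + strand TSS is the (0-based) start; two transcripts sharing it collapse
        assert genes["GA"].tss_list == (1000, 9000)
        # - strand TSS is the last transcribed base
        assert genes["GB"].tss_list == (4999,)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tsrc\ttranscript\t100\n")
        with pytest.raises(AnnotationParseError, match="line 1"):
            read_annotation(p, "gtf")

    def test_missing_strand_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t1001\t5000\t.\t.\t.\tgene_name "GX";\n'
            'chr1\tsrc\ttranscript\t1001\t5000\t.\t+\t.\tgene_name "GY";\n'
        )
        with caplog.at_level("WARNING", logger="exprnet"):
            genes = read_annotation(p, "gtf")
        assert [g.gene_symbol for g in genes] == ["GY"]
        assert "strand" in caplog.text

    def test_bed_strand_aware_tss(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr2\t1000\t1001\tGP\t0\t+\nchr2\t5000\t5001\tGM\t0\t-\n")
        genes = {g.gene_symbol: g for g in read_annotation(p, "bed")}
        assert genes["GP"].tss_list == (1000,)
        assert genes["GM"].tss_list == (5000,)


class TestDeriveRegions:
    @pytest.mark.parametrize(
        "strand,tss,expected",
        [
            ("+", 10000, (8000, 11000)),
            ("-", 10000, (9001, 12001)),
            ("+", 500, (0, 1500)),  # clamped at chromosome start
        ],
    )
    def test_promoter_window(self, strand, tss, expected):
        g = GeneAnnotation("G", "chr1", strand, (tss,))
        (r,) = derive_regions(g, 2000, 1000, "promoter")
        assert (r.start, r.end) == expected
        assert r.start <= tss < r.end

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_region_lengths(self, strand, rng):
        for tss in rng.integers(10_000, 1_000_000, size=50):
            g = GeneAnnotation("G", "chr1", strand, (int(tss),))
            (prom,) = derive_regions(g, 2000, 1000, "promoter")
            (area,) = derive_regions(g, 4000, 1000, "methyl_area")
            assert prom.end - prom.start == 3000
            assert area.end - area.start == 5000

    def test_strand_symmetry(self, rng):
        # reflecting coordinates and flipping strand mirrors the window
        L = 10_000_000
        for tss in rng.integers(10_000, 1_000_000, size=50):
            tss = int(tss)
            (fwd,) = derive_regions(GeneAnnotation("G", "c", "+", (tss,)), 2000, 1000)
            (rev,) = derive_regions(
                GeneAnnotation("G", "c", "-", (L - 1 - tss,)), 2000, 1000
            )
            # the half-open interval [a, b) reflected by x -> L-1-x is [L-b, L-a)
            assert (rev.start, rev.end) == (L - fwd.end, L - fwd.start)

    def test_negative_extents_rejected(self):
        g = GeneAnnotation("G", "chr1", "+", (1000,))
        with pytest.raises(ValueError):
            derive_regions(g, -1, 1000)


def _prom(gene, start, end, chrom="chr1"):
    return PromoterRegion(gene, chrom, start, end, tss=start, region_kind="promoter")


class TestMapTFCandidates:
    def test_overlap_and_halfopen_boundary(self):
        promoters = [_prom("g", 8000, 11000)]
        peaks = [
            TFPeak("t1", "chr1", 8100, 8200),
            TFPeak("t2", "chr1", 11000, 11100),  # touches only the open end
            TFPeak("t3", "chr2", 8100, 8200),  # wrong chromosome
        ]
        result = map_tf_candidates(peaks, promoters)
        assert result == {"g": {"t1"}}

    def test_tf_binding_two_promoters_listed_once(self):
        promoters = [_prom("g", 8000, 11000), _prom("g", 50_000, 53_000)]
        peaks = [TFPeak("t1", "chr1", 8100, 8200), TFPeak("t1", "chr1", 50_100, 50_200)]
        assert map_tf_candidates(peaks, promoters) == {"g": {"t1"}}

    def test_empty_peaks_valid(self):
        assert map_tf_candidates([], [_prom("g", 0, 3000)]) == {}

    def test_matches_per_base_brute_force(self, rng):
        # the interval-tree overlap agrees with a per-base scan
        for _ in range(50):
            ps, pe = sorted(rng.integers(0, 60, size=2) + [0, 1])
            qs, qe = sorted(rng.integers(0, 60, size=2) + [0, 1])
            brute = len(set(range(ps, pe)) & set(range(qs, qe))) > 0
            got = map_tf_candidates(
                [TFPeak("t", "c", int(qs), int(qe))],
                [_prom("g", int(ps), int(pe), chrom="c")],
            )
            assert (got == {"g": {"t"}}) == brute

    def test_rejects_non_promoter_regions(self):
        area = PromoterRegion("g", "chr1", 0, 5000, 100, "methyl_area")
        with pytest.raises(ValueError):
            map_tf_candidates([], [area])


def _area(gene, start, end):
    return PromoterRegion(gene, "chr1", start, end, tss=start, region_kind="methyl_area")


class TestAggregateMethylation:
    def probes(self, rows):
        df = pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "s1"])
        return df

    def test_mean_beta(self):
        probes = self.probes([("p1", "chr1", 100, 0.2), ("p2", "chr1", 200, 0.4)])
        out = aggregate_methylation(probes, [_area("g", 0, 5000)])
        assert out["s1"] == pytest.approx(0.3)

    def test_probe_in_overlapping_areas_counted_once(self):
        probes = self.probes([("p1", "chr1", 4800, 0.5), ("p2", "chr1", 100, 0.1)])
        out = aggregate_methylation(probes, [_area("g", 0, 5000), _area("g", 4000, 9000)])
        assert out["s1"] == pytest.approx(0.3)  # mean(0.5, 0.1), p1 not doubled

    def test_missing_betas_skipped(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "chrom": "chr1",
                "position": [10, 20, 30],
                "s1": [0.2, np.nan, 0.6],
            }
        )
        out = aggregate_methylation(probes, [_area("g", 0, 5000)])
        assert out["s1"] == pytest.approx(0.4)

    def test_no_probes_flags_gene(self):
        probes = self.probes([("p1", "chr1", 9000, 0.2)])
        with pytest.raises(MissingMethylationError):
            aggregate_methylation(probes, [_area("g", 0, 5000)])
        mat, missing = methylation_matrix(probes, {"g": [_area("g", 0, 5000)]})
        assert missing == ["g"]
        assert "g" not in mat.columns

    def test_beta_out_of_range_rejected(self):
        probes = self.probes([("p1", "chr1", 100, 1.2)])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            aggregate_methylation(probes, [_area("g", 0, 5000)])
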