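"""Transcript model, GTF round trip, duplicate collapse, and genomic
classification against brute-force oracles."""

import numpy as np
import pytest

from lncsuite.annotation import (
    AnnotationError,
    GenomeAnnotation,
    GTFParseError,
    RelationKind,
    TranscriptModel,
    classify_candidate,
    deduplicate_transcripts,
    exonic_overlap,
    genomic_relation,
    read_gtf,
    shift_transcript,
    write_bed6,
    write_gtf,
)


def tx(tid, exons, strand="+", chrom="chr1", biotype="candidate", gene=None):
    return TranscriptModel(tid, gene or tid, chrom, strand, tuple(exons), biotype)


class TestTranscriptModel:
    def test_length_sums_exons(self):
        t = tx("t1", [(100, 129), (299, 501)])
        assert t.length() == 29 + 202
        assert t.span == (100, 501)
        assert t.introns == ((129, 299),)

    @pytest.mark.parametrize(
        "exons",
        [[], [(10, 10)], [(20, 10)], [(0, 50), (40, 80)], [(50, 80), (0, 40)]],
    )
    def test_invalid_exons_rejected(self, exons):
        with pytest.raises(AnnotationError):
            tx("bad", exons)

    def test_bad_strand_rejected(self):
        with pytest.raises(AnnotationError):
            tx("bad", [(0, 10)], strand=".")


class TestReadGtf:
    def test_coordinate_conversion(self, tmp_path):
        # 1-based closed GTF exons 101-129 and 300-501 -> 0-based half-open
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t129\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t300\t501\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        ann = read_gtf(gtf)
        t = ann["t1"]
        assert t.exons == ((100, 129), (299, 501))
        assert t.length() == 231

    def test_empty_file(self, tmp_path):
        gtf = tmp_path / "e.gtf"
        gtf.write_text("")
        assert len(read_gtf(gtf)) == 0

    def test_gene_index_groups_transcripts(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t200\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
        )
        ann = read_gtf(gtf)
        assert {t.id for t in ann.gene_transcripts("g1")} == {"t1", "t2"}

    def test_malformed_line_reports_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\tonly-two-fields\n")
        with pytest.raises(GTFParseError, match="line 1"):
            read_gtf(gtf)

    def test_strand_mismatch_rejected(self, tmp_path):
        gtf = tmp_path / "mix.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t200\t300\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(AnnotationError):
            read_gtf(gtf)

    def test_round_trip(self, tmp_path, dataset):
        path = tmp_path / "rt.gtf"
        write_gtf(dataset.annotation, path)
        back = read_gtf(path)
        assert set(back.transcript_ids) == set(dataset.annotation.transcript_ids)
        for t in dataset.annotation:
            b = back[t.id]
            assert b.exons == t.exons and b.strand == t.strand
            assert b.biotype == t.biotype

    def test_bed6_export(self, tmp_path):
        ann = GenomeAnnotation([tx("t1", [(10, 50), (80, 120)], strand="-")])
        path = tmp_path / "o.bed"
        write_bed6(ann, path)
        assert path.read_text() == "chr1\t10\t120\tt1\t0\t-\n"


class TestDeduplicate:
    def test_identical_intron_chain_collapses(self):
        a = tx("a", [(0, 100), (200, 300)])
        b = tx("b", [(10, 100), (200, 320)])  # same intron (100,200)
        out = deduplicate_transcripts(GenomeAnnotation([a, b]))
        assert out.transcript_ids == ["b"]  # longer exonic length survives

    def test_opposite_strands_kept(self):
        a = tx("a", [(0, 100), (200, 300)], strand="+")
        b = tx("b", [(0, 100), (200, 300)], strand="-")
        assert len(deduplicate_transcripts(GenomeAnnotation([a, b]))) == 2

    def test_five_transcripts_two_pairs(self):
        ts = [
            tx("a", [(0, 100), (200, 300)]),
            tx("b", [(0, 100), (200, 300)]),
            tx("c", [(500, 600)]),
            tx("d", [(500, 600)]),
            tx("e", [(900, 1100)]),
        ]
        out = deduplicate_transcripts(GenomeAnnotation(ts))
        # brute-force pairwise comparison says 3 unique structures
        assert len(out) == 3

    def test_monoexonic_needs_identical_coordinates(self):
        a = tx("a", [(0, 100)])
        b = tx("b", [(0, 101)])
        assert len(deduplicate_transcripts(GenomeAnnotation([a, b]))) == 2

    def test_tie_breaks_lexicographic(self):
        a = tx("z", [(0, 100), (200, 300)])
        b = tx("a", [(0, 100), (200, 300)])
        out = deduplicate_transcripts(GenomeAnnotation([a, b]))
        assert out.transcript_ids == ["a"]


def brute_force_classify(t, known):
    """Per-base oracle for candidate classification."""
    sense = anti = False
    for k in known:
        if k.chrom != t.chrom:
            continue
        kbases = {p for s, e in k.exons for p in range(s, e)}
        tbases = {p for s, e in t.exons for p in range(s, e)}
        if kbases & tbases:
            if k.strand == t.strand:
                sense = True
            else:
                anti = True
    if sense:
        return "sense_overlap"
    if anti:
        return "antisense"
    for k in known:
        if k.chrom != t.chrom:
            continue
        for i0, i1 in k.introns:
            if i0 <= t.start and t.end <= i1:
                return "intronic"
    return "intergenic"


class TestClassify:
    def test_candidate_inside_intron(self):
        host = tx("h", [(0, 100), (5000, 5100)], biotype="known_mRNA")
        cand = tx("c", [(1000, 1400)])
        assert classify_candidate(cand, GenomeAnnotation([host])) == "intronic"

    def test_far_candidate_is_intergenic(self):
        host = tx("h", [(0, 100)], biotype="known_mRNA")
        cand = tx("c", [(50_000, 50_400)])
        assert classify_candidate(cand, GenomeAnnotation([host])) == "intergenic"

    def test_unknown_chromosome_is_intergenic(self):
        host = tx("h", [(0, 100)], biotype="known_mRNA")
        cand = tx("c", [(0, 400)], chrom="chrZ")
        assert classify_candidate(cand, GenomeAnnotation([host])) == "intergenic"

    def test_opposite_strand_exon_overlap_is_antisense(self):
        host = tx("h", [(0, 100), (5000, 5100)], strand="+", biotype="known_mRNA")
        cand = tx("c", [(50, 400)], strand="-")
        ref = GenomeAnnotation([host])
        assert classify_candidate(cand, ref) == "antisense"
        assert classify_candidate(cand, ref) == brute_force_classify(cand, [host])

    def test_agrees_with_per_base_oracle_on_random_annotations(self):
        rng = np.random.default_rng(42)
        known = []
        for i in range(40):
            start = int(rng.integers(0, 40_000))
            sizes = rng.integers(30, 120, int(rng.integers(1, 4)))
            exons, pos = [], start
            for j, sz in enumerate(sizes):
                exons.append((pos, pos + int(sz)))
                pos += int(sz) + int(rng.integers(100, 600))
            known.append(
                tx(f"k{i}", exons, strand="+-"[int(rng.integers(2))], biotype="known_mRNA")
            )
        ref = GenomeAnnotation(known)
        mismatches = 0
        for i in range(500):
            start = int(rng.integers(0, 42_000))
            n_ex = int(rng.integers(1, 3))
            exons, pos = [], start
            for j in range(n_ex):
                sz = int(rng.integers(40, 200))
                exons.append((pos, pos + sz))
                pos += sz + int(rng.integers(50, 300))
            cand = tx(f"c{i}", exons, strand="+-"[int(rng.integers(2))])
            if classify_candidate(cand, ref) != brute_force_classify(cand, known):
                mismatches += 1
        assert mismatches == 0


class TestGenomicRelation:
    def test_overlap(self):
        lnc = tx("l", [(0, 300)])
        gene = tx("g", [(200, 500)], biotype="known_mRNA")
        rel = genomic_relation(lnc, gene)
        assert rel.kind is RelationKind.OVERLAP and rel.distance_bp == 0

    def test_within_gene_body_without_exonic_overlap(self):
        gene = tx("g", [(0, 100), (10_000, 10_200)], biotype="known_mRNA")
        lnc = tx("l", [(2000, 2400)])
        rel = genomic_relation(lnc, gene)
        assert rel.kind is RelationKind.INTRON and rel.distance_bp == 0

    def test_gap_and_gene_strand_orientation(self):
        # lncRNA ends 23,747 bp before a + strand gene: 5' side -> upstream
        gene = tx("g", [(100_000, 100_500)], strand="+", biotype="known_mRNA")
        lnc = tx("l", [(75_853, 76_253)])
        rel = genomic_relation(lnc, gene)
        assert rel.distance_bp == 23_747
        assert rel.kind is RelationKind.UPSTREAM
        # same geometry, - strand gene: the 5' side flips
        gene_m = tx("gm", [(100_000, 100_500)], strand="-", biotype="known_mRNA")
        assert genomic_relation(lnc, gene_m).kind is RelationKind.DOWNSTREAM

    def test_relation_string_formats_with_thousands(self):
        gene = tx("g", [(100_000, 100_500)], strand="+", biotype="known_mRNA")
        lnc = tx("l", [(75_853, 76_253)])
        assert str(genomic_relation(lnc, gene)) == "Upstream:23,747"

    def test_different_chromosomes_give_none(self):
        lnc = tx("l", [(0, 300)], chrom="chr2")
        gene = tx("g", [(0, 300)], biotype="known_mRNA")
        assert genomic_relation(lnc, gene) is None

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = int(rng.integers(0, 5000))
            b = int(rng.integers(6000, 50_000))
            lnc = tx("l", [(a, a + 400)])
            gene = tx("g", [(b, b + 800)], strand="+-"[int(rng.integers(2))],
                      biotype="known_mRNA")
            rel = genomic_relation(lnc, gene)
            off = int(rng.integers(1, 100_000))
            rel2 = genomic_relation(shift_transcript(lnc, off), shift_transcript(gene, off))
            assert rel == rel2


class TestIntervalIndex:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        ts = []
        for i in range(1000):
            s = int(rng.integers(0, 500_000))
            ts.append(
                tx(f"t{i}", [(s, s + int(rng.integers(50, 2000)))],
                   strand="+-"[int(rng.integers(2))],
                   chrom=f"chr{int(rng.integers(1, 4))}")
            )
        ann = GenomeAnnotation(ts)
        for _ in range(100):
            chrom = f"chr{int(rng.integers(1, 4))}"
            q0 = int(rng.integers(0, 500_000))
            q1 = q0 + int(rng.integers(1, 5000))
            got = {t.id for t in ann.overlapping(chrom, q0, q1)}
            expect = {
                t.id for t in ts if t.chrom == chrom and t.start < q1 and q0 < t.end
            }
            assert got == expect
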