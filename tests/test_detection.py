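"""Individual filters of the retrogene cascade."""

import pytest

from retroforge.detection import (
    DetectionParams,
    classify_structure,
    detect_polyA,
    detect_tsd,
    filter_similarity,
    filter_te_overlap,
    select_query_set,
    synteny_context,
)
from retroforge.homology import AlignmentHit, JunctionCoverage
from retroforge.model import GeneModel, GenomeSet, Interval, TranscriptStructure


def _hit(identity, n_aligned, subject_residues=None):
    rm = tuple((i, (subject_residues or range(1, n_aligned + 1))[i - 1]) for i in range(1, n_aligned + 1)) \
        if subject_residues else tuple((i, i) for i in range(1, n_aligned + 1))
    return AlignmentHit(
        query_id="q", subject_id="s", percent_identity=identity,
        query_span=(1, n_aligned), subject_span=(rm[0][1], rm[-1][1]),
        aligned_length=n_aligned, raw_score=100, bit_score=50, e_value=1e-5,
        residue_map=rm,
    )


class TestSimilarityFilter:
    def test_identity_just_below_threshold_fails(self):
        ok, _ = filter_similarity(_hit(49.9, 60), 100, 100)
        assert not ok

    def test_passing_combination(self):
        # 40 aa aligned covering 55 % of query and 52 % of subject
        ok, _ = filter_similarity(_hit(60.0, 40), 72, 76)
        assert ok

    def test_short_alignment_fails_length_floor(self):
        ok, ev = filter_similarity(_hit(80.0, 30), 40, 40)
        assert not ok and "aligned=30aa" in ev

    def test_coverage_both_mode_requires_both(self):
        params = DetectionParams(coverage_mode="both")
        ok, _ = filter_similarity(_hit(60.0, 40), 70, 200, params)
        assert not ok  # subject coverage 20 %
        params = DetectionParams(coverage_mode="either")
        ok, _ = filter_similarity(_hit(60.0, 40), 70, 200, params)
        assert ok


def _parent_ts(n_cde, res_per_exon=10):
    per = res_per_exon * 3
    segs, pos = [], 1
    for _ in range(n_cde):
        segs.append(Interval("c", pos, pos + per - 1, "+"))
        pos += per + 40
    return TranscriptStructure("p", list(segs), segs, cds_nt="A" * (per * n_cde),
                               protein="K" * (res_per_exon * n_cde))


class TestClassifyStructure:
    def test_all_junctions_covered_is_intact(self):
        parent = _parent_ts(8)
        jc = JunctionCoverage("s", frozenset(range(1, 8)), 7)
        hit = _hit(90, 80)
        assert classify_structure(jc, hit, parent) == ("intact", 0)

    def test_missing_first_exon_is_incomplete(self):
        parent = _parent_ts(5)
        # aligned residues start at CDE 2 (residue 11)
        hit = _hit(90, 40, subject_residues=list(range(11, 51)))
        jc = JunctionCoverage("s", frozenset({2, 3, 4}), 4)
        assert classify_structure(jc, hit, parent) == ("incomplete", 1)

    def test_gap_in_middle_is_rejected(self):
        parent = _parent_ts(5)
        hit = _hit(90, 50)
        jc = JunctionCoverage("s", frozenset({1, 2, 4}), 4)
        assert classify_structure(jc, hit, parent) is None


class TestTeFilter:
    @pytest.mark.parametrize("frac,expected", [(0.5, False), (0.49, True), (0.0, True)])
    def test_threshold(self, frac, expected):
        g = GeneModel("g", "sp", Interval("c", 1, 100),
                      [_parent_ts(1)], te_overlap_fraction=frac)
        ok, _ = filter_te_overlap(g)
        assert ok is expected


def _genome_with_gene(region, utr3_len, downstream, strand="+"):
    """One 1-exon gene: 30 nt CDS + a 3'UTR of utr3_len, then `downstream`."""
    cds = "ATG" + "GCT" * 8 + "TAA"
    if strand == "+":
        seq = "C" * 50 + cds + region + downstream
        cds_iv = Interval("c", 51, 50 + len(cds), "+")
        exon = Interval("c", 51, 50 + len(cds) + utr3_len, "+")
    else:
        from retroforge.model import revcomp

        seq = downstream[::-1] + region[::-1] + revcomp(cds) + "C" * 50
        start = len(downstream) + len(region) + 1
        cds_iv = Interval("c", start, start + len(cds) - 1, "-")
        exon = Interval("c", start - utr3_len, start + len(cds) - 1, "-")
    utr3 = []
    if utr3_len:
        if strand == "+":
            utr3 = [Interval("c", cds_iv.end + 1, cds_iv.end + utr3_len, "+")]
        else:
            utr3 = [Interval("c", cds_iv.start - utr3_len, cds_iv.start - 1, "-")]
    t = TranscriptStructure("t", [exon], [cds_iv], utr3_exons=utr3,
                            cds_nt=cds, protein="M" + "A" * 8)
    g = GeneModel("g", "sp", exon, [t])
    return g, GenomeSet("sp", {"g": g}, {"c": seq})


class TestPolyA:
    def test_run_of_8_in_utr_found(self):
        g, gs = _genome_with_gene("GC" + "A" * 8 + "C", utr3_len=11, downstream="G" * 600)
        found, pos = detect_polyA(g, gs)
        assert found and pos == 3

    def test_run_of_7_not_found(self):
        g, gs = _genome_with_gene("GC" + "A" * 7 + "CC", utr3_len=11, downstream="G" * 600)
        found, _ = detect_polyA(g, gs)
        assert not found

    def test_fallback_window_without_utr(self):
        # no UTR annotation; tail sits ~460 nt after the stop, inside
        # avg_utr3 + 500 fallback window
        g, gs = _genome_with_gene("G" * 450 + "A" * 10 + "G" * 200, utr3_len=0, downstream="")
        found, _ = detect_polyA(g, gs, avg_utr3_len=100.0)
        assert found

    def test_minus_strand_sense_tail(self):
        g, gs = _genome_with_gene("GC" + "T" * 9 + "C", utr3_len=12, downstream="G" * 600,
                                  strand="-")
        # region string is reversed raw sequence: the T-run reads as sense-A
        found, _ = detect_polyA(g, gs)
        assert found


class TestTsd:
    def _gene_with_flanks(self, up, down):
        cds = "ATG" + "GCT" * 8 + "TAA"
        seq = up + cds + down
        iv = Interval("c", len(up) + 1, len(up) + len(cds), "+")
        t = TranscriptStructure("t", [iv], [iv], cds_nt=cds, protein="M" + "A" * 8)
        g = GeneModel("g", "sp", iv, [t])
        return g, GenomeSet("sp", {"g": g}, {"c": seq})

    def test_exact_repeat_found(self):
        g, gs = self._gene_with_flanks("G" * 16 + "ACGT", "CCGG" * 5)
        found, seq = detect_tsd(g, gs)
        assert not found or seq != ""
        g, gs = self._gene_with_flanks("G" * 16 + "ACGT", "ACGT" + "C" * 16)
        found, seq = detect_tsd(g, gs)
        assert found and seq == "ACGT"

    def test_longest_repeat_reported(self):
        g, gs = self._gene_with_flanks("G" * 14 + "TACGTA", "TACGTA" + "C" * 14)
        found, seq = detect_tsd(g, gs)
        assert found and seq == "TACGTA"

    def test_no_shared_kmer(self):
        g, gs = self._gene_with_flanks("G" * 20, "C" * 20)
        found, seq = detect_tsd(g, gs)
        assert not found and seq == ""


class TestQuerySelection:
    def _gene(self, gid, n_cde, n_exons=None, histone=False):
        n_exons = n_exons or n_cde
        exons = [Interval("c", 1 + i * 200, 100 + i * 200, "+") for i in range(n_exons)]
        cds = exons[-n_cde:]
        t = TranscriptStructure(gid + ".t", exons, list(cds), cds_nt="A" * 300,
                                protein="X" * 100)
        return GeneModel(gid, "sp", Interval("c", 1, 2000), [t], is_histone=histone)

    def test_utr_exons_do_not_disqualify(self):
        gs = GenomeSet("sp", {
            "multiexon_1cde": self._gene("multiexon_1cde", 1, n_exons=3),
            "hist": self._gene("hist", 1, histone=True),
            "twocde": self._gene("twocde", 2),
        }, {"c": "A" * 5000})
        ids = [g.gene_id for g in select_query_set(gs)]
        assert ids == ["multiexon_1cde"]


def test_synteny_context_chromosome_ends(zero_cohort):
    _, genomes, _ = zero_cohort
    gs = genomes["O"]
    chrom = sorted(gs.sequences)[0]
    order = gs.genes_in_order(chrom)
    first, middle = order[0], order[len(order) // 2]
    ctx = synteny_context(first, gs)
    assert ctx.upstream == () and len(ctx.downstream) == 5
    ctx_m = synteny_context(middle, gs)
    assert len(ctx_m.neighbors) == 10
    assert middle not in ctx_m.neighbors


def test_orphan_flags(zero_cohort):
    """Candidates with outgroup-only parents are orphans; same-species
    parents clear the flag."""
    from retroforge.detection import run_detection

    _, genomes, events = zero_cohort
    cands = {c.retro_gene_id: c for c in run_detection(genomes, ("A", "B"), "O")}
    lineage_retained = {
        e.gene_ids[0]
        for e in events
        if e.event_type == "retroposition_lineage"
    }
    lost = {g for e in events if e.event_type == "parental_loss" for g in e.gene_ids}
    for gid, c in cands.items():
        if gid in lineage_retained - lost:
            assert not c.orphan, gid
        if gid in lost:
            assert c.orphan, gid
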