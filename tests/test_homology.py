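"""Local protein alignment, E-value statistics, and junction projection."""

import functools
import math
import random

import pytest

from retroforge.homology import ProteinAligner, project_to_structure
from retroforge.model import Interval, TranscriptStructure

AAS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def al():
    return ProteinAligner()


def test_identical_sequences_full_span(al):
    rnd = random.Random(0)
    seq = "".join(rnd.choice(AAS) for _ in range(100))
    hit = al.align_pair("q", seq, "s", seq)
    assert hit is not None
    assert hit.percent_identity == 100.0
    assert hit.query_span == (1, 100) and hit.subject_span == (1, 100)
    assert hit.aligned_length == 100


def test_reversed_sequence_no_hit(al):
    """A random 50-mer vs its reverse scores too low for E <= 0.001."""
    rnd = random.Random(1)
    seq = "".join(rnd.choice(AAS) for _ in range(50))
    assert al.align_pair("q", seq, "s", seq[::-1]) is None


def test_subhit_placement(al):
    rnd = random.Random(2)
    subject = "".join(rnd.choice(AAS) for _ in range(100))
    query = subject[40:100]
    hit = al.align_pair("q", query, "s", subject)
    assert hit.subject_span == (41, 100)
    assert hit.query_span == (1, 60)


def test_empty_sequence_errors(al):
    with pytest.raises(ValueError):
        al.align_pair("q", "", "s", "MKV")


def test_score_symmetry_and_evalue_monotonicity(al):
    rnd = random.Random(3)
    a = "".join(rnd.choice(AAS) for _ in range(60))
    b = "".join(rnd.choice(AAS) for _ in range(60))
    assert al.score(a, b) == al.score(b, a)
    assert al.e_value(100, 60, 1000) > al.e_value(120, 60, 1000)
    assert al.e_value(120, 60, 1000) > al.e_value(140, 60, 1000)


def test_all_vs_all_symmetric_pair(al):
    rnd = random.Random(4)
    p = "".join(rnd.choice(AAS) for _ in range(80))
    q = "".join(rnd.choice(AAS) for _ in range(80))
    seqs = {"x": p, "y": p, "z": q}
    hits = al.all_vs_all(seqs, seqs, exclude_self=True, prefilter_k=None)
    pairs = {(h.query_id, h.subject_id) for h in hits}
    assert ("x", "y") in pairs and ("y", "x") in pairs
    assert not any("z" in pr for pr in pairs)
    assert al.all_vs_all({}, seqs) == []


# --- Smith-Waterman oracle: exhaustive enumeration on tiny sequences -------

BL62 = None


def _blosum(a, b):
    global BL62
    if BL62 is None:
        from Bio.Align import substitution_matrices

        BL62 = substitution_matrices.load("BLOSUM62")
    return BL62[a][b]


def brute_force_sw(a: str, b: str, open_cost=11, extend_cost=1) -> float:
    """Best local alignment score by recursive enumeration with affine gap
    states; independent of the production aligner's dynamic program."""

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = match, 1 = gap in a, 2 = gap in b; score of best
        # extension ending exactly at (i, j) in the given state
        options = []
        if state == 0:
            s = _blosum(a[i], b[j])
            prev = [best(i - 1, j - 1, st) for st in (0, 1, 2)] if i > 0 and j > 0 else [0.0]
            options.append(s + max(max(prev), 0.0))
        elif state == 1:  # consuming b[j], gap in a
            if j > 0:
                options.append(best(i, j - 1, 1) - extend_cost)
                options.append(max(best(i, j - 1, 0), 0.0) - open_cost - extend_cost)
            else:
                options.append(-open_cost - extend_cost)
        else:
            if i > 0:
                options.append(best(i - 1, j, 2) - extend_cost)
                options.append(max(best(i - 1, j, 0), 0.0) - open_cost - extend_cost)
            else:
                options.append(-open_cost - extend_cost)
        return max(options)

    m = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            m = max(m, best(i, j, 0))
    return m


@pytest.mark.parametrize("seed", range(6))
def test_sw_score_equals_bruteforce(al, seed):
    rnd = random.Random(seed)
    n = rnd.randint(5, 12)
    m = rnd.randint(5, 12)
    a = "".join(rnd.choice(AAS) for _ in range(n))
    b = "".join(rnd.choice(AAS) for _ in range(m))
    assert al.score(a, b) == pytest.approx(brute_force_sw(a, b))


# --- junction coverage ------------------------------------------------------


def _parent(n_cde: int, codons_per_exon: int = 10, split_codon: bool = False):
    """Parent transcript with n_cde coding exons; optionally make each
    junction fall inside a codon."""
    per = codons_per_exon * 3
    segs = []
    pos = 1
    lens = []
    for i in range(n_cde):
        ln = per + (1 if split_codon and i == 0 else 0)
        lens.append(ln)
    total = sum(lens)
    lens[-1] += (-total) % 3
    for ln in lens:
        segs.append(Interval("c", pos, pos + ln - 1, "+"))
        pos += ln + 50
    nt = sum(lens)
    return TranscriptStructure(
        "p", exons=list(segs), cds_segments=segs,
        cds_nt="A" * nt, protein="K" * (nt // 3),
    )


class FakeHit:
    def __init__(self, residues, subject_id="p"):
        self.subject_id = subject_id
        self.residue_map = tuple((i, r) for i, r in enumerate(sorted(residues), 1))

    def subject_residues(self):
        return frozenset(r for _, r in self.residue_map)


def test_junction_coverage_spanning_3prime(al):
    """5-CDE parent, alignment over CDEs 2..5 covers junctions {2,3,4}."""
    p = _parent(5)
    start_res = 11  # first residue of CDE 2
    hit = FakeHit(range(start_res, 51))
    jc = project_to_structure(hit, p)
    assert jc.n_junctions_total == 4
    assert jc.covered == frozenset({2, 3, 4})
    assert jc.covers_two_3prime_terminal


def test_junction_coverage_last_exon_only(al):
    p = _parent(5)
    hit = FakeHit(range(41, 51))  # confined to CDE 5
    jc = project_to_structure(hit, p)
    assert jc.covered == frozenset()
    assert not jc.covers_two_3prime_terminal


def test_junction_coverage_exact_boundaries(al):
    """Covering exactly the boundary residues of junctions 3 and 4 passes."""
    p = _parent(5)
    hit = FakeHit({30, 31, 40, 41})
    jc = project_to_structure(hit, p)
    assert jc.covered == frozenset({3, 4})
    assert jc.covers_two_3prime_terminal


def test_single_junction_parent_never_passes():
    p = _parent(2)
    hit = FakeHit(range(1, 21))
    jc = project_to_structure(hit, p)
    assert jc.covered == {1} and jc.n_junctions_total == 1
    assert not jc.covers_two_3prime_terminal


def test_codon_split_junction_counts_both_sides():
    """A residue spanning the junction nucleotides covers it on both sides."""
    p = _parent(3, split_codon=True)  # junction 1 at nt 31 (inside codon 11)
    assert p.cds_junction_positions()[0] % 3 != 0
    hit = FakeHit({11, 21, 22})  # residue 11 contains nts 31..33 (both sides of j1)
    jc = project_to_structure(hit, p)
    assert 1 in jc.covered


def test_projection_mismatch_errors():
    p = _parent(3)
    with pytest.raises(ValueError):
        project_to_structure(FakeHit({200}), p)
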