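"""Pairwise protein similarity search and projection onto gene structures.

Local Smith-Waterman alignment (BLOSUM62, affine gaps: a gap of length L
costs open + L * extend, defaults 11 + L) with Karlin-Altschul E-values
replaces an external BLASTP binary.  Hits are then projected onto the
subject's exon-intron structure to test which coding-exon junctions the
aligned region spans -- the core evidence that a single-coding-exon gene is
a processed (spliced) copy of a multi-exon gene rather than an unrelated
intronless locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .model import TranscriptStructure

__all__ = [
    "AlignmentHit",
    "JunctionCoverage",
    "ProteinAligner",
    "project_to_structure",
]

# Gapped Karlin-Altschul constants for BLOSUM62 with 11/1 gap costs.
KA_K = 0.041
KA_LAMBDA = 0.267


@dataclass
class AlignmentHit:
    """One local protein alignment, BLAST-hit-like."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_span: tuple[int, int]  # 1-based inclusive residue interval
    subject_span: tuple[int, int]
    aligned_length: int  # alignment columns, gaps included
    raw_score: float
    bit_score: float
    e_value: float
    residue_map: tuple[tuple[int, int], ...]  # 1-based (query_res, subject_res)

    def subject_residues(self) -> frozenset[int]:
        return frozenset(s for _, s in self.residue_map)

    def to_tab(self) -> str:
        """BLAST outfmt-6-compatible row (mismatch/gapopen left as 0)."""
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.subject_id,
                f"{self.percent_identity:.2f}",
                self.aligned_length,
                0,
                0,
                self.query_span[0],
                self.query_span[1],
                self.subject_span[0],
                self.subject_span[1],
                f"{self.e_value:.3g}",
                f"{self.bit_score:.1f}",
            )
        )


@dataclass(frozen=True)
class JunctionCoverage:
    """Which coding-exon junctions of a subject gene an alignment spans."""

    subject_id: str
    covered: frozenset[int]  # junction indices, 1 = most 5'
    n_junctions_total: int

    @property
    def covers_two_3prime_terminal(self) -> bool:
        """True iff the two most-3' junctions are both covered.

        A parent with a single junction (2 coding exons) can never satisfy
        the two-terminal-junction requirement and is therefore rejected as
        a parent under the default rule.
        """
        n = self.n_junctions_total
        if n < 2:
            return False
        return {n - 1, n} <= self.covered

    def all_covered(self) -> bool:
        return self.covered == frozenset(range(1, self.n_junctions_total + 1))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class ProteinAligner:
    """Smith-Waterman local aligner with Karlin-Altschul statistics.

    Parameters mirror BLASTP defaults: BLOSUM62, gap open 11, gap extend 1
    (a length-L gap costs ``11 + L``).  ``e_cutoff`` is the E-value
    threshold applied by :meth:`align_pair` and :meth:`all_vs_all`.
    """

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
        e_cutoff: float = 0.001,
        ka_k: float = KA_K,
        ka_lambda: float = KA_LAMBDA,
    ):
        self.e_cutoff = e_cutoff
        self.ka_k = ka_k
        self.ka_lambda = ka_lambda
        self._aligner = PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(matrix)
        # Biopython charges open_gap_score for the first gap position.
        self._aligner.open_gap_score = -(gap_open + gap_extend)
        self._aligner.extend_gap_score = -gap_extend

    def score(self, a: str, b: str) -> float:
        if not a or not b:
            raise ValueError("empty sequence")
        return float(self._aligner.score(a, b))

    def e_value(self, score: float, m: int, n: int) -> float:
        return self.ka_k * m * n * math.exp(-self.ka_lambda * score)

    def bit_score(self, score: float) -> float:
        return (self.ka_lambda * score - math.log(self.ka_k)) / math.log(2.0)

    def align_pair(
        self,
        query_id: str,
        query: str,
        subject_id: str,
        subject: str,
        db_size: int | None = None,
        e_cutoff: float | None = None,
    ) -> AlignmentHit | None:
        """Best local alignment, or None if its E-value exceeds the cutoff.

        ``db_size`` is the effective database length in residues (defaults
        to the subject length, i.e. a one-sequence database).
        """
        if not query or not subject:
            raise ValueError("empty sequence")
        e_cutoff = self.e_cutoff if e_cutoff is None else e_cutoff
        n = db_size if db_size is not None else len(subject)
        score = self.score(query, subject)
        if score <= 0:
            return None
        ev = self.e_value(score, len(query), n)
        if ev > e_cutoff:
            return None
        aln = self._aligner.align(query, subject)[0]
        qblocks, sblocks = aln.aligned
        residue_map = []
        identical = 0
        matched = 0
        for (qs, qe), (ss, se) in zip(qblocks, sblocks):
            for off in range(qe - qs):
                qi, si = qs + off, ss + off
                residue_map.append((qi + 1, si + 1))
                matched += 1
                if query[qi] == subject[si]:
                    identical += 1
        q_span = (qblocks[0][0] + 1, qblocks[-1][1])
        s_span = (sblocks[0][0] + 1, sblocks[-1][1])
        q_ext = q_span[1] - q_span[0] + 1
        s_ext = s_span[1] - s_span[0] + 1
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            percent_identity=100.0 * identical / matched,
            query_span=q_span,
            subject_span=s_span,
            aligned_length=q_ext + s_ext - matched,
            raw_score=score,
            bit_score=self.bit_score(score),
            e_value=ev,
            residue_map=tuple(residue_map),
        )

    def all_vs_all(
        self,
        queries: dict[str, str],
        subjects: dict[str, str],
        e_cutoff: float | None = None,
        exclude_self: bool = True,
        prefilter_k: int | None = 5,
        prefilter_min: int = 1,
    ) -> list[AlignmentHit]:
        """Score every ordered (query, subject) pair; keep hits with E <= cutoff.

        An optional shared-k-mer prefilter (default: at least one common
        5-mer) skips alignment of clearly unrelated pairs; set
        ``prefilter_k=None`` for the exhaustive search.  The E-value uses the
        total number of subject residues as the database size, as a database
        search would.
        """
        e_cutoff = self.e_cutoff if e_cutoff is None else e_cutoff
        db_size = sum(len(s) for s in subjects.values())
        kmer_index = None
        if prefilter_k is not None:
            kmer_index = {sid: _kmers(s, prefilter_k) for sid, s in subjects.items()}
        hits: list[AlignmentHit] = []
        for qid, q in queries.items():
            qkmers = _kmers(q, prefilter_k) if prefilter_k is not None else None
            for sid, s in subjects.items():
                if exclude_self and qid == sid:
                    continue
                if kmer_index is not None and len(q) > prefilter_k and len(s) > prefilter_k:
                    if len(qkmers & kmer_index[sid]) < prefilter_min:
                        continue
                hit = self.align_pair(qid, q, sid, s, db_size=db_size, e_cutoff=e_cutoff)
                if hit is not None:
                    hits.append(hit)
        return hits


def project_to_structure(hit: AlignmentHit, subject: TranscriptStructure) -> JunctionCoverage:
    """Map an alignment's subject residues onto the subject's CDE junctions.

    Residue ``i`` of the subject protein corresponds to spliced-CDS
    nucleotides ``3i-2..3i``.  Junction ``j`` is covered iff both the last
    residue of coding exon ``j`` and the first residue of coding exon
    ``j+1`` are aligned; when an intron splits a codon the two are the same
    residue and it counts for both sides of the junction.
    """
    prot_len = len(subject.protein)
    expected = subject.cds_length // 3
    if expected not in (prot_len, prot_len + 1):  # +1 when the stop is annotated
        raise ValueError(
            f"subject {subject.transcript_id}: protein length {prot_len} inconsistent "
            f"with CDS length {subject.cds_length}"
        )
    if hit.residue_map and max(s for _, s in hit.residue_map) > prot_len:
        raise ValueError(f"hit extends past subject protein of {subject.transcript_id}")
    aligned = hit.subject_residues()
    covered = set()
    junctions = subject.cds_junction_positions()
    for j, cum_nt in enumerate(junctions, start=1):
        last_res = (cum_nt + 2) // 3  # residue containing nucleotide cum_nt
        first_res = cum_nt // 3 + 1  # residue containing nucleotide cum_nt + 1
        if last_res in aligned and first_res in aligned:
            covered.add(j)
    return JunctionCoverage(
        subject_id=hit.subject_id,
        covered=frozenset(covered),
        n_junctions_total=len(junctions),
    )
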