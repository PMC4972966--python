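"""The retrogene-candidate filter cascade.

Starting from the single-coding-exon (1-CDE) genes of the two ingroup
species (minus histones), the cascade pairs each query with multi-exon
genes from all three proteomes by local protein alignment and applies, in
order: the similarity filter (>=50 % identity over >=50 % of both sequences
and >=35 aa), the junction-coverage requirement (the alignment must span at
least the two most-3' coding-exon junctions of the parent), structural
classification (intact vs 5'-incomplete), the transposable-element overlap
filter, and the segmental-duplication filter (no homology between the
candidate's and the parent's +-5-gene neighborhoods).  Survivors are
annotated with retroposition hallmarks (residual poly-A tail, target-site
duplication), chimeric-UTR and N-terminal-extension flags, and orphan
status (no surviving parent in the candidate's own genome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .homology import AlignmentHit, JunctionCoverage, ProteinAligner, project_to_structure
from .model import GeneModel, GenomeSet, TranscriptStructure

log = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "ParentMatch",
    "RetrogeneCandidate",
    "SyntenyContext",
    "HomologyService",
    "select_query_set",
    "filter_similarity",
    "classify_structure",
    "filter_te_overlap",
    "synteny_context",
    "filter_segmental_duplication",
    "detect_polyA",
    "detect_tsd",
    "annotate_extras",
    "run_detection",
]


@dataclass
class DetectionParams:
    e_cutoff: float = 0.001
    min_identity: float = 50.0  # percent
    min_coverage: float = 0.5  # of sequence length(s)
    coverage_mode: str = "both"  # 'both' (stricter) or 'either'
    min_aln_len: int = 35  # aligned residues
    min_parent_cdes: int = 3  # a 2-CDE parent cannot satisfy the junction rule
    te_threshold: float = 0.5
    n_neighbors: int = 5
    polyA_min_run: int = 8
    polyA_downstream: int = 500
    tsd_window: int = 20
    tsd_min_len: int = 4
    tsd_max_len: int = 6
    prefilter_k: int | None = 5
    utr_gain_min_identity: float = 70.0  # nt identity for UTR-exon homology
    utr_gain_min_coverage: float = 0.5


@dataclass
class ParentMatch:
    """One surviving candidate/parent pairing with its evidence."""

    parent_id: str
    parent_species: str
    hit: AlignmentHit
    junction_coverage: JunctionCoverage
    structural_class: str  # intact | incomplete
    missing_5prime_exons: int


@dataclass
class RetrogeneCandidate:
    retro_gene_id: str
    retro_species: str
    parents: list[ParentMatch]
    structural_class: str
    missing_5prime_exons: int
    polyA_found: bool = False
    polyA_position: int | None = None
    tsd_found: bool = False
    tsd_sequence: str = ""
    orphan: bool = True
    utr_exon_gain: bool = False
    n_terminal_extension: bool = False
    representative_parent: str | None = None
    filter_trace: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def parental_gene_id(self) -> str:
        return self.representative_parent or self.parents[0].parent_id

    @property
    def parental_species(self) -> str:
        pid = self.parental_gene_id
        for p in self.parents:
            if p.parent_id == pid:
                return p.parent_species
        return self.parents[0].parent_species


@dataclass(frozen=True)
class SyntenyContext:
    """Up to five upstream and five downstream neighbors, chromosomal order."""

    gene_id: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]

    @property
    def neighbors(self) -> tuple[str, ...]:
        return self.upstream + self.downstream


def select_query_set(gs: GenomeSet) -> list[GeneModel]:
    """All 1-CDE genes minus histone-flagged ones.

    A gene whose longest transcript has a single coding exon qualifies even
    if it has additional UTR-only exons.
    """
    out = []
    for g in gs.genes.values():
        if g.longest.n_cds_exons == 1 and not g.is_histone:
            out.append(g)
    return sorted(out, key=lambda g: g.gene_id)


def filter_similarity(
    hit: AlignmentHit, query_len: int, subject_len: int, params: DetectionParams | None = None
) -> tuple[bool, str]:
    """Identity >= 50 %, aligned region >= 50 % of length(s) and >= 35 aa."""
    params = params or DetectionParams()
    n_res = len(hit.residue_map)
    cov_q = n_res / query_len
    cov_s = n_res / subject_len
    cov_ok = (
        (cov_q >= params.min_coverage and cov_s >= params.min_coverage)
        if params.coverage_mode == "both"
        else (cov_q >= params.min_coverage or cov_s >= params.min_coverage)
    )
    ok = hit.percent_identity >= params.min_identity and cov_ok and n_res >= params.min_aln_len
    evidence = f"identity={hit.percent_identity:.1f}%,aligned={n_res}aa,cov_q={cov_q:.2f},cov_s={cov_s:.2f}"
    return ok, evidence


def classify_structure(
    jc: JunctionCoverage, hit: AlignmentHit, parent: TranscriptStructure
) -> tuple[str, int] | None:
    """Intact vs 5'-incomplete, or None for a rejected (gapped) pattern.

    Intact: every junction of the parent is covered.  Incomplete: only a 5'
    prefix of junctions is uncovered; ``missing_5prime_exons`` counts the
    parent's leading coding exons with no aligned residue at all.  An
    uncovered junction flanked by covered ones on both sides means the
    query is not a simple processed copy and the pairing is rejected.
    """
    n = jc.n_junctions_total
    allj = set(range(1, n + 1))
    uncovered = sorted(allj - jc.covered)
    if not uncovered:
        return "intact", 0
    if uncovered != list(range(1, len(uncovered) + 1)):
        return None  # gap in the middle: not a simple retrocopy
    aligned = hit.subject_residues()
    missing = 0
    cum = 0
    for seg in parent.cds_segments:
        first_res = cum // 3 + 1
        cum += len(seg)
        last_res = min((cum + 2) // 3, len(parent.protein))
        if not any(r in aligned for r in range(first_res, last_res + 1)):
            missing += 1
        else:
            break
    return "incomplete", missing


def filter_te_overlap(gene: GeneModel, params: DetectionParams | None = None) -> tuple[bool, str]:
    """Fail when >= 50 % of the gene span overlaps annotated TEs."""
    params = params or DetectionParams()
    ok = gene.te_overlap_fraction < params.te_threshold
    return ok, f"te_overlap={gene.te_overlap_fraction:.2f}"


def synteny_context(gene_id: str, gs: GenomeSet, n: int = 5) -> SyntenyContext:
    """The gene's up-to-n neighbors on each side (self excluded)."""
    g = gs.genes[gene_id]
    order = gs.genes_in_order(g.locus.chrom)
    i = order.index(gene_id)
    return SyntenyContext(
        gene_id=gene_id,
        upstream=tuple(order[max(0, i - n) : i]),
        downstream=tuple(order[i + 1 : i + 1 + n]),
    )


class HomologyService:
    """Cached pass/fail homology between arbitrary gene pairs.

    A pair "passes" when its best local alignment clears the E-value cutoff
    (single-pair database size) and the similarity filter.  Used by the
    segmental-duplication filter and by synteny comparisons.
    """

    def __init__(self, genomes: dict[str, GenomeSet], aligner: ProteinAligner, params: DetectionParams):
        self.genomes = genomes
        self.aligner = aligner
        self.params = params
        self._cache: dict[tuple[str, str], bool] = {}
        self._gene_index: dict[str, tuple[str, GeneModel]] = {}
        for sp, gs in genomes.items():
            for gid, g in gs.genes.items():
                self._gene_index[gid] = (sp, g)

    def species_of(self, gene_id: str) -> str:
        return self._gene_index[gene_id][0]

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index[gene_id][1]

    def passing(self, gid1: str, gid2: str) -> bool:
        key = (gid1, gid2) if gid1 <= gid2 else (gid2, gid1)
        if key in self._cache:
            return self._cache[key]
        p1 = self.gene(gid1).longest.protein
        p2 = self.gene(gid2).longest.protein
        ok = False
        if p1 and p2:
            hit = self.aligner.align_pair(gid1, p1, gid2, p2, e_cutoff=self.params.e_cutoff)
            if hit is not None:
                ok, _ = filter_similarity(hit, len(p1), len(p2), self.params)
        self._cache[key] = ok
        return ok


def filter_segmental_duplication(
    retro_ctx: SyntenyContext,
    parent_ctx: SyntenyContext,
    homology: HomologyService,
) -> tuple[bool, str]:
    """Fail when any candidate neighbor is homologous to any parent neighbor."""
    for rn in retro_ctx.neighbors:
        for pn in parent_ctx.neighbors:
            if homology.passing(rn, pn):
                return False, f"shared_neighbor={rn}~{pn}"
    return True, "no_shared_neighbors"


def _longest_a_run(seq: str) -> tuple[int, int]:
    """(length, 0-based start) of the longest A-run in *seq*."""
    best, best_start, run, start = 0, -1, 0, 0
    for i, c in enumerate(seq.upper()):
        if c == "A":
            if run == 0:
                start = i
            run += 1
            if run > best:
                best, best_start = run, start
        else:
            run = 0
    return best, best_start


def detect_polyA(
    gene: GeneModel, gs: GenomeSet, avg_utr3_len: float | None = None, params: DetectionParams | None = None
) -> tuple[bool, int | None]:
    """Scan the 3'UTR plus 500 bp downstream for a run of >= 8 sense-strand A.

    With no annotated 3'UTR, a window of the genome-wide average 3'UTR
    length plus 500 bp downstream of the stop codon is used instead.
    Returns (found, 1-based offset of the run within the scanned window).
    """
    params = params or DetectionParams()
    t = gene.longest
    strand = gene.locus.strand
    chrom = gene.locus.chrom
    if strand == "+":
        cds_end = max(c.end for c in t.cds_segments)
    else:
        cds_end = min(c.start for c in t.cds_segments)
    if t.utr3_exons:
        utr_len = sum(len(u) for u in t.utr3_exons)
    else:
        utr_len = int(round(avg_utr3_len if avg_utr3_len is not None else gs.avg_utr3_len))
    window = utr_len + params.polyA_downstream
    if strand == "+":
        seq = gs.fetch(chrom, cds_end + 1, cds_end + window, "+")
    else:
        seq = gs.fetch(chrom, cds_end - window, cds_end - 1, "-")
    run, start = _longest_a_run(seq)
    if run >= params.polyA_min_run:
        return True, start + 1
    return False, None


def detect_tsd(
    gene: GeneModel, gs: GenomeSet, params: DetectionParams | None = None
) -> tuple[bool, str]:
    """Longest exact 4-6 bp repeat shared by the two 20 bp flanks.

    Target-site duplications are direct repeats in the genome, so both
    windows are taken on the plus strand regardless of gene orientation.
    """
    params = params or DetectionParams()
    loc = gene.locus
    up = gs.fetch(loc.chrom, loc.start - params.tsd_window, loc.start - 1, "+")
    down = gs.fetch(loc.chrom, loc.end + 1, loc.end + params.tsd_window, "+")
    for L in range(params.tsd_max_len, params.tsd_min_len - 1, -1):
        up_mers = {up[i : i + L] for i in range(len(up) - L + 1)}
        for i in range(len(down) - L + 1):
            mer = down[i : i + L]
            if mer in up_mers:
                return True, mer
    return False, ""


def _utr_exon_intervals(t: TranscriptStructure):
    """Exons with no CDS overlap (pure UTR exons)."""
    out = []
    for e in t.exons:
        if not any(e.overlap(c) for c in t.cds_segments):
            out.append(e)
    return out


def annotate_extras(
    cand: RetrogeneCandidate,
    retro_gene: GeneModel,
    parent_gene: GeneModel,
    genomes: dict[str, GenomeSet],
    params: DetectionParams | None = None,
) -> None:
    """Set the chimeric-UTR-exon and N-terminal-extension flags in place.

    A UTR exon counts as *gained* when its nucleotide sequence has no
    passing local alignment against the parent's UTRs or against the
    parent's +-5-gene flanking region, suggesting it was acquired from the
    insertion site.
    """
    params = params or DetectionParams()
    retro_t = retro_gene.longest
    parent_t = parent_gene.longest
    cand.n_terminal_extension = (
        cand.structural_class == "incomplete" and len(retro_t.protein) > len(parent_t.protein)
    )
    utr_exons = _utr_exon_intervals(retro_t)
    if not utr_exons:
        cand.utr_exon_gain = False
        return
    retro_gs = genomes[retro_gene.species]
    parent_gs = genomes[parent_gene.species]
    ctx = synteny_context(parent_gene.gene_id, parent_gs, params.n_neighbors)
    flank_ids = ctx.neighbors + (parent_gene.gene_id,)
    lo = min(parent_gs.genes[g].locus.start for g in flank_ids)
    hi = max(parent_gs.genes[g].locus.end for g in flank_ids)
    target = parent_gs.fetch(parent_gene.locus.chrom, lo, hi, "+")
    from Bio.Align import PairwiseAligner

    nt_aln = PairwiseAligner()
    nt_aln.mode = "local"
    nt_aln.match_score = 2
    nt_aln.mismatch_score = -3
    nt_aln.open_gap_score = -5
    nt_aln.extend_gap_score = -2
    gained = False
    for ue in utr_exons:
        seq = retro_gs.fetch(ue.chrom, ue.start, ue.end, ue.strand)
        best = 0.0
        for tgt in (target, None):
            if tgt is None:
                break
            for probe in (seq, _rc(seq)):
                aln = nt_aln.align(probe, tgt)
                if len(aln) == 0:
                    continue
                a = aln[0]
                matched = sum(qe - qs for (qs, qe) in a.aligned[0])
                ident = sum(
                    1
                    for (qs, qe), (ss, se) in zip(a.aligned[0], a.aligned[1])
                    for off in range(qe - qs)
                    if probe[qs + off] == tgt[ss + off]
                )
                if matched:
                    pid = 100.0 * ident / matched
                    cov = matched / len(seq)
                    if pid >= params.utr_gain_min_identity and cov >= params.utr_gain_min_coverage:
                        best = max(best, pid)
        if best == 0.0:
            gained = True
            break
    cand.utr_exon_gain = gained


def _rc(seq: str) -> str:
    from .model import revcomp

    return revcomp(seq)


def run_detection(
    genomes: dict[str, GenomeSet],
    ingroups: tuple[str, str],
    outgroup: str,
    params: DetectionParams | None = None,
    aligner: ProteinAligner | None = None,
    homology: HomologyService | None = None,
) -> list[RetrogeneCandidate]:
    """Run the full cascade over a cohort; returns surviving candidates.

    Queries are the 1-CDE non-histone genes of the two ingroups; subjects
    are the longest-transcript proteins of all three species.  Each
    candidate keeps every surviving parent (the representative parent is
    chosen later by minimum dS) and a per-filter evidence trace.
    """
    params = params or DetectionParams()
    aligner = aligner or ProteinAligner(e_cutoff=params.e_cutoff)
    homology = homology or HomologyService(genomes, aligner, params)
    subjects: dict[str, str] = {}
    subject_species: dict[str, str] = {}
    for sp, gs in genomes.items():
        for gid, prot in gs.proteins().items():
            subjects[gid] = prot
            subject_species[gid] = sp

    queries: list[GeneModel] = []
    for sp in ingroups:
        queries.extend(select_query_set(genomes[sp]))
    log.info("query set: %d 1-CDE genes from %s", len(queries), "+".join(ingroups))

    query_seqs = {g.gene_id: g.longest.protein for g in queries if g.longest.protein}
    hits = aligner.all_vs_all(
        query_seqs, subjects, e_cutoff=params.e_cutoff, exclude_self=True, prefilter_k=params.prefilter_k
    )
    hits_by_query: dict[str, list] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)
    log.info("similarity search: %d hits (E <= %g)", len(hits), params.e_cutoff)

    candidates: list[RetrogeneCandidate] = []
    n_pass_sim = n_pass_jc = 0
    for gene in queries:
        qid = gene.gene_id
        qsp = gene.species
        trace: list[tuple[str, bool, str]] = []
        matches: list[ParentMatch] = []
        for hit in sorted(hits_by_query.get(qid, []), key=lambda h: -h.bit_score):
            sid = hit.subject_id
            ssp = subject_species[sid]
            parent_gene = genomes[ssp].genes[sid]
            parent_t = parent_gene.longest
            if parent_t.n_cds_exons < params.min_parent_cdes:
                continue
            ok, ev = filter_similarity(hit, len(query_seqs[qid]), len(subjects[sid]), params)
            trace.append((f"similarity:{sid}", ok, ev))
            if not ok:
                continue
            jc = project_to_structure(hit, parent_t)
            ok = jc.covers_two_3prime_terminal
            trace.append((f"junctions:{sid}", ok, f"covered={sorted(jc.covered)}/{jc.n_junctions_total}"))
            if not ok:
                continue
            cls = classify_structure(jc, hit, parent_t)
            if cls is None:
                trace.append((f"structure:{sid}", False, "mid-gap junction pattern"))
                continue
            structural_class, missing = cls
            trace.append((f"structure:{sid}", True, f"{structural_class},missing={missing}"))
            matches.append(ParentMatch(sid, ssp, hit, jc, structural_class, missing))
        if not matches:
            continue
        n_pass_sim += 1
        cand = RetrogeneCandidate(
            retro_gene_id=qid,
            retro_species=qsp,
            parents=matches,
            structural_class=matches[0].structural_class,
            missing_5prime_exons=matches[0].missing_5prime_exons,
            filter_trace=trace,
        )
        ok, ev = filter_te_overlap(gene, params)
        trace.append(("te_overlap", ok, ev))
        if not ok:
            continue
        retro_ctx = synteny_context(qid, genomes[qsp], params.n_neighbors)
        surviving = []
        for m in matches:
            parent_ctx = synteny_context(m.parent_id, genomes[m.parent_species], params.n_neighbors)
            ok, ev = filter_segmental_duplication(retro_ctx, parent_ctx, homology)
            trace.append((f"segdup:{m.parent_id}", ok, ev))
            if ok:
                surviving.append(m)
        if not surviving:
            continue
        n_pass_jc += 1
        cand.parents = surviving
        cand.structural_class = surviving[0].structural_class
        cand.missing_5prime_exons = surviving[0].missing_5prime_exons
        gs = genomes[qsp]
        cand.polyA_found, cand.polyA_position = detect_polyA(gene, gs, params=params)
        cand.tsd_found, cand.tsd_sequence = detect_tsd(gene, gs, params)
        cand.orphan = not any(m.parent_species == qsp for m in surviving)
        best = surviving[0]
        annotate_extras(cand, gene, genomes[best.parent_species].genes[best.parent_id], genomes, params)
        candidates.append(cand)
    log.info(
        "cascade: %d queries -> %d with passing parents -> %d candidates",
        len(queries),
        n_pass_sim,
        len(candidates),
    )
    return candidates
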