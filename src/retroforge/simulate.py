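"""Synthetic three-species cohort generator with planted, logged events.

Simulates an ingroup pair (A, B) plus an outgroup (O) descending from a
common ancestor along the species tree ((A,B),O).  Multi-exon gene models
with UTRs are generated for the ancestor, carried through the two
speciations (which preserves gene order, i.e. synteny), and modified by
planted evolutionary events:

* ancestral retroposition: an intron-free copy of a parent's spliced CDS is
  inserted at a random locus in the A/B ancestor and the parental gene is
  deleted there (it survives only in the outgroup);
* lineage-specific retroposition (parent retained, or additionally lost in
  the same lineage);
* 5'-truncated retroposition (whole 5' exons dropped, frame restored at the
  next codon boundary);
* relocation of one ingroup's copy of an ancestral retrogene;
* intron gain (1-2 new introns) in one ingroup's retrogene copy;
* retrogene family expansion by DNA-based duplication;
* segmental-duplication confounders (an intronless gene copy carried along
  with a flanking neighbor) and TE-overlap confounders.

Residual poly-A tails and 4-6 bp target-site duplications are planted with
configurable survival probabilities; their decay over time is modeled by
those probabilities rather than by explicit erosion.  Nucleotide divergence
is Jukes-Cantor substitution without indels; substitutions creating a
premature stop codon are reverted so every annotated CDS stays a clean ORF.
The simulation is fully deterministic given the seed.
"""

from __future__ import annotations

import copy
import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import translate_cds, write_annotation
from .model import GeneModel, GenomeSet, Interval, TranscriptStructure, revcomp

__all__ = ["SimulationConfig", "GroundTruthEvent", "simulate_cohort", "write_cohort"]

NT = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [a + b + c for a in NT for b in NT for c in NT if a + b + c not in STOPS]

SPECIES = ("A", "B", "O")
LINEAGE_OF = {"A": "ingroupA", "B": "ingroupB", "O": "outgroup"}


@dataclass
class SimulationConfig:
    """All knobs of the simulated world; defaults give a small but complete
    cohort (~200 ancestral genes) exercising every planted event type."""

    seed: int = 0
    n_ancestral_genes: int = 200
    # categorical distribution over coding-exon counts 1..8
    exon_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.16, 2: 0.09, 3: 0.10, 4: 0.10, 5: 0.15, 6: 0.15, 7: 0.15, 8: 0.10}
    )
    mean_exon_len: int = 150  # bp, coding exons
    mean_intron_len: int = 120  # bp
    mean_utr_len: int = 90  # bp per UTR
    intergenic_len: int = 300  # bp between neighboring genes
    # expected nucleotide substitutions per site on each branch
    rate_to_ancestor: float = 0.03  # root -> (A,B) ancestor
    rate_to_A: float = 0.03
    rate_to_B: float = 0.03
    rate_to_outgroup: float = 0.06
    # planted event counts
    n_ancestral_retro: int = 8
    n_lineage_retro_A: int = 5
    n_lineage_retro_B: int = 3
    n_relocations: int = 2
    n_intron_gains: int = 2
    n_parental_losses: int = 3
    n_retro_duplications: int = 2
    n_truncated_retro: int = 2
    n_segdup_confounders: int = 2
    n_te_confounders: int = 2
    # retroposition hallmarks
    polyA_survival_prob: float = 0.16
    tsd_survival_prob: float = 0.0
    polyA_len: tuple[int, int] = (8, 15)
    tsd_len: tuple[int, int] = (4, 6)
    cds_omega: float = 0.2  # strength of purifying selection on coding sequence
    n_histone_genes: int = 2
    n_chromosomes: int = 2
    utr_exon_prob: float = 0.08  # chance of a separate (non-coding) 5'UTR exon

    def __post_init__(self) -> None:
        for name, val in dataclasses.asdict(self).items():
            if name.startswith(("n_", "rate_", "mean_")) and isinstance(val, (int, float)) and val < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (4 <= self.tsd_len[0] <= self.tsd_len[1] <= 6):
            raise ValueError("tsd_len range must lie within [4, 6]")
        total = sum(self.exon_count_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("exon_count_distribution must sum to 1")
        if self.n_retro_duplications > self.n_ancestral_retro:
            raise ValueError("n_retro_duplications cannot exceed n_ancestral_retro")


@dataclass
class GroundTruthEvent:
    """One planted event, as it should be recovered downstream."""

    event_type: str  # retroposition_ancestral | retroposition_lineage | parental_loss |
    # relocation | intron_gain | retro_duplication | segmental_duplication | te_insertion
    lineage: str  # common_ancestor | ingroupA | ingroupB | outgroup
    gene_ids: tuple[str, ...]  # final (species-prefixed) ids of the genes created/affected
    source_gene: str  # base id of the parental/source gene
    polyA_planted: bool = False
    tsd_planted: bool = False
    truncated_exons: int = 0


@dataclass
class _SimGene:
    """A gene during simulation: sequence in transcription orientation plus
    gene-local (1-based) exon/CDS coordinates; ``left_spacer`` is the
    intergenic sequence preceding the gene on the chromosome."""

    base_id: str
    strand: str
    region: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    left_spacer: str
    tail3: str = ""  # residual poly-A, transcription orientation, outside the annotation
    tsd: str = ""  # direct repeat flanking the inserted element
    is_histone: bool = False
    is_te: bool = False

    def spliced_cds(self) -> str:
        return "".join(self.region[s - 1 : e] for s, e in self.cds)

    @property
    def n_cds_exons(self) -> int:
        return len(self.cds)


_Genome = dict[str, list[_SimGene]]


@dataclass
class _AncestralRecord:
    rid: str
    kind: str  # plain | relocate | intron_gain | truncated
    which: str | None  # lineage of the planted relocation
    src: str
    src_neighbors: tuple[str, ...]
    polyA: bool
    tsd: bool
    trunc: int


def _rand_seq(rng, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=n))


def _rand_len(rng, mean: int, minimum: int) -> int:
    return max(minimum, int(round(rng.normal(mean, 0.25 * mean))))


def _make_gene(rng, cfg: SimulationConfig, base_id: str, n_cde: int) -> _SimGene:
    exon_lens = [_rand_len(rng, cfg.mean_exon_len, 45) for _ in range(n_cde)]
    total = sum(exon_lens)
    exon_lens[-1] += (-total) % 3
    n_codons = sum(exon_lens) // 3
    codons = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)]
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    cds_nt = "".join(codons)
    utr5_len = _rand_len(rng, cfg.mean_utr_len, 20)
    utr3_len = _rand_len(rng, cfg.mean_utr_len, 20)
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    pos = 0
    utr5 = _rand_seq(rng, utr5_len)
    # optional dedicated 5'UTR exon (keeps CDE count unchanged)
    utr_exon = rng.random() < cfg.utr_exon_prob
    if utr_exon:
        half = utr5_len // 2
        pieces.append(utr5[:half])
        exons.append((1, half))
        pos = half
        intron = "GT" + _rand_seq(rng, _rand_len(rng, cfg.mean_intron_len, 40) - 4) + "AG"
        pieces.append(intron)
        pos += len(intron)
        utr5 = utr5[half:]
    offset = 0
    for i, elen in enumerate(exon_lens):
        exon_start = pos + 1
        chunk = ""
        if i == 0:
            chunk += utr5
        cds_start = pos + len(chunk) + 1
        chunk += cds_nt[offset : offset + elen]
        offset += elen
        cds.append((cds_start, cds_start + elen - 1))
        if i == n_cde - 1:
            chunk += _rand_seq(rng, utr3_len)
        pieces.append(chunk)
        pos += len(chunk)
        exons.append((exon_start, pos))
        if i < n_cde - 1:
            intron = "GT" + _rand_seq(rng, _rand_len(rng, cfg.mean_intron_len, 40) - 4) + "AG"
            pieces.append(intron)
            pos += len(intron)
    return _SimGene(
        base_id=base_id,
        strand="+" if rng.random() < 0.5 else "-",
        region="".join(pieces),
        exons=exons,
        cds=cds,
        left_spacer=_rand_seq(rng, _rand_len(rng, cfg.intergenic_len, 100)),
    )


def _make_retro(
    rng,
    cfg: SimulationConfig,
    base_id: str,
    parent: _SimGene,
    truncate_exons: int = 0,
) -> tuple[_SimGene, bool, bool]:
    """Intron-free copy of the parent's spliced CDS with fresh UTRs.

    ``truncate_exons`` drops that many whole 5' coding exons and trims to
    the next codon boundary so the copy still encodes a clean ORF.
    Returns (gene, polyA_planted, tsd_planted).
    """
    cds_nt = parent.spliced_cds()
    if truncate_exons:
        drop = sum(e - s + 1 for s, e in parent.cds[:truncate_exons])
        drop += (-drop) % 3  # restore reading frame at the next codon boundary
        cds_nt = cds_nt[drop:]
    utr5 = _rand_seq(rng, _rand_len(rng, cfg.mean_utr_len, 20))
    utr3 = _rand_seq(rng, _rand_len(rng, cfg.mean_utr_len, 20))
    region = utr5 + cds_nt + utr3
    gene = _SimGene(
        base_id=base_id,
        strand="+" if rng.random() < 0.5 else "-",
        region=region,
        exons=[(1, len(region))],
        cds=[(len(utr5) + 1, len(utr5) + len(cds_nt))],
        left_spacer=_rand_seq(rng, _rand_len(rng, cfg.intergenic_len, 100)),
    )
    polyA = rng.random() < cfg.polyA_survival_prob
    tsd = rng.random() < cfg.tsd_survival_prob
    if polyA:
        gene.tail3 = "A" * int(rng.integers(cfg.polyA_len[0], cfg.polyA_len[1] + 1))
    if tsd:
        gene.tsd = _rand_seq(rng, int(rng.integers(cfg.tsd_len[0], cfg.tsd_len[1] + 1)))
    return gene, polyA, tsd


_AA3 = {}  # codon -> amino acid, built lazily from the standard table


def _aa(codon: str) -> str:
    if not _AA3:
        from Bio.Data.CodonTable import standard_dna_table

        _AA3.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _AA3[stop] = "*"
    return _AA3.get(codon, "X")


def _mutate_gene(rng, gene: _SimGene, rate: float, cds_omega: float = 1.0) -> None:
    """Jukes-Cantor substitutions over the gene region.

    Coding positions evolve codon-aware: substitutions creating a stop are
    rejected, and nonsynonymous substitutions are accepted only with
    probability *cds_omega* -- a simple rejection model of purifying
    selection whose expected dN/dS equals cds_omega.  The terminal stop
    codon is pinned.  Introns, UTRs and the rest mutate freely.
    """
    if rate <= 0:
        return
    p = 0.75 * (1.0 - math.exp(-4.0 * rate / 3.0))
    seq = list(gene.region)
    cds_positions: list[int] = []
    for s, e in gene.cds:
        cds_positions.extend(range(s - 1, e))
    pos_to_cds = {pos: k for k, pos in enumerate(cds_positions)}
    n_codons = len(cds_positions) // 3
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        alt = [c for c in NT if c != seq[i]][rng.integers(0, 3)]
        k = pos_to_cds.get(int(i))
        if k is None:
            seq[i] = alt
            continue
        codon_idx = k // 3
        if codon_idx >= n_codons - 1:
            continue  # keep the terminal stop intact
        cpos = cds_positions[3 * codon_idx : 3 * codon_idx + 3]
        codon = "".join(seq[p0] for p0 in cpos)
        mutated = codon[: k % 3] + alt + codon[k % 3 + 1 :]
        if _aa(mutated) == "*":
            continue
        if _aa(mutated) != _aa(codon) and rng.random() > cds_omega:
            continue  # purged by purifying selection
        seq[i] = alt
    gene.region = "".join(seq)



def _insert_position(
    rng,
    genome: _Genome,
    avoid: list[tuple[str, int]] | tuple[str, int] | None = None,
    margin: int = 8,
):
    """Random (chrom, index) insertion slot at least *margin* genes away from
    every position in *avoid* (so planted loci stay outside the +-5-gene
    synteny windows of the loci they must not resemble)."""
    if isinstance(avoid, tuple):
        avoid = [avoid]
    avoid = avoid or []
    chroms = sorted(genome)
    for _ in range(200):
        chrom = chroms[rng.integers(0, len(chroms))]
        idx = int(rng.integers(0, len(genome[chrom]) + 1))
        if all(not (chrom == ac and abs(idx - ai) <= margin) for ac, ai in avoid):
            return chrom, idx
    # tiny/crowded genome: fall back to the slot farthest from every avoid
    best, best_d = None, -1
    for chrom in chroms:
        for idx in range(len(genome[chrom]) + 1):
            d = min((abs(idx - ai) for ac, ai in avoid if ac == chrom), default=10**9)
            if d > best_d:
                best, best_d = (chrom, idx), d
    return best


def _positions_of(genome: _Genome, base_ids) -> list[tuple[str, int]]:
    out = []
    for bid in base_ids:
        try:
            out.append(_locate(genome, bid))
        except KeyError:
            pass
    return out


def _locate(genome: _Genome, base_id: str) -> tuple[str, int]:
    for chrom, genes in genome.items():
        for i, g in enumerate(genes):
            if g.base_id == base_id:
                return chrom, i
    raise KeyError(base_id)


def _remove(genome: _Genome, base_id: str) -> _SimGene:
    chrom, i = _locate(genome, base_id)
    return genome[chrom].pop(i)


def _insert_intron(rng, cfg: SimulationConfig, gene: _SimGene, n_introns: int) -> None:
    """Split the single coding exon of a retrogene by 1-2 new introns."""
    for _ in range(n_introns):
        cds_s, cds_e = gene.cds[0][0], gene.cds[-1][1]
        # pick a split point well inside the coding region, between segments
        seg = gene.cds[int(rng.integers(0, len(gene.cds)))]
        if seg[1] - seg[0] < 80:
            continue
        cut = int(rng.integers(seg[0] + 30, seg[1] - 30))
        intron = "GT" + _rand_seq(rng, _rand_len(rng, cfg.mean_intron_len, 40) - 4) + "AG"
        ilen = len(intron)
        gene.region = gene.region[:cut] + intron + gene.region[cut:]

        def shift(iv):
            s, e = iv
            if e <= cut:
                return [(s, e)]
            if s > cut:
                return [(s + ilen, e + ilen)]
            return [(s, cut), (cut + 1 + ilen, e + ilen)]

        gene.cds = [x for iv in gene.cds for x in shift(iv)]
        gene.exons = [x for iv in gene.exons for x in shift(iv)]


def _assemble(species: str, genome: _Genome) -> tuple[GenomeSet, list[tuple[str, int, int]]]:
    """Lay the gene list out on chromosome sequences; return the GenomeSet
    and TE intervals (1-based inclusive) for the planted TE confounders."""
    sequences: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    te_intervals: list[tuple[str, int, int]] = []
    for chrom in sorted(genome):
        parts: list[str] = []
        pos = 0
        for g in genome[chrom]:
            parts.append(g.left_spacer)
            pos += len(g.left_spacer)
            if g.tsd:
                parts.append(g.tsd)
                pos += len(g.tsd)
            if g.strand == "+":
                body = g.region + g.tail3
                gene_start = pos + 1
                gene_end = pos + len(g.region)
            else:
                body = revcomp(g.region + g.tail3)
                gene_start = pos + 1 + len(g.tail3)
                gene_end = pos + len(body)
            parts.append(body)
            pos += len(body)
            if g.tsd:
                parts.append(g.tsd)
                pos += len(g.tsd)

            def to_chrom(iv):
                s, e = iv
                if g.strand == "+":
                    return Interval(chrom, gene_start + s - 1, gene_start + e - 1, "+")
                return Interval(chrom, gene_end - e + 1, gene_end - s + 1, "-")

            gid = f"{species}_{g.base_id}"
            exons = [to_chrom(iv) for iv in g.exons]
            cds = [to_chrom(iv) for iv in g.cds]
            spliced = g.spliced_cds()
            utr5, utr3 = _utrs_from(g, to_chrom)
            ts = TranscriptStructure(
                transcript_id=gid + ".t1",
                exons=exons,
                cds_segments=cds,
                utr5_exons=utr5,
                utr3_exons=utr3,
                cds_nt=spliced,
                protein=translate_cds(spliced),
            )
            locus = Interval(chrom, min(e.start for e in exons), max(e.end for e in exons), g.strand)
            genes[gid] = GeneModel(
                gene_id=gid,
                species=species,
                locus=locus,
                transcripts=[ts],
                is_histone=g.is_histone,
                te_overlap_fraction=1.0 if g.is_te else 0.0,
            )
            if g.is_te:
                te_intervals.append((chrom, locus.start, locus.end))
        parts.append("ACGT" * 50)  # trailing spacer
        sequences[chrom] = "".join(parts)
    return GenomeSet(species, genes, sequences), te_intervals


def _utrs_from(g: _SimGene, to_chrom):
    """Gene-local UTR pieces (exon minus CDS) mapped to chromosome intervals."""
    utr5, utr3 = [], []
    cds_s, cds_e = g.cds[0][0], g.cds[-1][1]
    for s, e in g.exons:
        if s < cds_s:
            utr5.append(to_chrom((s, min(e, cds_s - 1))))
        if e > cds_e:
            utr3.append(to_chrom((max(s, cds_e + 1), e)))
    return utr5, utr3


def simulate_cohort(cfg: SimulationConfig) -> tuple[dict[str, GenomeSet], list[GroundTruthEvent]]:
    """Simulate the three genomes and the ground-truth event log."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ancestral_genes
    cde_vals = sorted(cfg.exon_count_distribution)
    cde_probs = np.array([cfg.exon_count_distribution[v] for v in cde_vals], dtype=float)
    cde_probs /= cde_probs.sum()

    root: _Genome = {f"chr{c+1}": [] for c in range(cfg.n_chromosomes)}
    multi_pool: list[str] = []
    one_cde_ids: list[str] = []
    for i in range(n):
        n_cde = int(np.asarray(cde_vals)[rng.choice(len(cde_vals), p=cde_probs)])
        gid = f"g{i+1:04d}"
        gene = _make_gene(rng, cfg, gid, n_cde)
        chrom = f"chr{i % cfg.n_chromosomes + 1}"
        root[chrom].append(gene)
        if n_cde >= 3:
            multi_pool.append(gid)
        elif n_cde == 1:
            one_cde_ids.append(gid)
    for gid in one_cde_ids[: cfg.n_histone_genes]:
        chrom, i = _locate(root, gid)
        root[chrom][i].is_histone = True

    needed = (
        cfg.n_ancestral_retro
        + cfg.n_relocations
        + cfg.n_intron_gains
        + cfg.n_truncated_retro
        + cfg.n_lineage_retro_A
        + cfg.n_lineage_retro_B
        + cfg.n_parental_losses
        + cfg.n_segdup_confounders
        + cfg.n_te_confounders
    )
    if needed > len(multi_pool):
        raise ValueError(
            f"event counts require {needed} multi-exon source genes but only {len(multi_pool)} available"
        )
    rng.shuffle(multi_pool)
    cde_of: dict[str, int] = {}
    for chrom in root:
        for g in root[chrom]:
            cde_of[g.base_id] = g.n_cds_exons

    def draw_source(min_cde: int = 3) -> str:
        for i, gid in enumerate(multi_pool):
            if cde_of[gid] >= min_cde:
                return multi_pool.pop(i)
        raise ValueError(f"gene pool exhausted: no unused source with >= {min_cde} coding exons")

    events: list[GroundTruthEvent] = []
    retro_counter = 0
    # Planted copies must stay out of the +-5-gene synteny windows that the
    # detection filters inspect.  Two constraints follow: (i) a copy of
    # source X may not land near the (ancestral) neighborhood of X itself,
    # because those neighbors' orthologs flank the surviving parent in the
    # other genomes; (ii) it may not land near another planted copy whose
    # source lies ancestrally close to X, because each copy would then look
    # like a duplicated neighbor of the other's parent.  Anything else may
    # land anywhere, which keeps the small genomes from saturating.
    root_pos: dict[str, tuple[str, int]] = {}
    for _chrom in root:
        for _i, _g in enumerate(root[_chrom]):
            root_pos[_g.base_id] = (_chrom, _i)
    planted_src: dict[str, tuple[str, ...]] = {}  # planted base id -> source base ids
    # planted base id -> background genes flanking its insertion locus; a new
    # copy whose *source* is ancestrally close to such an anchor must not land
    # next to that planted gene, or the two families would cross-contaminate
    # each other's synteny windows
    planted_anchor: dict[str, tuple[str, ...]] = {}

    def _root_close(s1: str, s2: str, thresh: int = 10) -> bool:
        p1, p2 = root_pos.get(s1), root_pos.get(s2)
        return p1 is not None and p2 is not None and p1[0] == p2[0] and abs(p1[1] - p2[1]) <= thresh

    def _anchor_ids(genome: _Genome, chrom: str, idx: int, span: int = 5) -> tuple[str, ...]:
        genes = genome[chrom]
        flank = genes[max(0, idx - span) : idx + span]
        return tuple(g.base_id for g in flank if g.base_id in root_pos)

    # relocated ancestral retrogenes sit at different loci in A and B; their
    # two synteny windows must stay disjoint in family terms, so a new copy
    # of family F may not land near a relocated retro in one genome when F
    # already has a member near that retro's locus in the sister genome
    relocated_recs: list[_AncestralRecord] = []
    genomes_by_label: dict[str, _Genome] = {}

    def _family(base_id: str) -> str:
        return planted_src.get(base_id, (base_id,))[0]

    def _relocated_guard(
        genome: _Genome, label: str, sources: tuple[str, ...]
    ) -> list[tuple[str, int]]:
        other = genomes_by_label.get("B" if label == "A" else "A" if label == "B" else "")
        if other is None:
            return []
        out = []
        for rec in relocated_recs:
            try:
                here = _locate(genome, rec.rid)
                there = _locate(other, rec.rid)
            except KeyError:
                continue
            flank = other[there[0]][max(0, there[1] - 7) : there[1] + 8]
            fams = {_family(g.base_id) for g in flank}
            if set(sources) & fams:
                out.append(here)
        return out

    def _avoid_for(
        genome: _Genome,
        sources: tuple[str, ...],
        context_of: str | None = None,
        label: str = "",
    ) -> list[tuple[str, int]]:
        close = [
            pid
            for pid, psrcs in planted_src.items()
            if any(_root_close(a, b) for a in sources for b in psrcs)
            or any(_root_close(a, b) for a in sources for b in planted_anchor.get(pid, ()))
        ]
        avoid = _positions_of(genome, close)
        if context_of is not None and context_of in root_pos:
            c, i = root_pos[context_of]
            flank = [g.base_id for g in root[c][max(0, i - 5) : i + 6] if g.base_id != context_of]
            avoid += _positions_of(genome, flank + [context_of])
        avoid += _relocated_guard(genome, label, sources)
        return avoid

    def next_retro_id() -> str:
        nonlocal retro_counter
        retro_counter += 1
        return f"r{retro_counter:04d}"

    # ----- outgroup: plain copy of the root -----
    genome_O = copy.deepcopy(root)

    # ----- (A,B) ancestor: ancestral retropositions -----
    genome_AB = copy.deepcopy(root)
    ancestral_specs = (
        [("plain", None)] * cfg.n_ancestral_retro
        + [("relocate", "A" if k % 2 == 0 else "B") for k in range(cfg.n_relocations)]
        + [("intron_gain", "B")] * cfg.n_intron_gains
        + [("truncated", None)] * cfg.n_truncated_retro
    )
    ancestral_records: list[_AncestralRecord] = []
    plain_ancestral: list[str] = []
    for kind, which in ancestral_specs:
        # a truncated copy must come from a >=4-CDE parent: with one 5' exon
        # dropped it still has to span the two most-3' junctions
        src = draw_source(4 if kind == "truncated" else 3)
        trunc = 1 if kind == "truncated" else 0
        src_chrom, src_idx = _locate(genome_AB, src)
        parent = genome_AB[src_chrom][src_idx]
        flank = genome_AB[src_chrom][max(0, src_idx - 2) : src_idx + 3]
        src_neighbors = tuple(g.base_id for g in flank if g.base_id != src)
        rid = next_retro_id()
        retro, polyA, tsd = _make_retro(rng, cfg, rid, parent, truncate_exons=trunc)
        avoid = _avoid_for(genome_AB, (src,), context_of=src, label="AB")
        chrom, idx = _insert_position(rng, genome_AB, avoid=avoid, margin=9)
        planted_anchor[rid] = _anchor_ids(genome_AB, chrom, idx)
        genome_AB[chrom].insert(idx, retro)
        planted_src[rid] = (src,)
        _remove(genome_AB, src)  # parental loss in the common ancestor
        ancestral_records.append(_AncestralRecord(rid, kind, which, src, src_neighbors, polyA, tsd, trunc))
        if kind == "plain":
            plain_ancestral.append(rid)
    for chrom in genome_AB:
        for g in genome_AB[chrom]:
            _mutate_gene(rng, g, cfg.rate_to_ancestor, cfg.cds_omega)

    genome_A = copy.deepcopy(genome_AB)
    genome_B = copy.deepcopy(genome_AB)

    # ----- lineage events -----
    def lineage_events(genome: _Genome, sp: str) -> None:
        rate = cfg.rate_to_A if sp == "A" else cfg.rate_to_B
        for chrom in genome:
            for g in genome[chrom]:
                _mutate_gene(rng, g, rate / 2.0, cfg.cds_omega)
        if sp == "A":
            _apply_A_events(genome)
        else:
            _apply_B_events(genome)
        for chrom in genome:
            for g in genome[chrom]:
                _mutate_gene(rng, g, rate / 2.0, cfg.cds_omega)

    def _plant_lineage_retro(genome: _Genome, sp: str, lose_parent: bool) -> None:
        src = draw_source()
        src_chrom, src_idx = _locate(genome, src)
        parent = genome[src_chrom][src_idx]
        rid = next_retro_id()
        retro, polyA, tsd = _make_retro(rng, cfg, rid, parent)
        avoid = _avoid_for(genome, (src,), context_of=src, label=sp)
        chrom, idx = _insert_position(rng, genome, avoid=avoid, margin=9)
        planted_anchor[rid] = _anchor_ids(genome, chrom, idx)
        genome[chrom].insert(idx, retro)
        planted_src[rid] = (src,)
        events.append(
            GroundTruthEvent(
                "retroposition_lineage", LINEAGE_OF[sp], (f"{sp}_{rid}",), src, polyA, tsd, 0
            )
        )
        if lose_parent:
            _remove(genome, src)
            events.append(
                GroundTruthEvent("parental_loss", LINEAGE_OF[sp], (f"{sp}_{rid}",), src)
            )

    def _relocate(genome: _Genome, rec: _AncestralRecord, label: str) -> None:
        # move the retrogene somewhere outside both its old neighborhood and
        # the parent's former neighborhood (whose orthologs still flank it)
        old = _locate(genome, rec.rid)
        g = genome[old[0]].pop(old[1])
        avoid = _avoid_for(genome, (rec.src,), context_of=rec.src, label=label) + [old]
        chrom, idx = _insert_position(rng, genome, avoid=avoid, margin=9)
        # the sister copy keeps the old locus: both anchors stay live
        planted_anchor[rec.rid] = planted_anchor.get(rec.rid, ()) + _anchor_ids(genome, chrom, idx)
        genome[chrom].insert(idx, g)

    def _apply_A_events(genome: _Genome) -> None:
        for _ in range(cfg.n_lineage_retro_A):
            _plant_lineage_retro(genome, "A", lose_parent=False)
        for _ in range(cfg.n_parental_losses):
            _plant_lineage_retro(genome, "A", lose_parent=True)
        for k in range(cfg.n_retro_duplications):
            if not plain_ancestral:
                break
            rid = plain_ancestral[k % len(plain_ancestral)]
            rec = next(r for r in ancestral_records if r.rid == rid)
            chrom0, i0 = _locate(genome, rid)
            dup = copy.deepcopy(genome[chrom0][i0])
            dup.base_id = f"{rid}d{k+1}"
            dup.tail3, dup.tsd = "", ""
            dup.left_spacer = _rand_seq(rng, _rand_len(rng, cfg.intergenic_len, 100))
            avoid = _avoid_for(genome, (rec.src,), context_of=rec.src, label="A") + [(chrom0, i0)]
            chrom, idx = _insert_position(rng, genome, avoid=avoid, margin=9)
            planted_anchor[dup.base_id] = _anchor_ids(genome, chrom, idx)
            genome[chrom].insert(idx, dup)
            planted_src[dup.base_id] = (rec.src,)
            events.append(
                GroundTruthEvent(
                    "retro_duplication", "ingroupA", (f"A_{dup.base_id}", f"A_{rid}"), rec.src,
                )
            )
        for k in range(cfg.n_segdup_confounders):
            src = draw_source()
            src_chrom, src_idx = _locate(genome, src)
            parent = genome[src_chrom][src_idx]
            # intron-free copy of the gene, carried along with one flanking neighbor
            copy_id = f"sd{k+1:02d}"
            sd_gene, _, _ = _make_retro(rng, cfg, copy_id, parent)
            neighbor_idx = None
            for off in (-1, 1, -2, 2, -3, 3):
                j = src_idx + off
                if 0 <= j < len(genome[src_chrom]) and genome[src_chrom][j].base_id in cde_of:
                    neighbor_idx = j
                    break
            if neighbor_idx is None:
                neighbor_idx = src_idx - 1 if src_idx > 0 else src_idx + 1
            neighbor = copy.deepcopy(genome[src_chrom][neighbor_idx])
            neighbor.base_id = f"{copy_id}n"
            neighbor.left_spacer = _rand_seq(rng, _rand_len(rng, cfg.intergenic_len, 100))
            nbase = genome[src_chrom][neighbor_idx].base_id
            avoid = _avoid_for(genome, (src, nbase), label="A") + [(src_chrom, src_idx)]
            chrom, idx = _insert_position(rng, genome, avoid=avoid, margin=9)
            anchors = _anchor_ids(genome, chrom, idx)
            genome[chrom].insert(idx, sd_gene)
            genome[chrom].insert(idx + 1, neighbor)
            planted_src[sd_gene.base_id] = (src,)
            planted_src[neighbor.base_id] = (nbase,)
            planted_anchor[sd_gene.base_id] = anchors
            planted_anchor[neighbor.base_id] = anchors
            events.append(
                GroundTruthEvent(
                    "segmental_duplication", "ingroupA",
                    (f"A_{copy_id}", f"A_{neighbor.base_id}"), src,
                )
            )
        for k in range(cfg.n_te_confounders):
            src = draw_source()
            src_chrom, src_idx = _locate(genome, src)
            parent = genome[src_chrom][src_idx]
            te_gene, _, _ = _make_retro(rng, cfg, f"tc{k+1:02d}", parent)
            te_gene.is_te = True
            avoid = _avoid_for(genome, (src,), label="A") + [(src_chrom, src_idx)]
            chrom, idx = _insert_position(rng, genome, avoid=avoid, margin=9)
            planted_anchor[te_gene.base_id] = _anchor_ids(genome, chrom, idx)
            genome[chrom].insert(idx, te_gene)
            planted_src[te_gene.base_id] = (src,)
            events.append(
                GroundTruthEvent("te_insertion", "ingroupA", (f"A_tc{k+1:02d}",), src)
            )

    def _apply_B_events(genome: _Genome) -> None:
        for rec in ancestral_records:
            if rec.kind == "intron_gain":
                chrom, i = _locate(genome, rec.rid)
                _insert_intron(rng, cfg, genome[chrom][i], int(rng.integers(1, 3)))
        for _ in range(cfg.n_lineage_retro_B):
            _plant_lineage_retro(genome, "B", lose_parent=False)

    genomes_by_label["A"] = genome_A
    genomes_by_label["B"] = genome_B
    for rec in ancestral_records:
        if rec.kind == "relocate":
            relocated_recs.append(rec)
            _relocate(genome_A if rec.which == "A" else genome_B, rec, rec.which)
    lineage_events(genome_A, "A")
    lineage_events(genome_B, "B")
    for chrom in genome_O:
        for g in genome_O[chrom]:
            _mutate_gene(rng, g, cfg.rate_to_outgroup, cfg.cds_omega)

    # ----- log ancestral events with final ids -----
    for rec in ancestral_records:
        gene_ids = (f"A_{rec.rid}", f"B_{rec.rid}")
        events.append(
            GroundTruthEvent(
                "retroposition_ancestral", "common_ancestor", gene_ids, rec.src,
                rec.polyA, rec.tsd, rec.trunc,
            )
        )
        events.append(GroundTruthEvent("parental_loss", "common_ancestor", gene_ids, rec.src))
        if rec.kind == "relocate":
            events.append(
                GroundTruthEvent("relocation", LINEAGE_OF[rec.which], (f"{rec.which}_{rec.rid}",), rec.src)
            )
        elif rec.kind == "intron_gain":
            events.append(GroundTruthEvent("intron_gain", "ingroupB", (f"B_{rec.rid}",), rec.src))

    out: dict[str, GenomeSet] = {}
    te_map: dict[str, list[tuple[str, int, int]]] = {}
    for sp, genome in (("A", genome_A), ("B", genome_B), ("O", genome_O)):
        gs, te = _assemble(sp, genome)
        out[sp] = gs
        te_map[sp] = te
    for sp in out:
        out[sp].te_intervals = te_map[sp]  # type: ignore[attr-defined]
    return out, events


def write_cohort(cohort: tuple[dict[str, GenomeSet], list[GroundTruthEvent]], out_dir: str) -> None:
    """Write per-species GFF3 + genome/protein/CDS FASTA + TE BED + truth TSV."""
    genomes, events = cohort
    os.makedirs(out_dir, exist_ok=True)
    for sp, gs in genomes.items():
        prefix = os.path.join(out_dir, sp)
        write_annotation(
            gs,
            prefix + ".gff3",
            genome_fasta=prefix + ".genome.fa",
            protein_fasta=prefix + ".proteins.fa",
            cds_fasta=prefix + ".cds.fa",
        )
        with open(prefix + ".te.bed", "w") as bed:
            for chrom, start, end in getattr(gs, "te_intervals", []):
                bed.write(f"{chrom}\t{start - 1}\t{end}\tTE\n")
        with open(prefix + ".histones.txt", "w") as hh:
            for gid, g in sorted(gs.genes.items()):
                if g.is_histone:
                    hh.write(gid + "\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("event_type\tlineage\tgene_ids\tsource_gene\tpolyA\ttsd\ttruncated_exons\n")
        for ev in events:
            fh.write(
                f"{ev.event_type}\t{ev.lineage}\t{','.join(ev.gene_ids)}\t{ev.source_gene}\t"
                f"{int(ev.polyA_planted)}\t{int(ev.tsd_planted)}\t{ev.truncated_exons}\n"
            )
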