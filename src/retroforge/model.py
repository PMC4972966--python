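"""Core domain types for annotated genomes.

The pipeline works on per-species gene models: each protein-coding locus
carries one or more transcript structures (exons, CDS segments, UTRs) plus
the spliced coding sequence and its translation.  Coordinates are 1-based
inclusive throughout (GFF3 convention); conversions to half-open systems
happen explicitly at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "Interval",
    "TranscriptStructure",
    "GeneModel",
    "GenomeSet",
    "select_longest_transcript",
    "genome_summary",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "Interval") -> int:
        """Number of overlapping bases with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptStructure:
    """One transcript: ordered exons/CDS/UTRs plus spliced CDS and protein.

    ``exons`` and ``cds_segments`` are in transcription order (5'->3' of the
    mRNA); for minus-strand genes this is descending chromosomal order.
    """

    transcript_id: str
    exons: list[Interval]
    cds_segments: list[Interval]
    utr5_exons: list[Interval] = field(default_factory=list)
    utr3_exons: list[Interval] = field(default_factory=list)
    protein: str = ""
    cds_nt: str = ""

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_cds_exons(self) -> int:
        """Number of coding exons (CDEs)."""
        return len(self.cds_segments)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds_segments)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def cds_junction_positions(self) -> list[int]:
        """Spliced-CDS nucleotide offsets of the coding exon junctions.

        Junction ``j`` (1-based, 1 = most 5') sits after the returned
        nucleotide position (1-based within the spliced CDS).
        """
        out, cum = [], 0
        for seg in self.cds_segments[:-1]:
            cum += len(seg)
            out.append(cum)
        return out


@dataclass
class GeneModel:
    """A protein-coding locus with its transcript(s)."""

    gene_id: str
    species: str
    locus: Interval
    transcripts: list[TranscriptStructure]
    is_histone: bool = False
    te_overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if not 0.0 <= self.te_overlap_fraction <= 1.0:
            raise ValueError("te_overlap_fraction must be in [0, 1]")

    @property
    def longest(self) -> TranscriptStructure:
        return select_longest_transcript(self)


def select_longest_transcript(gene: GeneModel, by: str = "cds") -> TranscriptStructure:
    """Pick the representative transcript of a locus.

    ``by='cds'`` (default) selects the longest coding sequence, ``by='mrna'``
    the longest spliced transcript.  Ties break to the lexicographically
    smaller transcript_id, so the choice is deterministic.
    """
    if by == "cds":
        key = lambda t: (-t.cds_length, t.transcript_id)
    elif by == "mrna":
        key = lambda t: (-sum(len(e) for e in t.exons), t.transcript_id)
    else:
        raise ValueError(f"unknown selection mode {by!r}")
    return min(gene.transcripts, key=key)


class GenomeSet:
    """All gene models and chromosome sequences of one species."""

    def __init__(self, species: str, genes: dict[str, GeneModel], sequences: dict[str, str]):
        self.species = species
        self.genes = dict(genes)
        self.sequences = dict(sequences)
        self._order_cache: dict[str, list[str]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic sequence, 1-based inclusive, reverse-complemented on '-'.

        Coordinates are clipped to the chromosome; a chromosome absent from
        the set is a hard error naming the sequence.
        """
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not present in genome of {self.species}")
        seq = self.sequences[chrom]
        s = max(1, start)
        e = min(len(seq), end)
        if e < s:
            return ""
        sub = seq[s - 1 : e]
        return revcomp(sub) if strand == "-" else sub

    def genes_in_order(self, chrom: str) -> list[str]:
        """Gene IDs on *chrom* sorted by start coordinate."""
        if self._order_cache is None:
            self._order_cache = {}
            by_chrom: dict[str, list[GeneModel]] = {}
            for g in self.genes.values():
                by_chrom.setdefault(g.locus.chrom, []).append(g)
            for c, gs in by_chrom.items():
                self._order_cache[c] = [g.gene_id for g in sorted(gs, key=lambda g: (g.locus.start, g.gene_id))]
        return self._order_cache.get(chrom, [])

    def invalidate_order(self) -> None:
        self._order_cache = None

    @property
    def avg_utr3_len(self) -> float:
        """Mean annotated 3'UTR length over longest transcripts having one."""
        lens = []
        for g in self.genes.values():
            t = g.longest
            if t.utr3_exons:
                lens.append(sum(len(u) for u in t.utr3_exons))
        return float(sum(lens)) / len(lens) if lens else 0.0

    def proteins(self) -> dict[str, str]:
        """gene_id -> protein of the longest transcript."""
        return {gid: g.longest.protein for gid, g in self.genes.items()}


def _bin_counts(values: list[int]) -> dict[str, int]:
    bins = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    for v in values:
        bins[str(v) if v < 5 else ">=5"] += 1
    return bins


def genome_summary(genomes: dict[str, GenomeSet] | list[GenomeSet]) -> pd.DataFrame:
    """Per-species exon/CDE count table with percentages.

    Rows: one per (species, bin) with counts and percentages of genes whose
    longest transcript has 1, 2, 3, 4 or >=5 exons (UTR exons included) and
    coding exons, plus totals and mean introns per gene.
    """
    if isinstance(genomes, list):
        genomes = {g.species: g for g in genomes}
    rows = []
    for sp, gs in genomes.items():
        if len(gs) == 0:
            raise ValueError(f"genome of {sp} is empty")
        longest = [g.longest for g in gs.genes.values()]
        total = len(longest)
        exon_bins = _bin_counts([t.n_exons for t in longest])
        cde_bins = _bin_counts([t.n_cds_exons for t in longest])
        introns_per_gene = sum(t.n_introns for t in longest) / total
        for b in ("1", "2", "3", "4", ">=5"):
            rows.append(
                {
                    "species": sp,
                    "bin": b,
                    "n_genes_exons": exon_bins[b],
                    "pct_genes_exons": 100.0 * exon_bins[b] / total,
                    "n_genes_cdes": cde_bins[b],
                    "pct_genes_cdes": 100.0 * cde_bins[b] / total,
                    "total_genes": total,
                    "introns_per_gene": introns_per_gene,
                }
            )
    return pd.DataFrame(rows)
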