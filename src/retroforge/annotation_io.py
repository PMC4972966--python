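"""Readers and writers for GFF3 annotations, FASTA sequences and TE intervals.

``read_annotation`` turns a GFF3 + genome FASTA pair into a
:class:`~retroforge.model.GenomeSet`: every mRNA becomes a
``TranscriptStructure`` whose protein is derived by translating the spliced
CDS; UTRs are taken from explicit five_prime_UTR/three_prime_UTR features
when present and otherwise derived as exon-minus-CDS.  ``write_annotation``
emits files that round-trip bit-exactly through the reader.
"""

from __future__ import annotations

import logging

import gffutils
from Bio.Seq import Seq

from .model import GeneModel, GenomeSet, Interval, TranscriptStructure, revcomp

log = logging.getLogger(__name__)

__all__ = ["read_annotation", "write_annotation", "read_te_intervals", "translate_cds"]


def translate_cds(cds_nt: str) -> str:
    """Translate a spliced CDS (standard code), dropping a terminal stop."""
    prot = str(Seq(cds_nt).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def read_te_intervals(te_path: str) -> dict[str, list[tuple[int, int]]]:
    """TE intervals per chromosome from BED (0-based half-open) or GFF3."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(te_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if te_path.endswith((".gff", ".gff3")):
                chrom, start, end = parts[0], int(parts[3]), int(parts[4])
            else:  # BED
                chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
            out.setdefault(chrom, []).append((start, end))
    return out


def _overlap_fraction(locus: Interval, intervals: list[tuple[int, int]]) -> float:
    """Fraction of the gene span covered by (possibly overlapping) intervals."""
    span = [(max(locus.start, s), min(locus.end, e)) for s, e in intervals if s <= locus.end and e >= locus.start]
    if not span:
        return 0.0
    span.sort()
    covered, cur_s, cur_e = 0, *span[0]
    for s, e in span[1:]:
        if s > cur_e + 1:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s + 1
    return covered / len(locus)


def _read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _subtract(exon: Interval, cds_list: list[Interval]) -> list[tuple[int, int]]:
    """Parts of *exon* not covered by any CDS segment (chromosome coords)."""
    pieces = [(exon.start, exon.end)]
    for c in cds_list:
        nxt = []
        for s, e in pieces:
            if c.end < s or c.start > e:
                nxt.append((s, e))
                continue
            if s < c.start:
                nxt.append((s, c.start - 1))
            if e > c.end:
                nxt.append((c.end + 1, e))
        pieces = nxt
    return pieces


def read_annotation(
    gff3_path: str,
    fasta_path: str,
    te_path: str | None = None,
    histone_ids: set[str] | str | None = None,
    species: str | None = None,
) -> GenomeSet:
    """Load one species' annotation into a GenomeSet.

    Transcripts whose CDS length is not a multiple of three are excluded
    with a logged warning; a CDS referencing a chromosome missing from the
    FASTA is a hard error naming the sequence.  ``histone_ids`` may be a set
    of gene IDs or a path to a one-ID-per-line file; independently, genes
    whose GFF3 ``description``/``Note`` attribute contains "histone"
    (case-insensitive) are flagged.
    """
    sequences = _read_fasta(fasta_path)
    te = read_te_intervals(te_path) if te_path else {}
    if isinstance(histone_ids, str):
        with open(histone_ids) as fh:
            histone_ids = {line.strip() for line in fh if line.strip()}
    histone_ids = histone_ids or set()

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    species = species or gff3_path
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        if gene.seqid not in sequences:
            raise KeyError(f"chromosome {gene.seqid!r} referenced by {gene.id} missing from FASTA")
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            strand = mrna.strand
            exons = [
                Interval(f.seqid, f.start, f.end, strand)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            cds = [
                Interval(f.seqid, f.start, f.end, strand)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            utr5 = [
                Interval(f.seqid, f.start, f.end, strand)
                for f in db.children(mrna, featuretype="five_prime_UTR", order_by="start")
            ]
            utr3 = [
                Interval(f.seqid, f.start, f.end, strand)
                for f in db.children(mrna, featuretype="three_prime_UTR", order_by="start")
            ]
            if not exons:
                exons = list(cds)
            if not cds:
                log.warning("transcript %s has no CDS; skipped", mrna.id)
                continue
            if not utr5 and not utr3:
                utr5, utr3 = _derive_utrs(exons, cds, strand)
            cds_len = sum(len(c) for c in cds)
            if cds_len % 3 != 0:
                log.warning("transcript %s CDS length %d not a multiple of 3; excluded", mrna.id, cds_len)
                continue
            chrom_seq = sequences[gene.seqid]
            spliced = "".join(chrom_seq[c.start - 1 : c.end] for c in sorted(cds, key=lambda c: c.start))
            if strand == "-":
                spliced = revcomp(spliced)
                exons = sorted(exons, key=lambda i: -i.start)
                cds = sorted(cds, key=lambda i: -i.start)
                utr5 = sorted(utr5, key=lambda i: -i.start)
                utr3 = sorted(utr3, key=lambda i: -i.start)
            transcripts.append(
                TranscriptStructure(
                    transcript_id=mrna.id,
                    exons=exons,
                    cds_segments=cds,
                    utr5_exons=utr5,
                    utr3_exons=utr3,
                    cds_nt=spliced,
                    protein=translate_cds(spliced),
                )
            )
        if not transcripts:
            continue
        locus = Interval(gene.seqid, gene.start, gene.end, gene.strand)
        desc = " ".join(gene.attributes.get("description", []) + gene.attributes.get("Note", []))
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            species=species,
            locus=locus,
            transcripts=transcripts,
            is_histone=gene.id in histone_ids or "histone" in desc.lower(),
            te_overlap_fraction=_overlap_fraction(locus, te.get(gene.seqid, [])),
        )
    return GenomeSet(species, genes, sequences)


def _derive_utrs(exons, cds, strand):
    """UTR intervals as exon-minus-CDS, split into 5' and 3' by strand."""
    cds_min = min(c.start for c in cds)
    cds_max = max(c.end for c in cds)
    utr5, utr3 = [], []
    for exon in exons:
        for s, e in _subtract(exon, cds):
            iv = Interval(exon.chrom, s, e, strand)
            upstream = e < cds_min
            downstream = s > cds_max
            if not (upstream or downstream):
                continue  # internal non-coding piece inside the CDS span
            if (upstream and strand == "+") or (downstream and strand == "-"):
                utr5.append(iv)
            else:
                utr3.append(iv)
    return sorted(utr5), sorted(utr3)


def write_annotation(
    gs: GenomeSet,
    gff3_path: str,
    genome_fasta: str | None = None,
    protein_fasta: str | None = None,
    cds_fasta: str | None = None,
) -> None:
    """Write a GenomeSet back to GFF3 (+ optional FASTA files)."""
    with open(gff3_path, "w") as out:
        out.write("##gff-version 3\n")
        order = []
        for chrom in sorted(gs.sequences):
            order.extend(gs.genes_in_order(chrom))
        for gid in order:
            g = gs.genes[gid]
            loc = g.locus
            attrs = f"ID={g.gene_id}"
            if g.is_histone:
                attrs += ";description=histone"
            out.write(
                f"{loc.chrom}\tretroforge\tgene\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                out.write(
                    f"{loc.chrom}\tretroforge\tmRNA\t{min(e.start for e in t.exons)}\t"
                    f"{max(e.end for e in t.exons)}\t.\t{loc.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                feats = (
                    [("exon", e) for e in t.exons]
                    + [("CDS", c) for c in t.cds_segments]
                    + [("five_prime_UTR", u) for u in t.utr5_exons]
                    + [("three_prime_UTR", u) for u in t.utr3_exons]
                )
                for ftype, iv in sorted(feats, key=lambda x: (x[1].start, x[0])):
                    phase = "."
                    out.write(
                        f"{iv.chrom}\tretroforge\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                        f"{iv.strand}\t{phase}\tID={t.transcript_id}.{ftype}.{iv.start};Parent={t.transcript_id}\n"
                    )
    if genome_fasta:
        _write_fasta(genome_fasta, gs.sequences)
    if protein_fasta:
        _write_fasta(protein_fasta, gs.proteins())
    if cds_fasta:
        _write_fasta(cds_fasta, {gid: g.longest.cds_nt for gid, g in gs.genes.items()})


def _write_fasta(path: str, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as out:
        for name in seqs:
            out.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                out.write(s[i : i + width] + "\n")
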