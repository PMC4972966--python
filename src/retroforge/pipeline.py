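"""End-to-end orchestration: detection -> clustering -> trees -> events -> dN/dS.

This is the programmatic equivalent of the ``retroforge all`` command; each
stage can also be run on its own through the underlying modules.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import read_annotation
from .detection import DetectionParams, HomologyService, RetrogeneCandidate, run_detection
from .events import EvolutionaryEventCall, FamilyContext, infer_family_events, summarize_events
from .homology import ProteinAligner
from .model import GenomeSet
from .phylogeny import GeneTree, HomologGroup, build_tree, merge_groups, pairwise_orthologs
from .selection import (
    DnDsResult,
    backtranslate,
    choose_representative_parent,
    estimate_dnds,
    functionality_screen,
    ng86_counts,
)

log = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "run_pipeline", "load_cohort"]


@dataclass
class AnalysisResult:
    candidates: list[RetrogeneCandidate]
    groups: list[HomologGroup]
    trees: dict[str, GeneTree]
    event_calls: list[EvolutionaryEventCall]
    event_summary: pd.DataFrame
    dnds: dict[str, DnDsResult] = field(default_factory=dict)
    functional: dict[str, bool] = field(default_factory=dict)
    rbh_pairs: set[tuple[str, str]] = field(default_factory=set)


def load_cohort(
    cohort_dir: str, species: tuple[str, ...] = ("A", "B", "O")
) -> dict[str, GenomeSet]:
    """Read a cohort written by ``write_cohort`` (or following its layout)."""
    genomes = {}
    for sp in species:
        prefix = os.path.join(cohort_dir, sp)
        te = prefix + ".te.bed"
        hist = prefix + ".histones.txt"
        genomes[sp] = read_annotation(
            prefix + ".gff3",
            prefix + ".genome.fa",
            te_path=te if os.path.exists(te) else None,
            histone_ids=hist if os.path.exists(hist) else None,
            species=sp,
        )
    return genomes


def cluster_genes(
    genomes: dict[str, GenomeSet],
    aligner: ProteinAligner,
    params: DetectionParams,
    retrogene_ids: set[str] | None = None,
) -> tuple[list[HomologGroup], set[tuple[str, str]]]:
    """Reciprocal-best-hit pairs merged with same-species hits by single
    linkage into multi-species homolog groups."""
    proteomes = {sp: gs.proteins() for sp, gs in genomes.items()}
    species_of = {gid: sp for sp, prot in proteomes.items() for gid in prot}
    species = sorted(genomes)
    cross_hits: dict[tuple[str, str], list] = {}
    for i, a in enumerate(species):
        for b in species:
            if a == b:
                continue
            cross_hits[(a, b)] = aligner.all_vs_all(
                proteomes[a], proteomes[b], e_cutoff=params.e_cutoff,
                prefilter_k=params.prefilter_k,
            )
    rbh: set[tuple[str, str]] = set()
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            rbh |= pairwise_orthologs(cross_hits[(a, b)], cross_hits[(b, a)])
    edges = set(rbh)
    from .detection import filter_similarity

    for sp in species:
        for h in aligner.all_vs_all(
            proteomes[sp], proteomes[sp], e_cutoff=params.e_cutoff,
            exclude_self=True, prefilter_k=params.prefilter_k,
        ):
            ok, _ = filter_similarity(
                h, len(proteomes[sp][h.query_id]), len(proteomes[sp][h.subject_id]), params
            )
            if ok:
                edges.add((h.query_id, h.subject_id))
    groups = merge_groups(edges, species_of, retrogene_ids)
    log.info("clustering: %d RBH pairs, %d groups (%d with retrogenes)",
             len(rbh), len(groups), sum(g.contains_retrogene for g in groups))
    return groups, rbh


def run_pipeline(
    genomes: dict[str, GenomeSet],
    ingroups: tuple[str, str] = ("A", "B"),
    outgroup: str = "O",
    params: DetectionParams | None = None,
    seed: int = 0,
    n_bootstrap: int = 100,
    alpha: float = 0.05,
    with_dnds: bool = True,
) -> AnalysisResult:
    """Run the whole analysis over a three-species cohort."""
    params = params or DetectionParams()
    aligner = ProteinAligner(e_cutoff=params.e_cutoff)
    homology = HomologyService(genomes, aligner, params)

    candidates = run_detection(genomes, ingroups, outgroup, params, aligner, homology)
    cand_ids = {c.retro_gene_id for c in candidates}
    cand_by_id = {c.retro_gene_id: c for c in candidates}

    groups, rbh = cluster_genes(genomes, aligner, params, cand_ids)
    retro_groups = [g for g in groups if g.contains_retrogene]

    proteins = {gid: gs.genes[gid].longest.protein for gs in genomes.values() for gid in gs.genes}
    trees: dict[str, GeneTree] = {}
    for g in retro_groups:
        t = build_tree(g, proteins, aligner, n_bootstrap=n_bootstrap, seed=seed)
        if t is not None:
            trees[g.group_id] = t

    calls: list[EvolutionaryEventCall] = []
    for g in retro_groups:
        ctx = FamilyContext(
            g, cand_by_id, genomes, homology, rbh, ingroups, outgroup,
            tree=trees.get(g.group_id),
        )
        calls.extend(infer_family_events(ctx))
    summary = summarize_events(calls)

    dnds: dict[str, DnDsResult] = {}
    functional: dict[str, bool] = {}
    if with_dnds:
        for cand in candidates:
            # representative parent: smallest dS over all pairings (NG86
            # dS ranks the pairs; the ML fit is run on the representative)
            ds_by_parent: dict[str, float] = {}
            for m in cand.parents:
                ca = backtranslate(
                    m.hit,
                    genomes[cand.retro_species].genes[cand.retro_gene_id].longest.cds_nt,
                    genomes[m.parent_species].genes[m.parent_id].longest.cds_nt,
                )
                ng = ng86_counts(ca)
                ds = ng["dS"]
                ds_by_parent[m.parent_id] = ds if math.isfinite(ds) else float("inf")
            rep = choose_representative_parent(ds_by_parent)
            cand.representative_parent = rep
            m = next(p for p in cand.parents if p.parent_id == rep)
            ca = backtranslate(
                m.hit,
                genomes[cand.retro_species].genes[cand.retro_gene_id].longest.cds_nt,
                genomes[m.parent_species].genes[m.parent_id].longest.cds_nt,
            )
            try:
                dnds[cand.retro_gene_id] = estimate_dnds(ca, alpha=alpha)
            except ValueError as exc:
                log.warning("dN/dS skipped for %s: %s", cand.retro_gene_id, exc)
        functional = functionality_screen(dnds, alpha=alpha)

    return AnalysisResult(
        candidates=candidates,
        groups=groups,
        trees=trees,
        event_calls=calls,
        event_summary=summary,
        dnds=dnds,
        functional=functional,
        rbh_pairs=rbh,
    )
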