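"""Parsimony reconstruction of retrogene histories on ((A,B),O).

For each retrogene-containing homolog group the composition of the group
(which species carry a 1-CDE candidate, a multi-exon parent, or an
intron-gained ex-retrogene), the gene tree when one exists, and pairwise
synteny are combined to emit the minimum set of events explaining the
observed pattern:

* shared orthologous retrogenes in both ingroups with the parent surviving
  only in the outgroup mean a retroposition plus a parental loss in the
  ingroup ancestor; if the two retrogenes are not syntenic one of them was
  additionally relocated;
* a parent surviving in all three species alongside orthologous ingroup
  retrogenes pushes the retroposition before the outgroup split, with the
  parent retained and the retrocopy lost in the outgroup;
* a retrogene co-occurring with its parent in one species is a
  lineage-specific retroposition; a retrogene whose parent survives only in
  the sister ingroup implies the same plus a parental loss on the
  retrogene's branch (cheaper than an ancestral retroposition followed by
  two independent losses);
* extra same-species retrocopies forming a clade are DNA-based retrogene
  duplications;
* a 2-3-CDE ingroup gene that is the cross-ingroup ortholog of a 1-CDE
  retrogene with an outgroup parent is an intron-gained retrogene.

Groups matching no rule are emitted as ``unclassified``, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .detection import HomologyService, RetrogeneCandidate, synteny_context
from .model import GenomeSet
from .phylogeny import GeneTree, HomologGroup, are_syntenic

log = logging.getLogger(__name__)

__all__ = [
    "EvolutionaryEventCall",
    "infer_family_events",
    "detect_intron_gain",
    "summarize_events",
]

EVENT_TYPES = (
    "retroposition",
    "parental_loss",
    "relocation",
    "retro_duplication",
    "intron_gain",
    "parental_retention",
    "retrocopy_loss",
    "unclassified",
)
BRANCHES = (
    "common_ancestor",
    "ingroupA",
    "ingroupB",
    "outgroup",
    "pre_outgroup_split",
    "ambiguous",
)


@dataclass
class EvolutionaryEventCall:
    event_type: str
    branch: str
    genes: tuple[str, ...]
    group_id: str
    note: str = ""


class FamilyContext:
    """Everything the rules need about one retrogene-containing group."""

    def __init__(
        self,
        group: HomologGroup,
        candidates: dict[str, RetrogeneCandidate],
        genomes: dict[str, GenomeSet],
        homology: HomologyService,
        rbh_pairs: set[tuple[str, str]],
        ingroups: tuple[str, str],
        outgroup: str,
        tree: GeneTree | None = None,
        min_shared_synteny: int = 1,
    ):
        self.group = group
        self.genomes = genomes
        self.homology = homology
        self.tree = tree
        self.ingroups = ingroups
        self.outgroup = outgroup
        self.min_shared = min_shared_synteny
        self.lineage = {ingroups[0]: "ingroupA", ingroups[1]: "ingroupB", outgroup: "outgroup"}
        self.candidates = {g: candidates[g] for g in group.members if g in candidates}
        self.rbh = rbh_pairs | {(b, a) for a, b in rbh_pairs}
        self._ctx_cache: dict[str, object] = {}

    def cde(self, gid: str) -> int:
        sp = self.group.members[gid]
        return self.genomes[sp].genes[gid].longest.n_cds_exons

    def ctx(self, gid: str):
        if gid not in self._ctx_cache:
            sp = self.group.members[gid]
            self._ctx_cache[gid] = synteny_context(gid, self.genomes[sp])
        return self._ctx_cache[gid]

    def syntenic(self, g1: str, g2: str) -> bool:
        return are_syntenic(self.ctx(g1), self.ctx(g2), self.homology, self.min_shared)

    def linked(self, g1: str, g2: str) -> bool:
        """Orthology operationalized as RBH or sister leaves in the tree."""
        if (g1, g2) in self.rbh:
            return True
        if self.tree is not None:
            try:
                return self.tree.are_sisters(g1, g2)
            except Exception:
                return False
        return False


def detect_intron_gain(ctx: FamilyContext) -> tuple[list[EvolutionaryEventCall], set[str]]:
    """Find intron-gained ex-retrogenes in a family.

    A 2-3-CDE ingroup gene qualifies when it is the cross-ingroup ortholog
    (RBH or tree sister) of a 1-CDE candidate whose parent lies in the
    outgroup, and either has fewer coding exons than that parent or lies
    syntenic to the retrogene.  A non-syntenic gain is paired with a
    relocation call, mirroring the relocated-then-intron-gained cases.
    """
    calls: list[EvolutionaryEventCall] = []
    flagged: set[str] = set()
    by_sp = ctx.group.by_species()
    for sp in ctx.ingroups:
        other = ctx.ingroups[1] if sp == ctx.ingroups[0] else ctx.ingroups[0]
        for gid in by_sp.get(sp, []):
            if gid in ctx.candidates or not 2 <= ctx.cde(gid) <= 3:
                continue
            for cid, cand in ctx.candidates.items():
                if cand.retro_species != other:
                    continue
                o_parents = [p for p in cand.parents if p.parent_species == ctx.outgroup]
                if not o_parents or not ctx.linked(gid, cid):
                    continue
                parent_cdes = max(
                    ctx.genomes[ctx.outgroup].genes[p.parent_id].longest.n_cds_exons
                    for p in o_parents
                )
                syntenic = ctx.syntenic(gid, cid)
                if ctx.cde(gid) < parent_cdes or syntenic:
                    flagged.add(gid)
                    calls.append(
                        EvolutionaryEventCall(
                            "intron_gain", ctx.lineage[sp], (gid,), ctx.group.group_id,
                            note=f"ortholog_of={cid}",
                        )
                    )
                    if not syntenic:
                        calls.append(
                            EvolutionaryEventCall(
                                "relocation", ctx.lineage[sp], (gid,), ctx.group.group_id,
                                note="intron gain accompanied by relocation",
                            )
                        )
                    break
    return calls, flagged


def infer_family_events(ctx: FamilyContext) -> list[EvolutionaryEventCall]:
    """Apply the parsimony rules to one family, most specific first."""
    gid_grp = ctx.group.group_id
    A, B = ctx.ingroups
    O = ctx.outgroup
    calls, gained = detect_intron_gain(ctx)
    by_sp = ctx.group.by_species()

    # retro-like per species: 1-CDE candidates plus intron-gained orthologs
    retro: dict[str, list[str]] = {sp: [] for sp in (A, B, O)}
    for cid, cand in ctx.candidates.items():
        retro[cand.retro_species].append(cid)
    for gid in gained:
        retro[ctx.group.members[gid]].append(gid)
    # multi-exon homologs (potential parents): >=2 CDEs, not intron-gained
    parents: dict[str, list[str]] = {sp: [] for sp in (A, B, O)}
    for gid in ctx.group.members:
        if gid in ctx.candidates or gid in gained:
            continue
        if ctx.cde(gid) >= 2:
            parents[ctx.group.members[gid]].append(gid)

    retro_a, retro_b = sorted(retro[A]), sorted(retro[B])
    ortho_pairs = [(a, b) for a in retro_a for b in retro_b if ctx.linked(a, b)]
    all_retros = tuple(retro_a + retro_b)

    def call(event, branch, genes, note=""):
        calls.append(EvolutionaryEventCall(event, branch, tuple(genes), gid_grp, note))

    if retro_a and retro_b and ortho_pairs:
        # synteny is judged over every cross-ingroup pair: in an expanded
        # family the ortholog link may connect the relocated/duplicated copy
        # while the original pair still sits in conserved context
        syntenic_pairs = [(a, b) for a in retro_a for b in retro_b if ctx.syntenic(a, b)]
        if parents[A] and parents[B] and parents[O]:
            # parent retained everywhere: retroposition predates the outgroup split
            call("retroposition", "pre_outgroup_split", all_retros)
            call("parental_retention", "pre_outgroup_split", tuple(parents[A] + parents[B] + parents[O]))
            call("retrocopy_loss", "outgroup", all_retros)
        elif parents[A] and parents[B]:
            call("retroposition", "common_ancestor", all_retros)
            call("parental_retention", "common_ancestor", tuple(parents[A] + parents[B]))
        elif parents[O] and not parents[A] and not parents[B]:
            call("retroposition", "common_ancestor", all_retros)
            call("parental_loss", "common_ancestor", tuple(parents[O]))
            if not syntenic_pairs:
                a, b = ortho_pairs[0]
                branch = _relocated_branch(ctx, a, b, parents[O])
                call("relocation", branch, (a, b), note="orthologous retrogenes not syntenic")
        else:
            call("unclassified", "ambiguous", all_retros, note="orthologous retrogenes, no parent found")
    elif retro_a or retro_b:
        for sp, retros in ((A, retro_a), (B, retro_b)):
            if not retros:
                continue
            other = B if sp == A else A
            if parents[sp]:
                call("retroposition", ctx.lineage[sp], tuple(retros))
            elif parents[other]:
                # parent lost on the retrogene's own branch: cheaper than an
                # ancestral retroposition plus a retrocopy loss in the sister
                call("retroposition", ctx.lineage[sp], tuple(retros))
                call("parental_loss", ctx.lineage[sp], tuple(parents[other]))
            elif parents[O]:
                # parent survives only in the outgroup: it cannot have been
                # present on the ingroup branch, so the retroposition must be
                # ancestral, with the retrocopy lost in the sister ingroup
                call("retroposition", "common_ancestor", tuple(retros))
                call("parental_loss", "common_ancestor", tuple(parents[O]))
                call("retrocopy_loss", ctx.lineage[other], tuple(retros))
            else:
                call("unclassified", "ambiguous", tuple(retros), note="no parent in family")
    else:
        call("unclassified", "ambiguous", tuple(ctx.group.members), note="no retrogene resolved")

    # retrogene family expansion: extra same-species 1-CDE copies.  When the
    # parent is absent from the species an independent retroposition is
    # impossible, so the copies must be DNA-based duplications no matter
    # what the (often weakly resolved) tree says; with a same-species
    # parent present, tree monophyly arbitrates between the two readings.
    for sp, retros in ((A, retro_a), (B, retro_b)):
        copies = [r for r in retros if r in ctx.candidates]
        if len(copies) < 2:
            continue
        monophyletic = True
        if ctx.tree is not None and set(copies) <= set(ctx.tree.leaves()):
            monophyletic = ctx.tree.same_species_clade(copies)
        if monophyletic or not parents[sp]:
            note = "family expansion" if monophyletic else "family expansion (parent lost; tree unresolved)"
            for extra in copies[1:]:
                call("retro_duplication", ctx.lineage[sp], (extra,), note=note)
        else:
            for extra in copies[1:]:
                call("retroposition", ctx.lineage[sp], (extra,), note="non-monophyletic copies")
    return calls


def _relocated_branch(ctx: FamilyContext, a: str, b: str, o_parents: list[str]) -> str:
    """Pick the relocated lineage via outgroup synteny; 'ambiguous' if moot."""
    syn_a = any(ctx.syntenic(a, p) for p in o_parents)
    syn_b = any(ctx.syntenic(b, p) for p in o_parents)
    if syn_a and not syn_b:
        return ctx.lineage[ctx.group.members[b]]
    if syn_b and not syn_a:
        return ctx.lineage[ctx.group.members[a]]
    return "ambiguous"


def summarize_events(calls: list[EvolutionaryEventCall]) -> pd.DataFrame:
    """Count table: one row per (event_type, branch) with n_events and the
    number of distinct genes involved."""
    rows: dict[tuple[str, str], dict] = {}
    for c in calls:
        key = (c.event_type, c.branch)
        rec = rows.setdefault(key, {"event_type": c.event_type, "branch": c.branch, "n_events": 0, "genes": set()})
        rec["n_events"] += 1
        rec["genes"].update(c.genes)
    out = []
    for key in sorted(rows):
        rec = rows[key]
        out.append(
            {
                "event_type": rec["event_type"],
                "branch": rec["branch"],
                "n_events": rec["n_events"],
                "n_genes": len(rec["genes"]),
            }
        )
    df = pd.DataFrame(out, columns=["event_type", "branch", "n_events", "n_genes"])
    return df
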