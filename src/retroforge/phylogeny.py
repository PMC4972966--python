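"""Homolog grouping and gene-tree construction.

Cross-species orthologs are called as reciprocal best hits (RBH) on bit
score; multi-species homolog groups are the connected components of the
graph whose edges are RBH pairs plus same-species hits passing the
similarity filter (single-linkage merging).  Groups with >= 4 members get a
gene tree: proteins are multiply aligned (center-star built on the local
pairwise aligner), pairwise distances are d = -ln(S) with S the fraction of
identical residues over shared non-gap columns, the topology comes from
neighbor joining, supports from a column bootstrap, and the root from
midpoint rooting.  Synteny between two loci is decided by homology between
their +-5-gene neighbor sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from .detection import HomologyService, SyntenyContext
from .homology import AlignmentHit, ProteinAligner

__all__ = [
    "HomologGroup",
    "GeneTree",
    "pairwise_orthologs",
    "merge_groups",
    "center_star_alignment",
    "distance_matrix",
    "neighbor_joining",
    "build_tree",
    "midpoint_root",
    "are_syntenic",
]


@dataclass
class HomologGroup:
    group_id: str
    members: dict[str, str]  # gene_id -> species
    contains_retrogene: bool = False

    def __len__(self) -> int:
        return len(self.members)

    def by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, sp in self.members.items():
            out.setdefault(sp, []).append(gid)
        return out


@dataclass
class GeneTree:
    """A rooted gene tree plus per-edge bootstrap supports (0-100)."""

    group_id: str
    tree: TreeNode  # midpoint-rooted; leaf names are gene ids
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    def leaves(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def are_sisters(self, a: str, b: str) -> bool:
        """True iff leaves a and b share an immediate parent."""
        ta = self.tree.find(a)
        tb = self.tree.find(b)
        return ta.parent is tb.parent

    def same_species_clade(self, gene_ids: list[str]) -> bool:
        """True iff *gene_ids* form a monophyletic group in the tree."""
        if len(gene_ids) < 2:
            return True
        lca = self.tree.lca(gene_ids)
        return sorted(t.name for t in lca.tips()) == sorted(gene_ids)

    def to_newick(self) -> str:
        return str(self.tree).strip()


def pairwise_orthologs(
    hits_ab: list[AlignmentHit], hits_ba: list[AlignmentHit]
) -> set[tuple[str, str]]:
    """Reciprocal-best-hit pairs between two species.

    ``hits_ab`` are hits with queries from species a against species b and
    vice versa.  Best is by bit score; exact ties are all kept.
    """

    def best_map(hits: list[AlignmentHit]) -> dict[str, set[str]]:
        best: dict[str, tuple[float, set[str]]] = {}
        for h in hits:
            score, ids = best.get(h.query_id, (-math.inf, set()))
            if h.bit_score > score:
                best[h.query_id] = (h.bit_score, {h.subject_id})
            elif h.bit_score == score:
                ids.add(h.subject_id)
        return {q: ids for q, (_, ids) in best.items()}

    fwd = best_map(hits_ab)
    rev = best_map(hits_ba)
    pairs = set()
    for a, bs in fwd.items():
        for b in bs:
            if a in rev.get(b, ()):  # reciprocal
                pairs.add((a, b))
    return pairs


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_groups(
    edges: set[tuple[str, str]],
    species_of: dict[str, str],
    retrogene_ids: set[str] | None = None,
) -> list[HomologGroup]:
    """Single-linkage merging: connected components over homology edges."""
    uf = _UnionFind()
    for a, b in edges:
        uf.union(a, b)
    comps: dict[str, list[str]] = {}
    for gid in {g for e in edges for g in e}:
        comps.setdefault(uf.find(gid), []).append(gid)
    retrogene_ids = retrogene_ids or set()
    groups = []
    for i, (_, members) in enumerate(sorted(comps.items()), start=1):
        members = sorted(members)
        groups.append(
            HomologGroup(
                group_id=f"HG{i:04d}",
                members={m: species_of[m] for m in members},
                contains_retrogene=bool(set(members) & retrogene_ids),
            )
        )
    return groups


def center_star_alignment(seqs: dict[str, str], aligner: ProteinAligner) -> dict[str, str]:
    """Simple multiple alignment: align everything to the center sequence.

    The center is the sequence with the highest total pairwise score; the
    others are merged into its coordinate system with the classic
    once-a-gap-always-a-gap rule.  Adequate for the small, closely related
    families handled here; an externally computed alignment can be supplied
    downstream instead.
    """
    ids = sorted(seqs)
    if len(ids) == 1:
        return dict(seqs)
    totals = {i: 0.0 for i in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = aligner.score(seqs[ids[i]], seqs[ids[j]])
            totals[ids[i]] += s
            totals[ids[j]] += s
    center = max(ids, key=lambda i: (totals[i], -len(seqs[i])))
    cseq = seqs[center]
    # per-sequence alignment to the center, as (center_res, other_res) maps
    pair_maps = {}
    for other in ids:
        if other == center:
            continue
        hit = aligner.align_pair(center, cseq, other, seqs[other], e_cutoff=math.inf)
        pair_maps[other] = dict((c - 1, o - 1) for c, o in hit.residue_map) if hit else {}
    # build columns: for every center position, plus unaligned tails treated as gaps
    rows = {i: [] for i in ids}
    for cpos in range(len(cseq)):
        rows[center].append(cseq[cpos])
        for other in ids:
            if other == center:
                continue
            opos = pair_maps[other].get(cpos)
            rows[other].append(seqs[other][opos] if opos is not None else "-")
    return {i: "".join(r) for i, r in rows.items()}


def distance_matrix(alignment: dict[str, str], min_sites: int = 1) -> DistanceMatrix:
    """d = -ln(S) distances from pairwise identity over shared columns."""
    ids = sorted(alignment)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[ids[i]], alignment[ids[j]]
            shared = ident = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    shared += 1
                    if x == y:
                        ident += 1
            if shared < min_sites:
                d = 5.0  # effectively unrelated
            else:
                s = max(ident / shared, 1e-4)
                d = -math.log(s)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Unrooted NJ topology with negative branch lengths clamped to zero."""
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) == 2:
        # the only leaf path is the single edge: split it evenly
        half = sum(t.length or 0.0 for t in tips) / 2.0
        return TreeNode(
            children=[TreeNode(name=t.name, length=half) for t in tips]
        )
    return tree.copy().root_at_midpoint()


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.add(min(side, all_tips - side, key=sorted))
    return out


def build_tree(
    group: HomologGroup,
    seqs: dict[str, str],
    aligner: ProteinAligner | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    min_members: int = 4,
) -> GeneTree | None:
    """Midpoint-rooted NJ tree with column-bootstrap supports.

    Groups smaller than *min_members* are skipped (returns None), matching
    the practice of only analyzing families with at least four sequences.
    """
    ids = sorted(set(group.members) & set(seqs))
    if len(ids) < min_members:
        return None
    aligner = aligner or ProteinAligner()
    aln = center_star_alignment({i: seqs[i] for i in ids}, aligner)
    dm = distance_matrix(aln)
    main = midpoint_root(neighbor_joining(dm))
    # column bootstrap
    rng = np.random.default_rng(seed)
    cols = np.array([[aln[i][c] for c in range(len(aln[ids[0]]))] for i in ids])
    n_cols = cols.shape[1]
    counts: dict[frozenset[str], int] = {}
    main_bips = _bipartitions(main)
    for bp in main_bips:
        counts[bp] = 0
    for _ in range(n_bootstrap):
        pick = rng.integers(0, n_cols, size=n_cols)
        boot_aln = {ids[k]: "".join(cols[k][pick]) for k in range(len(ids))}
        boot = neighbor_joining(distance_matrix(boot_aln))
        for bp in _bipartitions(boot):
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_bootstrap for bp, c in counts.items()}
    # annotate nodes for newick output
    all_tips = frozenset(t.name for t in main.tips())
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=sorted)
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return GeneTree(group_id=group.group_id, tree=main, supports=supports)


def are_syntenic(
    ctx1: SyntenyContext,
    ctx2: SyntenyContext,
    homology: HomologyService,
    min_shared: int = 1,
) -> bool:
    """True iff >= *min_shared* of ctx1's neighbors have a passing homolog
    among ctx2's neighbors."""
    shared = 0
    for n1 in ctx1.neighbors:
        if any(homology.passing(n1, n2) for n2 in ctx2.neighbors):
            shared += 1
            if shared >= min_shared:
                return True
    return False
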