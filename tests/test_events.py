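"""Parsimony event rules on hand-built three-taxon families.

Each scenario constructs a minimal world (gene order, coding-exon counts,
declared neighbor homologies) and checks the emitted calls; a brute-force
scenario enumerator verifies that the emitted presence-changing events
(retroposition / parental loss / retrocopy loss / duplication) are a
minimum-cost explanation of the observed pattern.
"""

import itertools

import pytest
from skbio.tree import TreeNode

from retroforge.detection import ParentMatch, RetrogeneCandidate
from retroforge.events import FamilyContext, infer_family_events, summarize_events
from retroforge.model import GeneModel, GenomeSet, Interval, TranscriptStructure
from retroforge.phylogeny import GeneTree, HomologGroup

SPECIES = ("A", "B", "O")


def _gene(gid, sp, chrom, start, n_cde):
    segs = [
        Interval(chrom, start + i * 200, start + i * 200 + 90, "+") for i in range(n_cde)
    ]
    t = TranscriptStructure(
        transcript_id=gid + ".t",
        exons=list(segs),
        cds_segments=segs,
        cds_nt="ATG" * 30,
        protein="M" * 30,
    )
    locus = Interval(chrom, segs[0].start, segs[-1].end, "+")
    return GeneModel(gid, sp, locus, [t])


class FakeHomology:
    """Pass/fail homology declared explicitly per unordered pair."""

    def __init__(self, pairs):
        self.pairs = {frozenset(p) for p in pairs}

    def passing(self, a, b):
        return frozenset((a, b)) in self.pairs


def make_world(layout, homolog_pairs=(), candidates=(), rbh=(), tree=None):
    """layout: {species: [(gid, n_cde), ...]} in chromosomal order."""
    genomes = {}
    for sp, genes in layout.items():
        gm = {}
        for i, (gid, n_cde) in enumerate(genes):
            g = _gene(gid, sp, "chr1", 1 + i * 5000, n_cde)
            gm[gid] = g
        genomes[sp] = GenomeSet(sp, gm, {"chr1": "A" * 1_000_000})
    cand_map = {}
    for cid, sp, parent_specs in candidates:
        parents = [
            ParentMatch(pid, psp, hit=None, junction_coverage=None,
                        structural_class="intact", missing_5prime_exons=0)
            for pid, psp in parent_specs
        ]
        cand_map[cid] = RetrogeneCandidate(
            retro_gene_id=cid, retro_species=sp, parents=parents,
            structural_class="intact", missing_5prime_exons=0,
            orphan=not any(psp == sp for _, psp in parent_specs),
        )
    group_members = {}
    for sp, genes in layout.items():
        for gid, _ in genes:
            if gid.startswith(("r", "p", "x")):  # family members by convention
                group_members[gid] = sp
    group = HomologGroup("FAM", group_members, contains_retrogene=True)
    ctx = FamilyContext(
        group, cand_map, genomes, FakeHomology(homolog_pairs), set(rbh),
        ingroups=("A", "B"), outgroup="O",
        tree=tree,
    )
    return ctx


def _counts(calls, skip=("parental_retention", "relocation", "intron_gain", "unclassified")):
    return sorted((c.event_type, c.branch) for c in calls if c.event_type not in skip)


# --- brute-force parsimony oracle ------------------------------------------

ANC = {"root": ("A", "B", "O"), "CA": ("A", "B"), "A": ("A",), "B": ("B",), "O": ("O",)}
VOCAB = (
    [("retro", b) for b in ANC]
    + [("ploss", b) for b in ANC]
    + [("dup", t) for t in SPECIES]
    + [("rloss", t) for t in SPECIES]
)


def min_parsimony_cost(retro_counts, parent_present):
    """Minimum number of events explaining the tip pattern on ((A,B),O)."""
    def path(branch):
        return {"root": ["root"], "CA": ["root", "CA"], "A": ["root", "CA", "A"],
                "B": ["root", "CA", "B"], "O": ["root", "O"]}[branch]

    best = None
    for k in range(0, 5):
        if best is not None:
            break
        for combo in itertools.combinations_with_replacement(VOCAB, k):
            plosses = [b for t, b in combo if t == "ploss"]
            valid = True
            for t, b in combo:
                if t == "retro":
                    # parent must still exist when the retroposition happens
                    if any(pb in path(b)[:-1] for pb in plosses):
                        valid = False
                        break
            if not valid:
                continue
            copies = {sp: 0 for sp in SPECIES}
            for t, b in combo:
                if t == "retro":
                    for sp in ANC[b]:
                        copies[sp] += 1
            for t, b in combo:
                if t == "dup":
                    if copies[b] < 1:
                        valid = False
                        break
                    copies[b] += 1
            if not valid:
                continue
            for t, b in combo:
                if t == "rloss":
                    if copies[b] < 1:
                        valid = False
                        break
                    copies[b] -= 1
            if not valid:
                continue
            parent_ok = all(
                parent_present[sp] == (not any(pb in path(sp) for pb in plosses))
                for sp in SPECIES
            )
            if parent_ok and copies == retro_counts:
                best = k
                break
    return best


def _audit(ctx, calls):
    """Emitted presence-events must be a minimum-cost explanation."""
    retro_counts = {sp: 0 for sp in SPECIES}
    for cid, cand in ctx.candidates.items():
        retro_counts[cand.retro_species] += 1
    parent_present = {sp: False for sp in SPECIES}
    for gid, sp in ctx.group.members.items():
        if gid not in ctx.candidates and ctx.cde(gid) >= 2:
            parent_present[sp] = True
    emitted = len(_counts(calls))
    assert emitted == min_parsimony_cost(retro_counts, parent_present)


def test_rule_shared_ancestral_retro_with_outgroup_parent():
    """Syntenic orthologous retrogenes + outgroup parent: one retroposition
    and one parental loss in the common ancestor."""
    neighbors_a = [(f"nA{i}", 4) for i in range(3)]
    neighbors_b = [(f"nB{i}", 4) for i in range(3)]
    ctx = make_world(
        layout={
            "A": neighbors_a[:1] + [("rA", 1)] + neighbors_a[1:],
            "B": neighbors_b[:1] + [("rB", 1)] + neighbors_b[1:],
            "O": [("pO", 8)],
        },
        homolog_pairs=[("nA0", "nB0")],
        candidates=[("rA", "A", [("pO", "O")]), ("rB", "B", [("pO", "O")])],
        rbh=[("rA", "rB")],
    )
    calls = infer_family_events(ctx)
    assert _counts(calls) == [("parental_loss", "common_ancestor"), ("retroposition", "common_ancestor")]
    assert not any(c.event_type == "relocation" for c in calls)
    _audit(ctx, calls)


def test_rule_relocation_when_not_syntenic():
    ctx = make_world(
        layout={
            "A": [("nA0", 4), ("rA", 1), ("nA1", 4)],
            "B": [("nB0", 4), ("rB", 1), ("nB1", 4)],
            "O": [("pO", 8)],
        },
        homolog_pairs=[],  # disjoint neighborhoods
        candidates=[("rA", "A", [("pO", "O")]), ("rB", "B", [("pO", "O")])],
        rbh=[("rA", "rB")],
    )
    calls = infer_family_events(ctx)
    reloc = [c for c in calls if c.event_type == "relocation"]
    assert len(reloc) == 1 and reloc[0].branch == "ambiguous"
    _audit(ctx, calls)


def test_rule_lineage_specific_with_parent_retained():
    ctx = make_world(
        layout={"A": [("rA", 1), ("pA", 5)], "B": [("pB", 5)], "O": [("pO", 5)]},
        candidates=[("rA", "A", [("pA", "A"), ("pB", "B"), ("pO", "O")])],
    )
    calls = infer_family_events(ctx)
    assert _counts(calls) == [("retroposition", "ingroupA")]
    _audit(ctx, calls)


def test_rule_parent_lost_in_retro_lineage():
    """Retro in A, parent only in the sister ingroup (and outgroup):
    lineage retroposition plus parental loss on the same branch."""
    ctx = make_world(
        layout={"A": [("rA", 1)], "B": [("pB", 5)], "O": [("pO", 5)]},
        candidates=[("rA", "A", [("pB", "B"), ("pO", "O")])],
    )
    calls = infer_family_events(ctx)
    assert _counts(calls) == [("parental_loss", "ingroupA"), ("retroposition", "ingroupA")]
    _audit(ctx, calls)


def test_rule_single_retro_outgroup_parent_only():
    """Retro in one ingroup, parent only in the outgroup: the parent cannot
    have survived onto the ingroup branch, so the retroposition is ancestral
    and the sister ingroup lost the retrocopy."""
    ctx = make_world(
        layout={"A": [("rA", 1)], "B": [], "O": [("pO", 5)]},
        candidates=[("rA", "A", [("pO", "O")])],
    )
    calls = infer_family_events(ctx)
    assert _counts(calls) == [
        ("parental_loss", "common_ancestor"),
        ("retrocopy_loss", "ingroupB"),
        ("retroposition", "common_ancestor"),
    ]
    _audit(ctx, calls)


def test_rule_parent_retained_in_all_three():
    """Parent in A, B and O with orthologous ingroup retrogenes: the
    retroposition predates the outgroup split and the outgroup lost the
    retrocopy while every lineage kept the parent."""
    ctx = make_world(
        layout={
            "A": [("rA", 1), ("pA", 6)],
            "B": [("rB", 1), ("pB", 6)],
            "O": [("pO", 6)],
        },
        homolog_pairs=[],
        candidates=[("rA", "A", [("pA", "A")]), ("rB", "B", [("pB", "B")])],
        rbh=[("rA", "rB")],
    )
    calls = infer_family_events(ctx)
    types = {c.event_type: c.branch for c in calls}
    assert types["retroposition"] == "pre_outgroup_split"
    assert types["retrocopy_loss"] == "outgroup"
    assert "parental_retention" in types


def test_rule_duplication_extra_copy():
    newick = "((rA1:0.01,rA2:0.01):0.02,(rB:0.03,pO:0.05):0.01);"
    tree = GeneTree("FAM", TreeNode.read([newick]))
    neighbors = [("nA0", 4), ("nB0", 4)]
    ctx = make_world(
        layout={
            "A": [("nA0", 4), ("rA1", 1), ("rA2", 1)],
            "B": [("nB0", 4), ("rB", 1)],
            "O": [("pO", 6)],
        },
        homolog_pairs=[("nA0", "nB0")],
        candidates=[
            ("rA1", "A", [("pO", "O")]),
            ("rA2", "A", [("pO", "O")]),
            ("rB", "B", [("pO", "O")]),
        ],
        rbh=[("rA1", "rB")],
        tree=tree,
    )
    calls = infer_family_events(ctx)
    dups = [c for c in calls if c.event_type == "retro_duplication"]
    assert len(dups) == 1 and dups[0].branch == "ingroupA"
    _audit(ctx, calls)


def test_intron_gain_detection_and_family_call():
    """A 2-CDE ingroup gene orthologous to a 1-CDE retrogene with an
    outgroup parent is an intron-gained retrogene; the family still counts
    as one ancestral retroposition."""
    ctx = make_world(
        layout={
            "A": [("nA0", 4), ("rA", 1)],
            "B": [("nB0", 4), ("xB", 2)],
            "O": [("pO", 6)],
        },
        homolog_pairs=[("nA0", "nB0")],
        candidates=[("rA", "A", [("pO", "O")])],
        rbh=[("rA", "xB"), ("xB", "rA")],
    )
    calls = infer_family_events(ctx)
    gains = [c for c in calls if c.event_type == "intron_gain"]
    assert len(gains) == 1
    assert gains[0].branch == "ingroupB" and gains[0].genes == ("xB",)
    assert ("retroposition", "common_ancestor") in _counts(calls)
    assert ("parental_loss", "common_ancestor") in _counts(calls)


def test_unclassified_never_dropped():
    ctx = make_world(
        layout={"A": [("rA", 1)], "B": [], "O": []},
        candidates=[("rA", "A", [("pX", "B")])],  # parent not in the group
    )
    calls = infer_family_events(ctx)
    assert any(c.event_type == "unclassified" for c in calls)


def test_summarize_events_counts():
    ctx = make_world(
        layout={"A": [("rA", 1)], "B": [("pB", 5)], "O": [("pO", 5)]},
        candidates=[("rA", "A", [("pB", "B"), ("pO", "O")])],
    )
    calls = infer_family_events(ctx)
    df = summarize_events(calls)
    assert set(df.columns) == {"event_type", "branch", "n_events", "n_genes"}
    row = df[(df.event_type == "retroposition") & (df.branch == "ingroupA")]
    assert row.n_events.iloc[0] == 1
    assert summarize_events([]).empty
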