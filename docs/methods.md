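# Methods

This note documents the models, defaults and numerical choices behind
`retroforge`, and what the synthetic-data tests do and do not establish.

## Detection cascade

### Alignment and statistics

BLASTP-style search is replaced by exact Smith–Waterman local alignment
(Biopython's `PairwiseAligner`): BLOSUM62, affine gaps with a length-L gap
costing 11 + L. E-values use the Karlin–Altschul formula
`E = K·m·n·exp(−λS)` with the gapped constants K = 0.041, λ = 0.267 and the
total number of subject residues as database size, preserving the E ≤ 0.001
contract without an external binary. No heuristic seeding is used for the
reported alignments; an optional shared-k-mer prefilter (default: ≥ 1
common 5-mer) skips scoring of clearly unrelated pairs in all-vs-all
searches. At the divergences handled here a true homolog pair virtually
always shares a conserved 5-mer window, while an unrelated pair passes
about 1 % of the time, so the prefilter changes runtime, not results; it
can be disabled (`prefilter_k=None`) for an exhaustive search.

### Filter thresholds

All from the underlying screening design: E ≤ 0.001; identity ≥ 50 %;
aligned region ≥ 50 % of length and ≥ 35 aa; TE overlap < 50 % of the gene
span; zero homologous neighbors allowed between candidate and parent
±5-gene contexts. Two deliberate readings of ambiguous wording:

* the 50 % aligned-region coverage applies to **both** query and subject
  (stricter); `coverage_mode="either"` relaxes it;
* TE overlap is measured over the genomic span of the gene, not its
  spliced length (configurable in principle via the TE intervals supplied).

### Junction coverage

Subject residue *i* maps to spliced-CDS nucleotides 3i−2..3i. Junction *j*
is covered iff both the last residue of coding exon *j* and the first
residue of exon *j+1* are aligned; a codon-split junction lives in a single
residue which counts for both sides. `covers_two_3prime_terminal` demands
junctions {n−1, n}. A corollary: parents with 2 coding exons (one
junction) can never qualify, so the parent floor is 3 CDEs; and a
5′-truncated copy is only detectable from a ≥ 4-CDE parent. The simulator
therefore draws truncated-retro sources from ≥ 4-CDE genes — consistent
with observed incomplete retrogenes, whose parents have 5+ exons.

### Hallmarks

Poly-A: longest run of ≥ 8 sense-strand A in the annotated 3′UTR plus
500 bp downstream; without a UTR annotation, a window of the genome-average
3′UTR length + 500 bp after the stop codon. TSD: longest exact repeat of
length 4–6 shared by the 20 bp flanks immediately outside the gene span,
on the plus strand (direct repeats). Note that exact 4-mers recur in
random 20 bp windows with probability ≈ 0.7, so a 4 bp "TSD" alone carries
little evidence; the scan reports the longest match and its sequence so
downstream interpretation can weigh length. No erosion-aware matching is
attempted: in the real data hallmarks survive only in recent insertions.

## Homolog groups, trees, synteny

Cross-species orthologs are reciprocal best hits by bit score (ties keep
all pairs); groups are connected components over RBH edges plus
same-species hits that pass the similarity filter (single linkage). The
in-paralog expansion of full ortholog-clustering tools is intentionally
dropped — single-linkage merging dominates group composition.

Gene trees (groups ≥ 4): proteins are multiply aligned by center-star
(align everything to the sequence with the highest total pairwise score;
once-a-gap-always-a-gap). For the small, closely related families handled
here this is adequate, and the alignment stage is behind a function
boundary so an external MSA or ML tree can be substituted. Distances are
d = −ln(S), S = fraction of identical residues over shared non-gap columns
(floored at 1e−4); topology by neighbor joining (scikit-bio; negative NJ
branch lengths clamped to 0); supports from a 100-replicate column
bootstrap; root by midpoint (two-leaf trees handled explicitly — the
midpoint is the middle of the single edge).

Synteny between two loci: true iff ≥ `min_shared` (default 1) of one
locus's ±5 neighbors has a passing homolog among the other's ±5 neighbors.
The threshold mirrors the segmental-duplication filter's "minimum one".

## Event inference

Rules are applied per retrogene family, most specific first, on
`((ingroupA, ingroupB), outgroup)`:

1. parent in all three species + orthologous ingroup retrogenes →
   retroposition before the outgroup split, parent retained, retrocopy
   lost in the outgroup (this dating uses the tree/composition, not bare
   presence parsimony);
2. orthologous ingroup retrogenes, parent only in the outgroup, syntenic →
   one retroposition + one parental loss in the ingroup ancestor;
3. as (2) but non-syntenic → additionally one relocation; the relocated
   lineage is resolved by outgroup synteny when informative, otherwise the
   call carries branch `ambiguous` rather than a guess;
4. retrogene and parent in the same species → lineage-specific
   retroposition;
5. retrogene in one ingroup, parent surviving only in the sister ingroup
   (± outgroup) → lineage retroposition + parental loss on the same branch
   (cost 2, vs 3 for an ancestral event with two losses);
6. retrogene in one ingroup with the parent surviving **only** in the
   outgroup → the parent cannot have been present on the ingroup branch,
   so the retroposition is ancestral, with parental loss in the ingroup
   ancestor and retrocopy loss in the sister ingroup (cost 3; a unit test
   verifies this against a brute-force scenario enumerator);
7. extra same-species copies → one DNA-based duplication per extra copy.
   When the parent is absent from that species an independent
   retroposition is impossible and the duplication call stands regardless
   of the tree; with a same-species parent present, tree monophyly of the
   copies arbitrates.

"Orthologous retrogenes" is operationalized as cross-ingroup RBH **or**
sister leaves in the midpoint-rooted tree. Intron-gained ex-retrogenes:
2–3-CDE ingroup genes that are the cross-ingroup ortholog of a 1-CDE
candidate with an outgroup parent, and either have fewer CDEs than that
parent or lie syntenic to the retrogene; a non-syntenic gain is paired with
a relocation call. Unmatched families are emitted `unclassified`.

## dN/dS and the likelihood-ratio test

The aligned region of the candidate/parent protein alignment (not the full
CDS) is back-translated; residue gaps become codon gaps, and any
codon/residue disagreement is an error naming the column. The ML model is
a single-ω codon substitution model with equal frequencies over the 61
sense codons, transition/transversion ratio κ, and rate matrix normalized
to one expected substitution per codon per unit branch length; with
uniform frequencies the matrix is symmetric, so likelihood evaluation uses
one spectral decomposition per (κ, ω). Both fits (ω free; ω fixed at 0.5)
optimize by Nelder–Mead in log-parameter space; the free fit starts from
the fixed optimum so the LRT statistic 2(lnL_free − lnL_fixed) is
non-negative by construction. p-values come from χ²₁. dN and dS derive
from the fitted branch length split into synonymous/nonsynonymous flux,
with per-site denominators evaluated at ω = 1.

Defaults: α = 0.05, no multiple-testing correction (Benjamini–Hochberg can
be applied to the reported p-value column by the caller); saturation flag
at dS > 3 — saturated pairs are reported, never silently excluded, and not
called functional unless the override is set. With several candidate
parents the representative is the minimum-dS parent; the ranking uses the
closed-form NG86 dS (ties break to the smaller gene id) and the ML fit is
then run on the representative pair — a unit test checks NG86 and ML agree
in ordering.

NG86 counting follows the standard conventions: per-codon site fractions
exclude mutations to stops; multi-difference codons average syn/nonsyn
counts over all minimal pathways, discarding pathways through stops
(falling back to all pathways if none survive); Jukes–Cantor correction on
pN and pS.

Calibration (acceptance suite): under the null ω = 0.5 at 300 codons the
LRT rejects at a rate whose 95 % Wilson interval covers 0.05 (500
replicates); under ω = 0.1 power exceeds 0.8.

## The simulated world

Defaults describe a small cohort that exercises every phenomenon:
200 ancestral genes on 2 chromosomes; coding-exon counts from a
distribution matching a multicellular-alga-like genome (16 % single-CDE,
~60 % with ≥ 5); exon/intron/UTR/intergenic means 150/120/90/300 bp.
Branch substitution rates (root→ingroup-ancestor, ancestor→A, ancestor→B,
root→outgroup) default to 0.03/0.03/0.03/0.06 substitutions per site —
chosen so homology detection is reliable (protein identity ≈ 80–90 %
between ingroup and outgroup) while divergence-based inference still has
signal. This is deliberately *younger* than the real ~220-My-diverged
systems, where dS is saturated; consequently the simulated dS values
(~0.1–0.3) are informative rather than saturated, and the LRT's power at
these short alignments is moderate (roughly half to two-thirds of
candidates at true ω = 0.2 are called at α = 0.05).

Coding sequence evolves by Jukes–Cantor substitution with two codon-aware
rules: substitutions creating a premature stop are rejected, and
nonsynonymous substitutions are accepted with probability `cds_omega`
(default 0.2) — a rejection model of purifying selection whose expected
dN/dS equals `cds_omega`. There are no indels. The terminal stop codon is
pinned so translations stay comparable. Hallmark decay is modeled by
survival probabilities, not sequence erosion: poly-A tails survive with
probability 0.16 (matching the observed ~16 % of candidates with residual
tails) and TSDs with probability 0 by default (none were observed in the
motivating data; tests that exercise TSD detection set the probability
to 1).

Event counts default to a scaled-down history: 8 plain ancestral
retropositions, 2 relocations, 2 intron gains, 2 truncated copies (all
ancestral, each with parental loss in the ingroup ancestor), 5 + 3
lineage-specific retropositions in A/B, 3 A-specific events with parental
loss, 2 retrogene duplications in A, and 2 + 2 segmental-duplication/TE
confounders.

**Placement rules.** In a 200-gene genome, random insertion would
occasionally drop a retrocopy inside a synteny window that the filters
inspect, creating label noise that is an artifact of the scaled-down world
rather than of the biology. Insertions therefore avoid: (i) the ±5-gene
ancestral context of their own source; (ii) planted copies whose source or
insertion anchor is ancestrally close (≤ 10 genes) to the new copy's
source; (iii) for any relocated retrogene, slots that would make its two
lineage contexts share a gene family. Relocations are applied before all
other lineage events so these constraints see final loci. Within those
constraints placement is uniform.

**What a green synthetic test establishes.** That the cascade's logic and
thresholds, the event rules and the estimators are implemented correctly
and are mutually consistent at moderate divergence with clean annotations.
It does **not** establish performance on real annotations with fragmented
gene models, alternative transcripts, assembly gaps, saturated dS, TE-rich
intergenic sequence, or annotation errors — none of which the generator
emulates.

## Numerical details and edge cases

* CDS not a multiple of 3 → transcript excluded with a logged warning;
  missing chromosome → hard error naming the sequence.
* "Longest transcript" = longest CDS (the pipeline operates on proteins),
  ties to the lexicographically smaller transcript id; `by="mrna"`
  selects by spliced length instead.
* Distance floor S ≥ 1e−4 before −ln; pairs with no shared columns get
  d = 5.
* NJ can return tiny negative branch lengths; they are clamped to 0.
* The Yates-corrected χ² approximates the conditional exact test; the
  permutation-agreement test uses balanced-margin tables where that
  approximation is accurate to < 0.005. On strongly unbalanced margins
  Yates and the exact test can differ by several percent — as for any
  continuity-corrected χ².
* The 2×2 χ² requires all margins positive; zero margins raise.

## Known limitations

* Chimeric retrogenes fused with protein-coding parts of other genes are
  out of scope by design (the 1-CDE query definition cannot see them).
* The relocated lineage of rule (3) is usually unidentifiable from a
  3-taxon presence pattern; counts are reported under branch `ambiguous`.
* Center-star MSA and identity distances are crude for deep divergences;
  both sit behind interfaces where external tools can be substituted.
* The codon model has no codon-frequency estimation beyond the uniform
  default (an F1x4-style extension would reuse the same machinery via a
  similarity transform), no among-site rate variation, and no branch or
  site models.
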