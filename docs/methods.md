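# Methods

This note documents the models and procedures `firetrace` implements, the
parameters that matter, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Sequence model and coordinates

Sequences are strings over the IUPAC nucleotide alphabet, uppercased on
input (soft-masking is ignored). `N` is legal and propagated — real draft
genome elements arrive interrupted by Ns — never silently stripped.
Internal coordinates are 0-based half-open; user-facing reports are
1-based inclusive. Reverse complementation complements ambiguity codes as
base sets (Y↔R, K↔M; W, S, N are self-complementary) and is an involution
on the full alphabet.

## Element extraction

`locate_element` runs exact Smith–Waterman with affine gaps (a gap of
length L costs `gap_open + (L−1)·gap_extend`) on both strands; the DP is
Biopython's `PairwiseAligner`, with strand bookkeeping, identity
computation and the acceptance rule implemented here. Defaults are
BLASTN-like: match +2, mismatch −3, gap open −5, extend −2. A best hit
with aligned identity < 0.55, or covering fewer than 100 alignment
columns, is reported as *not found* (a distinct non-error outcome): a
genuine hit of a ~300 bp element covers most of the query, whereas the
best local alignment between unrelated sequences is short. Ties between
equal-scoring hits resolve to the smallest target start, then the +
strand. `trim_to_query` returns the target subsequence under the hit,
reverse-complemented for − strand hits, so every extracted element is in
query orientation.

In-silico PCR requires the forward primer on the + strand and the
reverse-complemented reverse primer downstream on the + strand within
`max_product`, each with at most `max_mismatches` mismatches and the
3′-terminal 3 bases exact (polymerase extension is 3′-anchored; no
published mismatch tolerance exists for the original primers, so the
anchor rule is declared here). Products include both primer sites and are
reported 5′→3′.

## Progressive multiple alignment

The MSA stage follows the classic progressive recipe: pairwise global
alignments give p-distance guide distances; a neighbor-joining guide tree
is midpoint-rooted; profiles are merged post-order, ties in merge order
broken by the smallest input leaf index. Profile columns are 4-vectors of
base frequencies (ambiguity codes contribute the mean over their sets;
gaps a zero vector) and column pairs score by the frequency-weighted
expected pair score. Gap penalties are affine and flat — no
position-specific modifiers and no sequence weighting, so byte-identical
output of any particular aligner is not promised. Traceback is
deterministic (diagonal > up > left).

Alignment scoring uses its own default, `MSA_SCORING` (match +2, mismatch
−3, gap open −10, extend −2), stiffer in gap opening than the local-search
scheme. The reason is structural: in global alignment of ~300 bp elements
that diverge mostly by substitution, a cheap gap opening lets the aligner
replace two mismatches with a compensating insertion/deletion pair, which
corrupts downstream p-distances; planted-truth benchmarks show topology
recovery is depressed by several points under the local-search scheme and
is flat across gap-open values from −8 to −16, so −10 is not a knife-edge
choice. This mirrors standard DNA aligner practice, where gap opening
outweighs a mismatch several-fold.

`trim_common` removes leading and trailing columns that contain any gap
(and all-gap columns anywhere), producing the common-length core on which
distances are computed. The pipeline order is align → trim; trimming first
would require coordinates that only the alignment provides.

## Consensus calling

Per column, among non-gap rows: the modal base is called if its frequency
reaches `plurality` (default 0.5); otherwise the minimal IUPAC code
covering all bases at frequency ≥ `ambiguity_floor` (default 0.25).
Columns with > 50% gaps are dropped. Each call records support, the
fraction of non-gap rows compatible with it. Rows that are more than 20%
N are excluded from consensus building (an N-riddled draft sequence only
dilutes calls); this cutoff is this package's policy for heavily
interrupted records. The consensus rule of the original commercial
software is unpublished; the rule above is declared and fixed.

## Distances and trees

The p-distance is the uncorrected proportion of differing sites under
**pairwise deletion**: a column is excluded for a pair when either row
carries a gap or any non-ACGT character (all ambiguity codes, not only N,
are treated as missing — a strict superset of the obvious rule, chosen
because a consensus ambiguity code does not witness a concrete base).
No multiple-hit, rate-bias or among-site-rate correction is applied.
A pair with zero comparable sites is an error naming the pair.

Neighbor joining is the Saitou–Nei algorithm. Ties in the Q-criterion
break to the lexicographically smallest index pair, for cross-platform
determinism. Negative two-point branch lengths are clamped to zero with
the deficit moved to the sister branch, preserving the pair's total; the
distances from a new internal node are floored at zero. Trees are
unrooted (trifurcating root) — figure-style rooting is presentation, left
to the user. Newick output prints branch lengths at 6 significant digits
and quotes labels containing spaces or metacharacters; parsing is
delegated to scikit-bio.

On exactly tree-additive inputs the implementation recovers the
generating topology with path lengths equal to the inputs to 1e-9, and it
matches the exhaustive least-squares-best topology over all 15 unrooted
5-taxon trees; both properties are enforced by tests.

## Dot matrix

A window of odd length `w` (default 15) on a diagonal is *on* when its
match count reaches `ceil(min_identity × w)` — 11 of 15 at the default
70%, the ceiling being this package's reading of an undocumented rounding
rule. Ambiguity codes match when base sets intersect, so clade consensi
compare sensibly. Adjacent on-windows merge into maximal segments (the
plotted diagonals); windows are indexed by start position, which differs
from a centered view only by a constant (w−1)/2 offset. Reverse-strand
windows compare against the reverse complement with coordinates mapped
back to the forward strand. Both strands are scanned by default, with a
flag to disable.

For unrelated sequences of uniform composition the on-window count
follows the Bin(15, 1/4) tail, P(X ≥ 11) ≈ 1.1e-4 — so a long comparison
*always* contains a few chance windows. `locate_by_dotplot` therefore
scores each query-length placement by identity-weighted segment coverage
and returns a candidate only when the best placement accumulates at least
3 windows' worth of coverage; below that floor the search reports
nothing rather than a chance window.

## Motif annotation

JASPAR-format PFMs (parsed with Biopython) become log-odds PWMs by

    w(b, i) = log2( (n(b,i) + pc·bg(b)) / (N(i) + pc) / bg(b) )

with pseudocount `pc = 0.8` split by background (the JASPAR/MOODS
convention) and uniform background by default. Scanning reports windows
whose **relative score** `(S − Smin)/(Smax − Smin)` reaches the threshold
(default 0.85), the standard "% match to the matrix" scale; Smax/Smin are
the best and worst achievable sums, and a PWM with Smax = Smin is
rejected by name. N contributes zero (background-like); other ambiguity
codes contribute the mean weight over their base set. Hits sort by
forward-strand position, '+' before '−'.

Overlapping hits of one transcription-factor family merge into annotation
blocks; families never merge with each other. The family table is
configuration (a TSV seeded with AP1, ETS, CEBP, RUNX, KLF families and a
macrophage-expressed flag), not hard-coded biology; the bundled PFMs are
synthetic consensus-shaped matrices, labelled as such, standing in for
database matrices the user should supply for real annotation work.

Core detection searches each clade consensus for an AP1 site and the
PU.1 site `CACTTCCYY` within `max_spacer` (default 20 bp — the conserved
arrangement is apposed, and the known displaced variant sits 6–7 bp away,
so 20 bp is a safe envelope). AP1 patterns are tried in order `TGAWTCA`
(the variant with central A/T conserved across land vertebrates) then
`TGASTCA` (the classical consensus, the snake form), so the variant is
preferred when both match. The spacer is measured from the end of the
upstream motif to the start of the downstream one, floored at zero for
overlapping pairs. The cross-clade verdict is *present* only when every
clade has a pair.

## Synthetic data generator

The generator is the study's null and positive control in one. An
`ElementArchitecture` fixes element length (default 300 bp), background
GC (default 0.5), and non-overlapping motif blocks, each with a
substitution-rate multiplier in [0, 1] (0 = frozen). The root is drawn
i.i.d. at the given GC with blocks instantiated base-by-base from their
IUPAC codes. Evolution along a tree applies Jukes–Cantor substitutions —
per site, with the branch length multiplied by the block's constraint —
and indels: event count Poisson with mean `indel_rate × L × t` (the rate
is per site per unit branch length, co-scaled with substitutions),
lengths geometric(1/2), insertion or deletion with equal probability,
confined to unconstrained spacer; deletions truncate at block
boundaries and motif coordinates are remapped through every event.
Branch lengths are expected substitutions/site at unconstrained sites.
One global seed fans out to per-branch RNG streams keyed by a
deterministic preorder branch index, so any subtree reproduces on its
own.

The default three-clade study (`default_study_specs`) plants the shared
frozen AP1+PU.1 core in every clade (snake clade: classical AP1 displaced
6 bp), plus clade-private blocks at constraint 0.2 shaped like CEBP,
RUNX, KLF and IRF consensus sites, on trees of 6 leaves with branch
lengths ~0.08.

What the generator does **not** emulate: substitution-rate heterogeneity
beyond per-block multipliers, transition/transversion bias, context
effects (CpG), large rearrangements, duplications, or alignment-breaking
repeat content. Tests passing on this generator therefore demonstrate
correctness of the pipeline's bookkeeping and statistics under its
stated model — not that real clade alignments are free of alignment
error, which for deep divergences (the reptile clades) is known to be
material.

## Problem sizes and runtime envelope

The tests and the acceptance script run the study at desk scale, chosen
so the full suite completes in a couple of minutes on one core: topology
recovery uses 100 replicates of 10-leaf, 300 bp clades (per-branch length
0.05–0.15, indel rate 0.005); Jukes–Cantor consistency uses 200
replicates × 300 sites at t ∈ {0.01, 0.05, 0.2} with a 3-standard-error
band; the dot-matrix null uses 30 random 300-mer pairs (~2.5M windows);
PWM oracle equivalence uses 50 random matrix/sequence pairs; the
core-element study uses 3 clades × 5 leaves. Exact-oracle tests (brute
force Smith–Waterman, exhaustive alignment enumeration, all 15 five-taxon
topologies, all-windows dot-matrix) run on instances small enough to
enumerate.

## Known limitations

- The progressive aligner has no iterative refinement; badly misaligned
  deep-divergence clades will propagate guide-tree errors.
- No bootstrap or other support values on trees (the method reports
  uncorrected-p branch lengths only, by design).
- PWM scores carry no p-value calibration; the relative-score threshold
  is a screening heuristic.
- In-silico PCR has no primer thermodynamics; it is a string-matching
  analogue of amplification.
- The one printed comparison this package cannot re-derive at desk scale
  is the primate identity check (human/bonobo/chimpanzee), which needs
  the published element sequences as input; the test encoding it fails
  with an explanatory message until `data/primate_fire.fa` is provided.
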