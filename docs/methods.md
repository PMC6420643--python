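# Methods

This note documents the models, parameter choices and numerical conventions
behind `deamtrace`, and what the synthetic-data tests do and do not show
about real data.

## Target screening

A protospacer hit is a 20-nt window followed by an NGG PAM that carries at
least one C at positions 4–8, counting position 1 at the PAM-distal end
(the standard convention for BE3-class editing windows). Coordinates are
0-based half-open in memory and 1-based in files; reverse-strand hits are
reported in forward-strand coordinates with strand `-`. Any N inside the
window or PAM disqualifies a hit. Spacer ranking counts perfect string
matches only (no mismatch tolerance), keeps spacers with at least
`min_matches = 2` hits, and breaks count ties lexicographically.
`pairwise_similarity` compares equal-length strings position-wise without
alignment; this is a deliberate, documented convention — alignment-based
similarity would require choices (scoring, gaps) the screening task does
not need.

## UMI molecule counting

Reads sharing a UMI form a family; the family's consensus is its modal
sequence when that mode reaches ≥ 70% of the reads, otherwise the family is
dropped from molecule counting. Families whose UMIs lie within Hamming
distance ≤ 2 are merged through the connected components of the plain
(undirected) Hamming-distance graph — not the count-directional variant
some deduplicators use — and each cluster retains the highest-count UMI
(ties: lexicographic). The uniformity statistic is the population
(ddof = 0) coefficient of variation of per-position molecule counts; the
population convention is a documented constant choice. An optional primer
prefilter keeps reads whose prefix matches the amplification primer at a
configurable identity (default 0.5).

## Binomial-mixture edit calling

Counts k of n at a site follow
`π·Binom(k; n, θ) + (1−π)·Binom(k; n, ε)`. EM runs from a fixed
initialisation (ε₀ = 0.005, θ₀ = 0.5, π₀ = 0.1) plus two seeded jittered
restarts, keeping the best log-likelihood; convergence is Δloglik < 1e−8 or
500 iterations. If the fit lands with θ < ε the components are swapped
(π ↦ 1−π) so the edited component always has the larger allele fraction.
An all-zero alt profile returns a degenerate fit with π ≈ 0 flagged rather
than raising. Under ploidy mode the edited component is an equal-weight
mixture over supplied allele-fraction levels (e.g. {1/3, 2/3, 1} for a
triploid-like genome) and only π and ε are re-estimated.

Hard thresholds for a call — depth strictly greater than 10, variant allele
count strictly greater than 2, posterior ≥ 0.95, VAF strictly above the
per-site background control (missing control = 0) — follow the confident-
marker definition; they are strict inequalities where stated as such.

Because deaminase editing is processive across the window, the two window
Cs of one spacer are merged into a single site: merged VAF is the mean of
the two VAFs, merged depth the minimum of the two (conservative), and a
zero-depth member falls back to the covered member's VAF.

Site selection removes, in order: blacklisted sites; near-saturated sites
(mean efficiency > 0.8 **or** normalised site probability > 0.004 — the two
descriptions are applied as an OR, the conservative reading); and the later
member of any pair with squared Pearson correlation > 0.8 across samples
(greedy, keeping earlier sites). Constant-column pairs count as redundant
only when identical. The filter is idempotent by construction.

## Bulk tree reconstruction

Vertices of the substitution graph can be read as either the edits or the
nodes (samples); this package peels **nodes** and uses the edit-level
Poisson-binomial computation to identify each component's ancestral node,
for two reasons: the iterative procedure removes nodes by definition (the
first ancestor node is a sample), and an edits-as-vertices recursion is not
robust to homoplasy — at simulation scale the same site converts
independently in many branches, and such sites bridge otherwise disjoint
clades.

The recursion:

1. **First ancestor.** The sample with the most connections, where two
   samples connect when their barcodes intersect or one contains the other
   (an unedited founder is everyone's ancestor). Ties prefer the smaller
   barcode, then the lexicographically smaller id.
2. **Clades by conditional overlap.** After removing a node, the remaining
   nodes' *conditional* barcodes (edits minus the removed ancestor chain's
   edits) are compared; an edge requires a non-empty intersection and
   Jaccard ≥ `min_overlap`. Default `min_overlap = 0.4`: under a
   per-division editing rate F, two sister nodes' novel barcodes overlap by
   chance at F/(2−F) ≤ 1/3 (for F ≤ 0.5) while a true mother–child pair
   overlaps at 1/(2−F) ≥ 0.51, so 0.4 separates the regimes across the
   whole plausible rate range. The threshold is exposed for data that
   violate these assumptions.
3. **Top node.** For each candidate edit x of a component, the detection
   rate p(x) is the fraction of nodes expressing edits co-occurring with x
   that also express x; the chance of seeing x together with partner y in
   at least one node is p(x−y) = 1 − (1 − p(x))^{N_y}. The number of
   realised connections of x is Poisson-binomial; the candidate with the
   largest P(X ≤ observed degree) wins (ties: larger expressing set, then
   lexicographic). Two exact shortcuts keep this fast: a candidate
   connected to every other member scores exactly 1 while any non-full
   candidate scores strictly less, and the score is monotone in
   (degree ↑, p ↓), so the exact DP only needs the Pareto frontier. The
   node expressing the top edit with the smallest conditional barcode is
   the component's ancestor, is attached under the previously removed node,
   and is peeled in turn.

The edit-level tree is assembled alongside: each peeled node contributes
its novel edits as a lexicographic chain under its parent's anchor edit; a
site already introduced elsewhere (homoplasy) keeps its first introduction.
Placement accuracy counts a node correct only when both its parent and its
depth match the truth.

The depth-weight-maximising traversal that preceded the overlap criterion
is retained behind `legacy_depth_weight=True` (components of the
unthresholded co-occurrence graph).

## Single-cell trees

Cell-to-cell distance is 1 − Jaccard over the selected binary sites, with
the both-empty pair defined as distance 0 (a documented convention).
Average linkage (UPGMA-style, scipy) builds the dendrogram; supports come
from ordinary Felsenstein site bootstrap — resample site columns with
replacement, recluster, count identical leaf subsets — reported as
fractions (×100 in Newick output). The approximately-unbiased multiscale
bootstrap used by pvclust is out of scope; ordinary bootstrap preserves the
testable contract (clean clades reach support ≥ 0.95, supports are binary
at one replicate, Monte-Carlo-consistent across seeds). Cophenetic
correlation is the Pearson correlation between original and tree-implied
distances and errors on constant input.

## Editing-rate dynamics

W(t) = exp(−r·t), anchored at W(0) = 1. A log-linear regression through the
origin initialises r, then bounded nonlinear least squares refines it.
Replicates are pooled as independent points. Rates scale with the time
unit (hours → days multiplies r by 24). The system's fitted value is about
0.06 edits per hour; the noiseless self-consistency test recovers it to
1e−6 and the σ = 0.01 noise test to ±0.005 over 100 seeds.

## Simulator

Synchronous binary divisions, one generation per simulated day. Sites are
Bernoulli-editable with probability 1 − dropout_rate (default 0.3, the
NHEJ-loss analogy). Biased sites (fraction 0.1 by default) accept edit
attempts more readily; the dice description is mapped to an effective rate
F/b with b = 0.9, capped at 1 — a documented choice among the possible
readings. Within a lineage a site converts once and is inherited; with a
fixed seed the whole tree is bit-reproducible.

**Editing-window protocol.** The per-generation accuracy curve treats g as
the number of generations the editor was active on the full depth-G tree:
barcodes are truncated to conversions born at or before g and the complete
tree is reconstructed each time. This is the protocol that produces the
characteristic behaviour — a sharp rise while new generations keep being
labelled, a peak as the editable sites are consumed (at fast rates, >70%
consumed at the peak), and diminishing or negative returns after — and it
is the protocol used by the acceptance script. The alternative
(`protocol="tree_depth"`), stopping the whole experiment at depth g, is
also available; it is trivially accurate for shallow trees.

**Problem sizes.** Sweeps follow up to 24 cells per generation
(`max_cells`, uniform frontier subsampling; a complete binary tree to
G = 15 would have 32,768 leaves). Acceptance runs use N = 800 sites
(N = 200 for the fast-rate consumption check), G = 1..15, 20 replicate
seeds per arm with seeds paired between arms. Triplet accuracy (mother +
two daughters placed correctly) is the primary metric; the fraction of
correctly ordered ancestor/descendant pairs is available as
`metric="pairwise"`.

**What the simulation does not capture.** No cell death, asynchronous
division, PCR/sequencing noise on barcodes, or allele dropout at readout —
the only noise sources are the editing process itself, site dropout and
site bias. Passing simulation tests therefore demonstrates the
reconstruction logic under the stated generative model, not performance on
real sequencing data. One known consequence: the measured accuracy penalty
from 30% site dropout is small (≈ 0–2 percentage points) because the
reconstruction retains ample signal at 560 of 800 sites except near
saturation; pipelines whose accuracy varies more strongly with target count
will show larger penalties.

## Degenerate inputs and tie-breaking (summary)

Empty barcodes place a node directly under the current ancestor; an
entirely edit-free input yields a single-root degenerate tree. All
tie-breaks are deterministic (documented per operation: lexicographic ids,
smaller barcode first, larger expressing set first), making every
reconstruction invariant to input ordering. Random number use is confined
to explicitly seeded generators; replicate seeds derive from
`numpy.random.SeedSequence` and stay below 2^31.
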