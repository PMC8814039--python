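# Methods

This note records the generative model, the algorithmic choices behind each
pipeline stage, the numerical details, and the known limitations.

## Generative model (simulator)

A single i.i.d. ancestor genome (per-base GC fraction 0.44 by default) gives
rise to:

- a **diploid relative**: each base substituted independently with
  probability `d0` (default 0.005), uniformly over the three alternatives;
- **K subgenomes** at pairwise-distinct divergences `d_s` (default K=3 at
  0.01 / 0.03 / 0.06).

Substitution-only mutation (no indels) keeps every coordinate trivially
mappable between homoeologous chromosomes, which the mis-mapping model and
the evaluation both rely on.

Each chromosome is decorated with a telomeric `(AAACCCT)^n` array at its 3'
end, the reverse-complement array at its 5' end, and a centromeric tandem
array (default 200 copies of a random 155-bp unit, each copy 5% mutated)
inserted at the midpoint.  Chromosomes are fragmented at exponentially
spaced breakpoints (mean 30 kb); fragments below the 5-kb minimum are
discarded and logged; kept fragments are reverse-complemented with
probability 1/2.

**Hi-C contacts.**  Exactly `N` locus pairs are drawn (default 2×10⁵).
With probability β₁ (default 0.02) a pair joins two distinct chromosomes of
one subgenome uniformly; otherwise both loci lie on one chromosome with
separation drawn from a truncated power law `s^-α` (default α=1) on
[1 kb, L], the second locus placed uniformly subject to the separation.
Each endpoint is then relocated, with probability `m` (default 0.05), to
the *homologous coordinate* on a uniformly chosen other subgenome —
the mechanism by which subgenome similarity corrupts scaffolding signal.
Endpoints falling in a discarded fragment are redrawn as part of batch
rejection, keeping the record count exactly `N`; a mis-mapped endpoint
whose target coordinate falls in a discarded gap keeps its original
location instead of triggering a second rejection loop.

All stages seed independent `numpy` generators as `default_rng([seed, tag])`
so every artefact is byte-reproducible given the seed.

A caveat discovered during development: drawing `s ~ s^-α` first and then
the position uniformly on `[0, L-s]` over-represents *end-to-end* contacts
(large `s` forces both endpoints toward opposite chromosome ends).  This is
a property of the generator, and the ordering objective must not trust
contacts blindly because of it (see below).

## Subgenome assignment

**Depth signal.**  For contig `c`, the profile value is the fraction of its
100-mer start positions whose canonical 100-mer occurs anywhere in the
diploid reference.  Under independent substitution the expected fraction is
`((1-d0)(1-d_s))^100`; at the default divergences the three bands sit near
0.58, 0.029 and 0.0012 — separated by orders of magnitude, hence clustering
on `log10(fraction + 1e-4)`.  A full-covariance Gaussian mixture with
deterministic quantile-spaced initial means gives posteriors; a contig is
assigned only when its top responsibility exceeds `0.5 + margin`
(margin 0.1), otherwise it stays unassigned for the later stages.  Cluster
labels are renumbered by decreasing mean match fraction, so cluster 1 is
the least-diverged subgenome.

100-mers are matched by a 64-bit polynomial rolling hash of the canonical
strand rather than exact packing (2-bit packing needs k ≤ 31).  With ~10⁷
distinct 100-mers per run, the expected number of colliding pairs at 64
bits is ~10¹⁴/2⁶⁴ ≈ 10⁻⁵ — negligible against a signal measured in
percent.  21-mers and 13-mers use exact 2-bit packing.

**Allelism graph.**  Anchors are canonical 21-mers occurring at most K
times in the whole contig set (low-copy ≈ single-copy per subgenome).  A
contig pair sharing ≥ 8 anchors whose offset pairs form a monotone chain
(longest chain by patience sorting, both relative orientations tried)
receives an edge: such collinearity over mostly-single-copy sequence is the
signature of homoeology.  Two guards matter in practice:

- *Self-repeat masking*: positions whose 21-mer recurs within the same
  contig (±10·k flank) are masked first.  Without this, centromeric tandem
  arrays straddling a contig break create collinear chains between
  *same-subgenome* neighbours — observed on the reference scenario before
  the mask, eliminated by it.
- *Anchor cap*: pairs sharing more than 2000 anchors are evenly subsampled
  before chain computation for bounded runtime; edge decisions at the
  8-anchor threshold are unaffected at simulated anchor densities.

**Conflict repair.**  Edges are visited in descending chain-length order;
when both endpoints share a label, the lower-confidence endpoint is moved
to its minimum-conflict label (ties → unassigned).  If the chosen
endpoint's minimum-conflict label is already its current one — moving it
cannot help — the other endpoint is moved instead; this case occurred in
testing as a single-pass deadlock where the *correctly* labelled endpoint
was selected by the confidence tie-break.  Passes repeat to a fixed point
(capped at 10).  Every move is to a minimum-conflict label, so the
intra-cluster edge count is monotone non-increasing — the property tested
on random graphs.  Finally, an unassigned contig whose allelic partners
occupy exactly K−1 distinct labels receives the remaining label.

**Hi-C correction.**  Affinity of a contig to a cluster is its mean link
density (contacts per Mb², from the end-resolved contact map) to the
cluster's members.  A labelled contig moves only when the best affinity
exceeds 2× its current one *and* the move strictly increases total
within-cluster density; an unassigned contig adopts the best cluster when
it beats the runner-up by the same margin.  At most 5 rounds, stopping at
the first round without changes.

## Chromosome building

Within each subgenome cluster, contigs are anchored to the diploid through
21-mers *unique in the reference*; the majority chromosome vote (≥ 0.6)
pre-assigns a group, the median reference offset of majority hits gives a
positional prior, and the anchor strand majority gives an orientation when
supported by ≥ 3 hits.  Ungrouped contigs join the group with the highest
mean link density.

The initial order is ascending median anchor offset; anchorless contigs are
placed by cheapest insertion (links gained to the new neighbours minus the
link severed between them — the naive added-link score was observed to
split strong adjacencies on ties) and oriented by maximizing the consistent
head/tail contact cells.  Refinement then applies 2-opt segment reversals
and single-contig relocations accepting only strict improvements of the
adjacency objective

    sum over adjacent pairs of  count(right end of i, left end of j)
                                / (w_i · w_j / 1e12),

i.e. the *density* of contacts joining abutting half-contig end windows.
Two deliberate deviations from a raw-count objective:

1. **Density, not counts.**  Raw end-cell counts grow with contig length,
   so an un-normalised objective strictly prefers evicting short contigs
   from between long neighbours; the contacts/Mb² normalisation removes
   this length bias.
2. **Anchor prior.**  Because the contact generator over-represents
   end-to-end pairs (see above), a contacts-only objective can genuinely
   prefer joining a chromosome's two extremes — measured: the wrong
   arrangement scores 1.58M against 1.24M for the true order.  Anchor
   evidence is independent of that artefact, so refinement never
   contradicts it: a reversal may span at most one anchor-placed contig
   and anchor-placed contigs are never relocated.  Contacts order and
   orient only where anchors are silent.  With this prior, both the
   noise-free and the 5%-mis-mapping reference scenarios recover every
   chromosome at |τ| = 1.0 and orientation accuracy 1.0.

A scaffold is reversal-symmetric, so each group is canonicalised: the
smallest-median-offset anchored contig (lexicographic smallest id when no
anchors) is put in '+' context.  AGP v2.1 rows are emitted 1-based with
`N 100 scaffold yes proximity_ligation` gap rows; splitting a scaffold on
its N-runs recovers every oriented contig byte-exactly (tested).

Established Hi-C scaffolders typically delegate within-group ordering to a
stochastic (genetic-algorithm) optimizer; the deterministic anchor-seeded
order with strict-improvement 2-opt used here is this package's own design
choice, preferred for reproducibility.

## QC and dating

**Subgenome-specific 13-mers.**  A 13-mer is informative for a subgenome
when its frequency there strictly exceeds 10× the maximum frequency in
every other subgenome (exclusive by construction).  Chromosomes are
clustered (average linkage, Euclidean) on their K-vector of
informative-k-mer occurrence sums — the full chromosome × k-mer matrix has
millions of columns and induces the same grouping — and the K-cluster cut
must reproduce the subgenome partition exactly.  *Limitation:* the rule is
computed from the provided grouping itself, so a corrupted assembly can be
self-consistent; a whole-chromosome swap between groups was observed to
pass, because the swap demotes exactly the k-mers that would expose it.
The check certifies internal consistency, not arbitrary-error detection.

**Feature scans.**  Centromeres: positions with `seq[i] == seq[i+155]` are
smoothed over one unit; maximal runs with windowed identity ≥ 0.8 spanning
≥ 10 units are reported largest-first.  Telomeres: occurrences of the
monomer and its reverse complement counted in 5-kb end windows, present at
≥ 10 copies.  Both scans show 100% recall and zero false positives on
decorated vs undecorated reference-scale sequence.

**Ks dating.**  Gaussian KDE (Silverman bandwidth) on a 2048-point grid
over [0, max]; local maxima below 10% of the global density maximum are
suppressed; endpoint maxima are kept.  `T = Ks/(2r)` with
r = 6.5×10⁻⁹ /site/year converts peaks to years; reported in Mya at one
decimal.  The two reference peaks 0.26 and 0.0598 give 20.0 and 4.6 Mya.

## Evaluation

Cluster labels are arbitrary, so assignment accuracy is computed after
Hungarian matching of clusters to subgenomes on the base-weighted confusion
matrix; unassigned contigs count toward the unassigned rate, not accuracy.
Ordering is scored per chromosome by Kendall τ with the direction (as-is vs
reversed-with-flips) chosen to maximise τ, reflecting scaffold reversal
symmetry; orientation and adjacency accuracies use the same direction.

## Problem sizes and runtime

The reference scenario (this package's default, chosen to exercise every
mechanism while staying desk-sized) is K=3 subgenomes × three 1-Mb
chromosomes, ~260 contigs of mean 30 kb, and 2×10⁵ contact pairs.  On one
CPU: simulation ~1 s, assignment ~30 s, building ~12 s, 13-mer validation
~15 s.  The acceptance script runs the noisy and noise-free scenarios end
to end in about 90 s.

## Limitations

- Substitution-only divergence: no indels or rearrangements, so anchor
  chains and homologous-coordinate mis-mapping are cleaner than reality.
- The depth law assumes a single diploid reference informative for all
  subgenomes through divergence *ordering*; subgenomes at equal divergence
  are declared invalid input rather than handled.
- The 13-mer partition check certifies internal consistency only (above).
- Contacts-only ordering (no anchors at all) is best-effort: cheapest
  insertion plus 2-opt can stall in local optima on adversarial inputs;
  with anchors present — the intended operating mode — ordering is exact
  on the reference scenarios.
- Centromere detection reports arrays of the configured unit length only;
  it is a periodicity scan, not a general tandem-repeat finder.
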