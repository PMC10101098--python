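# Methods

## Problem and model

The package infers the regulatory reach of two DNA-binding global regulators
(by default named veA and laeA, after the *Aspergillus nidulans* velvet-complex
proteins) from three evidence layers:

1. **Protein–DNA binding** — ChIP-seq peak calls. A gene is *peak-associated*
   (bound) when a peak's center falls inside its promoter window, defined as
   the 1.5-kb region immediately upstream of the **translation** start site
   (the first translated base — the anchor used throughout; transcription
   starts are not modeled). Windows are strand-aware, half-open, clipped at
   chromosome ends, and exclude the start base itself: `[tss−1500, tss)` on
   `+`, `[tss+1, tss+1501)` on `−`.
2. **Expression response** — a differential-expression table for the
   regulator's null mutant versus wild type. A gene is a DEG when
   `padj < 0.05` and `|log2FC| > 1`, both strict (exactly 2-fold is not
   "more than 2-fold"); genes with missing `padj` count as untested, hence
   non-DEG.
3. **Protein–protein associations** — a STRING-format links table with
   combined scores on the 0–1000 scale.

Target classes: **direct** = bound ∧ DEG; **putative direct** = bound ∧
¬DEG; **deg_only** = DEG without a promoter peak. Direct and putative-direct
partition the bound set by construction.

The **GRN** is the PPI subgraph induced by {regulator} ∪ direct ∪
putative-direct, keeping edges with combined score ≥ 150 (inclusive). Nodes
are defined by retained edges: an isolated target is not a node. The **core
section** is the induced subgraph on a seed (normally the regulator) and its
first neighbors, including neighbor–neighbor edges — guilt by association.
Edges are undirected; the network carries no direction of regulation.

For the two-regulator **common GRN**, the node universe is the intersection
of the two bound gene sets; a gene is direct only when direct for both
regulators, otherwise putative direct. Its core is seeded with whichever
regulator nodes are present in the common network (a deliberate choice: the
regulators need not survive the edge filters there).

## Peak geometry

The peak *center* is `start + summit_offset` when a summit is reported
(narrowPeak column 10 ≥ 0), else the floored midpoint. Two peak sets are
matched one-to-one by center distance ≤ 100 bp (inclusive): candidate pairs
are sorted by distance, ties broken on the sorted center pair and then the
sorted id pair, and accepted greedily. This key is invariant under swapping
the two arguments, so matching is symmetric and order-independent; on sets
of ≤ 20 peaks it provably equals exhaustive minimal-distance-first
enumeration (tested).

## Motif elicitation

A two-stage reconstruction of enriched-oligo motif discovery:

1. **Seeding.** Fixed ±100 bp windows around peak centers are the target
   set; the default background is one dinucleotide-preserving shuffle of
   each target (Altschul–Erickson Eulerian-walk construction: exact
   dinucleotide multiset, same first/last base, uniform over arrangements,
   seeded). Every k-mer (default k = 10) present in ≥ 2 target sequences is
   scored by the one-sided hypergeometric tail on sequence presence counts
   (a sequence counts once, either strand; k-mers are canonicalized with
   their reverse complement). The top seeds are kept after a Hamming-
   distance ≥ 3 redundancy filter; ties break lexicographically.
2. **ZOOPS-EM refinement.** Zero-or-one occurrence per sequence: with prior
   γ a sequence carries one site at a position/strand uniform over the
   2·(L−w+1) placements, else it is 0-order background. The PWM initializes
   from the seed at match probability 0.7; the M-step uses pseudocount 0.1.
   The recorded objective is the pseudocount-regularized (MAP)
   log-likelihood, which is provably non-decreasing; the raw likelihood can
   dip by ~1e-4 at convergence precisely because of the pseudocount prior.
3. **Reporting.** A sequence is motif-positive when its best log-odds
   score (either strand) reaches 0.6 of the PWM's maximum achievable
   log-odds; the report gives the motif-positive percentage of peaks and a
   log10 hypergeometric enrichment p versus background. Tails are computed
   in log space throughout, so magnitudes like 1e-80 do not underflow.

**Known limitation.** On motif-free input, ZOOPS-EM overfits: the PWM
adapts to the best-matching random windows and γ converges near 1, and the
rescanned enrichment — being in-sample — can look significant even though
no motif exists. The honest null diagnostic is the seeding-stage
hypergeometric p (≈ 0.25 on random sets versus ≈ 1e-5 and far below on
planted sets in the tested conditions); downstream users should judge a
motif by its seed significance and by recovery consistency, not by γ.

## Enrichment

Gene-set over-representation uses the exact hypergeometric upper tail
(log-space gamma-function summation; agrees with rational-arithmetic
enumeration for all universes ≤ 25, tested exhaustively). The default
mirrors a raw p < 0.05 cutoff with no multiple-testing correction;
Benjamini–Hochberg adjustment is available (`adjust="BH"`). Ratio
statistics print with round-half-away-from-zero (e.g. 166/178 → 93.26%).

## Synthetic study conditions

The generator plants a fully known truth so every stage has a known-answer
test. Defaults, chosen to echo the scale of a genome-wide two-regulator
study in a compact genome:

| parameter | default | rationale |
|---|---|---|
| n_genes / n_chrom | 1000 / 3 | compact but multi-chromosome |
| gene_spacing_bp | 3000 | promoters (1.5 kb) never overlap |
| frac_bound_a / frac_bound_b | 0.29 / 0.17 | ≈ bound-gene fractions of a genome-wide study (≈ 3.2k and 1.8k of 11k genes) |
| frac_shared_bound | 0.59 | ≈ fraction of the smaller bound set that is shared |
| frac_shared_close | 0.8 | shared-bound genes whose two peaks sit ≤ 100 bp apart |
| p_de_given_bound / p_de_given_unbound | 0.30 / 0.25 | DEG rates ≈ 0.21–0.31 genome-wide, modestly enriched for bound genes |
| lfc_magnitude | 2.0 | clear DEGs above the 2-fold cutoff |
| motif / frac_peaks_with_motif | TGATTGGCTG / 0.4 | the common consensus element; realistic sub-100% occurrence |
| n_core_genes | 20 | hub size of a first-neighbor core |
| p_background_edge | 0.01 | sparse decoy PPI, scores 0–399 straddling the 150 threshold |

DE tables are generated directly (the DE model fit is upstream of this
pipeline) and are threshold-consistent by construction: DEG rows draw
`padj ~ U(1e-6, 0.04)` and `|log2FC| > 1`; non-DEG rows draw
`padj ~ U(0.06, 1)` and `|log2FC| ≤ 1`. The planted truth is therefore
exact, and perfect status recovery by the pipeline is the expected outcome —
a correctness check of the plumbing, not a statement about noisy real data.

What the generator does **not** emulate: read-level noise and peak-calling
uncertainty (peaks are placed exactly inside their own promoter and promoters
never overlap, so assignment ambiguity from divergent promoters is exercised
only in unit tests); shrunken fold-change estimates; GC/nucleosome structure;
spurious motif occurrences are left wherever the random genome produces them
(~0.04% of windows for a 10-mer). Passing the end-to-end tests shows the
stages compose correctly under the planted conditions, not that the
thresholds are optimal for real ChIP/RNA-seq data.

One seed yields a byte-identical bundle (tested by hashing). The planted
PPI hub connects each regulator to bound genes only — otherwise the hub
edges could not survive the both-endpoints-are-targets rule, and first-
neighbor recovery would be vacuously impossible.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; GFF3 is converted on read.
- A fully clipped promoter (tss = 0 on `+`) yields an empty window, logged,
  never an error; such genes cannot be peak-associated.
- Midpoint of an odd-length peak floors; the boundary cases of every
  inclusive/exclusive rule (window end, 100-bp match, score 150, padj 0.05,
  2-fold) are pinned by explicit tests.
- With zero common direct targets the shared-direction percentage is
  undefined and reported as NaN, not 0.
- STRING edges deduplicate under endpoint swap keeping the maximum score,
  before and after alias mapping; self-loops (including alias-collapsed
  ones) drop.
- Problem sizes in the test-suite simulations (120-gene bundles for shared
  fixtures, 200×200-bp sequence sets with 20 replicates for motif recovery,
  exhaustive hypergeometric checks to N = 25) were chosen as the smallest
  sizes at which each property is meaningfully exercised.

## Limitations

Beyond the EM caveat above: the pipeline consumes peak calls and DE tables
as given (no recalibration); the GRN inherits STRING's biases and conveys
association, not causality or direction; enrichment ignores the GO graph
structure (no true-path propagation); and the motif stage reports fixed-width
ungapped motifs only.
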