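# Methods

This note documents the models, algorithms and numerical choices behind
`straindiff`, in the spirit of the methods documentation of mature
scientific packages: what each component assumes, which parameters matter,
and what the synthetic-data validation does and does not show.

## The synthetic genome-pair generator

The generator is first-class code, not a test fixture: it defines the
study conditions under which every downstream stage is validated.

**Ancestor.** A single circular chromosome (emitted linearised from
position 1) of i.i.d. nucleotides at a configurable GC fraction (default
0.44), packed with non-overlapping protein-coding genes on both strands
(lengths ~ N(900, 200²) bp, floored at 150 and rounded to codons) and three
near-identical rRNA-like multi-copy genes (1200 bp, 0–2 substitutions per
copy) that exercise the 16S machinery and create realistic repeat-induced
anchor ambiguity.  ORFs are made biologically valid (ATG start, terminal
stop, no internal stops) by *swapping* bases within the gene rather than
resampling them, so the genome-wide letter composition remains exactly the
i.i.d. draw and the GC fraction is binomial by construction.  Gene packing
fails loudly when the requested genes plus minimum intergenic spacing
(30 bp) exceed the genome length.

**Substitutions.** `substitution_rate` is defined as the *pairwise*
divergence — the aligned-site mismatch fraction between the two derived
genomes — because that is the quantity the downstream consumers (ANI,
anchor statistics) see.  Each lineage is mutated independently at the
per-site rate `q` solving `2q − (4/3)q² = rate` (uniform substitution to
the three other bases; two independent hits coincide with probability ⅓).
Inside CDS, substitutions are applied codon-wise and any substitution that
creates a premature stop is resampled among the remaining bases, so ORFs
and protein orthology survive; start and terminal stop codons are left
untouched (a deficit of 6 bp per gene, ≈0.5% of sites, negligible against
the binomial noise at the tested scales).

**Structural events.** Event loci are chosen disjointly with a minimum
spacing (4 kbp) on the ancestor: island insertions at intergenic points
(3–8 kbp, gene-bearing, GC offset +0.06, each island gene tagged as a
transposase/integrase mobility marker with probability 0.5 and carrying the
corresponding KO/COG marker ids); deletions and divergent replacements over
runs of 1–3 whole genes with mid-intergenic boundaries; one translocation
of a ~12 kbp feature-bearing block moved ≥ 50 kbp away — mirroring the
magnitudes reported for real strain pairs of this kind.  Events never span
the origin.  The truth log records every event in final coordinates of
both genomes, including the homologous counterpart interval (a deletion
from one genome implies an exclusive region *owned by the other*), which
makes it a direct oracle for the region classifier.

Defaults (200 kbp, 180 genes, 12% divergence, 5 insertions / 3 deletions /
2 divergent replacements / 1 translocation) are a desk-scale rendition of a
real ~2.4 Mbp strain pair at ANI ≈ 88%; they keep a full replicate under
half a second while preserving the per-event geometry (island and block
sizes are *not* scaled down).

**What the simulator does not model:** codon-usage bias, recombination,
tandem repeats beyond the rRNA copies, phage-specific sequence signatures,
and indel micro-heterogeneity inside homologous sequence (substitutions
only).  Consequently, passing the recovery tests shows the classifier
handles the *geometry* of structural variation at realistic divergence;
it does not certify performance on repeat-dense or indel-rich real
genomes.

## Region classification

**Anchors.** Maximal exact unique matches of length ≥ `k_min` (default 20)
on both strands, found via exact 2-bit-packed 64-bit k-mer codes (unique in
both genomes, merged along diagonals into maximal runs).  At 12%
divergence a 20-mer survives with probability 0.88²⁰ ≈ 0.077, i.e. an
anchor every ~13 bp on average — dense enough to chain, sparse enough that
random 20-mer collisions (expected ≈ 2·L²·4⁻²⁰) are negligible at desk
scales.  `k_min` is floored at 12 to keep that collision bound meaningful.

**Chaining.** The maximum-total-anchored-length chain that is strictly
increasing in both genomes (weighted LIS via a Fenwick tree) becomes the
main collinear chain.  Gaps between consecutive chained anchors are
absorbed into the growing block when both sides are ≤ `max_gap` (5 kbp),
their lengths are within a factor of two, and their global-alignment
identity (edlib NW) clears a floor — 0.55 for gaps ≤ 300 bp, 0.65 above.
The floor is deliberately below the nominal sequence identity because
inter-anchor gaps are *conditioned on containing no exact k-mer match* and
are therefore mismatch-enriched; random DNA aligns at ≈ 0.50–0.55
edit-identity, which sets the lower bound of the discriminable range.
Off-chain anchors are clustered by (strand, diagonal) with a tight
diagonal tolerance (200 bp — a translocated block keeps its diagonal
exactly, while unrelated leftover anchors at nearby diagonals must not
interleave); clusters anchoring < 200 bp are dropped as noise, clusters
overlapping main-chain coverage by > 20% are dropped as paralogous repeats
(in the simulations these are rRNA cross-copy matches), and surviving
blocks are extended along their diagonal by mismatch-tolerant X-drop
(+1/−3, drop 20) extension, which recovers the anchor-end jitter at block
junctions to within a few bases.

**Segmentation.** Each adjacency gap between consecutive main-chain blocks
is paired across the genomes (minus any translocated-block coverage), the
homologous flank residue on both sides is trimmed by the same X-drop
scoring, and the remaining cores are classified by feature content:
features on both sides → *divergent*; features on exactly one side →
*exclusive*, owned by the feature-bearing genome; features on neither side
→ merged into the flanking collinear region (silently below 50 bp, logged
as unclassified above, since an exclusive call requires at least one
annotated feature).  Feature containment (not mere overlap) is used, which
matches the simulator's convention of placing event boundaries in
intergenic space.  The final intervals are tiled so that each genome is
exactly partitioned — slack attaches to the nearest collinear region —
and this partition property is asserted in tests.

Known limitation: an insertion landing within ~100 bp of the genome end
can leave no anchored collinear neighbour on one side, in which case the
terminal residue is absorbed into the event region and the boundary error
exceeds the nominal tolerance; this affects a small percentage of events
in the recovery experiments and is the main contributor to the residual
error rate.

## Orthology and ANIb

Protein best hits follow the classic one-directional protocol: optimal
local alignment (Biopython `PairwiseAligner`, BLOSUM62, gap open 11 /
extend 1), discard hits with query coverage < 80% or e-value > 10⁻⁵, keep
the best survivor by bit score (ties: lower e-value, then lexicographic
subject id — fully deterministic and idempotent).  E-values use *ungapped*
Karlin–Altschul parameters (λ = 0.3176, K = 0.134 for BLOSUM62) applied to
gapped scores — a documented approximation that is conservative for the
high-identity regime this package targets; for exact replication of an
external search tool's statistics, precomputed 12-column tabular hits can
be ingested instead (`best_hits_from_table`), which is the recommended
route.  "Similarity" is the fraction of alignment columns with a positive
substitution score (the conventional "positives").  A shared-5-mer
prefilter skips hopeless pairs without affecting recall at the divergences
of interest.

ANIb fragments the query genome into consecutive 1020-bp pieces and aligns
each to the subject on both strands with bit-vector edit distance (edlib,
semi-global).  Because a forced whole-fragment alignment of unrelated DNA
still yields ≈ 50–55% edit-identity, the retention rule is evaluated on
the *best local segment* of the edit path (maximum-scoring run under
+1 match / −2 difference): retained if that segment covers ≥ 70% of the
fragment at ≥ 30% identity.  Homologous fragments at ≤ 15% divergence pass
with the whole fragment as the segment; unrelated fragments leave only
short positive segments and are rejected, so unrelated genomes report
"unalignable" rather than a spurious ~54%.  A cheap distance cap
(0.25 × fragment) runs first; the expensive cap (0.75 ×, the bound implied
by the 30% floor) only when neither strand hits.  Self-comparison yields
exactly 100%.  The one-directional value and the mean of both directions
are both exposed.

## Hydrogenase motif typing

Motifs are wildcard strings (`x`/`X` matches anything).  `scan` returns
the window minimising the number of non-wildcard mismatches (leftmost on
ties — deterministic), and a motif is *compatible* with a group when its
best window has ≤ `max_mismatch` mismatches (default 1, because published
group assignments tolerate single-residue deviations while noting them;
every deviation is reported as "observed instead of expected at position
p" so stricter users can re-threshold).  A group is called when all its
motifs are compatible.  The composite group 2b proximal motif
(`xCGGCx—xCxxxGG—xCP`) is stored as three independently scanned segments
because its internal spacing is not constrained.  The Tat export signal
`RRxFxK` is searched within the N-terminal 50 residues of the small
subunit (Tat signals are N-terminal; the window is exposed as a
parameter).  The shipped pattern file contains only motifs with stated
provenance; canonical pattern sets for further groups (e.g. the full 1b
L1–L4) must be supplied by the user from a published classification
scheme rather than guessed.

## Functional plasticity and the Welch test

Annotation transfer is one-way fill-in only: a KO present on exactly one
member of an ortholog pair is copied to the other; conflicting annotations
are left untouched and logged (the operation is idempotent).  Exclusive
annotation sets are set differences of the KO/COG universes after removing
transposase markers (KO K07483/K07497; COG2801/COG2963/COG3328) — the nine
transposase Pfam families are available as an alternative marker
vocabulary for genome surveys.  Exclusive genes are clustered into regions
when separated by ≤ 2 intervening genes (`max_gene_gap`, exposed because
no canonical value exists for this rule).

The Welch one-sided t-test is implemented from the formula (sample
variances with n−1 denominators, Welch–Satterthwaite degrees of freedom,
upper-tail Student-t p via `scipy.stats.t.sf`); SciPy's `ttest_ind` and an
exhaustive permutation test serve as independent oracles in the tests,
never as the implementation.  The degenerate all-equal case returns
p = 0.5 (no evidence either way); zero variance with unequal means raises.
Null-simulation calibration shows empirical type-I error within 0.05 ±
0.02 at α = 0.05 over 2000 replicates.

## qPCR quantification and 16S copy analysis

The quantification model is ΔCt with an assumed amplification efficiency
of 2.0 (perfect doubling; exposed as a parameter since no efficiency
correction is modelled): relative quantity `E^−(Ct_target − Ct_ref)`
against a single-copy housekeeping reference.  Technical replicates enter
as the sd of their mean (sd/√n); quantities propagate Ct uncertainty to
first order (`sd_q = q·ln E·√(sd_t² + sd_r²)`); inter-run calibration
divides by the run's calibrator quantity with ratio propagation; the
aggregation order is technical → biological → overall, with the mean-of-k
rule `√(Σsᵢ²)/k` at each level.  First-order propagation agrees with a
10⁵-draw Monte-Carlo oracle within 2% at the Ct dispersions typical of
triplicate assays; it degrades, as expected, for coefficient-of-variation
regimes far beyond that.

Multi-copy rRNA genes are aligned by a centre-star progressive global
aligner (match 2 / mismatch −3 / open −5 / extend −2, merged on the
ungapped centre coordinate system with per-position insertion padding) —
adequate for the > 99%-identical copies it is meant for, and not a general
MSA tool.  Consensus masking marks columns where exactly one copy deviates
from the agreeing rest: bulk sequencing of such a locus reports the
majority base and hides the variant.  Consensus ties emit IUPAC ambiguity
codes and are flagged.  Hypervariable regions (e.g. V1–V9) defined by
1-based coordinates on an ungapped reference row are mapped onto alignment
columns; reference gap columns inherit no label.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (NumPy `default_rng`,
split per stage); identical seeds give byte-identical outputs, asserted in
tests and verified by manifest checksums in the pipeline runner.  The
validation experiments use 200 kbp pairs (100 replicates for region
recovery, 10 seeds per divergence rate for ANIb), 50 kbp pairs over 20
seeds for ortholog recall, 2000 null replicates for test calibration, and
100 simulated 3-copy sets for consensus masking — sizes chosen so a full
validation completes in minutes on one CPU while leaving the per-event
geometry at realistic scale.
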