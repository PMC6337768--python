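# Methods

This note documents the models, parameters, numerical choices and known
limitations of the repeatscape pipeline, stage by stage.

## Synthetic genomes and the mutation model

The generator exists so that every downstream stage can be scored
against planted ground truth. Background sequence is i.i.d. with
configurable GC (default 0.36, typical of plant intergenic DNA). An LTR
retroelement is inserted as `[TSD][5'LTR][internal][3'LTR][TSD]`: both
LTR copies descend from one ancestral LTR and evolve independently
under a Kimura two-parameter process, so an element of age T at rate r
has expected pairwise LTR distance 2rT. The transition/transversion
ratio (α per-site transition rate over β per-class transversion rate)
defaults to 2.0; the literature the dating convention comes from does
not state one, so this is a module choice exposed in the configuration.
Substitution categories are drawn from the exact finite-time K2P
transition probabilities, not a single-hit approximation, which is what
makes the K2P estimator calibration test meaningful.

LTR termini are re-written to `TG…CA` after mutation: the detector
(like the suffix-array tool it re-implements) requires these conserved
termini, and the generator's contract is that planted elements are
detectable instances of the structural model. Mutations are
substitutions only by default; an optional indel rate (short 1–3 bp
events) exercises the dating aligner's gap handling.

The internal region carries, in order: a PBS (reverse complement of a
bundled tRNA 3′-end 18-mer, 15–18 nt, within a few bp of the 5′ LTR),
coding stretches for the requested domain order (reference peptides
back-translated with a fixed one-codon-per-residue table, so domain
recovery is well-posed), a purine tract (10–30 nt of A/G) ending just
before the 3′ LTR, all mutated at the element's age. "Feature-off"
decoys genuinely lack the feature: when the PPT is switched off the
terminal 60 bp are generated with every third base forced to a
pyrimidine, capping any 10-mer window below the 0.85 purine-fraction
floor — otherwise ~25% of random decoys would carry a chance PPT and
the filter-fidelity contract (featureless ⇒ discarded) could not hold.

Reads are sampled uniformly from both strands with uniform quality;
satellite arrays are tandem concatenations of independently mutated
monomer copies (default 2% per-copy divergence).

Standard study conditions, used by the tests, the analysis drivers and
the acceptance script:

| condition | value | why |
|---|---|---|
| annotation genome | 2 Mb, 50 LTR-REs, LTR 300–1500 bp, ages U(0, 3) Myr | enough elements for recall/precision at ±few % resolution; ages span young to clearly diverged |
| TIR/MITEs | 10 elements, 20–30 bp TIRs, 200–600 bp | the signature search's detection floor is ~15 bp TIRs |
| substitution rate r | 1.3 × 10⁻⁸ /site/yr | the standard rate used for plant LTR dating |
| satellite genome | 3 Mb at 0.6× coverage (301-bp reads), arrays of 52/325/365-bp monomers at 1.6–1.9% each | ~100+ reads per cluster keeps the binomial sd of the proportion estimator near 9%, well inside the ±20% recovery tolerance; at 1 Mb the same fractions give 20–40 reads and 16–22% sd, which no estimator can beat |

## LTR detection

Seeding uses exact 12-mers shared at a separation of 1–20 kb, with
hyper-abundant k-mers (> 40 occurrences) dropped to bound pair
enumeration; co-diagonal seeds (band 32 bp, gap ≤ 600 bp) are chained
and chains with ≥ 3 seeds become candidate regions. Boundaries are
refined by local alignment (+1/−1, gap −4 to open and −1 to extend —
one scoring scheme shared by all nucleotide alignments in the package)
of padded windows around the two repeats, then each terminus is snapped
to the nearest `TG`/`CA` within ±15 bp. Candidates are rejected if
either LTR leaves [100, 5000] bp, the LTR lengths differ by more than
20%, similarity falls below 0.60 (identical columns over aligned
columns, gap columns excluded), or the separation constraint breaks.
The distance constraint is interpreted between LTR *start* positions.

Two non-obvious guards:

* **Tandem-array guard.** A satellite array trivially contains direct
  repeats at LTR-like separations. A true LTR does not continue into
  the element's interior, so a candidate whose LTR also matches the
  immediately adjacent internal segment at ≥ min_similarity is rejected
  as an array artefact. Without this, arrays dominate the false
  positives.
* **Overlap resolution.** Overlapping candidates keep the higher LTR
  similarity, then the longer element — a deterministic tie-break.

The TSD is the longest exact 4–8 bp match between the immediate flanks
(longest wins; absent, with a warning, when flank is missing). TSD
presence is reported but not required: boundary snapping can shift a
candidate a few bp off the planted TSD without harming the element
call.

At these defaults a 100-kb random background yields no surviving
candidates; detection sensitivity degrades for LTR identity below
~0.85 (exact 12-mer seeds become sparse), which is ample for the
0–3 Myr study range (pairwise identity ≥ 0.92) but means the 0.60
similarity floor, not the seeder, is *not* the binding constraint for
very old elements.

## Internal annotation

PBS: best reverse-complement match of a tRNA 3′ end (length 18 down to
15) starting within 30 bp of the 5′ LTR with ≤ 1 mismatch; ties go to
fewer mismatches, longer match, lexicographic tRNA id. PPT: the
highest-purine-fraction window of length 10–30 ending within 30 bp of
the 3′ LTR, reported iff fraction ≥ 0.85 (ties: longer, then most 3′).
The purine-fraction rule is a monotone, testable surrogate for the
HMM the original tool uses; it has the same length bounds and a
measurable false-positive rate on random DNA (~25% per candidate),
which is why decoy construction suppresses purine runs (above).

Domains: six-frame translation aligned locally (BLOSUM62, gaps −11/−1)
against per-domain consensus peptides; hits at ≥ 50 bits (Karlin–
Altschul λ = 0.267, K = 0.041) are kept, best hit per domain. RT hits
are re-scored against the lineage-labelled RT library. The 50-bit floor
leaves random 3-kb internal regions hit-free.

TIR/MITE search: exact 12-mers matching the reverse complement of a
downstream 12-mer, chained on anti-diagonals (mirrored coordinates feed
the same chainer), ≥ 3 seeds. The exact-match chain extents delimit the
TIR pair symmetrically; identity is verified by global alignment of the
left TIR against the reverse complement of the right (≥ 0.85), element
span 50–5000 bp, TSD 2–10 bp required. Because a palindromic TSD (e.g.
`TA`) is itself part of the inverted repeat, symmetric trims of up to
~6 bp are scanned until a TSD appears immediately outside the element.
Elements < 800 bp without internal domain hits are MITEs. Chance
perfect inverted repeats ≥ 15 bp pass all structural checks at a rate
of roughly one per 100 kb; they are genuine sequence features and are
reported, which inflates the masked DNA class by ~2–3 percentage
points on the standard genome (within the ±5-point composition
tolerance).

## Classification and phylogeny

Precedence is domain order first (midpoints of the best INT and RT
hits), homology fallback second, unknown last. The homology fallback
accepts the best local hit at E < 10⁻¹⁰ (nucleotide; λ = ln 3 for the
+1/−1 scheme, K = 0.1 as a module constant) or E < 10⁻¹⁵ (translated,
BLOSUM62 parameters as above), strict inequality. Lineage assignment
requires global-alignment identity ≥ 0.45 to the best RT reference and
a ≥ 0.02 margin over the runner-up; close lineages therefore resolve to
unknown rather than to a coin flip. Both thresholds are configurable —
the source analyses state only "sufficient similarity".

The bundled reference library is synthetic and deterministic (fixed
internal seed): one consensus peptide per domain, plus RT variants
generated by hierarchical mutation (superfamily ancestors 25% from the
root; a Chromovirus/non-Chromovirus split inside Gypsy; 10% lineage
divergence). This makes within-superfamily identities ~0.8 and
cross-superfamily ones near noise, so lineage recovery and the clade
structure of the tree are well-posed. Real GyDB/Pfam-derived libraries
plug in through the same FASTA interface (`superfamily|lineage`
headers).

Redundancy removal is greedy: sequences visited by decreasing length
join the first representative at ≥ 0.90 identity. Distances are global
p-distances (mismatches over gap-free aligned columns). The tree is
standard neighbor joining — deterministic tie-break on the smallest
pair of node indices, negative branch lengths clamped to zero, final
three nodes joined at a trifurcating root by the three-point formula.
NJ replaces approximate-ML tree building: it is deterministic and
dependency-free, and the claims it supports (lineage monophyly,
Chromovirus vs Ogre/Tat+Athila clades) are topology-level. No bootstrap
support is computed.

## Insertion dating

LTR pairs are aligned globally; P and Q are counted over columns free
of gaps and ambiguous bases; k follows the K2P closed form and
T = k/(2r) with r = 1.3 × 10⁻⁸ by default (one rate for all elements,
including unclassified ones). Saturated pairs (either logarithm's
argument ≤ 0) are flagged and excluded from summaries rather than
clamped, which avoids biasing mean ages; summaries report group means,
standard errors, medians, quartiles and age-bin fractions. The dating
error at these LTR lengths is binomial-sampling dominated: an 800-bp
LTR pair at 1 Myr carries ~21 substitutions, giving ~20% relative sd
per element and ~13% median absolute error — the reason the recovery
tolerance is 15% on the median, not per element.

## Masking and composition

Library matching is seed-and-extend: shared 13-mers chained per
diagonal, the chained span verified by edit-distance (edlib) global
alignment; hits at ≥ 0.80 identity over ≥ 80 bp are kept, overlaps
between entries resolved by higher identity × length with losers
clipped. Chaining needs a run of exact 13-mers, so sensitivity falls
off below ~90% identity; the 0.80 floor is enforced but rarely the
binding constraint. Sequential passes subtract everything already
masked (first-pass-wins labelling), so intervals are disjoint by
construction and the composition report (per-label and per-class bp and
percent, plus a grand total) raises on overlapping input. Labels follow
a two-level `class/superfamily` scheme.

## Satellite discovery

The edge rule is fixed: a local alignment covering ≥ 55% of the shorter
read at ≥ 90% identity (gap-excluded), either strand. An exact
canonical-13-mer prefilter with a ≥ 2 shared-k-mer requirement prunes
chance pairs (a qualifying pair shares dozens of 13-mers); the
exhaustive all-pairs mode is kept and the test suite asserts component
equivalence on a mixed fixture. A conservative score lower bound skips
full alignment construction for hopeless pairs.

Clusters are connected components (the original tool uses community
detection on a weighted graph; recovery-based validation does not
distinguish them at these scales), size-sorted, singletons dropped.
Topology: member reads are strand-oriented by shared k-mers against the
longest read, a greedy maximum-weight walk of the k = 21 de Bruijn
graph is attempted, and a cluster is **circular** when the walk closes
a cycle of ≥ 21 nodes and ≥ 70% of member reads align to the tandem-
repeated cycle consensus at ≥ 85% identity. Read-level support replaces
a raw k-mer-mass criterion deliberately: at 2% per-copy divergence only
0.98²¹ ≈ 65% of 21-mers are mutation-free, so k-mer mass under-counts
the dominant cycle even for a textbook satellite, while read support is
robust to it. **Star** requires no cycle but one hub read adjacent to
≥ 70% of the cluster; everything else — including clusters below 20
reads, and read chains from single-copy regions — is linear/other.
The monomer length is the cycle node count (exact for divergence 0;
within ±2 bp at ≤ 5%), the consensus is the cycle sequence, and the
genome proportion is cluster reads over all sampled reads. Similarity
coverage is measured on the shorter read of a pair; rDNA clusters are
not specially recognized.

## Numerical and I/O conventions

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and BED conversions happen only at the format boundary.
All randomness flows through explicit seeds recorded in the run
manifest; re-running an identical configuration reproduces byte-
identical tables. Alignment tie-breaks follow the aligner's canonical
first optimal alignment; scores (not paths) are the tested contract.

## What passing tests do and do not show

The generator plants exactly the structures the detector models:
uniform background, substitution-only divergence, non-nested,
plus-strand elements with intact termini. Passing recovery tests
therefore validates the implementation of the models, not their
adequacy for real genomes, where nested insertions, solo LTRs,
segmental duplications, sequencing error and diverged termini all
occur and are out of scope here (no nested-insertion resolution, no
solo-LTR calling, no Helitron/non-LTR structural detection — those
classes are handled only by homology masking against labelled
libraries).
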