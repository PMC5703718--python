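# Methods

This note documents the models, parameter choices and numerical
conventions behind `numtsome`, and what the synthetic-data tests do and
do not demonstrate about real genomes.

## Coordinates and formats

All coordinates are 0-based half-open, everywhere: internal structures,
BED output, and truth records. BLAST tabular I/O converts to and from the
1-based inclusive BLAST dialect at the boundary, with minus-strand
subject hits encoded by `sstart > send` as BLAST does. The mitochondrial
genome is circular; intervals that span the origin are stored either
unwrapped (`end > mt_length`, used by HSPs) or flagged by
`start > end` (used by truth records); both forms are accepted by the
coverage module and normalized internally.

## Synthetic genome generator

The generator emulates what a NumtS pipeline faces on a real assembly;
it is the test bed for every downstream stage.

* **Background**: chromosomes are i.i.d. uniform over {A,C,G,T}
  (configurable composition). This maximizes contrast with the mt query
  and makes detection statistics easy to reason about; it does not model
  isochores, real repeats, or local composition.
* **mt genome**: random sequence with a human-like biased composition
  (A 0.31, C 0.31, G 0.13, T 0.25) tiled by 13 named loci (ND1…CYTB plus
  the control region) with realistic relative lengths. The compositional
  bias matters: the K2P substitution process has a uniform stationary
  distribution, so fragments drift toward the background composition as
  they age — the signal the dating stage uses.
* **Fragment decay**: each planted fragment is evolved to a chosen
  per-site substitution load ("age", substitutions/site) under Kimura's
  2-parameter model with transition/transversion rate ratio κ = 4.
  Per-site transition and transversion probabilities use the exact K2P
  transition functions at that load. Single-base indels are applied at
  `indel_rate × age` events/site (default `indel_rate` = 0.05 per unit
  substitution load), so an age-0 insertion is byte-identical to its mt
  source (strand-aware) — an invariant the tests rely on. No model of
  fixation, duplication, or gene conversion is attempted.
* **Placement**: insertion points keep ≥ 6 kb of background between
  fragments so every planted fragment corresponds 1:1 to one assembled
  NumtS; repeat elements are planted inside the 2-kb flanks and never
  span inter-insertion gaps by default (`n_bridge_pairs = 0`). Scenarios
  that exercise the unique-repeat merge rule construct bridges
  explicitly. 40% of fragments are drawn wholly from within one mt locus
  (default: the control region) to create a known coverage hotspot.
* **Contamination**: pure-mt contigs are verbatim mt fragments
  (occupancy 1.0); partial contigs carry one verbatim mt block occupying
  a configured fraction (defaults 0.85, 0.85, 0.5, 0.5) of their length.
* **Determinism**: one `numpy.random.default_rng(seed)` stream drives the
  whole generator; identical configs give byte-identical FASTA/BED.

What passing tests on this generator show: the pipeline's interval
logic, thresholds, scoring and statistics behave as specified under a
controlled decay model. What they do not show: performance on real
repeat structure, heterozygous NumtS, segmental duplications, or
assembly errors other than N-runs and mt contamination.

## HSP detection

The canonical input for real genomes is BlastN tabular output. The
built-in aligner is a stand-in for self-contained runs, not a BLAST
clone: exact k-mer seeds (word size 11) on both strands against the
doubled mt sequence (circularity), greedy chaining of seeds within a
50-diagonal band and 200-bp gap, ungapped X-drop extension (X = 20) of
chain boundaries, then a global alignment of the candidate region padded
by 200 bp and trimmed to its maximum-scoring contiguous column run
(Kadane over per-column scores: match +2, mismatch −3, gap open −5,
extend −2). The padding lets indel-interrupted terminal segments — in
particular the two arms of origin-spanning fragments — re-enter the
alignment; the trim removes flanking junk. Near-duplicate hits (≥ 90%
contained, same strand) are collapsed; partially overlapping hits are
kept because assembly merges them.

E-values use Karlin–Altschul statistics with λ solved numerically for the
configured match/mismatch scores under uniform composition and K fixed
at 0.21. They are approximate and used only for thresholding at the
10⁻³ default cutoff. Boundary accuracy is typically ≤ 10 bp at
divergence ≤ 0.15 substitutions/site; a score-optimal local alignment
may legitimately absorb a few lucky background bases past a true
boundary.

## Purging and assembly

Occupancy is computed from the *union* of hit intervals so overlapping
hits cannot push it past 1. Removal is strict (`> 0.80`): a contig at
exactly 80% survives. Chromosome-name purging is case-insensitive
substring matching against `random`, `chrun`, `unknown`.

Assembly is the transitive closure (union–find over all same-chromosome,
same-strand pairs) of: overlap, gap ≤ 2000 bp (inclusive at exactly
2000), or a gap covered to ≥ 90% of its length by exactly one repeat
interval. The 90% coverage fraction quantifies "intermingled by a unique
repeat" and is configurable. Opposite-strand neighbours never merge, and
mt-coordinate adjacency plays no role in merging; the mt interval union
is carried for reporting. Closure semantics (rather than a sorted sweep)
were chosen so the partition provably equals the pairwise-rule closure —
the brute-force oracle in the tests checks exactly that.

## Coverage and hotspots

Coverage is a difference array over mt positions; each record (HSP by
default, or each member mt interval of an assembled NumtS) increments
every position its mt interval covers, with origin-wrapping intervals
incrementing both ends of the circle. Hotspots are maximal circular runs
with count ≥ threshold; the default threshold is the 0.99 quantile of
nonzero counts, with absolute counts supported. Plotting (layered
transparent area graphs with locus boundary lines) is optional and
file-only.

## Repeats and correlations

Repeat co-occurrence uses ≥ 1 bp overlap; a repeat straddling a
locus/flank boundary counts in every class it touches. Counts are
normalized by the NumtS count. The dating subset removes any NumtS with
repeat overlap in its locus or 1-kb flanks, and repeat intervals are
subtracted from flank sequences before profile building. Spearman
correlations use average ranks for ties with the two-sided
t-approximation (scipy); significance is judged at α/n_tests
(Bonferroni). Assembly-statistics correlations consume a user-supplied
TSV; nothing is scraped.

## Profile-HMM dating

Architecture: a simplified single-hit glocal profile HMM — match,
insert and delete states per column, no multi-hit wing retraction, with
flanking background-emitting states N and C (self-loop 0.9) providing
free sequence endpoints while the full profile must be traversed.
Transitions: t(M→M) = 0.9, t(M→I) = t(M→D) = 0.05, t(I→I) = t(D→D) = 0.3,
remainder to M; entry splits 0.95/0.05 between M₁ and D₁; M_k and D_k
exit to C with probability 1. Emissions are pseudocount-smoothed column
frequencies, `(count + pc) / (n + 4·pc)`; match columns are alignment
columns with ≥ 50% residues.

Scores are log-odds in **nats**: the forward log-probability under the
profile minus the forward log-probability under a *null profile* with the
same length and transitions but background emissions. This null choice
makes transition costs cancel exactly, so a profile equal to the
background scores 0 for any sequence and profiles of different lengths
are comparable. The forward recursion is vectorized per row; the
within-row delete chain is solved as a prefix log-sum-exp scan, which the
exhaustive path-enumeration oracle verifies to ~1e-16 relative.

The mt profile for a NumtS is built from its mt counterpart region
(single sequence, smoothed); the flank profile from its concatenated
5′+3′ repeat-subtracted flanks. When a NumtS's own flanks exceed 30% N,
a consensus profile over all other NumtS flanks (end-truncated to the
shortest and stacked as a compositional pseudo-alignment) is used
instead. Flank profiles are a compositional proxy, not positional
homology — which is exactly the homogenization signal being measured.
The dating calibration scenario uses fixed 500-bp fragments on an age
grid of 0–0.25 substitutions/site so the score–age relation is not
confounded by length; with score differences unnormalized by length
(as defined), mixed lengths dilute but do not invert the trend.

## Phylogeny

K2P distances count transition and transversion proportions over
pairwise-deleted (gap/N-free) columns and apply the closed form; an
argument ≤ 0 raises a saturation error rather than returning NaN. The
delta-method variance is exposed for standard-error tests. Neighbor
joining is the textbook Saitou–Nei Q-criterion with deterministic
tie-breaking on the lexicographically smallest cluster-label pair and
negative branch lengths clamped to 0 with a warning; the final three
clusters join on a trifurcating seed node. Trees are dendropy objects
(Newick I/O, RF comparison for free); dendropy's own NJ implementation
serves as an independent topology cross-check in the tests, never as the
implementation.

Monophyly is tested as a bipartition question on the unrooted tree (a
species is monophyletic iff some edge separates exactly its leaves), so
the answer is invariant to rooting and leaf order; single-leaf species
are reported "not assessable".

Calibration assumes a strict clock: the input tree is midpoint-rooted
(already-rooted trees keep their rooting; outgroup rooting can be done
upstream), node heights are max distances to descendant leaves (which
guarantees ages monotone from root to tips), and all heights are scaled
so the calibration node — the MRCA of a given leaf set — sits at the
midpoint of its age window (default 95–105 Mya, i.e. 100). The window
endpoints propagate proportionally to per-node age intervals. Alignment
computation and ML tree search are deliberately out of scope; the module
consumes aligned FASTA.

## Tracks and mismatch records

BED6 with `track` headers; assembled NumtS and their mt-side intervals
cross-reference by name. Mismatch records come from a score-based affine
global alignment (match +2, mismatch −3, gap open −5, extend −2; numpy
Gotoh with a prefix-max scan for the horizontal gap state). Edit-distance
alignment is *not* used here: a minimum-edit path can explain clustered
substitutions with a compensating indel pair, fabricating indels in the
SNP pattern, whereas under this scoring two substitutions always beat a
gap pair. Mismatch positions are 0-based on the mt plus strand;
minus-strand NumtS are reverse-complemented before alignment. SAM output
is minimal single-hit records with M/I/D CIGARs.

## Problem sizes in the shipped scenarios

The documented end-to-end scenario uses 5 × 400-kb chromosomes with 50
insertions (ages ≤ 0.15, lengths 300–5000 bp), 3 pure-mt contigs and 4
partial contigs; it runs in a few seconds. The dating scenario uses 30 ×
500-bp fragments across six ages; the topology-recovery scenario uses
8 taxa × 1 kb × 5 replicates. These sizes were chosen to make the
statistical checks (recovery ≥ 90%, Spearman rho ≤ −0.5, RF = 0 in
≥ 4/5 replicates) well-powered while keeping any single run under a
minute on one core.

## Known limitations

* The built-in aligner's e-values are approximate; for publication-grade
  compilations on real assemblies, run BlastN and feed the tabular output
  through `read_blast_tab`.
* The decay model is a stand-in calibrated for recovery/dating tests;
  NumtS in real genomes also experience duplication, gene conversion and
  selection-linked context effects that are not modeled.
* The flank profile measures composition, not homology; its Δ score is a
  relative (not absolute) age coordinate.
* Strict-clock calibration inherits all the usual caveats of a single
  calibration point and rate constancy.
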