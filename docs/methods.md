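# Methods

## The ARSI measure

For a query sequence *S* over {A,C,G,T,N} and a reference set *G* of
genetic elements, define for each position *i* the match length
*L(i)* — the length of the longest substring starting at *i* that occurs
contiguously in at least one element of *G*. The score is
ARSI(G,S) = Σ L(i)/|S| (nucleotides). Two structural facts every profile
must satisfy, and which the test suite asserts on everything the engine
produces: 0 ≤ L(i) ≤ |S|−i, and L(i+1) ≥ L(i)−1 (a match stripped of its
first character is still a match).

Matching is exact and case-normalized; `N` matches nothing, on either
side; matching is strand-specific by default (pre-mRNA regulatory motifs
are strand-specific), with an optional both-strands mode that adds the
reverse complement of every reference element. Ties among reference
occurrences are irrelevant: only the length enters the score.

### Index implementation

The reference set is concatenated with separator symbols and indexed by
a generalized suffix automaton; the separator doubles as the code for
`N`, which makes "a match never spans two elements" and "N never
matches" the same property. Each automaton state stores up to two
distinct *owner* labels (which gene/element its substring occurs in),
propagated up the suffix-link tree; this is exactly the information
needed to answer leave-one-out queries — "longest match occurring in an
element of a *different* gene" — during a single amortized-linear
matching-statistics walk. Validity is monotone (a shorter substring
occurs in a superset of documents), so the greedy extension used by the
walk is optimal. The kernels are numba-compiled; building plus querying
a 1 Mb reference takes on the order of one second. Correctness is
arbitrated by an independent O(|S|²·|G|) brute-force substring scan in
the tests, including the grouped leave-one-out variant.

### Leave-one-out policy

Regional scores exclude, by default, *all* elements sharing the query's
gene id, not just the query element: a multi-intron gene is represented
by several duplicated transcripts, and element-only exclusion would let
them match each other and inflate the gene's score. A strict
element-only mode is available (`exclusion="element"`).

## Regions and transcripts

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted only at the file boundary. Regions scored:
5'UTR, ORF (concatenated CDS), each intron, 3'UTR, and fixed-length
flanks (default 250 nt, truncated at chromosome edges). UTRs missing
from the annotation are inferred from the exon−CDS difference; genomes
annotated without UTRs entirely (common for prokaryotes) can fall back
to fixed-length flanks as UTR stand-ins, with a logged notice — a
package choice, since no standard delimitation exists there. The first
mRNA per gene is used; overlapping genes are processed independently.

For profiles, a gene with *m* > 1 introns is duplicated *m* times, each
duplicate retaining one intron spliced-in with the others removed, so
every donor/acceptor site appears exactly once across duplicates.
Anchors: `orf_start` = first start-codon nucleotide, `orf_end` = first
stop-codon nucleotide, `five_ss`/`three_ss` = first/last intronic
nucleotide of the retained intron.

## Window profiles

Window length WL is odd (31/41/51/71 conventional, 41 default), step
1 nt, centered: the window at center *i* covers [i−(WL−1)/2, i+(WL−1)/2].
Window values are computed from the full-transcript match profile via
the min-truncation identity — the window's own match lengths equal
min(L_full(p), window_end − p) — which the tests verify against direct
per-window scoring; the two formulations are numerically identical, so
which one a reference implementation used is moot. The reference set
for profile windows is the full pre-mRNA (all introns retained) of every
other gene: windows straddle region boundaries, so region-matched
references are ill-defined there.

Aligned profiles span offsets ±floor((n−1/2)·WL) around the anchor
(n = 4 default, hence ±143 for WL = 41; the floor resolves the
non-integer extent conservatively and symmetrically). A gene contributes
to an offset only if a complete window fits inside its transcript; the
per-offset mean is over exactly the contributing genes, and offsets with
no genes are NaN, never zero.

## Null models

Three conservation-law-exact randomization schemes, applied singly or
together (the combined scheme is the default throughout):

- **codons** — synonymous codons pooled genome-wide by amino acid
  (stops are their own family, so incidental internal stops stay stops)
  and permuted within families. Conserves every protein sequence and
  the genome-wide codon multiset *exactly*. Genome-wide pooling (rather
  than per-gene) is the default because it is the weakest constraint
  that still fixes codon-usage bias and the proteome; per-gene pooling
  is a flag.
- **introns** — per-intron uniform permutation with fixed positions: the
  6-nt donor prefix, 3-nt acceptor suffix, and the best branch-motif hit
  (default TACTAAC, searched in the last 60 nt; rightmost full IUPAC
  match wins, reflecting the branch point's 3' localization; if no full
  match exists only the termini are fixed, logged per intron). Conserves
  per-intron composition, hence GC, exactly.
- **utrs** — cyclic rotation by a uniform nonzero offset; 5'UTRs keep
  their terminal 6 nt (the start-codon context — the length is a package
  choice) fixed and rotate only the prefix; 3'UTRs rotate whole.

Each scheme draws from its own RNG stream derived from the user seed, so
schemes commute exactly and the combined scheme equals sequential
application in any order — asserted in the tests, not just assumed.

Ensembles use R replicates (default 50; R ≥ 2 enforced since a SD is
needed). Z(o) = (real(o) − null mean(o)) / null SD(o) with sample SD
(ddof = 1); offsets with zero SD or missing data are flagged undefined
(NaN), never ±inf or silent zeros. Real-vs-random comparisons use the
two-sided Wilcoxon signed-rank test against one matched replicate;
all-zero differences return p = 1 with a notice.

## Expression statistics

Spearman correlation with average ranks; partial Spearman = Pearson on
residuals after regressing the *ranked* variables on the ranked controls
(with intercept), p from the t approximation on n−2−k df — with empty
controls this reduces to plain Spearman to machine precision (tested).
High/low splits default to the median with ties assigned high (the
policy is not standardized anywhere; quantile splits are available);
group comparisons use the two-sided Wilcoxon rank-sum test. p-values are
reported uncorrected, matching how such per-region tests are usually
presented; a Benjamini–Hochberg helper exists for multi-region batches.

## Synthetic data: what it emulates and what it does not

The generator builds the study conditions: 200 genes by default, half
"highly expressed", ORFs of 150–500 codons (ATG + stop-free interior +
stop), 5'UTRs of 50–150 nt, 3'UTRs of 80–200 nt, i.i.d. background at
GC 0.40; half the genes carry one intron (20% of those, two) of
80–400 nt with canonical GTATGT…TACTAAC…AG signals. A library of 30
distinct motifs (8–25 nt, background GC) is placed with start density
3.0 per 100 nt within ±50 nt of every anchor and 0.2 per 100 nt
elsewhere; placements never overlap each other or the protected
codons/splicing signals (rejection sampling — overlapping regulatory
codes exist in real genomes but would muddy the ground truth). In low
genes every placed copy is mutated at 0.15 per nt. Expression is
log-normal by class (μ_high = 3, μ_low = 1, σ = 0.6, natural log):
assigned by *class*, not by realized per-gene motif integrity, so the
score/expression correlation target is deliberately attenuated — the
honest version of the test. Intron probability 0.5 is far above real
budding-yeast frequency; it is chosen so splice-site analyses have
usable sample sizes at 200 genes.

What passing these tests shows: the pipeline recovers planted structure
of the kind the model assumes. What it does not show: performance on
real genomes, where motif sharing is confounded by paralogy, repeats,
codon-usage structure and uneven GC — the null models address exactly
those confounds, but the generator does not emulate them (no codon-usage
bias, no phylogenetic motif decay, no overlapping genes).

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to exercise each claim
meaningfully on a single CPU: oracle equivalence on 500 random
instances; conservation laws and recovery statistics on the 200-gene
default genome; Z-peak localization on ten independently generated
200-gene genomes with R = 20 nulls each (peak *location* depends on the
null mean/SD, which are stable well below the R = 50 default used for
reported Z magnitudes); error robustness on ~1.07 Mb of ORF sequence
(1100 genes) with ten independent 10⁻³-substitution replicates.

Degenerate inputs: empty reference sets, single-element leave-one-out,
sub-window transcripts, too-short introns/UTRs, non-triplet ORFs and
constant expression all fail or pass through with explicit errors,
warnings or flags as documented in the docstrings, never silently.

## Known limitations

- Exact matching only; no edit-distance tolerance and no weighting of a
  substring by its occurrence count (a natural refinement, deliberately
  out of scope).
- Alternative isoforms are not resolved (first mRNA per gene); introns
  inside UTRs are handled by the data model but not generated.
- The real-data path (FASTA + GFF3 of an annotated genome) is exercised
  on generated files; organism-scale runs require the user to supply
  genome downloads.
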