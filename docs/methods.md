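# Methods

This note records the models, parameter choices, and numerical decisions
behind regulonkit, and what the synthetic benchmarks do and do not show.

## Coordinate and data conventions

All coordinates are 0-based, half-open; GenBank's 1-based inclusive
coordinates are converted at the parser boundary. Genomes are FASTA +
tabular features (or GenBank); translations missing from the input are
derived with the bacterial genetic code (NCBI table 11). Upstream
regulatory windows are −400..+50 relative to the translation start, on the
coding strand, clamped at contig ends. By default the window may overlap
upstream coding sequence — the fixed window is the contract — with an
optional flag to truncate at the nearest upstream gene boundary. Ambiguity
code `N` is allowed in genomes; any scored window containing `N` receives
−∞ and can never pass a threshold.

## Operons and orthology

Operons are predicted by the standard prokaryotic distance heuristic:
consecutive same-strand genes with intergenic gap ≤ 100 bp (configurable)
are co-transcribed; the leader is the 5′-most gene in transcription order.

Orthology is bidirectional best hits (BBH) of Smith-Waterman local protein
alignments, BLOSUM62 with affine gaps (open 11, extend 1; a gap of length k
costs open + extend·(k−1)), at an inclusive 30% identity threshold. Identity
is identical aligned pairs over aligned columns, gap columns included in the
denominator — a conservative, testable definition. Best-hit score ties break
by lexicographic locus tag, making every result input-order invariant.
Ortholog groups collect a seed's BBH partners transitively; when two
candidates land in one genome the higher score to the seed wins. Regulator
domain trees are neighbor-joining on Poisson-corrected p-distances
(d = −ln(1−p), capped at p = 0.95; negative NJ branch lengths clamped to 0).
Neighbor joining replaces maximum likelihood deliberately: the tree only
groups paralogs into orthologous clusters, and NJ is deterministic and
dependency-light.

On the classic protein pair HEAGAWGHEE / PAWHEAE with BLOSUM50, the optimal
local score is 28 under a *linear* gap penalty of 8 and 26 under affine
(10, 1); the test suite pins both against an independent Gotoh DP oracle.

## Phylogenetic footprinting

Upstream regions are aligned by a deterministic progressive global aligner
(match +1, mismatch −1, gap −2; guide tree from average-linkage clustering
of pairwise alignment scores). The aligner is pluggable: any substitute must
satisfy the degapping invariant (each row, gaps removed, equals its input).
Column identity is the majority non-gap character frequency among non-gap
rows; columns with more than 50% gaps score 0 (the sources give no formula —
this is our definition). Conservation islands are maximal runs of columns
that (a) individually reach the identity threshold and (b) lie in at least
one window of `window_len` columns whose mean reaches it; runs shorter than
one window are dropped as indistinguishable from background. Defaults
window 10, identity 0.8 — far above the ≈0.25 background identity of
unrelated DNA; "island" is nowhere quantified in the source material, so
these thresholds are package decisions and are exposed as parameters.

## Motif models

A motif model is a 4×L count matrix over scored columns (for direct repeats
the two boxes concatenated — spacer columns are never counted or scored,
only the boxes at their fixed separation), a strictly positive background,
and a pseudocount (default 0.5). Frequencies, log-odds, and per-column
information content follow the formulas in the README. Background is
estimated from the input sequences by default (uniform by flag). The IUPAC
consensus writes a capital base at ≥ 0.7 frequency, a lowercase two-base
code at ≥ 0.8 pair frequency, else `n`; direct-repeat consensi include the
spacer as `n`s so their printed length is 2·box + spacer.

### Direct-repeat (spaced dyad) discovery

Grid search over box 10–18 × spacer 3–12 (an extended mode adds long-range
center distances, e.g. 60–80 bp for SusR-type dimers). Per geometry:
candidate dyads are seeded from the positions where the two prospective
boxes most resemble each other (a direct repeat is one box twice), then
refined under a one-occurrence-per-sequence (OOPS) rule — re-pick the
best-scoring occurrence in each sequence, rebuild the PWM — to an occupancy
fixed point (≤ 50 iterations; typically < 10).

Geometry selection maximizes the **pooled-box penalized information
content**: the two box occurrences of every site are pooled column-wise and
the objective is 2·Σ_j (IC_j − 0.5 bits). Two choices here matter and were
made for identifiability, not convenience:

* the 0.5-bit per-column penalty removes the length bias of raw total IC on
  finite samples (wider boxes always gain a little sampling IC);
* pooling is what pins the box boundary when training sequences are
  phylogenetically correlated. Orthologous upstream regions share ancestry,
  so the base just outside a true box is itself partially conserved and
  rewards an over-wide box under an unpooled objective; pooled with the
  other box's unconserved spacer-side column it loses its information,
  while genuine box columns stay sharp in both copies.

The returned model keeps the concatenated-box counts (box-specific
deviations preserved) and its OOPS occurrences as training sites.

### Palindrome EM

A MEME-style OOPS missing-data model: E-step computes the posterior over
start positions per sequence; M-step re-estimates frequencies from expected
counts and then averages the matrix with its own reverse complement, making
it *exactly* palindromic after every iteration (the symmetry holds to the
last bit, and is asserted). ZOOPS (zero-or-one occurrence) is available by
flag. Defaults: 20 random restarts (best by information content),
convergence at max |Δf| < 1e−6 or 200 iterations, all randomness from one
seeded generator.

## Scanning, thresholds, and the consistency check

Scans cover the upstream windows of all operon leaders, both strands;
overlapping hits within one center distance collapse to the best-scoring
one (ties: + strand, then smaller position). Threshold comparisons allow a
1e−9 tolerance so a site scoring exactly the training minimum is never lost
to floating-point summation order.

The scan threshold is the smallest training-site score. The plain rule is
kept as the default contract, but the workflows use a **leave-one-out**
variant: each training site is scored under the PWM built from the other
sites. Self-scoring is biased — a site's own bases sit in the counts it is
scored against — and with sharp motifs the plain minimum lands well above
the score of genuine sites of equal quality. Since a self-score always
exceeds the same site's LOO score, every training site still passes the LOO
threshold.

Membership follows the consistency check: an operon is accepted when sites
occur upstream of it and upstream of its orthologs in at least
`min_support` genomes that carry the orthologous regulator (`min_support`
counts all supporting genomes, the queried one included; default 2 —
"several genomes" is not quantified in the source material). Genes sharing
an accepted operon enter by operon inheritance. An optional, off-by-default
functional-link mode admits a non-conserved site scoring ≥ threshold + 2
bits upstream of a gene sharing a `functional_category` tag with an
accepted member — an explicit mechanization of what is otherwise expert
judgment. Raising `min_support` can only shrink the accepted set, by
construction.

Refinement rebuilds the PWM from the union of the original training sites
and the accepted sites, recomputes the LOO threshold, rescans, and
re-filters until the accepted set is a fixed point (≤ 10 rounds; a
non-converged loop returns its last state flagged). Keeping the original
training sites in the union is deliberate: refining from accepted hits
alone lets the threshold ratchet upward each round until only the strongest
sites survive.

## Motif comparison

Frequency matrices are compared over all column offsets with ≥ 4 aligned
columns, both orientations, by Pearson correlation of the flattened aligned
blocks; ties break by smaller |offset|, then forward orientation.
Significance is a seeded column-shuffle permutation test (default 1000
shuffles), chosen over tool-internal e-values so the null is explicit and
reproducible. Clustering is average linkage on d = 1 − r with
lexicographic leaf ordering, so results are input-order invariant.

## Synthetic benchmarks

The generator emulates the study design the pipeline targets: an ancestral
genome of stop-free random coding genes (GC 0.43, *Bacteroides*-like;
gene length 80–140 codons; operons of 1–3 genes, 20–60 bp inside and
250–420 bp between operons), descendants derived by independent per-base
substitution at the divergence rate (star phylogeny — tree-shaped evolution
is out of scope), and regulators whose target operons are the regulator's
own operon and its chromosomal neighbors first (the genome-context premise
of the footprinting workflow), plus distant operons found only by the scan.
Site positions are fixed in the ancestral frame — sites are inherited,
only their sequence turns over — and each genome samples its site from the
motif model at per-position fidelity 0.85, resampling any draw with more
than 25% non-consensus scored positions (a site that loses that many
contacts is no longer functional and would not persist under selection).
A direct-repeat consensus is one random box repeated. The manifest records
every planted site, family, and parameter; a packaged invariant asserts
each site is present at its recorded coordinates.

The default benchmark — 5 genomes, 40 genes each, divergence 0.2, one
(16,5) regulator with 6 target operons — is the condition under which
recovery statistics are reported: geometry recovery and membership F1 over
20 seeded runs (about 4 s per run on one CPU), and a matched null (no
planted regulator, a phantom regulator group spanning all genomes) for the
false-positive control. What passing these benchmarks does *not* show:
robustness to repeats, horizontal transfer, rearrangement, skewed codon
usage, or non-i.i.d. background — none of which the generator emulates.

## Known limitations

* The progressive aligner is O(L²) per merge and intended for upstream
  windows (≤ ~1 kb rows), not chromosome-scale alignment.
* OOPS discovery assumes every training sequence carries a site; workflows
  arrange this by construction, but user-supplied training sets with many
  siteless sequences dilute the model (use ZOOPS for the palindrome route).
* One motif model per regulator: variable spacers within one model and
  dinucleotide backgrounds are out of scope.
* The packaged census tables are reference data transcribed from the
  published study of *B. thetaiotaomicron*; the pipeline does not re-derive
  them from public genomes (that requires downloads and curation).
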