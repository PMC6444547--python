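# Methods

## Coordinate conventions

All genomic coordinates are GFF3 1-based inclusive; protein coordinates are
1-based. The coding-nucleotide offset `c` of an intron (number of coding
nucleotides 5′ of it within the mRNA) determines its phase `p = c mod 3` and
anchor residue: for `p = 0` the residue immediately 5′ of the junction
(`r = c/3`); for `p > 0` the residue whose codon the intron interrupts
(`r = ⌊c/3⌋ + 1`). The anchor convention is arbitrary but is applied
identically in simulation and inference, so every downstream result is
convention-invariant. Junctions at `c = 0` or `c = total CDS length` would
lie outside the coding region and are excluded. A trailing stop codon is
trimmed from the CDS before the divisible-by-3 check, because GFF3 dialects
differ on whether the stop belongs to the CDS; the emitter writes it,
the parser removes it, and junction offsets are unaffected either way.

Isoform policy: one isoform per gene, by default the one with the longest
total CDS, ties broken by lexicographically smallest transcript id. Genes
whose annotated phases disagree with the cumulative coding length, or whose
translation contains an internal stop, are flagged invalid, excluded
downstream, and counted in the validation report rather than silently
dropped.

## Splice-site homology

Two introns are homologous exactly when their anchor residues occupy the
same MSA column and their phases agree; phase is part of site identity
because a phase-0 and a phase-1 intron at the same column interrupt the
reading frame differently and have distinct evolutionary identities. No
fuzzy merging of near-miss columns (± k) is performed: with curated
alignments, exact columnar correspondence is the assumption, and inventing
homology between drifting columns would bias change counts downward. A gap
at a character's column means the region is not alignable for that species
and yields `unknown` (missing data — costless for either state in the
parsimony step); a stricter `absent` reading is available by flag. A species
with no row in the MSA (no ortholog recovered) contributes an all-unknown
row.

## Parsimony reconstruction

Each character is analysed on the rooted species tree by Sankoff dynamic
programming over states {absent, present}, with user-settable gain and loss
costs (default 1/1, i.e. direction-agnostic unweighted parsimony; a
Dollo-like regime is available as `gain_cost ≫ loss_cost` but is not used
for headline outputs). Unknown tips carry zero cost in both states, so they
neither attract events nor veto anything. Polytomies are handled natively
by the DP; no arbitrary resolution is performed. The tree is used as rooted
and no outgroup inference is attempted. Trees whose root has three or more
children are rejected as unrooted input at read time.

Tie handling follows the agnostic-range convention. Besides the optimal
score, the implementation computes, exactly, which states each node takes
in at least one most-parsimonious labeling and which (parent, child) state
pairs each branch realises, via outside ("rest of tree") cost vectors. Per
branch, the gain count over scenarios is then 1..1 if the gain transition
is the only optimal pair, 0..1 if it is one of several, 0..0 otherwise —
and likewise for losses; these ranges are independent of the scenario
enumeration and its cap. Summing ranges across characters is exact because
characters are independent. The explicit scenario set is also enumerated by
backtracking (default cap 10,000, with a truncation flag) and is used for
the parallel-change report: a character is flagged when *every* optimal
scenario places at least two events on branches neither of which is
ancestral to the other. "Retained in all species" counts characters present
in every known-state tip whose root state is present in every optimal
labeling; unknown tips do not veto retention.

Degenerate characters (all tips unknown) score 0 and are reported
separately. With unit costs, `n_changes` is the sum of per-site binary
small-parsimony scores and `n_variable_sites` counts characters with
score > 0.

## Structure metrics

Coding-exon sizes are nt/3 with fractional values retained (internal exon
boundaries need not respect codon boundaries; rounding would bias small
exons). First/last coding exons — and single-exon genes — shorter than 10 aa
are excluded by default, because such terminal stubs are frequently
mis-annotated UTR or placeholder exons; internal exons are never excluded.
Medians and the MAD (median absolute deviation from the median) are the
headline statistics; quartiles use linear interpolation. Note the quartiles,
unlike the medians and MAD, are not invariant under duplicating every gene.
Stratified gene sampling splits the reference size distribution into
equal-count terciles by rank (not fixed aa thresholds) and samples up to a
fixed number of candidates per stratum without replacement, reproducibly by
seed. Species with fewer than 3 genes are summarised but flagged low-n.

The genome-size correlation uses Spearman's rank correlation with average
ranks for ties; for n ≤ 10 species the two-sided p-value is exact — the
full permutation distribution of |ρ| over all n! pairings — otherwise the
asymptotic p is reported.

## The synthetic-data generator

The generator emulates what the inference stages are built for: ortholog
families whose intron complements evolve on a rooted species tree. It is a
deliberately simple generative model — the simplest one whose output a
parsimony method should be able to invert:

* A family starts with `n_ancestral_sites` introns at distinct
  (residue, phase) slots drawn uniformly from the `3L − 1` legal slots of an
  `L`-residue protein (defaults: 20 sites, L = 400, emulating a large,
  conserved, intron-rich insect gene; no phase bias is imposed).
* Along each branch, losses are Poisson with mean
  `loss_rate × branch_length × n_present` (sites chosen uniformly without
  replacement) and gains are Poisson with mean `gain_rate × branch_length`
  (defaults 0.02 and 0.3 per unit branch length: slow turnover, a handful
  of expected changes per family on an 8-species tree of unit branch
  lengths). Gains draw a slot unused anywhere in the history so far, so
  two lineages never create colliding characters and the emitted data
  round-trips to the exact tip presence matrix. An optional
  one-event-per-site mode freezes a site after its first event, giving
  homoplasy-free histories for exact-recovery checks.
* Emission: a random amino-acid sequence (first residue M), one random
  codon per residue, a stop codon in the final CDS feature, fixed-length
  60-nt introns with canonical GT…AG boundaries, 50-nt flanks, alternating
  strands across species (coordinates recomputed for minus-strand genes).
  Downstream stages consume coordinates only, never splice motifs or codon
  usage, so none of these simplifications matter to the tested claims.
* Optional indels insert or delete whole codons only, so true alignment
  columns stay well defined; a species never deletes a residue anchoring
  one of its own introns (the alternative would be an intron with no home,
  which real curated data would represent as a different gene model, out of
  scope here). The emitted MSA is the true homology.
* Genome sizes, when emitted, are an increasing affine function of the
  species' simulated intron count plus seeded Gaussian noise — the
  generator's world is one in which the positive genome-size/intron-number
  association holds, so the correlation stage has signal to detect.

What passing tests on this generator do **not** show: robustness to
alignment error (the MSA is true by construction), to substitution
saturation or rate heterogeneity (no sequence evolution is simulated), to
annotation error beyond the phase/translation checks, or to biased intron
phase distributions (gains are phase-uniform). On real data those factors
enter through the user-supplied alignment and annotations.

## The sized rehearsal study

The full-pipeline rehearsal constructs an 8-species study with exactly 148
variable splice sites carrying exactly 165 changes (three families, plus 24
constant ancestral sites for the retention report). Since 165 > 148, some
sites must carry two events; the construction uses 131 one-event sites
(a single gain or a single loss on a uniformly chosen branch) and 17
two-event sites (independent parallel losses of an ancestral site). For a
single event, the minimal change count is 1 whenever the pattern is
non-constant, which the construction guarantees. For parallel losses the
branch pair is sampled subject to: neither branch ancestral to the other,
and neither the absent-tip set nor the present-tip set forming a clade —
under which any single change is provably insufficient, so the minimal
count is exactly 2. These are clade-logic arguments, independent of the
parsimony implementation being exercised, which is why the pipeline's
aggregate totals must equal (148, 165) exactly rather than approximately.

## Problem sizes and numerical choices

Test and acceptance runs use: exhaustive oracle comparison on all 105
rooted binary 5-tip topologies × all 32 binary patterns plus 200 random
6–8-tip cases; 100 emitted-and-reparsed histories (proteins of 150 aa, 8
ancestral sites, four gain/loss rate pairs); 200 homoplasy-free and 200
elevated-rate families for recovery bounds; 100 low-rate replicates for the
event-recovery rate. These sizes give exact or tightly bounded checks while
keeping a full run in the order of seconds to a few minutes on one CPU.
Floating-point cost comparisons use an absolute tolerance of 1e-9; costs
are small integers in all default analyses, so ties are exact. Scenario
enumeration is capped at 10,000 labelings per character; the cap only
affects the parallel-change report (flagged when hit), never the ranges,
which derive from the cap-independent membership computation.

## Known limitations

* No probabilistic (ML/Bayesian) model of intron evolution; branch lengths
  are used by the simulator but deliberately ignored by the parsimony
  inference.
* Exact-column site identity may undercount homology in poorly aligned
  regions of real data; curation of the input MSA is the user's
  responsibility.
* UTR-adjacent introns are out of scope: the coding-offset bounds exclude
  junctions outside the CDS.
* The exact permutation p-value enumerates n! pairings and is capped at
  n = 10 species by default.
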