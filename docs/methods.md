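# Methods

`mitocomp` is a toolkit for comparative analysis of annotated animal
mitochondrial genomes, built around the statistics routinely reported in
mitogenome papers for birds and other vertebrates: base composition and
strand skews, codon usage (start/stop codons and RSCU), per-gene divergence
and selection (Ka/Ks), and distance-based topology checks on concatenated
matrices. A codon-model simulator generates fully annotated genomes with
known parameters, so every stage of the analysis is validated offline
against ground truth.

## Data model and coordinates

A `MitoGenomeRecord` is one nucleotide sequence over `{A,C,G,T,N}` plus an
ordered feature table of 1-based inclusive coordinates (GenBank convention);
a feature with `start > end` wraps the origin of a circular molecule.
Ambiguity codes other than `N` are rejected at parse time with an explicit
error; `N` is permitted but excluded from all composition counts. Gene names
are mapped through a user-extensible synonym table to canonical symbols
(`COI`, `Cyt b`, `12S`, `tRNA-Leu(UUR)`, `CR`, ...). Features of the four
analysed classes that cannot be named are reported on `record.warnings`,
never silently dropped. The control region is only ever taken from the
feature table; an unannotated long spacer is not auto-called as a D-loop.

Intergenic spacers are defined between features adjacent in genome order,
negative when annotations overlap; on circular records the closing
last-to-first spacer is included, so feature lengths plus spacer lengths
always tile the genome exactly (a tested invariant).

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), computed on whichever
strand a sequence is given in. Whole-genome statistics use the deposited
(plus) strand; per-gene and per-region statistics use the coding
orientation, obtained by reverse-complementing minus-strand genes. This is
why a minus-strand gene such as ND6 can show a skew far outside the range of
the plus-strand genes: its coding strand is the genome's light strand.
Report tables round half-up to two decimals, matching how such tables are
conventionally printed; raw unrounded values are retained alongside
(`df.attrs["raw"]`). Summary rows (mean, sample SD) are computed on the
unrounded values and rounded last.

## Codon usage

All codon work uses the vertebrate mitochondrial code (NCBI translation
table 2), which has four stop codons (TAA, TAG, AGA, AGG) and therefore 60
sense codons; the codon-count and RSCU tables cover exactly those 60.
RSCU(c) = count(c)·k/X for a synonymous family of size k with total count X;
unobserved families yield nulls rather than zeros. RSCU is computed per
species over the 13 PCGs pooled (per-gene tables are available).

Start codons are the first in-frame codon of each CDS; the conventional
vertebrate-mitochondrial set is {ATG, GTG, ATA, ATC, ATT} and anything else
is tallied with a warning. Stop codons are recorded verbatim from the
annotation: the trailing 1–2 nt of a CDS whose length is not a codon
multiple is reported as an incomplete stop (`T--`/`TA-`, completed in vivo
by polyadenylation), and a non-canonical annotated terminator (e.g. AAA) is
preserved and surfaces in the report instead of being re-translated away —
annotation artifacts are data here.

## Divergence and selection

Input is an in-frame codon alignment per gene. Mitochondrial PCGs are
essentially indel-free among congeners, so the package consumes alignments
rather than producing them: equal-length strand-corrected extractions are
stacked directly, the pipeline trims unequal *terminal* lengths (annotations
differ at alternative stops), and true internal indels require an externally
aligned FASTA. Cleaning removes the incomplete-stop tail, terminal stop
codons, and every codon column containing a gap in any taxon (complete
deletion at codon granularity); an internal stop surviving cleaning raises
an error naming the taxon and codon index, since it indicates a frame
problem.

Site classification is standard: a variable site has ≥ 2 nucleotide states;
parsimony-informative, ≥ 2 states each in ≥ 2 taxa; singleton, variable but
not informative (Vs = Pis + singletons, a tested identity). ts/tv is the
pooled count ratio of transitions to transversions over all pairs and sites
(a count ratio, not a model-based rate estimate — the two differ, and the
choice is stated here because printed tables rarely say which they use).
Aupd is the mean uncorrected p-distance over all C(n,2) pairs.

Ka/Ks follows Nei & Gojobori (1986) with equal-weight pathway averaging and
Jukes–Cantor correction:

* **Sites.** Each codon position contributes 1/3 of a site per possible
  nucleotide change; changes that preserve the amino acid count toward
  synonymous sites (S), changes that alter it toward nonsynonymous sites
  (N), and changes creating a stop toward neither, so S + N < 3 only for
  stop-adjacent codons. S and N totals are averaged over the two sequences
  of a pair.
* **Differences.** For each differing codon pair, synonymous (Sd) and
  nonsynonymous (Nd) changes are averaged over all minimal mutational
  pathways with equal weight, excluding pathways through stop codons; in
  the rare case that every pathway is blocked, stop-traversing pathways are
  used and the pair is flagged.
* **Correction.** pS = Sd/S and pN = Nd/N are corrected with
  d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 yields a null with a note.

Gene-level Ka/Ks defaults to the ratio of the mean dN to the mean dS over
all pairs (robust to pairs with dS = 0); mean-of-ratios is available behind
a flag. The implementation is verified codon-by-codon against an independent
brute-force pathway-enumeration oracle to 1e−9.

Two estimator properties worth knowing: (i) with strong transition bias NG
systematically *underestimates* ω, because transition-rich mutation makes
synonymous changes more frequent per NG-counted site than the unweighted
counting assumes — the neutrality-recovery harness below therefore runs
without transition bias; (ii) pathway averaging can attribute fractional
nonsynonymous differences to codons hit twice by purely synonymous
substitutions (e.g. TTA→CTA→CTT inside the Leu family reconstructs one
pathway through Phe), so Ka under ω = 0 is near, not exactly, zero.

## Supermatrices and topology tests

Gene alignments are concatenated in a fixed canonical order (13 PCGs in
genome order, then the rRNAs), independent of input order; missing
taxon×gene blocks are filled with `?` (`-` is reserved for alignment gaps),
and the partition table tiles the matrix without overlap (validated).
Exports are relaxed PHYLIP, NEXUS with a SETS/charset block, and RAxML-style
`DNA, name = start-end` partition files, all byte-stable; labels are
sanitized (whitespace → `_`) with the mapping available. NEXUS re-imports to
an identical sanitized matrix.

Bayesian/ML inference engines are deliberately out of scope: the package
exports their inputs and answers topology questions in-repo with
neighbor-joining (Saitou–Nei, Q-criterion) on p- or Jukes–Cantor distances,
plus explicit hypothesis trees. NJ uses a deterministic tie-break
(lexicographically smallest pair of cluster representatives) so results are
reproducible; on additive matrices it provably recovers the generating
topology and all path lengths (tested to 1e−9). Monophyly is judged after
rooting at a named outgroup; tree comparison uses the unrooted
Robinson–Foulds bipartition distance. The competing placements of the
golden-plover genus *Pluvialis* — sister to the
oystercatcher/ibisbill/avocet families on small multi-marker matrices
versus basal within the plover family on whole mitogenomes — are encoded as
hypothesis trees whose plover-family monophyly verdicts differ, which is
the in-repo form of that topological question.

## The simulator

`make_ancestor` builds an annotated ancestor with the avian mitogenome
architecture: 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus one control
region, ND6 and eight tRNAs on the minus strand, PCG lengths matching
typical shorebird values (ATP8 shortest at 168 bp CDS, ND5 longest at
1,815 bp), incomplete stops on ND2, COIII and ND4, alternative start codons
on COI, ND3 and ND5, and a configurable intergenic-spacer profile (default:
23 bp after tRNA-Tyr, 5 bp after tRNA-Asn). Composition targets (default
AT% 55, AT skew +0.14, GC skew −0.38, the range typical of shorebird
mitogenomes) are met by calibrating the sampling frequencies with a short
fixed-point iteration, because excluding stop codons while drawing PCG
bodies would otherwise bias realized composition; minus-strand genes are
drawn from mirrored frequencies so their reverse complement lands on the
plus-strand target.

`evolve` runs a continuous-time substitution process along a Newick tree
with exponential waiting times (Gillespie), which is exact under the model
and fast at 17 kb scale. PCG bodies evolve under a codon model with
HKY-style rates — proportional to the target frequency of the incoming
base, ×κ for transitions (default 8, giving pooled ts/tv count ratios near
the 3–5 observed in shorebird tables), ×ω per gene for amino-acid-changing
substitutions, stop codons forbidden; start codons and terminal stops are
held fixed. tRNAs, rRNAs, the control region and spacers evolve under the
HKY nucleotide model. Target-frequency weighting makes the configured
composition approximately stationary, so AT-richness and skew persist at
the tips instead of eroding toward uniformity. Branch lengths are expected
substitutions per nucleotide site; per gene, rates are normalized by the
ancestral mean per-site rate. Default per-gene ω mirrors the heterogeneity
seen in shorebird mitogenomes (COI/COIII 0.02 ... ATP8 0.16), all well
under 1 (purifying selection). Everything is seeded explicitly; there is no
global random state.

`fixture_set(seed)` deterministically regenerates the bundled study set —
12 genomes on a fixed published-shape tree — together with its ground truth
(tree, ω map, composition targets, spacer profile, gene order); it can
write GenBank flat files plus `truth.json`. Regeneration from the seed, not
serialized copies, is the reproducibility mechanism.

What the simulator does *not* emulate: replication-origin mutational
gradients, tRNA secondary-structure constraints, indels and rearrangements,
heteroplasmy, and annotation noise. Passing tests on simulated data
therefore demonstrate correctness of the statistics and estimators under
the stated models, not robustness to the full messiness of real
annotations; the reproduction tests against the twelve published shorebird
mitogenomes (which require a one-time fetch of the deposited records) cover
the latter.

## Validation harnesses and problem sizes

* NG vs brute-force pathway oracle: 100 random short CDS pairs (5–25
  codons), exact to 1e−9 on S, N, Sd, Nd, Ks, Ka.
* ω-ordering recovery: 50 replicates, 10-taxon tree, 300-codon genes at
  ω ∈ {0.05, 0.2, 0.8}, κ = 8; the estimated ordering must match in ≥ 95%.
* Near-neutral recovery: 50 two-taxon replicates at ω = 1, low divergence
  (0.05 total), 300 codons, κ = 1 — the unbiased-mutation condition under
  which NG's unweighted site counting is consistent (see above); the mean
  estimate must lie in [0.8, 1.2].
* NJ: exact recovery (RF = 0, path lengths to 1e−9) on random additive
  matrices of 4–11 taxa; ≥ 90% RF = 0 across 20 replicates of 2 kb neutral
  sequence on random 10-taxon trees via JC distances.
* The bundled 12-genome set drives the end-to-end pipeline test: NJ on
  whole-genome distances recovers the true tree (RF = 0), the cleaned
  concatenated PCG length is reproduced, and re-runs are byte-identical.

These sizes keep the whole suite in the tens of seconds while giving the
stochastic checks comfortable margins (the ordering harness passes 50/50,
the NJ noise harness 20/20 at the chosen divergences).

## Degenerate inputs and numerical conventions

Skews are null (not 0) when their denominator is empty; p-distance is null
with zero comparable sites; ts/tv is null with zero transversions; Ka/Ks is
null when dS is 0 or a JC correction is undefined. NJ requires a symmetric,
zero-diagonal, non-negative matrix of ≥ 3 taxa and breaks exact Q-ties
lexicographically. Rounding for printed tables is decimal half-up. The NG
pathway cache and rate tables are memoized per (ω, κ, frequency) triple.

## Known limitations

* The Ka/Ks implementation is classic NG86 + JC; DnaSP's "π-modified"
  variants can differ in later decimals on real data, and ML (codeml-style)
  estimates are out of scope.
* The pipeline's terminal-trim alignment shortcut assumes indel-free genes;
  genes with internal indels must be aligned externally.
* NJ is a topology-testing tool here, not a substitute for model-based
  inference; no bootstrap or posterior support is computed.
* The simulator's tRNAs are unconstrained nucleotide sequences — adequate
  for composition/divergence statistics, not for structure-aware work.
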