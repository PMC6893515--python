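# Methods

## The analysis problem

A landscape phage library displays a random 9-residue peptide fused to the
N-terminus of every copy of the major coat protein p8. After in vivo
circulation, the phage sub-population recovered from each tissue is sequenced
through a gp8-targeted amplicon: a single-end 150 bp read containing the
degenerate 27-nt insert between fixed flanking sequences
(`ATGCTGTCTTTCGCTGCA` upstream, `CCCGCAAAAGCGGCCTTTGACTCCCTGCAAGCTAGCGC`
downstream on the sense strand). Because the amplicon is short, roughly half
of the single-end reads sequence the anti-sense strand; both orientations are
usable, which about doubles read yield. The scientific object of interest is
not the full peptide but its overlapping 3-mers — elementary binding units
(EBUs), the shortest non-gapped fragments assumed able to seed protein–protein
interactions — whose per-tissue enrichment and co-occurrence structure this
package quantifies.

## Read processing

Orientation and trimming use linked-adapter semantics: the upstream flank,
exactly 27 nt, then the downstream flank, each flank matching with at most 2
substitutions (configurable; indels are not modelled because any indel breaks
the exact-size constraint anyway). Sense flanks are tried first, then
anti-sense flanks (reverse complements of the sense pair); an anti-sense hit
is reverse-complemented, with reversed qualities, into sense orientation. The
leftmost upstream candidate wins; a read matching both strand patterns is
rejected as ambiguous rather than assigned. Reads whose flanks are present but
wrongly spaced are tallied as size rejections, distinct from no-match
rejections, so the category counts always partition the input.

The quality filter runs **after** trimming and, by default, requires every
base of the 27-nt insert to reach Q ≥ 34 — the strictest reading of a
minimum-quality filter, evaluated on the insert only since the flanks are
discarded. Both the threshold and the required fraction of bases are
configurable, and a whole-read mode is provided (`quality_scope="read"`) since
it is equally defensible to filter before trimming. Note an interaction with
the simulator defaults: under a truncated-Gaussian quality model with mean 36
and sd 2, about 10 % of bases fall below Q 34, so the all-27-bases reading
passes only ~5 % of error-free reads; analyses of error-free synthetic runs
therefore set `q_min=0` (errors are what the filter exists to remove), or use
the fractional mode.

Identical inserts are collapsed into nucleotide variants (read support
conserved), translated in frame 0 with the standard genetic code — inserts
containing `N` or encoding a stop are rejected and tallied — and synonymous
variants are collapsed into peptide records carrying total read count and the
number of distinct encodings.

## Motif counting and tissue selectivity

Each 9-mer contributes its seven overlapping 3-mers. The default counting
unit is *unique peptide*: each distinct peptide contributes each of its
distinct 3-mers once, so deep resequencing of one clone cannot inflate a
motif; a read-weighted mode is provided. Frequencies are percentages of the
tissue's total motif tally. For the heatmap, motifs below 0.0125 % (1/8000,
the expected frequency of one motif under a uniform tally of all 8000
possible 3-mers) in every sample are dropped and both axes are clustered with
Ward linkage on Euclidean distance over the raw percentages (no
transformation).

Selectivity of motif *m* in a tissue against a normalizing sample (unselected
library by default; pooled other tissues or serum as alternatives — serum and
the library are excluded from the pool) is tested on the 2×2 table

    [[a, T_t − a], [c, T_n − c]]

where `a, c` are the motif's counts and `T_t, T_n` the total motif tallies.
The one-sided p-value is the hypergeometric tail `P(X ≥ a)` with all margins
fixed (`scipy.stats.hypergeom`; verified in the test suite against an exact
integer-arithmetic enumeration of every table with grand total ≤ 200 and
against `scipy.stats.fisher_exact`). Fold change is the frequency ratio
`(a/T_t)/(c/T_n)`; when the normalizer count is zero a Haldane-style 0.5
pseudocount is added to both numerator cells *for the fold only*, keeping
volcano plots finite without perturbing the test. Benjamini–Hochberg
correction is applied per (tissue, normalizer) family over all motifs tested
there (`statsmodels`; oracle-checked against an independent step-up
implementation), and a motif is called tissue-selective when adjusted
p < 0.05 **and** fold > 2. Depletion is out of scope: the test is one-sided
toward enrichment.

## EBU co-occurrence networks

Nodes are the tissue-selective motifs present in at least one recovered
peptide; an undirected edge weighted by the number of *distinct* peptides
containing both motifs (as possibly overlapping substrings) connects each
co-occurring pair. Edges with weight < 20 are filtered for display — the full
network is always retained in analysis outputs. Components are classified:

- **isolated** — a node with no surviving edges;
- **simple** — every edge of the component joins motifs that overlap by at
  least one residue in some supporting peptide (chain extension of a primary
  EBU into a longer motif, e.g. LMH/MHP/HPG inside `…LMHPG…`);
- **complex** — any component with an edge whose motifs only ever co-occur
  without overlapping (independent EBUs at variable spacing, e.g. VGS/SEG
  found both fused as `VGSEG` and separated by a two-residue gap).

The overlap threshold is configurable (`min_overlap`). One residue is the
default deliberately: in a chain of three consecutive windows the outer pair
(LMH–HPG) shares only one residue, so requiring a two-residue overlap would
misclassify the canonical chain as complex. Overlap is evaluated at actual
occurrence positions in supporting peptides, not on the motif strings,
because two motifs can overlap in one peptide and be disjoint in another.
The classification rule is an operational formalization of narratively
defined interaction types and is recorded as such in exported node metadata.

## Biodistribution arithmetic

TU/g = colonies × dilution / tissue mass in the titered aliquot; virions =
TU / batch infectivity (infectivity = biological titer / physical titer of a
standard preparation). qPCR standard curves are least-squares fits of Cq
versus log10(concentration) over ≥ 3 points spanning ≥ 2 decades; efficiency
is `100·(10^(−1/slope) − 1)` (−3.3219 cycles/decade ⇔ 100 %). Unknowns invert
the curve, `dilution × 10^((Cq − b)/m)`, and replicates are reported as
mean ± sample SD (ddof = 1), flagged when CV > 10 % (no outlier rejection).
vir/g = (phage conc ÷ mammalian-gDNA conc) × gDNA yield per gram;
%ID/g = 100 × vir/g ÷ injected dose. gDNA yields are inputs, not estimated.

## The synthetic-data generator

The generator emulates the study design: multiple tissue samples sharing one
background pool of unique 9-mers (uniform residue composition by default —
the composition of an unselected library is configurable but not assumed),
an *independent* draw of the same size standing in for the unselected library
sample (real tissue samples are effectively disjoint subsamples of a ~10⁹
-variant library), planted per-tissue motif enrichments, multinomial read
counts, per-read codon sampling (uniform over synonymous codons by default;
NNK and fixed-codon policies available), 50 % anti-sense reads, random 3′
padding of the 83-nt construct to 150 bp, substitution errors (default
5 × 10⁻⁴–10⁻³ per base is realistic for the platform; the round-trip contracts
use 0), and truncated-Gaussian qualities (mean 36, sd 2, clipped to [2, 40]).
Everything derives from one integer seed; identical configurations produce
byte-identical FASTQ output.

Planting a `fold`-fold enrichment injects motif-bearing peptides (motif at a
uniformly random position, other residues random) until the motif's
unique-peptide count reaches `fold ×` its **analytic** expectation — the
containment probability of the 3-mer in an i.i.d. 9-mer, computed exactly via
the motif's KMP automaton, times the pool size. Targeting the expectation
rather than the realized background draw makes the planted count essentially
deterministic, so recovery contracts test the method, not the luck of one
background sample; `fold = 1` plants nothing. Requested folds below 1 are
rejected as unreachable (peptides can only be added).

What the generator does **not** model — and hence what passing tests do not
establish about real data: PCR amplification bias (the emulated protocol
sequences without bacterial amplification), indels, position-dependent
quality decay, chimeric reads, barcode cross-talk, Phi-X spike-ins, and any
non-uniform residue composition of a real unselected library.

## Problem sizes and numerical choices

Round-trip and strand-handling contracts use 10,000 reads from a 500-peptide
pool; enrichment recovery and null calibration use 8 tissues × 20,000 unique
peptides over 10 seeds (a scale at which a 5-fold planted motif is
unambiguous: expected background count ≈ 17.5, planted ≈ 87); the Fisher
implementation is checked exhaustively against exact integer enumeration for
all 2×2 tables with grand total ≤ 200 (tolerance 1e-12; observed deviation
< 1e-15). Ties in flank matching break leftmost; empty inputs yield empty
outputs with zeroed statistics rather than errors, except where a
precondition is violated (empty motif tables, all-filtered heatmaps,
degenerate standard curves), which raise.

## Known limitations

- The quality filter's published description is one sentence; both the
  threshold semantics (minimum vs fraction of bases) and its scope (insert vs
  whole read) are genuinely open, so both are parameters with the strict
  reading as default.
- "All other tissues" pooling sums raw motif counts across the other tissue
  samples; whether serum belongs in that pool is unspecified upstream, and it
  is excluded here.
- The printed anti-sense downstream flank of the assay disagrees with the
  reverse complement of the sense upstream flank in its last two bases; the
  package derives anti-sense flanks by reverse complement (internally
  consistent, involution-testable) and offers a literal override.
- Component classification formalizes narrative categories; other defensible
  rules (e.g. requiring overlap in *every* supporting peptide) would
  reclassify borderline components.
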