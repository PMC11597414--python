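# Methods

This note documents the models, algorithms, defaults and limitations of
`duimito`.  It states how each quantity is defined and computed; every
empirical claim here is one the test suite or `scripts/acceptance.py`
computes itself.

## Data model and coordinates

A genome is a circular (or linear) DNA string with an ordered feature
list over a closed vocabulary: 13 protein-coding genes (cox1–3, cob,
nad1–6, nad4l, atp6, atp8), 2 rRNAs (rrnS, rrnL) and 22 tRNAs with
serine and leucine isoacceptors kept distinct (trnS1/trnS2,
trnL1/trnL2).  Internally all coordinates are 0-based half-open;
GenBank's 1-based inclusive convention is converted only at the file
boundary, which removes a whole class of off-by-one errors from UR
extraction.  Origin-spanning features on circular genomes are encoded as
`end < start` and all span arithmetic is modulo genome length.  Gene
names are normalized through an editable YAML synonym table; ambiguous
`tRNA-Ser`/`tRNA-Leu` annotations without an anticodon qualifier are
assigned the first unseen isoacceptor with a warning.  Sex type comes
from a `/sex` source qualifier, else a `_F`/`_M` filename suffix, else
`unknown` — the loader never guesses a species/sex mapping.

## Composition and codon usage

Skews follow the strand-asymmetry convention AT skew = (A−T)/(A+T),
GC skew = (G−C)/(G+C).  Ambiguity codes are excluded from all counts and
denominators, so a skew whose denominator is empty is reported as
undefined rather than zero.  Translation uses the invertebrate
mitochondrial code (NCBI table 5) throughout.  A CDS whose length is not
a codon multiple and ends in `T`/`TA` is flagged as an incomplete stop
(completed by transcript polyadenylation).  Because the IUPAC letter D
excludes C while some usages of "ATD" include it, the codon-usage report
carries both readings: the fraction of ATA/ATT/ATG starts (`atd`) and of
all ATN starts (`atn`).

## Divergence

Global alignment is Needleman–Wunsch (biopython's `PairwiseAligner`):
nucleotide scoring 1/−1 with affine gaps −2/−0.5; protein scoring
BLOSUM62 with gaps −11/−1; codon mode aligns the translations and
threads the nucleotides back, so every gap run is a codon multiple.
*p*-distances are uncorrected mismatch fractions over compared columns;
columns containing a gap or ambiguity in either sequence are excluded
(pairwise deletion — for two sequences this coincides with complete
deletion; the option exists for interface symmetry).  For unaligned
equal-length genome pairs the hamming form is used directly.  When
co-optimal alignments exist the reported alignment (and hence *p*) can
depend on argument order; *p* is symmetric for any fixed alignment.

### NG86 dN/dS

The dN/dS estimator is the Nei–Gojobori (1986) counting method, chosen
over ML codon models because it is fully specified, fast at desk scale
and verifiable against a brute-force oracle; its estimates agree with ML
in regime (ω < 1 under purifying selection) but not digit-for-digit, so
comparisons with ML-derived numbers are qualitative.  Definitions:

* **Sites.**  For each codon position, candidate changes that would
  create a stop codon are excluded and the position renormalized to
  contribute exactly one site: if s of the v valid changes are
  synonymous the position contributes s/v synonymous and 1−s/v
  nonsynonymous sites.  This makes N + S = 3 × (codons compared) an
  exact identity, which the property suite asserts.  Site counts are
  averaged over the two sequences.
* **Differences.**  Codon pairs differing at k positions are resolved by
  averaging the synonymous/nonsynonymous step counts over all k!
  minimal mutational pathways, excluding pathways that pass through a
  stop codon (unless every pathway does, in which case all are used).
* **Correction.**  pN = Nd/N and pS = Sd/S receive the Jukes–Cantor
  correction d = −(3/4)·ln(1 − (4/3)p), undefined for p ≥ 3/4; ω is
  undefined when dS is undefined or zero.

Codon columns with gaps, ambiguity codes or stop codons are skipped.
The acceptance suite checks the implementation against an independent
pathway-enumeration oracle on all 61×61 sense-codon pairs, and recovers
simulated ω ∈ {0.05, 0.5, 1.0} within 25 % (median of 20 replicates of
1000 codons at 10 % divergence).

### cox2 modifications and TMH scan

Each input cox2 is translated and globally aligned to a reference
protein.  A run of ≥30 consecutive non-reference codons internal to the
reference span is called an insertion; ≥30 codons beyond the reference
3′ terminus an extension; two disjoint ungapped copies of the reference
(identity > 0.5 each) a duplication.  The 30-codon threshold separates
genuine modifications (reported events start around 86 codons) from
ordinary indels.  Transmembrane helices use a Kyte–Doolittle sliding
window (window 19, mean hydropathy > 1.6, overlapping windows merged) —
a deliberate heuristic stand-in for HMM-based predictors, adequate for
the presence/absence question asked of modified regions.

## Unassigned regions

URs are maximal spans uncovered by any feature; on circular genomes the
gap spanning the origin is a single UR.  "Principal" URs exceed 150 nt;
the single longest UR (LUR) is the control-region candidate (ties go to
the first in genome order and are flagged).  Annotation overlaps are
excluded from URs with a warning.

### Tandem repeats

The scanner is a simplified re-implementation of the Benson-style
algorithm with the published default weights (match 2, mismatch 7,
indel 7, minimum score 50, maximum period 500) and a reporting floor of
1.8 copies; exact agreement with the original tool is not promised and
comparisons with published repeat counts are method-sensitive.
Pipeline: (1) k-mer recurrence distances propose candidate periods;
(2) for each period p, positive runs of the p-shifted match profile
locate candidate arrays; (3) a majority consensus is voted in the
candidate's phase over the whole local window (so every copy
contributes even when the seed segment covers only part of the array);
(4) the window is locally aligned (Smith–Waterman with the 2/7/7
weights) against the unrolled consensus — local alignment bridges
mutation clusters inside one array but terminates across unrelated
sequence; (5) the consensus is re-voted from the aligned span and array
boundaries are extended over exact matches, bridging an isolated
mismatch only when the next three positions match; (6) a consensus
whose own period is a proper divisor (self-identity ≥0.9 at that lag)
is collapsed, and overlapping calls keep the best score with
competitive harmonically-smaller periods superseding their multiples.
Copy number is array length / period to one decimal.  Boundary
resolution is ±a few nucleotides in AT-rich sequence, i.e. roughly
±0.1–0.2 copies at periods of 25–30; the false-positive rate on
i.i.d. uniform 500-mers is below 1 % at the default score.

### G-strings, motifs, homopolymers

G-strings are windows of 18–23 nt with ≥80 % G; qualifying windows are
clustered by overlap and the best window per cluster is reported
(highest G fraction, ties to the longer then leftmost window).  Motif
similarity to the control-region element library is ungapped
sliding-window identity over both orientations; the single best window
is reported when identity exceeds 0.5, ties resolved leftmost with
forward orientation first.  The shipped element library (TAS, CSB1,
mTF1, mt3, mt4) contains **synthetic stand-in sequences** of realistic
length and composition — the file is data, not code, and should be
replaced with curated element sequences for real-data work.
Homopolymer runs of ≥8 nt are tabulated for the UR summary table.

### Secondary structure

Folding is Nussinov base-pair maximization (Watson–Crick plus G:T
wobble, minimum loop 3) — an inventory of pairing capacity, not a
thermodynamic minimum-free-energy structure; no energy or stability
claim attaches to the output.  Stems are runs of ≥5 contiguous nested
pairs; a structure is labelled `stem_loop` when at least one stem
exists, and `hairpin` additionally when some stem has ≥10 pairs closing
a clean loop of ≤10 nt.  These labels are explicit heuristics and must
not be read as reproducing any particular published stem-loop/hairpin
distinction.  Sequences longer than 1000 nt are folded in overlapping
1000-nt windows (step 500, hard cap 3500 nt): pairs spanning farther
than one window are invisible, a deliberate trade of long-range
pairings for desk-scale runtime.  The traceback prefers the pairing
case so maximal structures decompose into visible stems; the pair count
is invariant to that choice and is verified against exhaustive
enumeration for sequences ≤14 nt.

## Gene order

Circular orders are canonicalized by rotation to cox1 (lexicographic
minimum if absent).  Reflection is *not* identified with the original
because all genes in these genomes lie on the forward strand, making
orientation meaningful.  Content differences come from multiset
comparison; breakpoint distance counts directed adjacencies of one
order missing from the other on the shared single-copy gene set.
Transposition search is exact for up to two moved genes (removal
subsets are tried exhaustively) — every single-gene tRNA move is
covered; beyond that a greedy removal is reported and flagged as
non-minimal, since minimal transposition distance is NP-hard.
Conserved clusters are the maximal runs contiguous and co-oriented in
both circular orders; on single-copy inputs their count equals the
breakpoint distance (property-tested).

## Phylogenetic patterns

Neighbor joining (scikit-bio's Saitou–Nei implementation) is plumbing
from a distance matrix to a tree; negative branch lengths are clamped
to zero with a warning.  Classification operates on a **rooted** tree —
"sister group" is root-dependent — so an explicit outgroup is required.
For each species with both F and M tips, rules apply in order:

1. *taxon_joining* — the smallest clade containing F and M holds no
   other sexed tips;
2. *gender_joining* — the sister group of F consists only of other
   species' F tips and the sister group of M only of M tips;
3. *masculinization_signature* — some other species' M tip lies inside
   the smallest clade containing the two species' F tips while this
   species' M attaches outside it; the conspecific partner of the pair
   receives the same label;
4. *indeterminate* otherwise.

Calls are emitted regardless of branch support (supports are carried as
annotations only), and species missing one sex tip are skipped with a
warning.  Singleton-genus cases that satisfy rule 1 are labelled
taxon_joining even where a study might prefer to stay tentative; the
evidence field preserves the clade composition for that judgement.

## Synthetic data

The generator emulates the structure these analyses assume: a circular
genome from a 37-gene template (all forward strand, realistic lengths
summing to ~15 kb before URs; a `scale` factor shrinks PCGs/rRNAs for
desk-scale runs), AT-biased sequence (default 68 % AT), and URs planted
with tandem arrays, a G-string, element motifs and an inverted repeat
so every principal UR can fold.  Planted arrays and G-strings get
guard bases at their edges that break the pattern's continuation,
making the planted extent maximal and hence a well-defined recovery
target.  The G-string's non-G bases are placed in the window interior
shared by all sub-windows so the full window is the best-scoring scan
hit.

F and M derive from a common ancestor by codon-aware substitution:
proposals in a protein-coding gene are rejected if they would create a
stop codon and accepted with probability ω when nonsynonymous
(synonymous and non-coding proposals always accepted); terminal stop
codons are frozen.  Divergence is controlled by realized hamming
p-distance rather than a rate×time parameter, so divergence-recovery
checks are exact by construction; ω control by proposal filtering
creates a genuine dN/dS signal without a full codon-model simulator.
Default ω is 0.1 (strong purifying selection, within the range reported
for mitochondrial PCGs); per-gene overrides are supported.  The M
genome receives 400 extra nt in its LUR by default, echoing the F/M
length asymmetry of real pairs, and rearrangement plans (move,
duplicate, delete) and cox2 modifications (in-frame insertion or 3′
extension, hydrophilic codon composition so no spurious TMH appears)
apply to the chosen genome.

Clade scenarios build an explicit true tree — taxon_joining: recent
F/M splits within species; gender_joining: one ancient F/M split with
mirrored species subtrees; masculinization: a gender-joining history
for exactly two species after which the first species' M is a recent
copy of its F — evolve the ancestor along it (branch lengths are
expected substitution proportions: species splits 0.06, F/M cherry
0.04, ancient gender split 0.12, masculinized copy 0.015, outgroup
0.25), and emit an outgroup genome for rooting.  Every genome passes
the completeness check unless a plan deletes genes, and identical
seeds give byte-identical output.

**What passing tests do and do not show.**  The generator produces
colinear, equal-length, substitution-only divergence with uniform rates
within each class, planted features with clean edges, and clock-like
clade evolution.  Real mitogenomes add indels, rate heterogeneity,
saturation at high divergence, annotation error and repeat arrays with
indel-mutated copies.  Recovery rates measured here are therefore upper
bounds on real-data performance, and the repeat scanner's copy-number
resolution in particular degrades when copies differ by indels.

## Pipeline and reproducibility

A single YAML config drives every threshold (UR thresholds live in one
`URConfig` dataclass); the report carries a provenance block (package
version, seed, config hash, thresholds) and is validated against the
JSON schema in `duimito/data/report_schema.json` by a small structural
validator.  Within a species pair the F cox2 copy serves as the
unmodified reference for its own comparison unless a reference is
configured.  Reruns with the same config and seed produce identical
reports; timestamps appear only in the log.  CLI exit codes are 0
(success), 1 (user error), 2 (internal error).

## Problem sizes used in the shipped checks

Oracle comparisons run the full 61×61 sense-codon grid, 1000 random
folds at ≤14 nt and 1000 random 8-gene permutations.  Parameter
recovery uses genomes at scale 0.3 (≈7 kb) and 1000-codon gene pairs
with 20 replicates per ω.  Planted-feature recovery uses 100 plants per
feature family at generator defaults; scenario classification runs 17
seeds per scenario with 3 species (2 for masculinization) at scale
0.25.  These sizes were chosen to make the whole validation suite a
desk-scale run while keeping every estimate's sampling error well
inside the asserted tolerances.
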