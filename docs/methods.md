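# Methods

This note documents the models, conventions and numerical choices behind
`rlkscan`, and what the simulation-based validation does and does not
establish.

## Sequence handling and pairwise alignment

Sequences are uppercase strings over the IUPAC nucleotide or amino-acid
alphabets; gaps (`-`) are legal only inside alignments.  Coordinates are
0-based half-open internally; all reports print 1-based inclusive
positions, matching the residue-numbering convention of the kinase
literature (e.g. "Thr-204").

Pairwise protein alignment uses BLOSUM62 with affine gaps, open 10 and
extend 0.5, the open cost charged on the first gap residue; in global mode
end gaps are free (the EMBOSS `needle` convention), which is the right
behaviour for kinase-domain fragments that span different subdomain
ranges.  Statistics follow the EMBOSS style: identity, similarity and gap
percentages are all computed over the full alignment length including gap
columns; similarity counts identities plus columns with a positive
substitution score.  Optimal-path ties are broken by the deterministic
traceback order of the dynamic-programming aligner.

## In-silico PCR

Matching is deliberately asymmetric, mirroring wet-lab degenerate priming:
a primer's IUPAC code matches any template base in its expansion, while a
template `N` matches any primer code.  The reverse primer is supplied
5'→3' on the antisense strand and its reverse complement is searched on
the forward strand downstream of the forward site.  Amplicons include both
primer sites; a trimming accessor removes them (trimmed is the pipeline
default, as cloned products are normally stripped of primer sequence
before analysis).  The implementation is checked exactly against a
brute-force IUPAC-expansion scan over all offset pairs.

## ORF screening

Translation runs from the requested frame offset to the last complete
codon; trailing 1–2 nt are ignored; codons containing ambiguity codes
translate to `X` rather than erroring.  A fragment is `intact` iff no
internal stop appears.  Detection of frameshift-degraded copies is a
property of remaining sequence length: with k in-frame codons downstream
of the indel, the chance that the shifted frame is stop-free is about
(58/61)^k, so an indel near the 3' end of a short fragment can escape.
The validation suite therefore asserts the ≥95% detection property for
indels with at least ~80 downstream codons; the generator itself places
indels uniformly.

## Back-translation

A codon-delimited nucleotide alignment is produced by expanding each
protein alignment column to one codon column (`-` → `---`), after
verifying that each CDS translates exactly to its ungapped aligned
protein.  The container enforces: length divisible by 3, whole-codon gap
runs, and stop-free ungapped reading frames.

## Kinase motif annotation

Subdomain anchors are configurable regular expressions with defaults from
the canonical protein-kinase subdomain motifs: glycine loop `G.G..G` (I),
VAIK lysine `[VAIL]A[IVLM]K` (II), alpha-C glutamate context (III, a weak
anchor), catalytic loop `H.[DN][LIVMFA]K..N` (VIB), `D[FLWY][GAS][LIVMFY][ASTCG]`
(VII, DFG) and `[ASG]PE` (VIII, APE).  Anchoring by motif rather than
fixed offset is required because cloned fragments start at different
subdomains.  Anchors are matched left-to-right in subdomain order; a
fragment qualifies as a kinase only if at least two strong anchors match
in order — with these default patterns, random 200-residue sequences are
rejected in ≥99% of draws.  Subdomain spans run anchor-to-anchor (the
last present subdomain runs to the fragment end); boundary conventions
differ between references, and anchor-to-anchor is the choice here.

Invariant residues are audited at anchored offsets; the anchor regexes
deliberately tolerate substitutions at auditable positions (e.g. DFG→DFA
still matches subdomain VII) so that a mismatch yields an `atypical`
classification rather than a missing anchor.  A fragment is atypical iff
at least one anchored invariant mismatches; anchors outside the fragment
are reported `not spanned` and do not count as mismatches.

The RD/non-RD call inspects the residue immediately N-terminal of the
catalytic aspartate — the `[DN]` of the VIB match: arginine → RD,
anything else → non-RD with that residue recorded as the substituent;
fragments not spanning VIB are `undetermined`.  If two candidate loops
match, the leftmost match after subdomain II wins (the pattern already
requires the downstream catalytic-loop lysine and asparagine, which makes
spurious matches rare).

Activation-segment consensus motifs are an editable table of
(offset-from-DFG, allowed residues, weight).  The shipped defaults carry
the functionally characterised residues of the Pto activation segment
(Ser-198, Thr-199 and the P+1-loop Thr-204, at offsets 8/9/14 from the
DFG aspartate) and their BRI1 counterparts with BRI1 Ser-1044 treated as
an insertion so that Ser-1042/Thr-1045 align with Pto Ser-198/Thr-199;
the alternative gap placement (Ser-1042 as the insertion) ships as a
second motif table.  These defaults are an implementer-transcribed
approximation of the full published consensus and are meant to be edited
for serious use.

## Phylogeny

Distances are Poisson-corrected amino-acid distances d = −ln(1 − p) with
rate uniformity among sites, p the proportion of differing residues over
comparable columns.  Gap handling defaults to pairwise deletion — kinase
fragments span different subdomain ranges, and complete deletion would
discard most columns — with complete deletion available.  p ≥ 1 is an
error naming the pair.

Neighbor joining follows Saitou–Nei on the Q criterion.  Ties are broken
by the smallest (i, j) index pair under input label order, making trees
reproducible; negative branch-length estimates are clamped to zero with
the raw value logged (a display/newick convention).  NJ recovers any
additive matrix exactly; the suite verifies this on 50 random trees of
5–12 taxa and cross-checks topologies against an independent NJ
implementation.  Maximum-likelihood tree inference is deliberately out of
scope: the NJ path is the classification backbone.

Bootstrap supports resample alignment columns with replacement; each
internal bipartition of the point-estimate tree is annotated with the
percentage of replicates containing it.  Replicates with undefined
distances are dropped and counted (error above 10%).  Support invariance
to leaf-order permutation holds whenever the distances are generic
(tie-free); with exactly tied distances the NJ tie-break depends on input
order by construction.

Subfamily assignment: a query receives subfamily S iff the smallest
enclosing clade with support ≥ 70% (configurable; the literature speaks
of "highly supported" without one number) contains reference leaves of S
only; mixed or unsupported yields `uncertain`.

## Ka/Ks estimation

The default estimator is Nei–Gojobori (1986) codon counting:

- **sites** — each codon position contributes one site, split by the
  fraction of its three single-nucleotide changes that are synonymous;
  changes to stop codons count as non-synonymous, so S + N = 3 exactly
  per codon; per-pair sites average the two sequences;
- **differences** — for codon pairs differing at k positions, the
  synonymous/non-synonymous step assignment is averaged uniformly over
  all k! minimal pathways, discarding pathways through stop codons (if
  every pathway hits a stop the codon pair is skipped and logged);
- **correction** — Jukes–Cantor d = −(3/4)·ln(1 − (4/3)p) applied to pn
  and ps; p ≥ 3/4 flags the estimate `saturated`.

ω = Ka/Ks with sentinels: Ks = 0 < Ka → +∞; Ka = Ks = 0 → NA.  Codon
columns with a gap or ambiguity in either row are skipped with the count
recorded.  The estimator is symmetric in its arguments and matches
brute-force neighbour/pathway enumeration exactly over all 61×61
sense-codon pairs.

`YN-approx` applies transition/transversion weighting on the same
machinery: kappa is estimated from four-fold degenerate third positions
under the Kimura two-parameter model (fallback 2.0 below 10 such sites;
clipped to [0.1, 20]), then both site fractions and pathway weights carry
κ per transition.  This is a documented approximation of the
Yang–Nielsen (yn00) model, not a reimplementation; analyses record the
method tag, and reproductions of yn00-based window values should be
expected to agree approximately, not exactly.

NG86 assumes no transition/transversion bias.  Under a generating process
with κ = 2 it underestimates ω (measured here: mean ≈ 0.85 at true
ω = 1), because transition-enriched change is disproportionately
synonymous.  The estimator-recovery validation therefore runs under the
estimator's own model (κ = 1), where mean recovered ω is within ±0.1 of
truth for ω ∈ {0.1, 0.5, 1.0} at Ks ≈ 0.3; a companion check shows
`YN-approx` restores ±0.1 recovery under κ = 2.

## Window scans and tests

Windows are 75 nt (25 codons) sliding in 15 nt steps over alignment
coordinates (gap columns count toward the window); an alignment of L nt
yields ⌊(L − 75)/15⌋ + 1 windows.  Within each window, ω is computed for
all unordered member pairs; undefined or saturated values, and pairs with
fewer than 10 comparable codons in the window, are excluded from the mean
and SEM with exclusion counts recorded — exclusion, rather than capping,
prevents arbitrary sentinels from dominating means.

Between-group comparisons use the two-sided rank-sum test on the
per-pair ω samples (exact enumeration when both sides have n ≤ 10,
otherwise the tie-corrected normal approximation), combined with the fold
change of window means; a window is flagged iff p < 10⁻⁴ and fold > 2.
The same machinery supports within-group window-vs-window contrasts
(highest vs lowest mean).  Each window's ω sample can also be tested
against 1 with a one-sided signed-rank test (H1: median > 1): exact
mid-rank sign-flip enumeration for n ≤ 12, normal approximation beyond;
an all-ones sample is degenerate and returns p = 1.

## Variability maps

A codon position is non-synonymously variable within a group iff ≥ 2
distinct amino acids are encoded among the group's gap-free members —
the amino-acid-level operationalisation matching position-shading style
displays.  A position is analysed iff at least one group has the column
gap-free in ≥ 2 members; per-group participation requires the same.
Sharing classes (exclusive / shared-by-2+ / shared-by-all) nest, and the
all-group sharing percentage is reported against both candidate
denominators (variable positions, and 2-plus-shared positions), since
published summaries are not always explicit about which is meant.

## The simulator

The generator emulates families of homologous kinase-domain coding
fragments: an ancestral sequence of uniform sense codons with canonical
anchor motifs planted at fixed offsets, evolved along a star-of-stars
guide tree (between-group branches, then within-group branches; a
balanced two-level option exists) under a continuous-time codon process —
stop-introducing changes forbidden, κ-weighted transitions, and a
region-specific ω multiplier on non-synonymous changes.  Defaults mimic
the empirical scale of degenerate-primer kinase surveys: 4 groups × 8
members, 165 codons (495 nt, the floor of typical fragment lengths),
κ = 2, between-group branch 0.35 and within-group branch 0.12 expected
substitutions per codon site, relaxed ω = 1 over the subdomain I–II,
V–VIA and VII–VIII analogue regions and ω = 0.1 elsewhere.

Branch lengths are calibrated at the ancestral composition (mean site
rate normalisation); a closed-form helper converts a target synonymous
divergence Ks into a branch length, accurate to ≈ 0.3 ± 0.05 in
validation.  The process is per-branch Gillespie event sampling — simple
and auditable against the recorded truth map, which logs every realized
substitution with lineage, position, codon change and syn/non-syn label.
Anchor codons are frozen so structural classification has exact planted
truth; each group's catalytic loop carries Arg (RD) or Cys (non-RD)
according to its flag.  Deterministic planting of shared non-synonymous
positions (half of each group's members switched to an alternative amino
acid) gives the variability module an exact oracle.  Simulation is
gapless by default so the alignment is the true homology; frameshifted
pseudogene copies are generated separately and never enter the codon
alignment.

**What passing these validations shows** — that every stage computes what
it claims on data with known truth, at realistic family sizes and
divergences.  **What they do not show** — robustness to alignment error
(alignments are inputs or true homology here), indel-rich histories,
recombination, heterotachy, or compositional biases of real genomic
sequence; reproduction of published values additionally depends on the
exact estimator variant (yn00 vs NG86) and alignment choices of the
original analyses.

## Pipeline

Stages run in the isolation order of a candidate-gene survey: amplify →
screen → annotate → phylogeny → selection → variability.  Each stage
writes plain-text artifacts (TSV/FASTA/newick) plus a JSON manifest with
the package version, seed, a hash of the scientific configuration and
per-stage counts; the same configuration and seed reproduce every
artifact byte-for-byte.  Any stage error halts the run with the stage
name, preserving completed artifacts.  In simulate mode the amplify stage
flanks each simulated CDS with concrete expansions of the configured
degenerate primers and recovers it by in-silico PCR, so the whole chain
is exercised end to end.

Problem sizes in the shipped tests and acceptance script (families of
4×8 × 165 codons, 100–200 bootstrap replicates, 50 estimator replicates,
20 detection runs) were chosen as the smallest scales at which the
validated properties are statistically unambiguous.
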