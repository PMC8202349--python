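# Methods

This note documents the models and procedures behind `peatmob`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data generators do and do not emulate.

## Read processing

Read pairs are merged by scanning every candidate 3′ overlap length from
`min_overlap` (default 10 nt) up to the shorter mate and selecting the
overlap with the lowest mismatch fraction (ties favour the longer overlap);
the merge is rejected when the best candidate exceeds
`max_mismatch_density` (default 0.25). Within the overlap the base with the
higher phred score is kept along with that score — no posterior
recalibration is attempted. On a phred tie the forward read's base wins,
which is the one asymmetry of the merger: merged output from (r1, r2) and
(r2, r1) are reverse complements of each other except at positions where
two different bases carry identical quality.

The quality filter discards a read iff any contiguous window of 50 nt has a
mean phred strictly below 20. Reads shorter than the window are evaluated
as one full-length window — the strictest reading of "any window". Sliding
means are computed from a cumulative sum, and the windowed decision is
cross-checked in the tests against an exhaustive per-window scan.

Primer matching is anchored at the read ends (amplicon reads begin at the
primers by construction), under IUPAC degeneracy with a configurable
per-primer mismatch budget (default 0). An ambiguous base in the *read*
(e.g. N) matches only the fully degenerate primer code N, so sequencer
uncertainty never satisfies a specific primer position. Every rejection at
every stage carries a reason code, and kept + rejected always equals the
input count.

## OTU inference

Dereplication collapses identical sequences, partitioning counts by sample
and ordering amplicons by decreasing total abundance (ties broken
lexicographically — every downstream tie-break in the package is
lexicographic, for determinism).

Chimera detection uses a deliberately simple, oracle-testable two-parent
model rather than a reimplementation of a published h-score: a query is
flagged iff splitting it at some breakpoint into a prefix matched
end-anchored against one candidate parent and a suffix against a different
parent explains it at least `min_improvement` (default 0.05, identity
fraction) better than the best single parent. De novo candidate parents
must be at least `min_parent_skew` (default 2.0) times more abundant than
the query, since a chimera cannot out-amplify its templates; in reference
mode any two database entries are candidates. Matching is ungapped and
end-anchored, which is exact for the single-crossover chimeras the
generator plants and a reasonable surrogate in general. A query identical
to a parent or database entry can never be flagged (single-parent identity
is already 1).

Reading-frame validation applies to the protein-coding *pmoA* amplicon
classes only. A trimmed sequence passes iff it contains only A/C/G/T, its
length is divisible by three, it begins with the expected serine codon TCG,
ends with the expected codon (TAT for the mb661 class, TCG for the A682
class) and contains no in-frame stop (TAA/TAG/TGA). The frame is anchored
at position 1 of the trimmed amplicon; the gene-numbering coordinates of
the anchor codons (188–190 and 658–660 / 679–681) are carried as metadata
describing where the amplicon sits on the gene, not as frame origins — the
printed gene coordinates are not mutually in frame (the 188→660 span is
473 nt), so anchoring at the amplicon start is the only self-consistent
choice. Validation runs per dereplicated amplicon, which is equivalent to
per read and cheaper. The 16S V3–V4 class skips frame checks entirely.

Clustering is single-linkage at Levenshtein distance ≤ d (default 1), grown
iteratively from unclustered seeds in decreasing-abundance order; the
result equals the connected components of the distance-≤ d graph, and the
tests verify exactly that against a brute-force dynamic-programming oracle.
Edit distances use the edlib library with the distance bounded at d, so
almost all pairs terminate early. The OTU representative is the most
abundant member. The "fastidious" refinement phase of the swarm algorithm
is not implemented.

After taxonomy assignment, OTUs are retained iff the representative length
lies in the closed class window (mb661: 465–474 nt; A682: 492–495; V3–V4:
370–435) and the taxonomy path mentions none of Archaea, chloroplast or
mitochondria (case-insensitive substring test).

## Taxonomy assignment

Reference databases are trimmed to the region between the primer sites
(forward site searched from the 5′ end, reverse-complemented reverse site
from the 3′ end) and dereplicated; identical trimmed sequences that
disagree on taxonomy collapse to the lowest common ancestor — the longest
common prefix of the semicolon paths. LCA is a documented design choice,
preferred over first-hit because it removes input-order dependence; the
same rule resolves tied best alignment scores during assignment.

Alignment is end-to-end (global:global) with affine gaps via biopython's
PairwiseAligner. Scores default to match +5, mismatch −4, gap open −10,
gap extend −1 (a gap of length k costs −10 − (k−1)); these are common
nucleotide defaults for global search tools and are configurable. Percent
identity is matches over alignment columns. There is no default identity
floor for assignment; `min_identity` can be set to blank low-identity
assignments.

## Community statistics

Counts are converted to relative abundances per sample; entries strictly
below `absence_threshold` (0.001) are set to zero with no renormalization.
The log transform maps x → log_b(x) + 1 for x > 0 and leaves zeros at zero
(b = 2 by default, configurable); a matrix containing non-integer values is
first divided by its smallest positive entry, so relative-abundance input
keeps all transformed values non-negative, matching the behaviour of the
reference implementation of this transformation.

Partial RDA centers the response, residualizes response and explanatory
blocks on the conditioning block (site) plus intercept, and takes the
singular decomposition of the fitted values of the residualized regression.
Inertias are on the variance scale (SS/(n−1)), and
conditioned + constrained + unconstrained = total holds to numerical
tolerance in every fit; the whole decomposition is cross-checked against
the R vegan package in the test suite. Rank computations use a
rank-revealing SVD; a term that is constant contributes zero constrained
inertia, while a term aliased with earlier terms or the condition raises an
error naming it.

Permutation tests permute rows of the reduced-model residuals while the
reduced-model fit (condition included) stays in place — the standard scheme
for partial ordination — with p = (1 + #{F\* ≥ F}) / (1 + m); p-values are
therefore bounded below by 1/(m+1). Terms are tested sequentially in
formula order, each against the model containing the preceding terms; axis
tests compare each eigenvalue to the residual mean square under
condition-only residual permutation (a simplification of the marginal axis
test). Type-I error of the term test is verified by simulation to sit
inside the 99 % binomial CI of the nominal 0.05 over 1000 null datasets.

IndVal uses specificity A (group mean over the sum of group means) times
fidelity B (occurrence frequency in the group), with each OTU scored by its
maximum over groups and tested by sample relabeling; "probability of a
higher indicator value" is implemented as a strictly-greater count with
add-one correction, so ties favour non-significance. Grouping is by
treatment only. No multiple-testing correction is applied across OTUs (the
protocol's raw α = 0.001 cutoff); a BH option exists but is off by default.
Exhaustive enumeration of all n! relabelings replaces sampling on request
(used by the tests at n = 4). Kruskal–Wallis tests delegate to scipy with
a guard that returns H = 0, p = 1 for all-identical data.

## Phylogeny

Jukes–Cantor distances use pairwise deletion: only columns where both taxa
have a plain base are compared; d = −(3/4)·ln(1 − 4p/3) is undefined at
p ≥ 3/4 and the offending pair is named in the error. Neighbor joining
follows Saitou–Nei, joining the pair minimizing
Q(i,j) = (r−2)·d(i,j) − R_i − R_j with ties to the smallest active index
pair; the final three lineages are resolved by the three-point formulas
into a trifurcating basal node, so the written tree is unrooted. Negative
branch lengths are clamped to zero, the presentation convention of the
usual tree software. On additive distances the generating tree is recovered
exactly; topology is also cross-checked against scikit-bio's NJ. Bootstrap
support resamples alignment columns with replacement, rebuilds JC+NJ per
replicate, and reports the percentage of replicates containing each
internal bipartition (canonicalized as the split side not containing the
alphabetically first taxon). Multiple sequence alignment itself is out of
scope: the module consumes aligned, equal-length input, with a window
selector for the analysis section (440 columns by default, start
user-chosen).

## Gas physics

Headspace CH₄ mass is n·M with n = f·p·V/(R·T); all mass computations are
linear in fraction, volume and pressure. Pore-water concentration sums the
headspace term and the dissolved term K_H·f·p·V_water and divides by the
extracted pore-water volume (5 mL in a 20 mL vial at 21 °C by default).
The Henry constant defaults to 1.4 × 10⁻³ mol L⁻¹ atm⁻¹ (standard
compilation value for CH₄ in water at 21 °C) and is configurable; no
temperature correction beyond a user-supplied constant is attempted.
Oxidation rates use a zero-order (linear) OLS fit of mass against time over
all timepoints, reported as −slope·24/dry-mass in µg g⁻¹ d⁻¹ with R²;
first-order kinetics are a non-goal. Vial and microcosm pressure default to
1 atm (the incubation protocol notes overpressure without a value), and
soil volume displacement uses wet mass at 1 g/mL, both configurable. The
default microcosm geometry (175 mL bottle, 15 g wet peat, 34 mL added air,
1 mL injected CH₄) gives a 195 mL gas volume and an initial headspace
fraction of 1/195 ≈ 0.51 %.

## Synthetic data

The generators emulate the study conditions with known ground truth:

- **Reference collections** of frame-valid *pmoA*-style amplicons across
  genera (random non-stop codons between the required anchor codons, length
  a multiple of 3 in the class window), each embedded in flanking sequence
  with concrete primer sites. Within-genus divergence is substitution-only
  (default 0.02/site), codon-safe so variants stay frame-valid.
- **Communities** over the crossed design two sites × grazed/exclosed ×
  seasonal dates. Baseline abundances are log-normal (σ = 1); per-sample
  log-normal jitter (σ = 0.3) adds overdispersion; counts are multinomial
  at fixed depth (10 000). Planted bioindicators get their expected
  abundance multiplied by the fold change in the favored treatment only,
  and start from the background *mean* abundance rather than a random draw:
  an extreme draw would shift every background OTU's relative abundance
  between treatments (a compositional effect), making detection reflect the
  draw rather than the planted effect. A synthetic CH₄-rate covariate with
  treatment-dependent mean (200 vs 60 µg g⁻¹ d⁻¹, 15 % CV) accompanies the
  metadata.
- **Paired reads**: fragment = forward primer + amplicon + reverse
  complement of the reverse primer; mates read the fragment ends inward
  (2 × 300 nt by default) and must overlap by at least `target_overlap`.
  Substitutions are i.i.d. per base; qualities follow a MiSeq-like profile
  (37 flat, decaying over the last 60 nt) with Gaussian jitter clamped to
  [2, 40], independent of the planted substitutions. Chimeras are
  single-crossover two-parent hybrids with the breakpoint uniform over the
  central 80 % of the fragment — a crossover in the outer tenth leaves a
  sequence essentially identical to one parent and is not a meaningful
  chimera. Frameshifts are single 1-nt indels. A truth table records every
  read's origin and artifact class.
- **Gas series**: mass(t) = initial − rate·t + Gaussian noise, clipped at
  zero and converted to headspace fractions by inverting the ideal gas law;
  default five timepoints over 44 h.

Not emulated: PCR bias, quality-score miscalibration, chimeras with more
than one crossover, indel-rich error processes, and any correlation between
quality scores and actual errors. Passing tests therefore demonstrate
correctness of the algorithms under these idealized conditions, not
performance on real MiSeq libraries.

## Problem sizes

The test suite and the acceptance script keep simulations at sizes chosen
to exercise each property well while remaining quick: clustering-oracle
equivalence uses 200 random instances of up to 100 amplicons; bioindicator
recovery uses 10 samples per treatment with 40 background OTUs at 10 000
permutations; permutation-test calibration uses 1000 null datasets of 16
samples × 30 OTUs at 199 permutations; artifact recovery uses ~2000 reads
over 8 reference genera. These sizes give stable pass/fail behaviour across
seeds (spot-checked over 20 seeds for the recovery runs).

## Known limitations

- The chimera model is positional and end-anchored; chimeras between very
  similar parents (e.g. congeneric strains a few substitutions apart) are
  intrinsically near-indistinguishable from their parents and can evade it.
- The axis permutation test is a simplification of the marginal test used
  by the reference ordination software.
- The merger does not model quality-aware posterior probabilities; the
  higher-phred base simply wins.
- NJ is the only tree method; likelihood or Bayesian inference is out of
  scope, as is multiple sequence alignment.
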