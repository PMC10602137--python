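# Methods

## Junction convention and matching model

A junction is the amino-acid V(D)J recombination product from the
conserved cysteine (IMGT position 104) through the conserved
phenylalanine/tryptophan (position 118); CDR3 is the junction minus those
two anchors, so junction and CDR3 nucleotide lengths differ by a constant
6 nt.  Lengths reported "in nt" are 3 × AA length when only the protein
sequence is known.  Comparisons are made at the amino-acid level by
default; sequences are canonicalized to uppercase.

The distance between junctions is the unit-cost Levenshtein distance
(substitution, insertion, deletion each cost 1).  Matching a query
repertoire against a subject repertoire evaluates, per unique query
junction, the minimum distance to the subject under a cutoff `k`
(default 1): candidate pairs with length difference above `k` are skipped
outright, distance 0 is resolved by hashing, and remaining candidates run
a banded dynamic program restricted to a diagonal band of half-width `k`.
These shortcuts are exact — the test suite checks identity with an
all-pairs full-matrix computation, and the scalar distance against an
independent external implementation (edlib).  Queries whose minimum
distance exceeds the cutoff carry a no-match sentinel rather than an
uncapped minimum; computing the true minimum for every query is exactly
the quadratic work the pruned matcher exists to avoid, and no downstream
analysis needs distances beyond the cutoff.  A query matching several
subject junctions counts once in per-junction tallies, so fractions are
per unique junction.

A query junction is called a tissue ("PIT") match when its minimum
distance is 0 or 1.  For distance-1 pairs the mismatch position is the
1-based index on the query of the substituted residue, or for an indel
the leftmost position at which optimal alignments disagree (an insertion
at the very end of the query is anchored at the last query position so
the anchor stays on the query).  Positions are localized to germline
regions using the decomposition below: position ≤ v3_len_aa → V region;
position > length − j5_len_aa → J region; otherwise the non-templated
recombination region.  V/J gene identity between matched records is by
name with allele suffixes stripped (`TRAV12-2*01` ≡ `TRAV12-2`).

## Sequence features

Hydrophobicity is the arithmetic mean of per-residue Eisenberg consensus
values (packaged as a data file; the scale spans −2.53 for arginine to
1.38 for isoleucine, with proline 0.12 and tyrosine 0.26 unit-tested as
anchors).

Germline decomposition of a junction nucleotide sequence is greedy: the
V 3' contribution is the longest junction prefix equal to the germline V
read from the conserved-Cys codon; the J 5' contribution is then the
longest remaining suffix equal to the germline J 5' end; the remainder is
non-templated N (P-addition nucleotides are folded into N, not modeled
separately).  Greediness over-assigns germline when an N nucleotide
coincides with the next germline nucleotide, so the reported v3 is an
upper bound and n a lower bound; the expected over-assignment per
boundary is below Σ_k 4^(−k) = 1/3 nt, and an exhaustive split-enumeration
oracle bounds the error in tests.  A full IMGT-alignment-style
decomposition was deliberately not attempted: its exact tie-breaking is
not reproducible from public descriptions, while the greedy rule is
simple, deterministic and has a provable bias direction.  Junctions whose
first three nucleotides do not match germline V are flagged
decomposition-failed rather than raising.

Back-translation of AA-only junctions ("stitching") fills the longest
AA prefix matching the germline V translation with germline codons,
likewise the longest suffix from germline J, and back-translates interior
residues with the most-frequent human codon per residue (packaged table).
The output always translates back to the input; for fully germline
junctions the decomposition of the stitched sequence returns n = 0.

Clonality flags: a junction is public when observed in ≥ 2 donors and
expanded when some single donor contributes ≥ 2 distinct cells with it
(within-donor expansion is the biologically coherent reading; a junction
recurring across donors is publicity, not clonal expansion).

## Statistics

Fisher 2×2 comparisons report the sample odds ratio and its log2; when a
cell is zero, the Haldane–Anscombe 0.5 correction is applied for the
estimate and CI while the exact p-value always uses raw counts.  The 95%
CI is the Woolf logit interval (the source analyses display CIs without
naming a method; Woolf is the standard closed form for the sample OR).
Wherever adjusted p-values appear, the correction is Benjamini–Hochberg
(again the source names none; BH is the field default for per-gene
scans).  The match-count threshold curve is compared to the equivalence
line by OLS of reference counts on query counts with intercept and a
t-test of slope = 1; the exact regression specification behind the
published slope is unstated, so OLS-with-intercept is the documented
default, not a claim of equivalence.  Set overlap uses the upper-tail
hypergeometric probability with a configurable universe size (default:
the number of unique junctions analyzed).  Feature distributions are
compared with two-sample Kolmogorov–Smirnov tests (asymptotic p,
one-sided alternatives supported).  Regressions with numerically exact
fits (residual sum of squares at floating-point zero) report p = 1 or 0
directly instead of evaluating a 0/0 t statistic.

Group-level analyses compute matched fractions per disease group
(optionally stratified by expansion, optionally down-sampled to equal
group sizes with a mandatory seed) with all pairwise Fisher tests
BH-adjusted; donor-level analyses compare per-donor matched fractions
between groups by two-sided Wilcoxon rank-sum, skipping pairs where a
group has fewer than two donors.

## Structure contacts

Structure models are read from PDB-format files (ATOM records; HETATM
ignored) via gemmi, with chain roles supplied by the caller.  A TCR
residue is a peptide contact when any of its atoms (hydrogens included if
present) lies strictly closer than the cutoff (default 5 Å) to any
peptide-chain atom; contacts are counted at residue level, once per
residue.  The k-d-tree acceleration is checked against an all-pairs scan.
Contacts map to externally supplied per-chain region intervals
(overlapping intervals are rejected; unannotated residues count as
"other").  The CDR1:CDR3 contact ratio is regressed on alpha junction
length by OLS with a slope-zero t-test; models with zero CDR3 contacts
have an undefined ratio and are excluded and counted.

## Synthetic data generator

The generator emulates the study conditions, not any specific dataset.
Its packaged germline set is synthetic but IMGT-shaped: 8 TRAV, 6 TRAJ,
6 TRBV, 1 TRBD and 6 TRBJ alleles with realistic segment lengths,
annotated FR1–FR3/CDR1/CDR2 (V) and FR4 (J) intervals, V junction
contributions of 15 nt beginning at the conserved Cys codon, and J
junction contributions of 30 nt ending at the conserved Phe codon.  CDR1
lengths are 15 nt for TRAV12-2, 18 nt for TRAV41 and 21 nt for
TRAV4/TRAV26-2, mirroring the gene-length structure that underlies the
CDR1-shift observation.  Junction-proximal germline sequence is generated
stop-free in all three reading frames, so trimming and frame shifts can
never read through a stop codon and the N-length distribution is never
distorted by rejection.

Per junction: V and J are drawn by configurable usage weights (uniform
default), V 3' trims are uniform on 0–6 nt and J 5' trims uniform on
0–8 nt (clamped to keep the anchor codons), and the N insertion length is
Poisson with mean 4 nt, frame-completed by the smallest adjustment that
makes the junction length divisible by 3 (+1 for a 2-residue excess, −1
for a 1-residue excess unless N is empty, then +2).  The resulting
baseline junctions have a median length of 42 nt (14 AA).  Free
(non-templated) nucleotides are drawn codon-wise conditioned on the fixed
germline positions, excluding stop codons.  Clone sizes are geometric
(default p = 0.8); donors default to 11 healthy control, 26 new-onset and
16 established-diabetes donors at 50 cells each.

Planted-shared clones are drawn from a shifted regime that states the
direction-of-effect conditions: N mean 2 nt (median junction 39 nt, one
residue shorter) and a hydrophobic tilt that samples N-overlapping codon
completions with weight exp(2.0 × Eisenberg), chosen a priori to yield
about a +0.05 median hydrophobicity shift.  Two-compartment simulation
plants an exact number of shared junctions verbatim in both compartments
(distance 0), optionally plus single-substitution variants (distance
exactly 1), and generates all other junctions with rejection against
cross-compartment identity, so planted counts are exact by construction.
Toy structure models place a 9-residue peptide along an axis, planned
contact residues ~3.6–3.7 Å away and all other residues ≥ 20 Å away,
giving more than 1 Å of margin on both sides of the 5 Å cutoff.

What the generator does **not** emulate: human V/J usage biases and
recombination statistics (no IGoR/OLGA-style inference), D-segment
decomposition for TRB, allele-level variation, sequencing error, or HLA
structure in donor assignment.  Passing tests therefore demonstrate that
the pipeline recovers planted truth and stated effect directions under a
simplified but structurally faithful model of V(D)J recombination — not
that any specific biological dataset would reproduce particular values.

## Problem sizes and numerical choices

Simulation-based tests use the cohort-scale unique-junction counts
(1,606 query / 9,798 subject) where the check concerns printed
percentages, and 200–800 junctions per side elsewhere; feature-shift
recovery uses 200 replicates of 500 junctions per group (length shift
held to α = 1e−4, the subtler hydrophobicity shift to the conventional
α = 0.05 with a median-sign requirement); null calibration pools ~1,000
p-values from KS, rank-sum and slope tests on effect-free data.  The
V-gene recovery check counts false positives in the planted direction
only, because boosting two genes compositionally depletes the remaining
ones — direction-blind counting would flag that true depletion as error.
Seeds are mandatory for every stochastic operation and recorded in run
manifests; reruns with the same configuration are byte-identical for all
deterministic outputs.

## Default filtering rules

The exact pre-analysis filtering used for the original repertoires is
not public; the defaults here are explicit and individually switchable,
not claimed to match: junction starts with C, ends with F or W, contains
no X or stop symbol, and is 6–30 AA long.  Removal counts are reported
per rule.

## Known limitations

The greedy decomposition's germline bias (documented above) slightly
deflates N-length estimates (~0.5 nt at N ≈ 5).  The mini germline set's
junction space is far smaller than the human locus, so chance distance-1
matches are more frequent in simulation than in real repertoires; exact
(distance-0) planted counts are unaffected.  The CLI's `enrich` and
`features` stages assume single-chain (TRA) tables; paired-chain analyses
are library-level operations.
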