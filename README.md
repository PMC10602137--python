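# pitmatch

TCR junctions as clonal barcodes: edit-distance matching of T cell
receptor alpha junctions between a blood repertoire and a tissue
repertoire, with the statistics and sequence-feature analyses needed to
interpret the overlap.

## The problem

Islet antigen reactive (IAR) CD4+ T cells circulate at very low frequency
in the blood of people with, or at risk of, type 1 diabetes.  Whether
those circulating cells are connected to the T cells actually
infiltrating the pancreas (PIT, pancreatic infiltrating T cells) cannot
be tested by biopsy.  Because V(D)J recombination makes TCR junction
sequences extraordinarily diverse, a junction shared between a blood
repertoire and a tissue repertoire is unlikely by chance and can be used
as a barcode linking the two compartments.

`pitmatch` implements that barcode analysis for anyone with AIRR-style
rearrangement tables: immunologists quantifying repertoire overlap
between compartments or cohorts, and methodologists who need a tested,
seeded reference implementation with a synthetic ground-truth generator.

## The method

Given a deduplicated query repertoire Q (blood) and subject repertoire S
(tissue), the matcher computes for every unique junction q ∈ Q the
minimum Levenshtein distance min_{s∈S} Lv(q, s), where Lv is the
unit-cost edit distance over amino-acid junctions (IMGT convention:
conserved C104 through F/W118).  A query junction is a *PIT match* when
its minimum distance is 0 (Lv0) or 1 (Lv1).  Candidate pairs are pruned
by length difference and evaluated with a banded dynamic program; results
are identical to the all-pairs full matrix (property-tested against an
independent oracle).

Around the matcher:

* **enrichment**: Fisher's exact test on matched/non-matched counts with
  log2 odds ratios and Woolf 95% CIs, seeded down-sampling of unselected
  repertoires, a slope test of match-count curves against the equivalence
  line, hypergeometric overlap of junction sets, two-sample
  Kolmogorov–Smirnov feature comparisons, per-V-gene enrichment with
  Benjamini–Hochberg correction, and disease-group / donor-level
  match-fraction analyses;
* **features**: junction length (nt = 3 × AA), mean Eisenberg
  hydrophobicity, greedy germline decomposition of the junction into
  V 3' / non-templated N / J 5' nucleotides, CDR/FR region lengths from
  germline annotation, public (≥ 2 donors) and expanded (> 1 cell in a
  donor) flags, and Stitchr-style germline-guided back-translation of
  AA-only junctions;
* **contacts**: residues of a TCR–pMHC structure model with any atom
  strictly within 5 Å of the peptide chain, mapped to CDR/FR intervals,
  and the regression of the alpha CDR1:CDR3 contact ratio on junction
  length;
* **synthetic data**: a V(D)J-style generator (packaged mini germline
  set, exonuclease trimming, frame-completed Poisson N insertion,
  geometric clone sizes, planted cross-compartment sharing with feature
  shifts, toy structure models) that records ground truth for every
  junction, so every pipeline stage can be tested against planted truth.

## Worked example

Match the packaged blood/tissue worked-example TCR set and test
enrichment with printed cohort counts (47 of 1,606 blood junctions
tissue-matched, versus 22 of 1,606 from an unselected repertoire):

```python
from pitmatch import fisher_or, hydrophobicity, levenshtein, match_junctions, dedupe
from pitmatch.reference_data import perfect_match_pairs

# ... build repertoires from the packaged table (see tests/test_acceptance.py)
table = match_junctions(blood, tissue, max_distance=1)
print(f"perfect matches: {len(table.matched_at(0))}/{len(table.min_distance)}")

res = fisher_or([[47, 1559], [22, 1584]])
print(f"log2 OR = {res.log2_odds_ratio:.3f}  "
      f"95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]  p = {res.p_value:.2e}")
print(f"hydrophobicity('CAVRMNTGFQKLVF') = {hydrophobicity('CAVRMNTGFQKLVF'):.3f}")
print("levenshtein('CASSPQGGNTEAFF', 'CASSVQGGNTEAFF') =",
      levenshtein('CASSPQGGNTEAFF', 'CASSVQGGNTEAFF'))
```

prints

```
perfect matches: 10/10
log2 OR = 1.118  95% CI [0.381, 1.855]  p = 3.20e-03
hydrophobicity('CAVRMNTGFQKLVF') = 0.137
levenshtein('CASSPQGGNTEAFF', 'CASSVQGGNTEAFF') = 1
```

All ten worked-example blood TRA junctions match their tissue
counterparts exactly; the 2×2 enrichment gives a log2 odds ratio above 1
(more than two-fold enrichment of tissue matches among blood-reactive
junctions); the two multi-specific TRB junctions differ by a single
residue.

A full simulated run (simulate → filter/dedupe → match → features →
enrich → contacts, with a reproducibility manifest):

```bash
pitmatch run --config config.json --out-dir out/
```

where `config.json` names a seed, e.g.
`{"seed": 1, "simulation": {"n_blood_unique": 300, "n_tissue_unique": 800}}`.

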