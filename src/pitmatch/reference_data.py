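"""Curated reference TCR sets packaged with the library.

Three small published sequence tables serve as worked examples and ground
truth for the matcher:

* perfect-match pairs — blood (IAR) and pancreas (PIT) TCRs sharing
  identical TRA junctions, with their quite different TRB partners;
* single-mismatch sets — islet-specific reference TRA junctions with
  variants observed in tissue at exactly one residue change each;
* multi-specific clones — three cross-reactive TCRs with an identical TRA
  chain and TRB junctions differing pairwise at a single position.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("pitmatch.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def perfect_match_pairs() -> pd.DataFrame:
    """Blood/tissue TCR pairs with perfectly matched TRA junctions.

    Columns: pair_id, source (IAR blood / PIT tissue), locus, v_gene,
    junction_aa, j_gene.  One tissue TRB partner was not determined and is
    absent.
    """
    return _load("reference_matched_pairs.tsv")


def single_mismatch_sets() -> pd.DataFrame:
    """Islet-specific reference junctions with distance-1 tissue variants.

    Columns: set_id (specificity), role (reference/variant), locus,
    v_gene, junction_aa, j_gene.
    """
    return _load("reference_mismatch_sets.tsv")


def multispecific_clones() -> pd.DataFrame:
    """Three cross-reactive clones sharing one TRA chain; TRB junctions
    differ pairwise at exactly one residue."""
    return _load("reference_multispecific.tsv")
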