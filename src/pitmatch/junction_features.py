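"""Per-junction sequence features.

Covers junction lengths (a junction of L residues spans 3L nucleotides),
mean Eisenberg hydrophobicity, germline decomposition of the junction into
V 3' / non-templated N / J 5' nucleotide contributions, CDR/FR region
lengths read from germline annotation, public/expanded clonality flags,
and germline-guided reconstruction of a plausible nucleotide sequence from
an amino-acid junction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from pitmatch.errors import ContractError
from pitmatch.repertoire_io import (
    FilterConfig,
    GermlineSegment,
    Repertoire,
    TcrChainRecord,
    passes_filter,
    translate_nt,
)


def _load_scale(name: str) -> dict[str, float | str]:
    with resources.files("pitmatch.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


#: Eisenberg consensus hydrophobicity, one value per standard residue.
EISENBERG: dict[str, float] = {k: float(v)
                               for k, v in _load_scale("eisenberg.tsv").items()}

#: Most-frequent human codon per residue (back-translation default).
HUMAN_CODONS: dict[str, str] = {k: str(v)
                                for k, v in _load_scale("human_codons.tsv").items()}


def hydrophobicity(junction_aa: str,
                   scale: dict[str, float] | None = None) -> float:
    """Mean per-residue hydrophobicity of a junction (Eisenberg scale)."""
    scale = scale if scale is not None else EISENBERG
    if not junction_aa:
        raise ContractError("empty junction")
    junction_aa = junction_aa.upper()
    unknown = set(junction_aa) - set(scale)
    if unknown:
        raise ContractError(f"residues not in scale: {sorted(unknown)}")
    return sum(scale[c] for c in junction_aa) / len(junction_aa)


@dataclass(frozen=True)
class Decomposition:
    """Germline split of a junction's nucleotides (V 3' / N / J 5')."""

    v3_len_nt: int
    n_len_nt: int
    j5_len_nt: int
    ok: bool = True

    @property
    def v3_len_aa(self) -> int:
        return self.v3_len_nt // 3

    @property
    def j5_len_aa(self) -> int:
        return self.j5_len_nt // 3


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix_len(a: str, b: str) -> int:
    return _common_prefix_len(a[::-1], b[::-1])


def decompose_junction(junction_nt: str, v: GermlineSegment,
                       j: GermlineSegment) -> Decomposition:
    """Greedy germline decomposition of a junction nucleotide sequence.

    The V 3' contribution is the longest junction prefix matching the
    germline V read from the conserved-Cys codon; the J 5' contribution is
    then the longest remaining suffix matching the germline J 5' end; the
    remainder is non-templated N.  Greediness can over-assign germline
    nucleotides when an N nucleotide coincides with the next germline one,
    so the reported v3 is an upper bound on (and n a lower bound of) the
    true recombination event.  Palindromic P nucleotides are folded into N.
    """
    if not junction_nt:
        raise ContractError("empty junction_nt")
    junction_nt = junction_nt.upper()
    v_region = v.v_junction_nt()
    j_region = j.j_junction_nt()
    v3 = _common_prefix_len(junction_nt, v_region)
    if v3 < 3:
        return Decomposition(0, len(junction_nt), 0, ok=False)
    rest = junction_nt[v3:]
    j5 = _common_suffix_len(rest, j_region)
    return Decomposition(v3, len(rest) - j5, j5, ok=True)


def decompose_bruteforce(junction_nt: str, v: GermlineSegment,
                         j: GermlineSegment) -> list[tuple[int, int, int]]:
    """All feasible (v3, n, j5) splits by exhaustive enumeration.

    Reference oracle: every split where the prefix matches germline V and
    the suffix matches germline J.  The greedy split is the one maximizing
    v3 first, then j5.
    """
    junction_nt = junction_nt.upper()
    v_region = v.v_junction_nt()
    j_region = j.j_junction_nt()
    max_v3 = _common_prefix_len(junction_nt, v_region)
    out = []
    for v3 in range(0, max_v3 + 1):
        rest = junction_nt[v3:]
        max_j5 = _common_suffix_len(rest, j_region)
        for j5 in range(0, max_j5 + 1):
            out.append((v3, len(junction_nt) - v3 - j5, j5))
    return out


def region_lengths(record: TcrChainRecord | str, v: GermlineSegment,
                   j: GermlineSegment) -> dict[str, int | None]:
    """FR/CDR nucleotide lengths for one chain.

    FR1-FR3 and CDR1/CDR2 come from the V germline annotation, FR4 from
    the J; CDR3 is the junction minus the two conserved anchor residues
    (6 nt).  Regions without annotation are None.
    """
    junction_aa = (record if isinstance(record, str)
                   else record.junction_aa)
    out: dict[str, int | None] = {}
    for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        out[f"{region.lower()}_len_nt"] = v.region_length_nt(region)
    out["fr4_len_nt"] = j.region_length_nt("FR4")
    out["cdr3_len_nt"] = 3 * len(junction_aa) - 6
    return out


def stitch_junction(junction_aa: str, v: GermlineSegment, j: GermlineSegment,
                    codon_policy: str = "human_most_frequent") -> str:
    """Reconstruct a plausible nucleotide sequence for an AA junction.

    The longest junction prefix matching the germline V translation is
    back-filled with germline V codons, the longest suffix matching the
    germline J translation with germline J codons, and interior residues
    are back-translated with the most-frequent human codon per residue.
    The translation of the output always equals the input.
    """
    if codon_policy != "human_most_frequent":
        raise ContractError(f"unknown codon policy {codon_policy!r}")
    if not passes_filter(junction_aa, FilterConfig()):
        raise ContractError(
            f"junction {junction_aa!r} fails the default quality rules")
    junction_aa = junction_aa.upper()
    L = len(junction_aa)

    v_nt = v.v_junction_nt()
    v_aa = translate_nt(v_nt)  # in frame: region starts at the Cys codon
    k_v = _common_prefix_len(junction_aa, v_aa)

    j_nt = j.j_junction_nt()
    off = len(j_nt) % 3  # frame anchored at the conserved F/W codon at the end
    j_nt_inframe = j_nt[off:]
    j_aa = translate_nt(j_nt_inframe)
    k_j = _common_suffix_len(junction_aa, j_aa)
    k_j = min(k_j, L - k_v)

    middle = junction_aa[k_v:L - k_j]
    nt = (v_nt[:3 * k_v]
          + "".join(HUMAN_CODONS[c] for c in middle)
          + (j_nt_inframe[-3 * k_j:] if k_j else ""))
    assert translate_nt(nt) == junction_aa
    return nt


@dataclass(frozen=True)
class ClonalityFlags:
    is_public: bool
    is_expanded: bool


def classify_public_expanded(rep: Repertoire) -> dict[str, ClonalityFlags]:
    """Public (seen in >= 2 donors) and expanded (> 1 cell within some
    donor) flags per unique junction."""
    donors: dict[str, set[str]] = defaultdict(set)
    cells: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in rep.records:
        donors[r.junction_aa].add(r.donor_id)
        cells[(r.junction_aa, r.donor_id)].add(r.cell_id)
    out = {}
    for junction, dset in donors.items():
        expanded = any(len(cells[(junction, d)]) > 1 for d in dset)
        out[junction] = ClonalityFlags(is_public=len(dset) >= 2,
                                       is_expanded=expanded)
    return out


@dataclass
class JunctionFeatures:
    """All per-junction features used downstream."""

    junction_aa: str
    length_aa: int
    length_nt: int
    hydrophobicity: float
    v3_len_nt: int | None = None
    n_len_nt: int | None = None
    j5_len_nt: int | None = None
    cdr1_len_nt: int | None = None
    cdr2_len_nt: int | None = None
    cdr3_len_nt: int | None = None
    fr1_len_nt: int | None = None
    fr2_len_nt: int | None = None
    fr3_len_nt: int | None = None
    fr4_len_nt: int | None = None
    is_public: bool = False
    is_expanded: bool = False

    @property
    def v3_len_aa(self) -> int:
        return 0 if self.v3_len_nt is None else self.v3_len_nt // 3

    @property
    def j5_len_aa(self) -> int:
        return 0 if self.j5_len_nt is None else self.j5_len_nt // 3


def compute_features(rep: Repertoire,
                     germline: dict[str, GermlineSegment] | None = None,
                     ) -> dict[str, JunctionFeatures]:
    """Feature table over the unique junctions of a repertoire.

    Germline-dependent features (decomposition, region lengths) are filled
    when a germline set is supplied and the record's V/J alleles resolve;
    otherwise they stay None.
    """
    from pitmatch.repertoire_io import lookup_segment

    flags = classify_public_expanded(rep)
    out: dict[str, JunctionFeatures] = {}
    for r in rep.records:
        jx = r.junction_aa
        if jx in out:
            continue
        feats = JunctionFeatures(
            junction_aa=jx,
            length_aa=len(jx),
            length_nt=(len(r.junction_nt) if r.junction_nt
                       else 3 * len(jx)),
            hydrophobicity=hydrophobicity(jx),
            is_public=flags[jx].is_public,
            is_expanded=flags[jx].is_expanded,
        )
        if germline:
            v = lookup_segment(germline, r.v_gene)
            jseg = lookup_segment(germline, r.j_gene)
            if v is not None and jseg is not None:
                nt = r.junction_nt
                if nt is None and passes_filter(jx):
                    nt = stitch_junction(jx, v, jseg)
                if nt:
                    dec = decompose_junction(nt, v, jseg)
                    if dec.ok:
                        feats.v3_len_nt = dec.v3_len_nt
                        feats.n_len_nt = dec.n_len_nt
                        feats.j5_len_nt = dec.j5_len_nt
                regions = region_lengths(r, v, jseg)
                for key, val in regions.items():
                    setattr(feats, key, val)
        out[jx] = feats
    return out


def features_to_dataframe(features: dict[str, JunctionFeatures]) -> pd.DataFrame:
    rows = []
    for f in features.values():
        d = dict(f.__dict__)
        d["v3_len_aa"] = f.v3_len_aa
        d["j5_len_aa"] = f.j5_len_aa
        rows.append(d)
    return pd.DataFrame(rows)
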