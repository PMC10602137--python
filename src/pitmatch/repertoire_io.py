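"""Reading, validating, filtering and deduplicating TCR repertoires.

A repertoire is a flat table of per-cell chain observations.  Two TSV
dialects are supported: the AIRR Rearrangement column names (``v_call``,
``junction_aa``, ...) and a simple dialect using this package's own field
names.  Germline V/J references are read from FASTA plus a region
annotation table (1-based inclusive intervals on the nucleotide sequence).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from pitmatch.errors import ContractError, ReferenceError_, RowError, SchemaError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
# Records tolerate X (unknown residue) and * (stop) so that filtering rules
# can act on them; strict reading rejects such rows up front.
RECORD_ALPHABET = AA_ALPHABET | {"X", "*"}

LOCI = {"TRA", "TRB"}
COMPARTMENTS = {"blood", "tissue", "unknown"}
DISEASE_GROUPS = {"HC", "1AAb", "2AAb", "newT1D", "T1D", "unknown"}
CELL_TYPES = {"CD4", "CD8", "unknown"}

_NT_ALPHABET = set("ACGT")


def normalize_gene(name: str) -> str:
    """Strip the allele suffix: ``TRAV12-2*01`` -> ``TRAV12-2``.

    Gene identity comparisons are done on the bare name; the allele is kept
    only for germline sequence lookups.
    """
    return name.split("*", 1)[0].strip()


def translate_nt(nt: str) -> str:
    """Translate complete codons with the standard table (trailing remainder
    nucleotides are ignored)."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


@dataclass(frozen=True)
class TcrChainRecord:
    """One chain observation from one cell."""

    record_id: str
    locus: str
    v_gene: str
    j_gene: str
    junction_aa: str
    cell_id: str
    donor_id: str = "unknown"
    junction_nt: str | None = None
    compartment: str = "unknown"
    disease_group: str = "unknown"
    cell_type: str = "unknown"

    def __post_init__(self):
        object.__setattr__(self, "junction_aa", self.junction_aa.upper())
        if self.junction_nt is not None:
            object.__setattr__(self, "junction_nt", self.junction_nt.upper())
        if not self.junction_aa:
            raise ValueError(f"{self.record_id}: empty junction_aa")
        bad = set(self.junction_aa) - RECORD_ALPHABET
        if bad:
            raise ValueError(
                f"{self.record_id}: invalid junction symbols {sorted(bad)}")
        if self.locus not in LOCI:
            raise ValueError(f"{self.record_id}: unknown locus {self.locus!r}")
        for gene, kind in ((self.v_gene, "V"), (self.j_gene, "J")):
            if gene and not gene.startswith(self.locus + kind):
                raise ValueError(
                    f"{self.record_id}: {kind} gene {gene!r} does not match "
                    f"locus {self.locus}")
        if self.junction_nt is not None:
            if len(self.junction_nt) != 3 * len(self.junction_aa):
                raise ValueError(
                    f"{self.record_id}: junction_nt length "
                    f"{len(self.junction_nt)} != 3 x {len(self.junction_aa)}")
            if translate_nt(self.junction_nt) != self.junction_aa:
                raise ValueError(
                    f"{self.record_id}: junction_nt does not translate to "
                    "junction_aa")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"{self.record_id}: unknown compartment {self.compartment!r}")
        if self.disease_group not in DISEASE_GROUPS:
            raise ValueError(
                f"{self.record_id}: unknown disease_group "
                f"{self.disease_group!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"{self.record_id}: unknown cell_type {self.cell_type!r}")

    @property
    def v_gene_normalized(self) -> str:
        return normalize_gene(self.v_gene)

    @property
    def j_gene_normalized(self) -> str:
        return normalize_gene(self.j_gene)


@dataclass(frozen=True)
class JunctionTally:
    """Per-junction aggregate: distinct cells, donor set, contributing rows."""

    cell_count: int
    donors: frozenset[str]
    record_ids: tuple[str, ...]


class Repertoire:
    """An ordered collection of chain records with per-junction tallies."""

    def __init__(self, records: list[TcrChainRecord]):
        self.records = list(records)
        self._unique: dict[str, JunctionTally] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Repertoire) and self.records == other.records

    @property
    def unique_junctions(self) -> dict[str, JunctionTally]:
        if self._unique is None:
            cells: dict[str, set[str]] = defaultdict(set)
            donors: dict[str, set[str]] = defaultdict(set)
            rids: dict[str, list[str]] = defaultdict(list)
            for r in self.records:
                cells[r.junction_aa].add(r.cell_id)
                donors[r.junction_aa].add(r.donor_id)
                rids[r.junction_aa].append(r.record_id)
            self._unique = {
                j: JunctionTally(len(cells[j]), frozenset(donors[j]),
                                 tuple(rids[j]))
                for j in cells
            }
        return self._unique

    def junction_set(self) -> set[str]:
        return set(self.unique_junctions)

    def subset(self, predicate) -> "Repertoire":
        return Repertoire([r for r in self.records if predicate(r)])

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["record_id", "locus", "v_gene", "j_gene", "junction_aa",
                "junction_nt", "cell_id", "donor_id", "compartment",
                "disease_group", "cell_type"]
        rows = [{c: getattr(r, c) for c in cols} for r in self.records]
        return pd.DataFrame(rows, columns=cols)


_AIRR_MAP = {
    "sequence_id": "record_id",
    "locus": "locus",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "junction_aa": "junction_aa",
    "junction": "junction_nt",
    "cell_id": "cell_id",
    "donor_id": "donor_id",
    "compartment": "compartment",
    "disease_group": "disease_group",
    "cell_type": "cell_type",
}
_AIRR_REQUIRED = ["locus", "v_call", "j_call", "junction_aa", "cell_id"]
_SIMPLE_REQUIRED = ["locus", "v_gene", "j_gene", "junction_aa", "cell_id"]


def read_repertoire(path, dialect: str = "airr_tsv",
                    on_error: str = "raise") -> Repertoire:
    """Read a repertoire TSV.

    Parameters
    ----------
    path : file path
    dialect : ``airr_tsv`` (AIRR Rearrangement column names) or
        ``simple_tsv`` (this package's own column names).
    on_error : ``raise`` (default) aborts with a :class:`RowError` listing
        the 1-based line numbers of malformed rows; ``skip`` drops them with
        a warning.
    """
    path = Path(path)
    if dialect not in ("airr_tsv", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = _AIRR_REQUIRED if dialect == "airr_tsv" else _SIMPLE_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if dialect == "airr_tsv":
        df = df.rename(columns={k: v for k, v in _AIRR_MAP.items()
                                if k in df.columns})

    records: list[TcrChainRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # line 1 is the header
        d = dict(zip(df.columns, row))
        kwargs = {
            "record_id": d.get("record_id") or f"row{line_no}",
            "locus": d.get("locus", ""),
            "v_gene": d.get("v_gene", ""),
            "j_gene": d.get("j_gene", ""),
            "junction_aa": d.get("junction_aa", ""),
            "junction_nt": d.get("junction_nt") or None,
            "cell_id": d.get("cell_id", ""),
            "donor_id": d.get("donor_id") or "unknown",
            "compartment": d.get("compartment") or "unknown",
            "disease_group": d.get("disease_group") or "unknown",
            "cell_type": d.get("cell_type") or "unknown",
        }
        try:
            rec = TcrChainRecord(**kwargs)
            if set(rec.junction_aa) - AA_ALPHABET:
                raise ValueError(
                    f"junction {rec.junction_aa!r} contains non-standard "
                    "symbols")
            records.append(rec)
        except ValueError as exc:
            bad.append((line_no, str(exc)))
    if bad:
        lines = [ln for ln, _ in bad]
        msg = "; ".join(f"line {ln}: {m}" for ln, m in bad[:10])
        if on_error == "raise":
            raise RowError(f"{path}: {len(bad)} malformed rows ({msg})",
                           lines=lines)
        warnings.warn(f"{path}: skipped {len(bad)} malformed rows ({msg})")
    return Repertoire(records)


def write_repertoire(rep: Repertoire, path, dialect: str = "simple_tsv") -> None:
    """Write a repertoire as TSV (inverse of :func:`read_repertoire`)."""
    df = rep.to_dataframe()
    if dialect == "airr_tsv":
        inv = {v: k for k, v in _AIRR_MAP.items()}
        df = df.rename(columns=inv)
    elif dialect != "simple_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = df.fillna("")
    df.to_csv(path, sep="\t", index=False)


@dataclass
class FilterConfig:
    """Junction quality rules; set a field to None/False to disable it."""

    require_start_c: bool = True
    require_end_fw: bool = True
    forbidden_chars: str | None = "X*"
    min_length_aa: int | None = 6
    max_length_aa: int | None = 30


def _filter_reason(j: str, rules: FilterConfig) -> str | None:
    if rules.require_start_c and not j.startswith("C"):
        return "no_leading_C"
    if rules.require_end_fw and not (j.endswith("F") or j.endswith("W")):
        return "no_trailing_FW"
    if rules.forbidden_chars and any(c in j for c in rules.forbidden_chars):
        return "forbidden_char"
    if rules.min_length_aa is not None and len(j) < rules.min_length_aa:
        return "too_short"
    if rules.max_length_aa is not None and len(j) > rules.max_length_aa:
        return "too_long"
    return None


def passes_filter(junction_aa: str, rules: FilterConfig | None = None) -> bool:
    return _filter_reason(junction_aa, rules or FilterConfig()) is None


def filter_junctions(rep: Repertoire, rules: FilterConfig | None = None,
                     return_report: bool = False):
    """Drop records whose junction violates a quality rule.

    With ``return_report=True`` also returns a dict mapping rule name to the
    number of records it removed (a record is attributed to the first rule
    it violates).
    """
    rules = rules or FilterConfig()
    kept: list[TcrChainRecord] = []
    removed: dict[str, int] = defaultdict(int)
    for r in rep.records:
        reason = _filter_reason(r.junction_aa, rules)
        if reason is None:
            kept.append(r)
        else:
            removed[reason] += 1
    out = Repertoire(kept)
    if return_report:
        return out, dict(removed)
    return out


def dedupe(rep: Repertoire, key: str = "junction_aa") -> Repertoire:
    """Keep one representative record per key, preserving first-seen order.

    ``key`` is ``junction_aa`` or ``junction_vj`` (junction plus normalized
    V and J gene names).  Cell/donor tallies remain available through
    ``unique_junctions`` of the returned repertoire because tallies are
    computed over the *original* records and carried over.
    """
    if key not in ("junction_aa", "junction_vj"):
        raise ContractError(f"unknown dedupe key {key!r}")
    seen: set = set()
    kept: list[TcrChainRecord] = []
    for r in rep.records:
        k = (r.junction_aa if key == "junction_aa"
             else (r.junction_aa, r.v_gene_normalized, r.j_gene_normalized))
        if k not in seen:
            seen.add(k)
            kept.append(r)
    out = Repertoire(kept)
    # carry the full tallies: uniqueness must not destroy cell/donor counts
    kept_j = {r.junction_aa for r in kept}
    out._unique = {j: t for j, t in rep.unique_junctions.items()
                   if j in kept_j}
    return out


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V or J allele with region annotation.

    ``region_bounds`` maps region name (FR1, CDR1, FR2, CDR2, FR3 for V;
    FR4 for J) to a 1-based inclusive (start, end) interval on ``nt``.
    """

    gene: str
    allele: str
    nt: str
    region_bounds: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.gene}*{self.allele}"

    @property
    def aa(self) -> str:
        return translate_nt(self.nt)

    def region_length_nt(self, region: str) -> int | None:
        if region not in self.region_bounds:
            return None
        s, e = self.region_bounds[region]
        return e - s + 1

    def v_junction_nt(self) -> str:
        """V contribution to the junction: the conserved-Cys codon (last
        codon of FR3) through the 3' end of the segment."""
        if "FR3" not in self.region_bounds:
            raise ContractError(f"{self.name}: no FR3 annotation")
        _, fr3_end = self.region_bounds["FR3"]
        return self.nt[fr3_end - 3:]

    def j_junction_nt(self) -> str:
        """J contribution to the junction: the 5' end of the segment through
        the conserved F/W codon (first codon of FR4)."""
        if "FR4" not in self.region_bounds:
            raise ContractError(f"{self.name}: no FR4 annotation")
        fr4_start, _ = self.region_bounds["FR4"]
        return self.nt[:fr4_start + 2]


_V_REGION_ORDER = ["FR1", "CDR1", "FR2", "CDR2", "FR3"]


def _parse_header(header: str) -> tuple[str, str]:
    # IMGT-style pipe-delimited headers keep the allele in field 2
    name = header.split("|")[1] if "|" in header else header.split()[0]
    if "*" in name:
        gene, allele = name.split("*", 1)
    else:
        gene, allele = name, "01"
    return gene, allele


def read_germline(fasta, regions) -> dict[str, GermlineSegment]:
    """Load germline segments from FASTA plus a region annotation TSV.

    The region table has columns ``allele`` (full name, e.g.
    ``TRAV12-2*01``), ``region``, ``start``, ``end`` with 1-based inclusive
    coordinates.  Returns a dict keyed by full allele name.
    """
    seqs: dict[str, str] = {}
    meta: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        gene, allele = _parse_header(rec.description)
        name = f"{gene}*{allele}"
        seqs[name] = str(rec.seq).upper()
        meta[name] = (gene, allele)
    df = pd.read_csv(regions, sep="\t", dtype={"allele": str, "region": str,
                                               "start": int, "end": int})
    missing_cols = {"allele", "region", "start", "end"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"region table missing columns {missing_cols}")
    bounds: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)
    for row in df.itertuples(index=False):
        if row.allele not in seqs:
            raise ReferenceError_(
                f"region row references absent allele {row.allele!r}")
        n = len(seqs[row.allele])
        if not (1 <= row.start <= row.end <= n):
            raise ReferenceError_(
                f"{row.allele} {row.region}: bounds {row.start}-{row.end} "
                f"outside sequence of length {n}")
        bounds[row.allele][row.region] = (int(row.start), int(row.end))

    out: dict[str, GermlineSegment] = {}
    for name, nt in seqs.items():
        b = bounds.get(name, {})
        ordered = [r for r in _V_REGION_ORDER if r in b]
        prev_end = 0
        for r in ordered:
            s, e = b[r]
            if s <= prev_end:
                raise ReferenceError_(
                    f"{name}: region {r} overlaps or is out of order")
            prev_end = e
        for r in ("CDR1", "CDR2"):
            if r in b:
                s, e = b[r]
                if (e - s + 1) % 3:
                    raise ReferenceError_(
                        f"{name}: {r} length {e - s + 1} not divisible by 3")
        gene, allele = meta[name]
        out[name] = GermlineSegment(gene=gene, allele=allele, nt=nt,
                                    region_bounds=dict(b))
    return out


def lookup_segment(germline: dict[str, GermlineSegment],
                   gene_name: str) -> GermlineSegment | None:
    """Find a segment by exact allele name or by bare gene name (first
    allele in sorted order)."""
    if gene_name in germline:
        return germline[gene_name]
    base = normalize_gene(gene_name)
    candidates = sorted(n for n in germline
                        if normalize_gene(n) == base)
    return germline[candidates[0]] if candidates else None
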