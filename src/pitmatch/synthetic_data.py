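"""Synthetic inputs with recorded ground truth.

Generates V(D)J-style junctions from a packaged mini germline set
(IMGT-shaped: realistic segment lengths with annotated CDR1/CDR2 and FR
intervals, but synthetic sequences), assembles single- and two-compartment
repertoires with controllable clone sizes, trimming, N insertion and
planted cross-compartment sharing, and builds toy TCR-pMHC structure
models with planted per-region peptide contacts.

Two generator regimes mirror the study conditions: the baseline regime
(non-matched junctions) and a shifted regime for planted-shared clones
with a shorter N region (about one residue shorter junctions) and a
hydrophobic tilt of N-encoded residues (about +0.05 mean Eisenberg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from pitmatch.contact_analysis import Atom, StructureModel
from pitmatch.errors import ConfigError
from pitmatch.junction_features import EISENBERG
from pitmatch.repertoire_io import (
    FilterConfig,
    GermlineSegment,
    Repertoire,
    TcrChainRecord,
    passes_filter,
    read_germline,
    translate_nt,
)

_STOPS = {"TAA", "TAG", "TGA"}
_NT = "ACGT"

_CODONS_BY_AA: dict[str, list[str]] = {}
_AA_BY_CODON: dict[str, str] = dict(standard_dna_table.forward_table)
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


def load_mini_germline() -> dict[str, GermlineSegment]:
    """The packaged mini germline set (8 TRAV, 6 TRAJ, 6 TRBV, 1 TRBD,
    6 TRBJ)."""
    data = resources.files("pitmatch.data")
    with resources.as_file(data.joinpath("mini_germline.fasta")) as fasta, \
            resources.as_file(data.joinpath("mini_germline_regions.tsv")) as reg:
        return read_germline(fasta, reg)


# ---------------------------------------------------------------------------
# mini germline construction (used once to write the packaged files; kept
# as tested code so the set can be regenerated or resized)

_MINI_PLAN = {
    # gene: (cdr1_len_nt, cdr2_len_nt, v_tail_after_cys_nt)
    "TRAV1-2": (18, 15, 12),
    "TRAV5": (18, 21, 12),
    "TRAV8-2": (21, 24, 12),
    "TRAV12-2": (15, 15, 12),
    "TRAV13-1": (18, 18, 12),
    "TRAV26-2": (21, 21, 12),
    "TRAV4": (21, 24, 12),
    "TRAV41": (18, 15, 12),
}
_MINI_TRAJ = ["TRAJ8", "TRAJ15", "TRAJ36", "TRAJ44", "TRAJ49", "TRAJ53"]
_MINI_TRBV = ["TRBV5-1", "TRBV7-2", "TRBV9", "TRBV12-4", "TRBV19", "TRBV28"]
_MINI_TRBJ = ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-5",
              "TRBJ2-7"]


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    aas = rng.choice(sorted(set(_CODONS_BY_AA) - {"C", "W"}), size=n_codons)
    return "".join(
        _CODONS_BY_AA[a][rng.integers(len(_CODONS_BY_AA[a]))] for a in aas)


def _stop_free_all_frames(rng: np.random.Generator, length: int) -> str:
    """A random nt string containing no stop codon in any reading frame."""
    while True:
        s = "".join(rng.choice(list(_NT)) for _ in range(length))
        if not any(s[i:i + 3] in _STOPS for i in range(len(s) - 2)):
            return s


def make_mini_germline(seed: int = 20230)\
        -> tuple[dict[str, str], pd.DataFrame]:
    """Build the mini germline set deterministically.

    Returns (sequences keyed by full allele name, region table).  V
    segments carry FR1/CDR1/FR2/CDR2/FR3 annotation with FR3 ending at the
    conserved Cys codon and a 12 nt germline tail into the junction; J
    segments carry FR4 starting at the conserved Phe codon, preceded by a
    27 nt junction contribution stop-free in all frames.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    rows = []
    for gene, (c1, c2, tail) in _MINI_PLAN.items():
        fr1, fr2 = 75, 51
        fr3_body = 36
        parts = {
            "FR1": _random_codons(rng, fr1 // 3),
            "CDR1": _random_codons(rng, c1 // 3),
            "FR2": _random_codons(rng, fr2 // 3),
            "CDR2": _random_codons(rng, c2 // 3),
            "FR3": _random_codons(rng, fr3_body // 3) + "TGT",
        }
        tail_nt = _stop_free_all_frames(rng, tail)
        nt = "".join(parts.values()) + tail_nt
        name = f"{gene}*01"
        seqs[name] = nt
        pos = 1
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
            end = pos + len(parts[region]) - 1
            rows.append({"allele": name, "region": region,
                         "start": pos, "end": end})
            pos = end + 1
    j_genes = _MINI_TRAJ + _MINI_TRBJ
    for gene in j_genes:
        head = _stop_free_all_frames(rng, 27)
        while head[-3:] in ("TTT", "TTC"):
            head = _stop_free_all_frames(rng, 27)
        fr4 = "TTC" + _random_codons(rng, 9)
        nt = head + fr4
        name = f"{gene}*01"
        seqs[name] = nt
        rows.append({"allele": name, "region": "FR4",
                     "start": len(head) + 1, "end": len(nt)})
    for gene in _MINI_TRBV:
        fr1, c1, fr2, c2 = 75, 15, 51, 18
        parts = {
            "FR1": _random_codons(rng, fr1 // 3),
            "CDR1": _random_codons(rng, c1 // 3),
            "FR2": _random_codons(rng, fr2 // 3),
            "CDR2": _random_codons(rng, c2 // 3),
            "FR3": _random_codons(rng, 12) + "TGT",
        }
        nt = "".join(parts.values()) + _stop_free_all_frames(rng, 10)
        name = f"{gene}*01"
        seqs[name] = nt
        pos = 1
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
            end = pos + len(parts[region]) - 1
            rows.append({"allele": name, "region": region,
                         "start": pos, "end": end})
            pos = end + 1
    seqs["TRBD1*01"] = _stop_free_all_frames(rng, 12)
    return seqs, pd.DataFrame(rows)


def write_mini_germline(out_fasta, out_regions, seed: int = 20230) -> None:
    seqs, regions = make_mini_germline(seed)
    with open(out_fasta, "w") as fh:
        for name, nt in seqs.items():
            fh.write(f">{name}\n{nt}\n")
    regions.to_csv(out_regions, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repertoire simulation

@dataclass
class SimulationConfig:
    """Generator settings; the defaults state the emulated study
    conditions.

    ``n_mean`` / ``shared_n_mean`` are Poisson means (nt) for the
    non-templated N insertion of baseline and planted-shared clones; drawn
    lengths are frame-completed by the smallest adjustment (+1 for a
    2-residue excess, -1 for a 1-residue excess unless N is empty, then
    +2) so every junction stays in frame.  ``hydrophobic_tilt`` reweights
    N-encoded residues of shared clones by softmax(tilt * Eisenberg).
    """

    seed: int = 0
    locus: str = "TRA"
    n_donors: dict[str, int] = field(
        default_factory=lambda: {"HC": 11, "newT1D": 26, "T1D": 16})
    cells_per_donor: int = 50
    clone_size_p: float = 0.8          # geometric; mean clone size 1/p
    v_usage: dict[str, float] | None = None
    j_usage: dict[str, float] | None = None
    v_trim_max: int = 6                # uniform 0..max, nt
    j_trim_max: int = 8
    n_mean: float = 4.0                # Poisson nt, baseline clones
    shared_n_mean: float = 2.0         # Poisson nt, planted-shared clones
    hydrophobic_tilt: float = 2.0
    sharing_rate: float = 0.029
    lv1_sharing_rate: float = 0.0
    n_blood_unique: int = 1606
    n_tissue_unique: int = 9798
    max_retries: int = 200

    def __post_init__(self):
        if not (0 <= self.sharing_rate <= 1):
            raise ConfigError("sharing_rate must be in [0, 1]")
        if not (0 < self.clone_size_p <= 1):
            raise ConfigError("clone_size_p must be in (0, 1]")
        if self.n_mean < 0 or self.shared_n_mean < 0:
            raise ConfigError("N-insertion means must be >= 0")


@dataclass(frozen=True)
class GeneratedJunction:
    junction_aa: str
    junction_nt: str
    v_name: str
    j_name: str
    true_v3: int
    true_n: int
    true_j5: int


class JunctionGenerator:
    """Draws in-frame C...F/W junctions with recorded germline truth."""

    def __init__(self, config: SimulationConfig,
                 germline: dict[str, GermlineSegment] | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.germline = germline if germline is not None \
            else load_mini_germline()
        self.rng = rng if rng is not None \
            else np.random.default_rng(config.seed)
        locus = config.locus
        self.v_segs = sorted(
            (s for s in self.germline.values()
             if s.gene.startswith(locus + "V")), key=lambda s: s.name)
        self.j_segs = sorted(
            (s for s in self.germline.values()
             if s.gene.startswith(locus + "J")), key=lambda s: s.name)
        if not self.v_segs or not self.j_segs:
            raise ConfigError(f"no {locus} V/J segments in germline set")
        self.v_weights = self._weights(self.v_segs, config.v_usage)
        self.j_weights = self._weights(self.j_segs, config.j_usage)
        self._aa_order = sorted(EISENBERG)
        tilt = config.hydrophobic_tilt
        w = np.exp(tilt * np.array([EISENBERG[a] for a in self._aa_order]))
        self._tilt_probs = w / w.sum()

    @staticmethod
    def _weights(segs, usage):
        if usage is None:
            return np.full(len(segs), 1 / len(segs))
        w = np.array([usage.get(s.gene, usage.get(s.name, 0.0))
                      for s in segs], dtype=float)
        if w.sum() <= 0:
            raise ConfigError("usage weights sum to zero")
        return w / w.sum()

    def _frame_complete(self, v3: int, j5: int, n: int) -> int:
        r = (v3 + j5 + n) % 3
        if r == 2:
            return n + 1
        if r == 1:
            return n - 1 if n >= 1 else n + 2
        return n

    def _sample_n_nt(self, length: int) -> str:
        idx = self.rng.integers(0, 4, size=length)
        return "".join(_NT[i] for i in idx)

    def generate(self, shifted: bool = False) -> GeneratedJunction:
        cfg = self.config
        for _ in range(cfg.max_retries):
            v = self.v_segs[self.rng.choice(len(self.v_segs),
                                            p=self.v_weights)]
            j = self.j_segs[self.rng.choice(len(self.j_segs),
                                            p=self.j_weights)]
            v_region = v.v_junction_nt()
            j_region = j.j_junction_nt()
            t_v = min(int(self.rng.integers(0, cfg.v_trim_max + 1)),
                      len(v_region) - 3)
            t_j = min(int(self.rng.integers(0, cfg.j_trim_max + 1)),
                      len(j_region) - 3)
            v3 = v_region[:len(v_region) - t_v]
            j5 = j_region[t_j:]
            lam = cfg.shared_n_mean if shifted else cfg.n_mean
            n = self._frame_complete(len(v3), len(j5),
                                     int(self.rng.poisson(lam)))
            nt = self._assemble(v3, j5, n, shifted)
            if nt is None:
                continue
            aa = translate_nt(nt)
            if not passes_filter(aa, FilterConfig()):
                continue
            return GeneratedJunction(
                junction_aa=aa, junction_nt=nt, v_name=v.name, j_name=j.name,
                true_v3=len(v3), true_n=n, true_j5=len(j5))
        raise ConfigError(
            "could not generate a junction satisfying the filter rules; "
            "the length window or germline set makes the config infeasible")

    def _assemble(self, v3: str, j5: str, n: int,
                  shifted: bool) -> str | None:
        """Fill the N nucleotides codon by codon.

        Positions inside the N region are free; positions from the
        germline V 3' / J 5' stay fixed.  For each codon with at least one
        free position the free nucleotides are drawn jointly over all
        completions that avoid a stop codon, weighted by the residue tilt
        for shifted clones (uniform otherwise) — so germline nucleotides
        are never touched and the drawn N length is never revised.
        """
        total = len(v3) + n + len(j5)
        template = list(v3 + "?" * n + j5)
        tilt = (self.config.hydrophobic_tilt if shifted else 0.0)
        for c in range(0, total, 3):
            codon = template[c:c + 3]
            free = [k for k, ch in enumerate(codon) if ch == "?"]
            if not free:
                if "".join(codon) in _STOPS:
                    return None  # pure-germline boundary stop; regenerate
                continue
            options, weights = [], []
            for combo in range(4 ** len(free)):
                trial = codon[:]
                x = combo
                for k in free:
                    trial[k] = _NT[x % 4]
                    x //= 4
                tri = "".join(trial)
                if tri in _STOPS:
                    continue
                aa = _AA_BY_CODON[tri]
                options.append(trial)
                weights.append(np.exp(tilt * EISENBERG[aa]))
            w = np.asarray(weights)
            pick = options[self.rng.choice(len(options), p=w / w.sum())]
            template[c:c + 3] = pick
        return "".join(template)


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["junction_aa", "junction_nt", "v_gene", "j_gene", "true_v3",
            "true_n", "true_j5", "clone_size", "donor_id", "disease_group",
            "compartment", "shared", "shared_lv1"]
    return pd.DataFrame(rows, columns=cols)


def simulate_repertoire(config: SimulationConfig,
                        germline: dict[str, GermlineSegment] | None = None,
                        ) -> tuple[Repertoire, pd.DataFrame]:
    """One-compartment repertoire with clonal expansion.

    Donors are drawn per disease group; clone sizes follow a geometric
    distribution with parameter ``clone_size_p`` truncated to the donor's
    remaining cell budget.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    gen = JunctionGenerator(config, germline, rng)
    records: list[TcrChainRecord] = []
    truth: list[dict] = []
    cell_no = 0
    for group in sorted(config.n_donors):
        for d in range(config.n_donors[group]):
            donor = f"{group}_donor{d}"
            remaining = config.cells_per_donor
            while remaining > 0:
                size = min(int(rng.geometric(config.clone_size_p)), remaining)
                gj = gen.generate()
                for _ in range(size):
                    cell = f"cell{cell_no}"
                    cell_no += 1
                    records.append(TcrChainRecord(
                        record_id=f"r{len(records)}", locus=config.locus,
                        v_gene=gj.v_name, j_gene=gj.j_name,
                        junction_aa=gj.junction_aa,
                        junction_nt=gj.junction_nt, cell_id=cell,
                        donor_id=donor, compartment="blood",
                        disease_group=group))
                truth.append({
                    "junction_aa": gj.junction_aa,
                    "junction_nt": gj.junction_nt, "v_gene": gj.v_name,
                    "j_gene": gj.j_name, "true_v3": gj.true_v3,
                    "true_n": gj.true_n, "true_j5": gj.true_j5,
                    "clone_size": size, "donor_id": donor,
                    "disease_group": group, "compartment": "blood",
                    "shared": False, "shared_lv1": False})
                remaining -= size
    return Repertoire(records), _truth_frame(truth)


def _generate_unique(gen: JunctionGenerator, n: int, forbidden: set[str],
                     shifted: bool = False,
                     max_factor: int = 50) -> list[GeneratedJunction]:
    out: list[GeneratedJunction] = []
    seen: set[str] = set(forbidden)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_factor * max(n, 1):
            raise ConfigError(
                f"could not generate {n} unique junctions; junction space "
                "too small for the requested counts")
        gj = gen.generate(shifted=shifted)
        if gj.junction_aa in seen:
            continue
        seen.add(gj.junction_aa)
        out.append(gj)
    return out


def _mutate_one_residue(gj: GeneratedJunction, rng: np.random.Generator,
                        forbidden: set[str],
                        max_retries: int = 100) -> GeneratedJunction | None:
    """A single interior substitution (keeps the C...F/W anchors) at
    Levenshtein distance exactly 1, with junction_nt kept consistent."""
    aa = gj.junction_aa
    residues = sorted(set(EISENBERG))
    for _ in range(max_retries):
        pos = int(rng.integers(1, len(aa) - 1))
        new = residues[rng.integers(len(residues))]
        if new == aa[pos]:
            continue
        mutated = aa[:pos] + new + aa[pos + 1:]
        if mutated in forbidden or not passes_filter(mutated):
            continue
        codons = _CODONS_BY_AA[new]
        codon = codons[rng.integers(len(codons))]
        nt = gj.junction_nt[:3 * pos] + codon + gj.junction_nt[3 * pos + 3:]
        return replace(gj, junction_aa=mutated, junction_nt=nt)
    return None


def _assemble_compartment(juncs, flags_lv1, shared_flags, config, rng,
                          compartment: str, donor_groups: list[tuple[str, str]],
                          ) -> tuple[Repertoire, list[dict]]:
    records: list[TcrChainRecord] = []
    truth: list[dict] = []
    cell_no = 0
    order = rng.permutation(len(juncs))
    for k, idx in enumerate(order):
        gj = juncs[idx]
        donor, group = donor_groups[k % len(donor_groups)]
        size = int(rng.geometric(config.clone_size_p))
        for c in range(size):
            records.append(TcrChainRecord(
                record_id=f"{compartment}_r{len(records)}",
                locus=config.locus, v_gene=gj.v_name, j_gene=gj.j_name,
                junction_aa=gj.junction_aa, junction_nt=gj.junction_nt,
                cell_id=f"{compartment}_cell{cell_no + c}",
                donor_id=donor, compartment=compartment,
                disease_group=group))
        cell_no += size
        truth.append({
            "junction_aa": gj.junction_aa, "junction_nt": gj.junction_nt,
            "v_gene": gj.v_name, "j_gene": gj.j_name, "true_v3": gj.true_v3,
            "true_n": gj.true_n, "true_j5": gj.true_j5, "clone_size": size,
            "donor_id": donor, "disease_group": group,
            "compartment": compartment, "shared": shared_flags[idx],
            "shared_lv1": flags_lv1[idx]})
    return Repertoire(records), truth


def simulate_two_compartments(config: SimulationConfig,
                              sharing_rate: float | None = None,
                              n_shared: int | None = None,
                              n_lv1: int | None = None,
                              germline: dict[str, GermlineSegment] | None = None,
                              ) -> tuple[Repertoire, Repertoire, pd.DataFrame]:
    """Blood (query) and tissue (subject) repertoires with planted sharing.

    ``n_shared`` junctions (default: sharing_rate x blood unique count)
    are generated under the shifted regime and appear verbatim in both
    compartments; ``n_lv1`` additional pairs are planted at Levenshtein
    distance exactly 1 (base junction in tissue, one-substitution variant
    in blood).  All other junctions are unique to their compartment at
    distance 0 by construction.
    """
    rng = np.random.default_rng(config.seed)
    gen = JunctionGenerator(config, germline, rng)
    rate = config.sharing_rate if sharing_rate is None else sharing_rate
    n_blood = config.n_blood_unique
    n_tissue = config.n_tissue_unique
    if n_shared is None:
        n_shared = round(rate * n_blood)
    if n_lv1 is None:
        n_lv1 = round(config.lv1_sharing_rate * n_blood)
    if n_shared + n_lv1 > min(n_blood, n_tissue):
        raise ConfigError("more planted sharing than unique junctions")

    shared = _generate_unique(gen, n_shared, set(), shifted=True)
    shared_set = {g.junction_aa for g in shared}
    lv1_bases = _generate_unique(gen, n_lv1, shared_set, shifted=True)
    lv1_variants: list[GeneratedJunction] = []
    taken = shared_set | {g.junction_aa for g in lv1_bases}
    for base in lv1_bases:
        var = _mutate_one_residue(base, rng, taken)
        if var is None:
            raise ConfigError("could not plant a distance-1 variant")
        taken.add(var.junction_aa)
        lv1_variants.append(var)

    tissue_only = _generate_unique(gen, n_tissue - n_shared - n_lv1, taken)
    taken |= {g.junction_aa for g in tissue_only}
    blood_only = _generate_unique(gen, n_blood - n_shared - n_lv1, taken)

    tissue_juncs = shared + lv1_bases + tissue_only
    tissue_shared = [True] * n_shared + [True] * n_lv1 \
        + [False] * len(tissue_only)
    tissue_lv1 = [False] * n_shared + [True] * n_lv1 \
        + [False] * len(tissue_only)
    blood_juncs = shared + lv1_variants + blood_only
    blood_shared = [True] * n_shared + [True] * n_lv1 \
        + [False] * len(blood_only)
    blood_lv1 = [False] * n_shared + [True] * n_lv1 \
        + [False] * len(blood_only)

    blood_donors = [(f"{g}_donor{d}", g)
                    for g in sorted(config.n_donors)
                    for d in range(config.n_donors[g])]
    tissue_donors = [(f"organ_donor{d}", "unknown") for d in range(12)]
    blood_rep, blood_truth = _assemble_compartment(
        blood_juncs, blood_lv1, blood_shared, config, rng, "blood",
        blood_donors)
    tissue_rep, tissue_truth = _assemble_compartment(
        tissue_juncs, tissue_lv1, tissue_shared, config, rng, "tissue",
        tissue_donors)
    return blood_rep, tissue_rep, _truth_frame(blood_truth + tissue_truth)


# ---------------------------------------------------------------------------
# structure simulation

#: 1-based residue intervals used for the toy models (IMGT-like layout).
DEFAULT_REGION_ANNOTATIONS: dict[str, dict[str, tuple[int, int]]] = {
    "tcr_alpha": {"FR1": (1, 26), "CDR1": (27, 38), "FR2": (39, 55),
                  "CDR2": (56, 65), "FR3": (66, 104), "CDR3": (105, 117),
                  "FR4": (118, 127)},
    "tcr_beta": {"FR1": (1, 26), "CDR1": (27, 38), "FR2": (39, 55),
                 "CDR2": (56, 65), "FR3": (66, 104), "CDR3": (105, 117),
                 "FR4": (118, 127)},
}

DEFAULT_CHAIN_ROLES = {"A": "tcr_alpha", "B": "tcr_beta", "P": "peptide",
                       "M": "mhc_alpha", "N": "mhc_beta"}


@dataclass
class SimulatedStructure:
    model: StructureModel
    truth_contacts: dict[str, set[int]]
    annotations: dict[str, dict[str, tuple[int, int]]]
    chain_roles: dict[str, str]


def simulate_structure(plan: dict[str, dict[str, int]],
                       seed: int = 0,
                       peptide_length: int = 9,
                       n_residues: int = 127) -> SimulatedStructure:
    """Toy TCR-pMHC model with exactly the planned peptide contacts.

    The peptide lies along the x axis; planned contact residues are placed
    4 Angstrom away (well under the 5 Angstrom cutoff) and every other TCR
    residue at least 20 Angstrom away, giving a comfortable margin on both
    sides.  Coordinates carry a small seeded jitter (<= 0.1 Angstrom).
    """
    rng = np.random.default_rng(seed)
    annotations = DEFAULT_REGION_ANNOTATIONS

    def jitter() -> float:
        return float(rng.uniform(-0.1, 0.1))

    atoms: list[Atom] = []
    for i in range(peptide_length):
        x = 3.5 * i
        atoms.append(Atom("P", i + 1, "ALA", "CA", x + jitter(), jitter(),
                          jitter()))
        atoms.append(Atom("P", i + 1, "ALA", "CB", x + jitter(),
                          1.2 + jitter(), jitter()))

    truth: dict[str, set[int]] = {}
    for chain_id, role, zsign in (("A", "tcr_alpha", 1.0),
                                  ("B", "tcr_beta", -1.0)):
        chain_plan = plan.get(role, {})
        regions = annotations[role]
        contact_set: set[int] = set()
        for region, count in chain_plan.items():
            if count < 0:
                raise ConfigError("negative contact count")
            if region not in regions:
                raise ConfigError(f"unknown region {region!r} for {role}")
            s, e = regions[region]
            if count > e - s + 1:
                raise ConfigError(
                    f"plan wants {count} contacts in {region} of {role} "
                    f"but the region has only {e - s + 1} residues")
            contact_set.update(range(s, s + count))
        truth[role] = contact_set
        for idx in range(1, n_residues + 1):
            if idx in contact_set:
                x = 3.5 * ((idx * 7) % peptide_length) + jitter()
                pos = (x, jitter(), zsign * 3.6 + zsign * abs(jitter()))
            else:
                pos = (3.5 * (idx % peptide_length) + jitter(),
                       25.0 + 4.0 * idx + jitter(), zsign * 12.0 + jitter())
            atoms.append(Atom(chain_id, idx, "GLY", "CA", *pos))
            atoms.append(Atom(chain_id, idx, "GLY", "N", pos[0],
                              pos[1] + 1.0, pos[2]))

    for chain_id, ybase in (("M", -200.0), ("N", -260.0)):
        for idx in range(1, 11):
            atoms.append(Atom(chain_id, idx, "ALA", "CA",
                              3.5 * idx + jitter(), ybase + jitter(),
                              jitter()))

    model = StructureModel(atoms=atoms, chain_roles=dict(DEFAULT_CHAIN_ROLES))
    return SimulatedStructure(model=model, truth_contacts=truth,
                              annotations=annotations,
                              chain_roles=dict(DEFAULT_CHAIN_ROLES))
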