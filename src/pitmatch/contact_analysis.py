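"""Peptide-contact analysis of TCR-pMHC structure models.

Identifies TCR residues with any atom strictly within a distance cutoff
(default 5 Angstrom) of any atom of the bound peptide chain, maps contact
residues to FR/CDR region intervals, and regresses the alpha-chain
CDR1:CDR3 contact ratio on junction length.  Contacts are counted at the
residue level: a residue counts once however many of its atoms are close.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy import stats
from statsmodels.api import OLS, add_constant

from pitmatch.errors import ContractError

TCR_ROLES = ("tcr_alpha", "tcr_beta")
VALID_ROLES = TCR_ROLES + ("peptide", "mhc_alpha", "mhc_beta")


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    atoms: list[Atom]
    chain_roles: dict[str, str]

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def chains_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.chain_roles.items() if r == role]


def load_structure(path, roles: dict[str, str]) -> StructureModel:
    """Read ATOM records from a PDB-format file (HETATM are ignored).

    ``roles`` maps chain id to one of tcr_alpha, tcr_beta, peptide,
    mhc_alpha, mhc_beta; exactly one peptide chain is required and it must
    contain at least one polymer atom.
    """
    for c, r in roles.items():
        if r not in VALID_ROLES:
            raise ContractError(f"unknown chain role {r!r} for chain {c}")
    peptide_chains = [c for c, r in roles.items() if r == "peptide"]
    if len(peptide_chains) != 1:
        raise ContractError("exactly one peptide chain role is required")
    for role in ("tcr_alpha", "tcr_beta"):
        if sum(r == role for r in roles.values()) > 1:
            raise ContractError(f"role {role} assigned more than once")

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    present = set()
    for model in st:
        for chain in model:
            present.add(chain.name)
            for res in chain:
                if res.het_flag != "A":  # skip HETATM
                    continue
                for at in res:
                    atoms.append(Atom(chain.name, res.seqid.num, res.name,
                                      at.name, at.pos.x, at.pos.y, at.pos.z))
        break  # first model only
    missing = set(roles) - present
    if missing:
        raise ContractError(f"role chains absent from file: {sorted(missing)}")
    model = StructureModel(atoms=atoms, chain_roles=dict(roles))
    if not model.chain_atoms(peptide_chains[0]):
        raise ContractError("peptide chain has no polymer atoms")
    for a in atoms:
        if not all(np.isfinite(v) for v in (a.x, a.y, a.z)):
            raise ContractError("non-finite coordinate")
    return model


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file (inverse of load_structure)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    by_chain: dict[str, dict[int, list[Atom]]] = defaultdict(
        lambda: defaultdict(list))
    for a in model.atoms:
        by_chain[a.chain_id][a.residue_index].append(a)
    for cid in by_chain:
        chain = gemmi.Chain(cid)
        for ridx in sorted(by_chain[cid]):
            res_atoms = by_chain[cid][ridx]
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(ridx, " ")
            res.het_flag = "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.element = gemmi.Element(a.atom_name[0])
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(str(path))


@dataclass
class ContactSummary:
    """Residue-level peptide contacts per TCR chain."""

    cutoff: float
    contact_residues: dict[str, set[int]]           # role -> residue indices
    region_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def total_contacts(self, role: str) -> int:
        return len(self.contact_residues.get(role, set()))

    def cdr1_cdr3_ratio(self, role: str = "tcr_alpha") -> float | None:
        counts = self.region_counts.get(role, {})
        cdr3 = counts.get("CDR3", 0)
        if cdr3 == 0:
            return None
        return counts.get("CDR1", 0) / cdr3


def _coords(atoms: list[Atom]) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


def find_peptide_contacts(model: StructureModel, cutoff: float = 5.0,
                          method: str = "grid") -> ContactSummary:
    """TCR residues with any atom strictly closer than ``cutoff`` to any
    peptide atom.

    ``method='grid'`` uses a k-d tree over peptide atoms; ``'brute'`` is
    the all-pairs reference scan.  Both give identical contact sets.
    """
    pep_chain = model.chains_with_role("peptide")[0]
    pep = _coords(model.chain_atoms(pep_chain))
    out: dict[str, set[int]] = {}
    for role in TCR_ROLES:
        chains = model.chains_with_role(role)
        if not chains:
            continue
        tcr_atoms = model.chain_atoms(chains[0])
        if not tcr_atoms:
            out[role] = set()
            continue
        xyz = _coords(tcr_atoms)
        if method == "grid":
            tree = cKDTree(pep)
            dmin, _ = tree.query(xyz, k=1)
        elif method == "brute":
            diff = xyz[:, None, :] - pep[None, :, :]
            dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
        else:
            raise ContractError(f"unknown method {method!r}")
        residues = {a.residue_index
                    for a, d in zip(tcr_atoms, dmin) if d < cutoff}
        out[role] = residues
    return ContactSummary(cutoff=cutoff, contact_residues=out)


def map_contacts_to_regions(summary: ContactSummary,
                            annotations: dict[str, dict[str, tuple[int, int]]],
                            ) -> ContactSummary:
    """Count contact residues per annotated region interval.

    ``annotations`` maps role -> region -> (start, end), 1-based inclusive
    residue indices.  Contacts outside every interval land in ``other``.
    Overlapping intervals for one chain are a contract error.
    """
    region_counts: dict[str, dict[str, int]] = {}
    for role, residues in summary.contact_residues.items():
        regions = annotations.get(role, {})
        items = sorted(regions.items(), key=lambda kv: kv[1][0])
        for (r1, (s1, e1)), (r2, (s2, e2)) in zip(items, items[1:]):
            if s2 <= e1:
                raise ContractError(
                    f"{role}: regions {r1} and {r2} overlap")
        counts = {region: 0 for region in regions}
        counts["other"] = 0
        for idx in residues:
            for region, (s, e) in regions.items():
                if s <= idx <= e:
                    counts[region] += 1
                    break
            else:
                counts["other"] += 1
        region_counts[role] = counts
    return ContactSummary(cutoff=summary.cutoff,
                          contact_residues=summary.contact_residues,
                          region_counts=region_counts)


@dataclass
class ContactRegression:
    slope: float
    intercept: float
    p_slope_zero: float
    n_used: int
    n_undefined: int


def contact_length_regression(summaries, lengths,
                              series: str = "ratio",
                              role: str = "tcr_alpha") -> ContactRegression:
    """OLS of a contact series on alpha junction length.

    ``series`` is ``ratio`` (CDR1:CDR3 contact ratio; models with zero
    CDR3 contacts are excluded and counted) or a region name (per-region
    contact count).  Tests the slope against zero.
    """
    ys, xs = [], []
    n_undef = 0
    for s, length in zip(summaries, lengths):
        if series == "ratio":
            r = s.cdr1_cdr3_ratio(role)
            if r is None:
                n_undef += 1
                continue
            ys.append(r)
        else:
            ys.append(s.region_counts.get(role, {}).get(series, 0))
        xs.append(length)
    if len(xs) < 3:
        raise ContractError("need >= 3 usable paired observations")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    model = OLS(y, add_constant(x)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    if model.ssr <= 1e-12 * max(float(y @ y), 1.0):
        p = 1.0 if abs(slope) < 1e-9 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(slope / se), df=model.df_resid))
    return ContactRegression(slope=slope, intercept=float(model.params[0]),
                             p_slope_zero=p, n_used=len(xs),
                             n_undefined=n_undef)
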