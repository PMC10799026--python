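"""Rigid-body superposition, per-residue deviation output, pocket contacts.

The structural side of the analysis compares GS coordinate models: a
least-squares (Kabsch) superposition of paired C-alpha atoms with
iterative outlier trimming yields global and per-residue deviations;
the per-residue values can be written back into the B-factor column of a
PDB file to drive a "putty" rendering; distance scans list the residues
lining an effector pocket and flag steric clashes when a ligand is
transplanted into a homologous structure.

PDB I/O goes through gemmi; all coordinates are in Angstrom, residue
numbering is taken from the file verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: van der Waals radii (Angstrom) by element symbol.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "MN": 1.61, "ZN": 1.39, "FE": 1.52, "NA": 2.27, "K": 2.75,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    icode: str
    res_name: str
    name: str
    altloc: str
    occupancy: float
    xyz: tuple
    b_factor: float
    element: str
    het: bool = False

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.res_num, self.icode)


@dataclass
class CoordinateSet:
    """A flat list of atoms parsed from (or destined for) a PDB file."""

    atoms: list

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("coordinate set has no atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def chain_atoms(self, chain: str) -> list:
        return [a for a in self.atoms if a.chain == chain]

    def c_alphas(self, chain: Optional[str] = None) -> list:
        return [a for a in self.atoms
                if a.name == "CA" and not a.het
                and (chain is None or a.chain == chain)]

    def ligand_atoms(self, res_name: str, chain: Optional[str] = None) -> list:
        """HETATM atoms of a named residue, e.g. AKG for 2-oxoglutarate."""
        return [a for a in self.atoms
                if a.res_name == res_name and (chain is None or a.chain == chain)]


def read_structure(source: Union[str, Path]) -> CoordinateSet:
    """Parse PDB text (path or literal string) into a CoordinateSet.

    Alternate locations are resolved per (chain, residue, atom name):
    the highest-occupancy conformer is kept, ties going to the
    alphabetically first altloc.
    """
    if isinstance(source, Path) or (isinstance(source, str) and
                                    "\n" not in source and Path(source).exists()):
        st = gemmi.read_structure(str(source), format=gemmi.CoorFormat.Pdb)
    else:
        st = gemmi.read_pdb_string(str(source))
    st.setup_entities()

    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                key = (chain.name, residue.seqid.num, residue.seqid.icode.strip(),
                       atom.name)
                cand = Atom(
                    chain=chain.name, res_num=residue.seqid.num,
                    icode=residue.seqid.icode.strip(), res_name=residue.name,
                    name=atom.name, altloc=(atom.altloc or ""),
                    occupancy=atom.occ,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    b_factor=atom.b_iso, element=atom.element.name.upper(),
                    het=het,
                )
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    kept = best[key]
                    if (cand.occupancy, _alt_rank(cand.altloc)) > \
                       (kept.occupancy, _alt_rank(kept.altloc)):
                        best[key] = cand
    atoms = [best[k] for k in order]
    if not atoms:
        raise ValueError("no atoms in structure")
    return CoordinateSet(atoms=atoms)


def _alt_rank(altloc: str) -> int:
    # higher is better; 'A' (or blank) wins occupancy ties
    if altloc in ("", "A"):
        return 1
    return -ord(altloc)


def to_pdb_string(cs: CoordinateSet) -> str:
    """Serialize a CoordinateSet as PDB text (via gemmi, %8.3f/%6.2f columns)."""
    # group atoms by chain and residue first: gemmi's add_* methods copy,
    # so containers must be complete before insertion
    chain_order: list[str] = []
    residues: dict[str, list[tuple]] = {}
    atoms_by_res: dict[tuple, list] = {}
    for a in cs.atoms:
        if a.chain not in chain_order:
            chain_order.append(a.chain)
            residues[a.chain] = []
        rkey = a.residue_key + (a.res_name,)
        if rkey not in atoms_by_res:
            residues[a.chain].append(rkey)
            atoms_by_res[rkey] = []
        atoms_by_res[rkey].append(a)

    st = gemmi.Structure()
    st.name = "gsreg"
    model = gemmi.Model("1")
    for chain_name in chain_order:
        chain = gemmi.Chain(chain_name)
        for rkey in residues[chain_name]:
            first = atoms_by_res[rkey][0]
            res = gemmi.Residue()
            res.name = first.res_name
            res.seqid = gemmi.SeqId(first.res_num, first.icode or " ")
            res.het_flag = "H" if first.het else "A"
            for a in atoms_by_res[rkey]:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.pos = gemmi.Position(*a.xyz)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                atom.element = gemmi.Element(a.element)
                if a.altloc:
                    atom.altloc = a.altloc
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))


def write_structure(cs: CoordinateSet, dest: Union[str, Path]) -> None:
    Path(dest).write_text(to_pdb_string(cs))


def select_chain_lowest_b(cs: CoordinateSet) -> str:
    """The chain with the lowest mean B-factor (tie-break: alphabetical)."""
    means = {}
    for ch in cs.chains():
        bs = [a.b_factor for a in cs.chain_atoms(ch)]
        means[ch] = sum(bs) / len(bs)
    return min(sorted(means), key=lambda ch: means[ch])


# ---------------------------------------------------------------------------
# Pairing and superposition


@dataclass(frozen=True)
class AtomPairing:
    """Index pairs into two atom lists, plus the mode that produced them."""

    indices_a: tuple
    indices_b: tuple
    mode: str

    def __post_init__(self) -> None:
        if len(self.indices_a) != len(self.indices_b) or not self.indices_a:
            raise ValueError("pairing must be non-empty and one-to-one")

    def __len__(self) -> int:
        return len(self.indices_a)


def pair_c_alpha(a: CoordinateSet, b: CoordinateSet,
                 mode: str = "by_residue_number",
                 chain_a: Optional[str] = None, chain_b: Optional[str] = None,
                 msa=None) -> tuple[AtomPairing, list, list]:
    """Match C-alpha atoms between two structures.

    ``by_residue_number`` pairs CAs sharing a residue number (and
    insertion code) within the selected chains (default: lowest-mean-B
    chain of each). ``by_alignment`` uses a two-row MSA whose rows are
    the two chains' sequences in order; columns where both rows are
    ungapped pair the corresponding CAs ordinally.

    Returns the pairing together with the two CA atom lists it indexes.
    """
    chain_a = chain_a or select_chain_lowest_b(a)
    chain_b = chain_b or select_chain_lowest_b(b)
    cas_a = a.c_alphas(chain_a)
    cas_b = b.c_alphas(chain_b)
    if not cas_a or not cas_b:
        raise ValueError("no C-alpha atoms in one of the selections")

    if mode == "by_residue_number":
        index_b = {(at.res_num, at.icode): j for j, at in enumerate(cas_b)}
        ia, ib = [], []
        for i, at in enumerate(cas_a):
            j = index_b.get((at.res_num, at.icode))
            if j is not None:
                ia.append(i)
                ib.append(j)
    elif mode == "by_alignment":
        if msa is None or len(msa) != 2:
            raise ValueError("by_alignment mode needs a two-row MSA")
        row_a, row_b = msa.records[0].residues, msa.records[1].residues
        ia, ib = [], []
        na = nb = 0
        for ca, cb in zip(row_a, row_b):
            if ca != "-" and cb != "-":
                if na < len(cas_a) and nb < len(cas_b):
                    ia.append(na)
                    ib.append(nb)
            if ca != "-":
                na += 1
            if cb != "-":
                nb += 1
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")

    if not ia:
        raise ValueError("empty pairing")
    return AtomPairing(tuple(ia), tuple(ib), mode), cas_a, cas_b


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, proper
    translation: np.ndarray    # applied as R @ x + t (moves B onto A)
    rmsd: float                # over the pairs used after trimming
    rmsd_all: float            # over all input pairs, final transform
    per_pair_deviation: np.ndarray  # over all input pairs
    n_pairs_used: int
    used_mask: np.ndarray
    trim_history: tuple        # ((n_pairs, rmsd), ...) per iteration


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimising |R q + t - p|.

    SVD-based; the reflection branch is excluded by flipping the sign of
    the smallest singular vector when det < 0, so R is always a proper
    rotation even for planar or mirror-degenerate point sets.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("need two equal (N>=3, 3) coordinate arrays")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = pc - rot @ qc
    dev = np.linalg.norm((rot @ q.T).T + t - p, axis=1)
    rmsd = float(np.sqrt(np.mean(dev ** 2)))
    return rot, t, rmsd


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray,
                     trim: bool = True, cutoff_factor: float = 2.0,
                     abs_cutoff: float = 3.0,
                     max_iter: int = 50) -> SuperpositionResult:
    """Superpose paired coordinates with optional iterative outlier trimming.

    Each round drops pairs deviating by more than
    ``max(cutoff_factor * rmsd, abs_cutoff)`` and refits, stopping at
    convergence or before fewer than half of the original pairs remain.
    Both the trimmed rmsd and the all-pair rmsd under the final
    transform are reported.
    """
    p = np.asarray(coords_a, dtype=float)
    q = np.asarray(coords_b, dtype=float)
    n0 = len(p)
    mask = np.ones(n0, dtype=bool)
    history = []
    rot, t, rmsd = kabsch(p, q)
    history.append((n0, rmsd))
    if trim:
        for _ in range(max_iter):
            dev = np.linalg.norm((rot @ q.T).T + t - p, axis=1)
            cutoff = max(cutoff_factor * rmsd, abs_cutoff)
            new_mask = mask & (dev <= cutoff)
            if new_mask.sum() == mask.sum():
                break
            if new_mask.sum() < max(3, int(np.ceil(n0 / 2))):
                logger.info("trimming stopped: would drop below half the pairs")
                break
            mask = new_mask
            rot, t, rmsd = kabsch(p[mask], q[mask])
            history.append((int(mask.sum()), rmsd))
    dev_all = np.linalg.norm((rot @ q.T).T + t - p, axis=1)
    rmsd_all = float(np.sqrt(np.mean(dev_all ** 2)))
    return SuperpositionResult(
        rotation=rot, translation=t, rmsd=rmsd, rmsd_all=rmsd_all,
        per_pair_deviation=dev_all, n_pairs_used=int(mask.sum()),
        used_mask=mask, trim_history=tuple(history),
    )


def superpose_structures(a: CoordinateSet, b: CoordinateSet,
                         mode: str = "by_residue_number",
                         chain_a: Optional[str] = None,
                         chain_b: Optional[str] = None,
                         msa=None, trim: bool = True,
                         ) -> tuple[SuperpositionResult, dict]:
    """Pair C-alphas and superpose; returns the result and a per-residue
    deviation map keyed by (chain, residue number, icode) of structure A."""
    pairing, cas_a, cas_b = pair_c_alpha(a, b, mode=mode, chain_a=chain_a,
                                         chain_b=chain_b, msa=msa)
    pa = np.array([cas_a[i].xyz for i in pairing.indices_a])
    pb = np.array([cas_b[j].xyz for j in pairing.indices_b])
    result = kabsch_superpose(pa, pb, trim=trim)
    per_residue = {
        cas_a[i].residue_key: float(d)
        for i, d in zip(pairing.indices_a, result.per_pair_deviation)
    }
    return result, per_residue


def write_putty(cs: CoordinateSet, per_residue_deviation: dict,
                sentinel: float = 0.0) -> str:
    """PDB text with the B column replaced by per-residue deviations (A).

    Residues absent from the deviation map get the sentinel value and
    are reported in the log, mirroring how unpaired residues are treated
    in putty renderings.
    """
    unpaired = []
    atoms = []
    for a in cs.atoms:
        if a.residue_key in per_residue_deviation:
            b = per_residue_deviation[a.residue_key]
        else:
            b = sentinel
            if a.residue_key not in unpaired:
                unpaired.append(a.residue_key)
        atoms.append(replace(a, b_factor=float(b)))
    if unpaired:
        logger.info("putty: %d residues without a deviation, set to %.2f",
                    len(unpaired), sentinel)
    return to_pdb_string(CoordinateSet(atoms))


# ---------------------------------------------------------------------------
# Pocket contacts and clashes


def contact_residues(cs: CoordinateSet, ligand_atoms: Sequence,
                     cutoff: float = 4.0) -> list[tuple]:
    """Residues with any atom within ``cutoff`` of any ligand atom.

    The ligand's own residues are excluded. Returns
    (chain, residue number, residue name, min distance), nearest first.
    """
    if not ligand_atoms:
        raise ValueError("empty ligand")
    lig_keys = {a.residue_key for a in ligand_atoms}
    lig_xyz = np.array([a.xyz for a in ligand_atoms])
    tree = cKDTree(lig_xyz)
    per_res: dict[tuple, float] = {}
    names: dict[tuple, str] = {}
    for a in cs.atoms:
        if a.residue_key in lig_keys:
            continue
        d, _ = tree.query(a.xyz)
        key = a.residue_key
        if d <= cutoff and d < per_res.get(key, np.inf):
            per_res[key] = float(d)
            names[key] = a.res_name
    out = [(k[0], k[1], names[k], per_res[k]) for k in per_res]
    return sorted(out, key=lambda r: r[3])


def clash_check(cs: CoordinateSet, placed_ligand: Sequence,
                overlap_cutoff: float = 0.4) -> list[tuple]:
    """Steric clashes between a transplanted ligand and a structure.

    An atom pair clashes when its distance is below the sum of van der
    Waals radii minus ``overlap_cutoff``; the returned overlap is how
    far inside that limit the pair sits. Unknown elements fall back to
    a 1.7 A radius with a warning. Returns
    (structure atom, ligand atom, distance, overlap), worst first.
    """
    if not placed_ligand:
        return []
    clashes = []
    lig_keys = {a.residue_key for a in placed_ligand}
    for la in placed_ligand:
        rl = _radius(la.element)
        for sa in cs.atoms:
            if sa.residue_key in lig_keys:
                continue
            rs = _radius(sa.element)
            d = float(np.linalg.norm(np.subtract(sa.xyz, la.xyz)))
            limit = rs + rl - overlap_cutoff
            if d < limit:
                clashes.append((sa, la, d, limit - d))
    return sorted(clashes, key=lambda c: -c[3])


def _radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        logger.warning("unknown element %r: using default vdW radius %.2f A",
                       element, DEFAULT_VDW)
        return DEFAULT_VDW
    return r
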