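"""Backbone geometry primitives.

Reads protein backbone coordinates (N, CA, C) from PDB text, computes the
phi/psi/omega dihedral angles and C-alpha distances that beta-turn assignment
consumes, and classifies peptide bonds as cis or trans.

Conventions
-----------
* Angles are reported in degrees in the half-open interval (-180, 180]
  (IUPAC sign convention).
* Residues are indexed 1-based by their position in the chain; the author
  sequence number from the PDB file is kept alongside for reporting.
* A residue missing any of N, CA or C is flagged incomplete; torsions are
  undefined across it and turns may not span it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "BackboneChain",
    "TorsionTriple",
    "read_backbone",
    "compute_torsions",
    "ca_distance",
    "is_cis_peptide",
    "dihedral",
    "to_pdb_string",
]

BACKBONE_ATOMS = ("N", "CA", "C")

#: Default |omega| cutoff (degrees) below which a peptide bond is called cis.
CIS_OMEGA_CUTOFF = 30.0


@dataclass(frozen=True)
class Residue:
    """One residue of a backbone chain.

    Coordinates are 3-vectors in Angstroms, or ``None`` when the atom is
    absent from the input (the residue is then *incomplete*).
    """

    seq_index: int
    name: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass(frozen=True)
class TorsionTriple:
    """phi/psi/omega for one residue; ``None`` marks an undefined angle.

    omega is the dihedral of the peptide bond *preceding* the residue:
    CA(i-1), C(i-1), N(i), CA(i).
    """

    phi: float | None
    psi: float | None
    omega: float | None


@dataclass
class BackboneChain:
    """An ordered protein chain holding only the backbone N/CA/C atoms."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence ('X' for unknown residue names)."""
        return "".join(THREE_TO_ONE.get(r.name.upper(), "X") for r in self.residues)

    def complete_mask(self) -> np.ndarray:
        return np.array([r.complete for r in self.residues], dtype=bool)


# Standard 20 amino acids, three-letter <-> one-letter.
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def _pick_atom(residue: gemmi.Residue, name: str) -> np.ndarray | None:
    """Return the coordinate of atom `name`, resolving altlocs by highest
    occupancy and then file order."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    if best is None:
        return None
    p = best.pos
    xyz = np.array([p.x, p.y, p.z], dtype=float)
    if not np.all(np.isfinite(xyz)):
        return None
    return xyz


def read_backbone(pdb_text: str, chain_id: str) -> BackboneChain:
    """Parse PDB-format text and extract the backbone of one chain.

    Residues are returned in author order.  Alternate locations are resolved
    to the highest-occupancy conformer (first on ties); residues lacking any
    of N, CA, C are kept but flagged incomplete.

    Raises
    ------
    ValueError
        If the chain does not exist (the message lists the available chains)
        or if no residue of the chain has a complete backbone.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models found in PDB text")
    model = structure[0]
    available = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain_id:
            target = ch
            break
    if target is None:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {', '.join(available) or '(none)'}"
        )
    residues: list[Residue] = []
    for res in target:
        if res.het_flag == "H" and res.name not in THREE_TO_ONE:
            # skip waters/ligands; keep modified residues that alias amino acids
            continue
        residues.append(
            Residue(
                seq_index=res.seqid.num,
                name=res.name,
                n=_pick_atom(res, "N"),
                ca=_pick_atom(res, "CA"),
                c=_pick_atom(res, "C"),
            )
        )
    chain = BackboneChain(chain_id=chain_id, residues=residues)
    if not any(r.complete for r in residues):
        raise ValueError(f"chain {chain_id!r} has no residue with a complete N/CA/C backbone")
    return chain


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _consecutive(a: Residue, b: Residue) -> bool:
    """True when b directly follows a in sequence and both are complete."""
    return a.complete and b.complete and (b.seq_index - a.seq_index == 1)


def compute_torsions(chain: BackboneChain) -> list[TorsionTriple]:
    """Compute (phi, psi, omega) for every residue of the chain.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1); omega(i) uses CA(i-1), C(i-1), N(i), CA(i).  Angles are undefined
    (``None``) at chain termini and across incomplete or non-consecutive
    residues.
    """
    res = chain.residues
    out: list[TorsionTriple] = []
    for i, r in enumerate(res):
        phi = psi = omega = None
        if r.complete:
            if i > 0 and _consecutive(res[i - 1], r):
                prev = res[i - 1]
                phi = dihedral(prev.c, r.n, r.ca, r.c)
                omega = dihedral(prev.ca, prev.c, r.n, r.ca)
            if i + 1 < len(res) and _consecutive(r, res[i + 1]):
                psi = dihedral(r.n, r.ca, r.c, res[i + 1].n)
        out.append(TorsionTriple(phi=phi, psi=psi, omega=omega))
    return out


def ca_distance(chain: BackboneChain, i: int, j: int) -> float:
    """Euclidean C-alpha distance (Angstrom) between residues i and j (1-based)."""
    for k in (i, j):
        if not 1 <= k <= len(chain):
            raise IndexError(f"residue index {k} outside chain of length {len(chain)}")
        if chain.residues[k - 1].ca is None:
            raise ValueError(f"residue {k} has no CA atom")
    return float(np.linalg.norm(chain.residues[i - 1].ca - chain.residues[j - 1].ca))


def is_cis_peptide(omega: float | None, cutoff: float = CIS_OMEGA_CUTOFF) -> bool:
    """True when the peptide bond with dihedral `omega` is cis (|omega| < cutoff)."""
    if omega is None:
        raise ValueError("omega is undefined; cannot classify cis/trans")
    return abs(omega) < cutoff


def to_pdb_string(chain: BackboneChain, chain_id: str | None = None) -> str:
    """Serialize the backbone as minimal PDB ATOM records (plus TER/END).

    The PDB chain column holds a single character; longer in-memory chain
    ids are written as 'A' unless `chain_id` overrides this.
    """
    cid = chain_id if chain_id is not None else chain.chain_id
    if len(cid) != 1:
        cid = "A"
    lines = []
    serial = 1
    elementof = {"N": "N", "CA": "C", "C": "C"}
    for res in chain.residues:
        for name in BACKBONE_ATOMS:
            xyz = getattr(res, name.lower())
            if xyz is None:
                continue
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res.name:>3s} {cid:1s}"
                f"{res.seq_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {elementof[name]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
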