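"""Beta-turn assignment and type classification.

A beta-turn is four consecutive residues i..i+3 whose CA(i)-CA(i+3) distance
is below 7 Angstrom and whose two central residues are not helical.  Turn
types are defined by the phi/psi dihedrals of residues i+1 and i+2: eight
defined classes (I, I', II, II', VIII, VIa1, VIa2, VIb) plus the catch-all
type IV for turns matching none of them.  A defined class matches when each
of the four dihedrals deviates at most ``tol`` (default 30 degrees) from the
canonical value, with a single dihedral allowed to deviate up to ``tol_one``
(default 40 degrees); types VIa1 and VIa2 additionally require a cis-proline
at position i+2.  Deviations are measured on the circle so that values near
+/-180 compare correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BackboneChain, ca_distance, compute_torsions, is_cis_peptide

__all__ = [
    "TURN_TYPES",
    "DEFINED_TYPES",
    "CanonicalAngles",
    "DEFAULT_TABLE",
    "TurnInstance",
    "TurnAnnotation",
    "classify_turn_type",
    "classify_turn_type_batch",
    "matching_types",
    "assign_turns",
    "position_labels",
    "label_sets",
    "annotation_table",
    "instance_table",
    "angular_deviation",
]

#: The nine turn types; IV is the catch-all.
TURN_TYPES = ("I", "I'", "II", "II'", "IV", "VIII", "VIa1", "VIa2", "VIb")

#: The eight geometrically defined types, in tie-break precedence order.
DEFINED_TYPES = ("I", "I'", "II", "II'", "VIII", "VIa1", "VIa2", "VIb")

#: Beta-turn CA(i)-CA(i+3) distance criterion in Angstrom.
TURN_CA_DISTANCE = 7.0


@dataclass(frozen=True)
class TypeDefinition:
    """Canonical (phi_i1, psi_i1, phi_i2, psi_i2) of one defined type."""

    phi2: float
    psi2: float
    phi3: float
    psi3: float
    cis_pro_required: bool = False

    @property
    def angles(self) -> tuple[float, float, float, float]:
        return (self.phi2, self.psi2, self.phi3, self.psi3)


#: Canonical dihedral table (Hutchinson/Thornton convention, as used by the
#: PROMOTIF assignment program).  Keys are type names; IV has no entry.
CanonicalAngles = dict[str, TypeDefinition]

DEFAULT_TABLE: CanonicalAngles = {
    "I": TypeDefinition(-60.0, -30.0, -90.0, 0.0),
    "I'": TypeDefinition(60.0, 30.0, 90.0, 0.0),
    "II": TypeDefinition(-60.0, 120.0, 80.0, 0.0),
    "II'": TypeDefinition(60.0, -120.0, -80.0, 0.0),
    "VIII": TypeDefinition(-60.0, -30.0, -120.0, 120.0),
    "VIa1": TypeDefinition(-60.0, 120.0, -90.0, 0.0, cis_pro_required=True),
    "VIa2": TypeDefinition(-120.0, 120.0, -60.0, 0.0, cis_pro_required=True),
    "VIb": TypeDefinition(-135.0, 135.0, -75.0, 160.0),
}


def angular_deviation(observed: float, canonical: float) -> float:
    """Absolute deviation between two angles, measured on the circle."""
    return abs((observed - canonical + 180.0) % 360.0 - 180.0)


def _matches(
    angles: tuple[float, float, float, float],
    definition: TypeDefinition,
    cis_pro_at_3: bool,
    tol: float,
    tol_one: float,
) -> bool:
    if definition.cis_pro_required and not cis_pro_at_3:
        return False
    devs = [angular_deviation(a, c) for a, c in zip(angles, definition.angles)]
    if max(devs) > tol_one:
        return False
    return sum(d > tol for d in devs) <= 1


def matching_types(
    angles: tuple[float, float, float, float],
    cis_pro_at_3: bool = False,
    table: CanonicalAngles | None = None,
    tol: float = 30.0,
    tol_one: float = 40.0,
) -> list[str]:
    """All defined types whose tolerance rules the four dihedrals satisfy,
    in precedence order."""
    table = DEFAULT_TABLE if table is None else table
    return [
        t
        for t in DEFINED_TYPES
        if t in table and _matches(angles, table[t], cis_pro_at_3, tol, tol_one)
    ]


def classify_turn_type(
    angles: tuple[float, float, float, float],
    cis_pro_at_3: bool = False,
    table: CanonicalAngles | None = None,
    tol: float = 30.0,
    tol_one: float = 40.0,
    rule: str = "precedence",
) -> str:
    """Classify a candidate turn window from its central dihedrals.

    Parameters
    ----------
    angles
        (phi_i+1, psi_i+1, phi_i+2, psi_i+2) in degrees, all defined.
    cis_pro_at_3
        Whether residue i+2 is a proline preceded by a cis peptide bond.
    rule
        ``"precedence"`` resolves multiple matches by the fixed order
        I, I', II, II', VIII, VIa1, VIa2, VIb; ``"best_fit"`` picks the
        matching type with the smallest total circular deviation.

    Returns the matched type name, or ``"IV"`` when no defined type matches.
    """
    if any(a is None for a in angles):
        raise ValueError("all four dihedral angles must be defined")
    table = DEFAULT_TABLE if table is None else table
    hits = matching_types(angles, cis_pro_at_3, table, tol, tol_one)
    if not hits:
        return "IV"
    if rule == "precedence":
        return hits[0]
    if rule == "best_fit":
        return min(
            hits,
            key=lambda t: sum(
                angular_deviation(a, c) for a, c in zip(angles, table[t].angles)
            ),
        )
    raise ValueError(f"unknown tie-break rule {rule!r}")


def classify_turn_type_batch(
    angles: np.ndarray,
    cis_pro_at_3: np.ndarray | bool = False,
    table: CanonicalAngles | None = None,
    tol: float = 30.0,
    tol_one: float = 40.0,
) -> np.ndarray:
    """Vectorized precedence-rule classification of many angle quadruples.

    `angles` is (n, 4); returns an (n,) array of type names.  Agrees with
    :func:`classify_turn_type` point for point (precedence tie-break).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 4:
        raise ValueError("angles must be an (n, 4) array")
    n = len(angles)
    cis = np.broadcast_to(np.asarray(cis_pro_at_3, dtype=bool), (n,))
    table = DEFAULT_TABLE if table is None else table
    out = np.full(n, "IV", dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for t in DEFINED_TYPES:
        if t not in table:
            continue
        defn = table[t]
        dev = np.abs(
            (angles - np.array(defn.angles) + 180.0) % 360.0 - 180.0
        )
        match = (dev.max(axis=1) <= tol_one) & ((dev > tol).sum(axis=1) <= 1)
        if defn.cis_pro_required:
            match &= cis
        hit = match & unassigned
        out[hit] = t
        unassigned &= ~match
    return out


@dataclass(frozen=True)
class TurnInstance:
    """One assigned turn: residues start..start+3 (1-based chain positions)."""

    start: int
    turn_type: str

    @property
    def residues(self) -> tuple[int, int, int, int]:
        return (self.start, self.start + 1, self.start + 2, self.start + 3)


@dataclass
class TurnAnnotation:
    """Per-residue turn labels for one chain."""

    length: int
    instances: list[TurnInstance] = field(default_factory=list)

    @property
    def in_turn(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for inst in self.instances:
            mask[inst.start - 1 : inst.start + 3] = True
        return mask

    def type_sets(self) -> list[set[str]]:
        sets: list[set[str]] = [set() for _ in range(self.length)]
        for inst in self.instances:
            for r in inst.residues:
                sets[r - 1].add(inst.turn_type)
        return sets

    def position_sets(self) -> list[set[int]]:
        return position_labels(self)


def assign_turns(
    chain: BackboneChain,
    helix_mask: np.ndarray | None = None,
    table: CanonicalAngles | None = None,
    tol: float = 30.0,
    tol_one: float = 40.0,
    max_distance: float = TURN_CA_DISTANCE,
    rule: str = "precedence",
) -> TurnAnnotation:
    """Assign beta-turns over every candidate window of a chain.

    A window i..i+3 qualifies when all four residues are complete and
    consecutive, CA(i)-CA(i+3) < `max_distance`, neither central residue is
    helical, and the central phi/psi dihedrals are defined.  Each qualifying
    window yields a TurnInstance typed by :func:`classify_turn_type`; the
    cis-proline flag is set only when residue i+2 is proline *and* the
    peptide bond preceding it is cis.
    """
    n = len(chain)
    if helix_mask is None:
        helix_mask = np.zeros(n, dtype=bool)
    helix_mask = np.asarray(helix_mask, dtype=bool)
    if helix_mask.shape != (n,):
        raise ValueError("helix_mask length must equal chain length")
    torsions = compute_torsions(chain)
    annotation = TurnAnnotation(length=n)
    for i in range(n - 3):  # 0-based window start
        r = chain.residues[i : i + 4]
        if not all(x.complete for x in r):
            continue
        if [x.seq_index for x in r] != list(range(r[0].seq_index, r[0].seq_index + 4)):
            continue
        if helix_mask[i + 1] or helix_mask[i + 2]:
            continue
        t1, t2 = torsions[i + 1], torsions[i + 2]
        if t1.phi is None or t1.psi is None or t2.phi is None or t2.psi is None:
            continue
        if ca_distance(chain, i + 1, i + 4) >= max_distance:
            continue
        cis_pro = (
            r[2].name.upper() == "PRO"
            and t2.omega is not None
            and is_cis_peptide(t2.omega)
        )
        turn_type = classify_turn_type(
            (t1.phi, t1.psi, t2.phi, t2.psi), cis_pro, table, tol, tol_one, rule
        )
        annotation.instances.append(TurnInstance(start=i + 1, turn_type=turn_type))
    return annotation


def position_labels(annotation: TurnAnnotation) -> list[set[int]]:
    """Per-residue turn-position sets.

    Residue r carries position p (1..4) whenever a turn instance starting at
    s covers it with r - s + 1 = p; residues shared by overlapping turns
    accumulate multiple positions.
    """
    sets: list[set[int]] = [set() for _ in range(annotation.length)]
    for inst in annotation.instances:
        for p, r in enumerate(inst.residues, start=1):
            sets[r - 1].add(p)
    return sets


def label_sets(
    annotation: TurnAnnotation,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[int, np.ndarray]]:
    """Build the general, type-specific and position-specific label tracks.

    Returns
    -------
    general : bool array, positive for residues inside any turn
    by_type : one bool track per turn type; positives are residues covered
        by an instance of that type (residues of other types are negatives)
    by_position : one bool track per turn position 1..4
    """
    n = annotation.length
    general = annotation.in_turn
    by_type = {t: np.zeros(n, dtype=bool) for t in TURN_TYPES}
    for inst in annotation.instances:
        by_type[inst.turn_type][inst.start - 1 : inst.start + 3] = True
    by_position = {p: np.zeros(n, dtype=bool) for p in (1, 2, 3, 4)}
    for r, pset in enumerate(position_labels(annotation)):
        for p in pset:
            by_position[p][r] = True
    return general, by_type, by_position


def annotation_table(chain: BackboneChain, annotation: TurnAnnotation) -> pd.DataFrame:
    """One row per residue: chain, seq index, aa, turn flag, types, positions."""
    types = annotation.type_sets()
    positions = annotation.position_sets()
    seq = chain.sequence
    rows = [
        {
            "chain": chain.chain_id,
            "seq_index": res.seq_index,
            "aa": seq[i],
            "in_turn": int(annotation.in_turn[i]),
            "types": ",".join(sorted(types[i])),
            "positions": ",".join(str(p) for p in sorted(positions[i])),
        }
        for i, res in enumerate(chain.residues)
    ]
    return pd.DataFrame(rows)


def instance_table(chain: BackboneChain, annotation: TurnAnnotation) -> pd.DataFrame:
    """One row per assigned turn instance."""
    rows = [
        {
            "chain": chain.chain_id,
            "start": chain.residues[inst.start - 1].seq_index,
            "type": inst.turn_type,
            "residues": ",".join(
                str(chain.residues[r - 1].seq_index) for r in inst.residues
            ),
        }
        for inst in annotation.instances
    ]
    return pd.DataFrame(rows, columns=["chain", "start", "type", "residues"])
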