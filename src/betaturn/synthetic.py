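"""Synthetic fixture generation.

Builds every input the pipeline consumes without external downloads:
backbone chains with beta-turns planted at known places and of known types,
and label-correlated sequence profiles plus secondary-structure / surface
accessibility tracks.  All generation is driven by a seeded
``numpy.random.Generator`` and is fully reproducible.

The backbone builder converts internal coordinates (bond lengths, bond
angles, torsions) to Cartesian atoms by sequential placement (the NeRF
construction).  Standard peptide bond geometry is used; the downstream
assignment depends only on the resulting torsions and CA distances, so any
self-consistent geometry set would serve equally well.

What the generator emulates: turn windows with canonical dihedrals plus
bounded jitter, extended flanks, cis-proline for the VIa types, profile
columns shifted on turn-favoring residues (Gly/Asp/Ser/Pro/Asn), and raised
coil probability and solvent exposure inside turns.  What it does not
emulate: side-chain packing, steric clashes, helices, or the long-range
correlation structure of real homology profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import AA_ORDER, SequenceProfile, StructTracks
from .geometry import BackboneChain, ONE_TO_THREE, Residue, ca_distance
from .turns import (
    DEFAULT_TABLE,
    DEFINED_TYPES,
    TURN_CA_DISTANCE,
    CanonicalAngles,
    TurnAnnotation,
    TurnInstance,
    matching_types,
)

__all__ = [
    "FixtureSpec",
    "FixtureChain",
    "build_backbone_from_torsions",
    "plant_turn_chain",
    "plant_overlap_pair",
    "synth_tracks",
    "make_dataset",
]

# Standard backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: Extended-strand dihedrals used for the flanks between planted turns.
EXTENDED_PHI = -120.0
EXTENDED_PSI = 130.0

#: Residues over-represented in turns (hydrophilic or small).
TURN_FAVORING = "GDSPN"

#: Default sampling weights for planted turn types, loosely following the
#: relative abundances observed in protein structures (type I most common).
DEFAULT_TYPE_WEIGHTS = {
    "I": 0.35, "I'": 0.08, "II": 0.20, "II'": 0.07,
    "VIII": 0.15, "VIa1": 0.05, "VIa2": 0.04, "VIb": 0.06,
}


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float
) -> np.ndarray:
    """Place atom D at bond length r from C, bond angle theta (B-C-D) and
    torsion chi (A-B-C-D), angles in degrees."""
    th = math.radians(theta)
    ph = math.radians(chi)
    d_local = np.array(
        [
            -r * math.cos(th),
            r * math.sin(th) * math.cos(ph),
            r * math.sin(th) * math.sin(ph),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def build_backbone_from_torsions(
    torsions: list[tuple[float | None, float | None, float | None]],
    names: list[str] | None = None,
    chain_id: str = "A",
) -> BackboneChain:
    """Build Cartesian backbone coordinates from per-residue (phi, psi, omega).

    ``torsions[i]`` provides phi and omega for residue i+1 (ignored for the
    first residue) and psi (ignored for the last).  ``None`` entries default
    to the extended phi/psi and trans omega.  Recomputing torsions on the
    result reproduces the inputs to well under 1e-4 degrees.
    """
    n = len(torsions)
    if n < 2:
        raise ValueError("need at least two residues of torsions")
    if names is None:
        names = ["ALA"] * n
    if len(names) != n:
        raise ValueError("names length must match torsions length")

    def _phi(i):
        v = torsions[i][0]
        return EXTENDED_PHI if v is None else v

    def _psi(i):
        v = torsions[i][1]
        return EXTENDED_PSI if v is None else v

    def _omega(i):
        v = torsions[i][2]
        return 180.0 if v is None else v

    coords: list[dict[str, np.ndarray]] = []
    ang = math.radians(ANGLE_N_CA_C)
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[i - 1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, _psi(i - 1))
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, _omega(i))
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, _phi(i))
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    residues = [
        Residue(seq_index=i + 1, name=names[i], n=c["N"], ca=c["CA"], c=c["C"])
        for i, c in enumerate(coords)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues)


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic dataset.

    Defaults give ~50 chains of ~100 residues with six planted turns each
    (~24% of residues inside a turn, close to the ~25% base rate of real
    protein data), a profile log-odds shift of delta=4 on turn-favoring
    residue columns inside turns, and unit noise.
    """

    n_chains: int = 50
    length_range: tuple[int, int] = (90, 110)
    turns_per_chain: int = 6
    type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    jitter: float = 20.0          # max per-angle dihedral jitter, degrees (< 25)
    delta: float = 4.0            # profile log-odds shift on turn-favoring columns
    sigma: float = 1.0            # profile noise s.d. (log-odds units)
    enrich: float = 0.40          # P(turn residue drawn from TURN_FAVORING)
    coil_boost: float = 2.5       # Dirichlet weight on coil inside turns
    rsa_turn_mean: float = 0.45   # mean relative accessibility inside turns
    rsa_other_mean: float = 0.38  # mean relative accessibility elsewhere
    seed: int = 0


@dataclass
class FixtureChain:
    """One synthetic chain bundled with its ground truth and input tracks."""

    chain_id: str
    chain: BackboneChain
    annotation: TurnAnnotation
    profile: SequenceProfile
    struct: StructTracks

    @property
    def sequence(self) -> str:
        return self.chain.sequence


#: Turn types built with a cis peptide bond before residue i+2.  VIa1/VIa2
#: require cis-proline by definition; VIb is also built cis (its classical
#: proline form) because the canonical VIb dihedrals only close the turn
#: below 7 Angstrom across a cis bond.
CIS_GEOMETRY_TYPES = frozenset({"VIa1", "VIa2", "VIb"})


def _jittered_window(
    turn_type: str,
    rng: np.random.Generator,
    jitter: float,
    table: CanonicalAngles,
    max_tries: int = 200,
) -> tuple[float, float, float, float]:
    """Canonical angles of `turn_type` plus uniform jitter, resampled until
    the planted type is the *unique* matching defined type (this excludes
    tie-break precedence conflicts by construction)."""
    canonical = table[turn_type].angles
    cis = turn_type in CIS_GEOMETRY_TYPES
    for _ in range(max_tries):
        angles = tuple(c + rng.uniform(-jitter, jitter) for c in canonical)
        if matching_types(angles, cis_pro_at_3=cis, table=table) == [turn_type]:
            return angles
    raise RuntimeError(f"could not sample unambiguous angles for type {turn_type}")


#: Per-turn torsion block: offsets -2..+3 relative to the 0-based index of
#: residue i+1.  Offsets 0/+1 carry the type's dihedrals; the buffer offsets
#: (-2, -1, +2, +3: residues i-1, i, i+3, i+4) are free and are searched so
#: that, in an extended context, only the turn's own window closes below the
#: 7 Angstrom criterion.
_BLOCK_OFFSETS = (-2, -1, 0, 1, 2, 3)
_FRAG_PAD = 6  # extended residues on each side of the block in the test fragment


def _turn_block(
    turn_type: str,
    rng: np.random.Generator,
    jitter: float,
    table: CanonicalAngles,
    max_tries: int = 500,
) -> dict[int, list[float]]:
    """Search a torsion block whose only sub-7-Angstrom window is the turn.

    Window CA distances depend solely on the torsions between the window's
    residues, so validating the block inside an extended fragment is exact
    for any chain placing the same block in an extended context.
    """
    cis = turn_type in CIS_GEOMETRY_TYPES
    for _ in range(max_tries):
        a = _jittered_window(turn_type, rng, jitter, table)
        block: dict[int, list[float]] = {
            0: [a[0], a[1], 180.0],
            1: [a[2], a[3], 0.0 if cis else 180.0],
        }
        for off in (-2, -1, 2, 3):
            block[off] = [rng.uniform(-180.0, 180.0), rng.uniform(-180.0, 180.0), 180.0]
        frag = [
            [EXTENDED_PHI, EXTENDED_PSI, 180.0]
            for _ in range(2 * _FRAG_PAD + len(_BLOCK_OFFSETS))
        ]
        center = _FRAG_PAD + 2  # fragment 0-based index of residue i+1
        for off, tors in block.items():
            frag[center + off] = tors
        chain = build_backbone_from_torsions([tuple(t) for t in frag])
        planted = center  # 1-based window start (residue i is 0-based center-1)
        ok = True
        for w in range(1, len(frag) - 2):
            d = ca_distance(chain, w, w + 3)
            if (d < TURN_CA_DISTANCE + 0.05) if w != planted else (d >= TURN_CA_DISTANCE - 0.05):
                ok = False
                break
        if ok:
            return block
    raise RuntimeError(f"could not build an isolated {turn_type} torsion block")


def _background_aa(rng: np.random.Generator) -> str:
    return AA_ORDER[rng.integers(len(AA_ORDER))]


def plant_turn_chain(
    length: int,
    plants: list[tuple[str, int]] | int,
    rng: np.random.Generator,
    jitter: float = 20.0,
    enrich: float = 0.55,
    type_weights: dict[str, float] | None = None,
    table: CanonicalAngles | None = None,
    chain_id: str = "A",
    max_tries: int = 50,
) -> tuple[BackboneChain, TurnAnnotation]:
    """Build a chain with beta-turns planted at known starts and types.

    `plants` is either an explicit list of (type, start) pairs (1-based
    starts) or a count of turns to place at random non-overlapping starts
    (windows separated by at least two residues).  Flanking residues get
    extended-region dihedrals; VIa windows get a proline at i+2 preceded by
    a cis peptide bond.  The built geometry is validated: every planted
    window must fall below the 7 Angstrom CA criterion and every other
    window must not, so the returned truth annotation is exactly what
    turn assignment recovers (jitter stays within the +/-30 degree rule).
    """
    table = DEFAULT_TABLE if table is None else table
    if jitter >= 25.0:
        raise ValueError("jitter must stay below 25 degrees for guaranteed recovery")
    weights = DEFAULT_TYPE_WEIGHTS if type_weights is None else type_weights
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()

    if isinstance(plants, int):
        starts = _sample_starts(length, plants, rng)
        chosen = [(types[rng.choice(len(types), p=probs)], s) for s in starts]
    else:
        chosen = sorted(plants, key=lambda x: x[1])
        _check_plants(length, chosen)
    torsions: list[list[float]] = [
        [EXTENDED_PHI, EXTENDED_PSI, 180.0] for _ in range(length)
    ]
    names = [ONE_TO_THREE[_background_aa(rng)] for _ in range(length)]
    for turn_type, start in chosen:
        block = _turn_block(turn_type, rng, jitter, table)
        for off, tors in block.items():
            idx = start + off  # `start` is also the 0-based index of residue i+1
            if 0 <= idx < length:
                torsions[idx] = list(tors)
        if turn_type in CIS_GEOMETRY_TYPES:
            names[start + 1] = "PRO"  # residue i+2
    in_turn = np.zeros(length, dtype=bool)
    for turn_type, start in chosen:
        in_turn[start - 1 : start + 3] = True
    for i in range(length):
        if in_turn[i] and names[i] != "PRO" and rng.random() < enrich:
            names[i] = ONE_TO_THREE[TURN_FAVORING[rng.integers(len(TURN_FAVORING))]]
    chain = build_backbone_from_torsions(
        [tuple(t) for t in torsions], names=names, chain_id=chain_id
    )
    planted_starts = {s for _, s in chosen}
    for w in range(1, length - 2):  # 1-based window starts
        d = ca_distance(chain, w, w + 3)
        if (w in planted_starts) != (d < TURN_CA_DISTANCE):
            raise RuntimeError(
                f"planted chain failed geometric validation at window {w}"
            )
    annotation = TurnAnnotation(
        length=length,
        instances=[TurnInstance(start=s, turn_type=t) for t, s in chosen],
    )
    return chain, annotation


#: Minimum start-to-start separation between planted turns: torsion blocks
#: span offsets -2..+3, and a 4-residue window cannot touch two blocks that
#: are 9 or more starts apart.
MIN_TURN_SEPARATION = 9


def _sample_starts(length: int, count: int, rng: np.random.Generator) -> list[int]:
    """Random 1-based turn starts separated by at least MIN_TURN_SEPARATION."""
    lo, hi = 3, length - 5
    for _ in range(500):
        starts = sorted(rng.choice(np.arange(lo, hi + 1), size=count, replace=False))
        if all(b - a >= MIN_TURN_SEPARATION for a, b in zip(starts, starts[1:])):
            return [int(s) for s in starts]
    raise RuntimeError(f"cannot place {count} separated turns in a chain of {length}")


def _check_plants(length: int, chosen: list[tuple[str, int]]) -> None:
    for _, s in chosen:
        if not 3 <= s <= length - 5:
            raise ValueError(f"turn start {s} too close to a chain terminus")
    for (_, a), (_, b) in zip(chosen, chosen[1:]):
        if b - a < MIN_TURN_SEPARATION:
            raise ValueError(
                f"turn starts must be separated by >= {MIN_TURN_SEPARATION}; "
                "use plant_overlap_pair for overlapping turns"
            )


def plant_overlap_pair(
    length: int,
    start: int,
    rng: np.random.Generator,
    chain_id: str = "A",
    first_type: str = "VIII",
    second_type: str = "VIa2",
    max_tries: int = 200,
) -> tuple[BackboneChain, TurnAnnotation]:
    """Build a five-residue turn made of two overlapping instances.

    The default pair (VIII at `start`, VIa2 at `start`+1) is geometrically
    consistent because the canonical (phi, psi) of VIII at i+2 equals that
    of VIa2 at its i+1.  The shared residues make one residue both position
    1 and position 2, and another both position 3 and position 4.
    """
    table = DEFAULT_TABLE
    a1 = table[first_type].angles
    a2 = table[second_type].angles
    if (a1[2], a1[3]) != (a2[0], a2[1]):
        raise ValueError(
            f"types {first_type}/{second_type} are dihedrally inconsistent at the shared residues"
        )
    if not 3 <= start <= length - 6:
        raise ValueError("overlap pair does not fit in the chain")
    for _ in range(max_tries):
        torsions: list[list[float]] = [
            [EXTENDED_PHI, EXTENDED_PSI, 180.0] for _ in range(length)
        ]
        names = [ONE_TO_THREE[_background_aa(rng)] for _ in range(length)]
        torsions[start][0], torsions[start][1] = a1[0], a1[1]
        torsions[start + 1][0], torsions[start + 1][1] = a1[2], a1[3]
        torsions[start + 2][0], torsions[start + 2][1] = a2[2], a2[3]
        for off in (-2, -1, 3, 4):  # free buffers around the 5-residue turn
            torsions[start + off][0] = rng.uniform(-180.0, 180.0)
            torsions[start + off][1] = rng.uniform(-180.0, 180.0)
        if second_type in CIS_GEOMETRY_TYPES:
            names[start + 2] = "PRO"
            torsions[start + 2][2] = 0.0
        chain = build_backbone_from_torsions(
            [tuple(t) for t in torsions], names=names, chain_id=chain_id
        )
        ok = True
        for i in range(1, length - 2):
            d = ca_distance(chain, i, i + 3)
            if i in (start, start + 1):
                ok &= d < TURN_CA_DISTANCE - 0.05
            else:
                ok &= d >= TURN_CA_DISTANCE + 0.05
            if not ok:
                break
        if ok:
            annotation = TurnAnnotation(
                length=length,
                instances=[
                    TurnInstance(start=start, turn_type=first_type),
                    TurnInstance(start=start + 1, turn_type=second_type),
                ],
            )
            return chain, annotation
    raise RuntimeError("could not build a clean overlapping-turn chain")


def synth_tracks(
    chain: BackboneChain,
    annotation: TurnAnnotation,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> tuple[SequenceProfile, StructTracks]:
    """Generate a label-correlated profile and structure tracks for a chain.

    Profile scores are integer log-odds N(0, sigma); the columns of the
    turn-favoring letters are shifted by +delta on turn residues whose own
    identity is one of those letters, so the enrichment signal reaches the
    profile only through composition — as in real homology profiles — and a
    fraction of turn residues stays profile-silent.  Turns additionally get
    a raised coil probability (Dirichlet coil weight `coil_boost` vs 2) and
    a raised mean relative accessibility.
    """
    length = len(chain)
    in_turn = annotation.in_turn
    scores = rng.normal(0.0, spec.sigma, size=(length, 20))
    fav = [AA_ORDER.index(a) for a in TURN_FAVORING]
    sequence = chain.sequence
    shifted = in_turn & np.array([aa in TURN_FAVORING for aa in sequence])
    scores[np.ix_(shifted, fav)] += spec.delta
    profile = SequenceProfile(
        sequence=chain.sequence, scores=np.rint(scores).astype(int)
    )
    hec = np.empty((length, 3))
    rsa = np.empty(length)
    conc = 8.0  # beta concentration for RSA sampling
    for i in range(length):
        if in_turn[i]:
            hec[i] = rng.dirichlet([1.0, 1.0, spec.coil_boost])
            mean = spec.rsa_turn_mean
        else:
            hec[i] = rng.dirichlet([2.0, 2.0, 2.0])
            mean = spec.rsa_other_mean
        rsa[i] = rng.beta(mean * conc, (1.0 - mean) * conc)
    struct = StructTracks(
        p_helix=hec[:, 0], p_strand=hec[:, 1], p_coil=hec[:, 2], rsa=rsa
    )
    return profile, struct


def make_dataset(spec: FixtureSpec) -> list[FixtureChain]:
    """Generate the full synthetic dataset described by `spec` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    out: list[FixtureChain] = []
    for k in range(spec.n_chains):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        cid = f"SYN{k:03d}"
        chain, annotation = plant_turn_chain(
            length,
            spec.turns_per_chain,
            rng,
            jitter=spec.jitter,
            enrich=spec.enrich,
            type_weights=spec.type_weights,
            chain_id=cid,
        )
        profile, struct = synth_tracks(chain, annotation, spec, rng)
        out.append(
            FixtureChain(
                chain_id=cid,
                chain=chain,
                annotation=annotation,
                profile=profile,
                struct=struct,
            )
        )
    return out
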