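"""Dataset construction utilities.

Chain ranking for homology reduction, pairwise global-alignment sequence
identity, the greedy Hobohm-1 reduction algorithm, a PISCES-style record
filter, and amino-acid composition statistics inside versus outside turns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .features import AA_ORDER
from .turns import TurnAnnotation

__all__ = [
    "ChainRecord",
    "rank_score",
    "pairwise_identity",
    "hobohm1",
    "length_dependent_threshold",
    "filter_records",
    "composition_stats",
]


@dataclass(frozen=True)
class ChainRecord:
    """One candidate chain: id, sequence, and the quality fields ranking uses.

    ``sequence_length`` may exceed ``pdb_length`` when some residues have no
    coordinates in the deposited structure.
    """

    id: str
    sequence: str
    resolution: float
    sequence_length: int
    pdb_length: int
    r_factor: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.pdb_length > self.sequence_length:
            raise ValueError("pdb_length cannot exceed sequence_length")


def rank_score(record: ChainRecord) -> float:
    """Empirical chain ranking score; lower is better.

    The default surrogate ``resolution * sequence_length / pdb_length``
    prefers high-resolution structures whose deposited coordinates cover the
    whole sequence: it increases with worse resolution and decreases (at
    fixed sequence length and resolution) as more residues are
    experimentally determined.  Any alternative with the same monotonicity
    can be passed to :func:`hobohm1` in its place.
    """
    if record.pdb_length == 0:
        raise ValueError(f"record {record.id} has pdb_length 0")
    return record.resolution * record.sequence_length / record.pdb_length


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment (BLOSUM62, gap 11/1).

    Identity = identical aligned positions / alignment length (gap columns
    included).  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / alignment.length


def length_dependent_threshold(alignment_length: int, floor: float = 25.0) -> float:
    """Length-corrected identity threshold (Sander/Schneider-style curve).

    Short alignments must be far more identical to count as homologous:
    t(L) = 290.15 * L**-0.562, floored at `floor` percent for long
    alignments.
    """
    if alignment_length <= 0:
        raise ValueError("alignment length must be positive")
    return max(floor, 290.15 * alignment_length ** -0.562)


def hobohm1(
    records: Sequence[ChainRecord],
    threshold: float = 25.0,
    rank: Callable[[ChainRecord], float] = rank_score,
    identity: Callable[[str, str], float] = pairwise_identity,
    length_dependent: bool = False,
) -> list[ChainRecord]:
    """Greedy homology reduction.

    Records are visited in rank order (best = lowest score first; ties by
    id) and accepted when their identity to every previously accepted
    record does not exceed the threshold.  With ``length_dependent`` the
    per-pair cutoff is :func:`length_dependent_threshold` of the shorter
    sequence length instead of the flat percentage.
    """
    if not records:
        raise ValueError("no records to reduce")
    ordered = sorted(records, key=lambda r: (rank(r), r.id))
    accepted: list[ChainRecord] = []
    for rec in ordered:
        ok = True
        for kept in accepted:
            cutoff = (
                length_dependent_threshold(min(len(rec.sequence), len(kept.sequence)))
                if length_dependent
                else threshold
            )
            if identity(rec.sequence, kept.sequence) > cutoff:
                ok = False
                break
        if ok:
            accepted.append(rec)
    return accepted


def filter_records(
    records: Sequence[ChainRecord],
    max_resolution: float = 3.0,
    max_r_factor: float = 0.2,
    min_length: int = 40,
    max_length: int = 10_000,
) -> list[ChainRecord]:
    """PISCES-style quality filter on resolution, R-factor and length.

    Records without an R-factor pass that criterion (value unknown).
    """
    out = []
    for rec in records:
        if rec.resolution > max_resolution:
            continue
        if rec.r_factor is not None and rec.r_factor > max_r_factor:
            continue
        if not min_length <= rec.sequence_length <= max_length:
            continue
        out.append(rec)
    return out


def composition_stats(
    annotations: Sequence["TurnAnnotation | np.ndarray"], sequences: Sequence[str]
) -> pd.DataFrame:
    """Per-amino-acid frequency inside turns and overall, as percentages.

    `annotations` may hold TurnAnnotation objects or boolean in-turn masks.
    Both columns sum to 100.  Residues outside the standard 20 letters are
    ignored.
    """
    if len(annotations) != len(sequences):
        raise ValueError("annotations and sequences differ in count")
    turn_counts = {a: 0 for a in AA_ORDER}
    all_counts = {a: 0 for a in AA_ORDER}
    for ann, seq in zip(annotations, sequences):
        mask = ann.in_turn if isinstance(ann, TurnAnnotation) else np.asarray(ann, bool)
        if len(mask) != len(seq):
            raise ValueError("annotation and sequence differ in length")
        for i, aa in enumerate(seq):
            if aa not in all_counts:
                continue
            all_counts[aa] += 1
            if mask[i]:
                turn_counts[aa] += 1
    n_turn = sum(turn_counts.values())
    n_all = sum(all_counts.values())
    if n_all == 0:
        raise ValueError("no standard residues counted")
    rows = [
        {
            "aa": a,
            "pct_in_turns": 100.0 * turn_counts[a] / n_turn if n_turn else np.nan,
            "pct_overall": 100.0 * all_counts[a] / n_all,
        }
        for a in sorted(AA_ORDER)
    ]
    return pd.DataFrame(rows)
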