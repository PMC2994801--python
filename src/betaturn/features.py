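"""Profile and structure-track parsing plus sliding-window encoding.

Each residue is described by 25 input neurons: 20 logistic-squashed
position-specific log-odds scores, one out-of-chain indicator, three
secondary-structure probabilities (helix/strand/coil) and the relative
surface accessibility.  A sliding window of `w` residues (w odd, 5..13)
centered on the residue of interest is concatenated into a 25*w input
vector; virtual positions beyond the chain termini carry the out-of-chain
pattern (indicator 1, all other values 0).

Second-layer networks consume per-residue tracks composed from first-layer
outputs according to the lettered setups A..M (e.g. setup M = four position
scores + the general turn score + helix/strand/coil + accessibility);
windowing then appends a per-position out-of-chain indicator.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit

__all__ = [
    "AA_ORDER",
    "SequenceProfile",
    "StructTracks",
    "ResidueFeatureTrack",
    "WindowedExample",
    "SETUPS",
    "read_psiblast_pssm",
    "write_psiblast_pssm",
    "read_struct_table",
    "write_struct_table",
    "read_fasta",
    "write_fasta",
    "squash",
    "first_layer_track",
    "encode_window",
    "window_matrix",
    "build_second_layer_track",
]

#: Amino-acid column order of the ASCII profile matrix (PSI-BLAST order).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

WINDOW_SIZES = (5, 7, 9, 11, 13)


@dataclass
class SequenceProfile:
    """A sequence with its L x 20 integer log-odds profile."""

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"profile shape {self.scores.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class StructTracks:
    """Per-residue helix/strand/coil probabilities and relative accessibility."""

    p_helix: np.ndarray
    p_strand: np.ndarray
    p_coil: np.ndarray
    rsa: np.ndarray

    def __post_init__(self) -> None:
        self.p_helix = np.asarray(self.p_helix, dtype=float)
        self.p_strand = np.asarray(self.p_strand, dtype=float)
        self.p_coil = np.asarray(self.p_coil, dtype=float)
        self.rsa = np.asarray(self.rsa, dtype=float)
        n = len(self.p_helix)
        if not (len(self.p_strand) == len(self.p_coil) == len(self.rsa) == n):
            raise ValueError("structure tracks have inconsistent lengths")
        for name in ("p_helix", "p_strand", "p_coil", "rsa"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
        total = self.p_helix + self.p_strand + self.p_coil
        if n and (total.min() < 0.99 or total.max() > 1.01):
            warnings.warn(
                "helix+strand+coil probabilities are not normalized to 1",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.p_helix)


@dataclass
class ResidueFeatureTrack:
    """A per-residue feature matrix plus the pattern used beyond the termini.

    `matrix` is (L, C); `pad_vector` (C,) is substituted for every virtual
    position outside the chain (its out-of-chain indicator is 1 and all
    other components are 0).
    """

    matrix: np.ndarray
    pad_vector: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.pad_vector = np.asarray(self.pad_vector, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.pad_vector.shape[0]:
            raise ValueError("pad vector width must match the track width")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class WindowedExample:
    center: int  # 1-based residue index
    window: int
    input: np.ndarray
    target: int | None = None


def squash(score) -> np.ndarray | float:
    """Logistic squashing 1/(1+exp(-x)) of raw log-odds into (0, 1)."""
    return expit(score)


# ---------------------------------------------------------------------------
# File formats


def write_psiblast_pssm(profile: SequenceProfile, with_footer: bool = True) -> str:
    """Serialize a profile in the ASCII layout of the iterative search tool."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AA_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        lines.append(
            f"{i:5d} {aa} " + " ".join(f"{int(v):3d}" for v in row)
        )
    if with_footer:
        lines += [
            "",
            "                      K         Lambda",
            "Standard Ungapped    0.1337     0.3176",
            "Standard Gapped      0.0410     0.2670",
        ]
    return "\n".join(lines) + "\n"


def read_psiblast_pssm(text: str) -> SequenceProfile:
    """Parse the ASCII profile matrix; trailing statistics are ignored.

    Raises ``ValueError`` (naming the line number) on malformed rows.
    """
    seq: list[str] = []
    rows: list[list[int]] = []
    expected = 1
    in_body = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            if in_body:
                break  # blank line after the body starts the footer
            continue
        if not tokens[0].isdigit() and not (tokens[0].lstrip("-").isdigit()):
            if in_body:
                break
            continue  # header lines
        try:
            idx = int(tokens[0])
        except ValueError:
            if in_body:
                break
            continue
        if idx != expected:
            if in_body:
                raise ValueError(f"line {lineno}: expected row index {expected}, got {idx}")
            continue
        if len(tokens) < 22:
            raise ValueError(f"line {lineno}: truncated profile row ({len(tokens)} fields)")
        aa = tokens[1]
        if len(aa) != 1 or not aa.isalpha():
            raise ValueError(f"line {lineno}: bad residue letter {aa!r}")
        try:
            values = [int(v) for v in tokens[2:22]]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer score ({exc})") from None
        in_body = True
        seq.append(aa)
        rows.append(values)
        expected += 1
    if not rows:
        raise ValueError("no profile rows found")
    return SequenceProfile(sequence="".join(seq), scores=np.array(rows, dtype=int))


STRUCT_COLUMNS = ("aa", "chain", "position", "rsa", "p_helix", "p_strand", "p_coil")


def write_struct_table(
    struct: StructTracks, sequence: str, chain_id: str = "A"
) -> str:
    """Write the whitespace-delimited structure-prediction table dialect."""
    lines = ["# " + " ".join(STRUCT_COLUMNS)]
    for i, aa in enumerate(sequence):
        lines.append(
            f"{aa} {chain_id} {i + 1:d} {struct.rsa[i]:.4f} "
            f"{struct.p_helix[i]:.4f} {struct.p_strand[i]:.4f} {struct.p_coil[i]:.4f}"
        )
    return "\n".join(lines) + "\n"


def read_struct_table(text: str) -> tuple[str, str, StructTracks]:
    """Read the structure table; returns (sequence, chain_id, tracks)."""
    df = pd.read_csv(
        io.StringIO(text),
        sep=r"\s+",
        comment="#",
        header=None,
        names=STRUCT_COLUMNS,
    )
    if df.empty:
        raise ValueError("structure table has no rows")
    sequence = "".join(df["aa"].astype(str))
    struct = StructTracks(
        p_helix=df["p_helix"].to_numpy(),
        p_strand=df["p_strand"].to_numpy(),
        p_coil=df["p_coil"].to_numpy(),
        rsa=df["rsa"].to_numpy(),
    )
    return sequence, str(df["chain"].iloc[0]), struct


def read_fasta(text: str) -> dict[str, str]:
    """Parse multi-record FASTA text into an id -> sequence mapping."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    return {rec.id: str(rec.seq) for rec in records}


def write_fasta(sequences: dict[str, str]) -> str:
    handle = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()],
        handle,
        "fasta",
    )
    return handle.getvalue()


# ---------------------------------------------------------------------------
# Window encoding


def first_layer_track(profile: SequenceProfile, struct: StructTracks) -> ResidueFeatureTrack:
    """The 25-value-per-residue first-layer encoding.

    Layout: 20 squashed profile scores, out-of-chain indicator (0 inside the
    chain), p(helix), p(strand), p(coil), relative accessibility.
    """
    if len(struct) != len(profile.sequence):
        raise ValueError("profile and structure tracks differ in length")
    length = len(profile.sequence)
    matrix = np.zeros((length, 25))
    matrix[:, :20] = squash(profile.scores)
    matrix[:, 21] = struct.p_helix
    matrix[:, 22] = struct.p_strand
    matrix[:, 23] = struct.p_coil
    matrix[:, 24] = struct.rsa
    pad = np.zeros(25)
    pad[20] = 1.0
    return ResidueFeatureTrack(matrix=matrix, pad_vector=pad)


def encode_window(track: ResidueFeatureTrack, center: int, window: int) -> WindowedExample:
    """Concatenate the residue vectors of a window centered on `center`.

    `center` is 1-based; positions before the first or after the last
    residue contribute the track's out-of-chain pad vector.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window size must be odd and positive, got {window}")
    if not 1 <= center <= len(track):
        raise IndexError(f"center {center} outside chain of length {len(track)}")
    half = window // 2
    parts = []
    for offset in range(-half, half + 1):
        pos = center - 1 + offset
        if 0 <= pos < len(track):
            parts.append(track.matrix[pos])
        else:
            parts.append(track.pad_vector)
    return WindowedExample(center=center, window=window, input=np.concatenate(parts))


def window_matrix(track: ResidueFeatureTrack, window: int) -> np.ndarray:
    """All window encodings of a chain stacked into an (L, C*window) matrix."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window size must be odd and positive, got {window}")
    half = window // 2
    length, width = track.matrix.shape
    padded = np.vstack(
        [np.tile(track.pad_vector, (half, 1)), track.matrix, np.tile(track.pad_vector, (half, 1))]
    )
    return np.concatenate(
        [padded[k : k + length] for k in range(window)], axis=1
    )


#: Second-layer setup letters -> channel composition.  Channels:
#: "pssm" (20 squashed profile values), "pos" (four first-layer position
#: scores), "gen" (the first-layer general turn score), "secrsa"
#: (helix/strand/coil + accessibility).
SETUPS: dict[str, tuple[str, ...]] = {
    "A": ("pssm", "secrsa"),
    "B": ("pssm", "gen", "secrsa"),
    "C": ("pssm", "gen"),
    "D": ("pssm", "pos"),
    "E": ("pos",),
    "F": ("gen", "secrsa"),
    "G": ("gen",),
    "H": ("pssm", "pos", "secrsa"),
    "I": ("pos", "secrsa"),
    "J": ("pssm", "pos", "gen", "secrsa"),
    "K": ("pssm", "pos", "gen"),
    "L": ("pos", "gen"),
    "M": ("pos", "gen", "secrsa"),
}


def build_second_layer_track(
    setup: str,
    gen_scores: np.ndarray | None = None,
    pos_scores: np.ndarray | None = None,
    struct: StructTracks | None = None,
    profile: SequenceProfile | None = None,
) -> ResidueFeatureTrack:
    """Compose the per-residue second-layer input track for a lettered setup.

    Channel blocks appear in the order pssm, pos(4), gen, sec-rsa(4); an
    out-of-chain indicator column is placed directly after the pssm block
    when present (so setup A reproduces the first-layer encoding exactly)
    and appended last otherwise.
    """
    setup = setup.upper()
    if setup not in SETUPS:
        raise ValueError(f"unknown setup {setup!r}; expected one of A..M")
    channels = SETUPS[setup]
    blocks: list[np.ndarray] = []
    length = None

    def _need(arr, name):
        if arr is None:
            raise ValueError(f"setup {setup} requires the {name} channel")
        return arr

    indicator_after_pssm = "pssm" in channels
    if "pssm" in channels:
        prof = _need(profile, "pssm")
        blocks.append(squash(prof.scores))
        length = len(prof.sequence)
        blocks.append(np.zeros((length, 1)))  # out-of-chain indicator
    if "pos" in channels:
        p = np.asarray(_need(pos_scores, "position-score"), dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("position scores must be an (L, 4) array")
        blocks.append(p)
        length = len(p) if length is None else length
    if "gen" in channels:
        g = np.asarray(_need(gen_scores, "general-score"), dtype=float)
        blocks.append(g.reshape(-1, 1))
        length = len(g) if length is None else length
    if "secrsa" in channels:
        s = _need(struct, "sec-rsa")
        blocks.append(
            np.column_stack([s.p_helix, s.p_strand, s.p_coil, s.rsa])
        )
        length = len(s) if length is None else length
    if not indicator_after_pssm:
        blocks.append(np.zeros((length, 1)))
    if len({len(b) for b in blocks}) != 1:
        raise ValueError("channel tracks differ in length")
    matrix = np.concatenate(blocks, axis=1)
    pad = np.zeros(matrix.shape[1])
    pad[20 if indicator_after_pssm else matrix.shape[1] - 1] = 1.0
    return ResidueFeatureTrack(matrix=matrix, pad_vector=pad)
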