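"""The 19-residue hydrophobic-crest motif: definition, scanning, conservation.

Septin NC-interfaces are stabilised by a ridge ("crest") of hydrophobic
residues running from the hook loop through the alpha0-helix to the first
residue of beta1.  Across yeast and human septins the crest sits inside a
19-position consensus

    V/I/F(1) G(2) F/I(3) x(4) x(5) L/I/V(6) P-or-h(7) x(8) Q(9) h(10)
    x(11..14) h(15) x(16..18) F/I(19)

where ``h`` is any residue scoring above 0.5 on the Eisenberg normalized
consensus hydrophobicity scale (with that threshold the hydrophobic set is
exactly {I, F, V, L}) and ``x`` is unconstrained.  The six key positions
1, 3, 6, 10, 15 and 19 carry the buried interface residues (in Cdc10:
V13, F15, I18, I22, L27, F31).

Real septin sequences violate individual soft constraints — Cdc10 has T at
position 7, Cdc12 an R at position 10 — so the default scan mode is
``scored``: the hard anchors {1, 3, 19} must hold and at least half of the
remaining constrained positions must pass.  ``strict`` requires every
constrained position; ``anchored`` evaluates one given window without any
thresholding (the right tool when the anchor residue is known).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EISENBERG_SCALE",
    "HydrophobicityScale",
    "MotifDefinition",
    "MotifMatch",
    "CREST_MOTIF",
    "KEY_POSITIONS",
    "scan_motif",
    "key_residue_numbers",
    "anchor_from_key",
    "key_hydrophobic_count",
    "column_conservation",
    "consensus_frequencies",
    "read_fasta",
    "CONSERVATION_CLASSES",
]

# Eisenberg normalized consensus hydrophobicity values, one per standard
# amino acid. At threshold 0.5 the hydrophobic set is exactly {I, F, V, L}.
EISENBERG_SCALE: dict[str, float] = {
    "I": 0.73, "F": 0.61, "V": 0.54, "L": 0.53, "W": 0.37,
    "M": 0.26, "A": 0.25, "G": 0.16, "C": 0.04, "Y": 0.02,
    "P": -0.07, "T": -0.18, "S": -0.26, "H": -0.40, "E": -0.62,
    "N": -0.64, "Q": -0.69, "D": -0.72, "K": -1.10, "R": -1.76,
}

KEY_POSITIONS: tuple[int, ...] = (1, 3, 6, 10, 15, 19)

# Offsets of the key positions from the anchor (position 1), 1-based.
_KEY_OFFSETS: dict[int, int] = {p: p - 1 for p in KEY_POSITIONS}

MOTIF_LENGTH = 19


@dataclass
class HydrophobicityScale:
    """A per-residue hydrophobicity table with a classification threshold."""

    name: str = "eisenberg_consensus"
    values: dict[str, float] = field(default_factory=lambda: dict(EISENBERG_SCALE))
    hydrophobic_threshold: float = 0.5

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} lacks residues {sorted(missing)}")
        lo, hi = min(self.values.values()), max(self.values.values())
        if not lo <= self.hydrophobic_threshold <= hi:
            raise ValueError("threshold outside the scale's score range")

    def is_hydrophobic(self, residue: str) -> bool:
        return self.values.get(residue, float("-inf")) > self.hydrophobic_threshold

    def hydrophobic_set(self) -> frozenset[str]:
        return frozenset(r for r in self.values if self.is_hydrophobic(r))


def _build_position_classes(scale: HydrophobicityScale) -> dict[int, frozenset[str]]:
    h = scale.hydrophobic_set()
    return {
        1: frozenset("VIF"),
        2: frozenset("G"),
        3: frozenset("FI"),
        6: frozenset("LIV"),
        7: frozenset("P") | h,
        9: frozenset("Q"),
        10: h,
        15: h,
        19: frozenset("FI"),
    }


@dataclass
class MotifDefinition:
    """The 19-position crest consensus.

    ``position_classes`` maps each constrained position to its allowed
    residue set; positions absent from the map are unconstrained (``x``).
    ``hard_positions`` must pass in scored mode; ``scored_positions`` (the
    remaining constrained positions) feed the match score.
    """

    scale: HydrophobicityScale = field(default_factory=HydrophobicityScale)
    length: int = MOTIF_LENGTH
    position_classes: dict[int, frozenset[str]] = field(default_factory=dict)
    key_positions: tuple[int, ...] = KEY_POSITIONS
    hard_positions: frozenset[int] = frozenset({1, 3, 19})

    def __post_init__(self) -> None:
        if not self.position_classes:
            self.position_classes = _build_position_classes(self.scale)
        if not set(self.key_positions) <= set(range(1, self.length + 1)):
            raise ValueError("key positions outside 1..length")
        if not self.hard_positions <= set(self.position_classes):
            raise ValueError("hard positions must be constrained positions")

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.position_classes))

    @property
    def scored_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.constrained_positions if p not in self.hard_positions)

    def position_passes(self, position: int, residue: str) -> bool:
        allowed = self.position_classes.get(position)
        if allowed is None:
            return True
        return residue in allowed


CREST_MOTIF = MotifDefinition()


@dataclass
class MotifMatch:
    sequence_id: str
    start: int                      # 1-based index into the scanned sequence
    start_residue_number: int       # author numbering of the anchor residue
    window: str
    per_position_pass: tuple[bool, ...]
    score: float                    # fraction of constrained positions passing
    key_hydrophobic_count: int

    def key_residues(self) -> dict[int, str]:
        return {p: self.window[p - 1] for p in KEY_POSITIONS}


def _evaluate_window(window: str, motif: MotifDefinition) -> tuple[tuple[bool, ...], float]:
    passes = []
    for pos in range(1, motif.length + 1):
        residue = window[pos - 1]
        if pos in motif.position_classes and residue == "X":
            passes.append(False)  # unknown residue cannot satisfy a constraint
        else:
            passes.append(motif.position_passes(pos, residue))
    constrained = motif.constrained_positions
    score = sum(passes[p - 1] for p in constrained) / len(constrained)
    return tuple(passes), score


def scan_motif(sequence: str, motif: MotifDefinition = CREST_MOTIF,
               mode: str = "scored", min_score: float = 0.5,
               sequence_id: str = "", numbering: list[int] | None = None,
               anchored_start: int | None = None) -> list[MotifMatch]:
    """Scan a one-letter sequence for crest-motif windows.

    ``numbering`` optionally maps each sequence index to an author residue
    number (defaults to 1..len).  Modes:

    - ``strict``:   every constrained position must pass;
    - ``scored``:   hard anchors pass and score >= ``min_score``;
    - ``anchored``: evaluate exactly the window starting at ``anchored_start``
      (1-based), no thresholding — always returns that one evaluated match.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if numbering is None:
        numbering = list(range(1, n + 1))
    if len(numbering) != n:
        raise ValueError("numbering map length differs from sequence length")

    if mode == "anchored":
        if anchored_start is None:
            raise ValueError("anchored mode requires anchored_start")
        if not 1 <= anchored_start <= n - motif.length + 1:
            raise ValueError(
                f"anchored window [{anchored_start}, {anchored_start + motif.length - 1}] "
                f"outside sequence of length {n}"
            )
        starts = [anchored_start]
    elif mode in ("strict", "scored"):
        if n < motif.length:
            raise ValueError(f"sequence shorter than motif ({n} < {motif.length})")
        starts = range(1, n - motif.length + 2)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    matches = []
    for start in starts:
        window = sequence[start - 1:start - 1 + motif.length]
        passes, score = _evaluate_window(window, motif)
        if mode == "strict" and not all(passes[p - 1] for p in motif.constrained_positions):
            continue
        if mode == "scored":
            if not all(passes[p - 1] for p in motif.hard_positions):
                continue
            if score < min_score:
                continue
        keys = "".join(window[p - 1] for p in KEY_POSITIONS)
        matches.append(MotifMatch(
            sequence_id=sequence_id,
            start=start,
            start_residue_number=numbering[start - 1],
            window=window,
            per_position_pass=passes,
            score=score,
            key_hydrophobic_count=sum(motif.scale.is_hydrophobic(r) for r in keys),
        ))
    return matches


def key_residue_numbers(anchor_residue_number: int,
                        numbering: list[int] | None = None) -> dict[int, int]:
    """Author residue numbers of the six key positions for a given anchor.

    With the anchor (key position 1) at author residue ``a`` and contiguous
    numbering, key positions 1, 3, 6, 10, 15, 19 sit at a, a+2, a+5, a+9,
    a+14, a+18.  If a ``numbering`` map (author numbers of the 19 window
    residues) is supplied and is non-contiguous, the mapped numbers are used
    and a warning is raised.
    """
    if numbering is not None:
        if len(numbering) != MOTIF_LENGTH:
            raise ValueError("numbering map must cover the 19-residue window")
        if numbering != list(range(numbering[0], numbering[0] + MOTIF_LENGTH)):
            warnings.warn("non-contiguous residue numbering in motif window",
                          stacklevel=2)
        return {p: numbering[off] for p, off in _KEY_OFFSETS.items()}
    a = anchor_residue_number
    return {p: a + off for p, off in _KEY_OFFSETS.items()}


def anchor_from_key(key_position: int, residue_number: int) -> int:
    """Anchor (key position 1) residue number given one key position's number.

    E.g. SEPT9's F297 at key position 19 implies the anchor at residue 279,
    which puts key position 10 at M288.
    """
    if key_position not in _KEY_OFFSETS:
        raise ValueError(f"{key_position} is not a key position {KEY_POSITIONS}")
    return residue_number - _KEY_OFFSETS[key_position]


def key_hydrophobic_count(match: MotifMatch,
                          scale: HydrophobicityScale | None = None) -> int:
    """Number of key positions (of 6) above the hydrophobicity threshold."""
    scale = scale or HydrophobicityScale()
    return sum(scale.is_hydrophobic(r) for r in match.key_residues().values())


# Physicochemical residue classes for the 0-10 conservation degree: a column
# is scored by its dominant class frequency, so conservative substitutions
# (I<->L, D<->E) do not destroy the score.
CONSERVATION_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("ILVM"), frozenset("FWY"), frozenset("C"), frozenset("AG"),
    frozenset("ST"), frozenset("NQ"), frozenset("DE"), frozenset("KR"),
    frozenset("H"), frozenset("P"),
)

_CLASS_OF: dict[str, int] = {
    r: i for i, cls in enumerate(CONSERVATION_CLASSES) for r in cls
}

GAP_CHARS = frozenset("-.")


def _check_alignment(alignment: list[tuple[str, str]]) -> int:
    if len(alignment) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return lengths.pop()


def column_conservation(alignment: list[tuple[str, str]],
                        columns: range | None = None) -> list[int]:
    """Per-column conservation degree 0 (not conserved) to 10 (absolute).

    Score = round(10 x highest physicochemical-class frequency over all rows).
    Gaps form their own non-scoring class, so an all-gap column scores 0 and
    gappy columns are penalised.  ``columns`` is a 0-based range (default:
    all columns).
    """
    ncol = _check_alignment(alignment)
    columns = columns if columns is not None else range(ncol)
    nrow = len(alignment)
    scores = []
    for col in columns:
        if not 0 <= col < ncol:
            raise IndexError(f"column {col} outside alignment of width {ncol}")
        counts = np.zeros(len(CONSERVATION_CLASSES))
        for _, seq in alignment:
            residue = seq[col].upper()
            if residue in GAP_CHARS:
                continue
            idx = _CLASS_OF.get(residue)
            if idx is not None:
                counts[idx] += 1
        scores.append(int(round(10.0 * counts.max() / nrow)))
    return scores


def consensus_frequencies(alignment: list[tuple[str, str]]
                          ) -> tuple[list[dict[str, float]], str, list[bool]]:
    """Per-column residue frequencies, majority consensus and tie flags.

    Frequencies are over non-gap residues (they sum to 1 in any column with
    at least one residue); the gap fraction is reported under the key
    ``'-'`` separately from the residue frequencies.  Consensus is the modal
    residue, alphabetical first on ties (flagged).
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = _check_alignment(alignment)
    freqs: list[dict[str, float]] = []
    consensus: list[str] = []
    tie_flags: list[bool] = []
    nrow = len(alignment)
    for col in range(ncol):
        residues = [seq[col].upper() for _, seq in alignment]
        non_gap = [r for r in residues if r not in GAP_CHARS]
        table: dict[str, float] = {}
        if non_gap:
            for r in sorted(set(non_gap)):
                table[r] = non_gap.count(r) / len(non_gap)
        gap_fraction = (nrow - len(non_gap)) / nrow
        if gap_fraction:
            table["-"] = gap_fraction
        freqs.append(table)
        if non_gap:
            best = max(table[r] for r in table if r != "-")
            winners = sorted(r for r in table if r != "-" and table[r] == best)
            consensus.append(winners[0])
            tie_flags.append(len(winners) > 1)
        else:
            consensus.append("-")
            tie_flags.append(False)
    return freqs, "".join(consensus), tie_flags


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA / aligned FASTA."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
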