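"""Core data model: residue-level tracks and 1-based closed intervals.

All public interfaces (file formats, reports, printed residue ranges) use
1-based closed coordinates, the convention of the structural-biology
literature (e.g. "residues 58-95").  Internal mask arithmetic is 0-based;
:meth:`Segment.to_slice` and :meth:`Segment.from_slice` are the single
conversion points, so no other code performs off-by-one arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 canonical amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letters accepted in protein sequences (canonical + unknown).
VALID_RESIDUES = frozenset(AA20 + "X")

#: Gap character used in alignments.
GAP = "-"

#: Annotation track names understood by the interval-track machinery.
TRACK_NAMES = frozenset(
    {
        "disorder",
        "morf",
        "aibs",
        "domain",
        "elm_CLV",
        "elm_LIG",
        "elm_MOD",
        "elm_TRG",
        "insertion",
        "mutation",
    }
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True, order=True)
class Segment:
    """A 1-based closed residue interval ``[start, end]``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_slice(self) -> slice:
        """0-based half-open slice covering this segment."""
        return slice(self.start - 1, self.end)

    @classmethod
    def from_slice(cls, s: slice) -> "Segment":
        return cls(s.start + 1, s.stop)

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence; may carry gaps when part of an MSA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass
class ScoreTrack:
    """Per-residue real values aligned to a protein sequence."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"score track for {self.protein_id!r} must be a non-empty vector")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class IntervalTrack:
    """Sorted, non-overlapping 1-based closed intervals on one protein."""

    protein_id: str
    track_name: str
    intervals: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping intervals {prev} and {cur} in track "
                    f"{self.track_name!r} of {self.protein_id!r}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def mask(self, length: int) -> np.ndarray:
        return segments_to_mask(self.intervals, length)


def segments_to_mask(segments, length: int) -> np.ndarray:
    """Boolean per-residue mask (0-based) covered by 1-based segments."""
    mask = np.zeros(length, dtype=bool)
    for seg in segments:
        if seg.end > length:
            raise ValueError(f"segment {seg} exceeds sequence length {length}")
        mask[seg.to_slice()] = True
    return mask


def mask_to_segments(mask) -> list[Segment]:
    """Maximal runs of True in a boolean mask, as 1-based closed segments."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)  # 0-based run starts
    ends = np.flatnonzero(diff == -1)  # 0-based exclusive run ends
    return [Segment.from_slice(slice(int(s), int(e))) for s, e in zip(starts, ends)]


def validate_sequence(sequence: str, *, allow_gaps: bool = False) -> None:
    allowed = VALID_RESIDUES | {GAP} if allow_gaps else VALID_RESIDUES
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
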