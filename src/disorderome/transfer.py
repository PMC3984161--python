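"""Function annotation of disordered segments by local-alignment transfer.

Each query segment is aligned against every entry of a function-labelled
disordered-segment library (DisProt-style) with the Smith-Waterman
algorithm under EMBOSS ``water`` defaults: BLOSUM62, gap open 10 charged on
the first gap residue, gap extend 0.5 on each subsequent one.  Sequence
similarity is the number of identical residues in the local alignment
divided by the larger of the alignment length and the length of the shorter
segment; a function label is transferred when similarity strictly exceeds
the 0.8 threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT, Config
from .core import validate_sequence


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment; ``length`` counts alignment columns."""

    aligned_a: str
    aligned_b: str
    score: float
    length: int
    n_identities: int

    def __post_init__(self) -> None:
        if self.n_identities > self.length:
            raise ValueError("identities cannot exceed alignment length")

    @classmethod
    def empty(cls) -> "LocalAlignment":
        return cls("", "", 0.0, 0, 0)


@dataclass(frozen=True)
class TransferHit:
    query_id: str
    library_id: str
    similarity: float
    function: str


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open_gap_score on the first gapped position and
    # extend_gap_score on each further one — the EMBOSS water convention.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    a: str,
    b: str,
    matrix: str = DEFAULT.substitution_matrix,
    gap_open: float = DEFAULT.gap_open,
    gap_extend: float = DEFAULT.gap_extend,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two segments.

    When no residue pair scores positively the optimal local alignment is
    empty and a zero-score :class:`LocalAlignment` is returned.  Ties among
    co-optimal alignments are broken deterministically (first traceback).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    validate_sequence(a)
    validate_sequence(b)
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return LocalAlignment.empty()
    alignment = next(iter(aligner.align(a, b)))
    counts = alignment.counts()
    return LocalAlignment(
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        score=float(score),
        length=int(alignment.length),
        n_identities=int(counts.identities),
    )


def segment_similarity(alignment: LocalAlignment, len_a: int, len_b: int) -> float:
    """Identities / max(alignment length, length of the shorter segment)."""
    if alignment.length == 0:
        return 0.0
    return alignment.n_identities / max(alignment.length, min(len_a, len_b))


def transfer_annotations(
    queries,
    library,
    threshold: float = DEFAULT.transfer_similarity,
    best_only: bool = False,
    config: Config = DEFAULT,
):
    """Annotate query segments against a labelled segment library.

    ``queries`` is a mapping id -> sequence (or iterable of (id, sequence)
    pairs); ``library`` an iterable of entries with ``entry_id``,
    ``sequence`` and ``function`` attributes.  A hit is emitted for every
    library entry whose similarity to the query strictly exceeds
    ``threshold`` (or only the best such entry with ``best_only``).

    Returns ``(hits, census)``: the hit list and a per-function count of
    annotated segments, where a segment carrying one function through
    several library entries counts once per distinct function.
    """
    if not library:
        raise ValueError("segment library is empty")
    items = queries.items() if hasattr(queries, "items") else list(queries)
    hits: list[TransferHit] = []
    for query_id, seq in items:
        candidates = []
        for entry in library:
            aln = smith_waterman(
                seq, entry.sequence, config.substitution_matrix, config.gap_open, config.gap_extend
            )
            similarity = segment_similarity(aln, len(seq), len(entry.sequence))
            if similarity > threshold:
                candidates.append(TransferHit(query_id, entry.entry_id, similarity, entry.function))
        if best_only and candidates:
            candidates = [max(candidates, key=lambda h: h.similarity)]
        hits.extend(candidates)
    annotated = {(h.query_id, h.function) for h in hits}
    census = Counter(function for _, function in annotated)
    return hits, dict(census)


def annotated_segment_count(hits) -> int:
    """Number of distinct query segments with at least one transferred label."""
    return len({h.query_id for h in hits})
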