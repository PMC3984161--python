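"""Alignment-column machinery for families of splice variants.

Per-chain annotation tracks (disorder, MoRFs, domains, linear motifs) are
lifted into the column space of a multiple sequence alignment, columns are
classified as identical / mutation / insertion sites, and majority-vote
profiles are built: an annotation enters the profile at a column when at
least half of the variants carry it there.  Overlap statistics between
column-space tracks (e.g. what fraction of insertion-site residues is
disordered) and linear-motif censuses are computed on top.

Column classification rules: a column containing at least one gap is an
insertion site (a splice-cassette difference); a gap-free column with a
single residue letter is identical; a gap-free column with several letters
is a mutation site.  A gapped column whose non-gap residues differ is
additionally flagged as a mutation, so the mutation and insertion classes
overlap and their fractions may total more than 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT, Config
from .core import GAP, IntervalTrack, Segment, mask_to_segments, segments_to_mask


def column_maps(msa) -> np.ndarray:
    """(n_chains, n_cols) array of 0-based residue indices, -1 at gaps."""
    n_cols = len(msa[0].sequence)
    maps = np.full((len(msa), n_cols), -1, dtype=int)
    for v, rec in enumerate(msa):
        if len(rec.sequence) != n_cols:
            raise ValueError(f"ragged alignment row {rec.id!r}")
        idx = 0
        for c, ch in enumerate(rec.sequence):
            if ch != GAP:
                maps[v, c] = idx
                idx += 1
    return maps


def presence_matrix(msa) -> np.ndarray:
    """(n_chains, n_cols) boolean: chain has a residue at the column."""
    return column_maps(msa) >= 0


def lift_track(msa, tracks: dict) -> np.ndarray:
    """Lift per-chain interval tracks into column space.

    ``tracks`` maps chain id -> :class:`IntervalTrack` (or plain segment
    list).  Returns a boolean (n_chains, n_cols) membership matrix:
    entry (v, c) is True iff column c maps to a residue of chain v that
    lies inside one of its intervals.  Gap positions stay False.  Intervals
    beyond a chain's ungapped length raise an error naming the chain.
    """
    maps = column_maps(msa)
    membership = np.zeros(maps.shape, dtype=bool)
    for v, rec in enumerate(msa):
        track = tracks.get(rec.id)
        if track is None:
            continue
        intervals = track.intervals if isinstance(track, IntervalTrack) else list(track)
        length = len(rec.ungapped)
        try:
            chain_mask = segments_to_mask(intervals, length)
        except ValueError as exc:
            raise ValueError(f"track exceeds chain {rec.id!r} (length {length}): {exc}") from exc
        present = maps[v] >= 0
        membership[v, present] = chain_mask[maps[v, present]]
    return membership


def project_track(msa, chain_id: str, column_segments) -> list[Segment]:
    """Map column-space segments back onto one chain's residue coordinates."""
    ids = [rec.id for rec in msa]
    v = ids.index(chain_id)
    maps = column_maps(msa)
    n_cols = maps.shape[1]
    col_mask = segments_to_mask(column_segments, n_cols)
    residue_idx = maps[v][col_mask & (maps[v] >= 0)]
    chain_mask = np.zeros(len(msa[v].ungapped), dtype=bool)
    chain_mask[residue_idx] = True
    return mask_to_segments(chain_mask)


def call_variation(msa) -> pd.DataFrame:
    """Classify each alignment column as identical / mutation / insertion.

    Returns a DataFrame with 1-based ``column`` plus boolean flags.  The
    classes are not disjoint: gapped columns whose non-gap residues differ
    carry both the insertion and the mutation flag.
    """
    if len(msa) < 2:
        raise ValueError("variation calling needs at least two chains")
    rows = [rec.sequence for rec in msa]
    n_cols = len(rows[0])
    records = []
    for c in range(n_cols):
        letters = [row[c] for row in rows]
        has_gap = GAP in letters
        residues = {ch for ch in letters if ch != GAP}
        mutated = len(residues) >= 2
        records.append(
            {
                "column": c + 1,
                "identical": not has_gap and len(residues) == 1,
                "mutation": mutated,
                "insertion": has_gap,
            }
        )
    return pd.DataFrame(records)


def variation_fractions(variation: pd.DataFrame) -> dict:
    """Column-class fractions in percent; classes overlap so they may total >100."""
    n = len(variation)
    return {
        "identical_pct": 100.0 * variation["identical"].mean(),
        "mutation_pct": 100.0 * variation["mutation"].mean(),
        "insertion_pct": 100.0 * variation["insertion"].mean(),
        "n_columns": n,
    }


def majority_profile(
    membership: np.ndarray,
    majority_fraction: float = DEFAULT.majority_fraction,
    presence: np.ndarray | None = None,
):
    """Columns where the annotation vote reaches the majority fraction.

    The vote denominator defaults to all variants in the alignment (rows of
    ``membership``), so an annotation confined to a minority splice cassette
    does not become "majority" merely because the other chains are gapped
    there.  Passing ``presence`` switches to a present-chains-only
    denominator.  Returns ``(vote, segments)`` where ``vote`` is the
    per-column fraction and ``segments`` the maximal 1-based column
    intervals with vote >= ``majority_fraction``.
    """
    membership = np.asarray(membership, dtype=bool)
    counts = membership.sum(axis=0).astype(float)
    if presence is None:
        denom = np.full(membership.shape[1], float(membership.shape[0]))
    else:
        denom = np.asarray(presence, dtype=bool).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vote = np.where(denom > 0, counts / np.maximum(denom, 1e-300), 0.0)
    return vote, mask_to_segments(vote >= majority_fraction)


def overlap_stats(track_a, track_b, length: int | None = None):
    """Percentage of A-positions lying inside B; NaN when A is empty.

    Both arguments are boolean masks or segment lists over the same
    coordinate space (``length`` required for segment lists).
    """
    mask_a = _as_mask(track_a, length)
    mask_b = _as_mask(track_b, length if length is not None else mask_a.size)
    if mask_a.size != mask_b.size:
        raise ValueError("tracks live in different coordinate spaces")
    n_a = mask_a.sum()
    if n_a == 0:
        return float("nan")
    return 100.0 * float((mask_a & mask_b).sum()) / float(n_a)


def _as_mask(track, length) -> np.ndarray:
    if isinstance(track, np.ndarray) and track.dtype == bool:
        return track
    arr = np.asarray(track)
    if arr.dtype != object and arr.ndim == 1 and arr.size and not isinstance(arr.flat[0], Segment):
        return arr.astype(bool)
    if length is None:
        raise ValueError("length required to rasterize segment lists")
    return segments_to_mask(list(track), length)


def elm_census(elm_tracks: dict) -> dict:
    """Number of motif sites per linear-motif type (one interval = one site)."""
    return {elm_type: len(list(track)) for elm_type, track in elm_tracks.items()}


def cterm_type(record) -> str:
    """Variant group label: the last three ungapped residues of the chain."""
    ungapped = record.ungapped
    if len(ungapped) < 3:
        raise ValueError(f"chain {record.id!r} shorter than 3 residues")
    return ungapped[-3:]


def group_by_cterm(records) -> dict:
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(cterm_type(rec), []).append(rec)
    return groups
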