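"""Disordered-segment extraction and per-protein disorder statistics.

A residue is called disordered when its propensity score reaches the 0.5
threshold; a disordered segment is a maximal run of at least 4 consecutive
disordered residues, and a long segment one of at least 30.  These
definitions drive the per-protein summaries (disorder content, segment
counts, fully-disordered flag), the cohort-level length distribution, and
the hub-protein binding-site table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT, Config
from .core import Segment, mask_to_segments


def binarize(scores, threshold: float = DEFAULT.disorder_threshold) -> np.ndarray:
    """Per-residue disorder calls: 1 iff score >= threshold.

    The tie at exactly the threshold is resolved inclusively, so predictors
    emitting 0.5 for ambiguous residues count those as disordered.
    """
    values = np.asarray(scores, dtype=float)
    return (values >= threshold).astype(np.int8)


def extract_segments(calls, min_len: int = DEFAULT.min_segment_len) -> list[Segment]:
    """Maximal runs of disordered calls of length >= ``min_len``, sorted."""
    calls = np.asarray(calls)
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("calls must be binary")
    return [seg for seg in mask_to_segments(calls.astype(bool)) if seg.length >= min_len]


@dataclass
class ProteinDisorderSummary:
    protein_id: str
    length: int
    content: float
    n_segments: int
    n_long_segments: int
    segment_lengths: list[int]
    fully_disordered: bool


def summarize_protein(protein_id, calls, config: Config = DEFAULT) -> ProteinDisorderSummary:
    """Disorder content, segment counts, and length list for one protein.

    Content is computed from the raw calls, not from the extracted segments,
    so sub-threshold runs still contribute to it.
    """
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError(f"zero-length protein {protein_id!r}")
    segs = extract_segments(calls, config.min_segment_len)
    lengths = [s.length for s in segs]
    content = float(calls.mean())
    return ProteinDisorderSummary(
        protein_id=protein_id,
        length=int(calls.size),
        content=content,
        n_segments=len(segs),
        n_long_segments=sum(1 for n in lengths if n >= config.long_segment_len),
        segment_lengths=lengths,
        fully_disordered=content == 1.0,
    )


def length_histogram(summaries, bin_edges, config: Config = DEFAULT):
    """Binned counts of segment lengths across a cohort plus the long fraction.

    Returns ``(counts, fraction_long)`` where counts partition all segments
    over ``bin_edges`` (right-open bins, final bin right-closed) and
    ``fraction_long`` is the share of segments of length >= 30.
    """
    lengths = np.array(
        [n for s in summaries for n in s.segment_lengths], dtype=float
    )
    if lengths.size == 0:
        raise ValueError("no disordered segments in cohort")
    counts, _ = np.histogram(lengths, bins=bin_edges)
    fraction_long = float((lengths >= config.long_segment_len).mean())
    return counts, fraction_long


def hub_table(graph, tracks, config: Config = DEFAULT) -> pd.DataFrame:
    """Per-hub census of disorder-based binding regions.

    Hubs are nodes with interaction degree >= ``config.hub_degree``.
    ``tracks`` maps protein id -> {"morf": IntervalTrack, "aibs":
    IntervalTrack}; proteins without tracks get explicit missing markers.
    """
    rows = []
    for node in sorted(graph.nodes()):
        degree = graph.degree(node)
        if degree < config.hub_degree:
            continue
        entry = tracks.get(node, {})
        morf = entry.get("morf")
        aibs = entry.get("aibs")
        rows.append(
            {
                "protein_id": node,
                "degree": degree,
                "n_morfs": len(morf) if morf is not None else pd.NA,
                "morf_locations": ", ".join(map(str, morf.intervals)) if morf is not None else pd.NA,
                "n_aibs": len(aibs) if aibs is not None else pd.NA,
                "aibs_locations": ", ".join(map(str, aibs.intervals)) if aibs is not None else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "degree", "n_morfs", "morf_locations", "n_aibs", "aibs_locations"],
    ).sort_values("degree", ascending=False, kind="stable").reset_index(drop=True)
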