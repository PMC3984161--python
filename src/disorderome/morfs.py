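"""Typing of molecular recognition features (MoRFs) from secondary structure.

MoRFs are short (5-25 residue) disordered regions that fold upon binding.
Each predicted region is typed by the 3-state secondary structure (H/E/C)
predicted over its residues: alpha when helix strictly dominates, beta when
strand dominates, gamma when coil dominates, and complex when no single
state covers more than the dominance fraction (default one half) of the
region.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT, Config
from .core import Segment

MORF_TYPES = ("alpha", "beta", "gamma", "complex")

_STATE_TO_TYPE = {"H": "alpha", "E": "beta", "C": "gamma"}


@dataclass(frozen=True)
class MoRFRegion:
    segment: Segment
    morf_type: str


def classify_morf(
    ss: str,
    region: Segment,
    dominance_fraction: float = DEFAULT.dominance_fraction,
    config: Config = DEFAULT,
) -> str:
    """Type one MoRF region from a 3-state secondary-structure string.

    ``ss`` uses the alphabet H (helix), E (strand), C (coil).  The region
    is typed after the state that covers strictly more than
    ``dominance_fraction`` of its residues; with no such state it is
    ``complex``.  Regions outside the expected 5-25 residue length range
    are typed anyway but trigger a warning.
    """
    if region.end > len(ss):
        raise ValueError(f"region {region} outside secondary-structure bounds (L={len(ss)})")
    states = ss[region.to_slice()]
    if bad := set(states) - set("HEC"):
        raise ValueError(f"invalid secondary-structure states {sorted(bad)}")
    lo, hi = config.morf_len_range
    if not lo <= region.length <= hi:
        warnings.warn(f"MoRF region {region} has length {region.length} outside [{lo}, {hi}]")
    counts = Counter(states)
    state, top = counts.most_common(1)[0]
    if top / region.length > dominance_fraction:
        return _STATE_TO_TYPE[state]
    return "complex"


def classify_regions(ss: str, regions, **kwargs) -> list[MoRFRegion]:
    return [MoRFRegion(r, classify_morf(ss, r, **kwargs)) for r in regions]


def morf_type_census(typed_by_protein: dict) -> dict:
    """Cohort-level census of typed MoRF regions.

    ``typed_by_protein`` maps protein id -> list of :class:`MoRFRegion`.
    Returns per-protein counts (DataFrame), the median / 25th / 75th centile
    of regions per protein, per-type totals and per-type fractions (summing
    to 1 over the four types).
    """
    rows = []
    totals = Counter()
    for pid, regions in typed_by_protein.items():
        by_type = Counter(r.morf_type for r in regions)
        totals.update(by_type)
        rows.append({"protein_id": pid, "n_morfs": len(regions), **{t: by_type.get(t, 0) for t in MORF_TYPES}})
    per_protein = pd.DataFrame(rows, columns=["protein_id", "n_morfs", *MORF_TYPES])
    counts = per_protein["n_morfs"].to_numpy(dtype=float) if len(per_protein) else np.array([0.0])
    grand_total = sum(totals.values())
    fractions = {
        t: (totals.get(t, 0) / grand_total if grand_total else np.nan) for t in MORF_TYPES
    }
    return {
        "per_protein": per_protein,
        "median": float(np.median(counts)),
        "q25": float(np.percentile(counts, 25)),
        "q75": float(np.percentile(counts, 75)),
        "totals": {t: totals.get(t, 0) for t in MORF_TYPES},
        "fractions": fractions,
    }
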