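"""Relative-entropy conservation from PSI-BLAST weighted observed percentages.

The per-residue conservation score is the Kullback-Leibler divergence
D(p || q) = sum_a p_a ln(p_a / q_a) between the residue's observed
amino-acid distribution p (the WOP row, normalised) and a fixed background
q.  Higher values mean stronger conservation.  The background defaults to
the Robinson & Robinson amino-acid frequencies used throughout the BLAST
family, and the logarithm is natural; both are configurable since different
conservation studies vary them.  WOP rows summing to zero (PSI-BLAST emits
these for residues without weighted observations) get a NaN score and are
excluded from every average.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import PSIBLAST_AA_ORDER, WopProfile
from .msa import column_maps

#: Robinson & Robinson (1991) background amino-acid frequencies, in
#: PSI-BLAST column order; the standard null model of the BLAST family.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

BACKGROUND = np.array([_ROBINSON[a] for a in PSIBLAST_AA_ORDER])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


def relative_entropy(p, q=BACKGROUND, base: float | None = None) -> float:
    """D(p || q) with the 0 ln 0 = 0 convention; NaN for an undefined p.

    ``base`` switches the logarithm (None = natural).  q must be strictly
    positive; p_a > 0 where q_a = 0 would make the divergence infinite and
    is rejected.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    if np.isnan(p).any():
        return float("nan")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("p is not a probability distribution")
    if (q <= 0).any():
        raise ValueError("background distribution must be strictly positive")
    mask = p > 0
    value = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    if base is not None:
        value /= np.log(base)
    return value


def conservation_track(profile: WopProfile, q=BACKGROUND, base: float | None = None) -> np.ndarray:
    """Per-residue conservation scores for one chain; NaN at zero-WOP rows."""
    probs = profile.probabilities()
    return np.array([relative_entropy(row, q, base) if not np.isnan(row).any() else np.nan for row in probs])


def lift_scores(msa, tracks: dict) -> np.ndarray:
    """(n_chains, n_cols) per-column scores; NaN at gaps and missing chains."""
    maps = column_maps(msa)
    lifted = np.full(maps.shape, np.nan)
    for v, rec in enumerate(msa):
        values = tracks.get(rec.id)
        if values is None:
            continue
        values = np.asarray(values, dtype=float)
        if values.size != len(rec.ungapped):
            raise ValueError(
                f"track for {rec.id!r} has {values.size} values, chain has {len(rec.ungapped)} residues"
            )
        present = maps[v] >= 0
        lifted[v, present] = values[maps[v, present]]
    return lifted


def average_conservation(msa, tracks: dict) -> np.ndarray:
    """Per-column mean conservation over the chains with a residue there.

    Gaps (and NaN-scored residues) are excluded from both numerator and
    denominator; all-gap columns give NaN.
    """
    lifted = lift_scores(msa, tracks)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-gap columns
        return np.nanmean(lifted, axis=0)


def region_mean_conservation(track, regions=None) -> float:
    """Mean score over all positions of the given regions (NaN excluded).

    ``regions`` is a list of 1-based segments or a boolean mask; None means
    the whole track.  An empty region set gives NaN.
    """
    track = np.asarray(track, dtype=float)
    if regions is None:
        selected = track
    else:
        regions = np.asarray(regions) if isinstance(regions, np.ndarray) else regions
        if isinstance(regions, np.ndarray) and regions.dtype == bool:
            selected = track[regions]
        else:
            from .core import segments_to_mask

            selected = track[segments_to_mask(list(regions), track.size)]
    selected = selected[~np.isnan(selected)]
    if selected.size == 0:
        return float("nan")
    return float(selected.mean())
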