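"""Synthetic-data generators emulating every input class of the pipeline.

Each generator is deterministic under its seed and returns the planted
ground truth alongside the generated data, so every analysis stage has a
generator whose truth it must recover: score tracks whose thresholded calls
reproduce a planted disorder content and segment-length mixture, splice
variant families with planted identical/mutation/insertion column fractions
and a planted insertion-disorder overlap, WOP profiles with analytically
known relative entropy, secondary-structure strings with planted MoRF types,
and function-labelled segment libraries with planted homologs and decoys.

The default parameters encode the study conditions of a channel-variant
interactome: 22 splice variants of ~1100 residues grouped by C-terminal
tail (DEC/VYR/ERL), partner cohorts of 64 and 97 proteins, a disorder
content near 18% for the channel with ~65% long segments, column identity
78.3% with 16.4% insertion and 8.1% mutation sites, 73% of insertion-site
residues disordered, and an 862-entry function-labelled segment library
queried by 441 disordered segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GAP, AA20, ProteinRecord, Segment, ScoreTrack, mask_to_segments
from .conservation import BACKGROUND, relative_entropy
from .io import FUNCTION_LABELS, PSIBLAST_AA_ORDER, LibraryEntry, WopProfile


def ensure_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("generators require an explicit seed")
    return np.random.default_rng(seed)


def random_sequence(length: int, rng, probs=None) -> str:
    """Random amino-acid sequence drawn from background frequencies."""
    if probs is None:
        probs = BACKGROUND
    letters = rng.choice(list(PSIBLAST_AA_ORDER), size=length, p=probs)
    return "".join(letters)


# ---------------------------------------------------------------------------
# Disorder cohorts (score tracks with planted segments)
# ---------------------------------------------------------------------------

@dataclass
class DisorderCohortSpec:
    """Conditions for a cohort of proteins with planted disordered segments."""

    n_proteins: int = 22
    length_mean: float = 1100.0
    length_sd: float = 60.0
    min_length: int = 60
    #: Target fraction of disordered residues per protein.
    content: float = 0.18
    #: Probability that a planted segment belongs to the long class.
    p_long: float = 0.65
    short_len: tuple[int, int] = (4, 29)
    long_len: tuple[int, int] = (30, 80)
    #: Probability that a protein is fully disordered.
    p_fully_disordered: float = 0.0
    #: Beta-noise sharpness for scores (scaled into [0, 0.5) / [0.5, 1]).
    beta_sharp: float = 8.0
    beta_flat: float = 2.0
    id_prefix: str = "P"


def bk_variant_cohort_spec(**overrides) -> DisorderCohortSpec:
    """Channel-variant-like cohort: 22 long chains, content 18%, 65% long."""
    return DisorderCohortSpec(**overrides)


def cytoplasmic_partner_spec(**overrides) -> DisorderCohortSpec:
    """Cytoplasmic-partner-like cohort: 64 shorter chains, content ~10%."""
    defaults = dict(
        n_proteins=64, length_mean=370.0, length_sd=130.0, content=0.10,
        p_long=0.38, p_fully_disordered=0.04, id_prefix="CYT",
    )
    defaults.update(overrides)
    return DisorderCohortSpec(**defaults)


def membrane_partner_spec(**overrides) -> DisorderCohortSpec:
    """Membrane/cytoskeletal-partner-like cohort: 97 chains, content ~14%."""
    defaults = dict(
        n_proteins=97, length_mean=370.0, length_sd=130.0, content=0.14,
        p_long=0.38, p_fully_disordered=0.04, id_prefix="MEM",
    )
    defaults.update(overrides)
    return DisorderCohortSpec(**defaults)


@dataclass
class DisorderCohort:
    records: list[ProteinRecord]
    tracks: list[ScoreTrack]
    truth_segments: dict[str, list[Segment]]
    truth_content: dict[str, float]
    spec: DisorderCohortSpec


def _sample_segment_lengths(budget: int, spec: DisorderCohortSpec, rng) -> list[int]:
    """Draw segment lengths until the disordered-residue budget is spent.

    The long/short class of each draw is an independent Bernoulli(p_long),
    never conditioned on the remaining budget — conditioning would deflate
    the long fraction.  The final draw may overshoot the budget; it is kept
    only when that lands total coverage closer to the target.
    """
    draws: list[tuple[int, tuple[int, int]]] = []
    consumed = 0
    while consumed < budget:
        go_long = rng.random() < spec.p_long
        lo, hi = spec.long_len if go_long else spec.short_len
        n = int(rng.integers(lo, hi + 1))
        draws.append((n, (lo, hi)))
        consumed += n
    # Trim the overshoot within class bounds so coverage matches the budget
    # while every segment keeps its drawn class.
    excess = consumed - budget
    lengths = [n for n, _ in draws]
    bounds = [b for _, b in draws]
    for i in rng.permutation(len(lengths)):
        if excess <= 0:
            break
        reducible = lengths[i] - bounds[i][0]
        take = min(reducible, excess)
        lengths[i] -= take
        excess -= take
    rng.shuffle(lengths)
    return lengths


def _place_lengths(L: int, lengths: list[int], rng) -> list[Segment]:
    """Place segments into [1, L], separated by at least one ordered residue."""
    lengths = list(lengths)
    while lengths and sum(lengths) + len(lengths) - 1 > L:
        lengths.pop()
    if not lengths:
        return []
    n = len(lengths)
    slack = L - sum(lengths) - (n - 1)
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    segments = []
    cursor = 0
    for i, length in enumerate(lengths):
        start = cursor + gaps[i] + (1 if i > 0 else 0)
        segments.append(Segment(start + 1, start + length))
        cursor = start + length
    return segments


def gen_disorder_cohort(spec: DisorderCohortSpec, seed) -> DisorderCohort:
    """Generate score tracks whose thresholded calls carry planted segments.

    Disordered residues receive scores in [0.5, 1] and ordered residues in
    [0, 0.5), so thresholding at 0.5 recovers the planted calls exactly;
    the planted content and segment-length mixture are then recovered up to
    the sampling variation of the length draws.
    """
    if not 0.0 <= spec.content <= 1.0:
        raise ValueError("content must be in [0, 1]")
    if 0.9 < spec.content < 1.0:
        raise ValueError("content above 0.9 is infeasible with ordered separators")
    if 0.0 < spec.content and spec.content * spec.length_mean < spec.short_len[0]:
        raise ValueError("content incompatible with the length distribution")
    rng = ensure_rng(seed)
    records, tracks, truth_segments, truth_content = [], [], {}, {}
    for i in range(spec.n_proteins):
        pid = f"{spec.id_prefix}{i + 1:03d}"
        L = max(spec.min_length, int(round(rng.normal(spec.length_mean, spec.length_sd))))
        if rng.random() < spec.p_fully_disordered:
            mask = np.ones(L, dtype=bool)
            segments = [Segment(1, L)]
        else:
            budget = int(round(spec.content * L))
            segments = _place_lengths(L, _sample_segment_lengths(budget, spec, rng), rng)
            mask = np.zeros(L, dtype=bool)
            for seg in segments:
                mask[seg.to_slice()] = True
        scores = np.where(
            mask,
            0.5 + 0.5 * rng.beta(spec.beta_sharp, spec.beta_flat, size=L),
            0.5 * rng.beta(spec.beta_flat, spec.beta_sharp, size=L),
        )
        records.append(ProteinRecord(pid, random_sequence(L, rng)))
        tracks.append(ScoreTrack(pid, scores))
        truth_segments[pid] = segments
        truth_content[pid] = float(mask.mean())
    return DisorderCohort(records, tracks, truth_segments, truth_content, spec)


# ---------------------------------------------------------------------------
# Splice-variant families (true MSA with planted column classes)
# ---------------------------------------------------------------------------

@dataclass
class VariantFamilySpec:
    """Conditions for a family of splice variants of one parent chain."""

    n_variants: int = 22
    parent_length: int = 1100
    #: Planted column-class fractions (identical / insertion are disjoint;
    #: mutation overlaps insertion, so the three may total more than 1).
    identical_frac: float = 0.783
    insertion_frac: float = 0.164
    mutation_frac: float = 0.081
    #: Fraction of insertion-site columns planted as disordered.
    insertion_disorder_overlap: float = 0.73
    #: Fraction of all columns covered by background disordered blocks.
    background_disorder_frac: float = 0.12
    insertion_block_len: tuple[int, int] = (20, 80)
    #: C-terminal tail tags and how many chains carry each.
    cterm_tags: tuple = (("DEC", 6), ("VYR", 9), ("ERL", 7))
    #: Linear-motif sites planted per type (each an interval in column space).
    elm_counts: dict = field(default_factory=lambda: {"LIG": 42, "MOD": 34, "TRG": 16, "CLV": 12})
    elm_len: tuple[int, int] = (3, 12)
    n_domains: int = 3
    domain_len: tuple[int, int] = (100, 220)
    n_morfs: int = 4
    morf_len: tuple[int, int] = (5, 25)
    id_prefix: str = "BK"


@dataclass
class VariantFamily:
    msa: list[ProteinRecord]          # aligned rows, gaps as '-'
    records: list[ProteinRecord]      # ungapped chains
    tags: dict[str, str]
    insertion_mask: np.ndarray        # per-column planted classes
    mutation_mask: np.ndarray
    identical_mask: np.ndarray
    disorder_mask: np.ndarray         # planted column-space disorder
    chain_disorder: dict[str, list[Segment]]
    elm_tracks: dict[str, list[Segment]]
    domain_segments: list[Segment]
    morf_segments: list[Segment]
    truth: dict
    spec: VariantFamilySpec


def _parent_runs(is_insertion_col: np.ndarray) -> list[tuple[int, int]]:
    """Maximal 0-based half-open runs of non-insertion columns."""
    return [(s.start - 1, s.end) for s in mask_to_segments(~is_insertion_col)]


def _place_in_runs(runs, lengths, rng, avoid: np.ndarray, max_tries: int = 400, min_len: int = 3):
    """Place intervals inside insertion-free column runs.

    Placements avoid the ``avoid`` mask and keep a 1-column gap among
    themselves (so same-track intervals never merge); different tracks may
    overlap each other by passing different ``avoid`` masks.  An interval
    that cannot be placed at its drawn length is progressively shortened
    (never below ``min_len``) so interval counts are preserved even in
    crowded column spaces.  Returns ``(segments, own_mask)``.
    """
    placed = []
    own = np.zeros_like(avoid)
    weights = np.array([hi - lo for lo, hi in runs], dtype=float)
    for length in lengths:
        ok = False
        while not ok and length >= min_len:
            for _ in range(max_tries):
                ridx = rng.choice(len(runs), p=weights / weights.sum())
                lo, hi = runs[ridx]
                if hi - lo < length:
                    continue
                start = int(rng.integers(lo, hi - length + 1))
                if avoid[start : start + length].any():
                    continue
                if own[max(start - 1, 0) : start + length + 1].any():
                    continue
                own[start : start + length] = True
                placed.append(Segment(start + 1, start + length))
                ok = True
                break
            else:
                length = max(min_len, int(length * 0.7)) if length > min_len else 0
        if not ok:
            raise ValueError("could not place interval; column space too crowded")
    return sorted(placed), own


def gen_variant_family(spec: VariantFamilySpec, seed) -> VariantFamily:
    """Generate a splice-variant family with its true alignment.

    Insertion sites are contiguous cassette blocks, each present in a random
    proper subset of chains; point mutations are planted on gap-free columns
    (and, to make the classes overlap, on some insertion columns); the last
    three parent columns carry the C-terminal group tags.  Column-space
    disorder covers a planted fraction of every insertion block plus
    background blocks, and is projected onto each chain as its disorder
    annotation.  The true alignment is emitted directly — no aligner runs.
    """
    rng = ensure_rng(seed)
    n = spec.n_variants
    if sum(k for _, k in spec.cterm_tags) != n:
        raise ValueError("cterm tag counts must sum to n_variants")
    if spec.identical_frac + spec.insertion_frac > 1.0:
        raise ValueError("identical and insertion fractions exceed 1")

    n_cols = int(round(spec.parent_length / (1.0 - spec.insertion_frac)))
    n_ins_cols = n_cols - spec.parent_length

    # Partition insertion columns into contiguous cassette blocks.
    block_lens = []
    remaining = n_ins_cols
    while remaining > 0:
        length = int(rng.integers(*spec.insertion_block_len)) if remaining > spec.insertion_block_len[1] else remaining
        length = min(length, remaining)
        block_lens.append(length)
        remaining -= length
    points = np.sort(
        rng.choice(np.arange(10, spec.parent_length - 10), size=len(block_lens), replace=False)
    )

    # Column layout: ("p", parent_index) or ("i", block_index).
    layout = []
    parent_pos = 0
    for point, block, length in zip(points, range(len(block_lens)), block_lens):
        while parent_pos < point:
            layout.append(("p", parent_pos))
            parent_pos += 1
        layout.extend(("i", block) for _ in range(length))
    while parent_pos < spec.parent_length:
        layout.append(("p", parent_pos))
        parent_pos += 1
    assert len(layout) == n_cols

    is_insertion = np.array([kind == "i" for kind, _ in layout])
    block_of_col = np.array([idx if kind == "i" else -1 for kind, idx in layout])

    # Chain bookkeeping: ids, tags, block presence.
    tags = {}
    ids = []
    i = 0
    for tag, count in spec.cterm_tags:
        for _ in range(count):
            pid = f"{spec.id_prefix}{i + 1:02d}"
            ids.append(pid)
            tags[pid] = tag
            i += 1
    presence = np.ones((n, n_cols), dtype=bool)
    for b in range(len(block_lens)):
        k = int(rng.integers(1, n))  # proper subset: 1 .. n-1 chains
        carriers = rng.choice(n, size=k, replace=False)
        cols = block_of_col == b
        presence[:, cols] = False
        presence[np.ix_(carriers, np.flatnonzero(cols))] = True

    # Mutation columns: gap-free count fixes the identical fraction exactly;
    # the remainder goes onto insertion columns with >= 2 carriers.  With
    # several C-terminal tag groups, the 3 tail columns differ between
    # groups and count among the gap-free mutation columns.
    parent_cols = np.flatnonzero(~is_insertion)
    tail_cols = parent_cols[-3:]
    n_forced = 3 if len({tag for tag, _ in spec.cterm_tags}) > 1 else 0
    n_mut = int(round(spec.mutation_frac * n_cols))
    n_mut_gapfree = int(round((1.0 - spec.identical_frac - spec.insertion_frac) * n_cols))
    n_mut_gapfree = min(max(n_mut_gapfree, n_forced), max(n_mut, n_forced))
    candidates = parent_cols[:-3]
    n_extra = n_mut_gapfree - n_forced
    mutation_cols = set(map(int, tail_cols)) if n_forced else set()
    if n_extra > 0:
        mutation_cols |= set(map(int, rng.choice(candidates, size=n_extra, replace=False)))
    ins_candidates = np.flatnonzero(is_insertion & (presence.sum(axis=0) >= 2))
    n_mut_ins = min(max(n_mut - n_mut_gapfree, 0), ins_candidates.size)
    if n_mut_ins > 0:
        mutation_cols |= set(map(int, rng.choice(ins_candidates, size=n_mut_ins, replace=False)))

    # Residues per column.
    letters = np.empty((n, n_cols), dtype="U1")
    aa = np.array(list(PSIBLAST_AA_ORDER))
    tag_index = {pid: list(dict(spec.cterm_tags)).index(tags[pid]) for pid in ids}
    for c in range(n_cols):
        base = aa[rng.choice(20, p=BACKGROUND)]
        letters[:, c] = base
        if c in mutation_cols and c not in set(map(int, tail_cols)):
            present_rows = np.flatnonzero(presence[:, c])
            k = int(rng.integers(1, present_rows.size))
            variant_rows = rng.choice(present_rows, size=k, replace=False)
            alt = aa[rng.choice(20)]
            while alt == base:
                alt = aa[rng.choice(20)]
            letters[variant_rows, c] = alt
    for j, c in enumerate(tail_cols):
        for v, pid in enumerate(ids):
            letters[v, c] = tags[pid][j]

    rows = []
    for v, pid in enumerate(ids):
        chars = np.where(presence[v], letters[v], GAP)
        rows.append(ProteinRecord(pid, "".join(chars)))
    records = [ProteinRecord(rec.id, rec.ungapped) for rec in rows]

    # Domains first (nothing else may overlap them), then planted disorder:
    # a contiguous sub-block of each cassette covering the target overlap
    # fraction, plus background blocks in insertion-free column runs.
    runs = _parent_runs(is_insertion)
    domain_segments, domain_mask = _place_in_runs(
        runs,
        [int(rng.integers(spec.domain_len[0], spec.domain_len[1] + 1)) for _ in range(spec.n_domains)],
        rng,
        np.zeros(n_cols, dtype=bool),
    )
    disorder = np.zeros(n_cols, dtype=bool)
    for b, length in enumerate(block_lens):
        cols = np.flatnonzero(block_of_col == b)
        cover = int(round(spec.insertion_disorder_overlap * length))
        if cover > 0:
            offset = int(rng.integers(0, length - cover + 1))
            disorder[cols[offset : offset + cover]] = True
    budget = int(round(spec.background_disorder_frac * n_cols))
    bg_lengths = []
    while budget >= 30:
        length = min(int(rng.integers(30, 81)), budget)
        bg_lengths.append(length)
        budget -= length
    bg_segments, _ = _place_in_runs(runs, bg_lengths, rng, domain_mask)
    for seg in bg_segments:
        disorder[seg.to_slice()] = True

    chain_disorder = {}
    maps_cache = None
    from .msa import column_maps, project_track  # local import avoids a cycle

    maps_cache = column_maps(rows)
    for v, pid in enumerate(ids):
        residue_idx = maps_cache[v][disorder & (maps_cache[v] >= 0)]
        chain_mask = np.zeros(len(records[v].sequence), dtype=bool)
        chain_mask[residue_idx] = True
        chain_disorder[pid] = mask_to_segments(chain_mask)

    # Linear motifs and MoRFs in insertion-free column runs outside domains
    # (motifs live outside globular domains), so every chain carries them
    # and majority profiles recover them exactly.  Different motif types may
    # overlap each other; intervals within one type stay separated.
    elm_tracks = {}
    for elm_type, count in spec.elm_counts.items():
        lengths = [int(rng.integers(spec.elm_len[0], spec.elm_len[1] + 1)) for _ in range(count)]
        elm_tracks[elm_type], _ = _place_in_runs(runs, lengths, rng, domain_mask)
    morf_segments, _ = _place_in_runs(
        runs,
        [int(rng.integers(spec.morf_len[0], spec.morf_len[1] + 1)) for _ in range(spec.n_morfs)],
        rng,
        domain_mask,
    )

    identical_mask = np.ones(n_cols, dtype=bool)
    identical_mask[is_insertion] = False
    identical_mask[sorted(mutation_cols & set(map(int, parent_cols)))] = False
    mutation_mask = np.zeros(n_cols, dtype=bool)
    mutation_mask[sorted(mutation_cols)] = True

    truth = {
        "identical_frac": float(identical_mask.mean()),
        "insertion_frac": float(is_insertion.mean()),
        "mutation_frac": float(mutation_mask.mean()),
        "insertion_disorder_overlap": float(disorder[is_insertion].mean()) if is_insertion.any() else float("nan"),
        "elm_counts": {t: len(track) for t, track in elm_tracks.items()},
    }
    return VariantFamily(
        msa=rows,
        records=records,
        tags=tags,
        insertion_mask=is_insertion,
        mutation_mask=mutation_mask,
        identical_mask=identical_mask,
        disorder_mask=disorder,
        chain_disorder=chain_disorder,
        elm_tracks=elm_tracks,
        domain_segments=domain_segments,
        morf_segments=morf_segments,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# WOP profiles with known true relative entropy
# ---------------------------------------------------------------------------

@dataclass
class WopSpec:
    n_residues: int = 300
    #: Dirichlet sharpness around the background; larger = closer to q
    #: (hence lower true relative entropy).  ``inf`` plants q exactly.  The
    #: default gives per-residue scores near 1 nat, the magnitude typical
    #: of profile-based conservation for a moderately conserved family.
    #: May also be a per-residue array, e.g. to plant extra conservation
    #: inside binding regions.
    concentration: float | np.ndarray = 0.25
    zero_row_rate: float = 0.02
    protein_id: str = "WOP"


@dataclass
class WopSample:
    profile: WopProfile
    true_probabilities: np.ndarray
    true_entropy: np.ndarray  # NaN at zero rows


def _round_to_percent(p: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of a distribution to integers summing 100."""
    scaled = p * 100.0
    floors = np.floor(scaled).astype(int)
    shortfall = 100 - floors.sum()
    order = np.argsort(-(scaled - floors))
    floors[order[:shortfall]] += 1
    return floors


def gen_wop(spec: WopSpec, seed) -> WopSample:
    conc = np.broadcast_to(
        np.asarray(spec.concentration, dtype=float), (spec.n_residues,)
    )
    if (conc <= 0).any():
        raise ValueError("concentration must be positive")
    rng = ensure_rng(seed)
    q = BACKGROUND
    residues = random_sequence(spec.n_residues, rng)
    rows = np.zeros((spec.n_residues, 20), dtype=int)
    true_p = np.full((spec.n_residues, 20), np.nan)
    true_h = np.full(spec.n_residues, np.nan)
    for i in range(spec.n_residues):
        if rng.random() < spec.zero_row_rate:
            continue  # PSI-BLAST-style all-zero row
        if np.isinf(conc[i]):
            p = q.copy()
        else:
            p = rng.dirichlet(conc[i] * 20.0 * q)
        true_p[i] = p
        true_h[i] = relative_entropy(p, q)
        rows[i] = _round_to_percent(p)
    profile = WopProfile(spec.protein_id, residues, rows)
    return WopSample(profile, true_p, true_h)


# ---------------------------------------------------------------------------
# Secondary structure with planted MoRF types
# ---------------------------------------------------------------------------

@dataclass
class MorfCohortSpec:
    n_proteins: int = 22
    length_mean: float = 1100.0
    length_sd: float = 60.0
    min_length: int = 80
    n_regions_mean: float = 3.0
    #: Planted type mixture (channel-like default: helix-heavy with coils).
    type_weights: dict = field(default_factory=lambda: {"alpha": 0.87, "beta": 0.0, "gamma": 0.13, "complex": 0.0})
    #: Per-residue probability of the dominant state inside a typed region.
    purity: float = 0.95
    id_prefix: str = "P"


_TYPE_TO_STATE = {"alpha": "H", "beta": "E", "gamma": "C"}


def gen_morf_cohort(spec: MorfCohortSpec, seed) -> dict:
    """Secondary-structure strings with planted MoRF regions and types.

    Returns protein id -> (ss_string, [(segment, true_type), ...]).  For
    alpha/beta/gamma regions the corresponding state is drawn per residue
    with probability ``purity``; complex regions cycle H, E, C so that no
    state reaches a majority.
    """
    rng = ensure_rng(seed)
    weights = spec.type_weights
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    out = {}
    for i in range(spec.n_proteins):
        pid = f"{spec.id_prefix}{i + 1:03d}"
        L = max(spec.min_length, int(round(rng.normal(spec.length_mean, spec.length_sd))))
        n_regions = int(rng.poisson(spec.n_regions_mean))
        lengths = [int(rng.integers(5, 26)) for _ in range(n_regions)]
        regions = _place_lengths(L, lengths, rng)
        ss = rng.choice(list("CHE"), size=L, p=[0.6, 0.25, 0.15])
        planted = []
        for seg in regions:
            morf_type = types[rng.choice(len(types), p=probs)]
            if morf_type == "complex":
                pattern = [("HEC")[k % 3] for k in range(seg.length)]
                ss[seg.to_slice()] = pattern
            else:
                state = _TYPE_TO_STATE[morf_type]
                others = [s for s in "HEC" if s != state]
                draw = np.where(
                    rng.random(seg.length) < spec.purity,
                    state,
                    rng.choice(others, size=seg.length),
                )
                ss[seg.to_slice()] = draw
            planted.append((seg, morf_type))
        out[pid] = ("".join(ss), planted)
    return out


# ---------------------------------------------------------------------------
# Function-labelled segment libraries with planted homologs
# ---------------------------------------------------------------------------

#: Label weights shaped like the observed function census of curated
#: disordered segments (protein-protein binding dominant, a long tail of
#: rare functions).
_LABEL_WEIGHTS = {
    "Protein-protein binding": 52, "Substrate/ligand binding": 36,
    "Protein-DNA binding": 21, "Flexible linkers/spacers": 14,
    "Phosphorylation": 13, "Intra-protein interaction": 8,
    "Protein-lipid interaction": 8, "Metal binding": 7,
    "Nuclear localization": 4, "Polymerization": 3, "Electron transfer": 3,
    "Entropic spring": 3, "Transactivation": 3, "Apoptosis Regulation": 1,
    "Cofactor/heme binding": 1, "Glycosylation": 1, "Protein-tRNA binding": 1,
    "Autoregulatory": 1, "Entropic bristle": 1,
}


@dataclass
class LibrarySpec:
    n_entries: int = 862
    n_queries: int = 441
    #: Fraction of queries planted as homologs of a library entry.
    planted_fraction: float = 89.0 / 441.0
    planted_identity: float = 0.85
    decoy_identity: float = 0.40
    entry_len: tuple[int, int] = (15, 70)
    label_weights: dict = field(default_factory=lambda: dict(_LABEL_WEIGHTS))


@dataclass
class LibrarySample:
    library: list[LibraryEntry]
    queries: dict[str, str]
    truth: dict[str, str | None]  # query id -> planted function (None = decoy)


def _mutate_to_identity(sequence: str, identity: float, rng) -> str:
    """Point-mutate a fraction (1 - identity) of positions to new residues."""
    seq = list(sequence)
    n_mut = int(round((1.0 - identity) * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        alternatives = [a for a in AA20 if a != seq[pos]]
        seq[pos] = alternatives[rng.choice(len(alternatives))]
    return "".join(seq)


def gen_library_with_queries(spec: LibrarySpec, seed) -> LibrarySample:
    """A labelled segment library plus queries with controlled identity.

    Planted queries are point-mutated copies of library entries at the
    planted identity (above the transfer threshold); decoys are mutated far
    below it.  The truth table records which label each query should
    receive at the 0.8 similarity threshold.
    """
    if spec.planted_identity <= spec.decoy_identity:
        raise ValueError("planted identity must exceed decoy identity")
    rng = ensure_rng(seed)
    labels = list(spec.label_weights)
    probs = np.array([spec.label_weights[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    library = [
        LibraryEntry(
            f"DP{i + 1:05d}",
            random_sequence(int(rng.integers(*spec.entry_len)), rng),
            labels[rng.choice(len(labels), p=probs)],
        )
        for i in range(spec.n_entries)
    ]
    n_planted = int(round(spec.planted_fraction * spec.n_queries))
    queries, truth = {}, {}
    for i in range(spec.n_queries):
        qid = f"Q{i + 1:04d}"
        if i < n_planted:
            source = library[rng.choice(len(library))]
            queries[qid] = _mutate_to_identity(source.sequence, spec.planted_identity, rng)
            truth[qid] = source.function
        else:
            source = library[rng.choice(len(library))]
            queries[qid] = _mutate_to_identity(source.sequence, spec.decoy_identity, rng)
            truth[qid] = None
    return LibrarySample(library, queries, truth)
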