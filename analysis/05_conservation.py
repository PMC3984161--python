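"""Evolutionary conservation of the variant family from WOP profiles.

Generates per-chain WOP profiles with extra sharpness (hence conservation)
planted inside MoRF columns, converts them to per-residue relative-entropy
tracks, averages across variants in column space, and reports region means
over the annotation tracks.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from disorderome import average_conservation, region_mean_conservation, segments_to_mask, synth
from disorderome.conservation import conservation_track
from disorderome.msa import column_maps

SEED = 20260920
RESULTS = Path("results")

CONC_BACKGROUND = 0.30  # moderate conservation (~0.9 nats)
CONC_MORF = 0.10        # strongly conserved binding regions (~1.6 nats)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fam = synth.gen_variant_family(synth.VariantFamilySpec(), SEED)
    n_cols = fam.insertion_mask.size
    morf_mask = segments_to_mask(fam.morf_segments, n_cols)
    domain_mask = segments_to_mask(fam.domain_segments, n_cols)

    # Per-chain WOP: concentration profile follows the chain's column classes.
    maps = column_maps(fam.msa)
    tracks = {}
    rng = np.random.default_rng(SEED)
    for v, rec in enumerate(fam.msa):
        present = maps[v] >= 0
        chain_len = int(present.sum())
        conc = np.full(chain_len, CONC_BACKGROUND)
        conc[morf_mask[present]] = CONC_MORF
        sample = synth.gen_wop(
            synth.WopSpec(n_residues=chain_len, concentration=conc, protein_id=rec.id),
            int(rng.integers(2**31)),
        )
        tracks[rec.id] = conservation_track(sample.profile)

    averaged = average_conservation(fam.msa, tracks)
    rows = [
        ("all residues", region_mean_conservation(averaged)),
        ("MoRF regions", region_mean_conservation(averaged, morf_mask)),
        ("globular domains", region_mean_conservation(averaged, domain_mask)),
        ("disordered residues", region_mean_conservation(averaged, fam.disorder_mask)),
        ("mutation sites", region_mean_conservation(averaged, fam.mutation_mask)),
        ("insertion sites", region_mean_conservation(averaged, fam.insertion_mask)),
    ]
    for elm_type, segs in fam.elm_tracks.items():
        rows.append((f"ELM {elm_type}", region_mean_conservation(averaged, segments_to_mask(segs, n_cols))))
    table = pd.DataFrame(rows, columns=["region", "mean_conservation_nats"]).round(3)
    table.to_csv(RESULTS / "conservation.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nMoRF columns stand out as the most conserved regions of the family.")


if __name__ == "__main__":
    main()
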