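"""Column-space profile of the splice-variant family.

Classifies alignment columns (identical / mutation / insertion), builds
majority-vote tracks, counts linear-motif sites per type, and crosses the
tracks: how disordered are insertion and mutation sites, and how much do
motifs overlap mutations and disorder.
"""

from pathlib import Path

import pandas as pd

from disorderome import (
    call_variation,
    elm_census,
    group_by_cterm,
    lift_track,
    majority_profile,
    overlap_stats,
    segments_to_mask,
    synth,
    variation_fractions,
)
from disorderome.msa import presence_matrix

SEED = 20260920
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fam = synth.gen_variant_family(synth.VariantFamilySpec(), SEED)
    n_cols = fam.insertion_mask.size

    fractions = variation_fractions(call_variation(fam.msa))
    groups = {tag: len(records) for tag, records in group_by_cterm(fam.records).items()}

    membership = lift_track(fam.msa, fam.chain_disorder)
    _, disorder_segs = majority_profile(membership, presence=presence_matrix(fam.msa))
    disorder_mask = segments_to_mask(disorder_segs, n_cols)

    census = elm_census(fam.elm_tracks)
    rows = []
    for elm_type, segs in fam.elm_tracks.items():
        elm_mask = segments_to_mask(segs, n_cols)
        rows.append(
            {
                "elm_type": elm_type,
                "n_sites": census[elm_type],
                "mutation_pct": overlap_stats(elm_mask, fam.mutation_mask),
                "disordered_pct": overlap_stats(elm_mask, disorder_mask),
            }
        )
    elm_table = pd.DataFrame(rows).round(1)
    elm_table.to_csv(RESULTS / "elm_profile.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        [
            {
                "n_variants": len(fam.msa),
                "n_columns": n_cols,
                **{k: round(v, 1) for k, v in fractions.items() if k != "n_columns"},
                "insertion_disordered_pct": round(overlap_stats(fam.insertion_mask, disorder_mask), 1),
                "mutation_disordered_pct": round(overlap_stats(fam.mutation_mask, disorder_mask), 1),
                **{f"n_{tag}": n for tag, n in sorted(groups.items())},
            }
        ]
    )
    summary.to_csv(RESULTS / "variant_profile.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print()
    print(elm_table.to_string(index=False))
    print(
        "\nInsertion sites are heavily disordered (splice cassettes land in "
        "flexible regions); motif sites sit outside globular domains."
    )


if __name__ == "__main__":
    main()
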