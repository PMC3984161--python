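"""Statistical comparisons between the channel and partner cohorts.

Per-protein measures (disorder content, segment counts) are compared with
the normality-gated t / rank-sum protocol; the population-level fraction of
fully disordered proteins is compared via ten random half-subsets per
cohort.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from disorderome import (
    binarize,
    compare_per_protein,
    compare_population_measure,
    summarize_protein,
    synth,
)

SEED = 20260920
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohorts = {}
    for offset, (group, spec) in enumerate(
        [
            ("BK_variants", synth.bk_variant_cohort_spec()),
            ("cytoplasmic_partners", synth.cytoplasmic_partner_spec()),
            ("membrane_partners", synth.membrane_partner_spec()),
        ]
    ):
        cohort = synth.gen_disorder_cohort(spec, SEED + offset)
        cohorts[group] = [
            summarize_protein(t.protein_id, binarize(t.values)) for t in cohort.tracks
        ]

    measures = {
        "content": lambda s: s.content,
        "n_segments": lambda s: s.n_segments,
        "n_long_segments": lambda s: s.n_long_segments,
    }
    pairs = [
        ("BK_variants", "cytoplasmic_partners"),
        ("BK_variants", "membrane_partners"),
        ("cytoplasmic_partners", "membrane_partners"),
    ]
    rows = []
    for name, fn in measures.items():
        for a, b in pairs:
            cmp = compare_per_protein(
                [fn(s) for s in cohorts[a]], [fn(s) for s in cohorts[b]],
                names=(a, b), measure=name,
            )
            rows.append(_row(cmp))
    for a, b in pairs:
        cmp = compare_population_measure(
            cohorts[a], cohorts[b],
            lambda subset: float(np.mean([s.fully_disordered for s in subset])),
            seed=SEED, names=(a, b), measure="fully_disordered_fraction",
        )
        rows.append(_row(cmp))

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "comparisons.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        "\nSegment counts separate the channel from its partners strongly; "
        "content differences are milder, matching the planted conditions."
    )


def _row(cmp):
    return {
        "measure": cmp.measure,
        "group_a": cmp.group_a,
        "group_b": cmp.group_b,
        "test": cmp.test,
        "p": None if cmp.p is None else float(f"{cmp.p:.3g}"),
        "tier": cmp.tier,
        "median_a": round(cmp.median_a, 4),
        "median_b": round(cmp.median_b, 4),
        "degenerate": cmp.degenerate,
    }


if __name__ == "__main__":
    main()
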