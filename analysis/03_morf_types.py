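"""MoRF typing census for the channel and partner cohorts.

Classifies planted MoRF regions from generated secondary-structure strings
and tabulates per-group type fractions and per-protein counts.  The channel
cohort is helix/coil dominated; partner cohorts carry a broader mixture
including strand MoRFs.
"""

from pathlib import Path

import pandas as pd

from disorderome import classify_regions, morf_type_census, synth

SEED = 20260920
RESULTS = Path("results")

COHORTS = {
    "BK_variants": synth.MorfCohortSpec(),
    "cytoplasmic_partners": synth.MorfCohortSpec(
        n_proteins=64, length_mean=370, length_sd=130, min_length=60, n_regions_mean=2.0,
        type_weights={"alpha": 0.44, "beta": 0.12, "gamma": 0.34, "complex": 0.10},
        id_prefix="CYT",
    ),
    "membrane_partners": synth.MorfCohortSpec(
        n_proteins=97, length_mean=370, length_sd=130, min_length=60, n_regions_mean=2.0,
        type_weights={"alpha": 0.47, "beta": 0.08, "gamma": 0.41, "complex": 0.04},
        id_prefix="MEM",
    ),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for offset, (group, spec) in enumerate(COHORTS.items()):
        cohort = synth.gen_morf_cohort(spec, SEED + offset)
        typed = {
            pid: classify_regions(ss, [seg for seg, _ in planted])
            for pid, (ss, planted) in cohort.items()
        }
        census = morf_type_census(typed)
        rows.append(
            {
                "group": group,
                "n_proteins": len(typed),
                "n_morfs": sum(census["totals"].values()),
                "median_per_protein": census["median"],
                "q25": census["q25"],
                "q75": census["q75"],
                **{f"{t}_pct": 100 * census["fractions"][t] for t in ("alpha", "beta", "gamma", "complex")},
            }
        )
    table = pd.DataFrame(rows).round(2)
    table.to_csv(RESULTS / "morf_census.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nHelix-forming MoRFs dominate the channel; partners add strand MoRFs.")


if __name__ == "__main__":
    main()
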