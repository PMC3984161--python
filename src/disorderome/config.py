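"""Fixed analysis constants, collected in one overridable dataclass.

Every threshold the pipeline applies lives here so that a single object
documents the analysis conditions.  The defaults encode the conventions of
the disorder-prediction literature: a residue is called disordered when its
propensity score is at least 0.5, a disordered segment needs at least 4
consecutive disordered residues, and a long segment at least 30.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class Config:
    #: Score at or above which a residue is called disordered.  Predictors
    #: emitting exactly 0.5 for ambiguous residues count as disordered.
    disorder_threshold: float = 0.5
    #: Minimum run of disordered residues forming a segment.
    min_segment_len: int = 4
    #: Minimum length of a "long" disordered segment.
    long_segment_len: int = 30
    #: Expected MoRF length range (violations warn, not fail).
    morf_len_range: tuple[int, int] = (5, 25)
    #: Fraction of variants that must carry an annotation at an alignment
    #: column for it to enter the majority-vote profile ("at least 50%").
    majority_fraction: float = 0.5
    #: Fraction of region residues one secondary-structure state must
    #: strictly exceed for a MoRF to be typed alpha/beta/gamma.
    dominance_fraction: float = 0.5
    #: Similarity above which (strictly) a function label is transferred.
    transfer_similarity: float = 0.8
    #: Significance level of the Anderson-Darling normality gate.
    ad_alpha: float = 0.05
    #: Number of random half-subsets in population-level comparisons.
    n_subsets: int = 10
    #: Fraction of each cohort drawn into every subset.
    subset_fraction: float = 0.5
    #: Minimum interaction degree defining a hub protein.
    hub_degree: int = 6
    #: Affine gap penalties and matrix for local alignment (EMBOSS water
    #: defaults: the opening penalty is charged on the first gap residue,
    #: the extension penalty on each subsequent one).
    gap_open: float = 10.0
    gap_extend: float = 0.5
    substitution_matrix: str = "BLOSUM62"

    def asdict(self) -> dict:
        return asdict(self)


#: Module-level default configuration shared by all operations.
DEFAULT = Config()
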