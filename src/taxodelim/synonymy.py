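"""Species-level synonym detection from ANI/dDDH matrices and 16S identity.

Two genomes are flagged as putative heterotypic synonyms when their average
nucleotide identity exceeds the species boundary (default 96%, the upper end
of the conventional 95-96% band) AND their digital DNA-DNA hybridization
exceeds 70%. Comparisons are strict (> cutoff). The tool only flags;
phenotype-based overrides and nomenclatural priority are judgment calls
outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import LabeledMatrix, SequenceRecord
from .errors import InvariantError
from .pairwise import align_pair, percent_identity

__all__ = ["SynonymCall", "flag_synonym_pairs", "sixteen_s_identity"]


@dataclass(frozen=True)
class SynonymCall:
    taxon_a: str
    taxon_b: str
    ani: float
    ddh: float
    verdict: str  # "same_species" | "distinct"
    ani_cutoff: float
    ddh_cutoff: float

    def __post_init__(self) -> None:
        expected = (
            "same_species" if self.ani > self.ani_cutoff and self.ddh > self.ddh_cutoff
            else "distinct"
        )
        if self.verdict != expected:
            raise InvariantError("verdict inconsistent with values and cutoffs")


def flag_synonym_pairs(
    ani: LabeledMatrix,
    ddh: LabeledMatrix,
    ani_cutoff: float = 96.0,
    ddh_cutoff: float = 70.0,
) -> list[SynonymCall]:
    """All unordered pairs strictly above both cutoffs, by descending ANI.

    Matrices must share a label universe and a scale; the cutoffs are
    interpreted on that scale (the percent defaults become 0.96/0.70 on
    fraction matrices), so rescaling matrices and cutoffs together leaves
    the verdicts unchanged.
    """
    if set(ani.labels) != set(ddh.labels):
        raise InvariantError("ANI and dDDH matrices cover different taxa")
    if ani.scale != ddh.scale:
        raise InvariantError("ANI and dDDH matrices are on different scales")
    top = 1.0 if ani.scale == "fraction" else 100.0
    if not (0 <= ani_cutoff <= top and 0 <= ddh_cutoff <= top):
        raise InvariantError(
            f"cutoffs ({ani_cutoff}, {ddh_cutoff}) outside the matrices' "
            f"{ani.scale} scale [0, {top}]"
        )
    calls: list[SynonymCall] = []
    labels = sorted(ani.labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vd = ani.value(a, b), ddh.value(a, b)
            if va > ani_cutoff and vd > ddh_cutoff:
                calls.append(
                    SynonymCall(a, b, va, vd, "same_species", ani_cutoff, ddh_cutoff)
                )
    calls.sort(key=lambda c: (-c.ani, c.taxon_a, c.taxon_b))
    return calls


def sixteen_s_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment core identity between two 16S rRNA gene sequences."""
    result = align_pair(a, b, mode="global")
    return percent_identity(result, "core")
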