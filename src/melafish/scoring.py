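"""Nucleus selection, criterion fractions, and the OR positivity rule.

The scoring procedure mirrors how a dermatopathologist plus an automated
enumeration system works through a slide: QC-failed (overlapped or poorly
hybridised) nuclei are discarded, the most abnormal tumour areas are chosen,
ten random nuclei per area are read, and the specimen is called positive when
any of the four abnormal-nucleus fractions strictly exceeds its cutoff.
Specimens yielding fewer than 20 evaluable nuclei are excluded outright.

All fraction/cutoff comparisons are strict and exact (rational arithmetic):
a specimen sitting exactly on a cutoff is negative.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    CRITERIA,
    Area,
    CriterionFractions,
    CutoffSet,
    FishCall,
    MelafishError,
    NucleusSignal,
    SpecimenRecord,
)

__all__ = [
    "DEFAULT_N_AREAS",
    "DEFAULT_NUCLEI_PER_AREA",
    "DEFAULT_MIN_NUCLEI",
    "nucleus_flags",
    "nucleus_abnormal",
    "area_abnormality_score",
    "select_nuclei",
    "criterion_fractions",
    "classify_specimen",
    "score_specimen",
    "score_cohort",
]

# Published enumeration protocol: >=3 abnormal areas, 10 random nuclei each,
# specimens with <20 evaluable nuclei excluded from the study.
DEFAULT_N_AREAS = 3
DEFAULT_NUCLEI_PER_AREA = 10
DEFAULT_MIN_NUCLEI = 20


class EmptyInputError(MelafishError):
    """Fractions are undefined for an empty nucleus list."""


def nucleus_flags(nucleus: NucleusSignal) -> dict[str, bool]:
    """Which of the four abnormality clauses this single nucleus satisfies."""
    return {
        "rreb1_gain": nucleus.rreb1 > 2,
        "ccnd1_gain": nucleus.ccnd1 > 2,
        "rreb1_gt_cep6": nucleus.rreb1 > nucleus.cep6,
        "myb_lt_cep6": nucleus.myb < nucleus.cep6,
    }


def nucleus_abnormal(nucleus: NucleusSignal) -> bool:
    """A nucleus is abnormal iff it satisfies any clause of the OR rule."""
    return any(nucleus_flags(nucleus).values())


def area_abnormality_score(area: Area) -> Fraction:
    """Fraction of QC-pass nuclei in the area that are abnormal.

    Operationalises the protocol's "areas with the most significant copy
    number changes": areas are ranked by this score for selection.  An area
    with no QC-pass nuclei scores 0.
    """
    nuclei = area.qc_pass_nuclei()
    if not nuclei:
        return Fraction(0)
    return Fraction(sum(nucleus_abnormal(n) for n in nuclei), len(nuclei))


def select_nuclei(
    specimen: SpecimenRecord,
    n_areas: int = DEFAULT_N_AREAS,
    nuclei_per_area: int = DEFAULT_NUCLEI_PER_AREA,
    rng: Optional[np.random.Generator] = None,
) -> list[NucleusSignal]:
    """Pick the nuclei that enter scoring for one specimen.

    QC-failed nuclei are removed first.  Areas are ranked by abnormality
    score (descending; ties broken lexicographically by ``area_id`` for
    reproducibility) and the top ``n_areas`` areas are retained.  Within each
    retained area, ``nuclei_per_area`` nuclei are sampled uniformly without
    replacement — all of them when the area holds fewer.
    """
    if rng is None:
        rng = np.random.default_rng()
    ranked = sorted(
        specimen.areas,
        key=lambda a: (-area_abnormality_score(a), a.area_id),
    )
    selected: list[NucleusSignal] = []
    for area in ranked[:n_areas]:
        nuclei = area.qc_pass_nuclei()
        if len(nuclei) <= nuclei_per_area:
            selected.extend(nuclei)
        else:
            idx = rng.choice(len(nuclei), size=nuclei_per_area, replace=False)
            selected.extend(nuclei[i] for i in sorted(idx))
    return selected


def criterion_fractions(nuclei: Sequence[NucleusSignal]) -> CriterionFractions:
    """Compute the four abnormal-nucleus fractions over QC-pass nuclei.

    Nuclei with zero centromere-6 signals stay in the denominators of the
    two CEP6-relative criteria: a truncated nucleus that lost its reference
    signal can still show RREB1 > CEP6, and removing it would silently shrink
    the denominator relative to the locus-gain criteria.
    """
    if not nuclei:
        raise EmptyInputError("criterion fractions are undefined for zero nuclei")
    counts = dict.fromkeys(CRITERIA, 0)
    for nucleus in nuclei:
        for name, fired in nucleus_flags(nucleus).items():
            counts[name] += fired
    return CriterionFractions.from_counts(counts, len(nuclei))


def classify_specimen(
    fractions: Optional[CriterionFractions],
    cutoffs: CutoffSet,
    specimen_id: str = "",
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
) -> FishCall:
    """Apply the four-criterion OR rule to one specimen's fractions.

    The specimen is excluded when fewer than ``min_nuclei`` nuclei were
    evaluable (``fractions=None`` means zero).  Otherwise it is positive iff
    any fraction strictly exceeds its cutoff; ``fired_criteria`` lists every
    satisfied clause.
    """
    if fractions is None or fractions.n_evaluated < min_nuclei:
        return FishCall(
            specimen_id=specimen_id, status="excluded", fractions=fractions
        )
    fired = tuple(
        name
        for name in CRITERIA
        if fractions.by_criterion(name) > cutoffs.by_criterion(name)
    )
    return FishCall(
        specimen_id=specimen_id,
        status="positive" if fired else "negative",
        fired_criteria=fired,
        fractions=fractions,
    )


def score_specimen(
    specimen: SpecimenRecord,
    cutoffs: CutoffSet,
    rng: Optional[np.random.Generator] = None,
    n_areas: int = DEFAULT_N_AREAS,
    nuclei_per_area: int = DEFAULT_NUCLEI_PER_AREA,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
) -> FishCall:
    """Select nuclei, compute fractions, and classify one specimen."""
    selected = select_nuclei(specimen, n_areas, nuclei_per_area, rng)
    fractions = criterion_fractions(selected) if selected else None
    return classify_specimen(fractions, cutoffs, specimen.specimen_id, min_nuclei)


def score_cohort(
    specimens: Iterable[SpecimenRecord],
    cutoffs: CutoffSet,
    seed: int = 0,
    n_areas: int = DEFAULT_N_AREAS,
    nuclei_per_area: int = DEFAULT_NUCLEI_PER_AREA,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
) -> list[FishCall]:
    """Score every specimen with an independent RNG stream per specimen.

    Streams are keyed by position in a seed-spawned sequence, so scoring a
    cohort twice with the same seed reproduces identical calls.
    """
    specimens = list(specimens)
    children = np.random.SeedSequence(seed).spawn(len(specimens))
    return [
        score_specimen(
            specimen,
            cutoffs,
            rng=np.random.default_rng(child),
            n_areas=n_areas,
            nuclei_per_area=nuclei_per_area,
            min_nuclei=min_nuclei,
        )
        for specimen, child in zip(specimens, children)
    ]
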