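"""Synthetic per-nucleus FISH cohorts with the assay's statistical structure.

The generator stands in for slides: each specimen is a mixture of diploid
nuclei and, with some probability, nuclei carrying a clonal copy-number
genotype drawn from an alteration spectrum (RREB1/6p25 gain, CCND1/11q13
gain, chromosome-6 polysomy, relative MYB loss, or a complex combination).
Observed counts are the true copy numbers passed through a sectioning noise
model: binomial signal dropout (nuclear truncation in 5 µm sections), a
small probability of a spurious split signal, and per-nucleus QC failure.

Clonal fraction varies deterministically across a specimen's areas
(a symmetric spread around the design's base fraction) so that downstream
area-selection enrichment has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    SUBTYPE_GROUP,
    Area,
    ConfigError,
    NucleusSignal,
    SpecimenRecord,
)

__all__ = [
    "CloneGenotype",
    "NoiseModel",
    "SpecimenDesign",
    "DIPLOID",
    "DEFAULT_SPECTRUM",
    "DEFAULT_NOISE",
    "DEFAULT_CLONE_PREVALENCE",
    "TABLE1_COMPOSITION",
    "simulate_nucleus",
    "simulate_specimen",
    "simulate_cohort",
    "table1_composition",
    "cohort_metadata",
]


@dataclass(frozen=True)
class CloneGenotype:
    """True copy numbers of the four probe targets in a clone."""

    n_rreb1: int
    n_ccnd1: int
    n_myb: int
    n_cep6: int

    def __post_init__(self) -> None:
        for name in ("n_rreb1", "n_ccnd1", "n_myb", "n_cep6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def copies(self) -> tuple[int, int, int, int]:
        return (self.n_rreb1, self.n_ccnd1, self.n_myb, self.n_cep6)


DIPLOID = CloneGenotype(2, 2, 2, 2)

#: Alteration spectrum with weights.  Chromosome-6 polysomy scales RREB1,
#: MYB and CEP6 together, so it trips the RREB1>2 clause but not RREB1>CEP6
#: — exactly the distinction the centromere reference probe exists to make.
#: Weights are set so the marginal clause prevalences among clone-bearing
#: melanomas approximate the reported per-probe sensitivities
#: (RREB1 ~60%, CCND1 ~38%, MYB ~37% of melanomas).
DEFAULT_SPECTRUM: tuple[tuple[CloneGenotype, float], ...] = (
    (CloneGenotype(4, 2, 2, 2), 0.25),  # focal 6p25 amplification
    (CloneGenotype(2, 4, 2, 2), 0.15),  # focal 11q13 amplification
    (CloneGenotype(3, 2, 3, 3), 0.20),  # chromosome-6 polysomy
    (CloneGenotype(2, 2, 1, 2), 0.15),  # relative 6q23 (MYB) loss
    (CloneGenotype(4, 4, 1, 2), 0.25),  # complex genotype, all clauses
)


@dataclass(frozen=True)
class NoiseModel:
    """Sectioned-tissue FISH observation noise.

    p_dropout — per-signal loss probability (nuclear truncation);
    p_split   — per-probe probability of one spurious extra signal;
    p_qc_fail — per-nucleus probability of being flagged unevaluable.
    """

    p_dropout: float = 0.10
    p_split: float = 0.02
    p_qc_fail: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_dropout", "p_split", "p_qc_fail"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


DEFAULT_NOISE = NoiseModel()

#: Probability that a specimen of each diagnosis group carries any
#: FISH-visible clone at all.  The melanoma value mirrors the fact that the
#: assay finds no abnormality in roughly 16% of confirmed melanomas; the
#: dysplastic and nevus values mirror their observed positivity rates.
DEFAULT_CLONE_PREVALENCE: dict[str, float] = {
    "nevus": 0.02,
    "dysplastic": 0.09,
    "melanoma": 0.84,
}

_DEFAULT_N_AREAS = 4
_DEFAULT_NUCLEI_PER_AREA = 25
_DEFAULT_CLONAL_FRACTION = 0.65
_DEFAULT_AREA_JITTER = 0.15


def _area_fractions(base: float, jitter: float, n_areas: int) -> tuple[float, ...]:
    """Symmetric deterministic spread of clonal fraction across areas."""
    if n_areas == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-1.0, 1.0, n_areas)
    return tuple(float(np.clip(base + jitter * o, 0.0, 1.0)) for o in offsets)


@dataclass(frozen=True)
class SpecimenDesign:
    """Generative parameters for one specimen's nuclei.

    ``clonal_fraction_by_area`` gives, per area, the fraction of nuclei
    carrying the clone genotype *if* the specimen carries a clone at all
    (drawn with probability ``p_detectable_clone``); a clone-free specimen is
    all diploid, noise only.
    """

    group: str
    subtype: str
    n_areas: int = _DEFAULT_N_AREAS
    nuclei_per_area: int = _DEFAULT_NUCLEI_PER_AREA
    clonal_fraction_by_area: tuple[float, ...] = ()
    p_detectable_clone: float = 0.0

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_GROUP or SUBTYPE_GROUP[self.subtype] != self.group:
            raise ValueError(f"subtype {self.subtype!r} not in group {self.group!r}")
        if self.n_areas < 1 or self.nuclei_per_area < 1:
            raise ValueError("n_areas and nuclei_per_area must be >= 1")
        if len(self.clonal_fraction_by_area) != self.n_areas:
            raise ValueError("clonal_fraction_by_area must have one entry per area")
        if not all(0 <= f <= 1 for f in self.clonal_fraction_by_area):
            raise ValueError("clonal fractions must lie in [0, 1]")
        if not 0 <= self.p_detectable_clone <= 1:
            raise ValueError("p_detectable_clone must lie in [0, 1]")

    @classmethod
    def for_group(
        cls,
        group: str,
        subtype: str,
        n_areas: int = _DEFAULT_N_AREAS,
        nuclei_per_area: int = _DEFAULT_NUCLEI_PER_AREA,
        clonal_fraction: float = _DEFAULT_CLONAL_FRACTION,
        area_jitter: float = _DEFAULT_AREA_JITTER,
        p_detectable_clone: Optional[float] = None,
    ) -> "SpecimenDesign":
        """Default design for a diagnosis group with study-level parameters."""
        if p_detectable_clone is None:
            p_detectable_clone = DEFAULT_CLONE_PREVALENCE[group]
        return cls(
            group=group,
            subtype=subtype,
            n_areas=n_areas,
            nuclei_per_area=nuclei_per_area,
            clonal_fraction_by_area=_area_fractions(
                clonal_fraction, area_jitter, n_areas
            ),
            p_detectable_clone=p_detectable_clone,
        )


def simulate_nucleus(
    genotype: CloneGenotype,
    noise: NoiseModel,
    rng: np.random.Generator,
    nucleus_id: str = "N1",
    area_id: str = "A1",
) -> NucleusSignal:
    """Observe one nucleus: binomial thinning plus a possible split signal.

    Each probe's observed count is Binomial(true copies, 1 − p_dropout) plus
    an independent +1 with probability p_split; qc_pass is drawn with
    probability 1 − p_qc_fail.
    """
    observed = []
    for copies in genotype.copies:
        kept = rng.binomial(copies, 1.0 - noise.p_dropout) if copies else 0
        kept += rng.random() < noise.p_split
        observed.append(int(kept))
    return NucleusSignal(
        nucleus_id=nucleus_id,
        area_id=area_id,
        rreb1=observed[0],
        ccnd1=observed[1],
        myb=observed[2],
        cep6=observed[3],
        qc_pass=bool(rng.random() >= noise.p_qc_fail),
    )


def _draw_genotype(
    spectrum: Sequence[tuple[CloneGenotype, float]], rng: np.random.Generator
) -> CloneGenotype:
    weights = np.array([w for _, w in spectrum], dtype=float)
    if weights.sum() <= 0:
        raise ConfigError("genotype spectrum weights must sum to a positive value")
    weights /= weights.sum()
    return spectrum[int(rng.choice(len(spectrum), p=weights))][0]


def simulate_specimen(
    design: SpecimenDesign,
    spectrum: Sequence[tuple[CloneGenotype, float]] = DEFAULT_SPECTRUM,
    noise: NoiseModel = DEFAULT_NOISE,
    rng: Optional[np.random.Generator] = None,
    specimen_id: str = "SP0001",
) -> SpecimenRecord:
    """Generate one specimen's areas of nuclei.

    With probability ``p_detectable_clone`` a single clone genotype is drawn
    from the spectrum and mixed into each area at that area's clonal
    fraction (per-nucleus Bernoulli); all remaining nuclei are diploid.
    Draws are vectorised per area, so large cohorts are cheap.
    """
    if rng is None:
        rng = np.random.default_rng()
    if design.p_detectable_clone > 0 and not spectrum:
        raise ConfigError("empty genotype spectrum with nonzero clone probability")
    has_clone = rng.random() < design.p_detectable_clone
    genotype = _draw_genotype(spectrum, rng) if has_clone else None

    areas = []
    diploid = np.array(DIPLOID.copies)
    for j, clone_frac in enumerate(design.clonal_fraction_by_area):
        n = design.nuclei_per_area
        copies = np.tile(diploid, (n, 1))
        if genotype is not None:
            clonal = rng.random(n) < clone_frac
            copies[clonal] = np.array(genotype.copies)
        kept = rng.binomial(copies, 1.0 - noise.p_dropout)
        split = rng.random((n, 4)) < noise.p_split
        observed = kept + split
        qc = rng.random(n) >= noise.p_qc_fail
        area_id = f"A{j + 1:02d}"
        nuclei = tuple(
            NucleusSignal(
                nucleus_id=f"{specimen_id}-{area_id}-N{i + 1:03d}",
                area_id=area_id,
                rreb1=int(observed[i, 0]),
                ccnd1=int(observed[i, 1]),
                myb=int(observed[i, 2]),
                cep6=int(observed[i, 3]),
                qc_pass=bool(qc[i]),
            )
            for i in range(n)
        )
        areas.append(Area(area_id=area_id, nuclei=nuclei))
    return SpecimenRecord(
        specimen_id=specimen_id,
        areas=tuple(areas),
        group=design.group,
        subtype=design.subtype,
    )


#: Validation-cohort composition by subtype: (group, subtype, n specimens).
#: 157 nevi + 176 dysplastic + 167 melanomas = 500 cases.
TABLE1_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("nevus", "Congenital", 8),
    ("nevus", "Compound", 37),
    ("nevus", "Intradermal", 62),
    ("nevus", "Junctional", 9),
    ("nevus", "Mild Atypia", 32),
    ("nevus", "Blue", 9),
    ("dysplastic", "Nevus-Moderate Atypia", 60),
    ("dysplastic", "Nevus-Severe Atypia", 29),
    ("dysplastic", "Nevus-Scalp", 38),
    ("dysplastic", "Nevus-Spitz", 49),
    ("melanoma", "Superficial Spreading", 71),
    ("melanoma", "Spindle cell/desmoplastic", 3),
    ("melanoma", "Nodular", 45),
    ("melanoma", "In Situ", 8),
    ("melanoma", "Metastatic", 40),
)


def table1_composition(**design_kwargs) -> list[tuple[SpecimenDesign, int]]:
    """Default composition mirroring the validation cohort's subtype counts."""
    return [
        (SpecimenDesign.for_group(group, subtype, **design_kwargs), n)
        for group, subtype, n in TABLE1_COMPOSITION
    ]


def simulate_cohort(
    composition: Sequence[tuple[SpecimenDesign, int]],
    seed: int,
    spectrum: Sequence[tuple[CloneGenotype, float]] = DEFAULT_SPECTRUM,
    noise: NoiseModel = DEFAULT_NOISE,
) -> list[SpecimenRecord]:
    """Generate a cohort; identical (composition, seed) yields identical data.

    Specimen ids run SP0001, SP0002, ... in composition order, and each
    specimen consumes its own spawned RNG stream, so per-specimen output is
    independent of the rest of the composition's sizes only in distribution,
    but fully reproducible for a fixed call.
    """
    total = sum(n for _, n in composition)
    if any(n < 0 for _, n in composition):
        raise ConfigError("n_specimens must be >= 0 for every design")
    children = np.random.SeedSequence(seed).spawn(total)
    specimens = []
    index = 0
    for design, n in composition:
        for _ in range(n):
            specimens.append(
                simulate_specimen(
                    design,
                    spectrum=spectrum,
                    noise=noise,
                    rng=np.random.default_rng(children[index]),
                    specimen_id=f"SP{index + 1:04d}",
                )
            )
            index += 1
    return specimens


def cohort_metadata(
    specimens: Sequence[SpecimenRecord],
) -> dict[str, tuple[str, str]]:
    """Extract the specimen_id -> (group, subtype) metadata mapping."""
    meta = {}
    for s in specimens:
        if s.group is None or s.subtype is None:
            raise ConfigError(f"specimen {s.specimen_id!r} lacks diagnosis labels")
        meta[s.specimen_id] = (s.group, s.subtype)
    return meta
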