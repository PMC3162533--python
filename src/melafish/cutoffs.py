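"""ROC analysis per criterion and specificity-first cutoff selection.

The validation design sweeps each criterion's fraction over a cutoff grid,
tracing sensitivity (melanoma fraction strictly above the cutoff) against
specificity (benign fraction at or below it — the complement of the strict
positivity rule).  Final cutoffs maximise specificity over sensitivity,
operationalised as: per criterion, the smallest grid cutoff whose
single-criterion specificity on the benign set reaches a floor (default
0.99), which maximises that criterion's sensitivity subject to the floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

from .model import CRITERIA, CriterionFractions, CutoffSet, MelafishError
from .scoring import classify_specimen

__all__ = [
    "DerivationError",
    "RocCurve",
    "CutoffDerivation",
    "default_grid",
    "roc_curve",
    "derive_cutoffs",
    "write_roc_table",
]


class DerivationError(MelafishError):
    """ROC derivation received unusable inputs or an unattainable floor."""


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep for one criterion: (cutoff, sensitivity, specificity)."""

    criterion: str
    points: tuple[tuple[Fraction, float, float], ...]


@dataclass(frozen=True)
class CutoffDerivation:
    """Derived cutoffs plus the combined OR-rule performance at them."""

    cutoffs: CutoffSet
    sensitivity: float  # combined OR rule, melanoma training set
    specificity: float  # combined OR rule, benign training set
    curves: dict[str, RocCurve]


def default_grid(step: Fraction = Fraction(1, 100)) -> tuple[Fraction, ...]:
    """Cutoff grid {0, step, 2·step, …, 1}."""
    if not 0 < step <= 1:
        raise DerivationError(f"grid step must lie in (0, 1], got {step}")
    n = int(1 / step)
    grid = [step * k for k in range(n + 1)]
    if grid[-1] != 1:
        grid.append(Fraction(1))
    return tuple(grid)


def roc_curve(
    benign: Sequence[CriterionFractions],
    melanoma: Sequence[CriterionFractions],
    criterion: str,
    grid: Optional[Sequence[Fraction]] = None,
) -> RocCurve:
    """Empirical ROC sweep for one criterion.

    At each cutoff c: sensitivity = share of melanoma specimens with
    fraction > c; specificity = share of benign specimens with fraction ≤ c.
    Comparisons are exact rational comparisons, mirroring the strict
    positivity rule.
    """
    if criterion not in CRITERIA:
        raise DerivationError(f"unknown criterion {criterion!r}")
    if not benign or not melanoma:
        raise DerivationError("both class lists must be non-empty")
    if grid is None:
        grid = default_grid()
    benign_f = [f.by_criterion(criterion) for f in benign]
    melanoma_f = [f.by_criterion(criterion) for f in melanoma]
    points = []
    for c in grid:
        sens = sum(f > c for f in melanoma_f) / len(melanoma_f)
        spec = sum(f <= c for f in benign_f) / len(benign_f)
        points.append((Fraction(c), sens, spec))
    return RocCurve(criterion=criterion, points=tuple(points))


def derive_cutoffs(
    benign: Sequence[CriterionFractions],
    melanoma: Sequence[CriterionFractions],
    specificity_floor: float = 0.99,
    grid: Optional[Sequence[Fraction]] = None,
    label: str = "derived",
) -> CutoffDerivation:
    """Select, per criterion, the smallest grid cutoff meeting the floor.

    The selection is independent per criterion; the returned object also
    reports the combined OR-rule sensitivity and specificity at the derived
    cutoffs on the same training lists (no exclusion rule is applied here —
    the inputs are already per-specimen fractions).
    """
    if not 0 <= specificity_floor <= 1:
        raise DerivationError(
            f"specificity_floor must lie in [0, 1], got {specificity_floor}"
        )
    if grid is None:
        grid = default_grid()
    curves = {}
    chosen: dict[str, Fraction] = {}
    for criterion in CRITERIA:
        curve = roc_curve(benign, melanoma, criterion, grid)
        curves[criterion] = curve
        for cutoff, _sens, spec in curve.points:
            if spec >= specificity_floor:
                chosen[criterion] = cutoff
                break
        else:
            raise DerivationError(
                f"specificity floor {specificity_floor} unattainable for "
                f"criterion {criterion!r} on the given grid"
            )
    cutoffs = CutoffSet(*(chosen[c] for c in CRITERIA), label=label)
    calls_m = [classify_specimen(f, cutoffs, min_nuclei=0) for f in melanoma]
    calls_b = [classify_specimen(f, cutoffs, min_nuclei=0) for f in benign]
    sensitivity = sum(c.status == "positive" for c in calls_m) / len(melanoma)
    specificity = sum(c.status == "negative" for c in calls_b) / len(benign)
    return CutoffDerivation(
        cutoffs=cutoffs,
        sensitivity=sensitivity,
        specificity=specificity,
        curves=curves,
    )


def write_roc_table(curves: dict[str, RocCurve], path: str | Path) -> None:
    """Write all curves to a TSV: criterion, cutoff, sensitivity, specificity."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("criterion\tcutoff\tsensitivity\tspecificity\n")
        for criterion in CRITERIA:
            if criterion not in curves:
                continue
            for cutoff, sens, spec in curves[criterion].points:
                handle.write(
                    f"{criterion}\t{float(cutoff):.4f}\t{sens:.6f}\t{spec:.6f}\n"
                )
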