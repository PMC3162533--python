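"""Cohort-level validation metrics and the study-results summary table.

Produces per-subtype and per-group case counts, positivity percentages
(one decimal, round half up — so 2/32 prints as 6.3), Wilson score interval
estimates, and the three headline metrics: sensitivity (melanoma group),
specificity (benign nevus group, mild atypia included per the cohort's
grouping), and the atypical positivity rate (moderate- or severe-atypia
nevi called positive).  Excluded specimens are reported separately and
removed from every denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .model import (
    GROUP_SUBTYPES,
    GROUPS,
    ConsistencyError,
    CriterionFractions,
    FishCall,
    MelafishError,
)

__all__ = [
    "MetricError",
    "SummaryRow",
    "CohortSummary",
    "TABLE2_COUNTS",
    "percent_positive",
    "binomial_interval",
    "summarize_cohort",
    "sensitivity",
    "specificity",
    "atypical_positivity_rate",
    "calls_from_counts",
    "write_summary_table",
    "summary_to_json",
    "format_summary",
]

#: Atypia severities whose positivity defines the atypical positivity rate.
ATYPICAL_SUBTYPES = ("Nevus-Moderate Atypia", "Nevus-Severe Atypia")

#: Published validation-cohort outcome counts:
#: (group, subtype, total cases, positive by FISH).
TABLE2_COUNTS: tuple[tuple[str, str, int, int], ...] = (
    ("nevus", "Congenital", 8, 0),
    ("nevus", "Compound", 37, 0),
    ("nevus", "Intradermal", 62, 1),
    ("nevus", "Junctional", 9, 0),
    ("nevus", "Mild Atypia", 32, 2),
    ("nevus", "Blue", 9, 0),
    ("dysplastic", "Nevus-Moderate Atypia", 60, 4),
    ("dysplastic", "Nevus-Severe Atypia", 29, 3),
    ("dysplastic", "Nevus-Scalp", 38, 3),
    ("dysplastic", "Nevus-Spitz", 49, 6),
    ("melanoma", "Superficial Spreading", 71, 57),
    ("melanoma", "Spindle cell/desmoplastic", 3, 2),
    ("melanoma", "Nodular", 45, 42),
    ("melanoma", "In Situ", 8, 6),
    ("melanoma", "Metastatic", 40, 33),
)


class MetricError(MelafishError):
    """A metric is undefined (zero denominator or missing rows)."""


def percent_positive(k: int, n: int) -> float:
    """100·k/n rounded half up to one decimal, computed in exact arithmetic."""
    if n <= 0:
        raise MetricError("percentage undefined for zero denominator")
    tenths = Fraction(1000 * k, n)
    rounded = (tenths + Fraction(1, 2)).__floor__()
    return rounded / 10


def binomial_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as fractions in [0,1]."""
    if n < 1:
        raise MetricError("interval undefined for n = 0")
    if not 0 <= k <= n:
        raise MetricError(f"need 0 <= k <= n, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(low), float(high)


@dataclass(frozen=True)
class SummaryRow:
    group: str
    subtype: Optional[str]  # None for group totals
    n_cases: int
    n_positive: int
    n_excluded: int
    percent_positive: Optional[float]  # one decimal; None if no evaluable cases
    ci_low: Optional[float]  # Wilson bounds as percentages
    ci_high: Optional[float]


@dataclass(frozen=True)
class CohortSummary:
    rows: tuple[SummaryRow, ...]
    group_totals: tuple[SummaryRow, ...]
    sensitivity: Optional[float]
    specificity: Optional[float]
    atypical_positivity_rate: Optional[float]


def _make_row(
    group: str, subtype: Optional[str], n_cases: int, n_positive: int, n_excluded: int
) -> SummaryRow:
    evaluable = n_cases - n_excluded
    if evaluable > 0:
        pct = percent_positive(n_positive, evaluable)
        low, high = binomial_interval(n_positive, evaluable)
        ci = (round(100 * low, 1), round(100 * high, 1))
    else:
        pct, ci = None, (None, None)
    return SummaryRow(
        group=group,
        subtype=subtype,
        n_cases=n_cases,
        n_positive=n_positive,
        n_excluded=n_excluded,
        percent_positive=pct,
        ci_low=ci[0],
        ci_high=ci[1],
    )


def summarize_cohort(
    metadata: Mapping[str, tuple[str, str]],
    calls: Sequence[FishCall],
) -> CohortSummary:
    """Aggregate per-specimen calls into the study-results table.

    Every call's specimen must appear in the metadata mapping
    (specimen_id -> (group, subtype)); subtype rows appear in canonical
    vocabulary order, restricted to subtypes with at least one call.
    """
    tallies: dict[str, list[int]] = {}  # subtype -> [cases, positive, excluded]
    for call in calls:
        if call.specimen_id not in metadata:
            raise ConsistencyError(
                f"call for specimen {call.specimen_id!r} has no metadata"
            )
        _group, subtype = metadata[call.specimen_id]
        t = tallies.setdefault(subtype, [0, 0, 0])
        t[0] += 1
        t[1] += call.status == "positive"
        t[2] += call.status == "excluded"

    rows = []
    group_rows = []
    for group in GROUPS:
        g_cases = g_pos = g_excl = 0
        seen_any = False
        for subtype in GROUP_SUBTYPES[group]:
            if subtype not in tallies:
                continue
            seen_any = True
            cases, pos, excl = tallies[subtype]
            g_cases += cases
            g_pos += pos
            g_excl += excl
            rows.append(_make_row(group, subtype, cases, pos, excl))
        if seen_any:
            group_rows.append(_make_row(group, None, g_cases, g_pos, g_excl))

    by_group = {r.group: r for r in group_rows}

    def _group_pct(group: str) -> Optional[float]:
        row = by_group.get(group)
        if row is None or row.percent_positive is None:
            return None
        return row.percent_positive

    sens = _group_pct("melanoma")
    spec_pct = _group_pct("nevus")
    spec = None if spec_pct is None else percent_positive(
        (by_group["nevus"].n_cases - by_group["nevus"].n_excluded)
        - by_group["nevus"].n_positive,
        by_group["nevus"].n_cases - by_group["nevus"].n_excluded,
    )
    atyp_cases = sum(tallies.get(s, [0, 0, 0])[0] for s in ATYPICAL_SUBTYPES)
    atyp_pos = sum(tallies.get(s, [0, 0, 0])[1] for s in ATYPICAL_SUBTYPES)
    atyp_excl = sum(tallies.get(s, [0, 0, 0])[2] for s in ATYPICAL_SUBTYPES)
    atyp = (
        percent_positive(atyp_pos, atyp_cases - atyp_excl)
        if atyp_cases - atyp_excl > 0
        else None
    )
    return CohortSummary(
        rows=tuple(rows),
        group_totals=tuple(group_rows),
        sensitivity=sens,
        specificity=spec,
        atypical_positivity_rate=atyp,
    )


def _group_total(summary: CohortSummary, group: str) -> SummaryRow:
    for row in summary.group_totals:
        if row.group == group:
            return row
    raise MetricError(f"group {group!r} absent from summary")


def sensitivity(summary: CohortSummary) -> float:
    """Percent of evaluable melanoma specimens called positive."""
    row = _group_total(summary, "melanoma")
    return percent_positive(row.n_positive, row.n_cases - row.n_excluded)


def specificity(summary: CohortSummary) -> float:
    """Percent of evaluable benign-nevus specimens called negative."""
    row = _group_total(summary, "nevus")
    evaluable = row.n_cases - row.n_excluded
    return percent_positive(evaluable - row.n_positive, evaluable)


def atypical_positivity_rate(summary: CohortSummary) -> float:
    """Percent of evaluable moderate/severe-atypia nevi called positive."""
    rows = [r for r in summary.rows if r.subtype in ATYPICAL_SUBTYPES]
    if not rows:
        raise MetricError("moderate/severe atypia rows absent from summary")
    cases = sum(r.n_cases - r.n_excluded for r in rows)
    pos = sum(r.n_positive for r in rows)
    return percent_positive(pos, cases)


def calls_from_counts(
    counts: Iterable[tuple[str, str, int, int]],
    n_evaluated: int = 30,
) -> tuple[dict[str, tuple[str, str]], list[FishCall]]:
    """Encode printed (group, subtype, cases, positives) rows as calls.

    Positive calls are given a saturated RREB1-gain fraction and negative
    calls all-zero fractions; this reconstructs published summary tables
    from their counts so the aggregation path can be validated against them.
    """
    metadata: dict[str, tuple[str, str]] = {}
    calls: list[FishCall] = []
    index = 0
    for group, subtype, n_cases, n_positive in counts:
        if not 0 <= n_positive <= n_cases:
            raise MetricError(
                f"{subtype}: need 0 <= positives <= cases, got {n_positive}/{n_cases}"
            )
        for i in range(n_cases):
            index += 1
            specimen_id = f"RC{index:04d}"
            metadata[specimen_id] = (group, subtype)
            positive = i < n_positive
            fractions = CriterionFractions(
                Fraction(n_evaluated if positive else 0, n_evaluated),
                Fraction(0),
                Fraction(0),
                Fraction(0),
                n_evaluated=n_evaluated,
            )
            calls.append(
                FishCall(
                    specimen_id=specimen_id,
                    status="positive" if positive else "negative",
                    fired_criteria=("rreb1_gain",) if positive else (),
                    fractions=fractions,
                )
            )
    return metadata, calls


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _row_cells(row: SummaryRow) -> list[str]:
    pct = "" if row.percent_positive is None else f"{row.percent_positive:.1f}"
    low = "" if row.ci_low is None else f"{row.ci_low:.1f}"
    high = "" if row.ci_high is None else f"{row.ci_high:.1f}"
    return [
        row.group,
        row.subtype if row.subtype is not None else "(all)",
        str(row.n_cases),
        str(row.n_positive),
        str(row.n_excluded),
        pct,
        low,
        high,
    ]


def write_summary_table(summary: CohortSummary, path: str | Path) -> None:
    """TSV mirroring the study-results table, group totals as "(all)" rows."""
    path = Path(path)
    header = [
        "group",
        "subtype",
        "n_cases",
        "n_positive",
        "n_excluded",
        "percent_positive",
        "ci_low",
        "ci_high",
    ]
    with path.open("w") as handle:
        handle.write("\t".join(header) + "\n")
        for group_row in summary.group_totals:
            for row in summary.rows:
                if row.group == group_row.group:
                    handle.write("\t".join(_row_cells(row)) + "\n")
            handle.write("\t".join(_row_cells(group_row)) + "\n")


def summary_to_json(summary: CohortSummary, path: str | Path) -> None:
    payload = {
        "rows": [asdict(r) for r in summary.rows],
        "group_totals": [asdict(r) for r in summary.group_totals],
        "sensitivity": summary.sensitivity,
        "specificity": summary.specificity,
        "atypical_positivity_rate": summary.atypical_positivity_rate,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def format_summary(summary: CohortSummary) -> str:
    """Human-readable study-results table."""
    lines = [
        f"{'Group':<12}{'Subtype':<28}{'Cases':>6}{'Pos':>5}{'Excl':>5}"
        f"{'%Pos':>8}{'CI95':>16}"
    ]
    for group_row in summary.group_totals:
        for row in summary.rows:
            if row.group != group_row.group:
                continue
            ci = (
                f"[{row.ci_low:.1f}, {row.ci_high:.1f}]"
                if row.ci_low is not None
                else ""
            )
            pct = f"{row.percent_positive:.1f}" if row.percent_positive is not None else ""
            lines.append(
                f"{row.group:<12}{row.subtype:<28}{row.n_cases:>6}"
                f"{row.n_positive:>5}{row.n_excluded:>5}{pct:>8}{ci:>16}"
            )
        pct = (
            f"{group_row.percent_positive:.1f}"
            if group_row.percent_positive is not None
            else ""
        )
        lines.append(
            f"{group_row.group:<12}{'(all)':<28}{group_row.n_cases:>6}"
            f"{group_row.n_positive:>5}{group_row.n_excluded:>5}{pct:>8}"
        )
    for label, value in (
        ("sensitivity", summary.sensitivity),
        ("specificity", summary.specificity),
        ("atypical positivity rate", summary.atypical_positivity_rate),
    ):
        if value is not None:
            lines.append(f"{label}: {value:.1f}%")
    return "\n".join(lines)
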