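"""Domain types and file I/O for four-probe melanocytic-lesion FISH data.

The assay counts fluorescent signals for four probes in each scored nucleus:
RREB1 (6p25), CCND1 (11q13), MYB (6q23) and the chromosome-6 centromere
reference D6Z1 (CEP6).  A specimen is summarised by four abnormal-nucleus
fractions and called positive when any fraction strictly exceeds its cutoff.

All fractions and cutoffs are held as exact :class:`fractions.Fraction`
values; percentages appear only at I/O boundaries, so cutoff comparisons are
never subject to double rounding.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "PROBES",
    "CRITERIA",
    "GROUPS",
    "GROUP_SUBTYPES",
    "SUBTYPE_GROUP",
    "CUTOFF_PRESETS",
    "MelafishError",
    "ParseError",
    "ConfigError",
    "ConsistencyError",
    "NucleusSignal",
    "Area",
    "SpecimenRecord",
    "CriterionFractions",
    "CutoffSet",
    "FishCall",
    "read_nuclei_table",
    "write_nuclei_table",
    "read_specimen_table",
    "write_specimen_table",
    "read_cutoffs",
    "write_cutoffs",
    "resolve_cutoffs",
    "read_calls",
    "write_calls",
]

# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

#: Probe name -> cytogenetic band of the target locus.
PROBES: Mapping[str, str] = {
    "RREB1": "6p25",
    "CCND1": "11q13",
    "MYB": "6q23",
    "CEP6": "cen6",
}

#: The four positivity criteria, in canonical order.  Each names the
#: abnormal-nucleus fraction it thresholds: locus gains of RREB1/CCND1
#: (count > 2), RREB1 in excess of the centromere-6 reference, and MYB
#: below the centromere-6 reference.
CRITERIA: tuple[str, ...] = (
    "rreb1_gain",
    "ccnd1_gain",
    "rreb1_gt_cep6",
    "myb_lt_cep6",
)

GROUPS: tuple[str, ...] = ("nevus", "dysplastic", "melanoma")

#: Closed subtype vocabulary per diagnosis group; labels follow the
#: published validation cohort's row names verbatim so summaries are
#: joinable against them.
GROUP_SUBTYPES: Mapping[str, tuple[str, ...]] = {
    "nevus": (
        "Congenital",
        "Compound",
        "Intradermal",
        "Junctional",
        "Mild Atypia",
        "Blue",
    ),
    "dysplastic": (
        "Nevus-Moderate Atypia",
        "Nevus-Severe Atypia",
        "Nevus-Scalp",
        "Nevus-Spitz",
    ),
    "melanoma": (
        "Superficial Spreading",
        "Spindle cell/desmoplastic",
        "Nodular",
        "In Situ",
        "Metastatic",
    ),
}

SUBTYPE_GROUP: Mapping[str, str] = {
    subtype: group for group, subs in GROUP_SUBTYPES.items() for subtype in subs
}


class MelafishError(Exception):
    """Base class for all package errors."""


class ParseError(MelafishError):
    """A tabular input violated its schema."""


class ConfigError(MelafishError):
    """A configuration value (cutoffs, designs, parameters) is invalid."""


class ConsistencyError(MelafishError):
    """Cross-table references do not line up."""


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusSignal:
    """Observed signal counts for one nucleus.

    Counts of zero are legal: sectioning tissue into 5 µm slices truncates
    nuclei and drops signals.  ``qc_pass=False`` marks overlapped or poorly
    hybridised nuclei, which never enter fraction computations.
    """

    nucleus_id: str
    area_id: str
    rreb1: int
    ccnd1: int
    myb: int
    cep6: int
    qc_pass: bool = True

    def __post_init__(self) -> None:
        for probe in ("rreb1", "ccnd1", "myb", "cep6"):
            value = getattr(self, probe)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValueError(
                    f"{probe} count must be a non-negative integer, got {value!r}"
                )

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.rreb1, self.ccnd1, self.myb, self.cep6)


@dataclass(frozen=True)
class Area:
    """One tumour area: an ordered collection of enumerated nuclei."""

    area_id: str
    nuclei: tuple[NucleusSignal, ...]

    def __post_init__(self) -> None:
        ids = [n.nucleus_id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate nucleus_id within area {self.area_id!r}")

    def qc_pass_nuclei(self) -> tuple[NucleusSignal, ...]:
        return tuple(n for n in self.nuclei if n.qc_pass)


@dataclass(frozen=True)
class SpecimenRecord:
    """A specimen's areas plus (optionally) its diagnosis labels."""

    specimen_id: str
    areas: tuple[Area, ...]
    group: Optional[str] = None
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subtype is not None:
            if self.subtype not in SUBTYPE_GROUP:
                raise ValueError(f"unknown subtype {self.subtype!r}")
            expected = SUBTYPE_GROUP[self.subtype]
            if self.group is not None and self.group != expected:
                raise ValueError(
                    f"subtype {self.subtype!r} belongs to group {expected!r}, "
                    f"not {self.group!r}"
                )
        elif self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def all_nuclei(self) -> tuple[NucleusSignal, ...]:
        return tuple(n for a in self.areas for n in a.nuclei)


def _exact_fraction(value: Fraction, n: int, name: str) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    if n > 0 and (value * n).denominator != 1:
        raise ValueError(f"{name} = {value} is not an integer multiple of 1/{n}")


@dataclass(frozen=True)
class CriterionFractions:
    """The four per-specimen abnormal-nucleus fractions.

    Each fraction is exactly (integer numerator) / ``n_evaluated``.
    """

    f_rreb1_gain: Fraction
    f_ccnd1_gain: Fraction
    f_rreb1_gt_cep6: Fraction
    f_myb_lt_cep6: Fraction
    n_evaluated: int

    def __post_init__(self) -> None:
        if self.n_evaluated < 0:
            raise ValueError("n_evaluated must be >= 0")
        for name in CRITERIA:
            _exact_fraction(self.by_criterion(name), self.n_evaluated, f"f_{name}")

    def by_criterion(self, criterion: str) -> Fraction:
        return getattr(self, f"f_{criterion}")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], n_evaluated: int
    ) -> "CriterionFractions":
        return cls(
            *(Fraction(counts[name], n_evaluated) for name in CRITERIA),
            n_evaluated=n_evaluated,
        )


@dataclass(frozen=True)
class CutoffSet:
    """The four decision thresholds of the OR positivity rule."""

    c_rreb1_gain: Fraction
    c_ccnd1_gain: Fraction
    c_rreb1_gt_cep6: Fraction
    c_myb_lt_cep6: Fraction
    label: str = ""

    def __post_init__(self) -> None:
        for name in CRITERIA:
            value = self.by_criterion(name)
            if not 0 <= value <= 1:
                raise ValueError(f"cutoff {name} must lie in [0, 1], got {value}")

    def by_criterion(self, criterion: str) -> Fraction:
        return getattr(self, f"c_{criterion}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.by_criterion(name)) for name in CRITERIA}


def _percent_cutoffs(label: str, *percents: int) -> CutoffSet:
    return CutoffSet(*(Fraction(p, 100) for p in percents), label=label)


#: Named cutoff presets.  "table3" carries this assay's derived values;
#: "discussion" swaps in the 22% CCND1 figure quoted in the study's prose
#: (the tabulated 19% is treated as authoritative); "gerami2009" carries the
#: previously published manual-scoring cutoffs of Gerami et al. (2009).
CUTOFF_PRESETS: Mapping[str, CutoffSet] = {
    "table3": _percent_cutoffs("table3", 16, 19, 53, 42),
    "discussion": _percent_cutoffs("discussion", 16, 22, 53, 42),
    "gerami2009": _percent_cutoffs("gerami2009", 29, 38, 55, 42),
}


@dataclass(frozen=True)
class FishCall:
    """The per-specimen classification outcome."""

    specimen_id: str
    status: str  # "positive" | "negative" | "excluded"
    fired_criteria: tuple[str, ...] = ()
    fractions: Optional[CriterionFractions] = None

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "excluded"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "positive") != bool(self.fired_criteria):
            raise ValueError("status 'positive' iff fired_criteria is non-empty")
        unknown = set(self.fired_criteria) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_NUCLEI_COLUMNS = (
    "specimen_id",
    "area_id",
    "nucleus_id",
    "rreb1",
    "ccnd1",
    "myb",
    "cep6",
    "qc_pass",
)

_TRUTHY = {"true", "t", "1", "yes"}
_FALSY = {"false", "f", "0", "no"}


def _parse_bool(raw: str, line_no: int, column: str) -> bool:
    lowered = raw.strip().lower()
    if lowered in _TRUTHY:
        return True
    if lowered in _FALSY:
        return False
    raise ParseError(f"line {line_no}: cannot parse {column}={raw!r} as boolean")


def _parse_count(raw: str, line_no: int, column: str) -> int:
    try:
        value = int(raw)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-integer {column} count {raw!r}"
        ) from None
    if value < 0:
        raise ParseError(f"line {line_no}: negative {column} count {value}")
    return value


def read_nuclei_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a per-nucleus signal TSV into specimen records.

    Expected header columns: specimen_id, area_id, nucleus_id, rreb1, ccnd1,
    myb, cep6, qc_pass.  The qc_pass column may be absent, in which case all
    nuclei are taken to pass QC (enumeration systems that pre-filter do not
    always export the flag).  Rows are grouped into areas per specimen in
    order of first appearance.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise ParseError(f"{path}: empty file")
        required = set(_NUCLEI_COLUMNS) - {"qc_pass"}
        missing = required - set(header)
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        has_qc = "qc_pass" in header

        # specimen_id -> area_id -> list of nuclei, insertion-ordered
        grouped: dict[str, dict[str, list[NucleusSignal]]] = {}
        for line_no, row in enumerate(reader, start=2):
            counts = {
                probe: _parse_count(row[probe], line_no, probe)
                for probe in ("rreb1", "ccnd1", "myb", "cep6")
            }
            qc = _parse_bool(row["qc_pass"], line_no, "qc_pass") if has_qc else True
            nucleus = NucleusSignal(
                nucleus_id=row["nucleus_id"],
                area_id=row["area_id"],
                qc_pass=qc,
                **counts,
            )
            grouped.setdefault(row["specimen_id"], {}).setdefault(
                row["area_id"], []
            ).append(nucleus)

    specimens = []
    for specimen_id, areas in grouped.items():
        try:
            specimens.append(
                SpecimenRecord(
                    specimen_id=specimen_id,
                    areas=tuple(
                        Area(area_id=aid, nuclei=tuple(nuclei))
                        for aid, nuclei in areas.items()
                    ),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: specimen {specimen_id!r}: {exc}") from exc
    return specimens


def write_nuclei_table(specimens: Iterable[SpecimenRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_NUCLEI_COLUMNS)
        for specimen in specimens:
            for area in specimen.areas:
                for n in area.nuclei:
                    writer.writerow(
                        [
                            specimen.specimen_id,
                            area.area_id,
                            n.nucleus_id,
                            n.rreb1,
                            n.ccnd1,
                            n.myb,
                            n.cep6,
                            "true" if n.qc_pass else "false",
                        ]
                    )


def read_specimen_table(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read specimen metadata (specimen_id, group, subtype) from a TSV.

    Returns a mapping specimen_id -> (group, subtype); subtypes are validated
    against the closed vocabulary and their group membership.
    """
    path = Path(path)
    metadata: dict[str, tuple[str, str]] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = {"specimen_id", "group", "subtype"} - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            subtype = row["subtype"]
            group = row["group"]
            if subtype not in SUBTYPE_GROUP:
                raise ParseError(f"line {line_no}: unknown subtype {subtype!r}")
            if SUBTYPE_GROUP[subtype] != group:
                raise ParseError(
                    f"line {line_no}: subtype {subtype!r} is not in group {group!r}"
                )
            if row["specimen_id"] in metadata:
                raise ParseError(
                    f"line {line_no}: duplicate specimen_id {row['specimen_id']!r}"
                )
            metadata[row["specimen_id"]] = (group, subtype)
    return metadata


def write_specimen_table(
    metadata: Mapping[str, tuple[str, str]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["specimen_id", "group", "subtype"])
        for specimen_id, (group, subtype) in metadata.items():
            writer.writerow([specimen_id, group, subtype])


def attach_metadata(
    specimens: Iterable[SpecimenRecord], metadata: Mapping[str, tuple[str, str]]
) -> list[SpecimenRecord]:
    """Return specimens with group/subtype labels filled in from metadata."""
    out = []
    for specimen in specimens:
        try:
            group, subtype = metadata[specimen.specimen_id]
        except KeyError:
            raise ConsistencyError(
                f"specimen {specimen.specimen_id!r} missing from metadata"
            ) from None
        out.append(replace(specimen, group=group, subtype=subtype))
    return out


# ---------------------------------------------------------------------------
# Cutoff I/O
# ---------------------------------------------------------------------------


def _normalize_cutoff(value: object, key: str) -> Fraction:
    if isinstance(value, str):
        stripped = value.strip()
        try:
            if stripped.endswith("%"):
                result = Fraction(stripped[:-1].strip()) / 100
            else:
                result = Fraction(stripped)
        except (ValueError, ZeroDivisionError):
            raise ConfigError(f"cutoff {key}: cannot parse {value!r}") from None
    elif isinstance(value, bool):
        raise ConfigError(f"cutoff {key}: boolean is not a valid cutoff")
    elif isinstance(value, (int, float)):
        # str() gives the shortest decimal repr, so JSON's 0.16 becomes the
        # exact fraction 4/25 rather than the nearest binary float.
        result = Fraction(str(value))
    else:
        raise ConfigError(f"cutoff {key}: unsupported type {type(value).__name__}")
    if not 0 <= result <= 1:
        raise ConfigError(f"cutoff {key}: {value!r} is outside [0, 1]")
    return result


def read_cutoffs(path: str | Path) -> CutoffSet:
    """Read a cutoff set from JSON.

    The object must contain the four criterion keys (``rreb1_gain``,
    ``ccnd1_gain``, ``rreb1_gt_cep6``, ``myb_lt_cep6``), each either a
    fraction in [0, 1] or a percent string such as ``"16%"``; an optional
    ``label`` is carried through.
    """
    path = Path(path)
    with path.open() as handle:
        try:
            raw = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a JSON object")
    missing = set(CRITERIA) - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing cutoff key(s) {sorted(missing)}")
    return CutoffSet(
        *(_normalize_cutoff(raw[name], name) for name in CRITERIA),
        label=str(raw.get("label", path.stem)),
    )


def write_cutoffs(cutoffs: CutoffSet, path: str | Path) -> None:
    path = Path(path)
    payload: dict[str, object] = {
        name: float(cutoffs.by_criterion(name)) for name in CRITERIA
    }
    payload["label"] = cutoffs.label
    path.write_text(json.dumps(payload, indent=2) + "\n")


def resolve_cutoffs(name_or_path: str) -> CutoffSet:
    """Resolve a preset name ("table3", "discussion", "gerami2009") or a JSON path."""
    if name_or_path in CUTOFF_PRESETS:
        return CUTOFF_PRESETS[name_or_path]
    path = Path(name_or_path)
    if path.exists():
        return read_cutoffs(path)
    raise ConfigError(
        f"{name_or_path!r} is neither a preset ({', '.join(CUTOFF_PRESETS)}) "
        "nor an existing file"
    )


# ---------------------------------------------------------------------------
# Calls I/O
# ---------------------------------------------------------------------------

_CALLS_COLUMNS = (
    "specimen_id",
    "status",
    "f_rreb1_gain",
    "f_ccnd1_gain",
    "f_rreb1_gt_cep6",
    "f_myb_lt_cep6",
    "n_evaluated",
    "fired_criteria",
)


def write_calls(calls: Iterable[FishCall], path: str | Path) -> None:
    """Write calls to TSV; fractions are stored exactly as "num/den" strings."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALLS_COLUMNS)
        for call in calls:
            f = call.fractions
            row: list[object] = [call.specimen_id, call.status]
            if f is None:
                row += ["", "", "", "", 0]
            else:
                row += [str(f.by_criterion(name)) for name in CRITERIA]
                row.append(f.n_evaluated)
            row.append(";".join(call.fired_criteria))
            writer.writerow(row)


def read_calls(path: str | Path) -> list[FishCall]:
    path = Path(path)
    calls = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_CALLS_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            fractions: Optional[CriterionFractions] = None
            if row["f_rreb1_gain"] != "":
                try:
                    fractions = CriterionFractions(
                        *(Fraction(row[f"f_{name}"]) for name in CRITERIA),
                        n_evaluated=int(row["n_evaluated"]),
                    )
                except (ValueError, ZeroDivisionError) as exc:
                    raise ParseError(f"line {line_no}: {exc}") from exc
            fired = tuple(c for c in row["fired_criteria"].split(";") if c)
            try:
                calls.append(
                    FishCall(
                        specimen_id=row["specimen_id"],
                        status=row["status"],
                        fired_criteria=fired,
                        fractions=fractions,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return calls
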