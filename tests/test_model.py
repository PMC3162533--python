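"""Domain types, vocabulary validation, and TSV/JSON round-trips."""

import json
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from melafish import (
    CRITERIA,
    CUTOFF_PRESETS,
    Area,
    ConfigError,
    CriterionFractions,
    FishCall,
    NucleusSignal,
    ParseError,
    SpecimenRecord,
    read_calls,
    read_cutoffs,
    read_nuclei_table,
    resolve_cutoffs,
    write_calls,
    write_cutoffs,
    write_nuclei_table,
)
from melafish.model import read_specimen_table, write_specimen_table

from conftest import make_nuclei


def _write_tsv(path, rows, header="specimen_id\tarea_id\tnucleus_id\trreb1\tccnd1\tmyb\tcep6\tqc_pass"):
    path.write_text("\n".join([header] + rows) + "\n")


class TestNucleiTable:
    def test_two_rows_one_area(self, tmp_path):
        p = tmp_path / "n.tsv"
        _write_tsv(p, ["S1\tA1\tn1\t2\t2\t2\t2\ttrue", "S1\tA1\tn2\t2\t2\t2\t2\ttrue"])
        specimens = read_nuclei_table(p)
        assert len(specimens) == 1
        assert len(specimens[0].areas) == 1
        assert len(specimens[0].areas[0].nuclei) == 2

    def test_thirty_rows_three_areas(self, tmp_path):
        p = tmp_path / "n.tsv"
        rows = [
            f"S1\tA{a}\tn{a}_{i}\t2\t2\t2\t2\ttrue"
            for a in (1, 2, 3)
            for i in range(10)
        ]
        _write_tsv(p, rows)
        (specimen,) = read_nuclei_table(p)
        assert len(specimen.areas) == 3
        assert all(len(a.nuclei) == 10 for a in specimen.areas)

    def test_negative_count_names_line(self, tmp_path):
        p = tmp_path / "n.tsv"
        _write_tsv(p, ["S1\tA1\tn1\t2\t2\t2\t2\ttrue", "S1\tA1\tn2\t-1\t2\t2\t2\ttrue"])
        with pytest.raises(ParseError, match="line 3"):
            read_nuclei_table(p)

    def test_non_integer_count(self, tmp_path):
        p = tmp_path / "n.tsv"
        _write_tsv(p, ["S1\tA1\tn1\t2.5\t2\t2\t2\ttrue"])
        with pytest.raises(ParseError, match="non-integer"):
            read_nuclei_table(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("specimen_id\tarea_id\tnucleus_id\trreb1\n" "S1\tA1\tn1\t2\n")
        with pytest.raises(ParseError, match="missing column"):
            read_nuclei_table(p)

    def test_qc_defaults_true_when_column_absent(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text(
            "specimen_id\tarea_id\tnucleus_id\trreb1\tccnd1\tmyb\tcep6\n"
            "S1\tA1\tn1\t2\t2\t2\t2\n"
        )
        (specimen,) = read_nuclei_table(p)
        assert specimen.areas[0].nuclei[0].qc_pass is True

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 2),  # area index
                st.tuples(*[st.integers(0, 6)] * 4),
                st.booleans(),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_round_trip_preserves_everything(self, tmp_path_factory, rows):
        areas: dict[str, list[NucleusSignal]] = {}
        for i, (a, counts, qc) in enumerate(rows):
            area_id = f"A{a}"
            areas.setdefault(area_id, []).append(
                NucleusSignal(f"n{i}", area_id, *counts, qc_pass=qc)
            )
        specimen = SpecimenRecord(
            "S1", tuple(Area(aid, tuple(ns)) for aid, ns in areas.items())
        )
        p = tmp_path_factory.mktemp("rt") / "n.tsv"
        write_nuclei_table([specimen], p)
        (back,) = read_nuclei_table(p)
        assert back.specimen_id == "S1"
        assert {a.area_id: a.nuclei for a in back.areas} == {
            a.area_id: a.nuclei for a in specimen.areas
        }


class TestDomainInvariants:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            NucleusSignal("n1", "A1", -1, 2, 2, 2)

    def test_duplicate_nucleus_ids_rejected(self):
        nuclei = make_nuclei([(2, 2, 2, 2), (2, 2, 2, 2)])
        dup = tuple(nuclei[:1] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            Area("A1", dup)

    def test_subtype_must_match_group(self):
        with pytest.raises(ValueError):
            SpecimenRecord("S1", (), group="nevus", subtype="Nodular")

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError, match="unknown subtype"):
            SpecimenRecord("S1", (), group="nevus", subtype="Halo")

    def test_fraction_must_be_exact_multiple(self):
        with pytest.raises(ValueError):
            CriterionFractions(
                Fraction(1, 7), Fraction(0), Fraction(0), Fraction(0), n_evaluated=20
            )

    def test_positive_status_requires_fired_criteria(self):
        with pytest.raises(ValueError):
            FishCall("S1", "positive", fired_criteria=())


class TestCutoffsIO:
    @pytest.mark.parametrize(
        "payload,expected",
        [
            (
                {"rreb1_gain": "16%", "ccnd1_gain": "19%", "rreb1_gt_cep6": "53%", "myb_lt_cep6": "42%"},
                (Fraction(16, 100), Fraction(19, 100), Fraction(53, 100), Fraction(42, 100)),
            ),
            (
                {"rreb1_gain": "29%", "ccnd1_gain": "38%", "rreb1_gt_cep6": "55%", "myb_lt_cep6": "42%"},
                (Fraction(29, 100), Fraction(38, 100), Fraction(55, 100), Fraction(42, 100)),
            ),
            (
                {"rreb1_gain": 0, "ccnd1_gain": 0, "rreb1_gt_cep6": 0, "myb_lt_cep6": 0},
                (Fraction(0), Fraction(0), Fraction(0), Fraction(0)),
            ),
        ],
    )
    def test_normalization(self, tmp_path, payload, expected):
        p = tmp_path / "c.json"
        p.write_text(json.dumps(payload))
        cutoffs = read_cutoffs(p)
        assert tuple(cutoffs.by_criterion(c) for c in CRITERIA) == expected

    def test_percent_string_and_fraction_agree(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        a.write_text(json.dumps({c: "16%" for c in CRITERIA}))
        b.write_text(json.dumps({c: 0.16 for c in CRITERIA}))
        assert [read_cutoffs(a).by_criterion(c) for c in CRITERIA] == [
            read_cutoffs(b).by_criterion(c) for c in CRITERIA
        ]

    def test_missing_key(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text(json.dumps({"rreb1_gain": 0.16}))
        with pytest.raises(ConfigError, match="missing cutoff key"):
            read_cutoffs(p)

    def test_out_of_range(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text(json.dumps({c: "150%" for c in CRITERIA}))
        with pytest.raises(ConfigError, match="outside"):
            read_cutoffs(p)

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "c.json"
        write_cutoffs(CUTOFF_PRESETS["table3"], p)
        back = read_cutoffs(p)
        for c in CRITERIA:
            assert back.by_criterion(c) == CUTOFF_PRESETS["table3"].by_criterion(c)

    def test_resolve_preset_and_unknown(self):
        assert resolve_cutoffs("gerami2009").c_rreb1_gain == Fraction(29, 100)
        with pytest.raises(ConfigError):
            resolve_cutoffs("no-such-preset.json")

    def test_presets_match_published_values(self):
        table3 = CUTOFF_PRESETS["table3"]
        assert table3.as_dict() == {
            "rreb1_gain": 0.16, "ccnd1_gain": 0.19,
            "rreb1_gt_cep6": 0.53, "myb_lt_cep6": 0.42,
        }
        assert CUTOFF_PRESETS["discussion"].c_ccnd1_gain == Fraction(22, 100)
        assert CUTOFF_PRESETS["gerami2009"].as_dict() == {
            "rreb1_gain": 0.29, "ccnd1_gain": 0.38,
            "rreb1_gt_cep6": 0.55, "myb_lt_cep6": 0.42,
        }


class TestSpecimenAndCallsIO:
    def test_specimen_table_round_trip(self, tmp_path):
        meta = {"S1": ("nevus", "Compound"), "S2": ("melanoma", "Nodular")}
        p = tmp_path / "s.tsv"
        write_specimen_table(meta, p)
        assert read_specimen_table(p) == meta

    def test_specimen_table_rejects_wrong_group(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("specimen_id\tgroup\tsubtype\nS1\tnevus\tNodular\n")
        with pytest.raises(ParseError):
            read_specimen_table(p)

    def test_calls_round_trip(self, tmp_path):
        fr = CriterionFractions(
            Fraction(5, 30), Fraction(0), Fraction(1, 30), Fraction(2, 30), 30
        )
        calls = [
            FishCall("S1", "positive", ("rreb1_gain",), fr),
            FishCall("S2", "negative", (), fr),
            FishCall("S3", "excluded", (), None),
        ]
        p = tmp_path / "calls.tsv"
        write_calls(calls, p)
        assert read_calls(p) == calls
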