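"""Record IO, reference panel fixture, criteria config and vehicle selection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import epi2sensa as e2
from epi2sensa import (
    GeneMarker,
    Role,
    TissueRecord,
    Vehicle,
    dilution_series,
    load_criteria,
    load_reference_panel,
    read_tissue_records,
    select_vehicle,
    write_tissue_records,
)
from epi2sensa.errors import (
    ConfigError,
    InsolubilityError,
    IntegrityError,
    RecordValueError,
    SchemaError,
)

from conftest import ct_map


def _sample_records():
    return [
        TissueRecord("lab1", "r1", "t1", Role.TEST, "CHEM", Vehicle.AOO,
                     12.5, 0.45, 0.05, None, ct_map({GeneMarker.ATF3: 4.0})),
        TissueRecord("lab1", "r1", "vc1", Role.VEHICLE, "", Vehicle.AOO,
                     0.0, 0.15, 0.05, None, ct_map()),
        TissueRecord("lab1", "r1", "kc1", Role.KILLED, "", Vehicle.AOO,
                     0.0, 1.15, 0.05, None, None),
    ]


@pytest.mark.parametrize("use_long_ct", [False, True])
def test_read_write_round_trip_is_identity(tmp_path, use_long_ct):
    records = _sample_records()
    path = tmp_path / "plates.csv"
    ct_path = tmp_path / "ct.csv" if use_long_ct else None
    write_tissue_records(records, path, ct_path)
    back = read_tissue_records(path, ct_path)
    assert back == records


def test_role_and_vehicle_tokens_are_case_insensitive(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "lab_id,run_id,tissue_id,role,chemical_code,vehicle,concentration,"
        "abs_490,abs_ref\n"
        "L,r1,t1,Killed,,aoo,0,1.2,0.05\n"
        "L,r1,t2,VC,,50% EtOH,0,0.15,0.05\n")
    recs = read_tissue_records(path)
    assert recs[0].role is Role.KILLED
    assert recs[1].role is Role.VEHICLE
    assert recs[1].vehicle is Vehicle.ETOH50


def test_unparseable_absorbance_names_row_and_column(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "lab_id,run_id,tissue_id,role,chemical_code,vehicle,concentration,"
        "abs_490,abs_ref\n"
        "L,r1,t1,vehicle,,AOO,0,NA,0.05\n")
    with pytest.raises(RecordValueError, match=r"row 1.*abs_490"):
        read_tissue_records(path)


def test_reader_error_cases(tmp_path):
    header = ("lab_id,run_id,tissue_id,role,chemical_code,vehicle,"
              "concentration,abs_490,abs_ref\n")
    p = tmp_path / "missing_col.csv"
    p.write_text("lab_id,run_id,tissue_id,role\nL,r,t,test\n")
    with pytest.raises(SchemaError, match="missing mandatory"):
        read_tissue_records(p)

    p = tmp_path / "bad_role.csv"
    p.write_text(header + "L,r1,t1,mystery,,AOO,0,0.1,0.05\n")
    with pytest.raises(RecordValueError, match="unknown role"):
        read_tissue_records(p)

    p = tmp_path / "dup.csv"
    p.write_text(header + "L,r1,t1,vehicle,,AOO,0,0.1,0.05\n"
                          "L,r1,t1,vehicle,,AOO,0,0.1,0.05\n")
    with pytest.raises(IntegrityError, match="duplicate"):
        read_tissue_records(p)


def test_record_invariants_enforced():
    with pytest.raises(RecordValueError):
        TissueRecord("l", "r", "t", Role.TEST, "C", Vehicle.AOO,
                     0.0, 0.1, 0.05)  # test tissue needs concentration > 0
    with pytest.raises(RecordValueError):
        TissueRecord("l", "r", "t", Role.KILLED, "", Vehicle.AOO,
                     0.0, 1.1, 0.05, ct={GeneMarker.GAPDH: 18.0})


class TestReferencePanel:
    def test_panel_composition(self):
        panel = load_reference_panel()
        assert len(panel) == 20
        assert sum(c.in_vivo_class == "sensitizer" for c in panel) == 14
        assert sum(c.pre_pro_hapten for c in panel) == 6

    def test_spot_check_against_independent_transcription(self):
        # A second, independently typed copy of a sample of panel cells.
        expected = {
            "97-00-7": (2.17, "1A", "positive", "positive"),
            "1166-52-5": (6.9, "1A", "negative", "negative"),
            "97-54-1": (3.04, "1B", "positive", "positive"),
            "84-66-2": (2.44, "not_classified", "positive", "negative"),
            "638-45-9": (3.99, "not_classified", "positive", "positive"),
            "57-09-0": (3.18, "not_classified", "negative", "negative"),
        }
        by_cas = {c.cas: c for c in load_reference_panel()}
        for cas, (logp, ghs, vrm, epi2) in expected.items():
            chem = by_cas[cas]
            assert chem.logp == pytest.approx(logp)
            assert chem.ghs_subcat == ghs
            assert chem.vrm_call == vrm
            assert chem.epi2sensa_call == epi2

    def test_vehicles_and_cetrimide_uses_ethanol(self):
        by_code = {c.code: c for c in load_reference_panel()}
        assert by_code["CET"].vehicle is Vehicle.ETOH50
        assert by_code["METOL"].vehicle is Vehicle.DW
        assert by_code["DNCB"].vehicle is Vehicle.AOO


class TestSelectVehicle:
    def test_all_soluble_at_top_prefers_aoo(self):
        screen = {(v, 50.0): True for v in Vehicle}
        assert select_vehicle(screen) == (Vehicle.AOO, 50.0)

    def test_highest_soluble_concentration_wins(self):
        screen = {}
        for conc in dilution_series():
            screen[(Vehicle.AOO, conc)] = conc <= 0.78125
            screen[(Vehicle.DW, conc)] = conc <= 12.5
            screen[(Vehicle.ETOH50, conc)] = conc <= 6.25
        assert select_vehicle(screen) == (Vehicle.DW, 12.5)

    def test_tie_broken_by_preference_order(self):
        screen = {}
        for conc in dilution_series():
            screen[(Vehicle.AOO, conc)] = conc <= 3.125
            screen[(Vehicle.DW, conc)] = conc <= 3.125
            screen[(Vehicle.ETOH50, conc)] = False
        assert select_vehicle(screen) == (Vehicle.AOO, 3.125)
        # cross-check the tie-break against exhaustive candidate enumeration:
        # among all (vehicle, conc) soluble pairs, the winner must have the
        # max conc and the earliest preference among max-conc vehicles
        soluble = [(v, c) for (v, c), ok in screen.items() if ok]
        cmax = max(c for _, c in soluble)
        order = list(e2.assay_model.VEHICLE_PREFERENCE)
        best = min((order.index(v) for v, c in soluble if c == cmax))
        assert select_vehicle(screen)[0] is order[best]

    def test_insoluble_everywhere_raises(self):
        screen = {(v, c): False for v in Vehicle for c in dilution_series()}
        with pytest.raises(InsolubilityError):
            select_vehicle(screen)

    @given(st.permutations(list(range(9))))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_entry_order(self, perm):
        items = [((v, c), (hash((v, c)) % 3 != 0))
                 for v in Vehicle for c in (50.0, 12.5, 0.78125)]
        shuffled = dict(items[i] for i in perm)
        baseline = dict(items)
        try:
            expected = select_vehicle(baseline)
        except InsolubilityError:
            with pytest.raises(InsolubilityError):
                select_vehicle(shuffled)
        else:
            assert select_vehicle(shuffled) == expected


def test_dilution_series_spans_50_down_to_0p0122():
    series = dilution_series()
    assert len(series) == 13
    assert series[0] == 50.0
    assert series[-1] == pytest.approx(0.0122, abs=1e-4)


class TestCriteriaConfig:
    def test_presets(self, vrm, epi2):
        assert vrm.min_active_genes == 1 and vrm.viability_threshold_pct == 80
        assert epi2.min_active_genes == 2 and epi2.viability_threshold_pct == 60
        for crit in (vrm, epi2):
            assert crit.gene_cutoffs[GeneMarker.ATF3] == 15
            assert crit.gene_cutoffs[GeneMarker.IL8] == 4
            assert GeneMarker.GAPDH not in crit.gene_cutoffs

    def test_yaml_overrides(self, tmp_path):
        cfg = tmp_path / "criteria.yaml"
        cfg.write_text(
            "base: Epi2SensA\nviability_threshold_pct: 70\n"
            "gene_cutoffs: {ATF3: 10}\n")
        crit = load_criteria(cfg)
        assert crit.viability_threshold_pct == 70
        assert crit.gene_cutoffs[GeneMarker.ATF3] == 10
        assert crit.gene_cutoffs[GeneMarker.GCLM] == 2  # untouched
        assert crit.min_active_genes == 2

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError):
            load_criteria({"base": "VRM", "not_a_field": 1})
        with pytest.raises(ConfigError):
            load_criteria({"viability_threshold_pct": 70})  # no base
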