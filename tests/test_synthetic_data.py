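"""Simulator contracts: determinism, ground-truth recovery, scenario behavior."""

import statistics

import pytest

from epi2sensa import (
    Call,
    ChemicalProfile,
    EPI2SENSA_CRITERIA,
    GENE_CUTOFFS,
    GeneMarker,
    MARKER_GENES,
    Role,
    SimulationConfig,
    VRM_CRITERIA,
    default_panel_profiles,
    evaluate_study,
    scenario_specificity_gain,
    simulate_dose_finding,
    simulate_study,
    evaluate_dose_finding,
    per_tissue_viability,
)
from epi2sensa.errors import ConfigError

NOISELESS = dict(ct_noise_sd=0.0, lab_fold_bias_sd=0.0, abs_noise_sd=0.0,
                 gapdh_ct_sd=0.0)


def _calls_by_chemical(records, criteria):
    return {ev.chemical_code: ev.call
            for ev in evaluate_study(records, criteria)}


class TestDeterminism:
    def test_same_seed_is_identical(self):
        profiles = default_panel_profiles(2, 1)
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=11)
        assert simulate_study(profiles, cfg) == simulate_study(profiles, cfg)

    def test_different_seed_differs(self):
        profiles = default_panel_profiles(2, 1)
        a = simulate_study(profiles, SimulationConfig(n_labs=1, seed=1))
        b = simulate_study(profiles, SimulationConfig(n_labs=1, seed=2))
        assert a != b


class TestNoiselessConstruction:
    def test_sensitizer_profile_called_sensitizer_every_run(self):
        profiles = default_panel_profiles(4, 0)
        cfg = SimulationConfig(n_labs=2, runs_per_chemical=2, seed=0,
                               **NOISELESS)
        calls = [ev.call for ev in
                 evaluate_study(simulate_study(profiles, cfg),
                                EPI2SENSA_CRITERIA)]
        assert all(c is Call.SENSITIZER for c in calls)

    def test_non_sensitizer_profile_called_negative_every_run(self):
        profiles = default_panel_profiles(0, 4)
        cfg = SimulationConfig(n_labs=2, runs_per_chemical=2, seed=0,
                               **NOISELESS)
        calls = [ev.call for ev in
                 evaluate_study(simulate_study(profiles, cfg),
                                EPI2SENSA_CRITERIA)]
        assert all(c is Call.NON_SENSITIZER for c in calls)

    def test_full_panel_recovery(self):
        profiles = default_panel_profiles()
        truth = {p.code: p.truth for p in profiles}
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=3,
                               **NOISELESS)
        calls = _calls_by_chemical(simulate_study(profiles, cfg),
                                   EPI2SENSA_CRITERIA)
        assert all(calls[c].value == truth[c] for c in truth)


class TestPlateStructure:
    def test_run_contains_all_roles_and_killed_has_no_ct(self):
        profiles = default_panel_profiles(1, 0)
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=5)
        records = simulate_study(profiles, cfg)
        roles = {r.role for r in records}
        assert roles == {Role.TEST, Role.VEHICLE, Role.PC_CLOTRIMAZOLE,
                         Role.PC_4NBB, Role.KILLED}
        assert all(r.ct is None for r in records if r.role is Role.KILLED)
        assert all(r.ct for r in records if r.role is not Role.KILLED)

    def test_killed_exceeds_vehicle_and_vehicle_meets_95(self):
        profiles = default_panel_profiles(1, 1)
        cfg = SimulationConfig(n_labs=2, runs_per_chemical=3, seed=9)
        records = simulate_study(profiles, cfg)
        by_run = {}
        for r in records:
            by_run.setdefault(r.run_id, []).append(r)
        pass_rates = []
        for run in by_run.values():
            vc = [r.delta_abs for r in run if r.role is Role.VEHICLE]
            kc = [r.delta_abs for r in run if r.role is Role.KILLED]
            assert statistics.fmean(kc) > statistics.fmean(vc)
            vias = [v.viability_pct for v in per_tissue_viability(run)
                    if v.tissue_id.split("-")[-1].startswith("vc")]
            pass_rates.append(sum(v >= 95 for v in vias) >= 2)
        assert statistics.fmean(pass_rates) >= 0.95

    def test_pc_fail_invalidates_runs(self):
        profiles = default_panel_profiles(1, 0)
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=5,
                               pc_fail=True)
        evs = evaluate_study(simulate_study(profiles, cfg), EPI2SENSA_CRITERIA)
        assert all(ev.call is Call.INVALID_RUN for ev in evs)


class TestDoseFinding:
    def test_duplicates_and_no_ct(self):
        profile = default_panel_profiles(1, 0)[0]
        cfg = SimulationConfig(seed=2)
        records = simulate_dose_finding(profile, cfg)
        test = [r for r in records if r.role is Role.TEST]
        assert all(r.ct is None for r in records)
        per_conc = {c: sum(r.concentration == c for r in test)
                    for c in cfg.dose_finding_doses}
        assert all(n == 2 for n in per_conc.values())

    def test_cytotoxic_profile_fails_dose_finding(self):
        profile = ChemicalProfile(
            code="TOX", truth="non_sensitizer", ic50=0.1, hill=2.0,
            gene_emax={g: 0.1 for g in MARKER_GENES},
            gene_ec50={g: 5.0 for g in MARKER_GENES})
        cfg = SimulationConfig(seed=2, **NOISELESS)
        records = simulate_dose_finding(profile, cfg)
        vias = {}
        full = per_tissue_viability(records)
        for r in records:
            if r.role is Role.TEST:
                v = next(x for x in full if x.tissue_id == r.tissue_id)
                vias.setdefault(r.concentration, []).append(v.viability_pct)
        result = evaluate_dose_finding(vias, EPI2SENSA_CRITERIA)
        assert not result.valid


class TestProfileValidation:
    def test_sensitizer_needs_two_strong_markers(self):
        with pytest.raises(ConfigError):
            ChemicalProfile(
                code="X", truth="sensitizer", ic50=40, hill=2,
                gene_emax={GeneMarker.ATF3: 60.0},
                gene_ec50={g: 5.0 for g in MARKER_GENES})

    def test_non_sensitizer_must_stay_below_cutoffs(self):
        with pytest.raises(ConfigError):
            ChemicalProfile(
                code="X", truth="non_sensitizer", ic50=40, hill=2,
                gene_emax={GeneMarker.GCLM: 10.0, GeneMarker.DNAJB4: 10.0},
                gene_ec50={g: 5.0 for g in MARKER_GENES})

    def test_bad_doses_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(doses=(60.0,))
        with pytest.raises(ConfigError):
            SimulationConfig(doses=(0.0,))
        with pytest.raises(ConfigError):
            SimulationConfig(killed_delta_abs=0.1, vc_delta_abs=0.2)


class TestSpecificityGainScenario:
    def test_spurious_prob_one_noiseless_separates_rules(self):
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=4,
                               **NOISELESS)
        _, records = scenario_specificity_gain(
            cfg, n_non_sensitizers=8, spurious_single_gene_prob=1.0)
        one_gene = _calls_by_chemical(records, VRM_CRITERIA)
        two_gene = _calls_by_chemical(records, EPI2SENSA_CRITERIA)
        assert all(c is Call.SENSITIZER for c in one_gene.values())
        assert all(c is Call.NON_SENSITIZER for c in two_gene.values())

    def test_spurious_prob_zero_gives_identical_specificity(self):
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=4,
                               **NOISELESS)
        _, records = scenario_specificity_gain(
            cfg, n_non_sensitizers=8, spurious_single_gene_prob=0.0)
        one_gene = _calls_by_chemical(records, VRM_CRITERIA)
        two_gene = _calls_by_chemical(records, EPI2SENSA_CRITERIA)
        assert one_gene == two_gene

    def test_single_spurious_run_activates_exactly_one_gene(self):
        cfg = SimulationConfig(n_labs=1, runs_per_chemical=1, seed=4,
                               **NOISELESS)
        _, records = scenario_specificity_gain(
            cfg, n_non_sensitizers=5, spurious_single_gene_prob=1.0)
        for ev in evaluate_study(records, VRM_CRITERIA):
            active = [g for g in MARKER_GENES
                      if ev.imax.get(g, 0) > GENE_CUTOFFS[g]]
            assert len(active) == 1
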