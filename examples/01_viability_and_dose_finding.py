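"""Dose-range finding: LDH viability against killed controls, dose selection.

Builds a small dose-finding experiment for a moderately cytotoxic chemical,
computes per-tissue viability with the killed-control formula, and selects
the main-study concentrations.
"""

from epi2sensa import (
    EPI2SENSA_CRITERIA,
    SimulationConfig,
    compute_viability,
    default_panel_profiles,
    evaluate_dose_finding,
    per_tissue_viability,
    simulate_dose_finding,
    Role,
)

# The viability formula on one hand-picked tissue: a test tissue releasing a
# quarter of the killed-control LDH (above vehicle baseline) is 75% viable.
v = compute_viability(0.35, delta_abs_vehicle=0.10, mean_delta_abs_killed=1.10)
print(f"single tissue viability: {v:.1f}%   (dAbs 0.35 vs vc 0.10, killed 1.10)")

# A simulated dose-finding run: duplicate tissues at six 2-fold doses.
profile = default_panel_profiles(1, 0)[0]
records = simulate_dose_finding(profile, SimulationConfig(seed=7))
viability = {x.tissue_id: x.viability_pct for x in per_tissue_viability(records)}

per_conc: dict[float, list[float]] = {}
for r in records:
    if r.role is Role.TEST:
        per_conc.setdefault(r.concentration, []).append(viability[r.tissue_id])

result = evaluate_dose_finding(per_conc, EPI2SENSA_CRITERIA,
                               chemical_code=profile.code)
print(f"\ndose finding for {profile.code} (cytotoxicity IC50 "
      f"{profile.ic50:g}%, threshold "
      f"{EPI2SENSA_CRITERIA.viability_threshold_pct:g}%):")
for conc in sorted(result.per_concentration, reverse=True):
    print(f"  {conc:8.4f}%  mean viability {result.per_concentration[conc]:6.1f}%")
print(f"valid: {result.valid};  main-study doses (highest passing + 3 lower): "
      f"{[f'{c:g}%' for c in result.selected_doses]}")
# The top selected dose is the highest concentration keeping mean viability
# at or above the threshold; lower doses complete the 4-point exposure series.
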