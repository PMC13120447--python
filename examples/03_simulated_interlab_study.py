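"""A full synthetic interlaboratory study: simulate, classify, validate.

Simulates three laboratories testing a 20-chemical panel (14 sensitizers,
6 non-sensitizers) in triplicate runs, evaluates every run under the
modified criteria, aggregates run calls by mode, and reports WLR, BLR and
predictivity against the known ground truth.
"""

import pandas as pd

from epi2sensa import (
    EPI2SENSA_CRITERIA,
    ReferenceChemical,
    SimulationConfig,
    Vehicle,
    default_panel_profiles,
    evaluate_study,
    run_calls_frame,
    simulate_study,
    study_metrics_from_calls,
    ps_report,
)

profiles = default_panel_profiles(spurious_single_gene_prob=0.25)
config = SimulationConfig(n_labs=3, runs_per_chemical=3,
                          ct_noise_sd=0.4, lab_fold_bias_sd=0.4, seed=2026)
records = simulate_study(profiles, config)
print(f"simulated {len(records)} tissue records "
      f"({config.n_labs} labs x {len(profiles)} chemicals x "
      f"{config.runs_per_chemical} runs)")

evaluations = evaluate_study(records, EPI2SENSA_CRITERIA)
calls = run_calls_frame(evaluations)
calls["run_index"] = calls.groupby(["lab_id", "chemical_code"]).cumcount() + 1

# ground truth plays the role of the in vivo reference classification
panel = [
    ReferenceChemical(
        code=p.code, name=p.code, cas="-", logp=0.0, pre_pro_hapten=False,
        in_vivo_class=p.truth,
        ghs_subcat="1B" if p.truth == "sensitizer" else "not_classified",
        vehicle=Vehicle.AOO, vrm_call="", epi2sensa_call="")
    for p in profiles
]
metrics = study_metrics_from_calls(calls, panel, "Epi2SensA")

print(f"\nWLR per lab: "
      f"{ {k: f'{100 * v:.1f}%' for k, v in sorted(metrics.wlr_per_lab.items())} }")
print(f"WLR average: {100 * metrics.wlr_average:.1f}%   "
      f"BLR: {100 * metrics.blr:.1f}%")
print(f"sensitivity {metrics.sensitivity_avg:.1f}%  "
      f"specificity {metrics.specificity_avg:.1f}%  "
      f"accuracy {metrics.accuracy_avg:.1f}%")

print("\nperformance-standards verdict:")
with pd.option_context("display.width", 100):
    print(ps_report(metrics).to_string(index=False))
# At these noise levels (elevated qPCR noise, per-lab fold bias, and a 25%
# chance of a spurious single-gene activation in non-sensitizer runs) the
# study loses some within-lab concordance and specificity while sensitivity
# stays at 100% — the same degradation pattern interlaboratory studies show,
# and the reason the two-gene rule exists: under the one-gene rule every
# spurious activation would become a false positive.
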