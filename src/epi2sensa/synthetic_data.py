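"""Synthetic multi-lab assay datasets with known ground truth.

No raw absorbance/Ct data from the validation study are published, so the
generator builds complete plates — vehicle controls, the two positive
controls (clotrimazole and 4-nitrobenzyl bromide), killed controls, and dose
series — whose statistical structure matches what the pipeline assumes:

* cytotoxicity follows a Hill curve, ``v(c) = 100 / (1 + (c/ic50)^hill)``,
  and the LDH delta-absorbance is back-computed from it between the vehicle
  and killed-control anchors, plus Gaussian absorbance noise;
* marker-gene induction follows ``fold(c) = 1 + emax * c^h / (c^h + ec50^h)``
  with Gaussian noise in Ct space (hence lognormal on folds, matching qPCR
  error structure) and a per-(lab, gene) multiplicative bias that is the
  minimal mechanism able to produce between-laboratory discordance;
* Ct values are synthesized around a GAPDH baseline; cytotoxic doses shift
  the GAPDH Ct upward (transcriptional shutdown), which is what the GAPDH
  drift check exists to catch;
* killed tissues carry no Ct values, and positive controls are generated to
  pass run acceptance (or to fail it, on request).

An optional *spurious single-gene* mechanism activates exactly one randomly
chosen marker in a non-sensitizer run — the failure mode that motivates the
two-gene prediction rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .assay_model import (
    GENE_CUTOFFS,
    GeneMarker,
    MARKER_GENES,
    PC_4NBB_CONC,
    PC_CLOTRIMAZOLE_CONC,
    Role,
    TissueRecord,
    Vehicle,
)
from .errors import ConfigError

#: Marker Ct offsets relative to GAPDH in unstimulated tissue (cycles).
_BASELINE_CT_OFFSET: dict[GeneMarker, float] = {
    GeneMarker.ATF3: 7.0,
    GeneMarker.GCLM: 5.0,
    GeneMarker.DNAJB4: 6.0,
    GeneMarker.IL8: 8.0,
}

#: Noise-free mean folds of the positive controls (clotrimazole drives
#: ATF3/IL-8, 4-NBB drives GCLM/DNAJB4), comfortably above/below cut-offs.
_PC_FOLDS = {
    Role.PC_CLOTRIMAZOLE: {GeneMarker.ATF3: 25.0, GeneMarker.IL8: 8.0,
                           GeneMarker.GCLM: 1.5, GeneMarker.DNAJB4: 1.5},
    Role.PC_4NBB: {GeneMarker.ATF3: 2.0, GeneMarker.IL8: 1.5,
                   GeneMarker.GCLM: 6.0, GeneMarker.DNAJB4: 6.0},
}
_PC_FAIL_FOLDS = {
    Role.PC_CLOTRIMAZOLE: {g: 1.2 for g in MARKER_GENES},
    Role.PC_4NBB: {g: 1.2 for g in MARKER_GENES},
}
_PC_VIABILITY = {Role.PC_CLOTRIMAZOLE: 92.0, Role.PC_4NBB: 88.0}
_PC_CONC = {Role.PC_CLOTRIMAZOLE: PC_CLOTRIMAZOLE_CONC,
            Role.PC_4NBB: PC_4NBB_CONC}


@dataclass(frozen=True)
class ChemicalProfile:
    """Ground-truth dose-response parameters for one simulated chemical.

    ``ic50`` is the cytotoxicity midpoint (percent concentration at 50%
    viability) with Hill slope ``hill``; ``gene_emax``/``gene_ec50``
    parameterize each marker's induction plateau (plateau fold = 1 + emax)
    and half-maximal concentration.  ``spurious_single_gene_prob`` is the
    per-run probability that one randomly chosen marker is driven above its
    cut-off regardless of ``truth`` (non-specific stress response).
    """

    code: str
    truth: str  # "sensitizer" | "non_sensitizer"
    ic50: float
    hill: float
    gene_emax: Mapping[GeneMarker, float]
    gene_ec50: Mapping[GeneMarker, float]
    gene_hill: float = 2.0
    spurious_single_gene_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.hill <= 0 or self.gene_hill <= 0 or self.ic50 <= 0:
            raise ConfigError(f"{self.code}: Hill parameters must be positive")
        above = sum(1 for g in MARKER_GENES
                    if self.gene_emax.get(g, 0.0) > GENE_CUTOFFS[g])
        if self.truth == "sensitizer" and above < 2:
            raise ConfigError(
                f"{self.code}: a sensitizer profile needs >=2 marker plateaus "
                f"above cut-off, got {above}")
        if self.truth == "non_sensitizer" and above != 0:
            raise ConfigError(
                f"{self.code}: a non-sensitizer profile must keep all marker "
                f"plateaus below cut-off (spurious mechanism excepted)")

    def viability(self, conc: float) -> float:
        return 100.0 / (1.0 + (conc / self.ic50) ** self.hill)

    def fold(self, gene: GeneMarker, conc: float) -> float:
        emax = self.gene_emax.get(gene, 0.0)
        ec50 = self.gene_ec50.get(gene, 5.0)
        ch = conc ** self.gene_hill
        return 1.0 + emax * ch / (ch + ec50 ** self.gene_hill)


@dataclass(frozen=True)
class SimulationConfig:
    """Study layout and noise model; the seed fully determines the output.

    Defaults mirror the interlaboratory study design: three full-panel
    laboratories, three runs per chemical (the repeat-testing used for WLR),
    triplicate main-study tissues and a four-dose 2-fold exposure series.
    """

    n_labs: int = 3
    runs_per_chemical: int = 3
    doses: tuple[float, ...] = (25.0, 12.5, 6.25, 3.125)
    dose_finding_doses: tuple[float, ...] = (50.0, 25.0, 12.5, 6.25, 3.125, 1.5625)
    n_test_tissues: int = 3
    n_vehicle_tissues: int = 3
    n_pc_tissues: int = 3
    n_killed_tissues: int = 3
    ct_noise_sd: float = 0.15           # per-well Ct replicate noise (cycles)
    lab_fold_bias_sd: float = 0.25      # per-(lab, gene) bias, log2 units
    abs_noise_sd: float = 0.02          # absorbance noise on delta-abs
    gapdh_ct_mean: float = 18.0
    gapdh_ct_sd: float = 0.3
    gapdh_cytotox_shift: float = 2.0    # GAPDH Ct shift at 0% viability
    vc_delta_abs: float = 0.12          # spontaneous LDH release
    killed_delta_abs: float = 1.20      # full-lysis LDH release
    abs_ref_baseline: float = 0.05
    vehicle: Vehicle = Vehicle.AOO
    pc_fail: bool = False               # generate positive controls that fail
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0 or self.abs_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        for d in tuple(self.doses) + tuple(self.dose_finding_doses):
            if not 0 < d <= 50:
                raise ConfigError(f"dose {d} outside (0, 50] percent")
        if self.killed_delta_abs <= self.vc_delta_abs:
            raise ConfigError("killed-control delta-abs must exceed vehicle's")


def _lab_ids(config: SimulationConfig) -> list[str]:
    return [f"lab{i + 1}" for i in range(config.n_labs)]


def _control_tissues(
    rng: np.random.Generator,
    config: SimulationConfig,
    lab: str,
    run_id: str,
    lab_bias: Mapping[tuple[str, GeneMarker], float],
) -> list[TissueRecord]:
    """Vehicle, positive-control and killed tissues for one run."""
    records: list[TissueRecord] = []
    for i in range(config.n_vehicle_tissues):
        delta = config.vc_delta_abs + rng.normal(0, config.abs_noise_sd)
        records.append(TissueRecord(
            lab_id=lab, run_id=run_id, tissue_id=f"{run_id}-vc{i + 1}",
            role=Role.VEHICLE, vehicle=config.vehicle,
            abs_490=config.abs_ref_baseline + delta,
            abs_ref=config.abs_ref_baseline,
            ct=_draw_cts(rng, config, fold_log2={}, viability=100.0)))
    pc_folds = _PC_FAIL_FOLDS if config.pc_fail else _PC_FOLDS
    for role in (Role.PC_CLOTRIMAZOLE, Role.PC_4NBB):
        v = _PC_VIABILITY[role]
        for i in range(config.n_pc_tissues):
            delta = (config.vc_delta_abs
                     + (1 - v / 100) * (config.killed_delta_abs - config.vc_delta_abs)
                     + rng.normal(0, config.abs_noise_sd))
            fold_log2 = {g: math.log2(f) + lab_bias[(lab, g)]
                         for g, f in pc_folds[role].items()}
            records.append(TissueRecord(
                lab_id=lab, run_id=run_id,
                tissue_id=f"{run_id}-{role.value}{i + 1}",
                role=role, vehicle=config.vehicle,
                concentration=_PC_CONC[role],
                abs_490=config.abs_ref_baseline + delta,
                abs_ref=config.abs_ref_baseline,
                ct=_draw_cts(rng, config, fold_log2=fold_log2, viability=v)))
    for i in range(config.n_killed_tissues):
        delta = config.killed_delta_abs + rng.normal(0, config.abs_noise_sd)
        records.append(TissueRecord(
            lab_id=lab, run_id=run_id, tissue_id=f"{run_id}-kc{i + 1}",
            role=Role.KILLED, vehicle=config.vehicle,
            abs_490=config.abs_ref_baseline + delta,
            abs_ref=config.abs_ref_baseline, ct=None))
    return records


def _draw_cts(
    rng: np.random.Generator,
    config: SimulationConfig,
    fold_log2: Mapping[GeneMarker, float],
    viability: float,
) -> dict[GeneMarker, float]:
    """Ct values of one tissue given its true log2 fold inductions."""
    shift = config.gapdh_cytotox_shift * min(1.0, max(0.0, 1.0 - viability / 100.0))
    gapdh = config.gapdh_ct_mean + shift + rng.normal(0, config.gapdh_ct_sd)
    cts = {GeneMarker.GAPDH: gapdh}
    for gene in MARKER_GENES:
        cts[gene] = (gapdh + _BASELINE_CT_OFFSET[gene]
                     - fold_log2.get(gene, 0.0)
                     + rng.normal(0, config.ct_noise_sd))
    return cts


def simulate_study(
    profiles: Sequence[ChemicalProfile],
    config: SimulationConfig,
) -> list[TissueRecord]:
    """Simulate the main study: every lab tests every chemical in repeat runs.

    Each run is self-contained (its own vehicle, positive-control and killed
    tissues) with triplicate test tissues at each configured dose.  One seeded
    generator drives the whole simulation; the same seed reproduces the same
    records exactly.
    """
    rng = np.random.default_rng(config.seed)
    labs = _lab_ids(config)
    lab_bias = {(lab, g): rng.normal(0, config.lab_fold_bias_sd)
                for lab in labs for g in MARKER_GENES}
    records: list[TissueRecord] = []
    for lab in labs:
        for profile in profiles:
            for k in range(config.runs_per_chemical):
                run_id = f"{lab}-{profile.code}-r{k + 1}"
                records.extend(_control_tissues(rng, config, lab, run_id, lab_bias))
                spurious_gene: GeneMarker | None = None
                if (profile.spurious_single_gene_prob > 0
                        and rng.random() < profile.spurious_single_gene_prob):
                    spurious_gene = MARKER_GENES[rng.integers(len(MARKER_GENES))]
                for conc in config.doses:
                    v = profile.viability(conc)
                    for i in range(config.n_test_tissues):
                        delta = (config.vc_delta_abs
                                 + (1 - v / 100)
                                 * (config.killed_delta_abs - config.vc_delta_abs)
                                 + rng.normal(0, config.abs_noise_sd))
                        fold_log2 = {}
                        for gene in MARKER_GENES:
                            f = profile.fold(gene, conc)
                            if gene is spurious_gene:
                                f = max(f, 2.5 * GENE_CUTOFFS[gene])
                            fold_log2[gene] = (math.log2(f)
                                               + lab_bias[(lab, gene)])
                        records.append(TissueRecord(
                            lab_id=lab, run_id=run_id,
                            tissue_id=f"{run_id}-{profile.code}-c{conc:g}-t{i + 1}",
                            role=Role.TEST, chemical_code=profile.code,
                            vehicle=config.vehicle, concentration=conc,
                            abs_490=config.abs_ref_baseline + delta,
                            abs_ref=config.abs_ref_baseline,
                            ct=_draw_cts(rng, config, fold_log2, v)))
    return records


def simulate_dose_finding(
    profile: ChemicalProfile,
    config: SimulationConfig,
    lab_id: str = "lab1",
) -> list[TissueRecord]:
    """Simulate a dose-range-finding run: duplicate tissues, up to six doses.

    Dose-finding tissues carry no Ct values — only the LDH readout is used.
    """
    rng = np.random.default_rng(config.seed)
    run_id = f"{lab_id}-{profile.code}-df"
    records: list[TissueRecord] = []
    for i in range(config.n_vehicle_tissues):
        delta = config.vc_delta_abs + rng.normal(0, config.abs_noise_sd)
        records.append(TissueRecord(
            lab_id=lab_id, run_id=run_id, tissue_id=f"{run_id}-vc{i + 1}",
            role=Role.VEHICLE, vehicle=config.vehicle,
            abs_490=config.abs_ref_baseline + delta,
            abs_ref=config.abs_ref_baseline))
    for i in range(config.n_killed_tissues):
        delta = config.killed_delta_abs + rng.normal(0, config.abs_noise_sd)
        records.append(TissueRecord(
            lab_id=lab_id, run_id=run_id, tissue_id=f"{run_id}-kc{i + 1}",
            role=Role.KILLED, vehicle=config.vehicle,
            abs_490=config.abs_ref_baseline + delta,
            abs_ref=config.abs_ref_baseline))
    for conc in config.dose_finding_doses:
        v = profile.viability(conc)
        for i in range(2):  # duplicate tissues
            delta = (config.vc_delta_abs
                     + (1 - v / 100) * (config.killed_delta_abs - config.vc_delta_abs)
                     + rng.normal(0, config.abs_noise_sd))
            records.append(TissueRecord(
                lab_id=lab_id, run_id=run_id,
                tissue_id=f"{run_id}-c{conc:g}-t{i + 1}",
                role=Role.TEST, chemical_code=profile.code,
                vehicle=config.vehicle, concentration=conc,
                abs_490=config.abs_ref_baseline + delta,
                abs_ref=config.abs_ref_baseline))
    return records


# Marker combinations cycled over simulated sensitizers, so the panel covers
# inflammatory (ATF3/IL-8), cytoprotective (GCLM/DNAJB4) and mixed responders.
_SENS_GENE_COMBOS: tuple[tuple[GeneMarker, ...], ...] = (
    (GeneMarker.GCLM, GeneMarker.DNAJB4),
    (GeneMarker.ATF3, GeneMarker.IL8),
    (GeneMarker.GCLM, GeneMarker.IL8),
    (GeneMarker.ATF3, GeneMarker.GCLM, GeneMarker.DNAJB4, GeneMarker.IL8),
)


def default_panel_profiles(
    n_sensitizers: int = 14,
    n_non_sensitizers: int = 6,
    spurious_single_gene_prob: float = 0.0,
) -> list[ChemicalProfile]:
    """A reference-panel-shaped set of profiles (14 sensitizers + 6 non).

    Sensitizers induce a cycling combination of markers with plateau folds at
    four times their cut-offs and sub-cytotoxic EC50s; non-sensitizers keep
    every plateau at a quarter of the cut-off.  ``spurious_single_gene_prob``
    is applied to the non-sensitizers only.
    """
    profiles: list[ChemicalProfile] = []
    for i in range(n_sensitizers):
        active = _SENS_GENE_COMBOS[i % len(_SENS_GENE_COMBOS)]
        emax = {g: (4.0 * GENE_CUTOFFS[g] if g in active
                    else 0.25 * GENE_CUTOFFS[g]) for g in MARKER_GENES}
        profiles.append(ChemicalProfile(
            code=f"SENS{i + 1:02d}", truth="sensitizer",
            ic50=40.0, hill=2.0, gene_emax=emax,
            gene_ec50={g: 5.0 for g in MARKER_GENES}))
    for i in range(n_non_sensitizers):
        emax = {g: 0.25 * GENE_CUTOFFS[g] for g in MARKER_GENES}
        profiles.append(ChemicalProfile(
            code=f"NONS{i + 1:02d}", truth="non_sensitizer",
            ic50=40.0, hill=2.0, gene_emax=emax,
            gene_ec50={g: 5.0 for g in MARKER_GENES},
            spurious_single_gene_prob=spurious_single_gene_prob))
    return profiles


def scenario_specificity_gain(
    config: SimulationConfig,
    n_non_sensitizers: int = 20,
    spurious_single_gene_prob: float = 0.5,
) -> tuple[list[ChemicalProfile], list[TissueRecord]]:
    """A non-sensitizer panel on which the one-gene rule false-positives.

    Each run has probability ``spurious_single_gene_prob`` of activating
    exactly one marker, so in expectation the one-gene (VRM) prediction rule
    produces strictly more false positives than the two-gene rule on the
    returned records.
    """
    profiles = default_panel_profiles(
        n_sensitizers=0, n_non_sensitizers=n_non_sensitizers,
        spurious_single_gene_prob=spurious_single_gene_prob)
    return profiles, simulate_study(profiles, config)
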