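"""LDH-based tissue viability, dose-finding validity and main-study dose selection.

Viability is inferred from LDH leakage into the basolateral medium: the
vehicle control fixes the spontaneous-release baseline (100% viability) and
the fully lysed *killed control* fixes maximal release (0% viability).  A test
tissue's viability is the linear interpolation between the two:

    viability % = 100 - (dAbs_test - dAbs_vc) / (mean dAbs_killed - dAbs_vc) * 100

where dAbs is the 490 nm absorbance minus the >=650 nm reference reading.
Values are deliberately not clamped: noise can push them slightly above 100%
or below 0%, and the acceptance rules are plain >= comparisons.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .assay_model import CriteriaSet, Role, TissueRecord
from .errors import DegenerateKilledControlError, MissingReferenceError

#: Viability above this is reported as suspicious in QC output (not fatal).
SUSPICIOUS_VIABILITY_PCT = 110.0


@dataclass(frozen=True)
class ViabilityResult:
    """Per-tissue viability with the method that produced it.

    ``method`` is ``"LDH"`` for the killed-control formula or
    ``"MTT_supplied"`` when an externally measured MTT viability was passed
    through verbatim (chemicals that interfere with the LDH readout).
    """

    tissue_id: str
    delta_abs: float
    viability_pct: float
    method: str  # "LDH" | "MTT_supplied"

    @property
    def suspicious(self) -> bool:
        return self.viability_pct > SUSPICIOUS_VIABILITY_PCT


@dataclass(frozen=True)
class DoseFindingResult:
    """Outcome of a dose-range-finding experiment for one chemical.

    ``valid`` requires at least one tested concentration with mean viability
    at or above the criteria threshold; ``selected_doses`` are the main-study
    concentrations (highest passing dose plus up to three lower tested doses,
    highest first).
    """

    chemical_code: str
    per_concentration: Mapping[float, float]
    valid: bool
    selected_doses: tuple[float, ...]


def compute_viability(
    delta_abs_test: float,
    delta_abs_vehicle: float,
    mean_delta_abs_killed: float,
) -> float:
    """Percent viability of one tissue from the LDH killed-control formula.

    Raises
    ------
    DegenerateKilledControlError
        If the killed-control mean does not strictly exceed the vehicle
        reference — the lysis failed and no denominator exists.
    """
    denom = mean_delta_abs_killed - delta_abs_vehicle
    if denom <= 0:
        raise DegenerateKilledControlError(
            f"killed-control dAbs ({mean_delta_abs_killed:.4g}) must strictly "
            f"exceed vehicle dAbs ({delta_abs_vehicle:.4g}); lysis may have failed")
    return 100.0 - (delta_abs_test - delta_abs_vehicle) / denom * 100.0


def per_tissue_viability(records: Sequence[TissueRecord]) -> list[ViabilityResult]:
    """Viability of every non-killed tissue in one run.

    The vehicle reference is the mean delta-absorbance over the run's vehicle
    tissues and the killed reference the mean over its killed tissues, so
    individual vehicle tissues can score below 100% (and trip the >=95%
    run-acceptance rule) while their average is exactly 100%.  Tissues with a
    supplied MTT viability bypass the LDH formula entirely.
    """
    vehicle = [r for r in records if r.role is Role.VEHICLE]
    killed = [r for r in records if r.role is Role.KILLED]
    ldh_needed = [r for r in records
                  if r.role is not Role.KILLED and r.mtt_viability_pct is None]
    if ldh_needed:
        if not killed:
            raise MissingReferenceError(
                "run has no killed-control tissues and no supplied MTT viability")
        if not vehicle:
            raise MissingReferenceError("run has no vehicle-control tissues")
    results: list[ViabilityResult] = []
    if killed and vehicle:
        vc_mean = statistics.fmean(r.delta_abs for r in vehicle)
        killed_mean = statistics.fmean(r.delta_abs for r in killed)
    for r in records:
        if r.role is Role.KILLED:
            continue
        if r.mtt_viability_pct is not None:
            results.append(ViabilityResult(
                r.tissue_id, r.delta_abs, r.mtt_viability_pct, "MTT_supplied"))
        else:
            results.append(ViabilityResult(
                r.tissue_id, r.delta_abs,
                compute_viability(r.delta_abs, vc_mean, killed_mean), "LDH"))
    return results


def evaluate_dose_finding(
    results: Mapping[float, Sequence[float]],
    criteria: CriteriaSet,
    chemical_code: str = "",
    max_selected: int = 4,
) -> DoseFindingResult:
    """Judge a dose-finding run and pick the main-study concentrations.

    ``results`` maps tested concentration to the viabilities of its duplicate
    tissues (aggregated by arithmetic mean, no outlier rejection).  The run is
    valid iff at least one concentration's mean viability reaches
    ``criteria.viability_threshold_pct``; the selected doses are the highest
    such concentration plus the next lower tested concentrations, up to
    ``max_selected`` in total, highest first.
    """
    if not results:
        raise ValueError("dose-finding input is empty")
    if any(len(v) == 0 for v in results.values()):
        raise ValueError("every concentration needs at least one viability value")
    means = {conc: statistics.fmean(v) for conc, v in results.items()}
    concs_desc = sorted(means, reverse=True)
    top = next((c for c in concs_desc
                if means[c] >= criteria.viability_threshold_pct), None)
    if top is None:
        return DoseFindingResult(chemical_code, means, False, ())
    start = concs_desc.index(top)
    selected = tuple(concs_desc[start:start + max_selected])
    return DoseFindingResult(chemical_code, means, True, selected)
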