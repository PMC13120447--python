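"""Run validity, concentration acceptance, gene activation and the prediction model.

A main-study run is judged in four stages:

1. *Run validity* — four acceptance criteria on the controls: at least two
   vehicle tissues at >=95% viability; both positive controls at >=80% mean
   viability; clotrimazole inducing ATF3 and IL-8 above their cut-offs; and
   4-nitrobenzyl bromide inducing GCLM and DNAJB4 above theirs.  An invalid
   run yields no chemical call.
2. *Concentration acceptance* — a tested concentration enters the prediction
   only if its mean viability reaches the criteria threshold (80% VRM / 60%
   modified) AND its mean GAPDH Ct is within +/-1 cycle of the vehicle control.
3. *Gene activation* — per gene, Imax is the maximum mean fold induction over
   the accepted concentrations; a gene is active when Imax strictly exceeds
   its cut-off (ATF3 > 15, GCLM > 2, DNAJB4 > 2, IL-8 > 4).  Activation is
   judged on Imax across all accepted concentrations, so two genes need not
   peak at the same concentration.
4. *Prediction* — sensitizer iff at least ``min_active_genes`` genes are
   active (1 for the VRM rule, 2 for the modified rule).  A valid run in
   which no concentration was accepted yields the distinct outcome
   ``no_accepted_concentration`` rather than a forced negative.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd

from .assay_model import CriteriaSet, GeneMarker, MARKER_GENES, Role, TissueRecord
from .errors import StructuralRunError
from .expression import FoldInduction, fold_induction
from .viability import per_tissue_viability


class Call(str, enum.Enum):
    SENSITIZER = "sensitizer"
    NON_SENSITIZER = "non_sensitizer"
    NO_ACCEPTED_CONCENTRATION = "no_accepted_concentration"
    INVALID_RUN = "invalid_run"


@dataclass(frozen=True)
class ConcentrationResult:
    concentration: float
    mean_viability: float
    gapdh_delta_ct: float
    gapdh_pass: bool
    accepted: bool
    mean_folds: Mapping[GeneMarker, float]
    active_genes: frozenset[GeneMarker]


@dataclass(frozen=True)
class RunEvaluation:
    """Full verdict for one chemical within one run."""

    lab_id: str
    run_id: str
    chemical_code: str
    criteria_name: str
    valid: bool
    failed_criteria: tuple[str, ...]
    per_concentration: tuple[ConcentrationResult, ...]
    imax: Mapping[GeneMarker, float]
    active_genes: frozenset[GeneMarker]
    call: Call


def _mean_viability(results, tissue_ids) -> float:
    vals = [v.viability_pct for v in results if v.tissue_id in tissue_ids]
    return statistics.fmean(vals)


def check_run_validity(
    records: Sequence[TissueRecord],
    criteria: CriteriaSet,
) -> tuple[bool, list[str]]:
    """Evaluate the four run-acceptance criteria; never short-circuits.

    Returns ``(valid, failed)`` where ``failed`` names every criterion that
    failed.  A run without vehicle or positive-control tissues raises
    :class:`StructuralRunError` — the checks cannot be evaluated at all.
    """
    by_role: dict[Role, list[TissueRecord]] = {}
    for r in records:
        by_role.setdefault(r.role, []).append(r)
    for role in (Role.VEHICLE, Role.PC_CLOTRIMAZOLE, Role.PC_4NBB):
        if role not in by_role:
            raise StructuralRunError(f"run has no {role.value} tissues")

    viability = per_tissue_viability(records)
    failed: list[str] = []

    vehicle_ids = {r.tissue_id for r in by_role[Role.VEHICLE]}
    n_ok = sum(1 for v in viability
               if v.tissue_id in vehicle_ids
               and v.viability_pct >= criteria.vehicle_viability_min_pct)
    if n_ok < criteria.vehicle_min_tissues:
        failed.append("vehicle_viability")

    clo_ids = {r.tissue_id for r in by_role[Role.PC_CLOTRIMAZOLE]}
    nbb_ids = {r.tissue_id for r in by_role[Role.PC_4NBB]}
    if (_mean_viability(viability, clo_ids) < criteria.pc_viability_min_pct
            or _mean_viability(viability, nbb_ids) < criteria.pc_viability_min_pct):
        failed.append("pc_viability")

    vehicle_cts = [r.ct for r in by_role[Role.VEHICLE] if r.ct]
    for role, genes, label in (
            (Role.PC_CLOTRIMAZOLE, criteria.pc_clotrimazole_genes,
             "pc_clotrimazole_induction"),
            (Role.PC_4NBB, criteria.pc_4nbb_genes, "pc_4nbb_induction")):
        pc_cts = [r.ct for r in by_role[role] if r.ct]
        if not pc_cts or not vehicle_cts:
            raise StructuralRunError(
                f"missing Ct values for {label.replace('_induction', '')}")
        fis = fold_induction(pc_cts, vehicle_cts, genes=sorted(genes, key=str))
        folds = {fi.gene: fi.mean_fold for fi in fis}
        if not all(folds.get(g, 0.0) > criteria.gene_cutoffs[g] for g in genes):
            failed.append(label)

    return (not failed), failed


def accept_concentrations(
    mean_viability: Mapping[float, float],
    gapdh_delta_ct: Mapping[float, float],
    criteria: CriteriaSet,
) -> dict[float, bool]:
    """Per-concentration acceptance: viability threshold AND GAPDH drift check.

    Both comparisons are boundary-inclusive: exactly 60% (or 80%) viability
    passes, and a GAPDH drift of exactly the tolerance passes.
    """
    return {
        conc: (mean_viability[conc] >= criteria.viability_threshold_pct
               and abs(gapdh_delta_ct[conc]) <= criteria.gapdh_dct_tolerance)
        for conc in mean_viability
    }


def call_genes(
    imax: Mapping[GeneMarker, float],
    criteria: CriteriaSet,
) -> frozenset[GeneMarker]:
    """Genes whose Imax strictly exceeds their cut-off (ties are inactive)."""
    return frozenset(
        g for g in MARKER_GENES
        if g in imax and imax[g] > criteria.gene_cutoffs[g])


def predict(
    valid: bool,
    accepted_concentrations: Collection[float],
    imax: Mapping[GeneMarker, float],
    criteria: CriteriaSet,
) -> Call:
    """The prediction model: count active genes against ``min_active_genes``."""
    if not valid:
        return Call.INVALID_RUN
    if not accepted_concentrations:
        return Call.NO_ACCEPTED_CONCENTRATION
    active = call_genes(imax, criteria)
    if len(active) >= criteria.min_active_genes:
        return Call.SENSITIZER
    return Call.NON_SENSITIZER


def evaluate_run(
    records: Sequence[TissueRecord],
    criteria: CriteriaSet,
    chemical_code: str | None = None,
) -> RunEvaluation:
    """Evaluate one chemical in one run end to end.

    ``records`` must hold the complete run (test tissues plus vehicle, both
    positive controls and killed tissues or an MTT path).  If the run carries
    several coded chemicals, ``chemical_code`` selects one.
    """
    codes = sorted({r.chemical_code for r in records if r.role is Role.TEST})
    if chemical_code is None:
        if len(codes) != 1:
            raise ValueError(
                f"run holds chemicals {codes}; pass chemical_code explicitly")
        chemical_code = codes[0]
    test = [r for r in records
            if r.role is Role.TEST and r.chemical_code == chemical_code]
    if not test:
        raise ValueError(f"no test tissues for chemical {chemical_code!r}")
    lab_id, run_id = test[0].lab_id, test[0].run_id

    valid, failed = check_run_validity(records, criteria)
    viability = {v.tissue_id: v for v in per_tissue_viability(records)}
    vehicle_cts = [r.ct for r in records if r.role is Role.VEHICLE and r.ct]

    per_conc: list[ConcentrationResult] = []
    by_conc: dict[float, list[TissueRecord]] = {}
    for r in test:
        by_conc.setdefault(r.concentration, []).append(r)
    for conc in sorted(by_conc, reverse=True):
        tissues = by_conc[conc]
        mean_v = statistics.fmean(
            viability[t.tissue_id].viability_pct for t in tissues)
        fis = fold_induction(
            [t.ct for t in tissues], vehicle_cts,
            chemical_code=chemical_code, concentration=conc)
        folds = {fi.gene: fi.mean_fold for fi in fis}
        dct = fis[0].gapdh_delta_ct if fis else 0.0
        accepted = accept_concentrations(
            {conc: mean_v}, {conc: dct}, criteria)[conc]
        per_conc.append(ConcentrationResult(
            concentration=conc, mean_viability=mean_v, gapdh_delta_ct=dct,
            gapdh_pass=abs(dct) <= criteria.gapdh_dct_tolerance,
            accepted=accepted, mean_folds=folds,
            active_genes=call_genes(folds, criteria)))

    accepted_concs = [c.concentration for c in per_conc if c.accepted]
    imax: dict[GeneMarker, float] = {}
    for c in per_conc:
        if not c.accepted:
            continue
        for gene, f in c.mean_folds.items():
            imax[gene] = max(imax.get(gene, float("-inf")), f)
    call = predict(valid, accepted_concs, imax, criteria)
    active = call_genes(imax, criteria) if accepted_concs else frozenset()

    return RunEvaluation(
        lab_id=lab_id, run_id=run_id, chemical_code=chemical_code,
        criteria_name=criteria.name, valid=valid,
        failed_criteria=tuple(failed), per_concentration=tuple(per_conc),
        imax=imax, active_genes=active, call=call)


def evaluate_study(
    records: Sequence[TissueRecord],
    criteria: CriteriaSet,
) -> list[RunEvaluation]:
    """Evaluate every (run, chemical) pair in a multi-run record table."""
    by_run: dict[tuple[str, str], list[TissueRecord]] = {}
    for r in records:
        by_run.setdefault((r.lab_id, r.run_id), []).append(r)
    evaluations: list[RunEvaluation] = []
    for (_, _), run_records in sorted(by_run.items()):
        codes = sorted({r.chemical_code for r in run_records
                        if r.role is Role.TEST})
        for code in codes:
            evaluations.append(evaluate_run(run_records, criteria, code))
    return evaluations


def run_calls_frame(evaluations: Iterable[RunEvaluation]) -> pd.DataFrame:
    """Tabulate evaluations in the ``run_calls.csv`` layout."""
    rows = []
    for ev in evaluations:
        row = {
            "lab_id": ev.lab_id, "run_id": ev.run_id,
            "chemical_code": ev.chemical_code,
            "criteria_name": ev.criteria_name,
            "valid": ev.valid,
            "failed_criteria": ";".join(ev.failed_criteria),
            "call": ev.call.value,
            "active_genes": ";".join(sorted(g.value for g in ev.active_genes)),
        }
        for gene in MARKER_GENES:
            row[f"imax_{gene.value}"] = ev.imax.get(gene, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
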