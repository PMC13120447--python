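"""Interlaboratory validation statistics: reproducibility and predictivity.

For each (laboratory, chemical) the per-run calls (invalid runs excluded) are
reduced to their *mode* — the most frequent call — and a concordance flag
(all valid runs identical).  From these:

* **WLR** (within-laboratory reproducibility): per laboratory, the fraction
  of repeatedly tested chemicals whose runs were fully concordant.
* **BLR** (between-laboratory reproducibility): the fraction of panel
  chemicals on which every laboratory that tested the chemical reached the
  same modal call.  Laboratories covering only a subset of the panel
  contribute to the chemicals they tested.
* **Predictivity**: modal calls against the in vivo reference classes give
  per-laboratory confusion counts, hence sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), accuracy (TP+TN)/N and balanced accuracy (sens+spec)/2.

Averages across laboratories are unweighted arithmetic means of the per-lab
percentages.  Reported values are rounded half-up to one decimal; comparisons
against the Performance-Standards minima (WLR/BLR >= 80%, sensitivity >= 85%,
specificity >= 65%, accuracy >= 85%) use the unrounded values.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assay_model import ReferenceChemical
from .classify import Call
from .errors import NoDataError, UnresolvedModeError

#: OECD Performance-Standards minima (percent).
PS_MINIMA: dict[str, float] = {
    "wlr_average": 80.0,
    "blr": 80.0,
    "sensitivity": 85.0,
    "specificity": 65.0,
    "accuracy": 85.0,
}

_CLASSIFIABLE = {Call.SENSITIZER.value, Call.NON_SENSITIZER.value}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the reporting convention used here)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChemicalSummary:
    """Mode-aggregated call for one chemical in one laboratory."""

    chemical_code: str
    lab_id: str
    run_calls: tuple[str, ...]      # valid runs only
    modal_call: str
    concordant: bool                # all valid run calls identical


def aggregate_runs(calls: Sequence[str | Call]) -> tuple[str, bool]:
    """Mode and concordance of a chemical's valid run calls.

    Invalid runs are dropped before aggregation.  An empty remainder raises
    :class:`NoDataError`; a three-way tie (three runs, three distinct calls)
    raises :class:`UnresolvedModeError` rather than breaking the tie silently.
    """
    valid = [Call(c).value for c in calls if Call(c) is not Call.INVALID_RUN]
    if not valid:
        raise NoDataError("no valid run calls to aggregate")
    counts = Counter(valid)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        raise UnresolvedModeError(f"no unique mode among calls {valid}")
    return ranked[0][0], len(counts) == 1


def summarize_chemical(
    chemical_code: str, lab_id: str, calls: Sequence[str | Call],
) -> ChemicalSummary:
    valid = tuple(Call(c).value for c in calls
                  if Call(c) is not Call.INVALID_RUN)
    modal, concordant = aggregate_runs(calls)
    return ChemicalSummary(chemical_code, lab_id, valid, modal, concordant)


def wlr(summaries: Sequence[ChemicalSummary]) -> float:
    """Within-laboratory reproducibility: fraction of concordant chemicals.

    Expects the laboratory's repeat-tested chemicals (nominally 12, each with
    three valid runs); if a different number is supplied the fraction is
    computed over what is available, with a warning.
    """
    if not summaries:
        raise NoDataError("no chemical summaries for WLR")
    if len(summaries) != 12:
        warnings.warn(
            f"WLR computed over {len(summaries)} chemicals (expected 12)",
            stacklevel=2)
    return sum(s.concordant for s in summaries) / len(summaries)


def blr(per_lab_modal: Mapping[str, Mapping[str, str]]) -> float:
    """Between-laboratory reproducibility over the chemical panel.

    ``per_lab_modal`` maps chemical -> {lab -> modal call}.  A chemical is
    concordant iff all laboratories that tested it agree; chemicals tested by
    fewer than two laboratories are excluded with a warning.
    """
    usable = {chem: labs for chem, labs in per_lab_modal.items()
              if len(labs) >= 2}
    dropped = set(per_lab_modal) - set(usable)
    if dropped:
        warnings.warn(
            f"BLR: excluded chemicals with <2 labs: {sorted(dropped)}",
            stacklevel=2)
    if not usable:
        raise NoDataError("no chemicals with >=2 labs for BLR")
    concordant = sum(
        1 for labs in usable.values() if len(set(labs.values())) == 1)
    return concordant / len(usable)


def predictivity(
    modal_calls: Mapping[str, str],
    reference: Mapping[str, str],
) -> dict:
    """Confusion counts and predictivity metrics vs in vivo classes.

    ``reference`` maps chemical -> "sensitizer" | "non_sensitizer".  Calls
    that are not classifiable (e.g. ``no_accepted_concentration``) are
    excluded; the number excluded is reported.  Percentages are returned
    unrounded under ``*_pct`` with half-up one-decimal companions under
    ``*_pct_rounded``.
    """
    tp = fp = tn = fn = excluded = 0
    for chem, call in modal_calls.items():
        if chem not in reference:
            raise NoDataError(f"no reference class for chemical {chem!r}")
        if call not in _CLASSIFIABLE:
            excluded += 1
            continue
        is_pos = call == Call.SENSITIZER.value
        is_sens = reference[chem] == "sensitizer"
        if is_pos and is_sens:
            tp += 1
        elif is_pos:
            fp += 1
        elif is_sens:
            fn += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    if n == 0:
        raise NoDataError("no classifiable calls for predictivity")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    acc = 100.0 * (tp + tn) / n
    bal = (sens + spec) / 2.0
    out = {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn, "n": n, "excluded": excluded,
        "sensitivity_pct": sens, "specificity_pct": spec,
        "accuracy_pct": acc, "balanced_accuracy_pct": bal,
    }
    for key in ("sensitivity", "specificity", "accuracy", "balanced_accuracy"):
        out[f"{key}_pct_rounded"] = round_half_up(out[f"{key}_pct"])
    return out


@dataclass(frozen=True)
class StudyMetrics:
    """Study-level reproducibility and predictivity summary."""

    criteria_name: str
    wlr_per_lab: Mapping[str, float]            # fractions
    wlr_average: float                          # fraction
    blr: float                                  # fraction
    per_lab_confusion: Mapping[str, Mapping[str, int]]
    per_lab_metrics: Mapping[str, Mapping[str, float]]   # percents
    sensitivity_avg: float
    specificity_avg: float
    accuracy_avg: float
    balanced_accuracy_avg: float
    ps_pass: Mapping[str, bool]

    def as_dict(self) -> dict:
        return {
            "criteria": self.criteria_name,
            "wlr_per_lab_pct": {k: round_half_up(100 * v)
                                for k, v in self.wlr_per_lab.items()},
            "wlr_average_pct": round_half_up(100 * self.wlr_average),
            "blr_pct": round_half_up(100 * self.blr),
            "per_lab_confusion": {k: dict(v)
                                  for k, v in self.per_lab_confusion.items()},
            "per_lab_metrics_pct": {
                lab: {m: round_half_up(v) for m, v in mm.items()}
                for lab, mm in self.per_lab_metrics.items()},
            "sensitivity_avg_pct": round_half_up(self.sensitivity_avg),
            "specificity_avg_pct": round_half_up(self.specificity_avg),
            "accuracy_avg_pct": round_half_up(self.accuracy_avg),
            "balanced_accuracy_avg_pct": round_half_up(self.balanced_accuracy_avg),
            "ps_pass": dict(self.ps_pass),
        }


def study_metrics_from_calls(
    calls: pd.DataFrame,
    panel: Sequence[ReferenceChemical],
    criteria_name: str = "",
) -> StudyMetrics:
    """Compute WLR, BLR and predictivity from a long table of run calls.

    ``calls`` needs columns ``lab_id, chemical_code, run_index, call`` (one
    criteria variant at a time; filter beforehand if the table mixes
    variants).  WLR is computed per laboratory over its repeat-tested
    (>=2 runs) chemicals; per-laboratory predictivity is computed for
    laboratories that tested the full panel, and study averages are
    unweighted means over those laboratories.
    """
    if "criteria" in calls.columns and calls["criteria"].nunique() > 1:
        raise ValueError("calls table mixes criteria variants; filter first")
    reference = {c.code: c.in_vivo_class for c in panel}
    panel_codes = set(reference)

    summaries: dict[str, dict[str, ChemicalSummary]] = {}
    for (lab, chem), grp in calls.groupby(["lab_id", "chemical_code"]):
        ordered = grp.sort_values("run_index")["call"].tolist()
        summaries.setdefault(lab, {})[chem] = summarize_chemical(
            chem, lab, ordered)

    wlr_per_lab: dict[str, float] = {}
    for lab, chems in summaries.items():
        repeat = [s for s in chems.values() if len(s.run_calls) >= 2]
        if repeat:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wlr_per_lab[lab] = wlr(repeat)
    if not wlr_per_lab:
        raise NoDataError("no laboratory has repeat-tested chemicals")
    wlr_average = sum(wlr_per_lab.values()) / len(wlr_per_lab)

    per_lab_modal: dict[str, dict[str, str]] = {}
    for lab, chems in summaries.items():
        for chem, s in chems.items():
            per_lab_modal.setdefault(chem, {})[lab] = s.modal_call
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        blr_value = blr(per_lab_modal)

    full_panel_labs = [lab for lab, chems in summaries.items()
                       if panel_codes.issubset(chems)]
    per_lab_confusion: dict[str, dict[str, int]] = {}
    per_lab_metrics: dict[str, dict[str, float]] = {}
    for lab in full_panel_labs:
        modal = {chem: s.modal_call for chem, s in summaries[lab].items()
                 if chem in panel_codes}
        p = predictivity(modal, reference)
        per_lab_confusion[lab] = {k: p[k] for k in ("tp", "fp", "tn", "fn")}
        per_lab_metrics[lab] = {
            "sensitivity": p["sensitivity_pct"],
            "specificity": p["specificity_pct"],
            "accuracy": p["accuracy_pct"],
            "balanced_accuracy": p["balanced_accuracy_pct"],
        }
    if not per_lab_metrics:
        raise NoDataError("no laboratory tested the full panel")

    def avg(metric: str) -> float:
        vals = [m[metric] for m in per_lab_metrics.values()]
        return sum(vals) / len(vals)

    sens_avg = avg("sensitivity")
    spec_avg = avg("specificity")
    acc_avg = avg("accuracy")
    bal_avg = avg("balanced_accuracy")

    metrics = StudyMetrics(
        criteria_name=criteria_name,
        wlr_per_lab=wlr_per_lab, wlr_average=wlr_average, blr=blr_value,
        per_lab_confusion=per_lab_confusion, per_lab_metrics=per_lab_metrics,
        sensitivity_avg=sens_avg, specificity_avg=spec_avg,
        accuracy_avg=acc_avg, balanced_accuracy_avg=bal_avg,
        ps_pass=ps_pass_map(100 * wlr_average, 100 * blr_value,
                            sens_avg, spec_avg, acc_avg))
    return metrics


def ps_pass_map(wlr_avg_pct: float, blr_pct: float, sens_pct: float,
                spec_pct: float, acc_pct: float) -> dict[str, bool]:
    return {
        "wlr_average": wlr_avg_pct >= PS_MINIMA["wlr_average"],
        "blr": blr_pct >= PS_MINIMA["blr"],
        "sensitivity": sens_pct >= PS_MINIMA["sensitivity"],
        "specificity": spec_pct >= PS_MINIMA["specificity"],
        "accuracy": acc_pct >= PS_MINIMA["accuracy"],
    }


def ps_report(metrics: StudyMetrics) -> pd.DataFrame:
    """One row per Performance-Standards criterion with pass/fail."""
    values = {
        "wlr_average": 100 * metrics.wlr_average,
        "blr": 100 * metrics.blr,
        "sensitivity": metrics.sensitivity_avg,
        "specificity": metrics.specificity_avg,
        "accuracy": metrics.accuracy_avg,
    }
    rows = [{
        "criterion": crit,
        "minimum_pct": PS_MINIMA[crit],
        "value_pct": round_half_up(values[crit]),
        "pass": values[crit] >= PS_MINIMA[crit],
    } for crit in PS_MINIMA]
    return pd.DataFrame(rows)
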