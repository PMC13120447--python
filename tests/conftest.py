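"""Shared builders for hand-constructed runs with exact folds/viabilities."""

from __future__ import annotations

import math

import pytest

from epi2sensa import (
    EPI2SENSA_CRITERIA,
    VRM_CRITERIA,
    GeneMarker,
    Role,
    TissueRecord,
    Vehicle,
)

# Marker Ct offsets vs GAPDH in unstimulated tissue; chosen here independently
# of the simulator so tests construct Ct values from first principles.
OFFSETS = {
    GeneMarker.ATF3: 7.0,
    GeneMarker.GCLM: 5.0,
    GeneMarker.DNAJB4: 6.0,
    GeneMarker.IL8: 8.0,
}

GAPDH_BASE = 18.0

VC_DABS = 0.10
KILLED_DABS = 1.10  # per-tissue; killed mean - vc mean = 1.00 exactly


def ct_map(folds: dict[GeneMarker, float] | None = None,
           gapdh: float = GAPDH_BASE) -> dict[GeneMarker, float]:
    """Ct values that decode to the given fold inductions exactly.

    A tissue with ``folds=None`` (or fold 1.0 everywhere) reproduces the
    vehicle baseline: marker Ct = GAPDH Ct + fixed offset.
    """
    folds = folds or {}
    cts = {GeneMarker.GAPDH: gapdh}
    for gene, off in OFFSETS.items():
        cts[gene] = gapdh + off - math.log2(folds.get(gene, 1.0))
    return cts


def viability_to_dabs(viability_pct: float) -> float:
    """Invert the LDH formula for the canonical vc=0.10 / killed=1.10 anchors."""
    return VC_DABS + (1.0 - viability_pct / 100.0) * (KILLED_DABS - VC_DABS)


def make_run(
    test_by_conc: dict[float, list[dict]] | None = None,
    chemical_code: str = "CHEM1",
    lab_id: str = "lab1",
    run_id: str = "run1",
    vehicle_dabs: tuple[float, ...] = (VC_DABS, VC_DABS, VC_DABS),
    killed_dabs: tuple[float, ...] = (KILLED_DABS,) * 3,
    pc_clo: dict | None = None,
    pc_nbb: dict | None = None,
    pc_viability: float = 90.0,
    vehicle_gapdh: float = GAPDH_BASE,
) -> list[TissueRecord]:
    """Build a complete run.

    ``test_by_conc`` maps concentration -> list of per-tissue specs, each a
    dict with keys ``folds`` (gene->fold), ``viability`` (percent) and
    optionally ``gapdh`` (raw GAPDH Ct).  Positive controls default to
    comfortably passing folds; pass ``pc_clo``/``pc_nbb`` to override.
    """
    pc_clo = pc_clo if pc_clo is not None else {
        GeneMarker.ATF3: 20.0, GeneMarker.IL8: 6.0}
    pc_nbb = pc_nbb if pc_nbb is not None else {
        GeneMarker.GCLM: 3.0, GeneMarker.DNAJB4: 3.0}
    records: list[TissueRecord] = []

    def rec(tissue_id, role, conc=0.0, dabs=VC_DABS, ct=None, code=""):
        return TissueRecord(
            lab_id=lab_id, run_id=run_id, tissue_id=tissue_id, role=role,
            chemical_code=code, vehicle=Vehicle.AOO, concentration=conc,
            abs_490=0.05 + dabs, abs_ref=0.05, ct=ct)

    for i, d in enumerate(vehicle_dabs):
        records.append(rec(f"vc{i+1}", Role.VEHICLE, dabs=d,
                           ct=ct_map(gapdh=vehicle_gapdh)))
    for i, d in enumerate(killed_dabs):
        records.append(rec(f"kc{i+1}", Role.KILLED, dabs=d))
    pc_dabs = viability_to_dabs(pc_viability)
    for i in range(2):
        records.append(rec(f"clo{i+1}", Role.PC_CLOTRIMAZOLE, conc=1.56,
                           dabs=pc_dabs, ct=ct_map(pc_clo)))
        records.append(rec(f"nbb{i+1}", Role.PC_4NBB, conc=0.78,
                           dabs=pc_dabs, ct=ct_map(pc_nbb)))
    for conc, tissues in (test_by_conc or {}).items():
        for i, spec in enumerate(tissues):
            records.append(rec(
                f"t-{conc:g}-{i+1}", Role.TEST, conc=conc,
                dabs=viability_to_dabs(spec.get("viability", 100.0)),
                ct=ct_map(spec.get("folds"),
                          gapdh=spec.get("gapdh", GAPDH_BASE)),
                code=chemical_code))
    return records


@pytest.fixture
def vrm():
    return VRM_CRITERIA


@pytest.fixture
def epi2():
    return EPI2SENSA_CRITERIA
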