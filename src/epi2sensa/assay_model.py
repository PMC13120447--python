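"""Domain types, CSV readers/writers, criteria presets and packaged fixtures.

The central record is one RhE tissue (a single insert on a plate) with its
role (test chemical, vehicle control, one of the two positive controls, or
killed control), its LDH absorbance pair, an optional externally supplied MTT
viability, and optional per-gene Ct values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FixtureError,
    InsolubilityError,
    IntegrityError,
    RecordValueError,
    SchemaError,
)


class GeneMarker(str, enum.Enum):
    """The four keratinocyte-activation marker genes plus the GAPDH reference.

    GAPDH is reference-only: it normalizes Ct values and gates concentration
    acceptance (Ct drift check) but never carries an induction cut-off.
    """

    ATF3 = "ATF3"
    GCLM = "GCLM"
    DNAJB4 = "DNAJB4"
    IL8 = "IL8"
    GAPDH = "GAPDH"


#: The marker genes that carry fold-induction cut-offs (GAPDH excluded).
MARKER_GENES: tuple[GeneMarker, ...] = (
    GeneMarker.ATF3,
    GeneMarker.GCLM,
    GeneMarker.DNAJB4,
    GeneMarker.IL8,
)


class Role(str, enum.Enum):
    TEST = "test"
    VEHICLE = "vehicle"
    PC_CLOTRIMAZOLE = "pc_clotrimazole"
    PC_4NBB = "pc_4nbb"
    KILLED = "killed"


class Vehicle(str, enum.Enum):
    """Application vehicles in order of preference."""

    AOO = "AOO"          # acetone:olive oil 4:1
    DW = "DW"            # distilled water
    ETOH50 = "EtOH50"    # 50% ethanol in DW


#: Solubility-screen preference order (most to least preferred).
VEHICLE_PREFERENCE: tuple[Vehicle, ...] = (Vehicle.AOO, Vehicle.DW, Vehicle.ETOH50)

_ROLE_ALIASES = {
    "test": Role.TEST,
    "tc": Role.TEST,
    "vehicle": Role.VEHICLE,
    "vc": Role.VEHICLE,
    "vehicle_control": Role.VEHICLE,
    "pc_clotrimazole": Role.PC_CLOTRIMAZOLE,
    "clotrimazole": Role.PC_CLOTRIMAZOLE,
    "pc_4nbb": Role.PC_4NBB,
    "4nbb": Role.PC_4NBB,
    "4-nbb": Role.PC_4NBB,
    "killed": Role.KILLED,
    "killed_control": Role.KILLED,
    "kc": Role.KILLED,
}

_VEHICLE_ALIASES = {
    "aoo": Vehicle.AOO,
    "dw": Vehicle.DW,
    "water": Vehicle.DW,
    "etoh50": Vehicle.ETOH50,
    "50% etoh": Vehicle.ETOH50,
    "50%etoh": Vehicle.ETOH50,
}

#: Positive-control exposure concentrations (% w/v). 4-NBB is quoted both as
#: 0.78% (exposure) and 0.10% (in the acceptance-criterion sentence); both are
#: recorded, and the exposure value is used by the simulator.
PC_CLOTRIMAZOLE_CONC = 1.56
PC_4NBB_CONC = 0.78
PC_4NBB_CONC_ALT = 0.10


def normalize_role(token: str) -> Role:
    try:
        return _ROLE_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise RecordValueError(f"unknown role token {token!r}") from None


def normalize_vehicle(token: str) -> Vehicle:
    try:
        return _VEHICLE_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise RecordValueError(f"unknown vehicle token {token!r}") from None


def normalize_gene(token: str) -> GeneMarker:
    t = str(token).strip().upper().replace("-", "")
    try:
        return GeneMarker(t)
    except ValueError:
        raise RecordValueError(f"unknown gene token {token!r}") from None


@dataclass(frozen=True)
class TissueRecord:
    """One RhE tissue's measurements within a run.

    ``abs_490`` / ``abs_ref`` are the raw LDH plate-reader absorbances at
    490 nm and at the reference wavelength (>=650 nm); the LDH signal used by
    the viability formula is their difference ``delta_abs``, which may be near
    zero (``abs_490 >= abs_ref`` is not required).  ``mtt_viability_pct``
    carries an externally supplied MTT viability for chemicals that interfere
    with the LDH readout.  ``ct`` maps gene to cycle threshold; killed tissues
    carry none (their RNA is not processed).
    """

    lab_id: str
    run_id: str
    tissue_id: str
    role: Role
    chemical_code: str = ""
    vehicle: Vehicle | None = None
    concentration: float = 0.0
    abs_490: float = 0.0
    abs_ref: float = 0.0
    mtt_viability_pct: float | None = None
    ct: Mapping[GeneMarker, float] | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise RecordValueError(
                f"tissue {self.tissue_id}: negative concentration")
        if self.abs_490 < 0 or self.abs_ref < 0:
            raise RecordValueError(
                f"tissue {self.tissue_id}: negative absorbance")
        if self.role is Role.TEST and not self.concentration > 0:
            raise RecordValueError(
                f"test tissue {self.tissue_id}: concentration must be > 0")
        if self.role is Role.KILLED and self.ct:
            raise RecordValueError(
                f"killed tissue {self.tissue_id}: Ct values not allowed")
        if self.ct is not None:
            for g, c in self.ct.items():
                if not (isinstance(c, (int, float)) and c > 0 and math.isfinite(c)):
                    raise RecordValueError(
                        f"tissue {self.tissue_id}: non-positive Ct for {g.value}")

    @property
    def delta_abs(self) -> float:
        """LDH signal: absorbance at 490 nm minus reference wavelength."""
        return self.abs_490 - self.abs_ref


@dataclass(frozen=True)
class CriteriaSet:
    """Every tunable threshold distinguishing the VRM from Epi2SensA criteria.

    Parameters
    ----------
    gene_cutoffs
        Fold-induction cut-off per marker gene; a gene is *activated* when its
        Imax strictly exceeds the cut-off.
    min_active_genes
        Minimum number of activated genes for a positive (sensitizer) call:
        1 for the VRM rule, 2 for the modified Epi2SensA rule.
    viability_threshold_pct
        Minimum mean tissue viability for a concentration to be accepted
        (and for dose-finding validity): 80 for the VRM, 60 for Epi2SensA.
    vehicle_viability_min_pct / vehicle_min_tissues
        Run acceptance: at least ``vehicle_min_tissues`` vehicle tissues must
        reach ``vehicle_viability_min_pct`` viability.
    pc_viability_min_pct
        Run acceptance: mean viability of each positive control.
    gapdh_dct_tolerance
        Concentration acceptance: the mean test GAPDH Ct must be within this
        many cycles of the vehicle-control mean (boundary inclusive).
    pc_clotrimazole_genes / pc_4nbb_genes
        Markers each positive control must induce above cut-off.
    """

    name: str
    gene_cutoffs: Mapping[GeneMarker, float]
    min_active_genes: int
    viability_threshold_pct: float
    vehicle_viability_min_pct: float = 95.0
    vehicle_min_tissues: int = 2
    pc_viability_min_pct: float = 80.0
    gapdh_dct_tolerance: float = 1.0
    pc_clotrimazole_genes: frozenset[GeneMarker] = frozenset(
        {GeneMarker.ATF3, GeneMarker.IL8})
    pc_4nbb_genes: frozenset[GeneMarker] = frozenset(
        {GeneMarker.GCLM, GeneMarker.DNAJB4})

    def __post_init__(self) -> None:
        if set(self.gene_cutoffs) != set(MARKER_GENES):
            raise ConfigError("gene_cutoffs must cover exactly the four marker genes")
        if not 1 <= self.min_active_genes <= 4:
            raise ConfigError("min_active_genes must be in 1..4")


#: Shared gene cut-offs (identical in both criteria variants).
GENE_CUTOFFS: dict[GeneMarker, float] = {
    GeneMarker.ATF3: 15.0,
    GeneMarker.GCLM: 2.0,
    GeneMarker.DNAJB4: 2.0,
    GeneMarker.IL8: 4.0,
}

VRM_CRITERIA = CriteriaSet(
    name="VRM",
    gene_cutoffs=GENE_CUTOFFS,
    min_active_genes=1,
    viability_threshold_pct=80.0,
)

EPI2SENSA_CRITERIA = CriteriaSet(
    name="Epi2SensA",
    gene_cutoffs=GENE_CUTOFFS,
    min_active_genes=2,
    viability_threshold_pct=60.0,
)

CRITERIA_PRESETS: dict[str, CriteriaSet] = {
    "VRM": VRM_CRITERIA,
    "Epi2SensA": EPI2SENSA_CRITERIA,
}


def load_criteria(source: str | Path | Mapping) -> CriteriaSet:
    """Resolve a criteria set from a preset name, YAML file, or mapping.

    A mapping (or YAML file) must carry ``base: VRM|Epi2SensA`` and may
    override any threshold field, e.g.::

        base: Epi2SensA
        viability_threshold_pct: 70
        gene_cutoffs: {ATF3: 10}
    """
    if isinstance(source, str) and source in CRITERIA_PRESETS:
        return CRITERIA_PRESETS[source]
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, Mapping):
        raise ConfigError(f"cannot interpret criteria source {source!r}")
    cfg = dict(source)
    base_name = cfg.pop("base", cfg.pop("name", None))
    if base_name not in CRITERIA_PRESETS:
        raise ConfigError(f"criteria config must name a base preset, got {base_name!r}")
    base = CRITERIA_PRESETS[base_name]
    overrides: dict = {}
    if "gene_cutoffs" in cfg:
        cutoffs = dict(base.gene_cutoffs)
        for gene, value in cfg.pop("gene_cutoffs").items():
            cutoffs[normalize_gene(gene)] = float(value)
        overrides["gene_cutoffs"] = cutoffs
    for key, value in cfg.items():
        if key not in CriteriaSet.__dataclass_fields__:
            raise ConfigError(f"unknown criteria field {key!r}")
        overrides[key] = value
    if overrides:
        overrides.setdefault("name", f"{base.name}+overrides")
        return replace(base, **overrides)
    return base


@dataclass(frozen=True)
class ReferenceChemical:
    """One entry of the 20-chemical reference panel (OECD performance standards)."""

    code: str
    name: str
    cas: str
    logp: float
    pre_pro_hapten: bool
    in_vivo_class: str            # "sensitizer" | "non_sensitizer"
    ghs_subcat: str               # "1A" | "1B" | "not_classified"
    vehicle: Vehicle
    vrm_call: str                 # "positive" | "negative"
    epi2sensa_call: str | None = None

    def __post_init__(self) -> None:
        not_classified = self.ghs_subcat == "not_classified"
        non_sens = self.in_vivo_class == "non_sensitizer"
        if not_classified != non_sens:
            raise FixtureError(
                f"{self.code}: GHS sub-category {self.ghs_subcat!r} inconsistent "
                f"with in vivo class {self.in_vivo_class!r}")


# ---------------------------------------------------------------------------
# Solubility screen / vehicle selection
# ---------------------------------------------------------------------------

def dilution_series(levels: int = 13, top: float = 50.0) -> list[float]:
    """The 2-fold solubility dilution grid: ``top/2**k`` for k=0..levels-1.

    The default reproduces the screen from 50% down to 0.0122%
    (0.0122 being the printed rounding of 50/2**12).
    """
    return [top / 2 ** k for k in range(levels)]


def select_vehicle(
    solubility: Mapping[tuple[Vehicle, float], bool],
) -> tuple[Vehicle, float]:
    """Pick the application vehicle from a solubility screen.

    If any vehicle dissolves the chemical at the top tested concentration,
    the first such vehicle in preference order (AOO > DW > 50% EtOH) wins.
    Otherwise the vehicle with the highest soluble concentration wins, ties
    broken by preference order.  The result does not depend on the iteration
    order of ``solubility``.
    """
    if not solubility:
        raise InsolubilityError("empty solubility screen")
    top = max(conc for (_, conc) in solubility)
    best: dict[Vehicle, float] = {}
    for (veh, conc), soluble in solubility.items():
        veh = Vehicle(veh)
        if soluble:
            best[veh] = max(best.get(veh, 0.0), conc)
    if not best:
        raise InsolubilityError("chemical insoluble in all vehicles at all levels")
    for veh in VEHICLE_PREFERENCE:
        if best.get(veh) == top:
            return veh, top
    max_conc = max(best.values())
    for veh in VEHICLE_PREFERENCE:
        if best.get(veh) == max_conc:
            return veh, max_conc
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = [
    "lab_id", "run_id", "tissue_id", "role", "chemical_code",
    "vehicle", "concentration", "abs_490", "abs_ref",
]
_CT_WIDE_COLUMNS = {f"ct_{g.value}": g for g in GeneMarker}


def _parse_float(value, row: int, column: str, *, optional: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)) or (
            isinstance(value, str) and not value.strip()):
        if optional:
            return None
        raise RecordValueError(f"row {row}: missing value in column {column!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RecordValueError(
            f"row {row}: cannot parse {value!r} in column {column!r}") from None


def read_tissue_records(
    path: str | Path,
    ct_path: str | Path | None = None,
) -> list[TissueRecord]:
    """Read per-tissue measurements from CSV.

    Ct values come either from wide columns ``ct_ATF3 .. ct_GAPDH`` in the
    main file or from a long-format companion file
    (``run_id,tissue_id,gene,ct``) passed as ``ct_path``.  Rows that fail
    validation are reported with their 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    ct_long: dict[tuple[str, str], dict[GeneMarker, float]] = {}
    if ct_path is not None:
        ct_df = pd.read_csv(ct_path, dtype=str, keep_default_na=False)
        need = {"run_id", "tissue_id", "gene", "ct"}
        if not need.issubset(ct_df.columns):
            raise SchemaError(
                f"{ct_path}: long-format Ct file needs columns {sorted(need)}")
        for i, row in enumerate(ct_df.itertuples(index=False), start=1):
            key = (row.run_id, row.tissue_id)
            gene = normalize_gene(row.gene)
            ct_val = _parse_float(row.ct, i, "ct")
            genes = ct_long.setdefault(key, {})
            if gene in genes:
                raise IntegrityError(
                    f"{ct_path}: duplicate Ct for {key} gene {gene.value}")
            genes[gene] = ct_val

    wide_cols = [c for c in df.columns if c in _CT_WIDE_COLUMNS]
    has_mtt = "mtt_viability_pct" in df.columns

    records: list[TissueRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        key = (row["run_id"], row["tissue_id"])
        if key in seen:
            raise IntegrityError(
                f"{path}: duplicate (run_id, tissue_id) = {key} at row {i}")
        seen.add(key)
        try:
            role = normalize_role(row["role"])
            vehicle_tok = str(row["vehicle"]).strip()
            vehicle = normalize_vehicle(vehicle_tok) if vehicle_tok else None
            ct: dict[GeneMarker, float] = {}
            for col in wide_cols:
                val = _parse_float(row[col], i, col, optional=True)
                if val is not None:
                    ct[_CT_WIDE_COLUMNS[col]] = val
            if key in ct_long:
                overlap = set(ct) & set(ct_long[key])
                if overlap:
                    raise IntegrityError(
                        f"{path}: Ct for {key} given both wide and long "
                        f"({sorted(g.value for g in overlap)})")
                ct.update(ct_long[key])
            record = TissueRecord(
                lab_id=str(row["lab_id"]),
                run_id=str(row["run_id"]),
                tissue_id=str(row["tissue_id"]),
                role=role,
                chemical_code=str(row["chemical_code"]).strip(),
                vehicle=vehicle,
                concentration=_parse_float(row["concentration"], i, "concentration"),
                abs_490=_parse_float(row["abs_490"], i, "abs_490"),
                abs_ref=_parse_float(row["abs_ref"], i, "abs_ref"),
                mtt_viability_pct=(
                    _parse_float(row["mtt_viability_pct"], i,
                                 "mtt_viability_pct", optional=True)
                    if has_mtt else None),
                ct=ct or None,
            )
        except RecordValueError as exc:
            raise RecordValueError(f"{path}: row {i}: {exc}") from None
        records.append(record)
    return records


def write_tissue_records(
    records: Iterable[TissueRecord],
    path: str | Path,
    ct_path: str | Path | None = None,
) -> None:
    """Write records to CSV; the inverse of :func:`read_tissue_records`.

    With ``ct_path`` the Ct values go to a long-format companion file,
    otherwise they are written as wide ``ct_*`` columns.
    """
    records = list(records)
    rows = []
    ct_rows = []
    for r in records:
        row = {
            "lab_id": r.lab_id, "run_id": r.run_id, "tissue_id": r.tissue_id,
            "role": r.role.value, "chemical_code": r.chemical_code,
            "vehicle": r.vehicle.value if r.vehicle else "",
            "concentration": r.concentration,
            "abs_490": r.abs_490, "abs_ref": r.abs_ref,
            "mtt_viability_pct": (
                "" if r.mtt_viability_pct is None else r.mtt_viability_pct),
        }
        if r.ct:
            if ct_path is not None:
                for gene, ct_val in r.ct.items():
                    ct_rows.append({"run_id": r.run_id, "tissue_id": r.tissue_id,
                                    "gene": gene.value, "ct": ct_val})
            else:
                for gene, ct_val in r.ct.items():
                    row[f"ct_{gene.value}"] = ct_val
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    if ct_path is not None:
        pd.DataFrame(
            ct_rows, columns=["run_id", "tissue_id", "gene", "ct"],
        ).to_csv(ct_path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["code", "name", "cas", "logp", "pre_pro_hapten",
                  "in_vivo_class", "ghs_subcat", "vehicle", "vrm_call",
                  "epi2sensa_call"]


def _data_path(filename: str):
    return resources.files("epi2sensa").joinpath("data", filename)


def load_reference_panel() -> list[ReferenceChemical]:
    """Load the packaged 20-chemical reference panel.

    The panel lists the performance-standards reference substances with their
    in vivo GHS classification, LogP, pre/pro-hapten status, application
    vehicle, and the consensus calls of the reference method (VRM) and the
    modified method.
    """
    with resources.as_file(_data_path("reference_panel.csv")) as p:
        df = pd.read_csv(p, dtype=str)
    if list(df.columns) != _PANEL_COLUMNS:
        raise FixtureError(
            f"reference panel columns {list(df.columns)} != {_PANEL_COLUMNS}")
    if len(df) != 20:
        raise FixtureError(f"reference panel has {len(df)} rows, expected 20")
    panel = [
        ReferenceChemical(
            code=row.code, name=row.name, cas=row.cas, logp=float(row.logp),
            pre_pro_hapten=row.pre_pro_hapten == "1",
            in_vivo_class=row.in_vivo_class, ghs_subcat=row.ghs_subcat,
            vehicle=normalize_vehicle(row.vehicle),
            vrm_call=row.vrm_call, epi2sensa_call=row.epi2sensa_call,
        )
        for row in df.itertuples(index=False)
    ]
    n_sens = sum(c.in_vivo_class == "sensitizer" for c in panel)
    if n_sens != 14:
        raise FixtureError(f"panel has {n_sens} sensitizers, expected 14")
    return panel


def load_validation_calls() -> pd.DataFrame:
    """Load the packaged per-run call table of the interlaboratory study.

    Columns: ``lab_id, chemical_code, criteria, run_index, call``.  This is a
    synthetic reconstruction: the study's per-run calls are not published, so
    the table was constructed once to be consistent with every published
    per-laboratory reproducibility and predictivity count (see the fixture
    header for provenance notes).
    """
    with resources.as_file(_data_path("interlab_calls_synthetic.csv")) as p:
        df = pd.read_csv(p, dtype={"run_index": int}, comment="#")
    need = {"lab_id", "chemical_code", "criteria", "run_index", "call"}
    if not need.issubset(df.columns):
        raise FixtureError(f"validation calls fixture missing {need - set(df.columns)}")
    return df
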