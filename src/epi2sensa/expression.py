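"""Fold induction of the marker genes from Ct values (2^-ddCt, GAPDH reference).

Per tissue, each marker's Ct is first normalized to the same tissue's GAPDH Ct
(dCt = Ct_gene - Ct_GAPDH); the test tissue's dCt is then referenced to the
mean vehicle-control dCt (ddCt), and fold induction is 2^-ddCt with the
amplification efficiency fixed at 2.0.  Per-tissue folds are averaged on the
linear scale by default (a geometric mean is available via ``mean=``).

The raw (un-normalized) GAPDH Ct means additionally feed the concentration
acceptance check: a concentration is only eligible for gene calls if its mean
GAPDH Ct drifted at most a fixed number of cycles (default 1.0, boundary
inclusive) from the vehicle control — larger drift signals RNA degradation or
cytotoxic transcriptional shutdown rather than induction.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .assay_model import CriteriaSet, GeneMarker, MARKER_GENES
from .errors import NormalizationError, RecordValueError


@dataclass(frozen=True)
class FoldInduction:
    """Mean fold induction of one gene at one (chemical, concentration)."""

    chemical_code: str
    concentration: float
    gene: GeneMarker
    per_tissue_fold: tuple[float, ...]
    mean_fold: float
    gapdh_delta_ct: float  # mean test GAPDH Ct - mean vehicle GAPDH Ct


def _check_cts(cts: Mapping[GeneMarker, float], label: str) -> None:
    if GeneMarker.GAPDH not in cts:
        raise NormalizationError(f"{label}: missing GAPDH Ct")
    for gene, ct in cts.items():
        if not (ct > 0 and math.isfinite(ct)):
            raise RecordValueError(f"{label}: non-positive Ct for {gene.value}")


def fold_induction(
    test_cts: Sequence[Mapping[GeneMarker, float]],
    vehicle_cts: Sequence[Mapping[GeneMarker, float]],
    chemical_code: str = "",
    concentration: float = 0.0,
    genes: Sequence[GeneMarker] = MARKER_GENES,
    mean: str = "arithmetic",
) -> list[FoldInduction]:
    """Fold induction per marker gene for one (chemical, concentration).

    ``test_cts`` / ``vehicle_cts`` hold one gene→Ct mapping per tissue.  Only
    genes present in every contributing tissue are computed; a tissue without
    a GAPDH Ct is an error.
    """
    if not vehicle_cts:
        raise NormalizationError("at least one vehicle-control tissue required")
    if not test_cts:
        raise NormalizationError("at least one test tissue required")
    if mean not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean {mean!r}")
    for i, cts in enumerate(test_cts):
        _check_cts(cts, f"test tissue #{i + 1}")
    for i, cts in enumerate(vehicle_cts):
        _check_cts(cts, f"vehicle tissue #{i + 1}")

    gapdh_delta_ct = (
        statistics.fmean(c[GeneMarker.GAPDH] for c in test_cts)
        - statistics.fmean(c[GeneMarker.GAPDH] for c in vehicle_cts))

    out: list[FoldInduction] = []
    for gene in genes:
        if gene is GeneMarker.GAPDH:
            continue
        if any(gene not in c for c in test_cts) or any(
                gene not in c for c in vehicle_cts):
            continue
        vc_dct = statistics.fmean(
            c[gene] - c[GeneMarker.GAPDH] for c in vehicle_cts)
        folds = tuple(
            2.0 ** -((c[gene] - c[GeneMarker.GAPDH]) - vc_dct) for c in test_cts)
        if mean == "arithmetic":
            mean_fold = statistics.fmean(folds)
        else:
            mean_fold = math.exp(statistics.fmean(math.log(f) for f in folds))
        out.append(FoldInduction(
            chemical_code=chemical_code, concentration=concentration,
            gene=gene, per_tissue_fold=folds, mean_fold=mean_fold,
            gapdh_delta_ct=gapdh_delta_ct))
    return out


def gapdh_qc(fi: FoldInduction, criteria: CriteriaSet) -> bool:
    """GAPDH Ct drift check: |mean test Ct - mean vehicle Ct| <= tolerance.

    The bound is inclusive: a drift of exactly the tolerance passes.
    """
    return abs(fi.gapdh_delta_ct) <= criteria.gapdh_dct_tolerance
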