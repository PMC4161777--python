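"""CTC calling: cytokeratin positivity plus cytomorphological criteria.

A segmented cell is called a circulating tumour cell when it is
cytokeratin-positive and satisfies the cytomorphological criteria used for
CK-stained cytospins: size larger than the white blood cells on the same
slide and a high nuclear-to-cytoplasmic ratio.  In the double-stain quality
control mode (pan-cytokeratin + CD45) a CD45-positive cell is excluded as a
haematopoietic cell with ectopic cytokeratin expression.

"Larger than white blood cells" is operationalized per image: the reference
WBC diameter is a quantile (default median) of the equivalent diameters of
CK-negative cells, and a candidate must exceed ``size_margin`` times that
reference.  The thresholds are deliberately config-exposed — the underlying
criteria are qualitative, so the defaults here are documented conventions of
this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segment import CellRecord


@dataclass
class CtcCriteria:
    """Thresholds for the CTC decision rule."""

    ck_positive_threshold: float
    wbc_diameter_reference: float | None = None
    size_margin: float = 1.25
    nc_ratio_min: float = 0.5
    cd45_mode: bool = False
    cd45_positive_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.size_margin < 1:
            raise ValueError("size_margin must be >= 1")
        if not 0 < self.nc_ratio_min <= 1:
            raise ValueError("nc_ratio_min must be in (0, 1]")


@dataclass(frozen=True)
class CtcCall:
    is_ctc: bool
    reasons: tuple[str, ...]  # every failed criterion, empty when is_ctc


def is_ck_positive(cell: CellRecord, ck_positive_threshold: float) -> bool:
    """Cytokeratin positivity: mean CK intensity over the cytoplasm."""
    return cell.mean_intensity("ck", "cytoplasm") >= ck_positive_threshold


def estimate_wbc_reference(
    cells: Sequence[CellRecord],
    ck_positive_threshold: float,
    quantile: float = 0.5,
    min_cells: int = 20,
) -> float:
    """Per-image WBC size reference from CK-negative cells.

    Returns the configured quantile (default: median) of the equivalent
    diameters of CK-negative cells.  With fewer than ``min_cells`` such cells
    the estimate is unreliable and an error instructs the caller to supply a
    configured fallback constant instead.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    diameters = [
        c.equivalent_diameter for c in cells if not is_ck_positive(c, ck_positive_threshold)
    ]
    if len(diameters) < min_cells:
        raise ValueError(
            f"only {len(diameters)} CK-negative cells (< {min_cells}); "
            "set CtcCriteria.wbc_diameter_reference to a fallback constant"
        )
    return float(np.quantile(diameters, quantile))


def call_ctc(cell: CellRecord, criteria: CtcCriteria) -> CtcCall:
    """Apply the CTC decision rule to one cell.

    The cell is a CTC iff it is CK-positive, its equivalent diameter is at
    least ``size_margin`` times the WBC reference, its N:C ratio is at least
    ``nc_ratio_min``, and (in double-stain mode) it is CD45-negative.
    ``reasons`` lists every failed criterion.
    """
    if criteria.wbc_diameter_reference is None:
        raise ValueError("criteria.wbc_diameter_reference is unset")
    if criteria.cd45_mode and criteria.cd45_positive_threshold is None:
        raise ValueError("cd45_mode requires cd45_positive_threshold")
    reasons: list[str] = []
    if not is_ck_positive(cell, criteria.ck_positive_threshold):
        reasons.append("ck_negative")
    if cell.equivalent_diameter < criteria.size_margin * criteria.wbc_diameter_reference:
        reasons.append("not_larger_than_wbc")
    if cell.nc_ratio < criteria.nc_ratio_min:
        reasons.append("low_nc_ratio")
    if criteria.cd45_mode:
        if cell.mean_intensity("cd45", "cell") >= criteria.cd45_positive_threshold:
            reasons.append("cd45_positive")
    return CtcCall(is_ctc=not reasons, reasons=tuple(reasons))
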