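"""End-to-end per-image analysis: segmentation -> CTC calls -> marker phenotypes.

`analyze_image` takes a multi-channel cytospin field and returns one row per
segmented cell with morphology, the CTC decision and, for CTCs, the ALDH1
exposure-equivalent level and TWIST localization plus the 4-way phenotype.
Marker intensities are background-subtracted against the per-channel
off-cell background before entering the exposure-time calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ctc_call as cc
from . import markers as mk
from . import segment as sg
from .simdata import CytospinImage


@dataclass
class PipelineParams:
    """Tunable knobs of the per-image pipeline (documented defaults)."""

    min_nucleus_area: float = 20.0
    dilation_limit: float = 12.0
    ck_k: float = 5.0  # CK threshold = background mean + k * sd
    twist_k: float = 5.0
    size_margin: float = 1.25
    nc_ratio_min: float = 0.5
    wbc_quantile: float = 0.5
    min_wbc_cells: int = 20
    wbc_fallback_diameter: float | None = None
    min_positive_fraction: float = 0.3
    cd45_mode: bool = False
    cd45_k: float = 5.0


def analyze_image(
    image: CytospinImage,
    calibration: mk.CalibrationModel | None = None,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Segment and phenotype every cell of one field.

    Returns a DataFrame with columns: cell_id, centroid_row/col, nucleus_area,
    cell_area, equivalent_diameter, nc_ratio, on_border, ck_mean_cytoplasm,
    is_ctc, fail_reasons, and (CTCs only, else NA) aldh1_exposure,
    aldh1_level, twist_loc, phenotype.
    """
    model = calibration or mk.CalibrationModel()
    p = params or PipelineParams()

    dapi = image.channel("dapi").astype(float)
    ck = image.channel("ck").astype(float)
    labels = sg.segment_nuclei(dapi, min_area=p.min_nucleus_area)
    channels = {name: image.channel(name).astype(float) for name in image.channel_names}

    nuc_any = labels > 0
    ck_threshold = sg.estimate_background_threshold(ck, exclude_mask=nuc_any, k=p.ck_k)
    cells = sg.extract_cells(
        labels, ck, channels, dilation_limit=p.dilation_limit, ck_threshold=ck_threshold
    )
    if not cells:
        return _empty_table()

    # Off-cell background per channel, for marker background subtraction.
    occupied = np.zeros_like(nuc_any)
    for cell in cells:
        occupied[cell.bbox] |= cell.cell_mask
    background = {name: float(np.median(chan[~occupied])) for name, chan in channels.items()}

    try:
        wbc_ref = cc.estimate_wbc_reference(
            cells, ck_threshold, quantile=p.wbc_quantile, min_cells=p.min_wbc_cells
        )
    except ValueError:
        if p.wbc_fallback_diameter is None:
            raise
        wbc_ref = p.wbc_fallback_diameter

    criteria = cc.CtcCriteria(
        ck_positive_threshold=ck_threshold,
        wbc_diameter_reference=wbc_ref,
        size_margin=p.size_margin,
        nc_ratio_min=p.nc_ratio_min,
        cd45_mode=p.cd45_mode,
        cd45_positive_threshold=(
            sg.estimate_background_threshold(channels["cd45"], exclude_mask=nuc_any, k=p.cd45_k)
            if p.cd45_mode and "cd45" in channels
            else None
        ),
    )
    has_markers = "aldh1" in channels and "twist" in channels
    twist_threshold = (
        sg.estimate_background_threshold(channels["twist"], exclude_mask=occupied, k=p.twist_k)
        if has_markers
        else None
    )

    rows = []
    for cell in cells:
        call = cc.call_ctc(cell, criteria)
        row = {
            "cell_id": cell.cell_id,
            "centroid_row": cell.centroid[0],
            "centroid_col": cell.centroid[1],
            "nucleus_area": cell.nucleus_area,
            "cell_area": cell.cell_area,
            "equivalent_diameter": cell.equivalent_diameter,
            "nc_ratio": cell.nc_ratio,
            "on_border": cell.on_border,
            "ck_mean_cytoplasm": cell.mean_intensity("ck", "cytoplasm"),
            "is_ctc": call.is_ctc,
            "fail_reasons": ";".join(call.reasons),
            "aldh1_exposure": pd.NA,
            "aldh1_level": pd.NA,
            "twist_loc": pd.NA,
            "phenotype": pd.NA,
        }
        if call.is_ctc and has_markers:
            aldh1_mean = max(
                0.0, cell.mean_intensity("aldh1", "interior") - background["aldh1"]
            )
            marker = mk.make_marker_call(
                aldh1_mean,
                cell.pixel_values(channels["twist"], "nucleus"),
                cell.pixel_values(channels["twist"], "cytoplasm"),
                model,
                twist_threshold,
                p.min_positive_fraction,
            )
            a = "high" if marker.aldh1_level == "high" else "lowneg"
            t = "nuc" if marker.twist_loc == "nuc" else "cytneg"
            row.update(
                aldh1_exposure=marker.aldh1_exposure,
                aldh1_level=marker.aldh1_level,
                twist_loc=marker.twist_loc,
                phenotype=f"{a}_{t}",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "cell_id",
            "centroid_row",
            "centroid_col",
            "nucleus_area",
            "cell_area",
            "equivalent_diameter",
            "nc_ratio",
            "on_border",
            "ck_mean_cytoplasm",
            "is_ctc",
            "fail_reasons",
            "aldh1_exposure",
            "aldh1_level",
            "twist_loc",
            "phenotype",
        ]
    )


def phenotype_counts(cell_table: pd.DataFrame) -> np.ndarray:
    """4-vector of CTC phenotype counts (high_nuc, high_cytneg, lowneg_nuc,
    lowneg_cytneg) from an `analyze_image` table."""
    from .cohort import PHENOTYPES

    ctcs = cell_table[cell_table["is_ctc"].astype(bool)]
    return np.array([(ctcs["phenotype"] == ph).sum() for ph in PHENOTYPES], dtype=int)
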