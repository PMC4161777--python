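"""Nucleus and cell segmentation plus the morphology features used for CTC calling.

Conventions: 0-based (row, col) pixel coordinates; segmentations are label
images; per-cell masks are boolean arrays local to a bounding box stored on
the record.  The nucleus comes from the DAPI channel (Otsu threshold, touching
nuclei split by a marker-based watershed on the distance transform); the cell
body is the cytokeratin-positive region connected to the nucleus, or a small
fixed dilation of the nucleus for CK-negative cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed


@dataclass
class CellRecord:
    """One segmented cell: masks, morphology, per-channel intensity summaries.

    ``nucleus_mask`` and ``cell_mask`` are boolean arrays on the ``bbox``
    window; the cytoplasm is cell minus nucleus.  ``channel_stats`` maps
    ``(channel, compartment)`` to ``(mean, total)`` intensity, with
    compartments ``nucleus``, ``cytoplasm``, ``cell`` and ``interior`` (the
    cell eroded by 2 px, used for edge-robust marker quantification).
    """

    cell_id: int
    bbox: tuple[slice, slice]
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    on_border: bool = False
    nucleus_area: float = 0.0
    cell_area: float = 0.0
    equivalent_diameter: float = 0.0
    nc_ratio: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    channel_stats: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask

    def mean_intensity(self, channel: str, compartment: str = "cell") -> float:
        return self.channel_stats[(channel, compartment)][0]

    def pixel_values(self, channel_image: np.ndarray, compartment: str) -> np.ndarray:
        """Raw pixel values of a full-frame channel over one compartment mask."""
        window = channel_image[self.bbox]
        mask = {
            "nucleus": self.nucleus_mask,
            "cytoplasm": self.cytoplasm_mask,
            "cell": self.cell_mask,
        }[compartment]
        return window[mask]


def _drop_small(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    lbl, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return (sizes >= min_area)[lbl]


def segment_nuclei(
    dapi_channel: np.ndarray,
    min_area: float = 20.0,
    threshold_offset: float = 0.0,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Label image of disjoint nuclei from the DAPI channel.

    Otsu thresholding (plus an optional offset) finds foreground; touching
    nuclei are split by a watershed seeded at the peaks of the smoothed
    distance transform.  A blank or nucleus-free channel yields an empty label
    image rather than an error.
    """
    img = np.asarray(dapi_channel, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("dapi_channel must be a non-empty 2-D array")
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    empty = np.zeros(img.shape, dtype=np.int32)
    smooth = ndi.gaussian_filter(img, 1.0)
    if np.ptp(smooth) < 1e-9:
        return empty
    fg = smooth > (threshold_otsu(smooth) + threshold_offset)
    # Nuclei are sparse on a cytospin field; a mostly-foreground threshold
    # means Otsu only split the noise floor.
    if not fg.any() or fg.mean() > 0.3:
        return empty
    fg = _drop_small(fg, min_area)
    if not fg.any():
        return empty

    dist = ndi.gaussian_filter(ndi.distance_transform_edt(fg), 1.0)
    blobs, _ = ndi.label(fg)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=blobs, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # A foreground blob can lose its peak to a flat plateau; keep it as one nucleus.
    missing = np.setdiff1d(np.unique(blobs[fg]), np.unique(blobs[markers > 0]))
    next_id = len(peaks) + 1
    for b in missing:
        pos = np.argwhere(blobs == b)[0]
        markers[pos[0], pos[1]] = next_id
        next_id += 1
    labels = watershed(-dist, markers, mask=fg).astype(np.int32)

    # Drop fragments below min_area and relabel densely.
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def estimate_background_threshold(
    channel: np.ndarray, exclude_mask: np.ndarray | None = None, k: float = 5.0
) -> float:
    """Positivity threshold: background mean + k * sd over non-excluded pixels."""
    px = np.asarray(channel, dtype=float)
    if exclude_mask is not None:
        px = px[~exclude_mask]
    if px.size == 0:
        raise ValueError("no background pixels available")
    return float(px.mean() + k * px.std())


def segment_cell(
    ck_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    dilation_limit: float = 12.0,
    ck_threshold: float | None = None,
    fallback_dilation: int = 2,
) -> np.ndarray:
    """Full-frame boolean cell mask for one nucleus.

    The cell is the nucleus plus the CK-positive region connected to it,
    truncated at ``dilation_limit`` px from the nucleus boundary.  When no CK
    signal adjoins the nucleus (a CK-negative cell), the cell defaults to the
    nucleus dilated by ``fallback_dilation`` px.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    ck = np.asarray(ck_channel, dtype=float)
    if ck_threshold is None:
        ck_threshold = estimate_background_threshold(ck, exclude_mask=nucleus_mask)

    # Work on a window around the nucleus for speed.
    pad = int(math.ceil(dilation_limit)) + fallback_dilation + 2
    rows, cols = np.nonzero(nucleus_mask)
    r0, r1 = max(0, rows.min() - pad), min(ck.shape[0], rows.max() + pad + 1)
    c0, c1 = max(0, cols.min() - pad), min(ck.shape[1], cols.max() + pad + 1)
    win = (slice(r0, r1), slice(c0, c1))
    nuc_w = nucleus_mask[win]
    fg = (ck[win] > ck_threshold) | nuc_w
    lbl, _ = ndi.label(fg)
    seed_label = lbl[nuc_w][0]
    cell_w = lbl == seed_label
    cell_w &= ndi.distance_transform_edt(~nuc_w) <= dilation_limit
    cell_w |= nuc_w
    if not (cell_w & ~nuc_w).any():
        cell_w = ndi.binary_dilation(nuc_w, structure=disk(fallback_dilation))

    cell = np.zeros_like(nucleus_mask)
    cell[win] = cell_w
    cell |= nucleus_mask
    return cell


def compute_morphology(
    cell: CellRecord, channels: Mapping[str, np.ndarray] | None = None
) -> CellRecord:
    """Fill areas, equivalent diameter, N:C ratio and per-channel summaries.

    The equivalent diameter is that of a circle with the cell's area; the N:C
    ratio is nucleus area over cell area, in (0, 1].
    """
    if not cell.nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    cell.nucleus_area = float(cell.nucleus_mask.sum())
    cell.cell_area = float(cell.cell_mask.sum())
    cell.equivalent_diameter = 2.0 * math.sqrt(cell.cell_area / math.pi)
    cell.nc_ratio = cell.nucleus_area / cell.cell_area
    rows, cols = np.nonzero(cell.nucleus_mask)
    cell.centroid = (
        float(rows.mean() + cell.bbox[0].start),
        float(cols.mean() + cell.bbox[1].start),
    )
    if channels:
        interior = ndi.binary_erosion(cell.cell_mask, structure=disk(2))
        if not interior.any():
            interior = cell.nucleus_mask
        compartments = {
            "nucleus": cell.nucleus_mask,
            "cytoplasm": cell.cytoplasm_mask,
            "cell": cell.cell_mask,
            "interior": interior,
        }
        for name, image in channels.items():
            window = np.asarray(image, dtype=float)[cell.bbox]
            for comp, mask in compartments.items():
                if mask.any():
                    vals = window[mask]
                    cell.channel_stats[(name, comp)] = (float(vals.mean()), float(vals.sum()))
                else:
                    cell.channel_stats[(name, comp)] = (0.0, 0.0)
    return cell


def extract_cells(
    labels: np.ndarray,
    ck_channel: np.ndarray,
    channels: Mapping[str, np.ndarray],
    dilation_limit: float = 12.0,
    ck_threshold: float | None = None,
) -> list[CellRecord]:
    """Segment the cell body of every labelled nucleus and compute features."""
    if ck_threshold is None:
        ck_threshold = estimate_background_threshold(ck_channel, exclude_mask=labels > 0)
    h, w = labels.shape
    records: list[CellRecord] = []
    for prop in regionprops(labels):
        full_nuc = labels == prop.label
        full_cell = segment_cell(
            ck_channel, full_nuc, dilation_limit=dilation_limit, ck_threshold=ck_threshold
        )
        rows, cols = np.nonzero(full_cell)
        bbox = (
            slice(int(rows.min()), int(rows.max()) + 1),
            slice(int(cols.min()), int(cols.max()) + 1),
        )
        on_border = (
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        rec = CellRecord(
            cell_id=int(prop.label),
            bbox=bbox,
            nucleus_mask=full_nuc[bbox],
            cell_mask=full_cell[bbox],
            on_border=bool(on_border),
        )
        records.append(compute_morphology(rec, channels))
    return records
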