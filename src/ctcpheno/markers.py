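"""ALDH1 exposure-time quantification and TWIST subcellular localization.

The imaging platform this package models reports marker expression as the
exposure time needed to detect a fluorescent signal: a brighter cell needs a
shorter exposure, so *lower* values mean *stronger* expression.  Exposure
readouts are quantized to a step-5 grid.  Per-cell ALDH1 levels (high / low /
negative) are assigned by cut-offs calibrated from labelled control cells;
TWIST is scored by where the signal sits: nuclear (regardless of any
cytoplasmic co-localization), exclusively cytoplasmic, or absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GRID_STEP = 5
#: Conversion constant of the default exposure map ``exposure = c / (I + eps)``.
#: With 16-bit intensities this puts the whole calibration grid (5..90+)
#: in the range ~600..12000 intensity units.
DEFAULT_EXPOSURE_SCALE = 60_000.0

ALDH1_LEVELS = ("high", "low", "neg")
TWIST_LOCS = ("nuc", "cyt", "neg")


@dataclass(frozen=True)
class ClassStats:
    """Observed exposure statistics of one labelled control-cell class."""

    lo: float
    hi: float
    median: float
    se: float
    n: int


@dataclass
class CalibrationModel:
    """Monotone map from mean intensity to exposure units plus class cut-offs.

    The exposure map is ``quantize_5(clip(scale / (intensity + eps)))``:
    strictly decreasing in intensity before quantization, then snapped to the
    step-5 grid and clipped to ``[GRID_STEP, max_exposure]``.

    Cut-offs follow the control-cell calibration convention: exposures at or
    below ``high_max`` are *high* expression, ``low_min..low_max`` is *low*,
    and ``neg_min`` or above is *negative*.  Grid values falling in the gaps
    (e.g. between ``high_max`` and ``low_min``) are unreachable from a
    well-calibrated model and are treated as errors.
    """

    scale: float = DEFAULT_EXPOSURE_SCALE
    high_max: int = 25
    low_min: int = 30
    low_max: int = 55
    neg_min: int = 60
    max_exposure: int = 90
    eps: float = 1.0
    class_stats: dict[str, ClassStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.high_max < self.low_min <= self.low_max < self.neg_min):
            raise ValueError(
                "cut-offs must satisfy high_max < low_min <= low_max < neg_min; "
                f"got {self.high_max}, {self.low_min}, {self.low_max}, {self.neg_min}"
            )
        for name in ("high_max", "low_min", "low_max", "neg_min", "max_exposure"):
            v = getattr(self, name)
            if v % GRID_STEP != 0:
                raise ValueError(f"{name}={v} is not a multiple of {GRID_STEP}")
        if self.max_exposure < self.neg_min:
            raise ValueError("max_exposure must reach into the negative class")
        if self.scale <= 0 or self.eps <= 0:
            raise ValueError("scale and eps must be positive")

    def intensity_for(self, exposure: float) -> float:
        """Inverse of the (unquantized) exposure map; used to render synthetic cells."""
        if exposure <= 0:
            raise ValueError("exposure must be positive")
        return self.scale / exposure - self.eps

    def grid_values(self, lo: int, hi: int) -> np.ndarray:
        """All grid exposures in ``[lo, hi]`` inclusive."""
        return np.arange(lo, hi + 1, GRID_STEP)


def quantize_exposure(raw: float, max_exposure: int) -> int:
    """Snap a raw exposure to the step-5 grid, clipped to ``[5, max_exposure]``."""
    q = GRID_STEP * math.floor(raw / GRID_STEP + 0.5)
    return int(min(max(q, GRID_STEP), max_exposure))


def intensity_to_exposure(mean_intensity: float, model: CalibrationModel) -> int:
    """Exposure-equivalent of a background-subtracted mean intensity.

    Brighter input gives a smaller-or-equal output; zero intensity saturates
    at the model's maximum grid value.
    """
    if not np.isfinite(mean_intensity) or mean_intensity < 0:
        raise ValueError(f"mean intensity must be finite and >= 0, got {mean_intensity}")
    raw = model.scale / (mean_intensity + model.eps)
    return quantize_exposure(raw, model.max_exposure)


def classify_aldh1(exposure: float, model: CalibrationModel) -> str:
    """Assign high / low / neg from a grid exposure value.

    Off-grid values and values in the calibration gaps are rejected: they are
    unreachable after quantization and indicate a mis-calibrated model.
    """
    if exposure % GRID_STEP != 0 or exposure < GRID_STEP:
        raise ValueError(f"exposure {exposure} is not on the step-{GRID_STEP} grid")
    if exposure <= model.high_max:
        return "high"
    if model.low_min <= exposure <= model.low_max:
        return "low"
    if exposure >= model.neg_min:
        return "neg"
    raise ValueError(
        f"exposure {exposure} falls in a calibration gap "
        f"({model.high_max}..{model.low_min} or {model.low_max}..{model.neg_min})"
    )


def derive_cutoffs(
    labeled_measurements: Mapping[str, Sequence[float]],
    *,
    scale: float = DEFAULT_EXPOSURE_SCALE,
) -> CalibrationModel:
    """Calibrate class cut-offs from labelled control-cell exposures.

    ``labeled_measurements`` maps each class name (``high``, ``low``, ``neg``)
    to the exposure values measured on control cells carrying that label.
    Cut-offs are the observed class boundaries; per-class range, median and
    standard error are retained on the model.  Overlapping class ranges are an
    error — the calibration is only usable when the classes separate.
    """
    missing = [c for c in ALDH1_LEVELS if c not in labeled_measurements]
    if missing:
        raise ValueError(f"missing control classes: {missing}")
    stats: dict[str, ClassStats] = {}
    for cls in ALDH1_LEVELS:
        vals = np.asarray(list(labeled_measurements[cls]), dtype=float)
        if vals.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 measurements")
        if np.any(vals % GRID_STEP != 0) or np.any(vals < GRID_STEP):
            raise ValueError(f"class {cls!r} has off-grid exposure values")
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        stats[cls] = ClassStats(
            lo=float(vals.min()),
            hi=float(vals.max()),
            median=float(np.median(vals)),
            se=se,
            n=int(vals.size),
        )
    for a, b in (("high", "low"), ("low", "neg")):
        if stats[a].hi >= stats[b].lo:
            raise ValueError(
                f"class ranges overlap: {a} [{stats[a].lo}, {stats[a].hi}] vs "
                f"{b} [{stats[b].lo}, {stats[b].hi}]"
            )
    return CalibrationModel(
        scale=scale,
        high_max=int(stats["high"].hi),
        low_min=int(stats["low"].lo),
        low_max=int(stats["low"].hi),
        neg_min=int(stats["neg"].lo),
        max_exposure=int(stats["neg"].hi),
        class_stats=stats,
    )


@dataclass(frozen=True)
class MarkerCall:
    """Per-cell marker readout: ALDH1 level and TWIST localization."""

    aldh1_exposure: int
    aldh1_level: str
    twist_nuclear_detected: bool
    twist_cytoplasmic_detected: bool
    twist_loc: str


def twist_localization(nuclear_detected: bool, cytoplasmic_detected: bool) -> str:
    """Localization rule: nuclear wins regardless of cytoplasmic co-localization;
    *cyt* requires signal exclusively in the cytoplasm."""
    if nuclear_detected:
        return "nuc"
    if cytoplasmic_detected:
        return "cyt"
    return "neg"


def classify_twist(
    nucleus_values: np.ndarray,
    cytoplasm_values: np.ndarray,
    detection_threshold: float,
    min_positive_fraction: float = 0.3,
) -> tuple[bool, bool, str]:
    """Detect TWIST per compartment and assign its localization.

    A compartment is positive when at least ``min_positive_fraction`` of its
    pixels exceed ``detection_threshold``.  An empty cytoplasm mask simply
    yields cytoplasmic-not-detected.
    """
    if not 0 < min_positive_fraction <= 1:
        raise ValueError("min_positive_fraction must be in (0, 1]")
    nucleus_values = np.asarray(nucleus_values, dtype=float)
    cytoplasm_values = np.asarray(cytoplasm_values, dtype=float)
    if nucleus_values.size == 0:
        raise ValueError("nucleus mask is empty")
    nuc = float(np.mean(nucleus_values > detection_threshold)) >= min_positive_fraction
    if cytoplasm_values.size == 0:
        cyt = False
    else:
        cyt = float(np.mean(cytoplasm_values > detection_threshold)) >= min_positive_fraction
    return nuc, cyt, twist_localization(nuc, cyt)


def make_marker_call(
    mean_aldh1_intensity: float,
    nucleus_twist: np.ndarray,
    cytoplasm_twist: np.ndarray,
    model: CalibrationModel,
    twist_threshold: float,
    min_positive_fraction: float = 0.3,
) -> MarkerCall:
    """Full per-cell marker call from background-subtracted intensities."""
    exposure = intensity_to_exposure(mean_aldh1_intensity, model)
    level = classify_aldh1(exposure, model)
    nuc, cyt, loc = classify_twist(
        nucleus_twist, cytoplasm_twist, twist_threshold, min_positive_fraction
    )
    return MarkerCall(
        aldh1_exposure=exposure,
        aldh1_level=level,
        twist_nuclear_detected=nuc,
        twist_cytoplasmic_detected=cyt,
        twist_loc=loc,
    )
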