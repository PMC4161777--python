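"""Synthetic cytospin images, spike-in experiments and cohort count tables.

Real input to this pipeline is a cytospin slide: a dense lawn of peripheral
blood mononuclear cells (PBMCs) with, rarely, a few tumour cells, imaged in
four fluorescence channels (DAPI nuclei, pan-cytokeratin, ALDH1, TWIST).  No
public image set accompanies the assay, so everything downstream is exercised
on simulated slides with known ground truth.

Scale conventions (nominal 1 px = 1 µm): PBMC nuclei ~8 px across with the
cell body little more than the nucleus; tumour cells ~18 px across with a
high nuclear-to-cytoplasmic area ratio.  A slide carries hundreds to a few
thousand PBMCs per synthetic field rather than the 250,000 of a physical
cytospin; patient-scale material is represented as many fields.  Intensities
live on the 16-bit camera range, and ALDH1 levels are rendered through the
inverse of the exposure-time calibration map so that classification is
round-trippable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi

from .markers import GRID_STEP, CalibrationModel
from .reference_data import ALDH1_CALIBRATION_TABLE

CHANNEL_NAMES = ("dapi", "ck", "aldh1", "twist")
CHANNEL_NAMES_CD45 = ("dapi", "ck", "cd45")

PHENOTYPE_ORDER = ("high_nuc", "high_cytneg", "lowneg_nuc", "lowneg_cytneg")

#: Study conditions of the two clinical settings: detection rate, mean CTC
#: burden of detected patients, and the pooled four-phenotype mix
#: (high/nuc, high/cyt-neg, low-neg/nuc, low-neg/cyt-neg).
EARLY_COHORT = dict(
    setting="early",
    n_patients=80,
    detection_rate=0.163,
    mean_ctc=31 / 13,
    phenotype_probs=(0.129, 0.258, 0.194, 0.419),
)
METASTATIC_COHORT = dict(
    setting="metastatic",
    n_patients=50,
    detection_rate=0.50,
    mean_ctc=91 / 25,
    phenotype_probs=(0.615, 0.220, 0.088, 0.077),
)


@dataclass(frozen=True)
class GroundTruthCell:
    """True identity of one rendered cell."""

    centre: tuple[float, float] | None  # (row, col); None = place automatically
    cell_kind: str  # "pbmc" | "tumour"
    true_aldh1_level: str = "neg"  # high | low | neg
    true_twist_loc: str = "neg"  # nuc | cyt | neg
    ck_positive: bool = False

    def __post_init__(self) -> None:
        if self.cell_kind not in ("pbmc", "tumour"):
            raise ValueError(f"unknown cell kind {self.cell_kind!r}")
        if self.cell_kind == "pbmc" and self.ck_positive:
            raise ValueError("PBMCs are cytokeratin-negative by definition")
        if self.true_aldh1_level not in ("high", "low", "neg"):
            raise ValueError(f"bad ALDH1 level {self.true_aldh1_level!r}")
        if self.true_twist_loc not in ("nuc", "cyt", "neg"):
            raise ValueError(f"bad TWIST localization {self.true_twist_loc!r}")

    @property
    def phenotype(self) -> str:
        a = "high" if self.true_aldh1_level == "high" else "lowneg"
        t = "nuc" if self.true_twist_loc == "nuc" else "cytneg"
        return f"{a}_{t}"


def tumour_cell(aldh1: str, twist: str, centre=None) -> GroundTruthCell:
    """Convenience constructor for a spiked tumour cell."""
    return GroundTruthCell(
        centre=centre,
        cell_kind="tumour",
        true_aldh1_level=aldh1,
        true_twist_loc=twist,
        ck_positive=True,
    )


@dataclass
class SimConfig:
    """Parameters of one synthetic cytospin field."""

    image_size: tuple[int, int] = (1024, 1024)
    n_pbmc: int = 800
    pbmc_nucleus_diameter: tuple[float, float] = (8.0, 0.7)  # mean, sd (px)
    tumour_cell_diameter: tuple[float, float] = (18.0, 1.0)  # mean, sd (px)
    tumour_nc_ratio: float = 0.7  # nucleus area / cell area
    #: (mean, sd) intensity of diffuse PBMC marker expression, per channel.
    pbmc_marker_background: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"aldh1": (600.0, 200.0), "twist": (500.0, 200.0)}
    )
    noise_sd: float = 60.0
    background_offset: float = 100.0
    dapi_amplitude: tuple[float, float] = (25000.0, 3000.0)
    ck_amplitude: tuple[float, float] = (12000.0, 1500.0)
    twist_amplitude: tuple[float, float] = (9000.0, 1000.0)
    #: fraction of the nuclear TWIST amplitude also rendered in the cytoplasm
    #: of TWIST-nuclear cells (the co-localization case).
    twist_cyt_coexpression: float = 0.6
    pixel_size_um: float = 1.0
    cell_margin: float = 4.0  # minimum edge-to-edge spacing between cells, px
    max_cells: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive in both dimensions")
        if self.tumour_cell_diameter[0] <= self.pbmc_nucleus_diameter[0]:
            raise ValueError("tumour cells must be larger than PBMCs on average")
        if not 0 < self.tumour_nc_ratio <= 1:
            raise ValueError("tumour_nc_ratio must be in (0, 1]")
        if min(self.pbmc_nucleus_diameter[1], self.tumour_cell_diameter[1]) < 0:
            raise ValueError("diameter sds must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_pbmc < 0:
            raise ValueError("n_pbmc must be >= 0")


@dataclass
class CytospinImage:
    """A multi-channel field of view plus its ground truth."""

    channels: np.ndarray  # (C, H, W) uint16
    channel_names: tuple[str, ...]
    pixel_size_um: float
    cells: list[GroundTruthCell]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


# ---------------------------------------------------------------------------
# rendering


def _disc_profile(shape, centre, radius):
    """Boolean disc mask on a local window."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def _add_disc(channel, centre, radius, value):
    """Add a flat disc of intensity onto a full-frame float channel."""
    h, w = channel.shape
    r = int(math.ceil(radius)) + 2
    r0, r1 = max(0, int(centre[0]) - r), min(h, int(centre[0]) + r + 1)
    c0, c1 = max(0, int(centre[1]) - r), min(w, int(centre[1]) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    local = _disc_profile((r1 - r0, c1 - c0), (centre[0] - r0, centre[1] - c0), radius)
    channel[r0:r1, c0:c1][local] += value


def _add_annulus(channel, centre, r_inner, r_outer, value):
    h, w = channel.shape
    r = int(math.ceil(r_outer)) + 2
    r0, r1 = max(0, int(centre[0]) - r), min(h, int(centre[0]) + r + 1)
    c0, c1 = max(0, int(centre[1]) - r), min(w, int(centre[1]) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[: r1 - r0, : c1 - c0]
    d2 = (rr - (centre[0] - r0)) ** 2 + (cc - (centre[1] - c0)) ** 2
    local = (d2 <= r_outer**2) & (d2 > r_inner**2)
    channel[r0:r1, c0:c1][local] += value


class _Placer:
    """Greedy non-overlapping placement with a uniform grid for neighbour lookup."""

    def __init__(self, shape, margin, rng):
        self.shape = shape
        self.margin = margin
        self.rng = rng
        self.cell = 24.0
        self.grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, p):
        return (int(p[0] // self.cell), int(p[1] // self.cell))

    def _conflicts(self, p, radius):
        k = self._key(p)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (r, c, rad) in self.grid.get((k[0] + di, k[1] + dj), ()):
                    if (p[0] - r) ** 2 + (p[1] - c) ** 2 < (radius + rad + self.margin) ** 2:
                        return True
        return False

    def insert(self, p, radius):
        if self._conflicts(p, radius):
            raise ValueError(
                f"cell at {p} overlaps an existing cell beyond the packing limit"
            )
        self.grid.setdefault(self._key(p), []).append((p[0], p[1], radius))

    def sample(self, radius, max_tries=200):
        h, w = self.shape
        lo = radius + 1
        for _ in range(max_tries):
            p = (
                float(self.rng.uniform(lo, h - lo)),
                float(self.rng.uniform(lo, w - lo)),
            )
            if not self._conflicts(p, radius):
                self.grid.setdefault(self._key(p), []).append((p[0], p[1], radius))
                return p
        raise ValueError(
            "could not place cell without overlap; image too crowded "
            f"(shape {self.shape}, {sum(map(len, self.grid.values()))} cells placed)"
        )


def _aldh1_target_intensity(level: str, model: CalibrationModel, rng) -> float:
    """Rendered ALDH1 intensity for a target expression level.

    The target exposure is drawn uniformly from the grid values of the level's
    calibrated range, then pushed through the inverse exposure map, so the
    measured mean intensity quantizes back into the same class.
    """
    lo, hi = {
        "high": (GRID_STEP, model.high_max),
        "low": (model.low_min, model.low_max),
        "neg": (model.neg_min, model.max_exposure),
    }[level]
    exposure = float(rng.choice(model.grid_values(lo, hi)))
    return model.intensity_for(exposure)


def generate_cytospin(
    config: SimConfig,
    spiked: Sequence[GroundTruthCell] = (),
    calibration: CalibrationModel | None = None,
) -> CytospinImage:
    """Render a four-channel synthetic cytospin field.

    Every cell gets a DAPI nucleus.  Tumour cells additionally get a
    cytokeratin cytoplasm (annulus between nucleus and cell boundary), a
    whole-cell ALDH1 intensity drawn from the calibrated level distribution,
    and TWIST in the nucleus and/or cytoplasm according to the cell's true
    localization.  PBMCs are CK-negative with diffuse low ALDH1/TWIST
    background.  Gaussian read noise (``noise_sd``) is added on top of a
    constant camera offset.

    The per-cell random streams are spawned from the config seed, so the same
    seed reproduces the image bit for bit and appending a spiked cell does not
    reshuffle the appearance of existing cells.
    """
    model = calibration or CalibrationModel()
    h, w = config.image_size
    n_cells = config.n_pbmc + len(spiked)
    if n_cells > config.max_cells:
        raise ValueError(f"{n_cells} cells exceeds max_cells={config.max_cells}")

    root = np.random.SeedSequence(config.seed)
    ss_place, ss_noise, ss_cells = root.spawn(3)
    place_rng = np.random.default_rng(ss_place)
    placer = _Placer((h, w), config.cell_margin, place_rng)

    # Order: spiked tumour cells first (fixed centres honoured), then PBMCs.
    kinds: list[GroundTruthCell] = list(spiked) + [
        GroundTruthCell(centre=None, cell_kind="pbmc") for _ in range(config.n_pbmc)
    ]
    cell_seeds = ss_cells.spawn(len(kinds))

    dapi = np.zeros((h, w), dtype=float)
    ck = np.zeros((h, w), dtype=float)
    aldh1 = np.zeros((h, w), dtype=float)
    twist = np.zeros((h, w), dtype=float)

    placed: list[GroundTruthCell] = []
    for gt, seed in zip(kinds, cell_seeds):
        rng = np.random.default_rng(seed)
        if gt.cell_kind == "tumour":
            d = max(6.0, rng.normal(*config.tumour_cell_diameter))
            r_cell = d / 2.0
            r_nuc = r_cell * math.sqrt(config.tumour_nc_ratio)
        else:
            d = max(4.0, rng.normal(*config.pbmc_nucleus_diameter))
            r_nuc = d / 2.0
            r_cell = r_nuc + 1.0  # scant PBMC cytoplasm
        if gt.centre is None:
            centre = placer.sample(r_cell)
        else:
            centre = (float(gt.centre[0]), float(gt.centre[1]))
            if not (r_cell < centre[0] < h - r_cell and r_cell < centre[1] < w - r_cell):
                raise ValueError(f"spiked centre {centre} does not fit in the image")
            placer.insert(centre, r_cell)
        gt = replace(gt, centre=centre)
        placed.append(gt)

        _add_disc(dapi, centre, r_nuc, max(0.0, rng.normal(*config.dapi_amplitude)))
        if gt.cell_kind == "tumour":
            _add_annulus(ck, centre, r_nuc, r_cell, max(0.0, rng.normal(*config.ck_amplitude)))
            _add_disc(aldh1, centre, r_cell, _aldh1_target_intensity(gt.true_aldh1_level, model, rng))
            amp = max(0.0, rng.normal(*config.twist_amplitude))
            if gt.true_twist_loc == "nuc":
                _add_disc(twist, centre, r_nuc, amp)
                _add_annulus(twist, centre, r_nuc, r_cell, amp * config.twist_cyt_coexpression)
            elif gt.true_twist_loc == "cyt":
                _add_annulus(twist, centre, r_nuc, r_cell, amp)
        else:
            a_mu, a_sd = config.pbmc_marker_background["aldh1"]
            t_mu, t_sd = config.pbmc_marker_background["twist"]
            _add_disc(aldh1, centre, r_cell, max(0.0, rng.normal(a_mu, a_sd)))
            _add_disc(twist, centre, r_cell, max(0.0, rng.normal(t_mu, t_sd)))

    # Soft edges for the channels segmentation sees; marker channels stay flat
    # so compartment means remain exactly the rendered values.
    dapi = ndi.gaussian_filter(dapi, 0.8)
    ck = ndi.gaussian_filter(ck, 0.8)

    noise_rng = np.random.default_rng(ss_noise)
    stack = np.stack([dapi, ck, aldh1, twist])
    stack += config.background_offset
    if config.noise_sd > 0:
        stack += noise_rng.normal(0.0, config.noise_sd, size=stack.shape)
    stack = np.clip(stack, 0, 65535).astype(np.uint16)
    return CytospinImage(
        channels=stack,
        channel_names=CHANNEL_NAMES,
        pixel_size_um=config.pixel_size_um,
        cells=placed,
    )


def generate_cytospin_cd45(
    config: SimConfig, spiked: Sequence[GroundTruthCell] = ()
) -> CytospinImage:
    """Double-stain QC variant of a field: DAPI / pan-cytokeratin / CD45.

    CD45 (the common leukocyte antigen) is rendered over PBMC cell bodies and
    absent from tumour cells, so CK-positive haematopoietic cells can be
    excluded downstream.  Geometry and the DAPI/CK channels follow the same
    per-cell streams as the triple-stain renderer.
    """
    base = generate_cytospin(config, spiked)
    h, w = config.image_size
    cd45 = np.zeros((h, w), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 45]))
    r_pbmc = config.pbmc_nucleus_diameter[0] / 2.0 + 1.0
    for gt in base.cells:
        if gt.cell_kind == "pbmc":
            _add_disc(cd45, gt.centre, r_pbmc, max(0.0, rng.normal(8000.0, 1000.0)))
    cd45 += config.background_offset
    if config.noise_sd > 0:
        cd45 += rng.normal(0.0, config.noise_sd, size=cd45.shape)
    channels = np.stack(
        [base.channel("dapi"), base.channel("ck"), np.clip(cd45, 0, 65535).astype(np.uint16)]
    )
    return CytospinImage(
        channels=channels,
        channel_names=CHANNEL_NAMES_CD45,
        pixel_size_um=config.pixel_size_um,
        cells=base.cells,
    )


def generate_control_measurements(
    ranges: dict[str, tuple[int, int, int]] | None = None,
    n_per_class: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, list[int]]:
    """Labelled control-cell exposure sets for cut-off calibration.

    Emulates measuring a fixed number of control cells per expression class
    (high / low / negative) on the exposure grid.  ``ranges`` maps each class
    to ``(lo, hi, median)``; the default is the positive-control cell line's
    published calibration row.  With ``noise_sd == 0`` the sets are
    deterministic — every grid value of the class range appears and the class
    median is exact.  With noise, measurements are drawn around the class
    median (sd ``noise_sd`` grid steps), snapped to the grid and clipped to
    the class range, as the labelling instrument itself would do.
    """
    if ranges is None:
        ranges = ALDH1_CALIBRATION_TABLE["HepG2"]
    rng = np.random.default_rng(seed)
    out: dict[str, list[int]] = {}
    for cls, (lo, hi, med) in ranges.items():
        grid = list(range(lo, hi + 1, GRID_STEP))
        if len(grid) > n_per_class:
            raise ValueError(f"n_per_class too small to span the {cls} range")
        if noise_sd == 0:
            vals = grid + [med] * (n_per_class - len(grid))
        else:
            draws = rng.normal(med, noise_sd * GRID_STEP, size=n_per_class)
            snapped = GRID_STEP * np.floor(draws / GRID_STEP + 0.5)
            vals = np.clip(snapped, lo, hi).astype(int).tolist()
        out[cls] = vals
    return out


# ---------------------------------------------------------------------------
# spike-in recovery experiment


def simulate_spike_in(
    concentration: float,
    stage_retention: Sequence[float],
    n_replicates: int = 3,
    seed: int = 0,
    pbmc_millions: float = 10.0,
) -> np.ndarray:
    """Simulated analogue of a tumour-cell spiking experiment.

    ``concentration`` is spiked cells per 10^6 PBMCs; ``pbmc_millions`` scales
    it to an absolute cell count per replicate.  Each spiked cell survives the
    processing stages (density-gradient separation, washes, cytocentrifugation,
    staining...) independently, with the product of the per-stage retention
    probabilities.  Returns the recovery fraction per replicate.
    """
    stage_retention = list(stage_retention)
    if not stage_retention:
        raise ValueError("stage_retention must not be empty")
    if any(not 0 <= p <= 1 for p in stage_retention):
        raise ValueError("retention probabilities must be in [0, 1]")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    n_spiked = max(1, int(round(concentration * pbmc_millions)))
    p_survive = float(np.prod(stage_retention))
    rng = np.random.default_rng(seed)
    survivors = rng.binomial(n_spiked, p_survive, size=n_replicates)
    return survivors / n_spiked


# ---------------------------------------------------------------------------
# cohort count tables


def generate_cohort_counts(
    setting: str,
    n_patients: int,
    detection_rate: float,
    phenotype_probs: Sequence[float],
    ctc_count_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
    mean_ctc: float = 2.5,
) -> pd.DataFrame:
    """Draw a per-patient phenotype count table with known generating parameters.

    Each patient has a detectable CTC burden with probability
    ``detection_rate``; detected patients draw a total CTC count (support >= 1,
    zero-truncated Poisson by default with mean ``mean_ctc``) and split it
    multinomially across the four phenotypes.
    """
    probs = np.asarray(phenotype_probs, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("phenotype_probs must be 4 non-negative values summing to 1")
    if not 0 <= detection_rate <= 1:
        raise ValueError("detection_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if ctc_count_sampler is None:
        def ctc_count_sampler(r: np.random.Generator) -> int:
            # zero-truncated Poisson via rejection; support >= 1
            lam = max(mean_ctc, 1.0 + 1e-9)
            while True:
                k = int(r.poisson(lam - 1.0)) + 1
                if k >= 1:
                    return k

    rows = []
    for i in range(n_patients):
        detected = rng.random() < detection_rate
        if detected:
            total = int(ctc_count_sampler(rng))
            if total < 1:
                raise ValueError("ctc_count_sampler must have support >= 1")
            counts = rng.multinomial(total, probs)
        else:
            total, counts = 0, np.zeros(4, dtype=int)
        rows.append(
            {
                "patient_id": f"{setting[:3]}-{i + 1:03d}",
                "setting": setting,
                "total_ctc": total,
                "n_high_nuc": int(counts[0]),
                "n_high_cytneg": int(counts[1]),
                "n_lowneg_nuc": int(counts[2]),
                "n_lowneg_cytneg": int(counts[3]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def write_cytospin(image: CytospinImage, path: str | Path) -> Path:
    """Write a multi-channel TIFF plus a YAML sidecar documenting the channels."""
    path = Path(path)
    tifffile.imwrite(path, image.channels, photometric="minisblack")
    sidecar = path.with_suffix(".yaml")
    meta = {
        "channel_order": list(image.channel_names),
        "pixel_size_um": image.pixel_size_um,
        "ground_truth": [
            {
                "centre_row": gt.centre[0],
                "centre_col": gt.centre[1],
                "cell_kind": gt.cell_kind,
                "true_aldh1_level": gt.true_aldh1_level,
                "true_twist_loc": gt.true_twist_loc,
                "ck_positive": gt.ck_positive,
            }
            for gt in image.cells
        ],
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_cytospin(path: str | Path) -> CytospinImage:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cells = [
        GroundTruthCell(
            centre=(gt["centre_row"], gt["centre_col"]),
            cell_kind=gt["cell_kind"],
            true_aldh1_level=gt["true_aldh1_level"],
            true_twist_loc=gt["true_twist_loc"],
            ck_positive=gt["ck_positive"],
        )
        for gt in meta["ground_truth"]
    ]
    return CytospinImage(
        channels=stack,
        channel_names=tuple(meta["channel_order"]),
        pixel_size_um=meta["pixel_size_um"],
        cells=cells,
    )
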