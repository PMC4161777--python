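import numpy as np
import pytest

import ctcpheno as cp


@pytest.fixture(scope="session")
def spiked_image():
    """One 512x512 field, 200 PBMCs, three tumour cells of known phenotype."""
    cfg = cp.SimConfig(image_size=(512, 512), n_pbmc=200, seed=7)
    spiked = [
        cp.tumour_cell("high", "nuc"),
        cp.tumour_cell("low", "cyt"),
        cp.tumour_cell("neg", "neg"),
    ]
    return cp.generate_cytospin(cfg, spiked)


@pytest.fixture(scope="session")
def spiked_cell_table(spiked_image):
    return cp.analyze_image(spiked_image)


@pytest.fixture(scope="session")
def pure_pbmc_image():
    cfg = cp.SimConfig(image_size=(512, 512), n_pbmc=200, seed=11)
    return cp.generate_cytospin(cfg, [])


def match_ground_truth(cell_table, image):
    """Pair each called CTC with the nearest ground-truth tumour cell."""
    tumours = [c for c in image.cells if c.cell_kind == "tumour"]
    pairs = []
    for _, row in cell_table[cell_table["is_ctc"].astype(bool)].iterrows():
        best = min(
            tumours,
            key=lambda c: (c.centre[0] - row.centroid_row) ** 2
            + (c.centre[1] - row.centroid_col) ** 2,
        )
        pairs.append((row, best))
    return pairs
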