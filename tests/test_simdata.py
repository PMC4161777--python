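"""Synthetic cytospin generator: determinism, ground truth, spike-in, cohorts."""

import numpy as np
import pytest

import ctcpheno as cp
from ctcpheno import simdata as sd


class TestGenerateCytospin:
    def test_pure_pbmc_field_has_no_ck_positive_ground_truth(self, pure_pbmc_image):
        assert len(pure_pbmc_image.cells) == 200
        assert all(not c.ck_positive for c in pure_pbmc_image.cells)
        assert all(c.cell_kind == "pbmc" for c in pure_pbmc_image.cells)

    def test_identical_seed_gives_bit_identical_images(self):
        cfg = cp.SimConfig(image_size=(256, 256), n_pbmc=60, seed=7)
        spiked = [cp.tumour_cell("high", "nuc")]
        a = cp.generate_cytospin(cfg, spiked)
        b = cp.generate_cytospin(cfg, spiked)
        assert np.array_equal(a.channels, b.channels)
        assert [c.centre for c in a.cells] == [c.centre for c in b.cells]

    def test_ground_truth_conserves_spiked_cells(self, spiked_image):
        tumours = [c for c in spiked_image.cells if c.cell_kind == "tumour"]
        assert len(tumours) == 3
        assert sorted(t.phenotype for t in tumours) == sorted(
            ["high_nuc", "lowneg_cytneg", "lowneg_cytneg"]
        )

    def test_tumour_ck_signal_present_pbmc_absent(self, spiked_image):
        ck = spiked_image.channel("ck").astype(float)
        bg = float(np.median(ck))
        for cell in spiked_image.cells:
            r, c = int(cell.centre[0]), int(cell.centre[1])
            # CK lives in the cytoplasm ring, ~just inside the cell boundary
            ring = ck[max(0, r - 9) : r + 10, max(0, c - 9) : c + 10].max()
            if cell.cell_kind == "tumour":
                assert ring > bg + 5000
            else:
                assert ck[r, c] < bg + 1000

    def test_zero_size_image_rejected(self):
        with pytest.raises(ValueError):
            cp.SimConfig(image_size=(0, 128))

    def test_tumour_must_be_larger_than_pbmc(self):
        with pytest.raises(ValueError, match="larger"):
            cp.SimConfig(pbmc_nucleus_diameter=(8, 1), tumour_cell_diameter=(7, 1))

    def test_overlapping_spiked_centres_rejected(self):
        cfg = cp.SimConfig(image_size=(256, 256), n_pbmc=0, seed=0)
        spiked = [
            cp.tumour_cell("high", "nuc", centre=(100.0, 100.0)),
            cp.tumour_cell("low", "cyt", centre=(103.0, 100.0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            cp.generate_cytospin(cfg, spiked)

    def test_spiked_centre_outside_image_rejected(self):
        cfg = cp.SimConfig(image_size=(256, 256), n_pbmc=0, seed=0)
        with pytest.raises(ValueError, match="fit"):
            cp.generate_cytospin(cfg, [cp.tumour_cell("high", "nuc", centre=(2.0, 100.0))])

    def test_tiff_roundtrip(self, tmp_path, spiked_image):
        path = sd.write_cytospin(spiked_image, tmp_path / "field.tiff")
        back = sd.read_cytospin(path)
        assert np.array_equal(back.channels, spiked_image.channels)
        assert back.channel_names == spiked_image.channel_names
        assert len(back.cells) == len(spiked_image.cells)


class TestSimulateSpikeIn:
    def test_perfect_retention_recovers_everything(self):
        rates = cp.simulate_spike_in(10, [1.0, 1.0], n_replicates=5, seed=0)
        assert np.all(rates == 1.0)

    def test_half_retention_within_binomial_error(self):
        # one stage at 0.5 over 10,000 spiked cells: binomial sd = 0.005
        rates = cp.simulate_spike_in(1000, [0.5], n_replicates=1, seed=1, pbmc_millions=10)
        assert abs(rates[0] - 0.5) < 3 * 0.005

    def test_product_rule_for_stage_losses(self):
        rates = cp.simulate_spike_in(1000, [0.9, 0.9], n_replicates=20, seed=2, pbmc_millions=10)
        se = np.sqrt(0.81 * 0.19 / 10_000)
        assert abs(rates.mean() - 0.81) < 4 * se

    def test_empty_retention_list_rejected(self):
        with pytest.raises(ValueError):
            cp.simulate_spike_in(10, [])

    @pytest.mark.parametrize("bad", [[1.2], [-0.1, 0.5]])
    def test_invalid_probability_rejected(self, bad):
        with pytest.raises(ValueError):
            cp.simulate_spike_in(10, bad)


class TestGenerateCohortCounts:
    def test_zero_detection_rate_gives_all_negative(self):
        table = cp.generate_cohort_counts("early", 50, 0.0, (0.25, 0.25, 0.25, 0.25), seed=0)
        assert (table["total_ctc"] == 0).all()

    def test_degenerate_phenotype_probs(self):
        table = cp.generate_cohort_counts("early", 50, 1.0, (1, 0, 0, 0), seed=0)
        assert (table["total_ctc"] == table["n_high_nuc"]).all()
        assert (table["total_ctc"] >= 1).all()

    def test_pooled_fractions_approach_generating_probs(self):
        probs = (0.6, 0.2, 0.1, 0.1)
        table = cp.generate_cohort_counts("early", 10_000, 0.8, probs, seed=3)
        cols = ["n_high_nuc", "n_high_cytneg", "n_lowneg_nuc", "n_lowneg_cytneg"]
        pooled = table[cols].sum().to_numpy(dtype=float)
        frac = pooled / pooled.sum()
        n = pooled.sum()
        for f, p in zip(frac, probs):
            assert abs(f - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            cp.generate_cohort_counts("early", 10, 0.5, (0.5, 0.5, 0.5, 0.5), seed=0)

    def test_seed_determinism(self):
        kw = dict(detection_rate=0.4, phenotype_probs=(0.4, 0.3, 0.2, 0.1), seed=9)
        a = cp.generate_cohort_counts("early", 40, **kw)
        b = cp.generate_cohort_counts("early", 40, **kw)
        assert a.equals(b)


class TestControlMeasurements:
    def test_noise_free_sets_span_ranges_with_exact_medians(self):
        labeled = cp.generate_control_measurements(n_per_class=500)
        for cls, (lo, hi, med) in sd.ALDH1_CALIBRATION_TABLE["HepG2"].items():
            vals = np.asarray(labeled[cls])
            assert vals.min() == lo and vals.max() == hi
            assert np.median(vals) == med
            assert len(vals) == 500
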