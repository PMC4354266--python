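"""Image feature extraction: segmentation recovery, morphology,
neighbour fraction, the 70% core/protrusion rule, texture suites,
ruffliness, QC, and the full 52-feature pipeline."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from phenoglyph.images import (FEATURE_SCHEMA, CellQC, LabeledImage,
                               QCThresholds, RegionTooSmallError,
                               gabor_features, haralick_features,
                               membrane_band, morphology_features,
                               neighbour_fraction, qc_filter, ruffliness,
                               segment_cells, segment_nuclei,
                               split_core_protrusion, ser_features,
                               extract_feature_table)
from phenoglyph.synthetic import (SynthImageSpec, CellBlueprint,
                                  synth_cell_image, two_plateau_cell)

from conftest import jaccard, match_to_truth


class TestSegmentation:
    def test_blank_image_zero_nuclei(self):
        assert segment_nuclei(np.zeros((64, 64))).n_objects == 0

    def test_three_disjoint_blobs_three_labels(self):
        img = np.zeros((128, 128))
        for r, c in [(30, 30), (30, 95), (95, 60)]:
            rr, cc = np.mgrid[0:128, 0:128]
            img[(rr - r) ** 2 + (cc - c) ** 2 < 12 ** 2] = 100.0
        assert segment_nuclei(img).n_objects == 3

    def test_touching_blobs_split_by_watershed(self):
        img = np.zeros((96, 96))
        rr, cc = np.mgrid[0:96, 0:96]
        img[(rr - 48) ** 2 + (cc - 36) ** 2 < 13 ** 2] = 100.0
        img[(rr - 48) ** 2 + (cc - 60) ** 2 < 13 ** 2] = 100.0
        assert segment_nuclei(img).n_objects == 2

    def test_cells_partition_connected_region_and_contain_seeds(self):
        img = np.zeros((96, 96))
        rr, cc = np.mgrid[0:96, 0:96]
        # one bright region containing two nuclei
        region = ((rr - 48) / 26) ** 2 + ((cc - 48) / 40) ** 2 < 1
        img[region] = 100.0
        nuc = np.zeros((96, 96))
        nuc[(rr - 48) ** 2 + (cc - 32) ** 2 < 8 ** 2] = 100.0
        nuc[(rr - 48) ** 2 + (cc - 64) ** 2 < 8 ** 2] = 100.0
        nuclei = segment_nuclei(nuc)
        assert nuclei.n_objects == 2
        cells = segment_cells(img, nuclei)
        assert cells.n_objects == 2
        for lab in (1, 2):
            nm = nuclei.labels == lab
            assert np.array_equal((cells.labels == lab) & nm, nm)

    def test_no_nuclei_no_cells(self):
        nuclei = segment_nuclei(np.zeros((32, 32)))
        assert segment_cells(np.ones((32, 32)), nuclei).n_objects == 0

    def test_planted_objects_recovered_on_clean_fixture(self, clean_image):
        nuclei = segment_nuclei(clean_image["nuclear"])
        cells = segment_cells(clean_image["cell_body"], nuclei)
        assert cells.n_objects == len(clean_image["truth"])
        for t in clean_image["truth"]:
            cm = match_to_truth(cells.labels, clean_image["cell_labels"],
                                t["label"])
            assert jaccard(cm, clean_image["cell_labels"] == t["label"]) \
                >= 0.95
            nm = match_to_truth(nuclei.labels, clean_image["nucleus_labels"],
                                t["label"])
            assert jaccard(nm, clean_image["nucleus_labels"] == t["label"]) \
                >= 0.95


class TestMorphology:
    def test_disc_form_factor_near_one(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 < 20 ** 2
        m = morphology_features(disc)
        assert m["form_factor"] == pytest.approx(1.0, abs=0.05)

    def test_rectangle_axis_ratio_from_second_moments(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 20:30] = True  # 40 x 10
        m = morphology_features(mask)
        assert m["length"] / m["width"] == pytest.approx(4.0, rel=0.02)

    def test_area_scales_with_pixel_size(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        m = morphology_features(mask, pixel_size=0.5)
        assert m["area"] == pytest.approx(25.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            morphology_features(np.zeros((8, 8), dtype=bool))


class TestNeighbourFraction:
    def test_isolated_cell_zero(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:24, 8:24] = 1
        assert neighbour_fraction(LabeledImage(labels))[1] == 0.0

    def test_enclosed_cell_is_one(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:28, 4:28] = 2
        labels[12:20, 12:20] = 1
        assert neighbour_fraction(LabeledImage(labels))[1] == 1.0

    def test_adjacent_squares_pixel_count_oracle(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[10:20, 5:15] = 1
        labels[10:20, 15:25] = 2
        nf = neighbour_fraction(LabeledImage(labels))
        # 10x10 square: 36 border px; 10 of them touch the other square
        assert nf[1] == pytest.approx(10 / 36)
        assert nf[2] == pytest.approx(10 / 36)

    def test_direct_scan_agrees(self, demo_image):
        cells = LabeledImage(demo_image["cell_labels"])
        nf = neighbour_fraction(cells)
        labels = cells.labels
        for lab, value in nf.items():
            mask = labels == lab
            border = mask & ~ndi.binary_erosion(mask, np.ones((3, 3)),
                                                border_value=0)
            count = 0
            for r, c in zip(*np.where(border)):
                window = labels[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                if np.any((window > 0) & (window != lab)):
                    count += 1
            assert value == pytest.approx(count / border.sum())


class TestCoreProtrusionSplit:
    def test_uniform_cell_has_no_protrusion(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        channel = np.where(mask, 50.0, 0.0)
        s = split_core_protrusion(mask, channel)
        assert s["relative_protrusion_area"] == 0.0

    def test_two_plateau_hand_computation(self):
        tp = two_plateau_cell()
        s = split_core_protrusion(tp["mask"], tp["channel"])
        assert s["threshold"] == pytest.approx(57.4)
        assert s["relative_protrusion_area"] == pytest.approx(0.2)

    def test_largest_component_wins(self):
        # two disjoint bright plateaus of 60 and 20 px; dim background 8 px
        mask = np.zeros((30, 30), dtype=bool)
        channel = np.zeros((30, 30))
        mask[2:8, 2:12] = True      # 60 px bright
        channel[2:8, 2:12] = 100.0
        mask[20:22, 2:12] = True    # 20 px bright, disjoint
        channel[20:22, 2:12] = 100.0
        mask[12:14, 2:6] = True     # 8 px dim
        channel[12:14, 2:6] = 5.0
        s = split_core_protrusion(mask, channel)
        assert s["core"].sum() == 60
        assert s["protrusion"].sum() == 28

    def test_brute_force_oracle_small_images(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mask = np.zeros((24, 24), dtype=bool)
            mask[4:20, 4:20] = True
            channel = rng.uniform(10, 100, (24, 24))
            s = split_core_protrusion(mask, channel)
            thr = 0.7 * channel[mask].mean()
            above = mask & (channel > thr)
            comp, n = ndi.label(above, np.ones((3, 3)))
            sizes = [(comp == i).sum() for i in range(1, n + 1)]
            core = comp == (1 + int(np.argmax(sizes)))
            assert np.array_equal(s["core"], core)
            assert s["protrusion_area_px"] == (mask & ~core).sum()


class TestSER:
    def test_constant_region_all_zero(self):
        mask = np.ones((32, 32), dtype=bool)
        vals = ser_features(mask, np.full((32, 32), 7.0))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vals.values())

    def test_bright_gaussian_spot_dominates_edge_at_core(self):
        # analytic: at the blob centre the gradient vanishes while the
        # Hessian trace peaks, so the core region must score spot > edge
        rr, cc = np.mgrid[0:64, 0:64]
        img = 100.0 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 3 ** 2))
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 < 9.1  # central 29 px
        vals = ser_features(mask, img)
        assert vals["spot"] > vals["edge"]
        assert vals["spot"] > vals["hole"]
        assert vals["spot"] > vals["ridge"]

    def test_step_edge_maximal_feature_is_edge(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        mask = np.zeros((64, 64), dtype=bool)
        mask[16:48, 30:34] = True  # 4 px band centred on the step
        vals = ser_features(mask, img)
        assert max(vals, key=vals.get) == "edge"

    def test_region_too_small_raises(self):
        with pytest.raises(RegionTooSmallError):
            ser_features(np.ones((3, 3), dtype=bool), np.zeros((3, 3)))


class TestGabor:
    def test_constant_region_zero(self):
        mask = np.ones((48, 48), dtype=bool)
        vals = gabor_features(mask, np.full((48, 48), 3.0))
        assert all(v == pytest.approx(0.0, abs=1e-18) for v in vals.values())

    def test_grating_peaks_at_matching_wavelength(self):
        cc = np.arange(96)[None, :] * np.ones((96, 1))
        img = 50.0 + 40.0 * np.sin(2 * np.pi * cc / 8.0)
        mask = np.zeros((96, 96), dtype=bool)
        mask[30:66, 30:66] = True
        vals = gabor_features(mask, img)
        best = max(vals, key=vals.get)
        assert best.endswith("_w8")

    def test_rotation_by_90_permutes_orientations(self):
        rng = np.random.default_rng(0)
        img = ndi.gaussian_filter(rng.uniform(0, 100, (80, 80)), 1.0)
        mask = np.zeros((80, 80), dtype=bool)
        mask[30:50, 30:50] = True
        vals = gabor_features(mask, img)
        vals_rot = gabor_features(np.rot90(mask), np.rot90(img))
        for w in (4, 8):
            assert vals_rot[f"gabor_o90_w{w}"] == pytest.approx(
                vals[f"gabor_o0_w{w}"], rel=1e-6)
            assert vals_rot[f"gabor_o45_w{w}"] == pytest.approx(
                vals[f"gabor_o135_w{w}"], rel=1e-6)


class TestHaralick:
    def test_constant_region_degenerate_glcm(self):
        mask = np.ones((16, 16), dtype=bool)
        vals = haralick_features(mask, np.full((16, 16), 9.0))
        assert vals["asm"] == pytest.approx(1.0)
        assert vals["contrast"] == pytest.approx(0.0)
        assert vals["entropy"] == pytest.approx(0.0)

    def test_checkerboard_contrast_closed_form(self):
        rr, cc = np.mgrid[0:16, 0:16]
        img = ((rr + cc) % 2).astype(float) * 10.0
        mask = np.ones((16, 16), dtype=bool)
        vals = haralick_features(mask, img, levels=32)
        # levels 0 and 31: horizontal/vertical pairs (2*240 each,
        # symmetric) always differ by 31 levels, diagonal pairs
        # (2*225 each) never do; pooled over the four directions:
        n_hv, n_diag = 2 * 16 * 15, 2 * 15 * 15
        expected = 31 ** 2 * (2 * n_hv) / (2 * n_hv + 2 * n_diag)
        assert vals["contrast"] == pytest.approx(expected, rel=1e-9)

    def test_entropy_invariant_to_affine_intensity_rescale(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (24, 24))
        mask = np.ones((24, 24), dtype=bool)
        a = haralick_features(mask, img)
        b = haralick_features(mask, 3.0 * img + 17.0)
        assert b["entropy"] == pytest.approx(a["entropy"], rel=1e-9)
        assert b["asm"] == pytest.approx(a["asm"], rel=1e-9)


class TestRuffliness:
    def test_uniform_disc_near_zero(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 < 20 ** 2
        channel = np.full((64, 64), 80.0)
        assert ruffliness(disc, channel) == pytest.approx(0.0, abs=1e-9)

    def test_lower_form_factor_raises_ruffliness(self):
        rr, cc = np.mgrid[0:96, 0:96]
        disc = (rr - 48) ** 2 + (cc - 48) ** 2 < 20 ** 2
        theta = np.arctan2(rr - 48, cc - 48)
        radius = 20 + 6 * np.cos(8 * theta)
        star = (rr - 48) ** 2 + (cc - 48) ** 2 < radius ** 2
        rng = np.random.default_rng(2)
        channel = ndi.gaussian_filter(rng.uniform(0, 100, (96, 96)), 1.0)
        ff_disc = morphology_features(disc)["form_factor"]
        ff_star = morphology_features(star)["form_factor"]
        assert ff_star < ff_disc
        # same membrane texture statistics, rougher outline -> higher score
        r_disc = ruffliness(disc, channel)
        r_star = ruffliness(star, channel)
        edge_disc = ser_features(membrane_band(disc), channel)["edge"]
        edge_star = ser_features(membrane_band(star), channel)["edge"]
        assert r_star / r_disc > (edge_star / edge_disc) * \
            (ff_disc / ff_star) * 0.99

    def test_linear_in_intensity_scale(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 < 20 ** 2
        rng = np.random.default_rng(3)
        channel = rng.uniform(0, 50, (64, 64))
        assert ruffliness(disc, 3.0 * channel) == pytest.approx(
            3.0 * ruffliness(disc, channel), rel=1e-9)


class TestQC:
    @staticmethod
    def _qc(intensity=100.0, area=500.0, border=False):
        return CellQC(mean_nuclear_intensity=intensity, area_px=area,
                      touches_border=border)

    def test_planted_outliers_removed(self):
        qcs = ([self._qc(100 + i) for i in range(6)]
               + [self._qc(300), self._qc(320)]      # mitotic
               + [self._qc(area=50)]                 # small
               + [self._qc(border=True)])            # border
        records = [{"i": i} for i in range(10)]
        kept = qc_filter(records, qcs)
        assert [r["i"] for r in kept] == [0, 1, 2, 3, 4, 5]

    def test_empty_input(self):
        assert qc_filter([], []) == []

    def test_thresholds_configurable(self):
        qcs = [self._qc(area=80.0), self._qc(area=120.0)]
        kept = qc_filter([{"i": 0}, {"i": 1}], qcs,
                         QCThresholds(min_area_px=60.0))
        assert len(kept) == 2


class TestFullPipeline:
    def test_five_cells_52_schema_columns(self, demo_table):
        assert demo_table.data.shape == (5, 52)
        assert list(demo_table.columns) == list(FEATURE_SCHEMA)

    def test_texture_block_is_40_columns(self, demo_table):
        tex = [c for c in demo_table.columns
               if ("ser_" in c or "gabor" in c or "haralick" in c)]
        assert len(tex) == 40
        assert sum(c.startswith("nuc_") for c in tex) == 20
        assert sum(c.startswith("cell_") for c in tex) == 20

    def test_feature_domains(self, demo_table):
        df = demo_table.data
        assert ((df["neighbour_fraction"] >= 0)
                & (df["neighbour_fraction"] <= 1)).all()
        assert ((df["relative_protrusion_area"] >= 0)
                & (df["relative_protrusion_area"] <= 1)).all()
        assert (df["cell_width"] <= df["cell_length"] + 1e-9).all()
        assert (df["nucleus_width"] <= df["nucleus_length"] + 1e-9).all()

    def test_pipeline_deterministic(self, demo_image, demo_table):
        again = extract_feature_table(demo_image["nuclear"],
                                      demo_image["cell_body"])
        assert again.data.equals(demo_table.data)

    def test_border_cell_filtered(self):
        blueprints = (
            CellBlueprint(center=(40, 40), cell_axes=(18, 15),
                          nucleus_axes=(7, 6)),
            CellBlueprint(center=(5, 64), cell_axes=(18, 15),
                          nucleus_axes=(7, 6)),  # touches the border
        )
        img = synth_cell_image(SynthImageSpec(shape=(128, 128),
                                              blueprints=blueprints,
                                              noise_sd=0.0, seed=0))
        table = extract_feature_table(img["nuclear"], img["cell_body"])
        assert len(table.data) == 1
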