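import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsbrain.constants import BACKGROUND, NORMAL, TUMOR, VESSEL
from hsbrain.hsio import HyperCube
from hsbrain.labeling import (GoldStandardMap, TrainingDataset,
                              assemble_dataset, assign_class, dataset_summary,
                              load_dataset, sam_angle, sam_select,
                              save_dataset)


class TestSamAngle:
    def test_identical_spectra_have_zero_angle(self):
        x = np.array([1.0, 2.0, 3.0])
        assert sam_angle(x, x) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(scale=st.floats(1e-3, 1e3),
           seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1.0, size=8)
        y = rng.uniform(0.1, 1.0, size=8)
        assert sam_angle(x, scale * y) == pytest.approx(sam_angle(x, y),
                                                        abs=1e-9)

    def test_orthogonal_spectra(self):
        assert sam_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sam_angle([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sam_angle([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSamSelect:
    @staticmethod
    def _cube():
        rng = np.random.default_rng(9)
        data = rng.uniform(0.1, 1.0, size=(6, 6, 8))
        return HyperCube(data, np.arange(8) + 400.0)

    def test_tiny_threshold_selects_proportional_pixels_only(self):
        cube = self._cube()
        cube.data[3, 3] = 2.0 * cube.data[1, 1]  # proportional -> angle 0
        mask = sam_select(cube, (1, 1), threshold=1e-9)
        expected = np.zeros((6, 6), dtype=bool)
        expected[1, 1] = expected[3, 3] = True
        np.testing.assert_array_equal(mask, expected)

    def test_pi_threshold_selects_all_nonzero(self):
        cube = self._cube()
        cube.data[0, 0] = 0.0
        mask = sam_select(cube, (2, 2), threshold=np.pi)
        assert mask.sum() == 35 and not mask[0, 0]

    def test_matches_brute_force_on_phantom_classes(self, fast_spec):
        """On a two-class phantom slice, thresholding at half the inter-class
        angle selects exactly the same-class pixels found by per-pixel SAM."""
        from hsbrain import calibrate, generate_scene

        scene = generate_scene(fast_spec, seed=3)
        cube = calibrate(scene.raw, scene.refs).cube
        truth = scene.truth.labels
        ref = tuple(np.argwhere(truth == TUMOR)[0])
        normal_px = cube.data[truth == NORMAL]
        ref_spec = cube.data[ref]
        inter = min(sam_angle(p, ref_spec) for p in normal_px)
        thr = inter / 2
        mask = sam_select(cube, ref, thr)
        brute = np.zeros_like(mask)
        for r in range(cube.rows):
            for c in range(cube.cols):
                spec = cube.data[r, c]
                if np.linalg.norm(spec) > 0:
                    brute[r, c] = sam_angle(spec, ref_spec) <= thr
        brute[ref] = True
        np.testing.assert_array_equal(mask, brute)
        # everything selected is tumor-class (or boundary), never normal
        assert not (mask & (truth == NORMAL)).any()

    @settings(derandomize=True, max_examples=15)
    @given(t1=st.floats(0.01, 1.5), t2=st.floats(0.01, 1.5))
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        cube = self._cube()
        small = sam_select(cube, (2, 2), lo)
        big = sam_select(cube, (2, 2), hi)
        assert np.all(big[small])  # small mask is a subset of the big one

    def test_zero_reference_rejected(self):
        cube = self._cube()
        cube.data[4, 4] = 0.0
        with pytest.raises(ValueError, match="zero"):
            sam_select(cube, (4, 4), 0.1)


class TestAssignClass:
    def test_empty_mask_leaves_map_unchanged(self):
        gold = GoldStandardMap.empty(3, 3)
        out = assign_class(gold, np.zeros((3, 3), bool), TUMOR)
        assert out.n_labeled == 0

    def test_disjoint_masks_add_counts(self):
        gold = GoldStandardMap.empty(3, 3)
        m1 = np.zeros((3, 3), bool); m1[0] = True
        m2 = np.zeros((3, 3), bool); m2[2] = True
        out = assign_class(assign_class(gold, m1, NORMAL), m2, TUMOR)
        assert out.class_counts()[NORMAL] == 3
        assert out.class_counts()[TUMOR] == 3
        assert out.n_labeled == 6

    def test_overlap_without_overwrite_is_error(self):
        gold = assign_class(GoldStandardMap.empty(3, 3),
                            np.ones((3, 3), bool), NORMAL)
        with pytest.raises(ValueError, match="overwrite"):
            assign_class(gold, np.ones((3, 3), bool), TUMOR)
        out = assign_class(gold, np.ones((3, 3), bool), TUMOR, overwrite=True)
        assert out.class_counts()[TUMOR] == 9

    def test_illegal_code_rejected(self):
        with pytest.raises(ValueError):
            assign_class(GoldStandardMap.empty(2, 2),
                         np.ones((2, 2), bool), 7)


def _cube_with_labels(n_labeled, code, bands=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = 5
    cols = 5
    cube = HyperCube(rng.uniform(0.1, 1, (rows, cols, bands)),
                     np.arange(bands) + 400.0)
    labels = np.zeros((rows, cols), dtype=np.int32)
    labels.ravel()[:n_labeled] = code
    return cube, GoldStandardMap(labels)


class TestAssembleDataset:
    def test_counts_add_across_cubes(self):
        c1, g1 = _cube_with_labels(10, NORMAL, seed=1)
        c2, g2 = _cube_with_labels(15, TUMOR, seed=2)
        ds = assemble_dataset([(c1, g1, "s1"), (c2, g2, "s2")])
        assert len(ds) == 25
        assert ds.class_counts[NORMAL] == 10
        assert ds.class_counts[TUMOR] == 15
        assert set(ds.groups) == {"s1", "s2"}

    def test_unlabeled_pixels_never_appear(self):
        c1, g1 = _cube_with_labels(7, VESSEL)
        ds = assemble_dataset([(c1, g1, 0)])
        assert len(ds) == 7 == g1.n_labeled

    def test_no_labeled_pixels_is_error(self):
        c1, g1 = _cube_with_labels(0, NORMAL)
        with pytest.raises(ValueError, match="no labeled"):
            assemble_dataset([(c1, g1, 0)])


class TestDatasetSummary:
    def test_published_campaign_totals(self):
        """Per-class/subtype counts matching the 22-patient, 36-capture
        labeling campaign sum to 377,556 signatures."""
        subtype_counts = {
            ("normal", ""): 117242,
            ("tumor", "GBM"): 12641,
            ("tumor", "anaplastic oligodendroglioma"): 1844,
            ("tumor", "lung"): 1936,
            ("tumor", "renal"): 21,
            ("tumor", "breast"): 325,
            ("vessel", ""): 57429,
            ("background", ""): 186118,
        }
        code_by_name = {"normal": NORMAL, "tumor": TUMOR, "vessel": VESSEL,
                        "background": BACKGROUND}
        labels, subtypes = [], []
        for (cls, sub), n in subtype_counts.items():
            labels.append(np.full(n, code_by_name[cls]))
            subtypes.append(np.full(n, sub, dtype=object))
        labels = np.concatenate(labels)
        subtypes = np.concatenate(subtypes)
        ds = TrainingDataset(np.zeros((len(labels), 1)), labels,
                             np.zeros(len(labels)), subtypes=subtypes)
        table = dataset_summary(ds)
        total = int(table.loc[table["class"] == "total", "pixels"].iloc[0])
        assert total == 377556 == len(ds)
        gbm = table[(table["class"] == "tumor") & (table["subtype"] == "GBM")]
        assert int(gbm["pixels"].iloc[0]) == 12641

    def test_total_row_conserves_n(self):
        c1, g1 = _cube_with_labels(12, NORMAL)
        ds = assemble_dataset([(c1, g1, 0)])
        table = dataset_summary(ds)
        assert int(table["pixels"].iloc[-1]) == len(ds)

    def test_single_class_total(self):
        c1, g1 = _cube_with_labels(5, BACKGROUND)
        ds = assemble_dataset([(c1, g1, 0)])
        table = dataset_summary(ds)
        assert len(table) == 2  # one class row + total
        assert int(table["pixels"].iloc[0]) == 5


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path):
        c1, g1 = _cube_with_labels(9, TUMOR)
        ds = assemble_dataset([(c1, g1, 3)])
        save_dataset(ds, tmp_path / "ds.csv")
        back = load_dataset(tmp_path / "ds.csv")
        np.testing.assert_allclose(back.spectra, ds.spectra)
        np.testing.assert_array_equal(back.labels, ds.labels)
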