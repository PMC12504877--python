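import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowdcc.cellcls import (
    CellRecord,
    OracleCellClassifier,
    ReferenceCellClassifier,
    classify_cells,
    confusion_matrix,
    crop_with_offset,
    rescreen_alert,
)
from marrowdcc.cellseg import MaskCandidate
from marrowdcc.imaging import BBox
from marrowdcc.synthetic import SceneParams, generate_case
from marrowdcc.taxonomy import DEFAULT_TAXONOMY, CellTaxonomy
from marrowdcc.tiling import TileRef


def test_taxonomy_has_22_classes_16_countable():
    assert len(DEFAULT_TAXONOMY) == 22
    assert len(DEFAULT_TAXONOMY.countable_names) == 16
    assert set(DEFAULT_TAXONOMY.excluded_names) == {
        "apoptotic cell", "atypical lymphocyte", "immature lymphocyte",
        "prolymphocyte", "smudge cell", "others",
    }


class TestCropWithOffset:
    def test_side_arithmetic(self):
        tile = np.random.default_rng(0).integers(0, 255, (200, 200, 3)).astype(np.uint8)
        crop = crop_with_offset(tile, BBox(90, 90, 110, 110), 12)
        assert crop.shape == (44, 44, 3)
        assert np.array_equal(crop, tile[78:122, 78:122])

    def test_zero_offset_square_box_is_exact_contents(self):
        tile = np.arange(100, dtype=np.uint8).reshape(10, 10)
        crop = crop_with_offset(tile, BBox(2, 3, 6, 7), 0)
        assert np.array_equal(crop, tile[3:7, 2:6])

    def test_corner_box_zero_padded_by_exact_geometry(self):
        tile = np.full((50, 50), 9, dtype=np.uint8)
        # box at the very corner: side 10+2·5=20, centred at (5,5) → 5 rows/cols outside
        crop = crop_with_offset(tile, BBox(0, 0, 10, 10), 5)
        assert crop.shape == (20, 20)
        n_pad = 20 * 20 - 15 * 15  # the in-tile part is [0,15)²
        assert (crop == 0).sum() == n_pad
        assert (crop[5:, 5:] == 9).all()

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            crop_with_offset(np.zeros((10, 10), dtype=np.uint8), BBox(1, 1, 3, 3), -1)


def _record(crop):
    ref = TileRef(0, 0, BBox(0, 0, 100, 100), 100)
    cand = MaskCandidate(score=1.0, bbox=BBox(10, 10, 20, 20), prompt=(5, 5), area=100)
    return CellRecord(tile=ref, candidate=cand, crop=crop)


class _FixedBackend:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict(self, crop_224, record=None):
        return self.probs


class TestClassifyCells:
    def _crop(self):
        return np.full((32, 32, 3), 128, dtype=np.uint8)

    def test_one_hot_is_confident(self):
        p = np.zeros(22)
        p[3] = 1.0
        (rec,) = classify_cells([_record(self._crop())], _FixedBackend(p))
        assert rec.label == DEFAULT_TAXONOMY.names[3]
        assert rec.confidence == 1.0
        assert not rec.needs_review

    def test_uniform_vector_needs_review(self):
        (rec,) = classify_cells([_record(self._crop())], _FixedBackend(np.full(22, 1 / 22)))
        assert rec.confidence == pytest.approx(1 / 22)
        assert rec.needs_review

    def test_tie_breaks_to_lowest_taxonomy_index(self):
        p = np.zeros(22)
        p[4] = p[9] = 0.5
        (rec,) = classify_cells([_record(self._crop())], _FixedBackend(p))
        assert rec.label == DEFAULT_TAXONOMY.names[4]

    def test_malformed_vector_drops_record(self):
        out = classify_cells([_record(self._crop())], _FixedBackend(np.full(22, 0.5)))
        assert out == []

    def test_review_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        records = []
        backends = []
        for _ in range(30):
            p = rng.dirichlet(np.ones(22) * 0.3)
            backends.append(p)
            records.append(_record(self._crop()))

        class VaryingBackend:
            def __init__(self):
                self.i = -1

            def predict(self, crop_224, record=None):
                self.i += 1
                return backends[self.i % len(backends)]

        counts = []
        for thr in (0.0, 0.3, 0.6, 0.9, 1.01):
            out = classify_cells(records, VaryingBackend(), review_threshold=thr)
            counts.append(sum(r.needs_review for r in out))
        assert counts == sorted(counts)


class TestOracleClassifier:
    def test_reads_ground_truth_labels(self, small_banded_case):
        case = small_banded_case
        clf = OracleCellClassifier(case)
        size = case.params.tile_size
        inst = case.cell_instances_gt[0]
        cand = MaskCandidate(
            score=1.0, bbox=inst.spec.bbox(size), prompt=(0, 0), area=10
        )
        rec = CellRecord(tile=inst.tile, candidate=cand, crop=np.zeros((8, 8, 3), np.uint8))
        p = clf.predict(np.zeros((224, 224, 3), np.uint8), record=rec)
        assert DEFAULT_TAXONOMY.names[int(np.argmax(p))] == inst.label


@pytest.fixture(scope="module")
def fitted():
    from marrowdcc.pipeline import _training_scene, fit_reference_cell_classifier

    clf = fit_reference_cell_classifier(tile_size=1600, seed=41)
    val_case = generate_case(_training_scene(1600), 42)
    return clf, val_case


class TestReferenceClassifier:
    def test_validation_accuracy_well_above_chance(self, fitted):
        clf, case = fitted
        ok = n = 0
        for inst in case.cell_instances_gt:
            img = case.tile_image(inst.tile.row_index, inst.tile.col_index)
            crop = crop_with_offset(img, inst.spec.bbox(1600), 12)
            from marrowdcc.imaging import resize_image

            p = clf.predict(resize_image(crop, (224, 224)))
            ok += DEFAULT_TAXONOMY.names[int(np.argmax(p))] == inst.label
            n += 1
        assert n > 100
        assert ok / n > 0.8

    def test_blank_crop_near_uniform(self, fitted):
        clf, _ = fitted
        p = clf.predict(np.full((224, 224, 3), 200, dtype=np.uint8))
        assert p.max() < 0.5

    def test_unfitted_classifier_raises(self):
        with pytest.raises(RuntimeError):
            ReferenceCellClassifier().predict(np.zeros((224, 224, 3), np.uint8))


class TestRescreenAlert:
    def _tax3(self):
        return CellTaxonomy(("a", "b", "c"), (True, True, True))

    def test_identity_matrix_no_alert(self):
        alert, offenders = rescreen_alert(np.eye(3) * 10, self._tax3())
        assert not alert and offenders == []

    def test_single_bad_class_no_alert(self):
        m = np.diag([10.0, 10.0, 5.0])
        m[2, 0] = 5.0  # class c at rate 0.5; needs more than one to alert
        alert, offenders = rescreen_alert(m, self._tax3())
        assert not alert and offenders == ["c"]

    def test_two_classes_at_threshold_alert(self):
        m = np.array([[88.0, 12.0, 0.0], [0.0, 90.0, 10.0], [0.0, 0.0, 50.0]])
        # rates: a = 0.12, b = 0.10, c = 0
        alert, offenders = rescreen_alert(m, self._tax3())
        assert alert and offenders == ["a", "b"]

    def test_empty_rows_excluded_from_rates(self):
        m = np.array([[0.0, 0.0, 0.0], [1.0, 8.0, 1.0], [0.0, 0.0, 10.0]])
        alert, offenders = rescreen_alert(m, self._tax3())
        assert offenders == ["b"] and not alert

    def test_all_empty_undefined(self):
        with pytest.raises(ValueError):
            rescreen_alert(np.zeros((3, 3)), self._tax3())

    @given(st.integers(0, 10 ** 6))
    def test_alert_iff_more_than_one_offender(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 20, (3, 3)).astype(float)
        tax = self._tax3()
        try:
            alert, offenders = rescreen_alert(m, tax)
        except ValueError:
            assert m.sum() == 0
            return
        rates = [
            1 - m[i, i] / m[i].sum() for i in range(3) if m[i].sum() > 0
        ]
        assert alert == (sum(r >= 0.10 for r in rates) > 1)
        assert len(offenders) == sum(r >= 0.10 for r in rates)


def test_confusion_matrix_counts():
    tax = CellTaxonomy(("a", "b"), (True, True))
    m = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], tax)
    assert m.tolist() == [[1, 1], [0, 1]]
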