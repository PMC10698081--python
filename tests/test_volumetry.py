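"""Volumetry: BSA, segmentation, disc summation, class volume sets."""

import numpy as np
import pandas as pd
import pytest

from respcine import phantom, volumetry
from respcine.errors import InsufficientDataError
from respcine.volumetry import LV_LABEL, RV_LABEL, SubjectRecord


class TestDuboisBsa:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(32, 135, 1.10), (20, 116, 0.81), (27, 130, 0.99)],
    )
    def test_study_cohort_values(self, weight, height, expected):
        assert volumetry.dubois_bsa(weight, height) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            volumetry.dubois_bsa(0, 150)


class TestSegmentPhantomFrame:
    def test_areas_match_analytic_ellipses(self, mini_config):
        img = phantom.render_frame(20.0, 16.0, 4.0, mini_config, 0)
        mask = volumetry.segment_phantom_frame(img)
        for label, volume, aspect in ((RV_LABEL, 20.0, 1.7), (LV_LABEL, 16.0, 1.0)):
            a, b = phantom._cavity_axes_px(volume, 0, mini_config, aspect)
            analytic = np.pi * a * b
            assert np.count_nonzero(mask == label) == pytest.approx(analytic, rel=0.03)

    def test_all_background_rejected(self):
        with pytest.raises(InsufficientDataError):
            volumetry.segment_phantom_frame(np.zeros((200, 200)))

    def test_deterministic(self, mini_config):
        img = phantom.render_frame(20.0, 16.0, 4.0, mini_config, 0)
        assert np.array_equal(
            volumetry.segment_phantom_frame(img), volumetry.segment_phantom_frame(img)
        )


def brute_force_stack_volume(masks, spacing, thickness, label):
    total = 0.0
    for m in masks:
        for row in m:
            for px in row:
                if px == label:
                    total += spacing * spacing * thickness
    return total / 1000.0


class TestStackVolume:
    def test_disc_summation_arithmetic(self):
        mask = np.zeros((40, 40), dtype=int)
        mask.flat[:1000] = 1
        assert volumetry.stack_volume([mask], 1.0, 8.0, 1) == pytest.approx(8.0)

    def test_empty_masks(self):
        assert volumetry.stack_volume([np.zeros((5, 5))], 1.6, 8.0, 1) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            volumetry.stack_volume([np.zeros((5, 5)), np.zeros((6, 6))], 1.6)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            masks = [rng.integers(0, 3, size=(8, 8)) for _ in range(3)]
            spacing = float(rng.uniform(0.5, 2.0))
            got = volumetry.stack_volume(masks, spacing, 8.0, 2)
            assert got == pytest.approx(brute_force_stack_volume(masks, spacing, 8.0, 2))


@pytest.fixture()
def record():
    return SubjectRecord(id="p", age_years=9, sex="M", weight_kg=32, height_cm=135)


class TestClassVolumeSet:
    def test_monotone_cycle_arithmetic(self, record):
        vols = np.linspace(120, 50, 25)  # max at phase 1, min at phase 25
        entries = volumetry.class_volume_set(
            {"RV": vols}, np.zeros(25, bool), record, resp_class=1
        )
        e = entries[0]
        assert e["edv_ml"] == pytest.approx(120)
        assert e["esv_ml"] == pytest.approx(50)
        assert e["sv_ml"] == pytest.approx(70)
        assert e["ef_pct"] == pytest.approx(100 * 70 / 120, abs=0.05)
        assert e["edvi"] == pytest.approx(120 / record.bsa_m2)

    def test_bsa_indexing(self):
        rec = SubjectRecord(id="p5", age_years=9, sex="M", weight_kg=32, height_cm=135)
        vols = np.linspace(120, 50, 25)
        e = volumetry.class_volume_set({"RV": vols}, np.zeros(25, bool), rec, 1)[0]
        assert e["edvi"] == pytest.approx(109.1, abs=0.5)

    def test_indexing_linearity(self, record):
        vols = np.linspace(120, 50, 25)
        e = volumetry.class_volume_set({"RV": vols}, np.zeros(25, bool), record, 1)[0]
        heavier = SubjectRecord(
            id="x", age_years=9, sex="M",
            weight_kg=record.weight_kg, height_cm=record.height_cm,
        )
        assert e["edvi"] * record.bsa_m2 == pytest.approx(e["edv_ml"])

    def test_borrowed_extreme_phases_not_selected(self, record):
        vols = np.linspace(120, 50, 25)
        borrowed = np.zeros(25, bool)
        borrowed[0] = True  # true ED phase borrowed: next-best clean phase wins
        e = volumetry.class_volume_set({"RV": vols}, borrowed, record, 1)[0]
        assert e["ed_phase"] == 2
        assert e["edv_ml"] == pytest.approx(vols[1])

    def test_insufficient_clean_phases(self, record):
        vols = np.linspace(120, 50, 25)
        with pytest.raises(InsufficientDataError):
            volumetry.class_volume_set({"RV": vols}, np.ones(25, bool), record, 1)

    def test_extreme_neighborhood_gate(self, record):
        vols = phantom.cardiac_volume_waveform(np.arange(25) / 25, 120, 50)
        borrowed = np.ones(25, bool)
        borrowed[[0, 21, 23, 24]] = False  # no clean phase near end-systole
        with pytest.raises(InsufficientDataError):
            volumetry.class_volume_set(
                {"RV": vols}, borrowed, record, 4,
                ref_phases={"RV": (1, 10)},
            )

    def test_phantom_end_expiratory_class_near_baseline(self, demo_result):
        """The shallowest expiration class EDV sits near the planted
        end-expiratory EDV0."""
        v = demo_result.volumes
        sel = v[(v["ventricle"] == "RV") & (v["resp_class"] == 5)]
        assert len(sel) == 1
        assert sel["edv_ml"].iloc[0] == pytest.approx(120.0, rel=0.05)


class TestClassifyRvOverload:
    table = pd.DataFrame({"age_min": [0.0], "age_max": [18.0], "rv_edvi_p90": [110.0]})

    def test_threshold_is_strict(self):
        assert not volumetry.classify_rv_overload(110.0, 9, self.table)

    def test_above_threshold(self):
        assert volumetry.classify_rv_overload(111.0, 9, self.table)

    def test_severe_overload(self):
        assert volumetry.classify_rv_overload(199.0, 7, self.table)

    def test_uncovered_age(self):
        with pytest.raises(ValueError):
            volumetry.classify_rv_overload(100.0, 40, self.table)
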