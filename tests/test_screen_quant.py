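import numpy as np
import pytest

from cftrflow import screen_quant as sq
from cftrflow import synthdata
from cftrflow.screen_quant import CellRecord, SegmentationParams
from cftrflow.synthdata.screen import ScreenSimParams, default_layout


@pytest.fixture(scope="module")
def rendered_plate():
    params = ScreenSimParams(
        treatments=default_layout(n_samples=4),
        cells_per_well_mean=50,
        noise_cv=0.1,
        seed=2,
    )
    return synthdata.generate_screen_plate(params), params


class TestSegmentation:
    def test_cell_count_recovered(self, rendered_plate):
        (images, cells, wells), _ = rendered_plate
        well = wells["well"].iloc[0]
        records = sq.segment_and_quantify(
            images[well]["nuclei"], images[well]["total"], images[well]["surface"]
        )
        truth_n = (cells["well"] == well).sum()
        assert abs(len(records) - truth_n) <= 2

    def test_uniform_zero_images_give_empty_list(self):
        z = np.zeros((64, 64), dtype=np.uint16)
        assert sq.segment_and_quantify(z, z, z) == []

    def test_shape_mismatch_rejected(self):
        a = np.zeros((32, 32), dtype=np.uint16)
        b = np.zeros((16, 16), dtype=np.uint16)
        with pytest.raises(ValueError, match="shape"):
            sq.segment_and_quantify(a, b, b)

    def test_painted_cell_intensity_within_one_percent(self):
        # one disk with known integrated intensities on a flat background
        h = w = 64
        bg = 100.0
        yy, xx = np.ogrid[:h, :w]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 36
        core = (yy - 32) ** 2 + (xx - 32) ** 2 <= 4
        area = disk.sum()
        total_true, surface_true = 8000.0, 2000.0
        nuclei = np.full((h, w), bg)
        nuclei[core] += 1000
        total = np.full((h, w), bg)
        total[disk] += total_true / area
        surface = np.full((h, w), bg)
        surface[disk] += surface_true / area
        total_img = total.round().astype(np.uint16)
        surface_img = surface.round().astype(np.uint16)
        recs = sq.segment_and_quantify(nuclei.astype(np.uint16), total_img, surface_img)
        painted_total = float((total_img.astype(float) - bg)[disk].sum())
        painted_surface = float((surface_img.astype(float) - bg)[disk].sum())
        assert len(recs) == 1
        assert recs[0].total_fluorescence == pytest.approx(painted_total, rel=0.01)
        assert recs[0].surface_fluorescence == pytest.approx(painted_surface, rel=0.01)
        assert painted_total == pytest.approx(total_true, rel=0.02)  # quantisation only


def _record(total=1000.0, surface=300.0, area=80, sat=0.0):
    return CellRecord(
        well="A01", cell=1, total_fluorescence=total, surface_fluorescence=surface,
        area=area, saturated_fraction=sat,
    )


class TestCellQc:
    def test_low_expression_excluded_with_reason(self):
        out = sq.qc_cells([_record(total=10.0)], expression_threshold=100.0)
        assert not out[0].qc_pass and out[0].qc_reason == "expression"

    def test_extreme_thresholds_are_identity(self):
        recs = [_record(), _record(total=1.0), _record(sat=1.0)]
        out = sq.qc_cells(recs, 0.0, (0.0, np.inf), 1.0)
        assert all(r.qc_pass for r in out)

    def test_enumerated_gates(self):
        recs = (
            [_record() for _ in range(7)]
            + [_record(total=1.0), _record(area=5), _record(sat=0.5)]
        )
        out = sq.qc_cells(recs, 100.0, (10, 500), 0.05)
        assert sum(r.qc_pass for r in out) == 7
        reasons = {r.qc_reason for r in out if not r.qc_pass}
        assert reasons == {"expression", "morphology", "saturation"}


class TestWellSummary:
    def test_odd_median(self):
        recs = [_record(surface=v) for v in (1.0, 2.0, 3.0)]
        s = sq.summarize_well(recs, "A01", "t", "sample")
        assert s.x == 2.0

    def test_even_median_midpoint(self):
        recs = [_record(surface=v) for v in (1.0, 2.0, 3.0, 4.0)]
        assert sq.summarize_well(recs, "A01", "t", "sample").x == 2.5

    def test_order_invariance(self):
        vals = [5.0, 1.0, 3.0, 2.0]
        a = sq.summarize_well([_record(surface=v) for v in vals], "A", "t", "sample").x
        b = sq.summarize_well([_record(surface=v) for v in reversed(vals)], "A", "t", "sample").x
        assert a == b

    def test_all_excluded_flags_invalid(self):
        recs = sq.qc_cells([_record(total=1.0)], 100.0)
        s = sq.summarize_well(recs, "A01", "t", "sample")
        assert not s.valid and s.n_cells_post == 0


def _summary(role, median_total):
    return sq.WellSummary(
        well="A01", treatment=role, role=role, n_cells_pre=10, n_cells_post=10,
        x=1.0, median_total=median_total,
    )


class TestPlateQc:
    def test_forty_percent_knockdown_passes(self):
        ok, eff = sq.qc_plate([_summary("NCtrl", 100.0), _summary("siCFTR", 60.0)])
        assert ok and eff == pytest.approx(0.40)

    def test_twenty_percent_knockdown_fails(self):
        ok, eff = sq.qc_plate([_summary("NCtrl", 100.0), _summary("siCFTR", 80.0)])
        assert not ok and eff == pytest.approx(0.20)

    def test_complete_knockdown(self):
        ok, eff = sq.qc_plate([_summary("NCtrl", 100.0), _summary("siCFTR", 0.0)])
        assert ok and eff == pytest.approx(1.0)

    def test_missing_controls_raise(self):
        with pytest.raises(ValueError):
            sq.qc_plate([_summary("NCtrl", 100.0)])


class TestEndToEnd:
    def test_zero_noise_plate_recovers_true_medians_exactly(self):
        params = ScreenSimParams(
            treatments=default_layout(n_samples=3),
            cells_per_well_mean=30,
            noise_cv=0.0,
            seed=3,
        )
        images, _, wells = synthdata.generate_screen_plate(params)
        _, summaries = sq.quantify_plate(images, wells[["well", "treatment", "role"]])
        truth = wells.set_index("well")["true_median_surface"]
        for s in summaries:
            assert s.x == pytest.approx(truth[s.well], abs=1e-9)

    def test_saturated_cells_are_gated(self):
        params = ScreenSimParams(
            treatments=default_layout(n_samples=2),
            cells_per_well_mean=40,
            noise_cv=0.1,
            saturation_rate=0.5,
            seed=6,
        )
        images, _, wells = synthdata.generate_screen_plate(params)
        cells, _ = sq.quantify_plate(
            images, wells[["well", "treatment", "role"]], max_saturated_fraction=0.05
        )
        assert (cells.loc[~cells.qc_pass, "qc_reason"] == "saturation").any()
        assert 0.2 < (~cells.qc_pass).mean() < 0.8
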