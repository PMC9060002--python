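import numpy as np
import pandas as pd
import pytest

from cftrflow import nucfrac as nf
from cftrflow import synthdata

GEOM = nf.VoxelGeometry(0.6, 0.5, 0.5)


def _sphere(shape, center, radius_vox):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radius_vox) ** 2
        + ((yy - center[1]) / radius_vox) ** 2
        + ((xx - center[2]) / radius_vox) ** 2
    ) <= 1


class TestGeometry:
    def test_invalid_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            nf.VoxelGeometry(0.0, 0.5, 0.5)

    def test_physical_radii_convert_per_axis(self):
        assert GEOM.radii_to_voxels((0.6, 0.5, 1.0)) == (1, 1, 2)


class TestSegmentNuclei:
    def test_two_separated_spheres_two_labels(self):
        vol = np.zeros((20, 64, 64))
        vol[_sphere(vol.shape, (10, 16, 16), 6)] = 1000
        vol[_sphere(vol.shape, (10, 48, 48), 6)] = 1000
        labels = nf.segment_nuclei(vol, GEOM)
        assert labels.max() == 2

    def test_touching_spheres_declumped(self):
        vol = np.zeros((20, 64, 64))
        vol[_sphere(vol.shape, (10, 32, 24), 7)] = 1000
        vol[_sphere(vol.shape, (10, 32, 35), 7)] = 1000  # overlapping pair
        labels = nf.segment_nuclei(vol, GEOM)
        assert labels.max() == 2

    def test_all_zero_volume_gives_no_labels(self):
        assert nf.segment_nuclei(np.zeros((8, 16, 16)), GEOM).max() == 0

    def test_2d_input_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            nf.segment_nuclei(np.zeros((16, 16)), GEOM)


class TestAssignCytoplasm:
    def test_single_nucleus_cell_is_superset(self):
        labels = np.zeros((10, 32, 32), dtype=np.int32)
        labels[_sphere(labels.shape, (5, 16, 16), 4)] = 1
        cells = nf.assign_cytoplasm(labels, GEOM, 2.0)
        assert ((cells > 0) & (labels > 0)).sum() == (labels > 0).sum()
        assert (cells > 0).sum() > (labels > 0).sum()

    def test_zero_distance_cells_equal_nuclei(self):
        labels = np.zeros((10, 32, 32), dtype=np.int32)
        labels[_sphere(labels.shape, (5, 16, 16), 4)] = 1
        assert np.array_equal(nf.assign_cytoplasm(labels, GEOM, 0.0), labels)

    def test_equidistant_voxel_goes_to_lower_label(self):
        labels = np.zeros((1, 1, 9), dtype=np.int32)
        labels[0, 0, 0], labels[0, 0, 8] = 1, 2
        cells = nf.assign_cytoplasm(labels, GEOM, 10.0)
        assert cells[0, 0, 4] == 1  # exact midpoint


class TestFilters:
    def test_small_border_and_interior(self, demo_stack, stack_params):
        df = nf.quantify_stack(
            demo_stack.nuclei_channel, demo_stack.signal_channel, GEOM, stack_params
        )
        truth = demo_stack.truth
        assert (df.excluded == "small").sum() == truth.small.sum()
        assert (df.excluded == "border").sum() == truth.border.sum()
        n_regular = len(truth) - truth.small.sum() - truth.border.sum()
        assert (df.excluded == "").sum() == n_regular

    def test_small_nucleus_volume_rule_at_147(self):
        rec_small = nf.CellFractionRecord(1, 100.0, 500.0, 1.0, 2.0, 0.5)
        rec_ok = nf.CellFractionRecord(2, 200.0, 500.0, 1.0, 2.0, 0.5)
        labels = np.zeros((4, 8, 8), dtype=np.int32)
        labels[1:3, 3:5, 3:5] = 1
        labels2 = labels.copy()
        labels2[labels2 == 1] = 0
        labels[1:3, 5:7, 5:7] = 2
        out = nf.filter_cells([rec_small, rec_ok], labels, labels)
        assert out[0].excluded == "small" and out[1].excluded == ""

    def test_raising_min_volume_never_keeps_more(self, demo_stack, stack_params):
        def kept(minvol):
            import dataclasses

            p = dataclasses.replace(stack_params, min_nuclear_volume_um3=minvol)
            df = nf.quantify_stack(
                demo_stack.nuclei_channel, demo_stack.signal_channel, GEOM, p
            )
            return (df.excluded == "").sum()

        assert kept(50.0) >= kept(147.0) >= kept(250.0)


class TestNuclearFraction:
    def test_uniform_signal_fraction_equals_volume_share(self):
        nuclei = np.zeros((10, 24, 24), dtype=np.int32)
        nuclei[_sphere(nuclei.shape, (5, 12, 12), 3)] = 1
        cells = nf.assign_cytoplasm(nuclei, GEOM, 1.5)
        signal = np.ones(nuclei.shape)
        rec = nf.measure_cells(nuclei, cells, signal, GEOM)[0]
        share = (nuclei == 1).sum() / (cells == 1).sum()
        assert rec.nuclear_fraction == pytest.approx(share, abs=1e-12)

    def test_all_signal_in_nucleus_gives_one(self):
        nuclei = np.zeros((10, 24, 24), dtype=np.int32)
        nuclei[_sphere(nuclei.shape, (5, 12, 12), 3)] = 1
        cells = nf.assign_cytoplasm(nuclei, GEOM, 2.0)
        signal = np.where(nuclei > 0, 5.0, 0.0)
        rec = nf.measure_cells(nuclei, cells, signal, GEOM)[0]
        assert rec.nuclear_fraction == pytest.approx(1.0, abs=1e-12)

    def test_zero_signal_cell_flagged(self):
        nuclei = np.zeros((6, 12, 12), dtype=np.int32)
        nuclei[2:4, 4:8, 4:8] = 1
        rec = nf.measure_cells(nuclei, nuclei, np.zeros(nuclei.shape), GEOM)[0]
        assert rec.excluded == "no_signal"

    def test_invariant_to_positive_scaling(self, demo_stack, stack_params):
        df1 = nf.quantify_stack(
            demo_stack.nuclei_channel, demo_stack.signal_channel, GEOM, stack_params
        )
        df2 = nf.quantify_stack(
            demo_stack.nuclei_channel, 7.3 * demo_stack.signal_channel, GEOM, stack_params
        )
        np.testing.assert_allclose(df1.nuclear_fraction, df2.nuclear_fraction, rtol=1e-9)


class TestCompare:
    def test_image_mean_arithmetic(self):
        df = pd.DataFrame(
            {"group": ["a", "a"], "image": [1, 1], "nuclear_fraction": [0.2, 0.4]}
        )
        df2 = pd.DataFrame(
            {"group": ["b", "b"], "image": [2, 2], "nuclear_fraction": [0.5, 0.5]}
        )
        means, _ = nf.summarize_and_compare(pd.concat([df, df2]))
        assert sorted(means["image_mean"]) == pytest.approx([0.3, 0.5])

    def test_identical_groups_p_one(self):
        rows = []
        for g in ("a", "b"):
            for img in range(3):
                rows.append({"group": g, "image": img, "nuclear_fraction": 0.1 * img + 0.3})
        _, p = nf.summarize_and_compare(pd.DataFrame(rows))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        rows = []
        for g, mu in (("wt", 0.4), ("f508del", 0.6)):
            for img in range(8):
                rows.append(
                    {"group": g, "image": f"{g}{img}", "nuclear_fraction": mu + rng.normal(0, 0.03)}
                )
        _, p = nf.summarize_and_compare(pd.DataFrame(rows))
        assert p < 0.05
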