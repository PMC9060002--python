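import numpy as np
import pandas as pd
import pytest

from cftrflow import io, synthdata
from cftrflow.synthdata.screen import ScreenSimParams, Treatment, default_layout


class TestScreenGenerator:
    def test_seed_determinism_bit_identical(self, small_screen_params):
        img1, cells1, wells1 = synthdata.generate_screen_plate(small_screen_params)
        img2, cells2, wells2 = synthdata.generate_screen_plate(small_screen_params)
        pd.testing.assert_frame_equal(cells1, cells2)
        for well in img1:
            for chan in img1[well]:
                assert np.array_equal(img1[well][chan], img2[well][chan])

    def test_no_effect_zero_noise_gives_identical_medians(self):
        params = ScreenSimParams(
            treatments=default_layout(n_samples=6), cells_per_well_mean=40, noise_cv=0.0, seed=1
        )
        _, wells = synthdata.simulate_screen_cells(params)
        nctrl = wells.loc[wells.role == "NCtrl", "true_median_surface"].iloc[0]
        samples = wells.loc[wells.role == "sample", "true_median_surface"]
        assert (samples == nctrl).all()

    def test_sicftr_knockdown_depth(self):
        params = ScreenSimParams(
            treatments=default_layout(n_samples=4),
            cells_per_well_mean=40,
            noise_cv=0.0,
            transfection_efficiency=0.8,
            seed=1,
        )
        _, wells = synthdata.simulate_screen_cells(params)
        kd = wells.loc[wells.role == "siCFTR", "true_median_total"].iloc[0]
        ctrl = wells.loc[wells.role == "NCtrl", "true_median_total"].iloc[0]
        assert kd <= 0.2 * ctrl + 1e-9

    def test_layout_without_nctrl_rejected(self):
        bad = (Treatment(well="A01", label="siCFTR", role="siCFTR"),)
        with pytest.raises(ValueError, match="NCtrl"):
            ScreenSimParams(treatments=bad)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            ScreenSimParams(treatments=default_layout(), cells_per_well_mean=0)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            Treatment(well="A01", label="x", effect=-1.0)

    def test_rendered_sums_match_truth(self):
        params = ScreenSimParams(
            treatments=default_layout(n_samples=2), cells_per_well_mean=20, noise_cv=0.1, seed=5
        )
        images, cells, _ = synthdata.generate_screen_plate(params, background=100.0)
        well = cells["well"].iloc[0]
        well_cells = cells[cells.well == well]
        img = images[well]["total"].astype(float) - 100.0
        painted = img[img > 0].sum()
        assert painted == pytest.approx(well_cells["true_total"].sum(), rel=0.01)


class TestStackGenerator:
    def test_determinism(self):
        p = synthdata.StackSimParams(n_cells=4, seed=2)
        a = synthdata.generate_confocal_stack(p)
        b = synthdata.generate_confocal_stack(p)
        assert np.array_equal(a.signal_channel, b.signal_channel)
        assert np.array_equal(a.nuclei_labels, b.nuclei_labels)

    def test_planted_fraction_exact_on_truth_labels(self):
        p = synthdata.StackSimParams(n_cells=4, nuclear_fraction_true=0.6, seed=2)
        st = synthdata.generate_confocal_stack(p)
        for row in st.truth.itertuples():
            nuc = st.signal_channel[st.nuclei_labels == row.cell].sum()
            cell = st.signal_channel[st.cell_labels == row.cell].sum()
            assert nuc / cell == pytest.approx(row.f_true, abs=1e-9)

    def test_fraction_one_puts_all_signal_in_nuclei(self):
        p = synthdata.StackSimParams(n_cells=4, nuclear_fraction_true=1.0, seed=3)
        st = synthdata.generate_confocal_stack(p)
        outside = st.signal_channel[st.nuclei_labels == 0].sum()
        assert outside == pytest.approx(0.0, abs=1e-9)

    def test_small_nucleus_below_volume_cutoff(self):
        p = synthdata.StackSimParams(n_cells=4, n_small_nuclei=1, seed=2)
        st = synthdata.generate_confocal_stack(p)
        small = st.truth[st.truth.small]
        assert (small["nuclear_volume_um3"] < 147.0).all()

    def test_oversized_nucleus_rejected(self):
        with pytest.raises(ValueError, match="larger than"):
            synthdata.StackSimParams(shape=(8, 64, 64), nucleus_radius_um=(4.0, 4.0, 4.0))


class TestMsGenerator:
    def test_decoys_only_yield_empty_consensus(self):
        from cftrflow import interactome

        params = synthdata.MsSimParams(
            universe_size=200,
            n_true={"wt": 1, "f508del": 1},
            core_size=1,
            detection_probability=1.0,
            decoy_rate=0.3,
            seed=4,
        )
        tables, truth = synthdata.generate_ms_replicates(params)
        decoy_only = [
            rep[~rep["accession"].isin(truth["wt"])] for rep in tables["wt"]
        ]
        assert len(interactome.replicate_consensus(decoy_only, "wt")) == 0

    def test_core_must_fit_in_smallest_condition(self):
        with pytest.raises(ValueError, match="core"):
            synthdata.MsSimParams(n_true={"wt": 10, "f508del": 50}, core_size=20)

    def test_replicate_tables_schema(self, ms_tables):
        tables, _ = ms_tables
        for reps in tables.values():
            for rep in reps:
                assert list(rep.columns) == ["accession", "gene", "unused_score", "confidence"]


class TestResources:
    def test_planted_term_ranks_first(self):
        from cftrflow import enrich

        background = [f"g{i}" for i in range(60)]
        query = background[:6]
        annotation = {"planted": set(query), "other": set(background[30:50])}
        res = enrich.ora(query, annotation, background)
        assert res.sort_values("p_value").iloc[0]["term"] == "planted"

    def test_roundtrip_through_module_readers(self, planted_resources, tmp_path):
        synthdata.write_resources(planted_resources, tmp_path)
        assert io.read_annotation(tmp_path / "annotation_bp.tsv") == planted_resources.annotation
        gmt = io.read_gmt(str(tmp_path / "hallmark.gmt"))
        assert {k: set(v) for k, v in gmt.items()} == planted_resources.hallmark
        assert set(io.read_gene_list(tmp_path / "background.txt")) == set(
            planted_resources.background
        )
        edges = io.read_edge_list(tmp_path / "edges.tsv")
        pd.testing.assert_frame_equal(edges, planted_resources.edges)
        cats = io.read_category_map(tmp_path / "category_map.tsv")
        assert cats == planted_resources.category_map

    def test_edge_scores_in_unit_interval(self, planted_resources):
        s = planted_resources.edges["combined_score"]
        assert ((s >= 0) & (s <= 1)).all()
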