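import numpy as np
import pytest
from hypothesis import settings

from cftrflow import interactome, nucfrac, synthdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_screen_params():
    """A compact plate: 10 samples with two planted effects, noisy."""
    effects = [1.0] * 8 + [2.0, 0.3]
    return synthdata.ScreenSimParams(
        treatments=synthdata.default_layout(n_samples=10, effects=effects),
        cells_per_well_mean=120,
        noise_cv=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def ms_tables():
    """Small MS instance with full detection: consensus equals the truth."""
    params = synthdata.MsSimParams(
        universe_size=400,
        n_true={"wt": 60, "f508del": 90},
        core_size=50,
        detection_probability=1.0,
        seed=3,
    )
    return synthdata.generate_ms_replicates(params)


@pytest.fixture(scope="session")
def interactor_gene_sets(ms_tables):
    tables, _ = ms_tables
    sets = {c: interactome.replicate_consensus(reps, c) for c, reps in tables.items()}
    return {c: frozenset(s.gene_by_accession[a] for a in s.accessions) for c, s in sets.items()}


@pytest.fixture(scope="session")
def planted_resources(interactor_gene_sets):
    """Annotation bundle planted over the small MS instance's gene sets."""
    return synthdata.generate_annotation_resources(
        interactor_gene_sets["wt"],
        interactor_gene_sets["f508del"],
        seed=7,
        background_size=1200,
        n_stage1=24,
        n_stage2_multi=7,
        n_stage2_membership=5,
        ref_overlap_core=20,
        ref_overlap_wt_specific=2,
        ref_overlap_f508_specific=6,
    )


@pytest.fixture(scope="session")
def demo_stack():
    """One stack with a small-nucleus, a border and a clumped-pair plant."""
    params = synthdata.StackSimParams(
        n_cells=8,
        nuclear_fraction_true=0.5,
        fraction_noise_sd=0.02,
        clumping_rate=0.25,
        border_cell_rate=0.125,
        n_small_nuclei=1,
        seed=4,
    )
    return synthdata.generate_confocal_stack(params)


@pytest.fixture(scope="session")
def stack_params():
    """Analysis parameters matched to the synthetic cell geometry."""
    return nucfrac.NucSegParams(cytoplasm_distance_um=(4.0, 4.0, 4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
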