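import pytest

from clonotrack.alignment import AlignmentParams
from clonotrack.clonotyping import define_clonotype_clusters
from clonotrack.io import chains_from_frame, meta_from_frame, qc_single_paired
from clonotrack.simulate import SimulationConfig, simulate_study
from clonotrack.tracking import match_clonotypes


@pytest.fixture(scope="session")
def study():
    """A small but complete synthetic cohort (16 patients, 2 timepoints,
    300 QC-clean cells per sample) with ground truth."""
    config = SimulationConfig(seed=7, cells_per_sample=300)
    chains, meta, truth = simulate_study(config)
    return config, chains, meta, truth


@pytest.fixture(scope="session")
def qc_result(study):
    _, chains, meta, _ = study
    cells, report = qc_single_paired(chains_from_frame(chains), meta_from_frame(meta))
    return cells, report


@pytest.fixture(scope="session")
def cells(qc_result):
    return qc_result[0]


@pytest.fixture(scope="session")
def meta_records(study):
    return meta_from_frame(study[2])


@pytest.fixture(scope="session")
def assignment(cells):
    """Alignment-distance clonotype assignment (cutoff 10) of the cohort."""
    return define_clonotype_clusters(cells, AlignmentParams(cutoff=10))


@pytest.fixture(scope="session")
def shared_sets(assignment, meta_records):
    return match_clonotypes(assignment, meta_records)
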