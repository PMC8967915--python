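"""Shared fixtures: synthetic datasets with ground truth.

Heavy simulations and QC runs are session-scoped so the statistical tests
and the structural tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import scqc
from scqc.simulate import SimulationSpec, cell_view, simulate_droplet_data


@pytest.fixture
def tiny_exp() -> scqc.QCExperiment:
    """4 genes x 3 barcodes, hand-countable."""
    mat = np.array(
        [
            [5, 0, 2],
            [3, 0, 0],
            [2, 0, 7],
            [0, 0, 1],
        ]
    )
    return scqc.QCExperiment(
        sp.csc_matrix(mat),
        gene_ids=["G1", "G2", "G3", "G4"],
        barcode_ids=["AAA", "CCC", "TTT"],
        level="Cell",
        sample="s1",
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The default droplet simulation: 900 cells + doublets, 20k empties."""
    return simulate_droplet_data(SimulationSpec(seed=10))


@pytest.fixture(scope="session")
def droplet_qc_result(default_fixture):
    exp, truth = default_fixture
    return scqc.run_droplet_qc(exp, seed=11), truth


@pytest.fixture(scope="session")
def doublet_fixture():
    """~2,000 cells, 3 well-separated types, 10% heterotypic doublets."""
    spec = SimulationSpec(
        n_genes=400,
        n_cell_types=3,
        cells_per_type=600,
        n_empty_droplets=1000,
        doublet_fraction=0.10,
        seed=2,
    )
    exp, truth = simulate_droplet_data(spec)
    return cell_view(exp, truth)


@pytest.fixture(scope="session")
def doublet_results(doublet_fixture):
    cell, _ = doublet_fixture
    knn = scqc.doublet_knn(cell, seed=3)
    cxds = scqc.doublet_cxds(cell)
    bcds = scqc.doublet_bcds(cell, seed=3)
    hybrid = scqc.doublet_hybrid(cxds, bcds)
    return {"knn": knn, "cxds": cxds, "bcds": bcds, "cxds_bcds_hybrid": hybrid}


@pytest.fixture(scope="session")
def contam_fixture():
    """Doublet-free fixture with per-cell contamination ~ Beta(2, 18)."""
    spec = SimulationSpec(
        n_genes=300,
        n_cell_types=3,
        cells_per_type=300,
        n_empty_droplets=2000,
        doublet_fraction=0.0,
        seed=5,
    )
    exp, truth = simulate_droplet_data(spec)
    return cell_view(exp, truth)


@pytest.fixture(scope="session")
def zero_contam_fixture():
    """Same design but (essentially) contamination-free cells."""
    spec = SimulationSpec(
        n_genes=300,
        n_cell_types=3,
        cells_per_type=300,
        n_empty_droplets=2000,
        doublet_fraction=0.0,
        contamination_a=1e-8,
        contamination_b=1.0,
        seed=6,
    )
    exp, truth = simulate_droplet_data(spec)
    return cell_view(exp, truth)


@pytest.fixture(scope="session")
def contam_result(contam_fixture):
    cell, _ = contam_fixture
    return scqc.decontx(cell, seed=4)


@pytest.fixture(scope="session")
def pipeline_sim():
    """Small simulation for end-to-end pipeline runs."""
    spec = SimulationSpec(
        n_genes=150,
        n_cell_types=2,
        cells_per_type=120,
        n_empty_droplets=3000,
        doublet_fraction=0.08,
        seed=21,
    )
    return simulate_droplet_data(spec)
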