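import numpy as np
import pytest
import scipy.sparse as sp

from chronocell import (
    CountMatrix,
    GeneSet,
    NormalizedMatrix,
    SimConfig,
    build_phase_bins,
    filter_cells,
    make_gene_sets,
    make_phase_table,
    normalize_log,
    phase_scores,
    simulate,
)


def make_counts(rng, n_cells=12, n_genes=20, lam=2.0, organelle=None, sample=None):
    """Small random CountMatrix for unit tests."""
    counts = rng.poisson(lam, size=(n_cells, n_genes))
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=np.array([f"bc{i}" for i in range(n_cells)], dtype=object),
        genes=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        sample=np.array(sample if sample is not None else ["s0"] * n_cells, dtype=object),
        organelle_class=np.array(
            organelle if organelle is not None else ["nuclear"] * n_genes, dtype=object
        ),
    )


def make_norm(values, genes=None, sample=None):
    """Wrap a dense array as a NormalizedMatrix (for scorer-level tests
    that do not need the normalization invariant)."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        barcodes=np.array([f"bc{i}" for i in range(n_cells)], dtype=object),
        genes=np.array(
            genes if genes is not None else [f"g{i}" for i in range(n_genes)], dtype=object
        ),
        sample=np.array(sample if sample is not None else ["s0"] * n_cells, dtype=object),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One moderate two-sample simulation shared across test modules.

    Fe-deficient sample carries a 100-gene iron regulon (+2 log FC), a
    2-h phase delay, and a 30% division fraction vs 7% in the replete
    sample; depth matches a typical droplet library.
    """
    iron = GeneSet("iron", [f"iron{i}" for i in range(100)])
    cfg = SimConfig(
        n_cells_per_sample=400,
        n_genes=2000,
        frac_rhythmic=0.2,
        amplitude=1.0,
        cell_phase_kappa=4.0,
        phase_delay=2.0,
        delay_sample="Fe-",
        regulons={"Fe-": (iron, 2.0)},
        division_frac_outside_window={"Fe+": 0.07, "Fe-": 0.30},
        mean_umis_per_cell=3300.0,
        seed=77,
    )
    matrix, truth = simulate(cfg)
    norm = normalize_log(filter_cells(matrix))
    phase_table = make_phase_table(truth)
    psm = phase_scores(norm, build_phase_bins(phase_table), seed=0)
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "norm": norm,
        "phase_table": phase_table,
        "psm": psm,
        "gene_sets": {gs.name: gs for gs in make_gene_sets(truth)},
    }
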