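import numpy as np
import pandas as pd
import pytest

import scregnet as sr

# The standard benchmark condition: 4 cell types x 100 cells, 10 TFs,
# 50 targets, 2 peaks/gene. Heavy network fixtures are session-scoped and
# shared; per-cell forests use 50 trees so the suite stays desk-scale.
BENCH_SEED = 1
N_TREES = 50
CELLS_PER_TYPE_SUBSET = 20


@pytest.fixture(scope="session")
def sim():
    """One seeded benchmark simulation, unpacked as a dict."""
    cfg = sr.SimulationConfig(seed=BENCH_SEED)
    ds, annot, peaks, hits, truth, cell_types, pseudotime = sr.simulate_multiome(cfg)
    return {
        "cfg": cfg, "dataset": ds, "annot": annot, "peaks": peaks,
        "motif_hits": hits, "truth": truth, "cell_types": cell_types,
        "pseudotime": pseudotime,
    }


@pytest.fixture(scope="session")
def bench_links(sim):
    ds = sim["dataset"]
    return sr.build_links(sim["annot"], sim["peaks"], ds.rna, ds.atac.values,
                          ds.atac.peak_ids, sim["motif_hits"])


@pytest.fixture(scope="session")
def bench_graph(sim):
    return sr.wnn_neighbors(sim["dataset"], k=30, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def subset_indices(sim):
    per_type = sim["cfg"].cells_per_type
    return [per_type * t + i for t in range(sim["cfg"].n_cell_types)
            for i in range(CELLS_PER_TYPE_SUBSET)]


@pytest.fixture(scope="session")
def multiome_networks(sim, bench_links, bench_graph, subset_indices):
    """Multiome-mode networks (expression + linked peaks) for 80 cells."""
    return sr.infer_networks_for_cells(
        subset_indices, bench_graph, sim["dataset"], bench_links, sim["annot"],
        mode="multiome", n_trees=N_TREES, seed=BENCH_SEED,
    )


@pytest.fixture(scope="session")
def expression_networks(sim):
    """Expression-only networks (RNA-only neighbors, no peaks) for 20 cells."""
    ds = sim["dataset"]
    graph = sr.rna_only_neighbors(ds.rna, k=30, seed=BENCH_SEED)
    empty_links = sr.GenePeakLinks({g: [] for g in ds.rna.genes})
    per_type = sim["cfg"].cells_per_type
    cells = [per_type * t + i for t in range(sim["cfg"].n_cell_types) for i in range(5)]
    return sr.infer_networks_for_cells(
        cells, graph, ds, empty_links, sim["annot"],
        mode="expression", n_trees=N_TREES, seed=BENCH_SEED,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A cheap simulation for unit-level checks."""
    cfg = sr.SimulationConfig(seed=3, cells_per_type=20, n_tfs=6, n_targets=12)
    ds, annot, peaks, hits, truth, cell_types, pseudotime = sr.simulate_multiome(cfg)
    return {
        "cfg": cfg, "dataset": ds, "annot": annot, "peaks": peaks,
        "motif_hits": hits, "truth": truth, "cell_types": cell_types,
        "pseudotime": pseudotime,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def pd_series(values, index):
    return pd.Series(values, index=index)
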