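import numpy as np
import pandas as pd
import pytest

import scfidelity as sf

# QC/selection thresholds scaled to the synthetic benchmark's size (300
# genes, libraries ~1000-8000); the defaults target full-scale data with
# tens of thousands of genes.
SMALL_CFG = dict(
    min_umi=500,
    min_genes=100,
    max_umi=20_000,
    min_cells_per_gene=3,
    var_mean_cutoff=0.1,
    var_dispersion_cutoff=0.1,
    n_pcs=10,
    resolution=1.0,
)


@pytest.fixture(scope="session")
def small_cfg() -> sf.AnalysisConfig:
    return sf.AnalysisConfig(rng_seed=7, **SMALL_CFG)


@pytest.fixture(scope="session")
def bench_data(small_cfg):
    """3-program planted-marker benchmark: 600 cells, marker fold 10."""
    spec = sf.make_benchmark_spec(
        n_programs=3, n_genes=300, n_cells=600, markers_per_program=20,
        marker_fold=10.0, rng_seed=7,
    )
    cm, truth = sf.generate_counts(spec)
    return spec, cm, truth


@pytest.fixture(scope="session")
def bench_pipeline(bench_data, small_cfg):
    """Filtered + normalized + clustered benchmark data with true labels."""
    spec, cm, truth = bench_data
    filtered = sf.filter_cells_genes(cm, small_cfg)
    nm = sf.normalize_log_scaled(filtered, small_cfg.scale_factor)
    var_genes = sf.select_variable_genes(nm, small_cfg)
    pca = sf.run_pca(nm, var_genes, n_pcs=small_cfg.n_pcs)
    snn = sf.build_snn_graph(pca, k=20, prune=small_cfg.snn_prune)
    labels = sf.cluster_graph(snn, resolution=small_cfg.resolution, seed=1)
    true_labels = pd.Series(truth.program_labels, index=cm.cell_ids).loc[nm.cell_ids]
    return dict(
        spec=spec, truth=truth, nm=nm, pca=pca, snn=snn,
        labels=labels, true_labels=true_labels,
    )


def toy_count_matrix(values, cells=None, genes=None, label="toy") -> sf.CountMatrix:
    values = np.asarray(values)
    cells = cells or [f"c{i + 1}" for i in range(values.shape[0])]
    genes = genes or [f"g{j + 1}" for j in range(values.shape[1])]
    return sf.CountMatrix(pd.DataFrame(values, index=cells, columns=genes), sample_label=label)
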