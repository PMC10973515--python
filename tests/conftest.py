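import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gliohypoxia as gh


def make_cells(counts: np.ndarray, gene_names=None, cell_ids=None,
               obs: dict | None = None) -> ad.AnnData:
    """AnnData from a dense cells x genes count array."""
    n_cells, n_genes = counts.shape
    gene_names = list(gene_names) if gene_names is not None else \
        [f"G{j:03d}" for j in range(n_genes)]
    cell_ids = list(cell_ids) if cell_ids is not None else \
        [f"C{i:03d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(obs or {}, index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    from gliohypoxia.io_formats import _compute_cell_totals
    _compute_cell_totals(adata)
    return adata


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort with truth, QC'd and log-normalised.

    Session-scoped: ~2k cells, shared by scoring/hypoxia/shift tests.
    """
    cfg = gh.small_config(seed=11, n_cells_per_patient=200, n_genes=800)
    cells, truth = gh.simulate_cells(cfg)
    cells = gh.filter_cells(cells)
    cells = gh.log_normalize(cells)
    truth = truth.loc[cells.obs_names]
    return cfg, cells, truth


@pytest.fixture(scope="session")
def state_signatures(small_cohort):
    cfg, _, _ = small_cohort
    return [gh.Signature(name=s, genes=list(cfg.state_programs[s]))
            for s in ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")]


@pytest.fixture
def mtx_dir(tmp_path):
    """Write a tiny 3-gene x 2-cell MTX triplet and return its directory."""
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 2 2\n"
        "1 1 5\n"
        "2 2 3\n"
    )
    (tmp_path / "genes.tsv").write_text("GA\nGB\nMT-1\n")
    (tmp_path / "barcodes.tsv").write_text("cell1\ncell2\n")
    return tmp_path
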