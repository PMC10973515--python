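"""Readers and writers for the delimited formats the pipeline touches.

Single-cell matrices travel as a 10x-style MatrixMarket triplet (matrix.mtx
plus genes.tsv and barcodes.tsv); gene sets as GMT; differential-expression
tables and all derived outputs as CSV/TSV.  In memory the cell matrix is an
:class:`anndata.AnnData` with cells as observations and genes as variables —
note that the MTX triplet on disk is genes x cells with 1-based indices
(MatrixMarket convention) while the AnnData is cells x genes, 0-based.

Gene symbols are matched case-sensitively everywhere; callers that need the
conventional upper-case normalisation for human symbols opt in explicitly
via ``normalize_symbols=True`` on the readers.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("gliohypoxia")

#: Prefix identifying mitochondrial genes when computing the QC mito
#: fraction.  Human nuclear-encoded symbols never start with "MT-".
MITO_PREFIX = "MT-"


def configure_logging(level: int = logging.INFO) -> None:
    """Send package log records to stderr with a structured prefix."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.setLevel(level)
    if not logger.handlers:
        logger.addHandler(handler)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ConsistencyError(ValueError):
    """Components of a multi-file input disagree in shape or content."""


# ---------------------------------------------------------------------------
# Signatures (gene sets)
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """A named, ordered set of gene symbols, optionally directioned.

    ``direction`` maps a subset of ``genes`` to "up" or "down"; it is
    required by the shared-signature derivation and ignored by scoring.
    """

    name: str
    genes: list[str]
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate symbols")
        bad = set(self.direction.values()) - {"up", "down"}
        if bad:
            raise ValueError(f"invalid direction labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @property
    def up_genes(self) -> list[str]:
        return [g for g in self.genes if self.direction.get(g) == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g in self.genes if self.direction.get(g) == "down"]


def read_gmt(path: str | Path, normalize_symbols: bool = False) -> list[Signature]:
    """Parse a tab-delimited GMT file into one :class:`Signature` per line.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Gene order
    is preserved; duplicate symbols within a line are dropped with a warning.
    Lines with fewer than three fields raise :class:`FormatError` naming the
    line number.
    """
    path = Path(path)
    signatures: list[Signature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name = fields[0]
            genes_raw = [g.strip() for g in fields[2:] if g.strip()]
            if normalize_symbols:
                genes_raw = [g.upper() for g in genes_raw]
            seen: dict[str, None] = {}
            dups = 0
            for g in genes_raw:
                if g in seen:
                    dups += 1
                else:
                    seen[g] = None
            if dups:
                logger.warning(
                    "GMT %s line %d (%s): dropped %d duplicate symbols",
                    path, lineno, name, dups,
                )
            signatures.append(Signature(name=name, genes=list(seen)))
    return signatures


def write_gmt(signatures: Sequence[Signature], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

#: Default column mapping for DEG tables: logical name -> column header.
DEFAULT_DEG_COLMAP = {
    "gene": "gene",
    "log2fc": "log2fc",
    "pval": "pval",
    "padj": "padj",
}


def read_deg_table(path: str | Path,
                   colmap: Mapping[str, str] | None = None,
                   sep: str | None = None,
                   normalize_symbols: bool = False) -> pd.DataFrame:
    """Read a per-gene differential-expression table.

    Returns a DataFrame with columns ``gene, log2fc, pval, padj`` (padj may
    be NaN when absent in the source).  Rows with unparseable numerics are
    dropped with a logged count; a duplicated gene symbol is an error, since
    per-contrast DEG tables are per-gene unique.

    ``sep=None`` sniffs comma vs tab from the header line.
    """
    path = Path(path)
    colmap = dict(DEFAULT_DEG_COLMAP, **(colmap or {}))
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [colmap[k] for k in ("gene", "log2fc", "pval") if colmap[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame({"gene": df[colmap["gene"]].astype(str)})
    if normalize_symbols:
        out["gene"] = out["gene"].str.upper()
    for key in ("log2fc", "pval", "padj"):
        col = colmap[key]
        if col in df.columns:
            out[key] = pd.to_numeric(df[col], errors="coerce")
        else:
            out[key] = np.nan
    n_before = len(out)
    keep = out["log2fc"].notna() & out["pval"].notna()
    dropped = int(n_before - keep.sum())
    if dropped:
        logger.info("read_deg_table %s: dropped %d rows with unparseable numerics",
                    path, dropped)
    out = out.loc[keep].reset_index(drop=True)
    dup = out["gene"][out["gene"].duplicated()].unique()
    if len(dup):
        raise ConsistencyError(
            f"{path}: duplicate gene symbols: {', '.join(sorted(dup)[:10])}"
        )
    for col in ("pval", "padj"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise FormatError(f"{path}: column {col} outside [0, 1]")
    if not np.isfinite(out["log2fc"]).all():
        raise FormatError(f"{path}: non-finite log2 fold-changes")
    return out


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Single-cell count matrices (10x-style MTX triplet)
# ---------------------------------------------------------------------------

def _compute_cell_totals(adata: ad.AnnData, mito_prefix: str = MITO_PREFIX) -> None:
    """Fill total_umi, n_genes_detected and mito_fraction in ``.obs``."""
    X = adata.X
    if sp.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        n_det = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        n_det = (X > 0).sum(axis=1)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if mito_mask.any():
        sub = X[:, np.flatnonzero(mito_mask)]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito = np.zeros(adata.n_obs)
    adata.obs["total_umi"] = total.astype(np.int64)
    adata.obs["n_genes_detected"] = n_det.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["mito_fraction"] = frac


def read_mtx_triplet(dir_path: str | Path,
                     matrix_file: str = "matrix.mtx",
                     genes_file: str = "genes.tsv",
                     barcodes_file: str = "barcodes.tsv",
                     meta_file: str = "cell_meta.csv",
                     mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Load a 10x-style MTX triplet directory into an AnnData.

    The on-disk matrix is genes x cells (1-based MatrixMarket indices); the
    returned AnnData is cells x genes with integer CSR counts in ``.X``.
    Per-cell QC totals are computed on load.  An optional ``cell_meta.csv``
    (column ``cell_id`` plus e.g. ``patient``/``idh_status``) is merged into
    ``.obs`` when present.
    """
    dir_path = Path(dir_path)
    for fname in (matrix_file, genes_file, barcodes_file):
        if not (dir_path / fname).exists():
            raise FormatError(f"{dir_path}: missing {fname}")
    mat = scipy.io.mmread(dir_path / matrix_file)  # genes x cells
    genes = pd.read_csv(dir_path / genes_file, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(dir_path / barcodes_file, sep="\t", header=None)[0].astype(str)
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes or len(barcodes) != n_cells:
        raise ConsistencyError(
            f"{dir_path}: matrix is {n_genes}x{n_cells} but "
            f"{len(genes)} gene names / {len(barcodes)} barcodes"
        )
    counts = sp.csr_matrix(mat.T)
    if counts.nnz and (counts.data < 0).any():
        raise FormatError(f"{dir_path}: negative counts")
    counts.data = counts.data.astype(np.int64)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    meta_path = dir_path / meta_file
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        if "cell_id" not in meta.columns:
            raise FormatError(f"{meta_path}: needs a cell_id column")
        meta = meta.set_index("cell_id")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ConsistencyError(
                f"{meta_path}: {len(missing)} barcodes absent from metadata"
            )
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].values
    _compute_cell_totals(adata, mito_prefix=mito_prefix)
    logger.info("read_mtx_triplet %s: %d cells x %d genes, %d nonzeros",
                dir_path, adata.n_obs, adata.n_vars, counts.nnz)
    return adata


def write_mtx_triplet(adata: ad.AnnData, dir_path: str | Path,
                      matrix_file: str = "matrix.mtx",
                      genes_file: str = "genes.tsv",
                      barcodes_file: str = "barcodes.tsv",
                      meta_file: str = "cell_meta.csv",
                      meta_columns: Sequence[str] = ("patient", "idh_status")) -> None:
    """Write an AnnData back out as a genes x cells MTX triplet."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(dir_path / matrix_file), mat, field="integer")
    pd.Series(adata.var_names).to_csv(dir_path / genes_file, sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(dir_path / barcodes_file, sep="\t",
                                      header=False, index=False)
    cols = [c for c in meta_columns if c in adata.obs.columns]
    if cols:
        meta = adata.obs[cols].copy()
        meta.insert(0, "cell_id", adata.obs_names)
        meta.to_csv(dir_path / meta_file, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML superset) pipeline run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
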