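"""DEG filtering, shared-signature derivation, and over-representation.

The shared hypoxia signature is derived by set algebra on two
differential-expression contrasts: genes passing |log2FC| > 1 and
BH-adjusted p < 0.01 in both contrasts with concordant sign form the shared
set, and its up-regulated subset is the signature used for per-cell
scoring.  Over-representation of a query set in a library of gene sets is
scored by the hypergeometric upper tail, with sets ranked by
``combined_score = odds_ratio * (-ln p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import Signature, logger


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sorted p(i) are scaled by m/i, monotonicity enforced from the largest
    rank down, capped at 1.  Raises on values outside [0, 1].
    """
    p = np.asarray(list(pvals) if not isinstance(pvals, np.ndarray) else pvals,
                   dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DegCutoffs:
    """DEG definition: |log2FC| strictly greater than ``min_abs_log2fc``
    and adjusted p strictly below ``max_padj``."""

    min_abs_log2fc: float = 1.0
    max_padj: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_padj <= 0:
            raise ValueError("cutoffs must be positive")


def filter_degs(tab: pd.DataFrame, cut: DegCutoffs = DegCutoffs(),
                name: str = "degs") -> Signature:
    """Select differentially expressed genes from a DEG table.

    Keeps genes with ``|log2fc| > min_abs_log2fc`` and
    ``padj < max_padj`` (both strict); when padj is absent it is computed
    from the raw p-values by BH.  Directions are labelled up/down from the
    sign of log2fc.
    """
    tab = tab.copy()
    if "padj" not in tab.columns or tab["padj"].isna().all():
        tab["padj"] = bh_adjust(tab["pval"].to_numpy())
    elif tab["padj"].isna().any():
        # adjust once over the full table; fill only where missing
        filled = bh_adjust(tab["pval"].to_numpy())
        tab["padj"] = tab["padj"].fillna(pd.Series(filled, index=tab.index))
    mask = (tab["log2fc"].abs() > cut.min_abs_log2fc) & (tab["padj"] < cut.max_padj)
    hits = tab.loc[mask]
    direction = {g: ("up" if fc > 0 else "down")
                 for g, fc in zip(hits["gene"], hits["log2fc"])}
    logger.info("filter_degs: %d/%d genes pass |log2FC|>%g & padj<%g",
                len(hits), len(tab), cut.min_abs_log2fc, cut.max_padj)
    return Signature(name=name, genes=list(hits["gene"]), direction=direction)


def derive_shared_signature(a: Signature, b: Signature
                            ) -> tuple[Signature, Signature]:
    """Intersect two directioned DEG signatures.

    Returns ``(shared, up_only)``: ``shared`` holds the symbols present in
    both inputs with matching direction (genes overlapping with opposing
    signs are excluded); ``up_only`` is the up-regulated subset of shared —
    the signature used for per-cell hypoxia scoring.  Gene order follows
    ``a``.
    """
    for sig in (a, b):
        undirected = [g for g in sig.genes if g not in sig.direction]
        if undirected:
            raise ValueError(
                f"{sig.name}: {len(undirected)} genes lack direction labels")
    b_dir = b.direction
    common = [g for g in a.genes if g in b_dir]
    concordant = [g for g in common if a.direction[g] == b_dir[g]]
    n_opposing = len(common) - len(concordant)
    if n_opposing:
        logger.info("derive_shared_signature: excluded %d genes with opposing "
                    "directionality (of %d overlapping)", n_opposing, len(common))
    shared = Signature(name=f"shared({a.name},{b.name})", genes=concordant,
                       direction={g: a.direction[g] for g in concordant})
    up_only = Signature(name=f"shared_up({a.name},{b.name})",
                        genes=shared.up_genes,
                        direction={g: "up" for g in shared.up_genes})
    return shared, up_only


def signature_overlap(a: Signature, b: Signature) -> tuple[int, float]:
    """Overlap size and Jaccard index of two gene sets."""
    sa, sb = set(a.genes), set(b.genes)
    k = len(sa & sb)
    union = len(sa | sb)
    return k, (k / union if union else 0.0)


@dataclass
class EnrichmentResult:
    """Over-representation of a query set in one library set."""

    set_name: str
    overlap_k: int
    set_size: int
    query_size: int
    universe_size: int
    pval: float
    padj: float
    odds_ratio: float
    combined_score: float


def _odds_ratio(k: int, set_size: int, query_size: int, universe: int) -> float:
    """2x2 odds ratio (query membership vs set membership) with Haldane's
    0.5 correction when any cell is zero."""
    a = k
    b = query_size - k
    c = set_size - k
    d = universe - query_size - set_size + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def ora_enrich(query: Signature, library: Sequence[Signature],
               universe: Iterable[str]) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each library set.

    Query and library genes outside the universe are dropped with a
    warning.  Per set the upper-tail p is P(overlap >= k); the combined
    score is ``odds_ratio * (-ln p)``; BH adjustment runs across the
    library; results are sorted by combined score, descending.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    q = [g for g in query.genes if g in uni]
    dropped = len(query.genes) - len(q)
    if dropped:
        logger.warning("ora_enrich: %d query genes outside universe dropped", dropped)
    if not q:
        raise ValueError("query has no genes in the universe")
    qset = set(q)
    N, n_query = len(uni), len(qset)
    results = []
    for sig in library:
        members = set(sig.genes) & uni
        k = len(members & qset)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n_query)
        pval = float(scipy.stats.hypergeom.sf(k - 1, N, K, n_query)) if K else 1.0
        pval = min(max(pval, np.nextafter(0, 1)), 1.0)
        orat = _odds_ratio(k, K, n_query, N)
        results.append(EnrichmentResult(
            set_name=sig.name, overlap_k=k, set_size=K, query_size=n_query,
            universe_size=N, pval=pval, padj=np.nan, odds_ratio=orat,
            combined_score=orat * (-np.log(pval)),
        ))
    padj = bh_adjust([r.pval for r in results])
    for r, adj in zip(results, padj):
        r.padj = float(adj)
    results.sort(key=lambda r: (-r.combined_score, r.set_name))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
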