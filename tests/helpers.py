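"""Independent brute-force oracles used by the test suite.

Each oracle restates its procedure from the definition, in plain loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import hashlib
import itertools
import math

import numpy as np


def bh_oracle(pvals):
    """Step-up Benjamini–Hochberg, by the definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev, 1.0)
        adj[i] = val
        prev = val
    return adj


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by summing the pmf."""
    total = math.comb(N, n)
    hi = min(K, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, hi + 1)) / total


def hypergeom_enumeration(universe: list, members: set, query: set) -> float:
    """P(overlap >= k) by exhaustively enumerating every subset of the
    universe with |query| elements.  Only feasible for tiny universes."""
    k_obs = len(members & query)
    n = len(query)
    total = 0
    at_least = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(set(combo) & members) >= k_obs:
            at_least += 1
    return at_least / total


def mww_u(a, b) -> float:
    """Mann–Whitney U of sample a vs b (ties counted half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1
            elif x == y:
                u += 0.5
    return u


def ranksum_exact_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of allocations.

    p = 2 * min(P(U <= u), P(U >= u)), capped at 1, over all
    C(n_a + n_b, n_a) equally likely assignments of the pooled values.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = mww_u(a, b)
    us = [mww_u(combo, [pooled[i] for i in range(len(pooled)) if i not in idx])
          for idx, combo in (
              (set(ix), [pooled[i] for i in ix])
              for ix in itertools.combinations(range(len(pooled)), n_a))]
    total = len(us)
    le = sum(1 for u in us if u <= u_obs) / total
    ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(le, ge))


def module_score_oracle(lognorm: np.ndarray, gene_names: list[str],
                        sig_name: str, sig_genes: list[str],
                        n_bins: int, n_ctrl: int, seed: int) -> np.ndarray:
    """Binned-control module score, step by step from its definition.

    lognorm is dense cells x genes.  Average expression per gene over all
    cells; genes ranked by (average, name) and cut into n_bins
    equal-frequency bins; per signature gene, n_ctrl control genes drawn
    with replacement from the gene's bin (members sorted by name, signature
    genes excluded; all non-signature genes if the bin has none), using a
    generator seeded by the first 4 bytes of sha256("seed:sig:gene");
    score = mean signature expression - mean over all pooled control draws.
    """
    n_cells, n_genes = lognorm.shape
    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    present = [g for g in sig_genes if g in name_to_idx]
    sig_idx_set = {name_to_idx[g] for g in present}

    avg = [float(np.mean(lognorm[:, j])) for j in range(n_genes)]
    order = sorted(range(n_genes), key=lambda j: (avg[j], gene_names[j]))
    rank = {j: r for r, j in enumerate(order)}
    bin_of = {j: (rank[j] * n_bins) // n_genes for j in range(n_genes)}
    members: dict[int, list[int]] = {}
    for j in range(n_genes):
        if j not in sig_idx_set:
            members.setdefault(bin_of[j], []).append(j)
    for b in members:
        members[b] = sorted(members[b], key=lambda j: gene_names[j])
    fallback = sorted((j for j in range(n_genes) if j not in sig_idx_set),
                      key=lambda j: gene_names[j])

    ctrl_draws: list[int] = []
    for g in present:
        j = name_to_idx[g]
        digest = hashlib.sha256(f"{seed}:{sig_name}:{g}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
        pool = members.get(bin_of[j], []) or fallback
        for d in rng.integers(0, len(pool), size=n_ctrl):
            ctrl_draws.append(pool[int(d)])

    scores = np.empty(n_cells)
    sig_idx = [name_to_idx[g] for g in present]
    for c in range(n_cells):
        sig_mean = sum(lognorm[c, j] for j in sig_idx) / len(sig_idx)
        ctrl_mean = sum(lognorm[c, j] for j in ctrl_draws) / len(ctrl_draws)
        scores[c] = sig_mean - ctrl_mean
    return scores


def lognorm_oracle(counts: np.ndarray, scale: float = 10_000.0) -> np.ndarray:
    """Element-wise ln(1 + scale * count / cell total), by loops."""
    out = np.zeros_like(counts, dtype=float)
    for c in range(counts.shape[0]):
        total = counts[c].sum()
        if total == 0:
            continue
        for j in range(counts.shape[1]):
            out[c, j] = math.log(1.0 + scale * counts[c, j] / total)
    return out
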