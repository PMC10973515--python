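"""Synthetic single-cell cohorts and bulk hypoxia contrasts with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-patient negative-binomial UMI counts over a shared gene
universe; six planted cell-state expression programs (MES1/MES2, AC, OPC,
NPC1/NPC2); a planted hypoxia program active in a small fraction of cells;
a hypoxia-coupled VEGFA-like marker gene; mitochondrial genes for QC; and
IDH-status-dependent coupling between hypoxia and state membership (hypoxic
cells of IDH-wildtype patients shift mainly to the mesenchymal-like state,
those of IDH-mutant patients to the astrocyte-like state).

Negative-binomial parameterisation, used everywhere in this module: mean
``mu`` and size (dispersion) ``r`` with ``Var = mu + mu^2 / r``.

All randomness flows from the single ``seed`` in :class:`SimConfig`; the
same seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io_formats import Signature, logger

RAW_STATES = ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")
STATES = ("MES", "AC", "OPC", "NPC")

#: raw sub-state -> collapsed state
COLLAPSE = {"MES1": "MES", "MES2": "MES", "AC": "AC",
            "OPC": "OPC", "NPC1": "NPC", "NPC2": "NPC"}

# Cohort geometry of the emulated study: 11 high-grade glioma patients,
# 5 IDH-wildtype and 6 IDH-mutant.
DEFAULT_PATIENTS = tuple(f"P{i:02d}" for i in range(1, 12))
DEFAULT_IDH = ("WT", "WT", "WT", "WT", "WT", "MUT", "MUT", "MUT", "MUT", "MUT", "MUT")

# Per-patient hypoxic fractions spanning the observed 1.7-5.5% range with a
# cohort mean near 3.8%.
DEFAULT_HYPOXIA_FRACTION = (0.055, 0.048, 0.040, 0.033, 0.025,
                            0.052, 0.044, 0.038, 0.031, 0.024, 0.017)

# Baseline (non-hypoxic) state composition, matching the pooled composition
# reported for non-hypoxic glioma cells.
DEFAULT_STATE_PRIORS = {"MES": 0.249, "AC": 0.209, "OPC": 0.165, "NPC": 0.377}

# State distribution of hypoxic cells, by IDH group.  WT hypoxic cells are
# strongly MES-shifted; MUT hypoxic cells AC-shifted with the MES shift
# essentially absent.  At the 5:6 WT:MUT cohort mix these pool to roughly
# MES 0.48 / AC 0.26 / OPC 0.07 / NPC 0.19 among hypoxic cells.
DEFAULT_HYPOXIA_STATE_SHIFT = {
    "WT": {"MES": 0.75, "AC": 0.15, "OPC": 0.03, "NPC": 0.07},
    "MUT": {"MES": 0.25, "AC": 0.35, "OPC": 0.10, "NPC": 0.30},
}


def _hypoxia_program_genes(n: int = 193) -> list[str]:
    """Planted hypoxia-response program; head genes carry the canonical
    hypoxia symbols (angiogenesis / glycolysis / autophagy / HIF feedback)."""
    named = ["VEGFA", "SLC2A1", "BNIP3", "EGLN3"]
    return (named + [f"HYP{i:04d}" for i in range(len(named) + 1, n + 1)])[:n]


def _state_program_genes(n_per_program: int = 30) -> dict[str, list[str]]:
    return {s: [f"{s}G{i:03d}" for i in range(1, n_per_program + 1)]
            for s in RAW_STATES}


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell cohort.

    Probability vectors (``state_priors`` and each entry of
    ``hypoxia_state_shift``) must sum to one; hypoxia fractions lie in
    [0, 1].  Effects are natural-log fold-changes applied multiplicatively
    to negative-binomial means.
    """

    patient_ids: Sequence[str] = DEFAULT_PATIENTS
    idh_status: Sequence[str] = DEFAULT_IDH
    n_cells_per_patient: int = 2777          # ~30,500 cells cohort-wide
    n_genes: int = 2000
    baseline_log_mean: tuple[float, float] = (-0.7, 1.0)  # lognormal (meanlog, sdlog) over NB means
    nb_dispersion: float = 2.0               # NB size r; Var = mu + mu^2/r
    state_programs: dict[str, list[str]] = field(default_factory=_state_program_genes)
    state_effect: float = 1.0
    hypoxia_program: list[str] = field(default_factory=_hypoxia_program_genes)
    hypoxia_effect: float = 1.4
    hypoxia_fraction: Sequence[float] = DEFAULT_HYPOXIA_FRACTION
    state_priors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_PRIORS))
    hypoxia_state_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_HYPOXIA_STATE_SHIFT.items()})
    marker_gene: str = "VEGFA"
    marker_baseline_mean: float = 0.1
    marker_hypoxic_mean: float = 8.0
    n_mito_genes: int = 13
    mito_mean: float = 8.0
    gene_names: Sequence[str] | None = None   # explicit universe; default auto-built
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.idh_status) != len(self.patient_ids):
            raise ValueError("idh_status and patient_ids lengths differ")
        fr = np.asarray(self.hypoxia_fraction, float)
        n_pat = len(self.patient_ids)
        if fr.ndim == 0:
            fr = np.full(n_pat, float(fr))
        elif fr.size != n_pat:
            if tuple(self.hypoxia_fraction) == DEFAULT_HYPOXIA_FRACTION:
                # untouched 11-patient default on a different cohort size:
                # keep the cohort-mean hypoxia level
                fr = np.full(n_pat, fr.mean())
            else:
                raise ValueError("hypoxia_fraction length does not match patients")
        if ((fr < 0) | (fr > 1)).any():
            raise ValueError("hypoxia_fraction outside [0, 1]")
        self.hypoxia_fraction = tuple(fr)
        for name, vec in [("state_priors", self.state_priors),
                          *((f"hypoxia_state_shift[{g}]", d)
                            for g, d in self.hypoxia_state_shift.items())]:
            if set(vec) != set(STATES):
                raise ValueError(f"{name} must cover states {STATES}")
            if abs(sum(vec.values()) - 1.0) > 1e-12:
                raise ValueError(f"{name} does not sum to 1")
        for eff in (self.state_effect, self.hypoxia_effect):
            if not np.isfinite(eff):
                raise ValueError("effects must be finite")

    @property
    def mito_genes(self) -> list[str]:
        return [f"MT-{i:02d}" for i in range(1, self.n_mito_genes + 1)]

    def gene_universe(self) -> list[str]:
        """Planted programs first, then mito genes, then background filler.

        An explicit ``gene_names`` universe is returned as-is (programs are
        validated against it at simulation time).
        """
        if self.gene_names is not None:
            return list(self.gene_names)
        genes: dict[str, None] = {}
        for g in self.hypoxia_program:
            genes[g] = None
        for prog in self.state_programs.values():
            for g in prog:
                genes[g] = None
        genes[self.marker_gene] = None
        for g in self.mito_genes:
            genes[g] = None
        n_bg = self.n_genes - len(genes)
        if n_bg < 0:
            raise ValueError("n_genes smaller than the planted programs")
        for i in range(1, n_bg + 1):
            genes[f"BG{i:04d}"] = None
        return list(genes)


def _split_to_raw(collapsed: dict[str, float]) -> np.ndarray:
    """Spread a 4-state distribution over the 6 raw sub-states (MES and NPC
    each split evenly between their two sub-programs)."""
    out = []
    for raw in RAW_STATES:
        parent = COLLAPSE[raw]
        n_sub = sum(1 for r in RAW_STATES if COLLAPSE[r] == parent)
        out.append(collapsed[parent] / n_sub)
    return np.asarray(out)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_r: float,
             shape: tuple[int, ...]) -> np.ndarray:
    p = size_r / (size_r + mu)
    return rng.negative_binomial(size_r, p, size=shape)


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw a synthetic cohort; returns (cells, truth).

    Per cell: patient, then raw state from the baseline priors; with the
    patient's hypoxia probability the cell is marked hypoxic and its state
    redrawn from the IDH-appropriate hypoxic-state distribution.  Counts are
    NB(mean = baseline x exp(active program effects), dispersion); the
    marker gene's mean is overridden by its hypoxia-conditional value; mito
    genes are program-independent.

    ``truth`` has one row per cell (true_state_raw, true_state,
    true_hypoxic); program membership is recorded in ``cells.var``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe()
    gene_idx = {g: i for i, g in enumerate(genes)}
    for prog_name, prog in [("hypoxia", config.hypoxia_program),
                            *config.state_programs.items()]:
        missing = [g for g in prog if g not in gene_idx]
        if missing:
            raise ValueError(f"program {prog_name}: genes not in universe: {missing[:5]}")
    missing = [g for g in (config.marker_gene, *config.mito_genes)
               if g not in gene_idx]
    if missing:
        raise ValueError(f"marker/mito genes not in universe: {missing[:5]}")
    n_genes = len(genes)

    # Baseline NB means shared across patients, drawn once.
    meanlog, sdlog = config.baseline_log_mean
    base_mu = rng.lognormal(meanlog, sdlog, size=n_genes)
    for g in config.mito_genes:
        base_mu[gene_idx[g]] = config.mito_mean
    base_mu[gene_idx[config.marker_gene]] = config.marker_baseline_mean

    hyp_idx = np.array([gene_idx[g] for g in config.hypoxia_program])
    prog_idx = {s: np.array([gene_idx[g] for g in config.state_programs[s]])
                for s in RAW_STATES}
    marker_i = gene_idx[config.marker_gene]

    prior_raw = _split_to_raw(config.state_priors)
    shift_raw = {g: _split_to_raw(d) for g, d in config.hypoxia_state_shift.items()}

    blocks, obs_rows, truth_rows = [], [], []
    for p_i, (patient, idh) in enumerate(zip(config.patient_ids, config.idh_status)):
        n = config.n_cells_per_patient
        state_i = rng.choice(len(RAW_STATES), size=n, p=prior_raw)
        hypoxic = rng.random(n) < config.hypoxia_fraction[p_i]
        n_hyp = int(hypoxic.sum())
        if n_hyp:
            state_i[hypoxic] = rng.choice(len(RAW_STATES), size=n_hyp,
                                          p=shift_raw[idh])
        counts = np.zeros((n, n_genes), dtype=np.int64)
        # draw per (raw state, hypoxic) group so each group shares one mean vector
        for s_i, s in enumerate(RAW_STATES):
            for hyp_flag in (False, True):
                mask = (state_i == s_i) & (hypoxic == hyp_flag)
                m = int(mask.sum())
                if m == 0:
                    continue
                mu = base_mu.copy()
                mu[prog_idx[s]] *= np.exp(config.state_effect)
                if hyp_flag:
                    mu[hyp_idx] *= np.exp(config.hypoxia_effect)
                    mu[marker_i] = config.marker_hypoxic_mean
                else:
                    mu[marker_i] = config.marker_baseline_mean
                counts[mask] = _nb_draw(rng, mu, config.nb_dispersion, (m, n_genes))
        blocks.append(sp.csr_matrix(counts))
        for c in range(n):
            obs_rows.append((f"{patient}_C{c:05d}", patient, idh))
        truth_rows.append(pd.DataFrame({
            "true_state_raw": [RAW_STATES[i] for i in state_i],
            "true_state": [COLLAPSE[RAW_STATES[i]] for i in state_i],
            "true_hypoxic": hypoxic,
        }))

    obs = pd.DataFrame(obs_rows, columns=["cell_id", "patient", "idh_status"]
                       ).set_index("cell_id")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    program = np.array(["background"] * n_genes, dtype=object)
    for s in RAW_STATES:
        program[prog_idx[s]] = s
    program[hyp_idx] = "hypoxia"
    program[[gene_idx[g] for g in config.mito_genes]] = "mito"
    program[marker_i] = "marker"
    var["program"] = program

    adata = ad.AnnData(X=sp.vstack(blocks).tocsr(), obs=obs, var=var)
    from .io_formats import _compute_cell_totals
    _compute_cell_totals(adata)
    truth = pd.concat(truth_rows, ignore_index=True)
    truth.index = adata.obs_names
    logger.info("simulate_cells: %d cells x %d genes, %.3f hypoxic",
                adata.n_obs, adata.n_vars, truth["true_hypoxic"].mean())
    return adata, truth


# ---------------------------------------------------------------------------
# Bulk differential-expression contrasts
# ---------------------------------------------------------------------------

# Planted DEG geometry of the two emulated hypoxia contrasts: contrast A has
# 634 DEGs (248 shared), contrast B 986 (248 shared); of the shared genes 5
# flip sign between contrasts, and the 243 concordant ones split 193 up /
# 50 down.
N_SHARED_UP = 193
N_SHARED_DOWN = 50
N_OPPOSING = 5
UNIQUE_A = (249, 137)   # up, down
UNIQUE_B = (438, 300)


def default_bulk_signatures() -> tuple[Signature, Signature, Signature, list[str]]:
    """Planted gene sets for the two bulk contrasts.

    Returns (shared, unique_a, unique_b, opposing) where ``shared`` carries
    direction labels for contrast A; ``opposing`` lists the shared genes
    whose sign flips in contrast B.  The shared up-regulated genes reuse the
    hypoxia-program symbols so the derived signature matches the program
    planted in the single-cell simulation.
    """
    up = _hypoxia_program_genes(N_SHARED_UP)
    down = [f"SHD{i:04d}" for i in range(1, N_SHARED_DOWN + 1)]
    opposing = [f"OPP{i:04d}" for i in range(1, N_OPPOSING + 1)]
    shared = Signature(
        name="shared_planted",
        genes=up + down + opposing,
        direction={**{g: "up" for g in up + opposing}, **{g: "down" for g in down}},
    )
    ua_up, ua_dn = UNIQUE_A
    ub_up, ub_dn = UNIQUE_B
    unique_a = Signature(
        name="unique_a",
        genes=[f"UQA{i:04d}" for i in range(1, ua_up + ua_dn + 1)],
        direction={f"UQA{i:04d}": ("up" if i <= ua_up else "down")
                   for i in range(1, ua_up + ua_dn + 1)},
    )
    unique_b = Signature(
        name="unique_b",
        genes=[f"UQB{i:04d}" for i in range(1, ub_up + ub_dn + 1)],
        direction={f"UQB{i:04d}": ("up" if i <= ub_up else "down")
                   for i in range(1, ub_up + ub_dn + 1)},
    )
    return shared, unique_a, unique_b, opposing


def simulate_bulk_contrast(
    n_reps: int,
    shared: Signature,
    unique_a: Signature,
    unique_b: Signature,
    opposing: Sequence[str] = (),
    n_background: int = 3600,
    effect_low: float = 1.8,
    effect_high: float = 3.0,
    rep_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two hypoxia-vs-normoxia DEG tables with planted structure.

    ``shared`` genes are differential in both contrasts (direction labels
    give contrast A's sign; genes listed in ``opposing`` flip sign in B);
    ``unique_a``/``unique_b`` genes are differential in one contrast only.
    Per gene, ``n_reps`` replicate log2-expression values per condition are
    drawn as N(0, rep_sd) around the planted shift; log2fc is the mean
    difference and p comes from a two-sample z-test at the known replicate
    noise scale (a deliberately simple stand-in for a count-model fit, and
    well-behaved at triplicate sample sizes), BH-adjusted per table.

    Planted |log2FC| is uniform on [effect_low, effect_high], comfortably
    above the downstream >1 cutoff.
    """
    if set(shared.genes) & (set(unique_a.genes) | set(unique_b.genes)):
        raise ValueError("shared and unique gene sets must be disjoint")
    if set(unique_a.genes) & set(unique_b.genes):
        raise ValueError("unique_a and unique_b must be disjoint")
    unknown = set(opposing) - set(shared.genes)
    if unknown:
        raise ValueError(f"opposing genes not in shared set: {sorted(unknown)[:5]}")
    for sig in (shared, unique_a, unique_b):
        missing_dir = [g for g in sig.genes if g not in sig.direction]
        if missing_dir:
            raise ValueError(f"{sig.name}: genes without direction labels")

    rng = np.random.default_rng(seed)
    genes = (list(shared.genes) + list(unique_a.genes) + list(unique_b.genes)
             + [f"BGB{i:04d}" for i in range(1, n_background + 1)])
    n_genes = len(genes)
    sign_dir = {"up": 1.0, "down": -1.0}

    planted = np.zeros((n_genes, 2))   # columns: contrast A, contrast B
    mag = rng.uniform(effect_low, effect_high, size=n_genes)
    opp = set(opposing)
    for i, g in enumerate(genes):
        if g in shared.direction:
            s = sign_dir[shared.direction[g]]
            planted[i, 0] = s * mag[i]
            planted[i, 1] = (-s if g in opp else s) * mag[i]
        elif g in unique_a.direction:
            planted[i, 0] = sign_dir[unique_a.direction[g]] * mag[i]
        elif g in unique_b.direction:
            planted[i, 1] = sign_dir[unique_b.direction[g]] * mag[i]

    tables = []
    for col in (0, 1):
        norm = rng.normal(0.0, rep_sd, size=(n_genes, n_reps))
        hyp = planted[:, [col]] + rng.normal(0.0, rep_sd, size=(n_genes, n_reps))
        log2fc = hyp.mean(axis=1) - norm.mean(axis=1)
        z = log2fc / (rep_sd * np.sqrt(2.0 / n_reps))
        pval = 2.0 * scipy.stats.norm.sf(np.abs(z))
        from .signatures import bh_adjust
        tab = pd.DataFrame({"gene": genes, "log2fc": log2fc, "pval": pval,
                            "padj": bh_adjust(pval)})
        tables.append(tab)
    return tables[0], tables[1]


def synthetic_hif_like_set(n_total: int = 48, n_overlap: int = 26,
                           name: str = "HIF_METAGENE_SYNTH") -> Signature:
    """Synthetic stand-in for a pan-cancer HIF-target metagene: a 48-gene
    set of which 26 lie in the planted shared-up hypoxia program.  Purely a
    constructed fixture for set-algebra checks — not the published set."""
    up = _hypoxia_program_genes(N_SHARED_UP)
    genes = up[:n_overlap] + [f"HIFX{i:03d}" for i in range(1, n_total - n_overlap + 1)]
    return Signature(name=name, genes=genes)


def small_config(seed: int = 0, n_cells_per_patient: int = 500,
                 n_genes: int = 800) -> SimConfig:
    """Cohort config at reduced size for fast replicate studies; same
    planted structure and probabilities as the defaults.

    The baseline expression level is scaled up by the gene-count reduction
    so per-cell UMI totals (and hence QC pass rates) match the full-size
    cohort.
    """
    base = SimConfig(seed=seed)
    meanlog, sdlog = base.baseline_log_mean
    meanlog += float(np.log(base.n_genes / n_genes))
    return replace(base, n_cells_per_patient=n_cells_per_patient,
                   n_genes=n_genes, baseline_log_mean=(meanlog, sdlog))
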