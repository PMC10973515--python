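"""Cell-state composition of hypoxic vs non-hypoxic cells, and IDH-group
comparison of the per-patient state shifts.

For each stratum (pooled, or one glioma patient) the proportions of the
four states (MES, AC, OPC, NPC) are computed separately within hypoxic and
non-hypoxic cells; the shift of a state is the difference
``delta = prop_hypoxic - prop_nonhypoxic``.  IDH-wildtype and IDH-mutant
patient groups are compared per state by a two-sided Wilcoxon rank-sum
test on the per-patient deltas (exact null by enumeration for small
tie-free samples, normal approximation with tie and continuity correction
otherwise).  No multiplicity correction is applied across the four states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import logger

STATES = ("MES", "AC", "OPC", "NPC")

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_LIMIT = 12


def state_composition(ann: pd.DataFrame, by_patient: bool = False) -> pd.DataFrame:
    """Per-state proportions within hypoxic and non-hypoxic cells.

    ``ann`` needs ``state`` and ``hypoxic`` columns (plus ``patient`` and
    ``idh_status`` when ``by_patient``).  Strata with zero cells in a class
    get NaN proportions with a warning, never silent zeros.
    """
    for col in ("state", "hypoxic"):
        if col not in ann.columns:
            raise ValueError(f"annotation column {col!r} missing")
    if by_patient:
        if "patient" not in ann.columns:
            raise ValueError("by_patient requires a 'patient' column")
        groups = list(ann.groupby("patient", observed=True, sort=True))
    else:
        groups = [("pooled", ann)]

    rows = []
    for patient, sub in groups:
        idh = (sub["idh_status"].iloc[0]
               if "idh_status" in sub.columns and len(sub) else "NA")
        hyp = sub[sub["hypoxic"].astype(bool)]
        non = sub[~sub["hypoxic"].astype(bool)]
        for cls, frame in (("hypoxic", hyp), ("nonhypoxic", non)):
            if len(frame) == 0:
                logger.warning("state_composition: stratum %s has no %s cells; "
                               "proportions reported as NaN", patient, cls)
        for state in STATES:
            n_h = int((hyp["state"] == state).sum())
            n_n = int((non["state"] == state).sum())
            p_h = n_h / len(hyp) if len(hyp) else np.nan
            p_n = n_n / len(non) if len(non) else np.nan
            rows.append({
                "patient": patient, "idh_status": idh, "state": state,
                "n_hypoxic": n_h, "n_nonhypoxic": n_n,
                "prop_hypoxic": p_h, "prop_nonhypoxic": p_n,
                "delta": p_h - p_n,
            })
    return pd.DataFrame(rows)


@dataclass
class GroupTest:
    """Two-sided rank-sum comparison of one state's shift between groups."""

    state: str
    group_a: str
    group_b: str
    statistic: float
    pval: float
    n_a: int
    n_b: int

    @property
    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.pval <= cut:
                return mark
        return "ns"


def rank_sum_test(a: Sequence[float], b: Sequence[float],
                  state: str = "", group_a: str = "a", group_b: str = "b"
                  ) -> GroupTest:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Uses the exact permutation null when the combined sample is small
    (n_a + n_b <= 12) and tie-free, otherwise the normal approximation
    with tie and continuity corrections.  The reported statistic is the
    Mann–Whitney U of the first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_LIMIT and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=True)
    return GroupTest(state=state, group_a=group_a, group_b=group_b,
                     statistic=float(res.statistic), pval=float(min(res.pvalue, 1.0)),
                     n_a=int(a.size), n_b=int(b.size))


def idh_shift_report(shift: pd.DataFrame
                     ) -> tuple[list[GroupTest], pd.DataFrame]:
    """Compare per-patient state shifts between IDH-WT and IDH-MUT groups.

    ``shift`` is a per-patient composition table (from
    ``state_composition(..., by_patient=True)``).  For each state the
    per-patient deltas of the two IDH groups are compared by rank-sum test.
    Returns the four tests and a per-patient summary (hypoxic fraction and
    per-state deltas).  Patient order does not affect the result.
    """
    for col in ("patient", "idh_status", "state", "delta"):
        if col not in shift.columns:
            raise ValueError(f"shift table column {col!r} missing")
    groups = set(shift["idh_status"])
    if not {"WT", "MUT"} <= groups:
        raise ValueError("need at least one patient in each IDH group (WT, MUT)")

    tests = []
    for state in STATES:
        sub = shift[shift["state"] == state].sort_values("patient")
        wt = sub.loc[sub["idh_status"] == "WT", "delta"].to_numpy()
        mut = sub.loc[sub["idh_status"] == "MUT", "delta"].to_numpy()
        tests.append(rank_sum_test(wt, mut, state=state,
                                   group_a="WT", group_b="MUT"))

    per_patient = []
    for patient, sub in shift.groupby("patient", observed=True, sort=True):
        n_h = int(sub["n_hypoxic"].sum())
        n_n = int(sub["n_nonhypoxic"].sum())
        row = {
            "patient": patient,
            "idh_status": sub["idh_status"].iloc[0],
            "n_cells": n_h + n_n,
            "frac_hypoxic": n_h / (n_h + n_n) if n_h + n_n else np.nan,
        }
        for state in STATES:
            srow = sub[sub["state"] == state]
            row[f"delta_{state}"] = float(srow["delta"].iloc[0]) if len(srow) else np.nan
        per_patient.append(row)
    summary = pd.DataFrame(per_patient)
    return tests, summary


def group_tests_to_frame(tests: Sequence[GroupTest]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(t) for t in tests])
    frame["stars"] = [t.stars for t in tests]
    return frame
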