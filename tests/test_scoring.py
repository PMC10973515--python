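import numpy as np
import pandas as pd
import pytest

import gliohypoxia as gh
from conftest import make_cells
from helpers import module_score_oracle

RAW = ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")


def lognormed(counts, gene_names=None):
    return gh.log_normalize(make_cells(counts, gene_names=gene_names))


def with_layer(values, gene_names=None):
    """AnnData whose lognorm layer is set directly to ``values``."""
    cells = make_cells(np.zeros_like(values, dtype=np.int64) + 1,
                       gene_names=gene_names)
    cells.layers["lognorm"] = np.asarray(values, dtype=float)
    return cells


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        cells = with_layer(np.full((6, 30), 0.7))
        sig = gh.Signature("s", [f"G{j:03d}" for j in range(0, 30, 3)])
        scores = gh.module_score(cells, sig, gh.ScoreParams(n_bins=5, n_ctrl=7))
        np.testing.assert_allclose(scores, 0.0, atol=1e-15)

    def test_additive_boost_on_signature_genes(self):
        base = np.full((4, 40), 0.3)
        sig_genes = [f"G{j:03d}" for j in range(5)]
        vals = base.copy()
        vals[:, :5] += 1.25
        cells = with_layer(vals)
        scores = gh.module_score(cells, gh.Signature("s", sig_genes),
                                 gh.ScoreParams(n_bins=4, n_ctrl=10))
        np.testing.assert_allclose(scores, 1.25, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_genes = 4, 10
        vals = rng.random((n_cells, n_genes)).round(3)
        names = [f"G{j:03d}" for j in range(n_genes)]
        cells = with_layer(vals, gene_names=names)
        sig = gh.Signature("sig", ["G001", "G004", "G007"])
        params = gh.ScoreParams(n_bins=2, n_ctrl=1, seed=seed)
        got = gh.module_score(cells, sig, params)
        want = module_score_oracle(vals, names, "sig", sig.genes, 2, 1, seed)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_invariant_to_cell_and_gene_permutation(self):
        rng = np.random.default_rng(5)
        vals = rng.random((8, 25))
        names = [f"G{j:03d}" for j in range(25)]
        sig = gh.Signature("s", ["G003", "G010", "G020"])
        params = gh.ScoreParams(n_bins=5, n_ctrl=20, seed=1)
        base = gh.module_score(with_layer(vals, names), sig, params)
        cperm = rng.permutation(8)
        cells_p = with_layer(vals[cperm], names)
        np.testing.assert_allclose(
            gh.module_score(cells_p, sig, params), base[cperm], atol=1e-12)
        gperm = rng.permutation(25)
        cells_g = with_layer(vals[:, gperm], [names[j] for j in gperm])
        np.testing.assert_allclose(
            gh.module_score(cells_g, sig, params), base, atol=1e-12)

    def test_invariant_to_global_constant_shift(self):
        rng = np.random.default_rng(6)
        vals = rng.random((5, 20))
        names = [f"G{j:03d}" for j in range(20)]
        sig = gh.Signature("s", ["G002", "G008"])
        params = gh.ScoreParams(n_bins=4, n_ctrl=15, seed=3)
        a = gh.module_score(with_layer(vals, names), sig, params)
        b = gh.module_score(with_layer(vals + 2.5, names), sig, params)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_absent_genes_warned_all_absent_errors(self, caplog):
        cells = with_layer(np.random.default_rng(0).random((3, 10)))
        with caplog.at_level("WARNING", logger="gliohypoxia"):
            gh.module_score(cells, gh.Signature("s", ["G001", "NOPE"]),
                            gh.ScoreParams(n_bins=2, n_ctrl=2))
        assert any("absent" in r.message for r in caplog.records)
        with pytest.raises(ValueError):
            gh.module_score(cells, gh.Signature("s", ["NOPE"]),
                            gh.ScoreParams(n_bins=2, n_ctrl=2))

    def test_requires_lognorm_layer(self):
        cells = make_cells(np.ones((3, 5), dtype=np.int64))
        with pytest.raises(ValueError, match="lognorm"):
            gh.module_score(cells, gh.Signature("s", ["G001"]))

    def test_program_cells_score_above_background(self, small_cohort):
        """Hypoxia-program-positive cells stochastically dominate."""
        cfg, cells, truth = small_cohort
        sig = gh.Signature("hyp", list(cfg.hypoxia_program))
        scores = gh.module_score(cells, sig, gh.ScoreParams(seed=11))
        hyp = truth["true_hypoxic"].to_numpy()
        q_pos = np.quantile(scores[hyp], [0.25, 0.5, 0.75])
        q_neg = np.quantile(scores[~hyp], [0.25, 0.5, 0.75])
        assert (q_pos > q_neg).all()


class TestScoreStates:
    def scores_frame(self, rows):
        return pd.DataFrame(rows, columns=[f"score_{n}" for n in RAW])

    def test_argmax_and_collapse(self, small_cohort, state_signatures):
        cfg, cells, truth = small_cohort
        ann = gh.score_states(cells, state_signatures, gh.ScoreParams(seed=11))
        assert set(ann["state"]) <= {"MES", "AC", "OPC", "NPC"}
        # argmax consistency
        scores = ann[[f"score_{n}" for n in RAW]].to_numpy()
        best = scores.argmax(axis=1)
        assert all(RAW[i] == s for i, s in zip(best, ann["state_raw"]))

    def test_planted_states_recovered(self, small_cohort, state_signatures):
        cfg, cells, truth = small_cohort
        ann = gh.score_states(cells, state_signatures, gh.ScoreParams(seed=11))
        acc = (ann["state"].to_numpy() == truth["true_state"].to_numpy()).mean()
        assert acc >= 0.95

    def test_tie_breaks_by_fixed_order(self):
        vals = np.full((2, 60), 0.5)
        names = ([f"{n}g{i}" for n in RAW for i in range(5)]
                 + [f"B{i:02d}" for i in range(30)])
        cells = with_layer(vals, gene_names=names)
        sigs = [gh.Signature(n, [f"{n}g{i}" for i in range(5)]) for n in RAW]
        ann = gh.score_states(cells, sigs, gh.ScoreParams(n_bins=3, n_ctrl=5))
        # constant matrix: all six scores 0 -> tie -> first label in order
        assert (ann["state_raw"] == "MES1").all()
        assert (ann["state"] == "MES").all()

    def test_missing_state_set_rejected(self, small_cohort, state_signatures):
        _, cells, _ = small_cohort
        with pytest.raises(ValueError, match="NPC2"):
            gh.score_states(cells, state_signatures[:5], gh.ScoreParams(seed=0))

    def test_invariant_to_common_score_shift(self):
        rows = [(0.4, 0.1, 0.3, 0.0, 0.0, 0.0)]
        ann = self.scores_frame(rows)
        ann2 = self.scores_frame([(v + 1.7 for v in rows[0])])
        for frame in (ann, ann2):
            scores = frame[[f"score_{n}" for n in RAW]].to_numpy()
            assert RAW[scores.argmax(axis=1)[0]] == "MES1"


class TestStateCoordinates:
    def frame(self, mes1=0.0, mes2=0.0, ac=0.0, opc=0.0, npc1=0.0, npc2=0.0):
        return pd.DataFrame([{
            "score_MES1": mes1, "score_MES2": mes2, "score_AC": ac,
            "score_OPC": opc, "score_NPC1": npc1, "score_NPC2": npc2,
        }])

    def test_full_symmetry_is_origin(self):
        ann = gh.state_coordinates(self.frame(0.2, 0.2, 0.2, 0.2, 0.2, 0.2))
        assert ann["coord_x"].iloc[0] == 0.0
        assert ann["coord_y"].iloc[0] == 0.0

    def test_pure_opc_points_up_left(self):
        ann = gh.state_coordinates(self.frame(opc=1.0))
        assert ann["coord_y"].iloc[0] == pytest.approx(1.0)
        assert ann["coord_x"].iloc[0] == pytest.approx(-1.0)   # -log2(1+1)

    def test_mes_hemisphere_sign_convention(self):
        ann = gh.state_coordinates(self.frame(mes1=0.8, ac=0.2))
        assert ann["coord_y"].iloc[0] < 0
        assert ann["coord_x"].iloc[0] > 0
        ann2 = gh.state_coordinates(self.frame(ac=0.8, mes1=0.2))
        assert ann2["coord_x"].iloc[0] < 0

    def test_npc_hemisphere_sign_convention(self):
        ann = gh.state_coordinates(self.frame(npc1=0.9, opc=0.1))
        assert ann["coord_y"].iloc[0] > 0
        assert ann["coord_x"].iloc[0] > 0

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError, match="score"):
            gh.state_coordinates(pd.DataFrame({"score_MES1": [0.1]}))
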