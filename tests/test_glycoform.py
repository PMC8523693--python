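"""Glycoform inference: hypothesis selection, transitions, BHM posteriors."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycodia import chem
from glycodia.glycan import GlycanComposition, enumerate_y_fragments, parse_glycan
from glycodia.glycoform import (
    GlycoformHypothesis,
    IdentificationTransition,
    aggregate_composition_pp,
    bhm_posterior,
    generate_identification_transitions,
    glycoform_qvalues,
    precursor_m_set,
    score_identification_transitions,
    select_background_glycoforms,
)
from glycodia.library import IsolationScheme

PEPTIDE = "AAJSTLK"
CORE = "(N(N(H(H)(H))))"


def wide_scheme():
    # one huge window so all candidates co-isolate
    return IsolationScheme(((0.0, 1e6),))


def brute_force_posterior(hypotheses, pep_ms2, transitions,
                          pep_ms1=None, m_set=None, pep_ms2_precursor=None):
    """Independent oracle: the full Bayes table with plain-float products."""
    comps = [h.composition for h in hypotheses if not h.is_null]
    n_comp = len(set(comps))
    counts = {}
    for c in comps:
        counts[c] = counts.get(c, 0) + 1
    prior, like_b, like_t = [], [], []
    for h in hypotheses:
        p = pep_ms2 if h.is_null else (1 - pep_ms2) / n_comp / counts[h.composition]
        lb = 1.0
        if pep_ms1 is not None:
            lb *= (1 - pep_ms1) if h.index in (m_set or set()) else pep_ms1
        for k, pk in (pep_ms2_precursor or {}).items():
            lb *= (1 - pk) if h.index == k else pk
        lt = 1.0
        for t in transitions:
            if t.kind != "Y" or t.is_decoy:
                continue
            lt *= (1 - t.pep) if h.index in t.hypotheses else t.pep
        prior.append(p)
        like_b.append(lb)
        like_t.append(lt)
    prior, like_b, like_t = map(np.array, (prior, like_b, like_t))
    p_g = prior * like_b
    p_g = p_g / p_g.sum()
    p_g_t = p_g * like_t
    return p_g, p_g_t / p_g_t.sum()


def simple_hypotheses(n, compositions=None):
    hyps = [GlycoformHypothesis(index=0)]
    for i in range(1, n + 1):
        comp = (compositions[i - 1] if compositions
                else GlycanComposition.from_dict({"H": i}))
        hyps.append(GlycoformHypothesis(
            index=i, structures=(parse_glycan(CORE),), composition=comp,
            precursor_mz=1000.0 + 10 * i, is_target=(i == 1),
        ))
    return hyps


class TestBackgroundSelection:
    def test_n_bg_zero_keeps_target_and_null(self):
        target = parse_glycan(CORE)
        db = [target, parse_glycan("(N(N(H(H)(H(H)))))")]
        hyps = select_background_glycoforms(
            PEPTIDE, (), target, 2, db, wide_scheme(), n_bg=0
        )
        assert len(hyps) == 2
        assert hyps[0].is_null and hyps[1].is_target

    def test_db_with_only_target(self):
        target = parse_glycan(CORE)
        hyps = select_background_glycoforms(
            PEPTIDE, (), target, 2, [target], wide_scheme(), n_bg=50
        )
        assert len(hyps) == 2 and hyps[1].is_target

    def test_ranking_by_jaccard(self):
        target = parse_glycan("(N(N(H(H)(H))))")
        close = parse_glycan("(N(N(H(H)(H(H)))))")  # shares most fragments
        far = parse_glycan("(N(F))")
        hyps = select_background_glycoforms(
            PEPTIDE, (), target, 2, [target, close, far], wide_scheme(), n_bg=1
        )
        bg = [h for h in hyps if not h.is_null and not h.is_target]
        assert len(bg) == 1
        assert bg[0].structures[0].canonical_text == close.canonical_text

    def test_out_of_window_candidates_excluded(self):
        scheme = IsolationScheme.uniform()
        target = parse_glycan(CORE)
        huge = parse_glycan("(N" + "(H" * 10 + ")" * 10 + ")")
        hyps = select_background_glycoforms(
            PEPTIDE, (), target, 2, [target, huge], scheme, n_bg=50
        )
        texts = {s.canonical_text for h in hyps if h.structures for s in h.structures}
        assert huge.canonical_text not in texts


class TestIdentificationTransitions:
    def test_shared_core_maps_to_both_hypotheses(self):
        a = parse_glycan("(N(N(H)))")
        b = parse_glycan("(N(N(F)))")
        hyps = [
            GlycoformHypothesis(0),
            GlycoformHypothesis(1, (a,), a.composition(), 900.0, True),
            GlycoformHypothesis(2, (b,), b.composition(), 892.0, False),
        ]
        trans = generate_identification_transitions(hyps, PEPTIDE, charges=(1,))
        by_comp = {str(t.composition): t.hypotheses for t in trans if t.kind == "Y"}
        assert by_comp["N(1)"] == frozenset({1, 2})
        assert by_comp["N(2)"] == frozenset({1, 2})
        # the symmetric difference is exactly the discriminating transitions
        assert by_comp["H(1)N(2)"] == frozenset({1})
        assert by_comp["F(1)N(2)"] == frozenset({2})

    def test_single_hypothesis_owns_every_transition(self):
        a = parse_glycan(CORE)
        hyps = [GlycoformHypothesis(0),
                GlycoformHypothesis(1, (a,), a.composition(), 900.0, True)]
        trans = generate_identification_transitions(hyps, PEPTIDE, charges=(1, 2))
        assert all(t.hypotheses == frozenset({1}) for t in trans if t.kind == "Y")

    def test_ms2_precursor_transitions_added(self):
        a = parse_glycan(CORE)
        hyps = [GlycoformHypothesis(0),
                GlycoformHypothesis(1, (a,), a.composition(), 900.0, True)]
        trans = generate_identification_transitions(hyps, PEPTIDE)
        assert sum(t.kind == "precursor" for t in trans) == 1


class TestTransitionScoring:
    def _features(self, target_mean, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "score_main": np.concatenate([
                rng.normal(target_mean, 1.0, n), rng.normal(0.0, 1.0, n)
            ]),
            "is_decoy": [False] * n + [True] * n,
        })

    def test_null_transitions_get_high_pep(self):
        f = self._features(0.0, 5000, seed=1)
        pep = score_identification_transitions(f, seed=2)
        assert np.median(pep[~f["is_decoy"]]) >= 0.9

    def test_separated_transitions_get_low_pep(self):
        f = self._features(5.0, 5000, seed=1)
        pep = score_identification_transitions(f, seed=2)
        strong = f["score_main"] > 4.0
        assert np.median(pep[strong & ~f["is_decoy"]]) <= 0.1

    def test_reproducible_under_seed(self):
        f = self._features(2.0, 500, seed=3)
        p1 = score_identification_transitions(f, seed=9)
        p2 = score_identification_transitions(f, seed=9)
        assert np.array_equal(p1, p2)

    def test_requires_decoys(self):
        f = pd.DataFrame({"score_main": [1.0, 2.0], "is_decoy": [False, False]})
        with pytest.raises(ValueError, match="decoy"):
            score_identification_transitions(f, seed=1)


class TestBHM:
    def test_priors_follow_peak_group_pep(self):
        hyps = simple_hypotheses(4)
        post = bhm_posterior(hyps, pep_ms2=0.2, transitions=[])
        assert post.prior == pytest.approx([0.2, 0.2, 0.2, 0.2, 0.2])

    def test_uninformative_evidence_returns_prior(self):
        hyps = simple_hypotheses(3)
        all_ids = frozenset({1, 2, 3})
        trans = [IdentificationTransition("Y", GlycanComposition.from_dict({"H": 1}),
                                          1, 500.0, all_ids, pep=0.5)]
        post = bhm_posterior(hyps, pep_ms2=0.5, transitions=trans,
                             pep_ms1=0.5, m_set=all_ids)
        # A0 differs from glycoforms via M membership; glycoforms stay equal
        assert post.p_g_t[1] == pytest.approx(post.p_g_t[2], abs=1e-12)
        assert post.p_g_t[2] == pytest.approx(post.p_g_t[3], abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        for n_hyp in (1, 2, 3, 4):
            for n_trans in (0, 2, 4, 6):
                hyps = simple_hypotheses(n_hyp)
                trans = []
                for j in range(n_trans):
                    members = frozenset(
                        int(i) for i in range(1, n_hyp + 1) if rng.random() < 0.6
                    ) or frozenset({1})
                    trans.append(IdentificationTransition(
                        "Y", GlycanComposition.from_dict({"H": j + 1}), 1,
                        500.0 + j, members, pep=float(rng.uniform(0.05, 0.95)),
                    ))
                pep_ms2 = float(rng.uniform(0.05, 0.95))
                pep_ms1 = float(rng.uniform(0.05, 0.95))
                m_set = frozenset({1}) if n_hyp >= 1 else frozenset()
                prec = {1: float(rng.uniform(0.05, 0.95))}
                post = bhm_posterior(hyps, pep_ms2, trans, pep_ms1, m_set, prec)
                bg, bgt = brute_force_posterior(hyps, pep_ms2, trans,
                                               pep_ms1, m_set, prec)
                np.testing.assert_allclose(post.p_g, bg, atol=1e-12)
                np.testing.assert_allclose(post.p_g_t, bgt, atol=1e-12)
                assert abs(post.p_g.sum() - 1.0) < 1e-10
                assert abs(post.p_g_t.sum() - 1.0) < 1e-10
                assert abs(post.prior.sum() - 1.0) < 1e-10

    def test_hand_computed_discriminating_transition(self):
        # 2 glycoforms + A0, one transition private to hypothesis 1, PEP 0.1
        hyps = simple_hypotheses(2)
        trans = [IdentificationTransition("Y", GlycanComposition.from_dict({"H": 1}),
                                          1, 500.0, frozenset({1}), pep=0.1)]
        post = bhm_posterior(hyps, pep_ms2=0.25, transitions=trans)
        # priors: (0.25, 0.375, 0.375); likelihoods: (0.1, 0.9, 0.1)
        expected = np.array([0.25 * 0.1, 0.375 * 0.9, 0.375 * 0.1])
        np.testing.assert_allclose(post.p_g_t, expected / expected.sum(), atol=1e-12)

    def test_stronger_private_evidence_raises_posterior(self):
        hyps = simple_hypotheses(3)
        last = None
        for pep in (0.9, 0.5, 0.2, 0.05):
            trans = [IdentificationTransition(
                "Y", GlycanComposition.from_dict({"H": 1}), 1, 500.0,
                frozenset({1}), pep=pep,
            )]
            post = bhm_posterior(hyps, pep_ms2=0.3, transitions=trans)
            if last is not None:
                assert post.p_g_t[1] > last
            last = post.p_g_t[1]


class TestCompositionAggregation:
    def test_isomer_pps_sum(self):
        comp = GlycanComposition.from_dict({"H": 5, "N": 2})
        hyps = [
            GlycoformHypothesis(0),
            GlycoformHypothesis(1, (parse_glycan(CORE),), comp, 900.0, True),
            GlycoformHypothesis(2, (parse_glycan(CORE),), comp, 900.0, False),
        ]
        from glycodia.glycoform import GlycoformPosterior

        post = GlycoformPosterior(hyps, np.array([0.4, 0.3, 0.3]),
                                  np.array([0.5, 0.3, 0.2]),
                                  np.array([0.5, 0.3, 0.2]))
        pps = aggregate_composition_pp(post)
        assert pps[comp] == pytest.approx(0.5)
        assert pps[None] == pytest.approx(0.5)
        assert sum(pps.values()) == pytest.approx(1.0, abs=1e-10)

    def test_single_structure_passthrough(self):
        comp = GlycanComposition.from_dict({"H": 3, "N": 2})
        hyps = simple_hypotheses(1, compositions=[comp])
        trans = []
        post = bhm_posterior(hyps, pep_ms2=0.2, transitions=trans)
        assert aggregate_composition_pp(post)[comp] == pytest.approx(post.p_g_t[1])


class TestGlycoformQ:
    def test_mean_pep_of_accepted(self):
        table = pd.DataFrame({
            "run_id": ["r1", "r1"],
            "glycopeptide_id": ["a", "b"],
            "pp": [0.99, 0.98],
        })
        out = glycoform_qvalues(table)
        assert sorted(out["q_glycoform"]) == pytest.approx([0.01, 0.015])

    def test_perfect_pp_gives_zero_pep(self):
        table = pd.DataFrame({
            "run_id": ["r1"], "glycopeptide_id": ["a"], "pp": [1.0],
        })
        out = glycoform_qvalues(table)
        assert out["pep_glycoform"].iloc[0] == 0.0
        assert out["q_glycoform"].iloc[0] == 0.0


class TestMSet:
    def test_within_tolerance_membership(self):
        hyps = [
            GlycoformHypothesis(0),
            GlycoformHypothesis(1, (parse_glycan(CORE),),
                                GlycanComposition.from_dict({"H": 3, "N": 2}),
                                1000.000, True),
            GlycoformHypothesis(2, (parse_glycan(CORE),),
                                GlycanComposition.from_dict({"H": 4, "N": 2}),
                                1000.005, False),
            GlycoformHypothesis(3, (parse_glycan(CORE),),
                                GlycanComposition.from_dict({"H": 5, "N": 2}),
                                1008.0, False),
        ]
        m = precursor_m_set(hyps, 1000.0, tol_ppm=10.0)
        assert m == frozenset({1, 2})
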