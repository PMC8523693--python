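"""Spectral library building: annotation, consensus, filters, RT calibration."""

import numpy as np
import pytest

from glycodia import chem
from glycodia.glycan import parse_glycan
from glycodia.library import (
    GPSM,
    AnnotatedTransition,
    IsolationScheme,
    RtCalibration,
    annotate_spectrum,
    build_consensus,
    calibrate_rt,
    filter_transitions,
    merge_libraries,
    select_best_structure,
    theoretical_transitions,
)

from conftest import make_entry

CORE = "(N(N(H(H)(H))))"


def make_gpsm(glycan_text=CORE, score=20.0, spectrum=None, rt=30.0, charge=2,
              peptide="AAJSTLK"):
    if spectrum is None:
        spectrum = np.zeros((0, 2))
    return GPSM(
        peptide=peptide, modifications=(), glycan=parse_glycan(glycan_text),
        charge=charge, total_score=score, rt=rt, spectrum=spectrum,
    )


class TestFragmentArithmetic:
    def test_y1_ion_of_ajk(self):
        # y1 of AJK is lysine: residue + water + proton
        _, y, _, _ = chem.backbone_fragment_masses("AJK")
        assert chem.mz_from_mass(y[0], 1) == pytest.approx(147.1128, abs=1e-3)

    def test_y0_doubly_charged(self):
        pep_mass = chem.peptide_mass("AAJSTLK")
        theos = theoretical_transitions("AAJSTLK", (), parse_glycan(CORE))
        y0_2 = [mz for s, o, c, z, mz in theos if s == "Y" and c == "" and z == 2]
        assert y0_2[0] == pytest.approx((pep_mass + 2 * chem.PROTON) / 2)

    def test_stub_ions_require_glycosite(self):
        theos = theoretical_transitions("AAJSTLK", (), parse_glycan("(N)"))
        # b1/b2 ions cover only A,A (no J): no -N1 stubs there
        assert not any(s == "b-N1" and o <= 2 for s, o, c, z, mz in theos)
        assert any(s == "b-N1" and o == 3 for s, o, c, z, mz in theos)


class TestAnnotate:
    def test_tolerance_window(self):
        theos = theoretical_transitions("AAJSTLK", (), parse_glycan(CORE))
        mz0 = theos[0][4]
        inside = make_gpsm(spectrum=[(mz0 * (1 + 10e-6), 500.0)])
        outside = make_gpsm(spectrum=[(mz0 * (1 + 25e-6), 500.0)])
        assert any(t.mz == pytest.approx(mz0) for t in annotate_spectrum(inside))
        assert not annotate_spectrum(outside)

    def test_annotation_records_theoretical_mz(self):
        theos = theoretical_transitions("AAJSTLK", (), parse_glycan(CORE))
        mz0 = theos[0][4]
        out = annotate_spectrum(make_gpsm(spectrum=[(mz0 * (1 + 10e-6), 500.0)]))
        assert out[0].mz == pytest.approx(mz0, abs=1e-9)


class TestSelectBestStructure:
    def test_summed_score_wins(self):
        s1a, s1b = make_gpsm("(N(H(F)))", 10.0), make_gpsm("(N(H(F)))", 5.0)
        s2 = make_gpsm("(N(H)(F))", 14.0)
        kept = select_best_structure([s1a, s2, s1b])
        assert len(kept) == 2
        assert all(g.glycan.canonical_text == "(N(H(F)))" for g in kept)

    def test_single_structure(self):
        gpsms = [make_gpsm(CORE, 5.0), make_gpsm(CORE, 2.0)]
        assert select_best_structure(gpsms) == gpsms

    def test_tie_breaks_by_canonical_string_stable_under_permutation(self):
        a, b = make_gpsm("(N(H(F)))", 10.0), make_gpsm("(N(H)(F))", 10.0)
        kept1 = select_best_structure([a, b])
        kept2 = select_best_structure([b, a])
        assert kept1[0].glycan.canonical_text == kept2[0].glycan.canonical_text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_structure([])


class TestConsensus:
    def _trans(self, intensities):
        """Y transitions keyed by composition with given intensities."""
        out = []
        for i, intensity in enumerate(intensities):
            if intensity is None:
                continue
            out.append(AnnotatedTransition("Y", None, f"N({i + 1})", 1,
                                           1000.0 + i, intensity))
        return out

    def test_single_replicate_unchanged(self):
        g = make_gpsm(score=7.0)
        trans = self._trans([10, 20, 30])
        entry = build_consensus([g], [trans])
        assert [t.intensity for t in entry.transitions] == [10, 20, 30]
        assert entry.replicate_count == 1

    def test_presence_threshold_strictly_above_60pct(self):
        gpsms = [make_gpsm(score=1.0) for _ in range(5)]
        base = [100.0] * 5
        # peak 0 in 3/5 replicates (60%: dropped), peak 1 in 4/5 (kept)
        reps = []
        for i in range(5):
            reps.append(self._trans([
                100.0 if i < 3 else None,
                100.0 if i < 4 else None,
                *base[:3],
            ]))
        entry = build_consensus(gpsms, reps)
        keys = {t.composition for t in entry.transitions}
        assert "N(1)" not in keys and "N(2)" in keys

    def test_weighted_mean_of_identical_replicates(self):
        gpsms = [make_gpsm(score=1.0), make_gpsm(score=3.0)]
        reps = [self._trans([10, 20, 30])] * 2
        entry = build_consensus(gpsms, reps)
        assert [t.intensity for t in entry.transitions] == [10, 20, 30]

    def test_dissimilar_replicate_discarded(self):
        gpsms = [make_gpsm(score=1.0) for _ in range(3)]
        good = self._trans([100, 100, 100])
        bad = [AnnotatedTransition("Y", None, "H(9)", 1, 2000.0, 999.0)]
        entry = build_consensus(gpsms, [good, good, bad])
        assert entry.replicate_count == 2
        assert all(t.composition != "H(9)" for t in entry.transitions)

    def test_permutation_invariance(self):
        gpsms = [make_gpsm(score=s) for s in (1.0, 2.0, 3.0)]
        reps = [self._trans([10, 20, 30]), self._trans([12, 22, 32]),
                self._trans([14, 24, 34])]
        e1 = build_consensus(gpsms, reps)
        order = [2, 0, 1]
        e2 = build_consensus([gpsms[i] for i in order], [reps[i] for i in order])
        assert [t.intensity for t in e1.transitions] == pytest.approx(
            [t.intensity for t in e2.transitions]
        )

    def test_all_dissimilar_falls_back_to_best_scoring(self):
        gpsms = [make_gpsm(score=1.0), make_gpsm(score=9.0)]
        a = self._trans([100, None, None])
        b = [AnnotatedTransition("Y", None, "H(8)", 1, 1500.0, 50.0)]
        entry = build_consensus(gpsms, [a, b])
        assert entry.replicate_count == 1
        assert entry.transitions[0].composition == "H(8)"


class TestFilterTransitions:
    def test_caps_and_quantifier_flags(self):
        pep = {("y", i + 1, 1): 100.0 + i for i in range(6)}
        pep.update({("b", i + 1, 1): 50.0 + i for i in range(6)})  # 12 total, 2 shared ordinals fine
        entry = make_entry(
            peptide="AAJSTLVVVVVVK",
            pep_intensities={("y", i + 1, 1): 100.0 + i for i in range(8)}
            | {("b", i + 1, 1): 50.0 + i for i in range(7)},
            gly_intensities={(f"N(2)H({i + 1})" if i else "N(2)", 1): 200.0 + i
                             for i in range(3)}
            | {(f"N(1)", 2): 90.0} | {("N(2)H(3)", 2): 80.0}
            | {("N(2)H(2)", 2): 70.0} | {("N(2)H(1)", 2): 60.0}
            | {("N(2)", 2): 55.0} | {("$", 1): 40.0} | {("", 1): 30.0}
            | {("N(1)", 1): 20.0} | {("", 2): 10.0} | {("$", 2): 5.0},
        )
        out = filter_transitions(entry, scan_range=(10.0, 1e6))
        peps = [t for t in out.transitions if t.part == "peptide"]
        glys = [t for t in out.transitions if t.part == "glycan"]
        assert len(peps) == 10 and len(glys) == 10
        assert sum(t.quantify for t in peps) == 6
        assert sum(t.quantify for t in glys) == 6
        # quantifiers are the most intense of each part
        assert min(t.intensity for t in peps if t.quantify) >= max(
            t.intensity for t in peps if not t.quantify
        )

    def test_too_few_glycan_transitions_drops_entry(self):
        entry = make_entry(gly_intensities={("N(1)", 1): 10.0, ("N(2)", 1): 5.0})
        assert filter_transitions(entry, scan_range=(10.0, 1e6)) is None

    def test_fragment_in_own_isolation_window_excluded(self):
        entry = make_entry()
        scheme = IsolationScheme.uniform()
        near = AnnotatedTransition("Y", None, "H(7)", 1, entry.precursor_mz + 1.0, 999.0)
        entry.transitions.append(near)
        out = filter_transitions(entry, scan_range=(10.0, 1e6), isolation_scheme=scheme)
        assert all(t.mz != pytest.approx(near.mz) for t in out.transitions)

    def test_min_max_invariant(self):
        entry = make_entry()
        out = filter_transitions(entry, scan_range=(10.0, 1e6))
        for part in ("peptide", "glycan"):
            n = len(out.part_transitions(part))
            assert 3 <= n <= 10
            assert sum(t.quantify for t in out.part_transitions(part)) <= 6


class TestRtCalibration:
    def test_identity_anchors(self):
        anchors = [(float(x), float(x)) for x in range(10, 50, 2)]
        cal = RtCalibration.fit(anchors)
        x = np.linspace(12, 46, 13)
        assert cal(x) == pytest.approx(x, abs=1e-6)

    def test_affine_anchors_recovered(self):
        anchors = [(float(x), 2.0 * x) for x in np.linspace(5, 55, 30)]
        entries = [make_entry(rt=r) for r in (10.0, 20.0, 40.0)]
        calibrated, _ = calibrate_rt(anchors, entries)
        for e, expected in zip(calibrated, (20.0, 40.0, 80.0)):
            assert e.rt == pytest.approx(expected, rel=0.01)

    def test_too_few_anchors(self):
        with pytest.raises(ValueError):
            RtCalibration.fit([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])


class TestMergeLibraries:
    def test_disjoint_union(self):
        a = [make_entry(peptide="AAJSTLK")]
        b = [make_entry(peptide="VVJVSAK")]
        assert len(merge_libraries([a, b])) == 2

    def test_duplicate_prefers_more_replicates(self):
        a = make_entry()
        a.replicate_count = 2
        b = make_entry()
        b.replicate_count = 5
        merged = merge_libraries([[a], [b]])
        assert len(merged) == 1 and merged[0].replicate_count == 5

    def test_merge_with_empty_is_identity(self):
        a = [make_entry()]
        merged = merge_libraries([a, []])
        assert len(merged) == 1 and merged[0].precursor_id == a[0].precursor_id
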