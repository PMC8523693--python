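"""Inference of co-isolated glycoforms from identification transitions.

With wide DIA isolation windows, glycopeptides sharing a peptide sequence
but carrying different glycans (glycoforms) are co-fragmented, and their HCD
spectra share most peptide fragments and core Y ions.  This module resolves
which glycoform generated a detected peak group:

1. background glycoforms — database glycans on the same peptide whose
   precursor m/z falls into the target's isolation window — are collected,
   isomeric structures with identical theoretical Y-fragment sets merged,
   ranked by Jaccard similarity of their Y-fragment sets to the target
   glycan, and capped at ``n_bg``;
2. the union of theoretical Y ions over all hypotheses ("identification
   transitions") plus per-hypothesis unfragmented-precursor transitions are
   generated in silico;
3. per-transition discriminant scores against decoy identification
   transitions yield transition PEPs;
4. a Bayesian hierarchical model integrates the peak-group PEP (prior),
   MS1/MS2-precursor conditionals, and transition conditionals into a
   posterior probability (PP) per glycoform hypothesis, aggregated to glycan
   compositions; glycoform-level q-values follow by PEP averaging of 1 - PP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import chem
from .glycan import (
    DEFAULT_REGISTRY,
    GlycanComposition,
    GlycanStruct,
    MonosaccharideRegistry,
    enumerate_y_fragments,
    jaccard_similarity,
    merge_isomers,
)
from .library import IsolationScheme
from .scoring import pep_to_qvalue, storey_pi0

__all__ = [
    "GlycoformHypothesis",
    "IdentificationTransition",
    "GlycoformPosterior",
    "select_background_glycoforms",
    "generate_identification_transitions",
    "score_identification_transitions",
    "bhm_posterior",
    "aggregate_composition_pp",
    "glycoform_qvalues",
]

PROB_FLOOR = 1e-12  # per-factor floor against log-space underflow


@dataclass(frozen=True)
class GlycoformHypothesis:
    """One glycoform hypothesis A_i (i = 0 is the incorrect-detection A0).

    ``structures`` is an isomer group with identical Y-fragment sets; empty
    for A0.  ``precursor_mz`` is the hypothesis' own glycopeptide precursor
    m/z at the query charge (None for A0).
    """

    index: int
    structures: Tuple[GlycanStruct, ...] = ()
    composition: Optional[GlycanComposition] = None
    precursor_mz: Optional[float] = None
    is_target: bool = False

    @property
    def is_null(self) -> bool:
        return self.index == 0


@dataclass
class IdentificationTransition:
    """One in-silico Y (or unfragmented precursor) identification transition.

    ``hypotheses`` holds the indices of the hypotheses this transition can
    originate from (the transition(i) sets); for precursor transitions it is
    the single hypothesis whose unfragmented precursor it traces.
    """

    kind: str  # "Y" or "precursor"
    composition: Optional[GlycanComposition]
    charge: int
    mz: float
    hypotheses: FrozenSet[int]
    pep: float = np.nan
    is_decoy: bool = False


def select_background_glycoforms(
    peptide: str,
    modifications: Sequence[chem.Modification],
    target_glycan: GlycanStruct,
    charge: int,
    glycan_db: Sequence[GlycanStruct],
    isolation_scheme: IsolationScheme,
    n_bg: int = 50,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> List[GlycoformHypothesis]:
    """Build the hypothesis list for one target glycopeptide precursor.

    Database glycans on the same peptide whose precursor m/z (at the query
    charge) shares an isolation window with the target are the candidates;
    isomer groups with identical Y-fragment sets are merged, ranked by
    Jaccard similarity to the target glycan (descending, ties by canonical
    string), and the top ``n_bg`` background groups are kept.  The target's
    own group is always included.  Hypothesis 0 is the incorrect-detection
    null A0.
    """
    pep_mass = chem.peptide_mass(peptide, modifications)
    target_mz = chem.mz_from_mass(pep_mass + target_glycan.mass(registry), charge)
    target_y = enumerate_y_fragments(target_glycan)
    target_text = target_glycan.canonical_text

    pool: Dict[str, GlycanStruct] = {target_text: target_glycan}
    for g in glycan_db:
        mz = chem.mz_from_mass(pep_mass + g.mass(registry), charge)
        if isolation_scheme.shares_window(target_mz, mz):
            pool.setdefault(g.canonical_text, g)

    by_comp: Dict[GlycanComposition, List[GlycanStruct]] = {}
    for g in pool.values():
        by_comp.setdefault(g.composition(), []).append(g)

    groups: List[Tuple[float, str, Tuple[GlycanStruct, ...]]] = []
    target_group: Optional[Tuple[float, str, Tuple[GlycanStruct, ...]]] = None
    for comp, structs in by_comp.items():
        for iso_group in merge_isomers(structs):
            jac = jaccard_similarity(enumerate_y_fragments(iso_group[0]), target_y)
            item = (jac, iso_group[0].canonical_text, tuple(iso_group))
            if any(s.canonical_text == target_text for s in iso_group):
                target_group = item
            else:
                groups.append(item)

    groups.sort(key=lambda t: (-t[0], t[1]))
    kept = groups[:n_bg]
    assert target_group is not None
    kept.insert(0, target_group)

    hypotheses = [GlycoformHypothesis(index=0)]
    for i, (_jac, _text, structs) in enumerate(kept, start=1):
        comp = structs[0].composition()
        hypotheses.append(
            GlycoformHypothesis(
                index=i,
                structures=structs,
                composition=comp,
                precursor_mz=chem.mz_from_mass(pep_mass + comp.mass(registry), charge),
                is_target=any(s.canonical_text == target_text for s in structs),
            )
        )
    return hypotheses


def generate_identification_transitions(
    hypotheses: Sequence[GlycoformHypothesis],
    peptide: str,
    modifications: Sequence[chem.Modification] = (),
    scan_range: Tuple[float, float] = (200.0, 2000.0),
    charges: Tuple[int, ...] = (1, 2, 3),
    include_ms2_precursors: bool = True,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> List[IdentificationTransition]:
    """Theoretical Y identification transitions for a hypothesis set.

    The union of discriminating Y-fragment compositions (Y0 is common to all
    glycoforms and omitted) over all hypotheses is generated at the given
    fragment charges within the scan range, each transition mapped to the
    set of hypotheses it can originate from.  With
    ``include_ms2_precursors``, one unfragmented-precursor transition per
    hypothesis is appended (MS2 precursor detection).
    """
    pep_mass = chem.peptide_mass(peptide, modifications)
    origin: Dict[GlycanComposition, set] = {}
    for h in hypotheses:
        if h.is_null:
            continue
        for comp in enumerate_y_fragments(h.structures[0]).discriminating:
            origin.setdefault(comp, set()).add(h.index)

    lo, hi = scan_range
    out: List[IdentificationTransition] = []
    for comp in sorted(origin, key=str):
        m = pep_mass + comp.mass(registry)
        for z in charges:
            mz = chem.mz_from_mass(m, z)
            if lo <= mz <= hi:
                out.append(IdentificationTransition("Y", comp, z, mz,
                                                    frozenset(origin[comp])))
    if include_ms2_precursors:
        for h in hypotheses:
            if h.is_null or h.precursor_mz is None:
                continue
            out.append(IdentificationTransition(
                "precursor", h.composition, 0, h.precursor_mz, frozenset({h.index})
            ))
    return out


def score_identification_transitions(
    features: pd.DataFrame,
    seed: int,
    score_columns: Optional[Sequence[str]] = None,
    lambda_: float = 0.4,
    grid_size: int = 512,
) -> np.ndarray:
    """Per-transition PEPs from target vs decoy identification transitions.

    A univariate discriminant (LDA over the score columns, or the single
    column itself) is converted into a PEP by a two-groups mixture:
    ``PEP(s) = pi0 * f_decoy(s) / f_target(s)`` with kernel density
    estimates on a regular grid and Storey's pi0, clipped to [0, 1].
    """
    if "is_decoy" not in features.columns:
        raise ValueError("transition feature table requires an is_decoy column")
    is_decoy = features["is_decoy"].to_numpy(dtype=bool)
    if not is_decoy.any():
        raise ValueError("no decoy identification transitions to train against")
    if score_columns is None:
        score_columns = [c for c in features.columns if c.startswith("score_")]
    X = features[list(score_columns)].to_numpy(dtype=float)
    if X.shape[1] > 1:
        lda = LinearDiscriminantAnalysis()
        lda.fit(X, (~is_decoy).astype(int))
        s = lda.decision_function(X)
    else:
        s = X[:, 0].copy()
    if s[is_decoy].mean() > s[~is_decoy].mean():
        s = -s

    pi0 = storey_pi0(s[~is_decoy], s[is_decoy], lambda_)
    bw = 1.06 * s.std() * len(s) ** (-1 / 5)
    lo, hi = s.min() - 3 * bw, s.max() + 3 * bw
    edges = np.linspace(lo, hi, grid_size + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    step = edges[1] - edges[0]

    def kde(v: np.ndarray) -> np.ndarray:
        hist, _ = np.histogram(v, bins=edges)
        dens = gaussian_filter1d(hist.astype(float), sigma=bw / step, mode="constant")
        total = dens.sum() * step
        return dens / total if total > 0 else np.full(grid_size, 1.0 / (hi - lo))

    f0 = kde(s[is_decoy])
    f1 = kde(s[~is_decoy])
    f1 = np.maximum(f1, 1e-12 * f1.max())
    pep_grid = np.clip(pi0 * f0 / f1, 0.0, 1.0)
    return np.interp(s, centers, pep_grid)


@dataclass
class GlycoformPosterior:
    """Posterior probabilities for one peak group's hypothesis set."""

    hypotheses: List[GlycoformHypothesis]
    prior: np.ndarray  # P(A_i), Eq over MS2 peak-group PEP
    p_g: np.ndarray  # P(G_i): posterior with precursor evidence
    p_g_t: np.ndarray  # P(G_i | T): posterior with transition evidence

    def pp_by_composition(self) -> Dict[Optional[GlycanComposition], float]:
        """PP per glycan composition (isomer-group PPs summed); key ``None``
        carries the incorrect-detection probability P(A0 | T)."""
        out: Dict[Optional[GlycanComposition], float] = {}
        for h, pp in zip(self.hypotheses, self.p_g_t):
            key = None if h.is_null else h.composition
            out[key] = out.get(key, 0.0) + float(pp)
        return out

    def pp(self, composition: GlycanComposition) -> float:
        return self.pp_by_composition().get(composition, 0.0)


def _hypothesis_priors(
    hypotheses: Sequence[GlycoformHypothesis], pep_ms2: float
) -> np.ndarray:
    """Priors from the MS2 peak-group PEP.

    P(A0) = PEP_MS2; the remaining 1 - PEP_MS2 is divided equally over the N
    candidate glycan *compositions* and, within a composition, equally over
    its isomer-structure groups (considered separately in the model).
    """
    comps = [h.composition for h in hypotheses if not h.is_null]
    n_comp = len(set(comps))
    comp_counts: Dict[GlycanComposition, int] = {}
    for c in comps:
        comp_counts[c] = comp_counts.get(c, 0) + 1
    prior = np.empty(len(hypotheses))
    for i, h in enumerate(hypotheses):
        if h.is_null:
            prior[i] = pep_ms2
        else:
            prior[i] = (1.0 - pep_ms2) / n_comp / comp_counts[h.composition]
    return prior


def precursor_m_set(
    hypotheses: Sequence[GlycoformHypothesis],
    target_precursor_mz: float,
    tol_ppm: float = 10.0,
) -> FrozenSet[int]:
    """Hypotheses whose precursor m/z lies within ``tol_ppm`` of the target
    precursor m/z (the M set of the MS1 conditional); A0 is never a member."""
    members = {
        h.index
        for h in hypotheses
        if not h.is_null
        and h.precursor_mz is not None
        and abs(chem.ppm_error(h.precursor_mz, target_precursor_mz)) <= tol_ppm
    }
    return frozenset(members)


def bhm_posterior(
    hypotheses: Sequence[GlycoformHypothesis],
    pep_ms2: float,
    transitions: Sequence[IdentificationTransition],
    pep_ms1: Optional[float] = None,
    m_set: Optional[FrozenSet[int]] = None,
    pep_ms2_precursor: Optional[Mapping[int, float]] = None,
) -> GlycoformPosterior:
    """Integrate peak-group, precursor and transition evidence (log space).

    Priors come from ``pep_ms2``; the MS1 conditional uses ``pep_ms1`` and
    the in-tolerance set ``m_set``; ``pep_ms2_precursor`` maps hypothesis
    index -> PEP of that hypothesis' unfragmented-precursor transition; each
    Y transition contributes ``1 - pep`` to hypotheses it can originate from
    and ``pep`` to the rest.  Factors are floored at ``PROB_FLOOR``.  Both
    returned posterior vectors are normalized to unit sum.
    """
    hyp = list(hypotheses)
    n = len(hyp)
    prior = _hypothesis_priors(hyp, pep_ms2)

    log_b = np.zeros(n)
    if pep_ms1 is not None:
        members = m_set if m_set is not None else frozenset()
        for i, h in enumerate(hyp):
            p = (1.0 - pep_ms1) if h.index in members else pep_ms1
            log_b[i] += np.log(max(p, PROB_FLOOR))
    if pep_ms2_precursor:
        for k, pep_k in pep_ms2_precursor.items():
            for i, h in enumerate(hyp):
                p = (1.0 - pep_k) if h.index == k else pep_k
                log_b[i] += np.log(max(p, PROB_FLOOR))

    log_post = np.log(np.maximum(prior, PROB_FLOOR)) + log_b
    log_post -= log_post.max()
    p_g = np.exp(log_post)
    if p_g.sum() == 0:
        raise ValueError("all precursor conditionals vanished; degenerate evidence")
    p_g /= p_g.sum()

    log_t = np.zeros(n)
    for t in transitions:
        if t.is_decoy or t.kind != "Y":
            continue
        pep_j = float(t.pep)
        for i, h in enumerate(hyp):
            p = (1.0 - pep_j) if h.index in t.hypotheses else pep_j
            log_t[i] += np.log(max(p, PROB_FLOOR))

    log_full = np.log(np.maximum(p_g, PROB_FLOOR)) + log_t
    log_full -= log_full.max()
    p_g_t = np.exp(log_full)
    if p_g_t.sum() == 0:
        raise ValueError("all transition conditionals vanished; degenerate evidence")
    p_g_t /= p_g_t.sum()

    return GlycoformPosterior(hyp, prior, p_g, p_g_t)


def aggregate_composition_pp(
    posterior: GlycoformPosterior,
) -> Dict[Optional[GlycanComposition], float]:
    """PP per glycan composition: the sum over its isomeric structure groups
    (whose priors were pre-divided equally).  ``None`` keys P(A0 | T)."""
    return posterior.pp_by_composition()


def glycoform_qvalues(
    table: pd.DataFrame,
    run_q: float = 0.05,
    best_run_q: float = 0.01,
) -> pd.DataFrame:
    """Glycoform-level q-values and the default reporting filter.

    ``table`` needs one row per target peak group (background-only hits
    excluded upstream) with columns ``run_id``, ``glycopeptide_id`` and
    ``pp`` (the PP of the library glycan composition).  The glycoform PEP is
    1 - PP; q-values are computed per run by PEP averaging.  The returned
    table adds ``pep_glycoform``, ``q_glycoform`` and a ``reported`` flag
    (q < ``run_q`` in every run and < ``best_run_q`` in at least one).
    """
    out = table.copy()
    out["pep_glycoform"] = 1.0 - out["pp"].to_numpy(dtype=float)
    out["q_glycoform"] = np.nan
    for _run, sub in out.groupby("run_id"):
        out.loc[sub.index, "q_glycoform"] = pep_to_qvalue(
            sub["pep_glycoform"].to_numpy()
        )
    per_gp = out.groupby("glycopeptide_id")["q_glycoform"].agg(["max", "min"])
    ok = per_gp[(per_gp["max"] < run_q) & (per_gp["min"] < best_run_q)].index
    out["reported"] = out["glycopeptide_id"].isin(ok)
    return out
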