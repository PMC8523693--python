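"""Semi-empirical spectrum and RT prediction by k-nearest-neighbor fragment
swapping.

The MS2 spectrum of an unobserved glycopeptide (peptide P, glycan G, charge
n+) is predicted by combining the peptide fragment peaks of library entries
that share P (choosing the k whose glycans are nearest to G) with the glycan
fragment peaks of entries that share G (the k whose peptides are nearest to
P), merged by the mean peptide-to-glycan intensity ratio of the neighbor
spectra.  Peptides are vectorized to amino-acid composition and glycans to
monosaccharide composition (Hex, HexNAc, NeuAc, Fuc); neighborhoods use
Euclidean distance.  RTs are Gaussian-distance-weighted means of same-
peptide entries, charge states pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .glycan import DEFAULT_REGISTRY, GlycanComposition, MonosaccharideRegistry
from .library import (
    AnnotatedTransition,
    IsolationScheme,
    LibraryEntry,
    PrecursorId,
    filter_transitions,
)

__all__ = [
    "peptide_vector",
    "glycan_vector",
    "NeighborSet",
    "find_neighbors",
    "predict_spectrum",
    "predict_rt",
    "cross_validate",
    "extend_library",
]

GLYCAN_VECTOR_CODES = ("H", "N", "A", "F")


def peptide_vector(peptide: str) -> np.ndarray:
    """Amino-acid composition vector (20 counts; the glycosite marker J
    counts as asparagine)."""
    seq = peptide.replace("J", "N")
    return np.array([seq.count(a) for a in chem.AMINO_ACIDS], dtype=float)


def glycan_vector(comp: GlycanComposition) -> np.ndarray:
    """Monosaccharide composition vector over (Hex, HexNAc, NeuAc, Fuc)."""
    return np.array([comp.get(c) for c in GLYCAN_VECTOR_CODES], dtype=float)


@dataclass
class NeighborSet:
    """Neighborhoods of one prediction target.

    ``s_pk`` are the k same-peptide entries whose glycans are nearest to the
    target glycan; ``s_gk`` the k same-glycan entries whose peptides are
    nearest to the target peptide.  ``rt_neighbors`` are the k same-peptide
    entries for RT prediction (charge states pooled) with their glycan
    distances.
    """

    s_pk: List[LibraryEntry]
    s_gk: List[LibraryEntry]
    rt_neighbors: List[Tuple[LibraryEntry, float]]
    k: int


def _k_nearest(
    candidates: Sequence[Tuple[LibraryEntry, float]], k: int
) -> List[Tuple[LibraryEntry, float]]:
    """k nearest by distance; ties at the boundary resolve by input order."""
    ranked = sorted(enumerate(candidates), key=lambda t: (t[1][1], t[0]))
    return [c for _, c in ranked[:k]]


def find_neighbors(
    peptide: str,
    modifications: Sequence[chem.Modification],
    glycan_composition: GlycanComposition,
    charge: int,
    library: Sequence[LibraryEntry],
    k: int = 3,
    use_knn: bool = True,
) -> Optional[NeighborSet]:
    """Locate the peptide- and glycan-sharing neighborhoods of a target.

    Entries identical to the target precursor are excluded.  Returns None
    (prediction skipped) when either neighborhood holds fewer than k
    entries.  With ``use_knn=False`` the full candidate sets are used
    (the no-KNN baseline).
    """
    target_pid = (peptide, tuple(modifications), glycan_composition, charge)
    gv = glycan_vector(glycan_composition)
    pv = peptide_vector(peptide)

    s_p: List[Tuple[LibraryEntry, float]] = []
    s_g: List[Tuple[LibraryEntry, float]] = []
    rt_pool: List[Tuple[LibraryEntry, float]] = []
    for e in library:
        if e.is_decoy:
            continue
        pid = e.precursor_id
        if (pid.peptide, pid.modifications, pid.glycan_composition, pid.charge) == target_pid:
            continue
        if pid.peptide == peptide:
            d = float(np.linalg.norm(glycan_vector(pid.glycan_composition) - gv))
            rt_pool.append((e, d))
            if pid.charge == charge:
                s_p.append((e, d))
        if pid.glycan_composition == glycan_composition and pid.charge == charge:
            d = float(np.linalg.norm(peptide_vector(pid.peptide) - pv))
            s_g.append((e, d))

    if len(s_p) < k or len(s_g) < k or len(rt_pool) < k:
        return None
    if use_knn:
        s_pk = [e for e, _ in _k_nearest(s_p, k)]
        s_gk = [e for e, _ in _k_nearest(s_g, k)]
        rt_neighbors = _k_nearest(rt_pool, k)
    else:
        s_pk = [e for e, _ in s_p]
        s_gk = [e for e, _ in s_g]
        rt_neighbors = rt_pool
    return NeighborSet(s_pk, s_gk, rt_neighbors, k)


def _entry_weight(e: LibraryEntry) -> float:
    return float(e.provenance.get("score_sum", 1.0)) or 1.0


def _consensus_part(
    entries: Sequence[LibraryEntry],
    part: str,
    min_median_dp: float = 0.5,
    presence_fraction: float = 0.6,
) -> Dict[Tuple, Tuple[float, AnnotatedTransition]]:
    """Consensus intensities of one spectrum part across neighbor entries.

    Mirrors the replicate-consensus rules of library building: dissimilar
    entries (median pairwise cosine < 0.5 on the part) are dropped, peaks in
    more than 60% of survivors are kept, intensities are score-weighted
    means.  Returns {transition key: (intensity, template transition)}.
    """
    part_lists = [e.part_transitions(part) for e in entries]

    def dp(a, b):
        da = {t.key: t.intensity for t in a}
        db = {t.key: t.intensity for t in b}
        keys = set(da) | set(db)
        va = np.array([da.get(kk, 0.0) for kk in keys])
        vb = np.array([db.get(kk, 0.0) for kk in keys])
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        return float(va @ vb / (na * nb)) if na > 0 and nb > 0 else 0.0

    keep = list(range(len(entries)))
    if len(entries) > 1:
        keep = [
            i for i in range(len(entries))
            if np.median([dp(part_lists[i], part_lists[j])
                          for j in range(len(entries)) if j != i]) >= min_median_dp
        ]
        if not keep:
            keep = [int(np.argmax([_entry_weight(e) for e in entries]))]

    n_rep = len(keep)
    weights = {i: _entry_weight(entries[i]) for i in keep}
    by_key: Dict[Tuple, List[Tuple[float, AnnotatedTransition]]] = {}
    for i in keep:
        for t in part_lists[i]:
            by_key.setdefault(t.key, []).append((weights[i], t))

    out: Dict[Tuple, Tuple[float, AnnotatedTransition]] = {}
    for key, hits in by_key.items():
        if n_rep > 1 and len(hits) <= presence_fraction * n_rep:
            continue
        w = np.array([h[0] for h in hits])
        v = np.array([h[1].intensity for h in hits])
        out[key] = (float(np.average(v, weights=w)), hits[0][1])
    return out


def predict_spectrum(
    peptide: str,
    modifications: Sequence[chem.Modification],
    glycan_composition: GlycanComposition,
    charge: int,
    neighbors: NeighborSet,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> Optional[LibraryEntry]:
    """Predict the library entry of (P, G, n+) from its neighborhoods.

    The peptide part is the consensus of the same-peptide neighbors, the
    glycan part the consensus of the same-glycan neighbors; the two parts
    are scaled so their summed-intensity ratio equals the mean
    peptide/glycan ratio r over the union of neighbor spectra.  Y-ion and
    backbone m/z are recomputed for the target precursor.
    """
    pep_cons = _consensus_part(neighbors.s_pk, "peptide")
    gly_cons = _consensus_part(neighbors.s_gk, "glycan")
    if not pep_cons or not gly_cons:
        return None

    seen = set()
    ratios = []
    for e in list(neighbors.s_pk) + list(neighbors.s_gk):
        pid = e.precursor_id
        key = (pid.peptide, pid.modifications, pid.glycan_composition, pid.charge)
        if key in seen:
            continue
        seen.add(key)
        pep_sum = sum(t.intensity for t in e.part_transitions("peptide"))
        gly_sum = sum(t.intensity for t in e.part_transitions("glycan"))
        if pep_sum > 0 and gly_sum > 0:
            ratios.append(pep_sum / gly_sum)
    if not ratios:
        return None
    r = float(np.mean(ratios))

    pep_mass = chem.peptide_mass(peptide, modifications)
    b, y, b_site, y_site = chem.backbone_fragment_masses(peptide, modifications)

    transitions: List[AnnotatedTransition] = []
    for (series, ordkey, z), (intensity, tmpl) in pep_cons.items():
        i = (ordkey or 1) - 1
        masses = b if series.startswith("b") else y
        sites = b_site if series.startswith("b") else y_site
        if i >= len(masses):
            continue
        if series.endswith(("-N1", "$")) and not sites[i]:
            continue
        m = masses[i]
        if series.endswith("-N1"):
            m += chem.HEXNAC
        elif series.endswith("$"):
            m += chem.CROSS_RING_OFFSET
        transitions.append(AnnotatedTransition(series, ordkey, None, z,
                                               chem.mz_from_mass(m, z), intensity))
    pep_total = sum(t.intensity for t in transitions)

    gly_transitions: List[AnnotatedTransition] = []
    for (series, compkey, z), (intensity, tmpl) in gly_cons.items():
        if compkey == "$":
            m = pep_mass + chem.CROSS_RING_OFFSET
        else:
            m = pep_mass + GlycanComposition.parse(compkey or "").mass(registry)
        gly_transitions.append(AnnotatedTransition("Y", None, compkey, z,
                                                   chem.mz_from_mass(m, z), intensity))
    gly_total = sum(t.intensity for t in gly_transitions)
    if pep_total <= 0 or gly_total <= 0:
        return None
    # scale the glycan part so that (peptide sum)/(glycan sum) == r
    scale = pep_total / (r * gly_total)
    gly_transitions = [replace(t, intensity=t.intensity * scale) for t in gly_transitions]

    transitions.extend(gly_transitions)
    transitions.sort(key=lambda t: t.mz)

    glycan_struct = next(
        e.glycan_struct for e in neighbors.s_gk if e.glycan_struct is not None
    )
    pid = PrecursorId(peptide, tuple(modifications), glycan_composition, charge)
    return LibraryEntry(
        precursor_id=pid,
        glycan_struct=glycan_struct,
        precursor_mz=chem.glycopeptide_precursor_mz(
            peptide, glycan_composition, charge, modifications, registry
        ),
        rt=predict_rt(neighbors),
        transitions=transitions,
        replicate_count=0,
        provenance={"source": "semi-empirical", "ratio": r},
    )


def predict_rt(neighbors: NeighborSet) -> float:
    """Gaussian-distance-weighted mean RT over the same-peptide neighbors.

    Weights are exp(-d_i^2 / (2 sigma^2)) with sigma^2 the mean squared
    glycan distance over the neighborhood; all-zero distances (sigma^2 = 0)
    degrade to equal weights.  Charge states are pooled.
    """
    d = np.array([dist for _, dist in neighbors.rt_neighbors], dtype=float)
    rts = np.array([e.rt for e, _ in neighbors.rt_neighbors], dtype=float)
    sigma2 = float(np.mean(d**2))
    if sigma2 <= 0:
        w = np.ones_like(d)
    else:
        w = np.exp(-(d**2) / (2.0 * sigma2))
    return float(np.sum(w * rts) / np.sum(w))


def _spectrum_dp(a: LibraryEntry, b: LibraryEntry) -> float:
    da = {t.key: t.intensity for t in a.transitions}
    db = {t.key: t.intensity for t in b.transitions}
    keys = set(da) | set(db)
    va = np.array([da.get(k, 0.0) for k in keys])
    vb = np.array([db.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    return float(va @ vb / (na * nb)) if na > 0 and nb > 0 else 0.0


def cross_validate(
    library: Sequence[LibraryEntry],
    k: int = 3,
    use_knn: bool = True,
) -> Dict[str, object]:
    """Leave-one-out cross-validation of the KNN prediction.

    Each predictable precursor is pulled out of the library, predicted from
    the remaining entries, and compared to its experimental entry by dot
    product (annotation-aligned cosine) and RT error.  Returns per-precursor
    results and distribution summaries (median DP, RT error IQR, Pearson r
    of predicted vs experimental RT).
    """
    rows = []
    targets = [e for e in library if not e.is_decoy]
    for e in targets:
        pid = e.precursor_id
        nb = find_neighbors(
            pid.peptide, pid.modifications, pid.glycan_composition, pid.charge,
            targets, k=k, use_knn=use_knn,
        )
        if nb is None:
            continue
        pred = predict_spectrum(
            pid.peptide, pid.modifications, pid.glycan_composition, pid.charge, nb
        )
        if pred is None:
            continue
        rows.append({
            "peptide": pid.peptide,
            "glycan": str(pid.glycan_composition),
            "charge": pid.charge,
            "dp": _spectrum_dp(pred, e),
            "rt_predicted": pred.rt,
            "rt_experimental": e.rt,
            "rt_error": pred.rt - e.rt,
        })
    if not rows:
        return {"results": rows, "n": 0, "median_dp": np.nan,
                "rt_iqr": np.nan, "rt_pearson_r": np.nan}
    dps = np.array([r["dp"] for r in rows])
    errs = np.array([r["rt_error"] for r in rows])
    rp = np.array([r["rt_predicted"] for r in rows])
    re_ = np.array([r["rt_experimental"] for r in rows])
    pearson = float(np.corrcoef(rp, re_)[0, 1]) if len(rows) > 1 and re_.std() > 0 else np.nan
    return {
        "results": rows,
        "n": len(rows),
        "median_dp": float(np.median(dps)),
        "rt_iqr": float(np.percentile(errs, 75) - np.percentile(errs, 25)),
        "rt_pearson_r": pearson,
    }


def extend_library(
    base: Sequence[LibraryEntry],
    combinations: Sequence[Tuple[str, Tuple[chem.Modification, ...], GlycanComposition, int]],
    k: int = 3,
    scan_range: Tuple[float, float] = (200.0, 2000.0),
    isolation_scheme: Optional[IsolationScheme] = None,
) -> List[LibraryEntry]:
    """Extend a library with predictions for listed (peptide, modifications,
    glycan composition, charge) combinations absent from the base.

    Base entries take precedence; predicted entries pass the standard
    transition filters (3/3 minimum, 10+10 cap) before joining.
    """
    existing = {
        (e.precursor_id.peptide, e.precursor_id.modifications,
         e.precursor_id.glycan_composition, e.precursor_id.charge)
        for e in base if not e.is_decoy
    }
    out = list(base)
    for peptide, mods, comp, charge in combinations:
        if (peptide, tuple(mods), comp, charge) in existing:
            continue
        nb = find_neighbors(peptide, mods, comp, charge, base, k=k)
        if nb is None:
            continue
        pred = predict_spectrum(peptide, mods, comp, charge, nb)
        if pred is None:
            continue
        pred = filter_transitions(pred, scan_range, isolation_scheme)
        if pred is None:
            continue
        out.append(pred)
        existing.add((peptide, tuple(mods), comp, charge))
    return out
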