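"""Synthetic data generation for desk-scale validation of the pipeline.

The generators emulate the statistical structure the estimators assume:

* glycan databases grown from the N-glycan trimannosyl core;
* glycopeptide spectral libraries with separable peptide-part / glycan-part
  fragment intensity structure (so fragment-swap prediction is learnable)
  and smooth peptide-dependent retention times;
* four-class candidate peak-group feature tables (target plus the three
  decoy classes) whose target classes follow configured mixture proportions
  pi = (pi00, pi01, pi10, pi11) with Gaussian sub-scores separated on the
  informative axes;
* glycan-entrapment benchmarks in which entrapment glycopeptides are
  *targets* sharing an isolation window (and all core Y ions) with a truly
  present glycoform, so that only transition-level glycoform inference can
  separate them.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .decoys import glycoform_decoy_transitions
from .glycan import (
    DEFAULT_REGISTRY,
    GlycanComposition,
    GlycanNode,
    GlycanStruct,
    enumerate_y_fragments,
    parse_glycan,
)
from .glycoform import (
    GlycoformHypothesis,
    IdentificationTransition,
    generate_identification_transitions,
    select_background_glycoforms,
)
from .library import (
    GPSM,
    IsolationScheme,
    LibraryEntry,
    build_consensus,
    filter_transitions,
    select_best_structure,
)

__all__ = [
    "SimConfig",
    "N_GLYCAN_CORE",
    "simulate_glycan_db",
    "simulate_library",
    "simulate_peak_group_features",
    "EntrapmentBenchmark",
    "simulate_entrapment_benchmark",
]

N_GLYCAN_CORE = "(N(N(H(H)(H))))"

# crude hydrophobicity scale (arbitrary units) for smooth RT generation
_HYDRO = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3, "J": -3.5,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Class separations are in units of the sub-score standard deviation; two
    of the four sub-scores per axis are informative at the configured
    separation, the others are pure noise.  Defaults follow the benchmark
    design: four-class proportions pi over targets, 3-sigma separations,
    one candidate peak group per queried precursor.
    """

    seed: int = 1
    n_precursors: int = 200
    pi: Tuple[float, float, float, float] = (0.25, 0.15, 0.15, 0.45)
    separation_peptide: float = 3.0
    separation_glycan: float = 3.0
    n_subscores: int = 4
    n_informative: int = 2
    # library generation
    peptide_length: Tuple[int, int] = (8, 14)
    glycans_per_peptide: Tuple[int, int] = (1, 3)
    replicates: Tuple[int, int] = (2, 4)
    replicate_sigma: float = 0.2
    mz_jitter_ppm: float = 5.0
    gradient_minutes: float = 60.0
    scan_range: Tuple[float, float] = (200.0, 2000.0)
    # entrapment benchmark
    n_entrapment_pairs: int = 2000
    target_present_prob: float = 0.9
    entrapment_glycan_separation: float = 2.0
    transition_separation: float = 3.0
    ms1_separation: float = 3.0
    n_bg: int = 50


def _derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic child generator keyed by strings/ints (stable hashing)."""
    h = zlib.crc32("|".join(map(str, keys)).encode())
    return np.random.default_rng((int(seed) * 1000003 + h) % (2**31))


def _attach_leaf(struct: GlycanStruct, node_index: int, code: str) -> GlycanStruct:
    """New structure with a leaf of `code` attached to the preorder-indexed node."""
    counter = [0]

    def rebuild(node: GlycanNode) -> GlycanNode:
        my_index = counter[0]
        counter[0] += 1
        children = tuple(rebuild(c) for c in node.children)
        if my_index == node_index:
            children = children + (GlycanNode(code),)
        return GlycanNode(node.code, children)

    return GlycanStruct(rebuild(struct.root).canonicalize())


def simulate_glycan_db(
    seed: int, n_structures: int, max_nodes: int = 12,
    leaf_codes: Sequence[str] = ("H", "N", "F", "A"),
    leaf_weights: Sequence[float] = (0.5, 0.2, 0.15, 0.15),
) -> List[GlycanStruct]:
    """Random N-glycan structures grown from the trimannosyl core.

    Starting from the core, leaves are attached at random nodes of randomly
    chosen existing structures; structures are deduplicated by canonical
    string.  Every output contains the core as a rooted subtree.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    core = parse_glycan(N_GLYCAN_CORE)
    pool: Dict[str, GlycanStruct] = {core.canonical_text: core}
    ordered = [core]
    attempts = 0
    while len(ordered) < n_structures and attempts < 50 * n_structures:
        attempts += 1
        base = ordered[int(rng.integers(len(ordered)))]
        if base.node_count >= max_nodes:
            continue
        node = int(rng.integers(base.node_count))
        code = str(rng.choice(list(leaf_codes), p=np.asarray(leaf_weights) / sum(leaf_weights)))
        new = _attach_leaf(base, node, code)
        if new.canonical_text not in pool:
            pool[new.canonical_text] = new
            ordered.append(new)
    return ordered[:n_structures]


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    """Tryptic-like peptide containing one N-glycosylation sequon J-X-S/T."""
    aas = [a for a in chem.AMINO_ACIDS if a not in "KR"]
    seq = [str(rng.choice(aas)) for _ in range(length - 1)]
    seq.append(str(rng.choice(["K", "R"])))
    site = int(rng.integers(0, length - 3))
    seq[site] = "J"
    if seq[site + 1] == "P":
        seq[site + 1] = "A"
    seq[site + 2] = str(rng.choice(["S", "T"]))
    return "".join(seq)


def _peptide_rt(peptide: str, glycan_nodes: int, gradient: float) -> float:
    """Smooth RT: hydrophobicity mapped into the gradient + glycan-size offset."""
    h = sum(_HYDRO[a] for a in peptide) / len(peptide)
    base = (h + 4.5) / 9.0  # scale roughly into [0, 1]
    return float(np.clip(0.1 + 0.75 * base, 0.05, 0.9)) * gradient + 0.3 * glycan_nodes


def _fragment_intensity(seed: int, *keys: object) -> float:
    """Log-normal reference intensity, deterministic in its keys."""
    return float(np.exp(_derive_rng(seed, *keys).normal(0.0, 1.0)))


def simulate_library(
    config: SimConfig,
    glycan_db: Optional[Sequence[GlycanStruct]] = None,
) -> Tuple[List[LibraryEntry], List[GPSM]]:
    """Simulate DDA GPSMs and build a consensus library from them.

    Fragment reference intensities are separable: the peptide part depends
    only on (peptide, fragment), the glycan part only on (glycan, fragment),
    which is the structure the fragment-swap predictor assumes.  Replicate
    GPSM spectra multiply the reference intensities by log-normal noise and
    jitter the peak m/z within the stated ppm tolerance.  The returned
    entries have passed consensus building and transition filtering.
    """
    rng = np.random.default_rng(config.seed)
    if glycan_db is None:
        glycan_db = simulate_glycan_db(config.seed + 1, max(10, config.n_precursors // 10))
    scheme = IsolationScheme.uniform()

    gpsms: List[GPSM] = []
    made = 0
    guard = 0
    while made < config.n_precursors and guard < 20 * config.n_precursors:
        guard += 1
        peptide = _random_peptide(rng, int(rng.integers(*config.peptide_length)))
        n_gly = int(rng.integers(config.glycans_per_peptide[0],
                                 config.glycans_per_peptide[1] + 1))
        idx = rng.choice(len(glycan_db), size=min(n_gly, len(glycan_db)), replace=False)
        for gi in idx:
            glycan = glycan_db[int(gi)]
            charge = int(rng.choice([2, 3, 4], p=[0.45, 0.4, 0.15]))
            mz = chem.glycopeptide_precursor_mz(peptide, glycan.composition(), charge)
            if not 700 <= mz <= 1636:
                continue
            rt = _peptide_rt(peptide, glycan.node_count, config.gradient_minutes)
            n_rep = int(rng.integers(config.replicates[0], config.replicates[1] + 1))
            for rep in range(n_rep):
                gpsms.append(_simulate_gpsm(config, peptide, glycan, charge, rt, rep, rng))
            made += 1
            if made >= config.n_precursors:
                break

    entries: List[LibraryEntry] = []
    by_pid: Dict[object, List[GPSM]] = {}
    for g in gpsms:
        by_pid.setdefault(g.precursor_id, []).append(g)
    for pid, group in by_pid.items():
        kept = select_best_structure(group)
        entry = build_consensus(kept)
        entry = filter_transitions(entry, config.scan_range, scheme)
        if entry is not None:
            entries.append(entry)
    entries.sort(key=lambda e: (e.precursor_id.peptide,
                                str(e.precursor_id.glycan_composition),
                                e.precursor_id.charge))
    return entries, gpsms


def _simulate_gpsm(
    config: SimConfig,
    peptide: str,
    glycan: GlycanStruct,
    charge: int,
    rt: float,
    replicate: int,
    rng: np.random.Generator,
) -> GPSM:
    pep_mass = chem.peptide_mass(peptide)
    gtext = glycan.canonical_text
    peaks: List[Tuple[float, float]] = []

    b, y, _bs, _ys = chem.backbone_fragment_masses(peptide)
    for series, masses in (("b", b), ("y", y)):
        for i, m in enumerate(masses):
            ref = _fragment_intensity(config.seed, "pep", peptide, series, i + 1)
            mz = chem.mz_from_mass(m, 1)
            peaks.append((mz, ref))
    for comp in enumerate_y_fragments(glycan).fragments:
        ref = _fragment_intensity(config.seed, "gly", gtext, str(comp))
        for z in (1, 2):
            mz = chem.mz_from_mass(pep_mass + comp.mass(), z)
            peaks.append((mz, ref * (1.2 if z == 1 else 0.8)))

    lo, hi = config.scan_range
    out = []
    for mz, ref in peaks:
        if not lo <= mz <= hi:
            continue
        jitter = 1.0 + rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm) * 1e-6
        noise = float(np.exp(rng.normal(0.0, config.replicate_sigma)))
        out.append((mz * jitter, ref * noise * 1000.0))
    for _ in range(5):  # unassigned background peaks
        out.append((float(rng.uniform(lo, hi)), float(rng.uniform(1.0, 30.0))))
    out.sort()
    spectrum = np.array(out)

    return GPSM(
        peptide=peptide,
        modifications=(),
        glycan=glycan,
        charge=charge,
        total_score=float(rng.uniform(10.0, 40.0)),
        rt=rt + float(rng.normal(0.0, 0.15)),
        spectrum=spectrum,
        run_id=f"dda_rep{replicate}",
    )


def _class_subscores(
    rng: np.random.Generator,
    n: int,
    non_null: np.ndarray,
    separation: float,
    n_subscores: int,
    n_informative: int,
) -> np.ndarray:
    X = rng.normal(0.0, 1.0, size=(n, n_subscores))
    X[:, :n_informative] += separation * non_null[:, None]
    return X


def simulate_peak_group_features(
    config: SimConfig,
    n_targets: Optional[int] = None,
    run_id: str = "run1",
) -> pd.DataFrame:
    """Four-class candidate peak-group feature table with ground truth.

    Targets draw their (peptide non-null, glycan non-null) class from the
    configured proportions pi = (pi00, pi01, pi10, pi11).  Decoy classes
    follow the mixture identities the model assumes: peptide decoys are
    always peptide-null with the targets' glycan-state mixture, glycan
    decoys the mirror image, both decoys fully null.  Columns ``true_*``
    carry the generating truth and are ignored by the scoring pipeline.
    """
    n = n_targets if n_targets is not None else config.n_precursors
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("class proportions must be non-negative and sum to 1")

    rows = []
    for label in ("target", "peptide_decoy", "glycan_decoy", "both_decoy"):
        cls = rng.choice(4, size=n, p=pi)  # 0=00, 1=01, 2=10, 3=11
        pep_ok = np.isin(cls, (2, 3))
        gly_ok = np.isin(cls, (1, 3))
        if label == "peptide_decoy":
            pep_ok = np.zeros(n, dtype=bool)
        elif label == "glycan_decoy":
            gly_ok = np.zeros(n, dtype=bool)
        elif label == "both_decoy":
            pep_ok = np.zeros(n, dtype=bool)
            gly_ok = np.zeros(n, dtype=bool)
        Xp = _class_subscores(rng, n, pep_ok.astype(float), config.separation_peptide,
                              config.n_subscores, config.n_informative)
        Xg = _class_subscores(rng, n, gly_ok.astype(float), config.separation_glycan,
                              config.n_subscores, config.n_informative)
        prefix = {"target": "t", "peptide_decoy": "pd",
                  "glycan_decoy": "gd", "both_decoy": "bd"}[label]
        for i in range(n):
            row = {
                "run_id": run_id,
                "precursor_id": f"{prefix}{i:06d}",
                "glycopeptide_id": f"{prefix}{i:06d}",
                "peak_group_id": f"{prefix}{i:06d}_pg0",
                "rt": float(rng.uniform(0.0, config.gradient_minutes)),
                "label": label,
                "true_peptide_ok": bool(pep_ok[i]),
                "true_glycan_ok": bool(gly_ok[i]),
            }
            for j in range(config.n_subscores):
                row[f"pep_score{j}"] = Xp[i, j]
                row[f"gly_score{j}"] = Xg[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EntrapmentBenchmark:
    """A simulated glycan-entrapment experiment.

    ``features`` is the candidate peak-group table (entrapment entries are
    *targets*); ``queries`` describes each queried precursor including its
    entrapment flag and whether its glycoform is truly present;
    ``hypotheses`` / ``transitions`` hold the glycoform inference inputs per
    query; ``ms1`` carries MS1 precursor scores with decoys.
    """

    features: pd.DataFrame
    queries: pd.DataFrame
    hypotheses: Dict[str, List[GlycoformHypothesis]]
    transitions: Dict[str, List[IdentificationTransition]]
    transition_scores: pd.DataFrame
    ms1: pd.DataFrame
    glycan_db: List[GlycanStruct]
    isolation_scheme: IsolationScheme
    config: SimConfig


def _replace_one_leaf(struct: GlycanStruct, old: str, new: str) -> Optional[GlycanStruct]:
    """Replace one leaf of code `old` (deepest-first) by `new`; None if absent."""
    done = [False]

    def rebuild(node: GlycanNode) -> GlycanNode:
        children = tuple(rebuild(c) for c in node.children)
        if not done[0]:
            for idx, c in enumerate(children):
                if c.code == old and not c.children:
                    done[0] = True
                    children = children[:idx] + (GlycanNode(new),) + children[idx + 1:]
                    break
        return GlycanNode(node.code, children)

    out = rebuild(struct.root)
    return GlycanStruct(out.canonicalize()) if done[0] else None


def simulate_entrapment_benchmark(config: SimConfig) -> EntrapmentBenchmark:
    """Glycan-entrapment benchmark: entrapment targets share windows and core
    Y ions with truly present glycoforms.

    High-mannose-like glycans (core plus extra hexoses) act as the sample
    glycome; for each target (peptide, glycan, charge) an entrapment entry
    replaces one hexose leaf by a fucose (16 Da lighter), kept only when the
    two precursors share a DIA isolation window.  Entrapment glycoforms are
    never present; target glycoforms are present with the configured
    probability.  Peak-group sub-scores give entrapment entries full peptide
    evidence and partial glycan evidence (shared-core transitions), so the
    2D FDR alone cannot fully separate them; their private fucosylated Y
    transitions carry noise-level signal only.
    """
    rng = np.random.default_rng(config.seed)
    scheme = IsolationScheme.uniform()

    # sample glycome: chains of extra hexoses on the core, one structure each
    yeast: List[GlycanStruct] = []
    g = parse_glycan(N_GLYCAN_CORE)
    yeast.append(g)
    for _ in range(7):
        g = _attach_leaf(g, g.node_count - 1, "H")
        yeast.append(g)
    entrap_of: Dict[str, GlycanStruct] = {}
    for gy in yeast[1:]:
        ge = _replace_one_leaf(gy, "H", "F")
        if ge is not None:
            entrap_of[gy.canonical_text] = ge
    db = yeast + list(entrap_of.values())

    # paired target / entrapment precursors sharing an isolation window
    pairs = []
    seen_peptides = set()
    guard = 0
    while len(pairs) < config.n_entrapment_pairs and guard < 50 * config.n_entrapment_pairs:
        guard += 1
        peptide = _random_peptide(rng, int(rng.integers(*config.peptide_length)))
        if peptide in seen_peptides:
            continue
        gy = yeast[1 + int(rng.integers(len(yeast) - 1))]
        ge = entrap_of[gy.canonical_text]
        charge = int(rng.choice([2, 3]))
        mz_y = chem.glycopeptide_precursor_mz(peptide, gy.composition(), charge)
        mz_e = chem.glycopeptide_precursor_mz(peptide, ge.composition(), charge)
        if not (700 <= mz_y <= 1636 and 700 <= mz_e <= 1636):
            continue
        if not scheme.shares_window(mz_y, mz_e):
            continue
        seen_peptides.add(peptide)
        pairs.append((peptide, gy, ge, charge, mz_y, mz_e))

    present = rng.random(len(pairs)) < config.target_present_prob

    # cache Y-fragment sets per glycan
    frag_cache = {s.canonical_text: enumerate_y_fragments(s).discriminating for s in db}

    feature_rows = []
    query_rows = []
    hyp_map: Dict[str, List[GlycoformHypothesis]] = {}
    trans_map: Dict[str, List[IdentificationTransition]] = {}
    trans_rows = []
    ms1_rows = []

    def add_query(qid, peptide, struct, charge, mz, is_entrap, pair_present):
        query_rows.append({
            "precursor_id": qid,
            "glycopeptide_id": qid,
            "peptide": peptide,
            "glycan": struct.canonical_text,
            "glycan_composition": str(struct.composition()),
            "charge": charge,
            "precursor_mz": mz,
            "is_entrapment": is_entrap,
            "truly_present": (not is_entrap) and pair_present,
        })

        # peak-group sub-scores for the query and its three decoys
        if is_entrap:
            pep_mean = config.separation_peptide if pair_present else 0.0
            gly_mean = config.entrapment_glycan_separation if pair_present else 0.0
        else:
            pep_mean = config.separation_peptide if pair_present else 0.0
            gly_mean = config.separation_glycan if pair_present else 0.0
        for label, pm, gm in (
            ("target", pep_mean, gly_mean),
            ("peptide_decoy", 0.0, gly_mean),
            ("glycan_decoy", pep_mean, 0.0),
            ("both_decoy", 0.0, 0.0),
        ):
            row = {
                "run_id": "run1",
                "precursor_id": f"{qid}_{label}" if label != "target" else qid,
                "glycopeptide_id": f"{qid}_{label}" if label != "target" else qid,
                "peak_group_id": f"{qid}_{label}_pg0",
                "rt": float(rng.uniform(0.0, config.gradient_minutes)),
                "label": label,
            }
            for j in range(config.n_subscores):
                inf = j < config.n_informative
                row[f"pep_score{j}"] = rng.normal(pm if inf else 0.0, 1.0)
                row[f"gly_score{j}"] = rng.normal(gm if inf else 0.0, 1.0)
            feature_rows.append(row)

        # glycoform hypotheses and identification transitions
        hyps = select_background_glycoforms(
            peptide, (), struct, charge, db, scheme, n_bg=config.n_bg
        )
        hyp_map[qid] = hyps
        transitions = generate_identification_transitions(
            hyps, peptide, (), scan_range=config.scan_range
        )
        trans_map[qid] = transitions

        present_comps = set()
        present_indices = set()
        if pair_present:
            # the truly present glycoform of this peptide/window is the yeast glycan
            for h in hyps:
                if h.is_null:
                    continue
                texts = {s.canonical_text for s in h.structures}
                if (not is_entrap and struct.canonical_text in texts) or (
                    is_entrap and entrap_pair_text[qid] in texts
                ):
                    present_indices.add(h.index)
                    present_comps |= frag_cache[h.structures[0].canonical_text]
        for ti, t in enumerate(transitions):
            if t.kind == "Y":
                signal = t.composition in present_comps
            else:  # unfragmented precursor of hypothesis k
                signal = bool(t.hypotheses & present_indices)
            score = rng.normal(config.transition_separation if signal else 0.0, 1.0)
            trans_rows.append({
                "precursor_id": qid, "transition_index": ti,
                "score_main": score, "is_decoy": False,
            })
        # decoy identification transitions: decoy peptide mass, target glycan frags
        _seq, decoy_trans = glycoform_decoy_transitions(
            peptide, (), sorted(frag_cache[struct.canonical_text], key=str),
            rng, charges=(1, 2, 3),
        )
        for di, (_comp, _z, dmz) in enumerate(decoy_trans):
            if not config.scan_range[0] <= dmz <= config.scan_range[1]:
                continue
            trans_rows.append({
                "precursor_id": qid, "transition_index": -1 - di,
                "score_main": rng.normal(0.0, 1.0), "is_decoy": True,
            })

        # MS1 precursor evidence at the query m/z
        ms1_signal = (not is_entrap) and pair_present
        ms1_rows.append({
            "precursor_id": qid,
            "score_main": rng.normal(config.ms1_separation if ms1_signal else 0.0, 1.0),
            "is_decoy": False,
        })
        ms1_rows.append({
            "precursor_id": f"{qid}_decoy",
            "score_main": rng.normal(0.0, 1.0),
            "is_decoy": True,
        })

    entrap_pair_text: Dict[str, str] = {}
    for i, (peptide, gy, ge, charge, mz_y, mz_e) in enumerate(pairs):
        qid_t = f"tgt{i:06d}"
        qid_e = f"ent{i:06d}"
        entrap_pair_text[qid_e] = gy.canonical_text
        add_query(qid_t, peptide, gy, charge, mz_y, False, bool(present[i]))
        add_query(qid_e, peptide, ge, charge, mz_e, True, bool(present[i]))

    return EntrapmentBenchmark(
        features=pd.DataFrame(feature_rows),
        queries=pd.DataFrame(query_rows),
        hypotheses=hyp_map,
        transitions=trans_map,
        transition_scores=pd.DataFrame(trans_rows),
        ms1=pd.DataFrame(ms1_rows),
        glycan_db=db,
        isolation_scheme=scheme,
        config=config,
    )
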