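"""Spectral library construction from DDA glycopeptide-spectrum matches.

A confident set of GPSMs is turned into a consensus library: per precursor,
the best-supported glycan structure is selected, spectra are annotated with
theoretical peptide (b/y and HexNAc-stub) and glycan (Y) fragments, replicate
spectra are merged into consensus entries, transitions are filtered to the
DIA-usable set, and retention times are calibrated into the DIA gradient
space with LOWESS using shared identifications as anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from . import chem
from .glycan import (
    DEFAULT_REGISTRY,
    GlycanComposition,
    GlycanStruct,
    MonosaccharideRegistry,
    enumerate_y_fragments,
)

__all__ = [
    "GPSM",
    "AnnotatedTransition",
    "PrecursorId",
    "LibraryEntry",
    "IsolationScheme",
    "RtCalibration",
    "select_best_structure",
    "annotate_spectrum",
    "build_consensus",
    "filter_transitions",
    "calibrate_rt",
    "merge_libraries",
]

PEPTIDE_SERIES = ("b", "y", "b-N1", "y-N1", "b$", "y$")


@dataclass(frozen=True)
class PrecursorId:
    """Identity of a glycopeptide precursor in the library.

    The glycan is identified by composition (isomeric structures collapse at
    the precursor level); the annotated structure is kept on the entry.
    """

    peptide: str
    modifications: Tuple[chem.Modification, ...]
    glycan_composition: GlycanComposition
    charge: int


@dataclass
class GPSM:
    """One glycopeptide-spectrum match from a DDA search (pGlyco3-style)."""

    peptide: str  # contains >=1 glycosite marker "J"
    modifications: Tuple[chem.Modification, ...]
    glycan: GlycanStruct
    charge: int
    total_score: float
    rt: float  # minutes
    spectrum: np.ndarray  # (n, 2) array of (m/z, intensity), m/z ascending
    run_id: str = ""

    def __post_init__(self) -> None:
        if not 2 <= self.charge <= 6:
            raise ValueError(f"precursor charge {self.charge} outside 2..6")
        if "J" not in self.peptide:
            raise ValueError("glycopeptide must contain a glycosite marker 'J'")
        self.spectrum = np.asarray(self.spectrum, dtype=float).reshape(-1, 2)
        if len(self.spectrum) > 1 and np.any(np.diff(self.spectrum[:, 0]) < 0):
            raise ValueError("spectrum m/z must be ascending")

    @property
    def precursor_id(self) -> PrecursorId:
        return PrecursorId(
            self.peptide, tuple(self.modifications), self.glycan.composition(), self.charge
        )


@dataclass(frozen=True)
class AnnotatedTransition:
    """One annotated fragment peak.

    ``series`` is b/y (optionally with one HexNAc, -N1, or its cross-ring
    fragment, $) for the peptide part, or Y for the glycan part.  Y ions are
    keyed by glycan composition; the Y$ cross-ring ion uses the special
    composition marker ``"$"``.
    """

    series: str
    ordinal: Optional[int]  # b/y ordinal; None for Y series
    composition: Optional[str]  # Y composition text ("" = Y0, "$" = Y$); None for b/y
    charge: int
    mz: float
    intensity: float
    quantify: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def part(self) -> str:
        return "glycan" if self.series == "Y" else "peptide"

    @property
    def key(self) -> Tuple[str, object, int]:
        """Annotation identity used to align replicate spectra."""
        return (self.series, self.ordinal if self.series != "Y" else self.composition, self.charge)


@dataclass
class LibraryEntry:
    """One glycopeptide precursor with its annotated transitions."""

    precursor_id: PrecursorId
    glycan_struct: GlycanStruct
    precursor_mz: float
    rt: float
    transitions: List[AnnotatedTransition]
    replicate_count: int = 1
    is_decoy: bool = False
    decoy_type: str = ""
    provenance: Dict[str, object] = field(default_factory=dict)

    def part_transitions(self, part: str) -> List[AnnotatedTransition]:
        return [t for t in self.transitions if t.part == part]


@dataclass(frozen=True)
class IsolationScheme:
    """DIA isolation windows as (lower, upper) m/z bounds (may overlap)."""

    windows: Tuple[Tuple[float, float], ...]

    @classmethod
    def uniform(
        cls, first_center: float = 700.0, n_windows: int = 40,
        width: float = 25.0, overlap: float = 1.0,
    ) -> "IsolationScheme":
        """The default scheme: 40 windows of 25 Da width with 1 Da overlap,
        centers starting at 700 Da (spacing = width - overlap)."""
        step = width - overlap
        wins = tuple(
            (first_center + i * step - width / 2, first_center + i * step + width / 2)
            for i in range(n_windows)
        )
        return cls(wins)

    def windows_containing(self, mz: float) -> List[int]:
        return [i for i, (lo, hi) in enumerate(self.windows) if lo <= mz < hi]

    def shares_window(self, mz_a: float, mz_b: float) -> bool:
        return bool(set(self.windows_containing(mz_a)) & set(self.windows_containing(mz_b)))


def select_best_structure(gpsms: Sequence[GPSM]) -> List[GPSM]:
    """Keep the GPSMs annotated with the best-supported glycan structure.

    All inputs must share (peptide, modifications, glycan composition,
    charge).  The identification scores of GPSMs are summed per annotated
    structure and only GPSMs of the top-scoring structure are retained.
    Exact ties break deterministically by canonical structure string.
    """
    if not gpsms:
        raise ValueError("no GPSMs given")
    pids = {g.precursor_id for g in gpsms}
    if len(pids) > 1:
        raise ValueError("GPSMs must share one precursor identity")
    score_sums: Dict[str, float] = {}
    for g in gpsms:
        key = g.glycan.canonical_text
        score_sums[key] = score_sums.get(key, 0.0) + g.total_score
    best = min(score_sums, key=lambda k: (-score_sums[k], k))
    return [g for g in gpsms if g.glycan.canonical_text == best]


def _match_peak(spectrum: np.ndarray, mz: float, tol_ppm: float) -> Optional[float]:
    """Intensity of the spectrum peak nearest to `mz` within the tolerance."""
    if len(spectrum) == 0:
        return None
    idx = np.searchsorted(spectrum[:, 0], mz)
    best = None
    for i in (idx - 1, idx):
        if 0 <= i < len(spectrum):
            err = abs(chem.ppm_error(spectrum[i, 0], mz))
            if err <= tol_ppm and (best is None or err < best[0]):
                best = (err, spectrum[i, 1])
    return None if best is None else best[1]


def theoretical_transitions(
    peptide: str,
    modifications: Sequence[chem.Modification],
    glycan: GlycanStruct,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
    cross_ring_offset: float = chem.CROSS_RING_OFFSET,
) -> List[Tuple[str, Optional[int], Optional[str], int, float]]:
    """All theoretical fragments of a glycopeptide.

    Returns tuples (series, ordinal, composition, charge, mz) covering:
    Y ions (including Y0 and the Y$ cross-ring ion) at charges 1-3; backbone
    b/y at charges 1-2; b/y with one HexNAc (b-N1/y-N1) and with the HexNAc
    cross-ring fragment (b$/y$), both restricted to fragments containing the
    glycosite, at charges 1-2.
    """
    out: List[Tuple[str, Optional[int], Optional[str], int, float]] = []
    pep_mass = chem.peptide_mass(peptide, modifications)

    for comp in enumerate_y_fragments(glycan).fragments:
        m = pep_mass + comp.mass(registry)
        for z in (1, 2, 3):
            out.append(("Y", None, str(comp) if comp.total else "", z, chem.mz_from_mass(m, z)))
    for z in (1, 2, 3):  # Y$: cross-ring fragment of the reducing-end HexNAc
        out.append(("Y", None, "$", z, chem.mz_from_mass(pep_mass + cross_ring_offset, z)))

    b, y, b_site, y_site = chem.backbone_fragment_masses(peptide, modifications)
    for series, masses, sites in (("b", b, b_site), ("y", y, y_site)):
        for i, (m, has_site) in enumerate(zip(masses, sites)):
            for z in (1, 2):
                out.append((series, i + 1, None, z, chem.mz_from_mass(m, z)))
                if has_site:
                    out.append((f"{series}-N1", i + 1, None, z,
                                chem.mz_from_mass(m + chem.HEXNAC, z)))
                    out.append((f"{series}$", i + 1, None, z,
                                chem.mz_from_mass(m + cross_ring_offset, z)))
    return out


def annotate_spectrum(
    gpsm: GPSM,
    tol_ppm: float = 20.0,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
    cross_ring_offset: float = chem.CROSS_RING_OFFSET,
) -> List[AnnotatedTransition]:
    """Annotate a GPSM spectrum against the theoretical fragment set.

    The nearest observed peak within ±``tol_ppm`` claims each annotation; the
    transition m/z recorded is the theoretical value.
    """
    out = []
    for series, ordinal, comp, z, mz in theoretical_transitions(
        gpsm.peptide, gpsm.modifications, gpsm.glycan, registry, cross_ring_offset
    ):
        intensity = _match_peak(gpsm.spectrum, mz, tol_ppm)
        if intensity is not None and intensity > 0:
            out.append(AnnotatedTransition(series, ordinal, comp, z, mz, intensity))
    out.sort(key=lambda t: t.mz)
    return out


def _dot_product(a: Sequence[AnnotatedTransition], b: Sequence[AnnotatedTransition]) -> float:
    """Cosine similarity of two annotated peak lists aligned by annotation key."""
    da = {t.key: t.intensity for t in a}
    db = {t.key: t.intensity for t in b}
    keys = set(da) | set(db)
    va = np.array([da.get(k, 0.0) for k in keys])
    vb = np.array([db.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def build_consensus(
    replicates: Sequence[GPSM],
    transitions_per_replicate: Optional[Sequence[Sequence[AnnotatedTransition]]] = None,
    min_median_dp: float = 0.5,
    presence_fraction: float = 0.6,
    tol_ppm: float = 20.0,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> LibraryEntry:
    """Merge replicate GPSMs of one precursor into a consensus entry.

    (i) replicates whose median pairwise dot product to the others falls
    below ``min_median_dp`` are discarded; (ii) only peaks present in
    strictly more than ``presence_fraction`` of the surviving replicates are
    kept; (iii) consensus intensities are identification-score-weighted means
    (m/z values are theoretical, hence common).  RT is the score-weighted
    mean of the surviving replicates.  If every replicate is dissimilar to
    the others the single best-scoring replicate is kept instead.
    """
    if not replicates:
        raise ValueError("no replicates")
    pids = {g.precursor_id for g in replicates}
    if len(pids) > 1:
        raise ValueError("replicates must share one precursor identity")

    if transitions_per_replicate is None:
        transitions_per_replicate = [annotate_spectrum(g, tol_ppm, registry) for g in replicates]
    annotated = list(zip(replicates, transitions_per_replicate))

    if len(annotated) > 1:
        keep = []
        for i, (gi, ti) in enumerate(annotated):
            dps = [_dot_product(ti, tj) for j, (_, tj) in enumerate(annotated) if j != i]
            if float(np.median(dps)) >= min_median_dp:
                keep.append((gi, ti))
        if not keep:  # all mutually dissimilar: fall back to best-scoring
            keep = [max(annotated, key=lambda gt: gt[0].total_score)]
        annotated = keep

    n_rep = len(annotated)
    weights = np.array([g.total_score for g, _ in annotated], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(n_rep)

    by_key: Dict[Tuple, List[Tuple[int, AnnotatedTransition]]] = {}
    for r, (_, trans) in enumerate(annotated):
        for t in trans:
            by_key.setdefault(t.key, []).append((r, t))

    consensus: List[AnnotatedTransition] = []
    for key, hits in by_key.items():
        if n_rep > 1 and len(hits) <= presence_fraction * n_rep:
            continue
        w = np.array([weights[r] for r, _ in hits])
        intens = np.array([t.intensity for _, t in hits])
        mzs = np.array([t.mz for _, t in hits])
        t0 = hits[0][1]
        consensus.append(
            AnnotatedTransition(
                t0.series, t0.ordinal, t0.composition, t0.charge,
                float(np.average(mzs, weights=w)), float(np.average(intens, weights=w)),
            )
        )
    consensus.sort(key=lambda t: t.mz)

    g0 = annotated[0][0]
    rt = float(np.average([g.rt for g, _ in annotated], weights=weights))
    pid = g0.precursor_id
    return LibraryEntry(
        precursor_id=pid,
        glycan_struct=g0.glycan,
        precursor_mz=chem.glycopeptide_precursor_mz(
            pid.peptide, pid.glycan_composition, pid.charge, pid.modifications, registry
        ),
        rt=rt,
        transitions=consensus,
        replicate_count=n_rep,
        provenance={"score_sum": float(sum(g.total_score for g, _ in annotated))},
    )


def filter_transitions(
    entry: LibraryEntry,
    scan_range: Tuple[float, float] = (200.0, 2000.0),
    isolation_scheme: Optional[IsolationScheme] = None,
    max_per_part: int = 10,
    quantify_per_part: int = 6,
    min_per_part: int = 3,
) -> Optional[LibraryEntry]:
    """Apply the DIA transition filters to one library entry.

    Fragments outside the scan range, or falling inside any isolation window
    that contains the precursor m/z (self-interference), are excluded.  The
    ``max_per_part`` most intense peptide and glycan transitions are kept and
    the top ``quantify_per_part`` of each part are flagged as quantifiers;
    intensity ties break by ascending m/z.  Returns None (entry dropped) if
    fewer than ``min_per_part`` transitions remain in either part.
    """
    lo, hi = scan_range
    own_windows = (
        set(isolation_scheme.windows_containing(entry.precursor_mz))
        if isolation_scheme is not None else set()
    )

    def excluded(t: AnnotatedTransition) -> bool:
        if not lo <= t.mz <= hi:
            return True
        if isolation_scheme is not None and own_windows:
            if set(isolation_scheme.windows_containing(t.mz)) & own_windows:
                return True
        return False

    kept: List[AnnotatedTransition] = []
    for part in ("peptide", "glycan"):
        cands = [t for t in entry.part_transitions(part) if not excluded(t)]
        cands.sort(key=lambda t: (-t.intensity, t.mz))
        cands = cands[:max_per_part]
        if len(cands) < min_per_part:
            return None
        kept.extend(
            replace(t, quantify=(i < quantify_per_part)) for i, t in enumerate(cands)
        )
    kept.sort(key=lambda t: t.mz)
    return replace(entry, transitions=kept)


@dataclass
class RtCalibration:
    """A LOWESS mapping from source-gradient RT to target-gradient RT.

    Fitted on anchor pairs (shared identifications between runs).  Evaluation
    interpolates the smoothed anchor curve; outside the anchor range the edge
    segments are extended linearly.
    """

    anchors_source: np.ndarray
    anchors_target: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray

    @classmethod
    def fit(
        cls,
        anchors: Sequence[Tuple[float, float]],
        min_anchors: int = 10,
        frac: float = 0.667,
        iterations: int = 3,
    ) -> "RtCalibration":
        if len(anchors) < min_anchors:
            raise ValueError(
                f"{len(anchors)} anchor pairs given but at least {min_anchors} required"
            )
        src = np.array([a[0] for a in anchors], dtype=float)
        tgt = np.array([a[1] for a in anchors], dtype=float)
        sm = _lowess(tgt, src, frac=frac, it=iterations, return_sorted=True)
        gx, gy = sm[:, 0], sm[:, 1]
        gx, idx = np.unique(gx, return_index=True)
        gy = gy[idx]
        return cls(src, tgt, gx, gy)

    def __call__(self, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        out = np.interp(rt, self.grid_x, self.grid_y)
        if len(self.grid_x) >= 2:  # linear extension beyond the anchor range
            lo_slope = (self.grid_y[1] - self.grid_y[0]) / (self.grid_x[1] - self.grid_x[0])
            hi_slope = (self.grid_y[-1] - self.grid_y[-2]) / (self.grid_x[-1] - self.grid_x[-2])
            out = np.where(rt < self.grid_x[0],
                           self.grid_y[0] + (rt - self.grid_x[0]) * lo_slope, out)
            out = np.where(rt > self.grid_x[-1],
                           self.grid_y[-1] + (rt - self.grid_x[-1]) * hi_slope, out)
        return out


def calibrate_rt(
    anchors: Sequence[Tuple[float, float]],
    entries: Sequence[LibraryEntry],
    min_anchors: int = 10,
    frac: float = 0.667,
    iterations: int = 3,
) -> Tuple[List[LibraryEntry], RtCalibration]:
    """Calibrate library RTs into the DIA gradient space.

    Returns the calibrated entries and the fitted calibration (whose anchors
    can be exported as a TraML reference set for the extraction step).
    """
    cal = RtCalibration.fit(anchors, min_anchors=min_anchors, frac=frac, iterations=iterations)
    rts = cal(np.array([e.rt for e in entries]))
    return [replace(e, rt=float(r)) for e, r in zip(entries, rts)], cal


def merge_libraries(libraries: Sequence[Sequence[LibraryEntry]]) -> List[LibraryEntry]:
    """Merge libraries into one entry per precursor.

    Duplicate precursors resolve to the entry with the higher replicate
    count, then the higher summed identification score, then the later
    library in the argument order (newest provenance).
    """
    merged: Dict[PrecursorId, Tuple[int, LibraryEntry]] = {}
    for lib_index, lib in enumerate(libraries):
        for entry in lib:
            pid = entry.precursor_id
            incumbent = merged.get(pid)
            if incumbent is None:
                merged[pid] = (lib_index, entry)
                continue
            inc_idx, inc = incumbent
            cand_rank = (
                entry.replicate_count,
                float(entry.provenance.get("score_sum", 0.0)),
                lib_index,
            )
            inc_rank = (
                inc.replicate_count,
                float(inc.provenance.get("score_sum", 0.0)),
                inc_idx,
            )
            if cand_rank > inc_rank:
                merged[pid] = (lib_index, entry)
    out = [e for _, e in merged.values()]
    out.sort(key=lambda e: (e.precursor_id.peptide, str(e.precursor_id.glycan_composition),
                            e.precursor_id.charge))
    return out
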