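"""Decoy library generation for target-decoy error rate estimation.

Three decoy classes are appended to a target library: *peptide decoys*
(reversed peptide sequence keeping a C-terminal K/R in place, target glycan),
*glycan decoys* (target peptide, each Y-ion m/z shifted by a random 1-30 Da mass,
sparing Y0 and Y$), and *both decoys* (both operations applied).  The
combined library is exactly four times the size of the target library.

A separate decoy type serves glycoform inference: identification transitions
built from a random same-length peptide sequence (PTMs kept in place, at
least 1 Da away in mass from the target peptide) combined with the target
glycan fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .glycan import DEFAULT_REGISTRY, GlycanComposition, MonosaccharideRegistry
from .library import AnnotatedTransition, LibraryEntry, PrecursorId

__all__ = [
    "reverse_peptide",
    "peptide_decoy",
    "glycan_decoy",
    "both_decoy",
    "build_decoy_library",
    "glycoform_decoy_transitions",
]

MASS_SHIFT_RANGE = (1.0, 30.0)  # Da, added to singly-charged Y fragment masses


def reverse_peptide(
    sequence: str, modifications: Sequence[chem.Modification] = ()
) -> Tuple[str, Tuple[chem.Modification, ...]]:
    """Reverse a peptide keeping a C-terminal arginine/lysine unmoved.

    The glycosite marker ``J`` travels with its residue and modification
    positions are remapped accordingly.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty peptide")
    keep_last = sequence[-1] in "KR"
    prefix_len = n - 1 if keep_last else n
    index_map = {i: prefix_len - 1 - i for i in range(prefix_len)}
    if keep_last:
        index_map[n - 1] = n - 1
    rev = "".join(sequence[i] for i in sorted(index_map, key=index_map.get))
    new_mods = tuple(
        (name, index_map[pos - 1] + 1, delta) for name, pos, delta in modifications
    )
    return rev, tuple(sorted(new_mods, key=lambda m: m[1]))


def _shuffle_peptide(
    sequence: str,
    modifications: Sequence[chem.Modification],
    rng: np.random.Generator,
) -> Tuple[str, Tuple[chem.Modification, ...]]:
    """Seeded shuffle keeping a C-terminal K/R fixed (reversal fallback)."""
    n = len(sequence)
    keep_last = sequence[-1] in "KR"
    prefix_len = n - 1 if keep_last else n
    perm = rng.permutation(prefix_len)
    index_map = {int(src): int(dst) for dst, src in enumerate(perm)}
    if keep_last:
        index_map[n - 1] = n - 1
    shuffled = "".join(sequence[i] for i in sorted(index_map, key=index_map.get))
    new_mods = tuple((name, index_map[pos - 1] + 1, delta) for name, pos, delta in modifications)
    return shuffled, tuple(sorted(new_mods, key=lambda m: m[1]))


def _retarget_peptide_transitions(
    entry: LibraryEntry,
    decoy_seq: str,
    decoy_mods: Tuple[chem.Modification, ...],
    registry: MonosaccharideRegistry,
) -> List[AnnotatedTransition]:
    """Recompute transition m/z for a decoy peptide, keeping intensities.

    Backbone fragments are recomputed from the decoy sequence at the same
    series/ordinal/charge; Y ions shift with the (unchanged, for reversal)
    peptide mass.
    """
    b, y, b_site, y_site = chem.backbone_fragment_masses(decoy_seq, decoy_mods)
    pep_mass = chem.peptide_mass(decoy_seq, decoy_mods)
    out: List[AnnotatedTransition] = []
    for t in entry.transitions:
        if t.series == "Y":
            if t.composition == "$":
                m = pep_mass + chem.CROSS_RING_OFFSET
            else:
                comp = GlycanComposition.parse(t.composition or "")
                m = pep_mass + comp.mass(registry)
            out.append(replace(t, mz=chem.mz_from_mass(m, t.charge)))
            continue
        base = t.series[0]
        masses = b if base == "b" else y
        i = (t.ordinal or 1) - 1
        if i >= len(masses):
            continue
        m = masses[i]
        if t.series.endswith("-N1"):
            m += chem.HEXNAC
        elif t.series.endswith("$"):
            m += chem.CROSS_RING_OFFSET
        out.append(replace(t, mz=chem.mz_from_mass(m, t.charge)))
    out.sort(key=lambda t: t.mz)
    return out


def peptide_decoy(
    entry: LibraryEntry,
    rng: np.random.Generator,
    existing_ids: Optional[set] = None,
    max_retries: int = 20,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> Optional[LibraryEntry]:
    """Peptide decoy: reversed sequence, target glycan.

    Palindromic or otherwise colliding reversals fall back to up to
    ``max_retries`` seeded shuffles; returns None if no collision-free decoy
    is found.
    """
    pid = entry.precursor_id
    seq, mods = reverse_peptide(pid.peptide, pid.modifications)
    existing = existing_ids if existing_ids is not None else set()
    tries = 0
    while (seq == pid.peptide or (seq, mods, pid.glycan_composition, pid.charge) in existing):
        if tries >= max_retries:
            return None
        seq, mods = _shuffle_peptide(pid.peptide, pid.modifications, rng)
        tries += 1
    new_pid = PrecursorId(seq, mods, pid.glycan_composition, pid.charge)
    transitions = _retarget_peptide_transitions(entry, seq, mods, registry)
    return replace(
        entry,
        precursor_id=new_pid,
        precursor_mz=chem.glycopeptide_precursor_mz(
            seq, pid.glycan_composition, pid.charge, mods, registry
        ),
        transitions=transitions,
        is_decoy=True,
        decoy_type="peptide",
    )


def glycan_decoy(entry: LibraryEntry, rng: np.random.Generator) -> LibraryEntry:
    """Glycan decoy: every Y-ion m/z (except Y0 and Y$) receives an
    independent uniform [1, 30) Da mass shift on the singly-charged fragment
    mass (divided by charge for multi-charged ions).  Peptide-part
    transitions, Y0, Y$, RT and the precursor m/z are unchanged.
    """
    lo, hi = MASS_SHIFT_RANGE
    out = []
    for t in entry.transitions:
        if t.series == "Y" and t.composition not in ("", "$"):
            shift = float(rng.uniform(lo, hi))
            out.append(replace(t, mz=t.mz + shift / t.charge))
        else:
            out.append(t)
    out.sort(key=lambda t: t.mz)
    return replace(entry, transitions=out, is_decoy=True, decoy_type="glycan")


def both_decoy(
    entry: LibraryEntry,
    rng: np.random.Generator,
    existing_ids: Optional[set] = None,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> Optional[LibraryEntry]:
    """Both decoy: peptide reversal followed by glycan mass shifts."""
    pd = peptide_decoy(entry, rng, existing_ids, registry=registry)
    if pd is None:
        return None
    gd = glycan_decoy(pd, rng)
    return replace(gd, decoy_type="both")


def build_decoy_library(
    targets: Sequence[LibraryEntry],
    seed: int,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> List[LibraryEntry]:
    """Append one peptide, one glycan and one both decoy per target entry.

    Deterministic under ``seed`` and input order.  The combined library is 4x
    the target library size (entries whose peptide decoy cannot avoid a
    collision are skipped with a warning).
    """
    rng = np.random.default_rng(seed)
    target_ids = {
        (e.precursor_id.peptide, e.precursor_id.modifications,
         e.precursor_id.glycan_composition, e.precursor_id.charge)
        for e in targets
    }
    combined: List[LibraryEntry] = list(targets)
    for entry in targets:
        pd = peptide_decoy(entry, rng, target_ids, registry=registry)
        gd = glycan_decoy(entry, rng)
        bd = both_decoy(entry, rng, target_ids, registry=registry)
        if pd is None or bd is None:
            warnings.warn(
                f"skipping decoys for {entry.precursor_id.peptide}: "
                "no collision-free peptide decoy found"
            )
            continue
        combined.extend([pd, gd, bd])
    return combined


def glycoform_decoy_transitions(
    peptide: str,
    modifications: Sequence[chem.Modification],
    fragment_compositions: Sequence[GlycanComposition],
    rng: np.random.Generator,
    charges: Tuple[int, ...] = (1, 2, 3),
    min_mass_diff: float = 1.0,
    max_retries: int = 100,
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> Tuple[str, List[Tuple[GlycanComposition, int, float]]]:
    """Decoy identification transitions for glycoform inference.

    A random sequence over the 20 amino acids with the same length as the
    target is drawn (glycosite marker and PTMs kept at their positions),
    resampled until its mass differs from the target peptide mass by at
    least ``min_mass_diff`` Da.  Y transitions are then built from the decoy
    peptide mass and the target glycan fragment compositions.

    Returns (decoy_sequence, [(composition, charge, mz), ...]).
    """
    target_mass = chem.peptide_mass(peptide, modifications)
    aas = np.array(list(chem.AMINO_ACIDS))
    for _ in range(max_retries):
        letters = rng.choice(aas, size=len(peptide))
        seq = "".join(
            peptide[i] if peptide[i] == "J" else str(letters[i]) for i in range(len(peptide))
        )
        decoy_mass = chem.peptide_mass(seq, modifications)
        if abs(decoy_mass - target_mass) >= min_mass_diff:
            transitions = [
                (comp, z, chem.mz_from_mass(decoy_mass + comp.mass(registry), z))
                for comp in fragment_compositions
                for z in charges
            ]
            return seq, transitions
    raise RuntimeError(
        f"could not draw a decoy sequence {min_mass_diff} Da away from {peptide!r} "
        f"in {max_retries} tries"
    )
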