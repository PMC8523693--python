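"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from glycodia import chem
from glycodia.glycan import GlycanComposition, GlycanNode, GlycanStruct, parse_glycan
from glycodia.library import AnnotatedTransition, LibraryEntry, PrecursorId


def brute_force_y_fragments(struct: GlycanStruct) -> set:
    """Independent oracle: compositions of all root-containing connected node
    subsets, found by exhaustive enumeration over the power set."""
    nodes: List[Tuple[str, int]] = []

    def visit(node: GlycanNode, parent: int) -> None:
        idx = len(nodes)
        nodes.append((node.code, parent))
        for c in node.children:
            visit(c, idx)

    visit(struct.root, -1)
    n = len(nodes)
    frags = {GlycanComposition()}
    for mask in range(1, 2**n):
        sel = {i for i in range(n) if mask >> i & 1}
        if 0 not in sel:
            continue
        # connected and root-containing <=> every selected node's parent is
        # selected (or it is the root)
        if all(nodes[i][1] in sel or nodes[i][1] == -1 for i in sel):
            frags.add(GlycanComposition.from_dict(Counter(nodes[i][0] for i in sel)))
    return frags


def make_entry(
    peptide: str = "AAJSTLK",
    glycan_text: str = "(N(N(H(H)(H))))",
    charge: int = 2,
    rt: float = 30.0,
    modifications: Tuple = (),
    pep_intensities: Dict[Tuple[str, int, int], float] | None = None,
    gly_intensities: Dict[Tuple[str, int], float] | None = None,
    score_sum: float = 20.0,
) -> LibraryEntry:
    """Library entry with explicit per-fragment intensities.

    ``pep_intensities`` maps (series, ordinal, charge) -> intensity;
    ``gly_intensities`` maps (composition text, charge) -> intensity.
    Defaults give 5 peptide (y1..y5 at 1+) and 5 glycan transitions.
    """
    from glycodia.glycan import enumerate_y_fragments

    glycan = parse_glycan(glycan_text)
    pep_mass = chem.peptide_mass(peptide, modifications)
    b, y, _, _ = chem.backbone_fragment_masses(peptide, modifications)

    if pep_intensities is None:
        pep_intensities = {("y", i + 1, 1): 100.0 + 10 * i for i in range(5)}
    if gly_intensities is None:
        comps = sorted(
            (str(c) for c in enumerate_y_fragments(glycan).discriminating), key=str
        )[:5]
        gly_intensities = {(c, 1): 200.0 + 10 * i for i, c in enumerate(comps)}

    transitions = []
    for (series, ordinal, z), intensity in pep_intensities.items():
        masses = b if series.startswith("b") else y
        m = masses[ordinal - 1]
        if series.endswith("-N1"):
            m += chem.HEXNAC
        transitions.append(
            AnnotatedTransition(series, ordinal, None, z, chem.mz_from_mass(m, z), intensity)
        )
    for (comp_text, z), intensity in gly_intensities.items():
        if comp_text == "$":
            m = pep_mass + chem.CROSS_RING_OFFSET
        else:
            m = pep_mass + GlycanComposition.parse(comp_text).mass()
        transitions.append(
            AnnotatedTransition("Y", None, comp_text, z, chem.mz_from_mass(m, z), intensity)
        )
    transitions.sort(key=lambda t: t.mz)
    pid = PrecursorId(peptide, tuple(modifications), glycan.composition(), charge)
    return LibraryEntry(
        precursor_id=pid,
        glycan_struct=glycan,
        precursor_mz=chem.glycopeptide_precursor_mz(
            peptide, glycan.composition(), charge, modifications
        ),
        rt=rt,
        transitions=transitions,
        replicate_count=1,
        provenance={"score_sum": score_sum},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
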