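"""Mass constants and glycopeptide fragment m/z arithmetic.

Peptide masses are computed from the pyteomics monoisotopic residue table.
The glycosite marker ``J`` denotes an N-glycosylated asparagine and carries
the residue mass of asparagine; the attached glycan mass is added separately
where needed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

from .glycan import DEFAULT_REGISTRY, GlycanComposition, MonosaccharideRegistry

PROTON = 1.00727646688
WATER = 18.0105646863
HEXNAC = 203.07937

#: Mass offset of the cross-ring ^0,2X0 fragment of the reducing-end HexNAc
#: (the "Y$" ion): peptide mass + this offset.  Composition C4H5NO; the value
#: is configuration-overridable because conventions differ between tools.
CROSS_RING_OFFSET = 83.03711

_AA_MASS: Dict[str, float] = dict(_pmass.std_aa_mass)
_AA_MASS["J"] = _AA_MASS["N"]  # glycosylated asparagine

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

Modification = Tuple[str, int, float]  # (name, 1-based position, delta mass Da)


def residue_masses(sequence: str) -> List[float]:
    try:
        return [_AA_MASS[a] for a in sequence]
    except KeyError as e:
        raise ValueError(f"unknown amino acid {e.args[0]!r} in {sequence!r}") from None


def peptide_mass(sequence: str, modifications: Sequence[Modification] = ()) -> float:
    """Monoisotopic neutral mass of the (naked) peptide, modifications applied."""
    m = sum(residue_masses(sequence)) + WATER
    for _name, _pos, delta in modifications:
        m += delta
    return m


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON) / charge


def glycopeptide_precursor_mz(
    sequence: str,
    glycan_composition: GlycanComposition,
    charge: int,
    modifications: Sequence[Modification] = (),
    registry: MonosaccharideRegistry = DEFAULT_REGISTRY,
) -> float:
    return mz_from_mass(
        peptide_mass(sequence, modifications) + glycan_composition.mass(registry), charge
    )


def backbone_fragment_masses(
    sequence: str, modifications: Sequence[Modification] = ()
) -> Tuple[List[float], List[float], List[bool], List[bool]]:
    """Neutral masses of b and y backbone fragments and glycosite containment.

    Returns (b_masses, y_masses, b_has_site, y_has_site) where index i holds
    the fragment of ordinal i+1.  b_i covers residues [1, i+1]; y_i covers the
    C-terminal i+1 residues.  Modification deltas are assigned to the fragment
    containing their residue position.
    """
    res = residue_masses(sequence)
    n = len(res)
    mod_at = [0.0] * n
    for _name, pos, delta in modifications:
        if not 1 <= pos <= n:
            raise ValueError(f"modification position {pos} outside peptide of length {n}")
        mod_at[pos - 1] += delta

    b_masses, b_site = [], []
    acc = 0.0
    site = False
    for i in range(n - 1):
        acc += res[i] + mod_at[i]
        site = site or sequence[i] == "J"
        b_masses.append(acc)
        b_site.append(site)

    y_masses, y_site = [], []
    acc = WATER
    site = False
    for i in range(n - 1, 0, -1):
        acc += res[i] + mod_at[i]
        site = site or sequence[i] == "J"
        y_masses.append(acc)
        y_site.append(site)

    return b_masses, y_masses, b_site, y_site


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6
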