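"""N-glycan tree structures, compositions, and theoretical Y-fragment enumeration.

Glycan structures are rooted trees of monosaccharides written in the canonical
parenthesis notation used by glycopeptide search engines of the pGlyco family,
e.g. ``(N(N(H(H)(H))))`` for the N-glycan trimannosyl chitobiose core.  Each
node is one monosaccharide; the root is the reducing-end HexNAc attached to
the peptide.

Y ions are glycopeptide fragments that retain the intact peptide plus a
root-containing connected portion of the glycan.  Their glycan parts are
therefore exactly the root-containing connected subtrees, plus the empty set
(Y0, the naked peptide).  Because Y ions of equal monosaccharide composition
have equal m/z, fragment identity throughout this package is keyed by
composition rather than topology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "Monosaccharide",
    "MonosaccharideRegistry",
    "DEFAULT_REGISTRY",
    "GlycanComposition",
    "GlycanNode",
    "GlycanStruct",
    "YFragmentSet",
    "parse_glycan",
    "enumerate_y_fragments",
    "jaccard_similarity",
    "merge_isomers",
]


class GlycanParseError(ValueError):
    """Malformed canonical glycan string."""


class GlycanVocabularyError(ValueError):
    """Monosaccharide code not present in the registry."""


@dataclass(frozen=True)
class Monosaccharide:
    """One monosaccharide type: a one-letter code and its residue mass (Da)."""

    code: str
    name: str
    residue_mass: float

    def __post_init__(self) -> None:
        if self.residue_mass <= 0:
            raise ValueError(f"residue mass of {self.code!r} must be positive")


#: Monoisotopic residue masses (Da) of the common N-glycan building blocks,
#: computed from standard atomic masses of the dehydrated residues.
_DEFAULT_MONOSACCHARIDES = (
    Monosaccharide("H", "Hex", 162.05282),
    Monosaccharide("N", "HexNAc", 203.07937),
    Monosaccharide("F", "dHex", 146.05791),
    Monosaccharide("A", "NeuAc", 291.09542),
    Monosaccharide("G", "NeuGc", 307.09033),
    Monosaccharide("X", "Xyl", 132.04226),
)


class MonosaccharideRegistry:
    """Extensible registry mapping one-letter codes to monosaccharides.

    The default registry covers the pGlyco-style vocabulary (H, N, F, A, G,
    X).  Additional codes can be registered from configuration.
    """

    def __init__(self, monosaccharides: Iterable[Monosaccharide] = _DEFAULT_MONOSACCHARIDES):
        self._by_code: Dict[str, Monosaccharide] = {}
        for m in monosaccharides:
            self.add(m)

    def add(self, mono: Monosaccharide) -> None:
        if mono.code in self._by_code:
            raise ValueError(f"duplicate monosaccharide code {mono.code!r}")
        self._by_code[mono.code] = mono

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Monosaccharide:
        try:
            return self._by_code[code]
        except KeyError:
            raise GlycanVocabularyError(f"unknown monosaccharide code {code!r}") from None

    def residue_mass(self, code: str) -> float:
        return self[code].residue_mass

    def codes(self) -> Tuple[str, ...]:
        return tuple(self._by_code)

    @classmethod
    def from_config(cls, entries: Mapping[str, float]) -> "MonosaccharideRegistry":
        """Build a registry from a ``{code: residue_mass}`` mapping."""
        return cls(Monosaccharide(c, c, m) for c, m in entries.items())


DEFAULT_REGISTRY = MonosaccharideRegistry()


@dataclass(frozen=True)
class GlycanComposition:
    """A multiset of monosaccharide codes (glycan 'composition').

    Stored as a sorted tuple of (code, count) pairs so that instances are
    hashable and can be used as set elements / dict keys.
    """

    counts: Tuple[Tuple[str, int], ...] = ()

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "GlycanComposition":
        items = tuple(sorted((c, int(n)) for c, n in counts.items() if n > 0))
        for code, n in items:
            if n < 0:
                raise ValueError("negative monosaccharide count")
        return cls(items)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def mass(self, registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> float:
        return sum(registry.residue_mass(code) * n for code, n in self.counts)

    def get(self, code: str) -> int:
        return dict(self.counts).get(code, 0)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        merged = dict(self.counts)
        for code, n in other.counts:
            merged[code] = merged.get(code, 0) + n
        return GlycanComposition.from_dict(merged)

    def __str__(self) -> str:
        return "".join(f"{code}({n})" for code, n in self.counts) or "-"

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse the ``H(5)N(2)`` textual form produced by :meth:`__str__`."""
        if text in ("", "-"):
            return cls()
        counts: Dict[str, int] = {}
        i = 0
        while i < len(text):
            j = text.index("(", i)
            k = text.index(")", j)
            code = text[i:j]
            counts[code] = counts.get(code, 0) + int(text[j + 1 : k])
            i = k + 1
        return cls.from_dict(counts)


@dataclass(frozen=True)
class GlycanNode:
    """One monosaccharide node with its (canonically ordered) children."""

    code: str
    children: Tuple["GlycanNode", ...] = ()

    def serialize(self) -> str:
        return f"({self.code}{''.join(c.serialize() for c in self.children)})"

    def canonicalize(self) -> "GlycanNode":
        kids = tuple(sorted((c.canonicalize() for c in self.children),
                            key=lambda n: n.serialize()))
        return GlycanNode(self.code, kids)

    def node_count(self) -> int:
        return 1 + sum(c.node_count() for c in self.children)


@dataclass(frozen=True)
class GlycanStruct:
    """A rooted glycan tree in canonical form."""

    root: GlycanNode

    @property
    def canonical_text(self) -> str:
        return self.root.serialize()

    @property
    def node_count(self) -> int:
        return self.root.node_count()

    def composition(self) -> GlycanComposition:
        counts: Dict[str, int] = {}

        def visit(node: GlycanNode) -> None:
            counts[node.code] = counts.get(node.code, 0) + 1
            for c in node.children:
                visit(c)

        visit(self.root)
        return GlycanComposition.from_dict(counts)

    def mass(self, registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> float:
        return self.composition().mass(registry)

    def __str__(self) -> str:
        return self.canonical_text


def parse_glycan(text: str, registry: MonosaccharideRegistry = DEFAULT_REGISTRY) -> GlycanStruct:
    """Parse a canonical parenthesis string into a :class:`GlycanStruct`.

    The children of every node are re-ordered canonically (lexical order of
    the serialized subtrees) so that ``parse_glycan(t).canonical_text`` is a
    unique representation of the tree, stable under input child permutation.

    Raises
    ------
    GlycanParseError
        On unbalanced parentheses or stray characters.
    GlycanVocabularyError
        On a monosaccharide code absent from the registry.
    """
    if not text:
        raise GlycanParseError("empty glycan string")

    pos = 0

    def parse_node() -> GlycanNode:
        nonlocal pos
        if pos >= len(text) or text[pos] != "(":
            raise GlycanParseError(f"expected '(' at position {pos} in {text!r}")
        pos += 1
        start = pos
        while pos < len(text) and text[pos] not in "()":
            pos += 1
        code = text[start:pos]
        if not code:
            raise GlycanParseError(f"missing monosaccharide code at position {start} in {text!r}")
        registry[code]  # raises GlycanVocabularyError for unknown codes
        children: List[GlycanNode] = []
        while pos < len(text) and text[pos] == "(":
            children.append(parse_node())
        if pos >= len(text) or text[pos] != ")":
            raise GlycanParseError(f"unbalanced parentheses in {text!r}")
        pos += 1
        return GlycanNode(code, tuple(children))

    root = parse_node()
    if pos != len(text):
        raise GlycanParseError(f"trailing characters after position {pos} in {text!r}")
    return GlycanStruct(root.canonicalize())


@dataclass(frozen=True)
class YFragmentSet:
    """The set of theoretical Y-fragment glycan compositions of one glycan.

    Always contains the empty composition (Y0) and the full composition.
    The cross-ring Y$ ion is a peptide-plus-fragment species common to all
    N-glycans and is handled by mass offset elsewhere; it carries no
    composition and is not a member of this set.

    ``discriminating`` drops the empty composition: Y0 (like Y$) is shared by
    every glycoform on the same peptide and contributes nothing to ranking
    glycoforms by distinguishability.
    """

    fragments: frozenset  # of GlycanComposition

    def __post_init__(self) -> None:
        if GlycanComposition() not in self.fragments:
            raise ValueError("Y-fragment set must contain the empty composition (Y0)")

    @property
    def discriminating(self) -> frozenset:
        return self.fragments - {GlycanComposition()}

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, comp: GlycanComposition) -> bool:
        return comp in self.fragments


def enumerate_y_fragments(glycan: GlycanStruct) -> YFragmentSet:
    """Enumerate compositions of all root-containing connected subtrees.

    This is the in-silico generation of all theoretical Y ions: any connected
    subgraph of the glycan tree that contains the root survives as the glycan
    part of a Y fragment.  The empty composition (Y0) is included.  Identity
    is by composition, so topologically distinct subtrees of equal composition
    collapse to a single fragment.
    """

    def node_options(node: GlycanNode) -> List[GlycanComposition]:
        # All compositions of connected subtrees of `node`'s subtree that
        # contain `node` itself.
        own = GlycanComposition.from_dict({node.code: 1})
        child_opts: List[List[GlycanComposition]] = []
        for child in node.children:
            opts = node_options(child)
            child_opts.append([GlycanComposition()] + opts)  # child may be absent
        results = set()
        for combo in itertools.product(*child_opts) if child_opts else [()]:
            total = own
            for comp in combo:
                total = total + comp
            results.add(total)
        return list(results)

    frags = set(node_options(glycan.root))
    frags.add(GlycanComposition())
    return YFragmentSet(frozenset(frags))


def jaccard_similarity(a: YFragmentSet, b: YFragmentSet) -> float:
    """Jaccard similarity of two Y-fragment sets on their discriminating parts.

    ``|A∩B| / |A∪B|`` over the fragment compositions excluding Y0 (and Y$,
    which is never composition-keyed).  Symmetric, 1.0 iff the discriminating
    sets are identical.
    """
    fa, fb = a.discriminating, b.discriminating
    union = fa | fb
    if not union:
        return 1.0
    return len(fa & fb) / len(union)


def merge_isomers(structs: Sequence[GlycanStruct]) -> List[List[GlycanStruct]]:
    """Group isomeric structures whose theoretical Y-fragment sets coincide.

    All inputs must share one monosaccharide composition.  Structures in one
    group are indistinguishable by Y ions and are treated as a single
    glycoform hypothesis downstream.
    """
    if not structs:
        return []
    comps = {s.composition() for s in structs}
    if len(comps) > 1:
        raise ValueError("merge_isomers requires structures of one composition")
    groups: Dict[frozenset, List[GlycanStruct]] = {}
    for s in structs:
        key = enumerate_y_fragments(s).fragments
        groups.setdefault(key, []).append(s)
    # deterministic order: by canonical text of the first member
    ordered = [sorted(g, key=lambda s: s.canonical_text) for g in groups.values()]
    ordered.sort(key=lambda g: g[0].canonical_text)
    return ordered
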