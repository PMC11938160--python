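"""Modular N-glycan structures and their classification.

An N-glycan is represented as a rooted tree of monosaccharide nodes using
single-letter symbols:

    N = HexNAc, H = Hex, F = Fucose (dHex), S = Neu5Ac, G = Neu5Gc

Structures are serialized in a nested-parenthesis grammar::

    node     := SYMBOL child*
    child    := '(' node ')'

e.g. ``N(F)(N(H(H)(H(N(H)))))`` is a core-fucosylated hybrid glycan.  The
*canonical* serialization orders sibling subtrees lexicographically by their
own serialization, so every topology has exactly one canonical string.

The classification follows the modular view of N-glycans: every structure is
decomposed into a core (the chitobiose N-N plus the trimannosyl H(H)(H),
optionally core-fucosylated and/or carrying a bisecting HexNAc), a set of
antennae (HexNAc-initiated branches on the two arm mannoses), and terminal
decorations (fucose, Neu5Ac, Neu5Gc).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "SYMBOLS",
    "Composition",
    "GlycanNode",
    "GlycanStructure",
    "BranchClass",
    "BranchTaxonomy",
    "FeatureAnnotation",
    "GlycanParseError",
    "GlycanClassificationError",
    "parse_composition",
    "parse_structure",
    "classify_subtype",
    "classify_core",
    "count_antennae",
    "decompose_branches",
    "annotate_features",
    "annotate_composition",
    "default_taxonomy",
]

#: Closed residue alphabet in canonical composition order.
SYMBOLS = ("N", "H", "F", "S", "G")

SUBTYPES = ("oligo-mannose", "hybrid", "complex")
CORE_CLASSES = (
    "typical",
    "core-fucosylated",
    "bisected",
    "bisected-core-fucosylated",
)
SIALYL_CATEGORIES = (
    "none",
    "sialyl-Lewis",
    "terminal-sialyl-LacNAc",
    "antenna-sialyl-LacNAc",
    "bi-sialyl-LacNAc",
)

UNCLASSIFIED_BRANCH = "unclassified-branch"


class GlycanParseError(ValueError):
    """A composition or structure string could not be parsed."""


class GlycanClassificationError(ValueError):
    """A structure does not contain a recognisable N-glycan core."""


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

_COMP_TOKEN = re.compile(r"([A-Za-z])(\d+)")


@dataclass(frozen=True)
class Composition:
    """Monosaccharide counts of one glycan, e.g. ``N4H5F1G2``."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {s: int(self.counts.get(s, 0)) for s in SYMBOLS}
        for sym, n in self.counts.items():
            if sym not in SYMBOLS:
                raise GlycanParseError(f"unknown residue symbol {sym!r}")
            if n < 0:
                raise GlycanParseError(f"negative count for residue {sym!r}")
        if sum(clean.values()) < 2:
            raise GlycanParseError("composition must contain at least 2 residues")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, symbol: str) -> int:
        return self.counts[symbol]

    def total(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # canonical order N,H,F,S,G; zero counts omitted
        return "".join(f"{s}{self.counts[s]}" for s in SYMBOLS if self.counts[s])

    @classmethod
    def from_string(cls, text: str) -> "Composition":
        return parse_composition(text)


def parse_composition(text: str) -> Composition:
    """Parse a composition string such as ``"N4H5F1G2"``.

    Each symbol may appear at most once; counts must be positive integers.
    """
    if not text:
        raise GlycanParseError("empty composition string")
    pos = 0
    counts: dict[str, int] = {}
    for m in _COMP_TOKEN.finditer(text):
        if m.start() != pos:
            raise GlycanParseError(
                f"malformed composition near {text[pos:]!r} in {text!r}"
            )
        sym, num = m.group(1), int(m.group(2))
        if sym not in SYMBOLS:
            raise GlycanParseError(f"unknown residue symbol {sym!r} in {text!r}")
        if sym in counts:
            raise GlycanParseError(f"duplicate residue symbol {sym!r} in {text!r}")
        if num == 0:
            raise GlycanParseError(f"zero count for residue {sym!r} in {text!r}")
        counts[sym] = num
        pos = m.end()
    if pos != len(text):
        raise GlycanParseError(f"malformed composition near {text[pos:]!r} in {text!r}")
    return Composition(counts)


# ---------------------------------------------------------------------------
# Structure tree
# ---------------------------------------------------------------------------


@dataclass
class GlycanNode:
    symbol: str
    children: list["GlycanNode"] = field(default_factory=list)

    def serialize(self) -> str:
        if self.symbol not in SYMBOLS:
            raise GlycanParseError(f"unknown residue symbol {self.symbol!r}")
        parts = sorted(c.serialize() for c in self.children)
        return self.symbol + "".join(f"({p})" for p in parts)

    def walk(self) -> Iterator["GlycanNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


def _parse_node(text: str, pos: int) -> tuple[GlycanNode, int]:
    if pos >= len(text):
        raise GlycanParseError("unexpected end of structure string")
    sym = text[pos]
    if sym not in SYMBOLS:
        raise GlycanParseError(f"unknown residue symbol {sym!r} at position {pos}")
    node = GlycanNode(sym)
    pos += 1
    while pos < len(text) and text[pos] == "(":
        child, pos = _parse_node(text, pos + 1)
        if pos >= len(text) or text[pos] != ")":
            raise GlycanParseError(f"unbalanced parentheses at position {pos}")
        node.children.append(child)
        pos += 1
    return node, pos


@dataclass(frozen=True)
class GlycanStructure:
    """A rooted N-glycan topology; ``id`` is the canonical serialization."""

    root: GlycanNode
    id: str = ""

    def __post_init__(self) -> None:
        if self.root.symbol != "N":
            raise GlycanParseError(
                f"root residue must be N (HexNAc), got {self.root.symbol!r}"
            )
        object.__setattr__(self, "id", self.root.serialize())

    def serialize(self) -> str:
        return self.id

    def composition(self) -> Composition:
        counts: dict[str, int] = {}
        for node in self.root.walk():
            counts[node.symbol] = counts.get(node.symbol, 0) + 1
        return Composition(counts)

    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.walk())

    def __hash__(self) -> int:
        return hash(self.id)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GlycanStructure) and self.id == other.id

    @classmethod
    def from_string(cls, text: str) -> "GlycanStructure":
        return parse_structure(text)


def parse_structure(text: str) -> GlycanStructure:
    """Parse a nested-parenthesis structure string into a tree.

    ``serialize(parse_structure(t)) == t`` holds for canonical ``t``;
    non-canonically ordered sibling lists are accepted and canonicalised.
    """
    if not text:
        raise GlycanParseError("empty structure string")
    root, pos = _parse_node(text, 0)
    if pos != len(text):
        raise GlycanParseError(f"trailing characters at position {pos} in {text!r}")
    return GlycanStructure(root)


# ---------------------------------------------------------------------------
# Core anatomy
# ---------------------------------------------------------------------------


@dataclass
class _CoreAnatomy:
    root: GlycanNode  # reducing-end GlcNAc
    core_fucoses: list[GlycanNode]  # F children of the root
    second_glcnac: GlycanNode
    central_mannose: GlycanNode
    arm_mannoses: list[GlycanNode]  # H children of the central mannose (<=2)
    bisecting: GlycanNode | None  # N child of the central mannose


def _locate_core(g: GlycanStructure) -> _CoreAnatomy:
    root = g.root
    n_children = [c for c in root.children if c.symbol == "N"]
    f_children = [c for c in root.children if c.symbol == "F"]
    if len(n_children) != 1 or len(n_children) + len(f_children) != len(root.children):
        raise GlycanClassificationError(
            f"cannot locate chitobiose core in {g.id!r}: the reducing-end HexNAc "
            "must carry exactly one HexNAc plus optional core fucoses"
        )
    second = n_children[0]
    h_children = [c for c in second.children if c.symbol == "H"]
    if len(h_children) != 1 or len(second.children) != 1:
        raise GlycanClassificationError(
            f"cannot locate central core mannose in {g.id!r}"
        )
    central = h_children[0]
    arms = [c for c in central.children if c.symbol == "H"]
    bisect = [c for c in central.children if c.symbol == "N"]
    if len(arms) > 2 or len(bisect) > 1 or len(arms) + len(bisect) != len(
        central.children
    ):
        raise GlycanClassificationError(
            f"central mannose of {g.id!r} must carry at most two arm mannoses "
            "and at most one bisecting HexNAc"
        )
    return _CoreAnatomy(
        root=root,
        core_fucoses=f_children,
        second_glcnac=second,
        central_mannose=central,
        arm_mannoses=arms,
        bisecting=bisect[0] if bisect else None,
    )


def _antennae(core: _CoreAnatomy) -> list[GlycanNode]:
    """HexNAc-initiated branches on the two arm mannoses (bisect excluded)."""
    out: list[GlycanNode] = []
    for arm in core.arm_mannoses:
        out.extend(c for c in arm.children if c.symbol == "N")
    return out


def _arm_hex_extended(core: _CoreAnatomy) -> bool:
    """True if any arm mannose carries further Hex (mannose) extensions."""
    return any(
        c.symbol == "H" for arm in core.arm_mannoses for c in arm.children
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_subtype(g: GlycanStructure) -> str:
    """Classify into oligo-mannose / hybrid / complex.

    oligo-mannose: only Hex beyond the core (Man3-Man9 pattern), no fucose or
    sialic acid, no antennae, no bisect.  complex: every arm extension is a
    HexNAc-initiated antenna.  hybrid: at least one Hex-extended (mannosidic)
    arm together with at least one HexNAc-initiated antenna.
    """
    core = _locate_core(g)
    ant = _antennae(core)
    comp = g.composition()
    undecorated = comp["F"] == 0 and comp["S"] == 0 and comp["G"] == 0
    if not ant and core.bisecting is None and undecorated:
        # arms may only carry Hex chains; core location already guarantees
        # everything below the arms is reachable only through H or N nodes
        if all(n.symbol == "H" for arm in core.arm_mannoses for n in arm.walk()):
            return "oligo-mannose"
    if _arm_hex_extended(core) and ant:
        return "hybrid"
    if ant or not _arm_hex_extended(core):
        return "complex"
    # degenerate: mannosidic arms plus decorations/bisect but no antenna
    return "hybrid"


def classify_core(g: GlycanStructure) -> str:
    """Classify the core as typical / core-fucosylated / bisected / both."""
    core = _locate_core(g)
    fuc = bool(core.core_fucoses)
    bis = core.bisecting is not None
    if fuc and bis:
        return "bisected-core-fucosylated"
    if bis:
        return "bisected"
    if fuc:
        return "core-fucosylated"
    return "typical"


def count_antennae(g: GlycanStructure) -> int:
    """Number of HexNAc-initiated antennae on the arm mannoses (0 for
    oligo-mannose; the bisecting HexNAc is never counted)."""
    return len(_antennae(_locate_core(g)))


# ---------------------------------------------------------------------------
# Branch taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchClass:
    code: str
    template: GlycanStructure
    sialyl_category: str
    sialic_type: str  # none | Neu5Ac | Neu5Gc

    def __post_init__(self) -> None:
        if self.sialyl_category not in SIALYL_CATEGORIES:
            raise ValueError(f"unknown sialyl category {self.sialyl_category!r}")
        if self.sialic_type not in ("none", "Neu5Ac", "Neu5Gc", "mixed"):
            raise ValueError(f"unknown sialic type {self.sialic_type!r}")


LACDINAC_CODES = frozenset({"N2", "N2S", "N2G", "N2F"})
LEWIS_CODES = frozenset({"NHF", "NHFS", "NHFG"})


class BranchTaxonomy:
    """The branch-structure classes antennae are matched against.

    The default table has exactly 17 entries; a user-supplied TSV with
    columns ``code``, ``template``, ``sialyl_category``, ``sialic_type``
    replaces it wholesale.
    """

    def __init__(self, entries: list[BranchClass]):
        self.entries = list(entries)
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("branch codes must be unique")
        self._by_template: dict[str, BranchClass] = {}
        for e in self.entries:
            key = e.template.id
            if key in self._by_template:
                raise ValueError(f"duplicate branch template {key!r}")
            self._by_template[key] = e
        self._by_code = {e.code: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[BranchClass]:
        return iter(self.entries)

    def get(self, code: str) -> BranchClass:
        return self._by_code[code]

    def match(self, antenna: GlycanNode) -> BranchClass | None:
        """Exact-topology match of an antenna subtree against the templates.

        Templates are full antenna topologies, so at most one can match;
        ambiguity is impossible by construction (duplicate templates are
        rejected at load time).
        """
        return self._by_template.get(antenna.serialize())

    def sialylated_branch_types(self) -> list[BranchClass]:
        """Entries carrying a sialyl category (the category x sialic-acid
        grid of sialylated non-LacdiNAc branches)."""
        return [e for e in self.entries if e.sialyl_category != "none"]

    @classmethod
    def from_tsv(cls, path) -> "BranchTaxonomy":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"code", "template", "sialyl_category", "sialic_type"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy file missing columns: {sorted(missing)}")
        entries = [
            BranchClass(
                code=row.code,
                template=parse_structure(row.template),
                sialyl_category=row.sialyl_category,
                sialic_type=row.sialic_type,
            )
            for row in df.itertuples()
        ]
        return cls(entries)


def default_taxonomy() -> BranchTaxonomy:
    """The built-in 17-entry branch taxonomy."""
    path = resources.files("glycoscape") / "data" / "branch_taxonomy.tsv"
    with resources.as_file(path) as p:
        return BranchTaxonomy.from_tsv(p)


def decompose_branches(
    g: GlycanStructure, taxonomy: BranchTaxonomy
) -> list[str]:
    """Map every antenna of ``g`` to a branch-class code.

    Returns one code per antenna (a multiset as a sorted list); antennae with
    no matching template are reported as ``unclassified-branch`` with a
    warning, never dropped.
    """
    core = _locate_core(g)
    codes: list[str] = []
    for antenna in _antennae(core):
        hit = taxonomy.match(antenna)
        if hit is None:
            warnings.warn(
                f"antenna {antenna.serialize()!r} of glycan {g.id!r} matches no "
                "branch template",
                stacklevel=2,
            )
            codes.append(UNCLASSIFIED_BRANCH)
        else:
            codes.append(hit.code)
    return sorted(codes)


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureAnnotation:
    """Derived structural labels of one glycan."""

    subtype: str
    core: str
    branches: tuple[str, ...]
    antenna_count: int
    fucosylation: str  # none | core-only | antenna-only | both
    sialylation: str  # none | Neu5Ac-only | Neu5Gc-only | both
    has_lacdinac: bool
    has_lewis: bool
    sialyl_branch_types: tuple[tuple[str, str], ...] = ()
    confidence: str = "structure"  # structure | composition-only


def _fucosylation_state(g: GlycanStructure, core: _CoreAnatomy) -> str:
    n_core_fuc = len(core.core_fucoses)
    n_total_fuc = g.composition()["F"]
    n_antenna_fuc = n_total_fuc - n_core_fuc
    if n_core_fuc and n_antenna_fuc:
        return "both"
    if n_core_fuc:
        return "core-only"
    if n_antenna_fuc:
        return "antenna-only"
    return "none"


def _sialylation_state(comp: Composition) -> str:
    s, g_ = comp["S"], comp["G"]
    if s and g_:
        return "both"
    if s:
        return "Neu5Ac-only"
    if g_:
        return "Neu5Gc-only"
    return "none"


def annotate_features(
    g: GlycanStructure, taxonomy: BranchTaxonomy | None = None
) -> FeatureAnnotation:
    """Full modular annotation of one glycan structure."""
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
    core = _locate_core(g)
    codes = decompose_branches(g, taxonomy)
    sialyl_types = []
    for code in codes:
        if code == UNCLASSIFIED_BRANCH:
            continue
        entry = taxonomy.get(code)
        if entry.sialyl_category != "none":
            sialyl_types.append((entry.sialyl_category, entry.sialic_type))
    return FeatureAnnotation(
        subtype=classify_subtype(g),
        core=classify_core(g),
        branches=tuple(codes),
        antenna_count=len(_antennae(core)),
        fucosylation=_fucosylation_state(g, core),
        sialylation=_sialylation_state(g.composition()),
        has_lacdinac=any(c in LACDINAC_CODES for c in codes),
        has_lewis=any(c in LEWIS_CODES for c in codes),
        sialyl_branch_types=tuple(sorted(set(sialyl_types))),
    )


def annotate_composition(comp: Composition) -> FeatureAnnotation:
    """Lower-confidence annotation for records that carry only a composition.

    Oligo-mannose is recognisable from composition alone (N2 H3-H9, no
    decorations); anything else is labelled complex with unknown fucose
    position.  Flagged ``composition-only``.
    """
    if comp["N"] == 2 and 3 <= comp["H"] <= 9 and not (
        comp["F"] or comp["S"] or comp["G"]
    ):
        subtype = "oligo-mannose"
    else:
        subtype = "complex"
    return FeatureAnnotation(
        subtype=subtype,
        core="core-fucosylated" if (subtype != "oligo-mannose" and comp["F"]) else "typical",
        branches=(),
        antenna_count=0 if subtype == "oligo-mannose" else max(comp["N"] - 2, 0),
        fucosylation="none" if comp["F"] == 0 else "unknown-position",
        sialylation=_sialylation_state(comp),
        has_lacdinac=False,
        has_lewis=False,
        confidence="composition-only",
    )
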