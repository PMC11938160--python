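"""Independent brute-force oracles used to cross-check the classifiers.

Everything here works by naive traversal and permutation matching, never
through canonical serialization, so agreement with the package's
classifiers is a genuine dual-route check.
"""

from itertools import permutations

from glycoscape.glycans import GlycanNode, GlycanStructure, BranchTaxonomy


def tree_iso(a: GlycanNode, b: GlycanNode) -> bool:
    """Unordered rooted-tree isomorphism by exhaustive child permutation."""
    if a.symbol != b.symbol or len(a.children) != len(b.children):
        return False
    if not a.children:
        return True
    for perm in permutations(b.children):
        if all(tree_iso(ca, cb) for ca, cb in zip(a.children, perm)):
            return True
    return False


def _count_nodes(node: GlycanNode) -> int:
    return 1 + sum(_count_nodes(c) for c in node.children)


def _find_core(g: GlycanStructure):
    """(root, second GlcNAc, central mannose, arm mannoses) by direct walk."""
    root = g.root
    assert root.symbol == "N"
    second = [c for c in root.children if c.symbol == "N"]
    assert len(second) == 1
    central = [c for c in second[0].children if c.symbol == "H"]
    assert len(central) == 1
    arms = [c for c in central[0].children if c.symbol == "H"]
    return root, second[0], central[0], arms


def brute_antennae(g: GlycanStructure) -> list[GlycanNode]:
    _, _, _, arms = _find_core(g)
    return [c for arm in arms for c in arm.children if c.symbol == "N"]


def brute_count_antennae(g: GlycanStructure) -> int:
    return len(brute_antennae(g))


def brute_subtype(g: GlycanStructure) -> str:
    _, _, central, arms = _find_core(g)
    ant = brute_antennae(g)
    bisected = any(c.symbol == "N" for c in central.children)
    symbols = [n.symbol for n in g.root.walk()]
    decorated = any(s in ("F", "S", "G") for s in symbols)
    arm_subtree_all_hex = all(
        n.symbol == "H" for arm in arms for n in arm.walk()
    )
    if not ant and not bisected and not decorated and arm_subtree_all_hex:
        return "oligo-mannose"
    hex_extended = any(
        c.symbol == "H" for arm in arms for c in arm.children
    )
    if hex_extended and ant:
        return "hybrid"
    if ant or not hex_extended:
        return "complex"
    return "hybrid"


def brute_core(g: GlycanStructure) -> str:
    root, _, central, _ = _find_core(g)
    fuc = any(c.symbol == "F" for c in root.children)
    bis = any(c.symbol == "N" for c in central.children)
    return {
        (False, False): "typical",
        (True, False): "core-fucosylated",
        (False, True): "bisected",
        (True, True): "bisected-core-fucosylated",
    }[(fuc, bis)]


def brute_decompose(g: GlycanStructure, taxonomy: BranchTaxonomy) -> list[str]:
    """Match every antenna against every template by permutation
    isomorphism; resolve multiple hits by most residues, then code."""
    codes = []
    for antenna in brute_antennae(g):
        hits = [
            e for e in taxonomy if tree_iso(antenna, e.template.root)
        ]
        if not hits:
            codes.append("unclassified-branch")
        else:
            hits.sort(key=lambda e: (-_count_nodes(e.template.root), e.code))
            codes.append(hits[0].code)
    return sorted(codes)


def brute_sequons(sequence: str) -> list[tuple[int, str]]:
    """Naive window scan for N-X(!=P)-S/T."""
    seq = sequence.upper()
    out = []
    for i in range(len(seq)):
        window = seq[i : i + 3]
        if len(window) == 3 and window[0] == "N" and window[1] != "P":
            if window[2] == "T":
                out.append((i + 1, "N-X-T"))
            elif window[2] == "S":
                out.append((i + 1, "N-X-S"))
    return out
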