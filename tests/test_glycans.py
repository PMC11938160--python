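"""Glycan parsing, serialization and modular classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _brute
from glycoscape.glycans import (
    CORE_CLASSES,
    SUBTYPES,
    BranchTaxonomy,
    Composition,
    GlycanParseError,
    GlycanClassificationError,
    annotate_composition,
    annotate_features,
    classify_core,
    classify_subtype,
    count_antennae,
    decompose_branches,
    parse_composition,
    parse_structure,
)


class TestComposition:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("N4H5F1G2", {"N": 4, "H": 5, "F": 1, "S": 0, "G": 2}),
            ("N2H3", {"N": 2, "H": 3, "F": 0, "S": 0, "G": 0}),
            ("N4H5F1S1G1", {"N": 4, "H": 5, "F": 1, "S": 1, "G": 1}),
        ]
        + [(f"N2H{h}", {"N": 2, "H": h, "F": 0, "S": 0, "G": 0}) for h in range(5, 10)],
    )
    def test_parse(self, text, expected):
        assert parse_composition(text).counts == expected

    @pytest.mark.parametrize(
        "bad",
        ["", "X4H5", "N4N2", "N0H5", "N4H", "4N5H", "N4 H5", "N-1H5"],
    )
    def test_parse_errors(self, bad):
        with pytest.raises(GlycanParseError):
            parse_composition(bad)

    def test_round_trip_is_canonical(self):
        # symbol order fixed to N,H,F,S,G; zero counts dropped
        assert str(parse_composition("N4H5F1G2")) == "N4H5F1G2"
        assert str(Composition({"G": 2, "N": 4, "H": 5, "F": 1})) == "N4H5F1G2"

    @given(
        st.fixed_dictionaries(
            {},
            optional={s: st.integers(1, 12) for s in ("N", "H", "F", "S", "G")},
        ).filter(lambda d: sum(d.values()) >= 2)
    )
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_property(self, counts):
        comp = Composition(counts)
        assert parse_composition(str(comp)).counts == comp.counts


class TestStructureParsing:
    def test_man5_node_count_matches_composition(self, library):
        man5 = next(g for g in library if str(g.composition()) == "N2H5")
        assert man5.n_nodes() == 7
        assert man5.composition().counts == {"N": 2, "H": 5, "F": 0, "S": 0, "G": 0}

    def test_biantennary_core_fucosylated_composition(self):
        g = parse_structure("N(F)(N(H(H(N(H)))(H(N(H)))))")
        # brute-force node count by traversal
        counts = {}
        for node in g.root.walk():
            counts[node.symbol] = counts.get(node.symbol, 0) + 1
        assert counts == {"N": 4, "H": 5, "F": 1}
        assert g.composition().counts == {"N": 4, "H": 5, "F": 1, "S": 0, "G": 0}

    def test_round_trip_on_library_and_random(self, library, random_structures):
        for g in library + random_structures:
            assert parse_structure(g.id).id == g.id

    def test_non_canonical_input_is_canonicalised(self):
        assert parse_structure("N(N(H(H)(H)))(F)").id == "N(F)(N(H(H)(H)))"

    @pytest.mark.parametrize(
        "bad", ["", "H(N)", "N(", "N)", "N(N))", "N(Z)", "N()"]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(GlycanParseError):
            parse_structure(bad)


class TestSubtype:
    def test_man5_is_oligo_mannose(self, library):
        man5 = next(g for g in library if str(g.composition()) == "N2H5")
        assert classify_subtype(man5) == "oligo-mannose"

    def test_biantennary_is_complex(self):
        g = parse_structure("N(N(H(H(N(H)))(H(N(H)))))")
        assert classify_subtype(g) == "complex"

    def test_mixed_arms_is_hybrid(self):
        # one mannosidic arm (extra Hex), one HexNAc-initiated antenna
        g = parse_structure("N(N(H(H(H))(H(N(H)))))")
        assert classify_subtype(g) == "hybrid"

    def test_no_core_raises(self):
        with pytest.raises(GlycanClassificationError):
            classify_subtype(parse_structure("N(H)"))


class TestCore:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("N(N(H(H)(H)))", "typical"),
            ("N(F)(N(H(H)(H)))", "core-fucosylated"),
            ("N(N(H(H)(H)(N)))", "bisected"),
            ("N(F)(N(H(H)(H)(N)))", "bisected-core-fucosylated"),
        ],
    )
    def test_four_classes(self, text, expected):
        assert classify_core(parse_structure(text)) == expected


class TestBranches:
    def test_lacnac_and_neugc_antennae(self, taxonomy):
        g = parse_structure("N(N(H(H(N(H)))(H(N(H(G))))))")
        assert decompose_branches(g, taxonomy) == ["NH", "NHG"]

    def test_lacdinac(self, taxonomy):
        g = parse_structure("N(N(H(H(N(N)))(H)))")
        assert decompose_branches(g, taxonomy) == ["N2"]

    def test_oligo_mannose_has_no_branches(self, taxonomy, library):
        man9 = next(g for g in library if str(g.composition()) == "N2H9")
        assert decompose_branches(man9, taxonomy) == []

    def test_unmatched_antenna_warns_not_drops(self, taxonomy):
        # an antenna bearing two fucoses matches no template
        g = parse_structure("N(N(H(H(N(F)(F)(H)))(H)))")
        with pytest.warns(UserWarning, match="no branch template"):
            codes = decompose_branches(g, taxonomy)
        assert codes == ["unclassified-branch"]


class TestAntennae:
    def test_examples(self, library):
        bi = parse_structure("N(N(H(H(N(H)))(H(N(H)))))")
        assert count_antennae(bi) == 2
        tetra = parse_structure("N(N(H(H(N(H))(N(H)))(H(N(H))(N(H)))))")
        assert count_antennae(tetra) == 4
        man9 = next(g for g in library if str(g.composition()) == "N2H9")
        assert count_antennae(man9) == 0

    def test_bisecting_hexnac_not_counted(self):
        g = parse_structure("N(N(H(H(N(H)))(H(N(H)))(N)))")
        assert count_antennae(g) == 2

    def test_bounds_on_fixtures(self, library, random_structures):
        for g in library + random_structures:
            assert 0 <= count_antennae(g) <= 6


class TestAnnotation:
    def test_core_fucosylated_neugc_biantennary(self, taxonomy):
        # structure of composition N4H5F1G2 with the fucose on the core
        g = parse_structure("N(F)(N(H(H(N(H(G))))(H(N(H(G))))))")
        ann = annotate_features(g, taxonomy)
        assert str(g.composition()) == "N4H5F1G2"
        assert ann.fucosylation == "core-only"
        assert ann.sialylation == "Neu5Gc-only"
        assert ann.subtype == "complex"

    def test_dual_fucosylation(self, taxonomy):
        g = parse_structure("N(F)(N(H(H(N(F)(H)))(H(N(H)))))")
        assert annotate_features(g, taxonomy).fucosylation == "both"

    def test_mixed_sialylation(self, taxonomy):
        g = parse_structure("N(N(H(H(N(H(S))))(H(N(H(G))))))")
        ann = annotate_features(g, taxonomy)
        assert ann.sialylation == "both"
        assert ann.sialyl_branch_types == (
            ("terminal-sialyl-LacNAc", "Neu5Ac"),
            ("terminal-sialyl-LacNAc", "Neu5Gc"),
        )

    def test_lacdinac_and_lewis_flags(self, taxonomy):
        g = parse_structure("N(N(H(H(N(N)))(H(N(F)(H)))))")
        ann = annotate_features(g, taxonomy)
        assert ann.has_lacdinac and ann.has_lewis

    def test_composition_only_fallback_flags_lower_confidence(self):
        ann = annotate_composition(parse_composition("N2H5"))
        assert ann.subtype == "oligo-mannose"
        assert ann.confidence == "composition-only"
        assert annotate_composition(parse_composition("N4H5F1")).subtype == "complex"


class TestTaxonomy:
    def test_default_cardinalities(self, taxonomy):
        assert len(taxonomy) == 17
        assert len(taxonomy.sialylated_branch_types()) == 8
        lacdinac = [e for e in taxonomy if e.code.startswith("N2")]
        assert {e.code for e in lacdinac} == {"N2", "N2S", "N2G", "N2F"}
        # every LacdiNAc template has the GalNAc-GlcNAc (N-N) backbone
        for e in lacdinac:
            assert e.template.root.symbol == "N"
            assert any(c.symbol == "N" for c in e.template.root.children)

    def test_duplicate_codes_rejected(self, taxonomy):
        entries = taxonomy.entries + [taxonomy.entries[0]]
        with pytest.raises(ValueError):
            BranchTaxonomy(entries)

    def test_user_taxonomy_round_trip(self, taxonomy, tmp_path):
        path = tmp_path / "tax.tsv"
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "code": e.code,
                    "template": e.template.id,
                    "sialyl_category": e.sialyl_category,
                    "sialic_type": e.sialic_type,
                }
                for e in taxonomy
            ]
        ).to_csv(path, sep="\t", index=False)
        reloaded = BranchTaxonomy.from_tsv(path)
        assert {e.code for e in reloaded} == {e.code for e in taxonomy}


class TestOracleEquivalence:
    """Classifiers agree with brute-force traversal/permutation matching."""

    def test_partition_labels(self, library, random_structures):
        seen_sub, seen_core = set(), set()
        for g in library + random_structures:
            s, c = classify_subtype(g), classify_core(g)
            assert s in SUBTYPES and c in CORE_CLASSES
            seen_sub.add(s)
            seen_core.add(c)
        assert seen_sub == set(SUBTYPES)
        assert seen_core == set(CORE_CLASSES)

    def test_against_brute_force(self, taxonomy, library, random_structures):
        for g in library + random_structures:
            assert classify_subtype(g) == _brute.brute_subtype(g)
            assert classify_core(g) == _brute.brute_core(g)
            assert count_antennae(g) == _brute.brute_count_antennae(g)
            assert decompose_branches(g, taxonomy) == _brute.brute_decompose(
                g, taxonomy
            )

    def test_composition_conservation(self, library, random_structures):
        for g in library + random_structures:
            counts = {}
            for node in g.root.walk():
                counts[node.symbol] = counts.get(node.symbol, 0) + 1
            assert {s: counts.get(s, 0) for s in "NHFSG"} == dict(
                g.composition().counts
            )
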