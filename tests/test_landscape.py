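"""Feature proportions, changed fractions, rankings and phosphosite mix."""

import numpy as np
import pytest

from glycoscape.igp import AnnotationTable, CHANNELS_10PLEX, IgpRecord, PhosphoRecord
from glycoscape.landscape import (
    changed_fraction_by_feature,
    feature_proportions,
    phosphosite_distribution,
    protein_fucosylation_classes,
    protein_sialic_classes,
    rank_glycans_by_sites,
)

MAN5 = "N(N(H(H)(H(H(H)))))"
BI_COMPLEX = "N(N(H(H(N(H)))(H(N(H)))))"  # N4H5, two NH antennae
BI_COREFUC = "N(F)(N(H(H(N(H)))(H(N(H)))))"
HYBRID = "N(N(H(H(H))(H(N(H)))))"
SIAL_AC = "N(N(H(H(N(H(S))))(H(N(H)))))"
SIAL_GC = "N(N(H(H(N(H(G))))(H(N(H)))))"
LACDINAC = "N(N(H(H(N(N)))(H(N(H)))))"


def _igp(protein, site, structure, psm="x"):
    from glycoscape.glycans import parse_structure

    comp = str(parse_structure(structure).composition())
    return IgpRecord(
        protein_id=protein, glycosite=site, peptide="KNATK",
        glycan_composition=comp, glycan_structure=structure,
        psm_id=f"{protein}-{site}-{psm}",
        channel_intensities={c: 1.0 for c in CHANNELS_10PLEX},
    )


class TestProportions:
    def test_four_igp_subtype_fractions(self, taxonomy):
        records = [
            _igp("P1", 10, BI_COMPLEX),
            _igp("P1", 20, BI_COREFUC),
            _igp("P2", 10, HYBRID),
            _igp("P3", 10, MAN5),
        ]
        table = feature_proportions(records, "subtype", taxonomy=taxonomy)
        assert table.proportions("all") == {
            "complex": 0.5, "hybrid": 0.25, "oligo-mannose": 0.25,
        }
        assert table.denominators["all"] == {"unique_igps": 4, "glycoproteins": 3}

    def test_single_igp_group_is_one(self, taxonomy):
        table = feature_proportions([_igp("P1", 10, MAN5)], "subtype",
                                    taxonomy=taxonomy)
        assert table.proportions("all") == {"oligo-mannose": 1.0}
        assert "all" in table.small_groups  # below default min size

    def test_partition_axes_sum_to_one(self, taxonomy, default_study_dir):
        from glycoscape.igp import load_igp_table

        records = load_igp_table(default_study_dir["igp"]).records
        for axis in ("subtype", "core", "fucosylation", "sialylation",
                     "antenna_count"):
            table = feature_proportions(records, axis, taxonomy=taxonomy)
            assert sum(table.proportions("all").values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_category_grouping_mirrors_egg_coat_pattern(self, taxonomy):
        # one category whose IGPs are all core-fucosylated
        records = [
            _igp("ZP2", 10, BI_COREFUC),
            _igp("ZP3", 10, BI_COREFUC),
            _igp("ZP3", 30, LACDINAC),
            _igp("Q1", 10, BI_COMPLEX),
            _igp("Q2", 10, MAN5),
        ]
        annotations = AnnotationTable(
            {"ZP2": {"egg coat"}, "ZP3": {"egg coat"},
             "Q1": {"lysosome"}, "Q2": {"lysosome"}}
        )
        table = feature_proportions(
            records, "core", annotations=annotations, group_by="category",
            taxonomy=taxonomy, min_group_size=1,
        )
        egg = table.proportions("egg coat")
        assert egg.get("core-fucosylated", 0.0) == pytest.approx(2 / 3)
        lys = table.proportions("lysosome")
        assert lys.get("core-fucosylated", 0.0) == 0.0

    def test_brute_force_counter_agreement(self, taxonomy):
        # nested-loop recount of the subtype proportions
        records = [
            _igp("P1", 10, BI_COMPLEX), _igp("P1", 20, MAN5),
            _igp("P2", 10, HYBRID), _igp("P2", 20, SIAL_AC),
            _igp("P3", 10, LACDINAC),
        ]
        from glycoscape.glycans import classify_subtype, parse_structure

        table = feature_proportions(records, "subtype", taxonomy=taxonomy)
        keys = {r.key: r.glycan_structure for r in records}
        for value, prop in table.proportions("all").items():
            manual = sum(
                1 for s in keys.values()
                if classify_subtype(parse_structure(s)) == value
            )
            assert prop == pytest.approx(manual / len(keys))

    def test_unknown_axis_raises(self, taxonomy):
        with pytest.raises(ValueError, match="axis"):
            feature_proportions([_igp("P1", 10, MAN5)], "colour",
                                taxonomy=taxonomy)


class TestChangedFractions:
    def _records_sites(self, n, structure):
        return [_igp("P1", 10 * (i + 1), structure) for i in range(n)]

    def test_four_of_ten_lacdinac_sites_changed(self, taxonomy):
        records = self._records_sites(10, LACDINAC)
        calls = {
            str(records[i].key): ("up" if i < 2 else "down") if i < 4
            else "unchanged"
            for i in range(10)
        }
        table = changed_fraction_by_feature(calls, records, "branch",
                                            taxonomy=taxonomy)
        assert table.fraction("N2") == pytest.approx(0.4)
        row = table.frame.set_index("feature").loc["N2"]
        assert row["up"] == 2 and row["down"] == 2 and row["total"] == 10

    def test_no_changes_all_zero(self, taxonomy):
        records = self._records_sites(5, BI_COMPLEX)
        table = changed_fraction_by_feature({}, records, "subtype",
                                            taxonomy=taxonomy)
        assert (table.frame["fraction"] == 0.0).all()

    def test_all_changed_all_one(self, taxonomy):
        records = self._records_sites(5, BI_COMPLEX)
        calls = {str(r.key): "up" for r in records}
        table = changed_fraction_by_feature(calls, records, "subtype",
                                            taxonomy=taxonomy)
        assert (table.frame["fraction"] == 1.0).all()

    def test_changed_never_exceeds_total(self, taxonomy, default_study_dir):
        from glycoscape.igp import load_igp_table

        records = load_igp_table(default_study_dir["igp"]).records
        rng = np.random.default_rng(5)
        keys = list({str(r.key) for r in records})
        calls = {k: str(rng.choice(["up", "down", "unchanged"])) for k in keys}
        for axis in ("subtype", "core", "branch", "fucosylation"):
            table = changed_fraction_by_feature(calls, records, axis,
                                                taxonomy=taxonomy)
            assert (table.frame["changed"] <= table.frame["total"]).all()
            assert np.allclose(
                table.frame["fraction"],
                table.frame["changed"] / table.frame["total"],
            )


class TestRanking:
    def test_rank_by_distinct_sites(self, taxonomy):
        records = (
            [_igp("P1", s, BI_COMPLEX) for s in (10, 20, 30)]
            + [_igp("P2", s, SIAL_AC) for s in (10, 20)]
            + [_igp("P3", 10, LACDINAC)]
        )
        ranked = rank_glycans_by_sites(records, taxonomy=taxonomy)
        assert ranked["glycan"].tolist() == [BI_COMPLEX, SIAL_AC, LACDINAC]
        assert ranked["n_sites"].tolist() == [3, 2, 1]

    def test_permutation_invariance_and_tie_break(self, taxonomy):
        records = [_igp("P1", 10, SIAL_GC), _igp("P2", 10, SIAL_AC)]
        fwd = rank_glycans_by_sites(records, taxonomy=taxonomy)
        rev = rank_glycans_by_sites(records[::-1], taxonomy=taxonomy)
        assert fwd.equals(rev)
        # tie broken by canonical glycan string
        assert fwd["glycan"].tolist() == sorted([SIAL_AC, SIAL_GC])

    def test_n_larger_than_distinct_returns_all(self, taxonomy):
        records = [_igp("P1", 10, MAN5)]
        assert len(rank_glycans_by_sites(records, n=99, taxonomy=taxonomy)) == 1

    def test_exclude_oligomannose_on_man5_only(self, taxonomy):
        records = [_igp("P1", 10, MAN5), _igp("P2", 20, MAN5)]
        ranked = rank_glycans_by_sites(records, exclude_oligomannose=True,
                                       taxonomy=taxonomy)
        assert ranked.empty

    def test_restrict_to_changed_subset(self, taxonomy):
        records = [_igp("P1", 10, BI_COMPLEX), _igp("P2", 10, SIAL_AC)]
        changed = {str(records[1].key)}
        ranked = rank_glycans_by_sites(records, restrict_keys=changed,
                                       taxonomy=taxonomy)
        assert ranked["glycan"].tolist() == [SIAL_AC]


class TestPhosphosites:
    def _phos(self, pid, site, residue):
        return PhosphoRecord(pid, site, residue,
                             {c: 1.0 for c in CHANNELS_10PLEX})

    def test_fractions_match_constructed_mix(self):
        records = (
            [self._phos("P1", i, "S") for i in range(867)]
            + [self._phos("P2", i, "T") for i in range(110)]
            + [self._phos("P3", i, "Y") for i in range(23)]
        )
        dist = phosphosite_distribution(records)
        assert dist == pytest.approx({"S": 0.867, "T": 0.110, "Y": 0.023})
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_all_serine(self):
        dist = phosphosite_distribution([self._phos("P1", 1, "S")])
        assert dist == {"S": 1.0, "T": 0.0, "Y": 0.0}

    def test_one_each_thirds(self):
        records = [self._phos("P1", 1, "S"), self._phos("P1", 2, "T"),
                   self._phos("P1", 3, "Y")]
        dist = phosphosite_distribution(records)
        assert dist["S"] == pytest.approx(1 / 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            phosphosite_distribution([])


class TestProteinClasses:
    def test_fucosylation_classes(self, taxonomy):
        dual_structure = "N(F)(N(H(H(N(F)(H)))(H(N(H)))))"
        records = [
            _igp("A", 10, BI_COREFUC),   # core only
            _igp("B", 10, dual_structure),  # both on one glycan
            _igp("C", 10, BI_COREFUC),
            _igp("C", 20, "N(N(H(H(N(F)(H)))(H(N(H)))))"),  # antenna only
            _igp("D", 10, BI_COMPLEX),
        ]
        classes = protein_fucosylation_classes(records, taxonomy)
        assert classes == {"A": "core-only", "B": "dual", "C": "dual",
                           "D": "none"}

    def test_sialic_classes(self, taxonomy):
        records = [
            _igp("A", 10, SIAL_AC),
            _igp("B", 10, SIAL_GC),
            _igp("C", 10, SIAL_AC), _igp("C", 20, SIAL_GC),
            _igp("D", 10, MAN5),
        ]
        classes = protein_sialic_classes(records, taxonomy)
        assert classes == {"A": "Neu5Ac-only", "B": "Neu5Gc-only",
                           "C": "dual", "D": "none"}
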