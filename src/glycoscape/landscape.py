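"""Landscape statistics over annotated site-specific glycans.

Proportion tables answer "what fraction of unique glycopeptides in this
group carry feature X" (overall or per annotation category); changed-
fraction tables answer "of all glycosites carrying feature X, how many
changed with age"; rankings order glycans by the number of glycosites they
occupy.  Two denominators are used deliberately and reported explicitly:
proportion tables count unique IGPs, changed-fraction tables count modified
glycosites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .glycans import (
    BranchTaxonomy,
    FeatureAnnotation,
    annotate_composition,
    annotate_features,
    default_taxonomy,
    parse_composition,
    parse_structure,
)
from .igp import IgpRecord, PhosphoRecord, AnnotationTable, UniqueIgpKey

__all__ = [
    "PROPORTION_AXES",
    "PARTITION_AXES",
    "ProportionTable",
    "ChangedFractionTable",
    "annotate_records",
    "feature_proportions",
    "changed_fraction_by_feature",
    "rank_glycans_by_sites",
    "phosphosite_distribution",
    "protein_fucosylation_classes",
    "protein_sialic_classes",
]

#: Axes for which per-IGP feature values partition the set (proportions sum
#: to 1); the branch axis is multiset-valued and exempt.
PARTITION_AXES = ("subtype", "core", "fucosylation", "sialylation", "antenna_count")
PROPORTION_AXES = PARTITION_AXES + ("branch",)


def annotate_records(
    records: Iterable[IgpRecord],
    taxonomy: BranchTaxonomy | None = None,
) -> dict[UniqueIgpKey, FeatureAnnotation]:
    """Annotate every unique IGP; glycans are annotated once per distinct
    structure string (composition-only records fall back to heuristics)."""
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
    cache: dict[str, FeatureAnnotation] = {}
    out: dict[UniqueIgpKey, FeatureAnnotation] = {}
    for rec in records:
        key = rec.key
        if key in out:
            continue
        gstr = key.glycan
        if gstr not in cache:
            if rec.glycan_structure and rec.glycan_structure != "unknown":
                cache[gstr] = annotate_features(parse_structure(gstr), taxonomy)
            else:
                cache[gstr] = annotate_composition(parse_composition(gstr))
        out[key] = cache[gstr]
    return out


def _feature_values(ann: FeatureAnnotation, axis: str) -> set[str]:
    if axis == "subtype":
        return {ann.subtype}
    if axis == "core":
        return {ann.core}
    if axis == "fucosylation":
        return {ann.fucosylation}
    if axis == "sialylation":
        return {ann.sialylation}
    if axis == "antenna_count":
        return {str(ann.antenna_count)}
    if axis == "branch":
        return set(ann.branches)
    raise ValueError(f"unknown feature axis {axis!r}")


# ---------------------------------------------------------------------------
# Proportion tables
# ---------------------------------------------------------------------------


@dataclass
class ProportionTable:
    """Per-group feature-value fractions over unique IGPs.

    ``frame`` is long-format (group, feature, n, proportion); denominators
    carry the unique-IGP and glycoprotein counts behind each group.
    """

    axis: str
    frame: pd.DataFrame
    denominators: dict[str, dict[str, int]]
    small_groups: list[str] = field(default_factory=list)

    def proportions(self, group: str = "all") -> dict[str, float]:
        sub = self.frame[self.frame["group"] == group]
        return dict(zip(sub["feature"], sub["proportion"]))


def feature_proportions(
    records: Iterable[IgpRecord],
    axis: str,
    annotations: AnnotationTable | None = None,
    group_by: str = "all",
    taxonomy: BranchTaxonomy | None = None,
    min_group_size: int = 3,
) -> ProportionTable:
    """Fraction of unique IGPs carrying each value of ``axis``.

    ``group_by='all'`` yields one overall group; ``group_by='category'``
    yields one group per annotation category, an IGP counting in every
    category its protein is annotated with (GO semantics, many-to-many).
    Groups with fewer unique IGPs than ``min_group_size`` are kept but
    flagged.
    """
    if axis not in PROPORTION_AXES:
        raise ValueError(f"unknown feature axis {axis!r}")
    ann_by_key = annotate_records(records, taxonomy)
    if group_by == "all":
        groups: dict[str, list[UniqueIgpKey]] = {"all": list(ann_by_key)}
    elif group_by == "category":
        if annotations is None:
            raise ValueError("group_by='category' requires an annotation table")
        groups = {}
        for key in ann_by_key:
            for cat in annotations.categories(key.protein_id):
                groups.setdefault(cat, []).append(key)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    denominators: dict[str, dict[str, int]] = {}
    small: list[str] = []
    for group in sorted(groups):
        keys = groups[group]
        n_igps = len(keys)
        denominators[group] = {
            "unique_igps": n_igps,
            "glycoproteins": len({k.protein_id for k in keys}),
        }
        if n_igps < min_group_size:
            small.append(group)
        counts: dict[str, int] = {}
        for key in keys:
            for value in _feature_values(ann_by_key[key], axis):
                counts[value] = counts.get(value, 0) + 1
        for value in sorted(counts):
            rows.append(
                {
                    "group": group,
                    "feature": value,
                    "n": counts[value],
                    "proportion": counts[value] / n_igps,
                }
            )
    frame = pd.DataFrame(rows, columns=["group", "feature", "n", "proportion"])
    return ProportionTable(axis=axis, frame=frame, denominators=denominators,
                           small_groups=small)


# ---------------------------------------------------------------------------
# Changed fractions
# ---------------------------------------------------------------------------


@dataclass
class ChangedFractionTable:
    """Changed / total counts per feature value, over modified glycosites."""

    axis: str
    frame: pd.DataFrame  # feature, total, changed, up, down, fraction
    notes: list[str] = field(default_factory=list)

    def fraction(self, feature: str) -> float:
        sub = self.frame[self.frame["feature"] == feature]
        return float(sub["fraction"].iloc[0]) if len(sub) else 0.0


def changed_fraction_by_feature(
    calls: Mapping[str, str],
    records: Iterable[IgpRecord],
    axis: str,
    taxonomy: BranchTaxonomy | None = None,
    denominator: str = "glycosites",
) -> ChangedFractionTable:
    """Per feature value: fraction of entries carrying it that changed.

    ``calls`` maps unique-IGP key strings to up/down/unchanged (as produced
    by the differential model).  With ``denominator='glycosites'`` the unit
    is the (protein, glycosite) pair; with ``'igps'`` it is the unique IGP.
    """
    if axis not in PROPORTION_AXES:
        raise ValueError(f"unknown feature axis {axis!r}")
    if denominator not in ("glycosites", "igps"):
        raise ValueError(f"unknown denominator {denominator!r}")
    ann_by_key = annotate_records(records, taxonomy)

    def unit(key: UniqueIgpKey):
        if denominator == "glycosites":
            return (key.protein_id, key.glycosite)
        return key

    total: dict[str, set] = {}
    up: dict[str, set] = {}
    down: dict[str, set] = {}
    for key, ann in ann_by_key.items():
        call = calls.get(str(key), "unchanged")
        for value in _feature_values(ann, axis):
            total.setdefault(value, set()).add(unit(key))
            if call == "up":
                up.setdefault(value, set()).add(unit(key))
            elif call == "down":
                down.setdefault(value, set()).add(unit(key))

    rows, notes = [], []
    for value in sorted(total):
        n_total = len(total[value])
        if n_total == 0:  # pragma: no cover - sets are never empty here
            notes.append(f"feature {value!r} has zero denominator; omitted")
            continue
        n_up, n_down = len(up.get(value, ())), len(down.get(value, ()))
        n_changed = len(up.get(value, set()) | down.get(value, set()))
        rows.append(
            {
                "feature": value,
                "total": n_total,
                "changed": n_changed,
                "up": n_up,
                "down": n_down,
                "fraction": n_changed / n_total,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["feature", "total", "changed", "up", "down", "fraction"]
    )
    return ChangedFractionTable(axis=axis, frame=frame, notes=notes)


# ---------------------------------------------------------------------------
# Rankings and phosphosites
# ---------------------------------------------------------------------------


def rank_glycans_by_sites(
    records: Iterable[IgpRecord],
    n: int | None = 10,
    exclude_oligomannose: bool = False,
    restrict_keys: set[str] | None = None,
    taxonomy: BranchTaxonomy | None = None,
) -> pd.DataFrame:
    """Rank glycans by the number of distinct glycosites carrying them.

    Ties break on the canonical glycan string; ``restrict_keys`` (key
    strings) limits the count to e.g. the changed subset.  Output columns:
    glycan, composition, n_sites.
    """
    ann_by_key = annotate_records(records, taxonomy)
    comp_by_glycan: dict[str, str] = {}
    sites: dict[str, set] = {}
    for rec in records:
        key = rec.key
        if restrict_keys is not None and str(key) not in restrict_keys:
            continue
        if exclude_oligomannose and ann_by_key[key].subtype == "oligo-mannose":
            continue
        sites.setdefault(key.glycan, set()).add((key.protein_id, key.glycosite))
        comp_by_glycan.setdefault(key.glycan, rec.glycan_composition)
    ranked = sorted(sites.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if n is not None:
        ranked = ranked[:n]
    return pd.DataFrame(
        [
            {"glycan": g, "composition": comp_by_glycan[g], "n_sites": len(s)}
            for g, s in ranked
        ],
        columns=["glycan", "composition", "n_sites"],
    )


def phosphosite_distribution(records: Iterable[PhosphoRecord]) -> dict[str, float]:
    """pS / pT / pY fractions over unique phosphosites (sum to 1)."""
    sites = {(r.protein_id, r.site, r.residue) for r in records}
    if not sites:
        raise ValueError("no phosphosites to summarise")
    counts = {"S": 0, "T": 0, "Y": 0}
    for _, _, residue in sites:
        counts[residue] += 1
    n = len(sites)
    return {res: counts[res] / n for res in ("S", "T", "Y")}


# ---------------------------------------------------------------------------
# Glycoprotein-level "solely modified" classes
# ---------------------------------------------------------------------------


def _protein_classes(
    records: Iterable[IgpRecord],
    taxonomy: BranchTaxonomy | None,
    feature: Callable[[FeatureAnnotation], set[str]],
    labels: tuple[str, str],
) -> dict[str, str]:
    ann_by_key = annotate_records(records, taxonomy)
    seen: dict[str, set[str]] = {}
    for key, ann in ann_by_key.items():
        seen.setdefault(key.protein_id, set()).update(feature(ann))
    first, second = labels
    out: dict[str, str] = {}
    for pid, kinds in seen.items():
        has_first, has_second = first in kinds, second in kinds
        if has_first and has_second:
            out[pid] = "dual"
        elif has_first:
            out[pid] = f"{first}-only"
        elif has_second:
            out[pid] = f"{second}-only"
        else:
            out[pid] = "none"
    return out


def protein_fucosylation_classes(
    records: Iterable[IgpRecord], taxonomy: BranchTaxonomy | None = None
) -> dict[str, str]:
    """Classify glycoproteins as solely core-fucosylated (``core-only``),
    solely antenna-fucosylated (``antenna-only``), ``dual`` or ``none`` by
    aggregating all their glycan annotations."""

    def fuc(ann: FeatureAnnotation) -> set[str]:
        out = set()
        if ann.fucosylation in ("core-only", "both"):
            out.add("core")
        if ann.fucosylation in ("antenna-only", "both"):
            out.add("antenna")
        return out

    return _protein_classes(records, taxonomy, fuc, ("core", "antenna"))


def protein_sialic_classes(
    records: Iterable[IgpRecord], taxonomy: BranchTaxonomy | None = None
) -> dict[str, str]:
    """Classify glycoproteins as solely Neu5Ac-, solely Neu5Gc-modified,
    ``dual`` or ``none`` by aggregating all their glycan annotations."""

    def sial(ann: FeatureAnnotation) -> set[str]:
        out = set()
        if ann.sialylation in ("Neu5Ac-only", "both"):
            out.add("Neu5Ac")
        if ann.sialylation in ("Neu5Gc-only", "both"):
            out.add("Neu5Gc")
        return out

    return _protein_classes(records, taxonomy, sial, ("Neu5Ac", "Neu5Gc"))
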