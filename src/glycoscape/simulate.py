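"""Synthetic glycoproteomic studies with planted ground truth.

The generator emulates the *post-search* tables of a 10-plex TMT
glycoproteomic experiment on two pooled groups (5 young vs 5 aged
channels): an intact-glycopeptide PSM table, a global-proteome table, a
phosphopeptide table, the protein FASTA (with valid N-X-S/T sequons at
every declared glycosite) and an annotation table — plus a ground-truth
table recording, for every unique IGP, whether and at which level (protein
expression vs glycosylation) an aging effect was planted.

Intensity model: for channel ``c`` of an IGP with base abundance ``B``,

    I_c = B x loading_c x fold(group_c) x 2^eps,   eps ~ N(0, sigma)

where ``loading_c`` is a per-channel sample-loading factor shared by all
three sub-proteomes (so proteome-derived global scaling can remove it),
``fold`` is the planted aged/young effect, and ``sigma = log2(1 + CV)``
models multiplicative reporter noise.  Pooling of animals into channels is
represented only through the (small) channel CV.  A small
missing-at-random dropout sets intensities to zero to exercise imputation.

Default effects plant the study's three headline alteration classes:
elevated sialylation, reduced LacdiNAc, and bidirectional core-fucosylation
changes, plus protein-expression-level changes on a subset of proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .glycans import (
    BranchTaxonomy,
    FeatureAnnotation,
    GlycanNode,
    GlycanStructure,
    SUBTYPES,
    annotate_features,
    default_taxonomy,
)
from .igp import CHANNELS_10PLEX, DEFAULT_GROUP_MAP

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "build_glycan_library",
    "simulate_study",
]

_AA = "ACDEFGHIKLMQRVWY"  # residues used as sequence filler (no N/P/S/T)
_CATEGORIES = (
    "egg coat",
    "endoplasmic reticulum",
    "Golgi apparatus",
    "lysosome",
    "cell surface",
    "extracellular matrix",
    "cytoskeleton",
    "ion channel complex",
)


# ---------------------------------------------------------------------------
# Glycan library
# ---------------------------------------------------------------------------


def _node(symbol: str, *children: GlycanNode) -> GlycanNode:
    return GlycanNode(symbol, list(children))


def _assemble(
    arm1: Sequence[str] = (),
    arm2: Sequence[str] = (),
    arm1_hex: int = 0,
    arm2_hex: int = 0,
    core_fucose: bool = False,
    bisect: bool = False,
) -> GlycanStructure:
    """Build a glycan from the trimannosyl core.

    ``arm1``/``arm2`` are branch-template strings attached as antennae;
    ``arm*_hex`` adds chained mannoses to an arm (oligo-mannose / hybrid
    arms).
    """
    from .glycans import parse_structure

    def build_arm(branches: Sequence[str], n_hex: int) -> GlycanNode:
        arm = _node("H")
        for b in branches:
            arm.children.append(parse_structure(b).root)
        tip = arm
        for _ in range(n_hex):
            nxt = _node("H")
            tip.children.append(nxt)
            tip = nxt
        return arm

    central = _node("H", build_arm(arm1, arm1_hex), build_arm(arm2, arm2_hex))
    if bisect:
        central.children.append(_node("N"))
    root_children = [_node("N", central)]
    if core_fucose:
        root_children.append(_node("F"))
    return GlycanStructure(_node("N", *root_children))


def _oligomannose(n_hex: int) -> GlycanStructure:
    """Man(n_hex) structure, n_hex in 5..9 (Man5-Man9)."""
    if not 3 <= n_hex <= 9:
        raise ValueError("oligo-mannose needs 3-9 Hex")
    extra = n_hex - 3
    a2 = min(extra, 2)  # 6-arm carries up to two direct mannoses
    return _assemble(arm1_hex=extra - a2, arm2_hex=a2)


def build_glycan_library(
    taxonomy: BranchTaxonomy | None = None,
    subtypes: Sequence[str] = SUBTYPES,
) -> list[GlycanStructure]:
    """The default structure library spanning the full feature taxonomy.

    Covers all three subtypes, all four core classes, every branch code of
    the taxonomy, antenna counts 1-6, Man5-Man9 and the most prevalent
    ovarian bi-antennary sialylated compositions.  Every structure
    validates under the classifiers.  ``subtypes`` restricts the output;
    an unknown subtype raises.
    """
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
    unknown = set(subtypes) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unreachable subtype(s) requested: {sorted(unknown)}")
    t = {e.code: e.template.id for e in taxonomy}
    lib: list[GlycanStructure] = []

    # oligo-mannose series Man5-Man9
    lib += [_oligomannose(h) for h in range(5, 10)]

    # prevalent bi-antennary (top-composition) structures
    lib += [
        _assemble([t["NHG"]], [t["NHG"]], core_fucose=True),   # N4H5F1G2
        _assemble([t["NHG"]], [t["NHG"]]),                     # N4H5G2
        _assemble([t["NHG"]], [t["NH"]], core_fucose=True),    # N4H5F1G1
        _assemble([t["NHS"]], [t["NHG"]], core_fucose=True),   # N4H5F1S1G1
        _assemble([t["NHS"]], [t["NH"]]),                      # N4H5S1
        _assemble([t["NHG"]], [t["NH"]]),                      # N4H5G1
        _assemble([t["NHS"]], [t["NHS"]], core_fucose=True),   # N4H5F1S2
        _assemble([t["NH"]], [t["NH"]], core_fucose=True),     # N4H5F1
    ]

    # hybrids (one mannosidic arm, one antennary arm)
    lib += [
        _assemble([t["NHG"], t["N"]], arm2_hex=2, core_fucose=True),  # N4H6F1G1
        _assemble([t["NHS"], t["N"]], arm2_hex=2, core_fucose=True),  # N4H6F1S1
        _assemble([t["NH"]], arm2_hex=2),
        _assemble([t["N2"]], arm2_hex=1),
    ]

    # one bi-antennary structure per branch code (full code coverage)
    for code in sorted(t):
        lib.append(_assemble([t[code]], [t["NH"]]))

    # core-class coverage: bisected with/without core fucose
    lib += [
        _assemble([t["NH"]], [t["NH"]], bisect=True),
        _assemble([t["NHG"]], [t["NH"]], bisect=True, core_fucose=True),
        _assemble([t["N2"]], [t["NH"]], bisect=True, core_fucose=True),
    ]

    # antenna counts 1-6
    lib += [
        _assemble([t["NH"]]),
        _assemble([t["NH"], t["NHS"]], [t["NH"]]),                            # 3
        _assemble([t["NH"], t["NHS"]], [t["NH"], t["NHG"]]),                  # 4
        _assemble([t["NH"], t["NHS"], t["NHF"]], [t["NH"], t["NHG"]]),        # 5
        _assemble([t["NH"], t["NHS"], t["NHF"]], [t["NH"], t["NHG"], t["N2"]]),  # 6
    ]

    # LacdiNAc variants on core-fucosylated cores (zona-pellucida style)
    lib += [
        _assemble([t["N2"]], [t["NH"]], core_fucose=True),
        _assemble([t["N2S"]], [t["N2"]], core_fucose=True),
        _assemble([t["N2G"]], [t["NH"]], core_fucose=True),
        _assemble([t["N2F"]], [t["N2"]], core_fucose=True),
    ]

    # dual- and antenna-fucosylated structures
    lib += [
        _assemble([t["NHF"]], [t["NH"]], core_fucose=True),
        _assemble([t["NHFS"]], [t["NHG"]], core_fucose=True),
        _assemble([t["NHF"]], [t["NHF"]]),
    ]

    seen: set[str] = set()
    out: list[GlycanStructure] = []
    for g in lib:
        ann = annotate_features(g, taxonomy)  # validates classifiability
        if ann.subtype not in subtypes:
            continue
        if g.id not in seen:
            seen.add(g.id)
            out.append(g)
    return out


def random_structure(
    rng: np.random.Generator, taxonomy: BranchTaxonomy | None = None
) -> GlycanStructure:
    """Draw one random valid glycan structure (for property testing).

    Subtype, core decoration, antenna count (1-6) and branch identities are
    sampled uniformly-ish; oligo-mannose draws a random Man5-Man9 topology.
    """
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
    kind = rng.random()
    if kind < 0.25:  # oligo-mannose, random arm split
        extra = int(rng.integers(2, 7))  # Hex total 5..9
        a2 = int(rng.integers(0, extra + 1))
        return _assemble(arm1_hex=extra - a2, arm2_hex=a2)
    templates = [e.template.id for e in taxonomy]
    core_fucose = bool(rng.random() < 0.4)
    bisect = bool(rng.random() < 0.15)
    if kind < 0.45:  # hybrid: antennary arm + mannosidic arm
        n_ant = int(rng.integers(1, 4))
        arm1 = [templates[i] for i in rng.integers(0, len(templates), n_ant)]
        return _assemble(arm1, arm2_hex=int(rng.integers(1, 3)),
                         core_fucose=core_fucose, bisect=bisect)
    n_ant = int(rng.integers(1, 7))
    picks = [templates[i] for i in rng.integers(0, len(templates), n_ant)]
    split = int(rng.integers(0, n_ant + 1))
    arm1, arm2 = picks[:split], picks[split:]
    # keep <=3 antennae per arm so the topology stays biosynthetically sane
    while len(arm1) > 3:
        arm2.append(arm1.pop())
    while len(arm2) > 3:
        arm1.append(arm2.pop())
    return _assemble(arm1, arm2, core_fucose=core_fucose, bisect=bisect)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect class.

    ``selector`` picks the targets: a feature-class name (``sialylated``,
    ``lacdinac``, ``core-fucosylated``, ``antenna-fucosylated``,
    ``oligo-mannose``, ``all``) for glycosylation-level effects, or
    ``protein-random`` for protein-expression-level effects.  ``fraction``
    subsamples the matching targets (used to split a class into opposite
    directions); ``fold`` is the aged/young ratio (>1 up, <1 down).
    """

    selector: str
    level: str  # "protein" | "glycosylation"
    fold: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.level not in ("protein", "glycosylation"):
            raise ValueError(f"unknown effect level {self.level!r}")


DEFAULT_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec("protein-random", "protein", 2.0, fraction=0.10),
    EffectSpec("sialylated", "glycosylation", 2.0),
    EffectSpec("lacdinac", "glycosylation", 0.5),
    EffectSpec("core-fucosylated", "glycosylation", 1.8, fraction=0.5),
    EffectSpec("core-fucosylated", "glycosylation", 0.55, fraction=1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults follow the emulated design: 10-plex TMT with 5 young + 5 aged
    pooled channels, glycoproteins carrying up to 33 sites with a geometric
    site/glycoform distribution, log-normal base abundances, 10 % reporter
    CV (pooled channels), 2 % missing-at-random dropout.
    """

    seed: int = 42
    n_proteins: int = 200
    frac_glycoproteins: float = 0.7
    sites_geometric_p: float = 0.6
    max_sites: int = 33
    glycans_geometric_p: float = 0.55
    max_glycans_per_site: int = 8
    psm_poisson_rate: float = 1.2
    n_phosphosites: int = 300
    phospho_residue_probs: tuple[float, float, float] = (0.867, 0.110, 0.023)
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    channel_cv: float = 0.10
    loading_log2_sd: float = 0.25
    dropout: float = 0.02
    frac_fail_id: float = 0.06  # PSMs planted to fail identification filters
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.channel_cv <= 0:
            raise ValueError("channel_cv must be positive")


@dataclass
class GroundTruth:
    """Planted truth: one row per unique IGP and one per protein."""

    igps: pd.DataFrame  # key, protein_id, true_source, true_total_fold, true_glyco_fold
    proteins: pd.DataFrame  # protein_id, true_fold

    def truly_changed_keys(self) -> set[str]:
        mask = self.igps["true_source"] != "null"
        return set(self.igps.loc[mask, "key"])


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    igp_table: pd.DataFrame
    protein_table: pd.DataFrame
    phospho_table: pd.DataFrame
    sequences: dict[str, str]
    annotations: pd.DataFrame  # protein_id, category
    ground_truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write the study as plain-text files (TSV + FASTA)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "igp": out / "igp.tsv",
            "proteins": out / "proteins.tsv",
            "phospho": out / "phospho.tsv",
            "fasta": out / "proteins.fasta",
            "annotations": out / "annotations.tsv",
            "ground_truth_igps": out / "ground_truth_igps.tsv",
            "ground_truth_proteins": out / "ground_truth_proteins.tsv",
        }
        kw = dict(sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        self.igp_table.to_csv(paths["igp"], **kw)
        self.protein_table.to_csv(paths["proteins"], **kw)
        self.phospho_table.to_csv(paths["phospho"], **kw)
        self.annotations.to_csv(paths["annotations"], **kw)
        self.ground_truth.igps.to_csv(paths["ground_truth_igps"], **kw)
        self.ground_truth.proteins.to_csv(paths["ground_truth_proteins"], **kw)
        records = [
            SeqRecord(Seq(self.sequences[pid]), id=pid, description="synthetic")
            for pid in sorted(self.sequences)
        ]
        SeqIO.write(records, str(paths["fasta"]), "fasta")
        return paths


# ---------------------------------------------------------------------------
# Effect selectors
# ---------------------------------------------------------------------------


def _matches(ann: FeatureAnnotation, selector: str) -> bool:
    if selector == "all":
        return True
    if selector == "sialylated":
        return ann.sialylation != "none"
    if selector == "lacdinac":
        return ann.has_lacdinac
    if selector == "core-fucosylated":
        return ann.core in ("core-fucosylated", "bisected-core-fucosylated")
    if selector == "antenna-fucosylated":
        return ann.fucosylation in ("antenna-only", "both")
    if selector == "oligo-mannose":
        return ann.subtype == "oligo-mannose"
    raise ValueError(f"unknown effect selector {selector!r}")


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------


def _truncated_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    return int(min(rng.geometric(p), cap))


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate one complete synthetic study (deterministic per seed)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    taxonomy = default_taxonomy()
    library = build_glycan_library(taxonomy)
    annotations = {g.id: annotate_features(g, taxonomy) for g in library}
    sigma = float(np.log2(1.0 + cfg.channel_cv))
    channels = list(CHANNELS_10PLEX)
    group = np.array([DEFAULT_GROUP_MAP[c] for c in channels])
    aged = group == "aged"

    # shared per-channel sample-loading factors
    loading = np.exp2(rng.normal(0.0, cfg.loading_log2_sd, size=len(channels)))

    protein_ids = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    n_glyco = int(round(cfg.frac_glycoproteins * cfg.n_proteins))
    glyco_ids = list(rng.choice(protein_ids, size=n_glyco, replace=False))
    glyco_ids.sort()

    # --- plan glycosites and glycoforms -----------------------------------
    igp_plan: list[dict] = []  # one entry per unique IGP
    site_plan: dict[str, list[int]] = {}
    for pid in glyco_ids:
        n_sites = _truncated_geometric(rng, cfg.sites_geometric_p, cfg.max_sites)
        positions = [20 + 10 * i for i in range(n_sites)]
        site_plan[pid] = positions
        for pos in positions:
            n_glycans = _truncated_geometric(
                rng, cfg.glycans_geometric_p, cfg.max_glycans_per_site
            )
            picks = rng.choice(len(library), size=min(n_glycans, len(library)),
                               replace=False)
            for gi in sorted(picks):
                g = library[gi]
                igp_plan.append(
                    {"protein_id": pid, "glycosite": pos, "glycan": g,
                     "ann": annotations[g.id]}
                )

    # --- plant effects ----------------------------------------------------
    protein_fold = {pid: 1.0 for pid in protein_ids}
    protein_effect_ids: set[str] = set()
    for eff in cfg.effects:
        if eff.level != "protein":
            continue
        if eff.selector != "protein-random":
            raise ValueError(
                f"protein-level effects use selector 'protein-random', "
                f"got {eff.selector!r}"
            )
        candidates = [p for p in glyco_ids if p not in protein_effect_ids]
        n_pick = int(round(eff.fraction * len(candidates)))
        picked = rng.choice(candidates, size=n_pick, replace=False)
        for pid in picked:
            protein_fold[pid] = eff.fold
            protein_effect_ids.add(pid)

    glyco_fold = np.ones(len(igp_plan))
    assigned = np.zeros(len(igp_plan), dtype=bool)
    for eff in cfg.effects:
        if eff.level != "glycosylation":
            continue
        for i, entry in enumerate(igp_plan):
            if assigned[i] or entry["protein_id"] in protein_effect_ids:
                continue
            if _matches(entry["ann"], eff.selector):
                if eff.fraction >= 1.0 or rng.random() < eff.fraction:
                    glyco_fold[i] = eff.fold
                    assigned[i] = True

    # --- emit IGP PSM rows ------------------------------------------------
    igp_rows: list[dict] = []
    truth_rows: list[dict] = []
    psm_counter = 0
    for i, entry in enumerate(igp_plan):
        pid, pos, g = entry["protein_id"], entry["glycosite"], entry["glycan"]
        comp = str(g.composition())
        total_fold = protein_fold[pid] * glyco_fold[i]
        if pid in protein_effect_ids:
            source = "protein-level"
        elif glyco_fold[i] != 1.0:
            source = "glycosylation-level"
        else:
            source = "null"
        key = f"{pid}@{pos}:{g.id}"
        truth_rows.append(
            {
                "key": key,
                "protein_id": pid,
                "glycosite": pos,
                "glycan": g.id,
                "true_source": source,
                "true_total_fold": total_fold,
                "true_glyco_fold": glyco_fold[i],
                "protein_true_fold": protein_fold[pid],
            }
        )
        base = float(np.exp2(rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)))
        n_psm = 1 + int(rng.poisson(cfg.psm_poisson_rate))
        peptide = f"PEP{pid}N{pos}"
        for _ in range(n_psm):
            psm_counter += 1
            eps = rng.normal(0.0, sigma, size=len(channels))
            vals = base * loading * np.where(aged, total_fold, 1.0) * np.exp2(eps)
            drop = rng.random(len(channels)) < cfg.dropout
            vals = np.where(drop, 0.0, vals)
            fail = rng.random() < cfg.frac_fail_id
            mode = int(rng.integers(0, 3)) if fail else -1
            row = {
                "protein_id": pid,
                "glycosite": pos,
                "peptide": peptide,
                "glycan_composition": comp,
                "glycan_structure": g.id,
                "psm_id": f"PSM{psm_counter:06d}",
                "peptide_fdr": round(float(rng.uniform(0.05, 0.5)), 4)
                if mode == 0 else round(float(rng.uniform(0, 0.009)), 4),
                "glycan_fdr": round(float(rng.uniform(0.05, 0.5)), 4)
                if mode == 1 else round(float(rng.uniform(0, 0.009)), 4),
                "by_ion_count": int(rng.integers(1, 5))
                if mode == 2 else int(rng.integers(5, 30)),
                "oxonium_top10_count": int(rng.integers(2, 8)),
            }
            row.update({c: float(v) for c, v in zip(channels, vals)})
            igp_rows.append(row)

    igp_table = pd.DataFrame(igp_rows)

    # --- proteome table ---------------------------------------------------
    prot_rows = []
    for pid in protein_ids:
        base = float(np.exp2(rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)))
        eps = rng.normal(0.0, sigma, size=len(channels))
        vals = base * loading * np.where(aged, protein_fold[pid], 1.0) * np.exp2(eps)
        row = {"protein_id": pid, "fdr": round(float(rng.uniform(0, 0.009)), 4)}
        row.update({c: float(v) for c, v in zip(channels, vals)})
        prot_rows.append(row)
    protein_table = pd.DataFrame(prot_rows)

    # --- phosphopeptide table --------------------------------------------
    residues = np.array(["S", "T", "Y"])
    phos_rows = []
    seen_sites: set[tuple[str, int]] = set()
    while len(phos_rows) < cfg.n_phosphosites:
        pid = protein_ids[int(rng.integers(0, len(protein_ids)))]
        site = int(rng.integers(5, 400))
        if (pid, site) in seen_sites:
            continue
        seen_sites.add((pid, site))
        residue = str(rng.choice(residues, p=list(cfg.phospho_residue_probs)))
        base = float(np.exp2(rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)))
        eps = rng.normal(0.0, sigma, size=len(channels))
        vals = base * loading * np.where(aged, protein_fold[pid], 1.0) * np.exp2(eps)
        row = {"protein_id": pid, "site": site, "residue": residue,
               "fdr": round(float(rng.uniform(0, 0.009)), 4)}
        row.update({c: float(v) for c, v in zip(channels, vals)})
        phos_rows.append(row)
    phospho_table = pd.DataFrame(phos_rows)

    # --- FASTA with valid sequons at every declared glycosite -------------
    sequences: dict[str, str] = {}
    for pid in protein_ids:
        positions = site_plan.get(pid, [])
        length = max(60, (positions[-1] + 10) if positions else 60)
        seq = list(rng.choice(list(_AA), size=length))
        for pos in positions:  # 1-based Asn index
            seq[pos - 1] = "N"
            seq[pos] = str(rng.choice(list(_AA)))  # X, never proline
            seq[pos + 1] = "T" if rng.random() < 0.6 else "S"
        sequences[pid] = "".join(seq)

    # --- annotations ------------------------------------------------------
    ann_rows = []
    for pid in protein_ids:
        n_cat = 1 + int(rng.integers(0, 3))
        cats = rng.choice(len(_CATEGORIES), size=n_cat, replace=False)
        for c in sorted(cats):
            ann_rows.append({"protein_id": pid, "category": _CATEGORIES[c]})
    annotations_table = pd.DataFrame(ann_rows)

    truth = GroundTruth(
        igps=pd.DataFrame(truth_rows),
        proteins=pd.DataFrame(
            [{"protein_id": p, "true_fold": protein_fold[p]} for p in protein_ids]
        ),
    )
    return SimulatedStudy(
        config=cfg,
        igp_table=igp_table,
        protein_table=protein_table,
        phospho_table=phospho_table,
        sequences=sequences,
        annotations=annotations_table,
        ground_truth=truth,
    )
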