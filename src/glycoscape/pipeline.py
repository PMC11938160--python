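"""End-to-end pipeline: load/filter -> normalise -> test -> attribute ->
landscape, driven by one serialisable run configuration.

Every stage writes plain TSV/JSON into the output directory so any stage
can be inspected or re-run from its persisted inputs; the fully resolved
configuration is written alongside, making a run reproducible from the
output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from . import igp as igp_mod
from . import landscape as land_mod
from . import quant as quant_mod
from .glycans import default_taxonomy, BranchTaxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run."""

    igp: str
    proteins: str
    out_dir: str
    phospho: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    taxonomy: str | None = None  # TSV path; None = built-in table
    peptide_fdr_max: float = 0.01
    glycan_fdr_max: float = 0.01
    min_by_ions: int = 5
    min_oxonium: int = 2
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    log_scale: bool = True
    equal_var: bool = True
    bh: bool = False
    attribution_fc_gate: float = 1.5
    axes: list[str] = field(
        default_factory=lambda: ["subtype", "core", "branch", "fucosylation",
                                 "sialylation", "antenna_count"]
    )
    group_map: dict[str, str] = field(
        default_factory=lambda: dict(igp_mod.DEFAULT_GROUP_MAP)
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    igp_res = igp_mod.load_igp_table(cfg.igp)
    prot_res = igp_mod.load_protein_table(cfg.proteins)
    phos_res = igp_mod.load_phospho_table(cfg.phospho) if cfg.phospho else None
    records = igp_res.records
    if cfg.fasta:
        sequences = igp_mod.load_fasta(cfg.fasta)
        records = igp_mod.flag_non_sequon_records(records, sequences)
    annotations = (
        igp_mod.load_annotations(cfg.annotations) if cfg.annotations else None
    )
    return records, igp_res.diagnostics, prot_res, phos_res, annotations


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the JSON metrics summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "run_config.yaml")
    taxonomy: BranchTaxonomy = (
        BranchTaxonomy.from_tsv(cfg.taxonomy) if cfg.taxonomy else default_taxonomy()
    )
    summary: dict = {"parameters": asdict(cfg)}

    records, diagnostics, prot_res, phos_res, annotations = _load(cfg)
    summary["load"] = {
        "igp_psms": len(records),
        "igp_rejected": len(diagnostics),
        "proteins": len(prot_res.records),
        "phosphosites": len(phos_res.records) if phos_res else 0,
        "non_sequon_flagged": sum(
            1 for r in records if "non-sequon-site" in r.flags
        ),
    }

    # identification filters
    filt = igp_mod.apply_identification_filters(
        records,
        peptide_fdr_max=cfg.peptide_fdr_max,
        glycan_fdr_max=cfg.glycan_fdr_max,
        min_by_ions=cfg.min_by_ions,
        min_oxonium=cfg.min_oxonium,
    )
    summary["filters"] = filt.counts
    if not filt.glycan_level:
        raise PipelineError("stage 'filter' failed: no records pass the filters")

    # quantification: proteome factors drive cross-omic scaling
    prot_matrix = quant_mod.protein_matrix(prot_res.records, cfg.group_map)
    factors = quant_mod.scaling_factors(prot_matrix)
    prot_norm = quant_mod.normalize_within_set(prot_matrix)
    igp_matrix = quant_mod.aggregate_psms(filt.glycan_level, cfg.group_map)
    igp_norm = quant_mod.apply_global_scaling(igp_matrix, factors)

    model_kw = dict(
        fc_up=cfg.fc_up, fc_down=cfg.fc_down, alpha=cfg.alpha,
        log_scale=cfg.log_scale, equal_var=cfg.equal_var, bh=cfg.bh,
    )
    igp_diff = quant_mod.TwoGroupDifferentialModel(igp_norm, **model_kw).fit()
    prot_diff = quant_mod.TwoGroupDifferentialModel(prot_norm, **model_kw).fit()
    igp_diff.to_tsv(out / "diff_igps.tsv")
    prot_diff.to_tsv(out / "diff_proteins.tsv")
    summary["differential"] = {
        "igps": {"up": igp_diff.n_up, "down": igp_diff.n_down,
                 "tested": len(igp_diff.frame)},
        "proteins": {"up": prot_diff.n_up, "down": prot_diff.n_down,
                     "tested": len(prot_diff.frame)},
    }

    phos_diff = None
    if phos_res and phos_res.records:
        phos_matrix = quant_mod.phospho_matrix(phos_res.records, cfg.group_map)
        phos_norm = quant_mod.apply_global_scaling(phos_matrix, factors)
        phos_diff = quant_mod.TwoGroupDifferentialModel(phos_norm, **model_kw).fit()
        phos_diff.to_tsv(out / "diff_phospho.tsv")
        summary["differential"]["phospho"] = {
            "up": phos_diff.n_up, "down": phos_diff.n_down,
            "tested": len(phos_diff.frame),
        }

    # attribution
    attribution = attr_mod.AttributionModel(
        igp_diff, prot_diff, fc_gate=cfg.attribution_fc_gate, alpha=cfg.alpha
    ).fit()
    attribution.to_tsv(out / "attribution.tsv")
    summary["attribution"] = {
        "sources": attribution.source_counts(),
        "glycoproteins": attribution.glycoprotein_summary(),
    }

    # landscape statistics
    calls = dict(zip(igp_diff.frame.index.astype(str), igp_diff.frame["call"]))
    quantified_keys = set(calls)
    quantified = [r for r in filt.glycan_level if str(r.key) in quantified_keys]
    summary["landscape"] = {}
    for axis in cfg.axes:
        prop = land_mod.feature_proportions(quantified, axis, taxonomy=taxonomy)
        prop.frame.to_csv(out / f"proportions_{axis}.tsv", sep="\t", index=False)
        summary["landscape"][axis] = {
            "all": prop.proportions("all"),
            "denominators": prop.denominators["all"],
        }
        if annotations is not None:
            by_cat = land_mod.feature_proportions(
                quantified, axis, annotations=annotations, group_by="category",
                taxonomy=taxonomy,
            )
            by_cat.frame.to_csv(
                out / f"proportions_{axis}_by_category.tsv", sep="\t", index=False
            )
        cft = land_mod.changed_fraction_by_feature(
            calls, quantified, axis, taxonomy=taxonomy
        )
        cft.frame.to_csv(out / f"changed_fraction_{axis}.tsv", sep="\t", index=False)

    ranked = land_mod.rank_glycans_by_sites(quantified, n=10, taxonomy=taxonomy)
    ranked.to_csv(out / "top_glycans.tsv", sep="\t", index=False)
    changed_keys = {
        str(k) for k, c in calls.items() if c in ("up", "down")
    }
    ranked_changed = land_mod.rank_glycans_by_sites(
        quantified, n=10, restrict_keys=changed_keys,
        exclude_oligomannose=True, taxonomy=taxonomy,
    )
    ranked_changed.to_csv(out / "top_changed_glycans.tsv", sep="\t", index=False)
    summary["top_glycans"] = ranked["glycan"].tolist()

    if phos_res and phos_res.records:
        summary["phosphosite_distribution"] = land_mod.phosphosite_distribution(
            phos_res.records
        )

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
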