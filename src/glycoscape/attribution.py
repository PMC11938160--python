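"""Attribute differential glycopeptides to protein-expression vs
glycosylation-level change.

A changed intact glycopeptide can move because its carrier protein moved, or
because the site-specific glycosylation itself changed.  The *normalized
glycosylation* ratio — the glycopeptide fold change divided by its protein's
fold change — separates the two: when the protein itself is significantly
changed (|log2 FC| beyond the gate and p below alpha) the glycopeptide
change is attributed to the protein-expression level, otherwise to the
glycosylation level.  Glycopeptides whose protein was not quantified stay
``unattributed``.  The same machinery applies unchanged to
phosphopeptide-vs-protein comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import DifferentialResults

__all__ = ["AttributionModel", "AttributionResults", "protein_of_key"]

SOURCES = ("protein-level", "glycosylation-level", "unattributed")


def protein_of_key(key: str) -> str:
    """Protein accession of a feature key (``P123@45:N(...)`` -> ``P123``)."""
    return key.split("@", 1)[0]


class AttributionModel:
    """Attribute each differential feature to its change source.

    Parameters
    ----------
    feature_results
        Fitted differential results at the glycopeptide (or phosphopeptide)
        level; rows indexed by ``protein@site:glycan`` keys.
    protein_results
        Fitted differential results of the global proteome, indexed by
        accession.
    fc_gate, alpha
        A protein counts as changed when ``|log2 FC| >= log2(fc_gate)`` and
        (if ``require_protein_p``) its p-value is below ``alpha``.
    """

    def __init__(
        self,
        feature_results: DifferentialResults,
        protein_results: DifferentialResults,
        fc_gate: float = 1.5,
        alpha: float = 0.05,
        require_protein_p: bool = True,
    ):
        if fc_gate <= 1:
            raise ValueError("fc_gate must exceed 1")
        self.feature_results = feature_results
        self.protein_results = protein_results
        self.fc_gate = fc_gate
        self.alpha = alpha
        self.require_protein_p = require_protein_p

    def _protein_changed(self, fc: float, p: float) -> bool:
        if not np.isfinite(fc) or fc <= 0:
            return False
        gate = abs(np.log2(fc)) >= np.log2(self.fc_gate)
        if self.require_protein_p:
            return bool(gate and p < self.alpha)
        return bool(gate)

    def fit(self, changed_only: bool = True) -> "AttributionResults":
        """Attribute features (by default only those called up/down)."""
        feats = self.feature_results.frame
        if changed_only:
            feats = feats[feats["call"].isin(["up", "down"])]
        prot = self.protein_results.frame
        rows = []
        for key, row in feats.iterrows():
            pid = protein_of_key(str(key))
            igp_fc = float(row["fold_change"])
            if pid in prot.index:
                p_fc = float(prot.at[pid, "fold_change"])
                p_p = float(prot.at[pid, "p_value"])
                norm_fc = igp_fc / p_fc if p_fc > 0 else np.nan
                source = (
                    "protein-level"
                    if self._protein_changed(p_fc, p_p)
                    else "glycosylation-level"
                )
            else:
                p_fc, p_p, norm_fc, source = np.nan, np.nan, np.nan, "unattributed"
            rows.append(
                {
                    "key": key,
                    "protein_id": pid,
                    "igp_fc": igp_fc,
                    "igp_call": row["call"],
                    "protein_fc": p_fc,
                    "protein_p": p_p,
                    "normalized_glyco_fc": norm_fc,
                    "source": source,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "key", "protein_id", "igp_fc", "igp_call", "protein_fc",
                "protein_p", "normalized_glyco_fc", "source",
            ],
        ).set_index("key")
        return AttributionResults(model=self, frame=frame)


@dataclass
class AttributionResults:
    """Per-feature change-source attribution plus glycoprotein summary."""

    model: AttributionModel
    frame: pd.DataFrame

    def source_counts(self) -> dict[str, int]:
        counts = self.frame["source"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in SOURCES}

    def glycoprotein_summary(self) -> dict:
        """Change-source percentages over glycoproteins with differential
        features; a glycoprotein with *any* protein-level attribution counts
        as protein-level."""
        if self.frame.empty:
            return {
                "n_glycoproteins": 0,
                "pct_protein_level": float("nan"),
                "pct_glycosylation_level": float("nan"),
                "pct_unattributed": float("nan"),
            }
        by_prot = self.frame.groupby("protein_id")["source"].agg(set)
        n = len(by_prot)
        n_protein = sum("protein-level" in s for s in by_prot)
        n_unattr = sum(s == {"unattributed"} for s in by_prot)
        n_glyco = n - n_protein - n_unattr
        return {
            "n_glycoproteins": n,
            "pct_protein_level": 100.0 * n_protein / n,
            "pct_glycosylation_level": 100.0 * n_glyco / n,
            "pct_unattributed": 100.0 * n_unattr / n,
        }

    def summary(self) -> str:
        counts = self.source_counts()
        gp = self.glycoprotein_summary()
        lines = [
            "Change-source attribution",
            "=" * 48,
            f"differential features:  {len(self.frame)}",
            f"  protein-level:        {counts['protein-level']}",
            f"  glycosylation-level:  {counts['glycosylation-level']}",
            f"  unattributed:         {counts['unattributed']}",
            f"glycoproteins affected: {gp['n_glycoproteins']}",
            f"  protein-level:        {gp['pct_protein_level']:.1f} %",
            f"  glycosylation-level:  {gp['pct_glycosylation_level']:.1f} %",
            f"  unattributed:         {gp['pct_unattributed']:.1f} %",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="key")
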