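"""Post-search identification tables: records, I/O, sequon scan, filters.

The pipeline consumes search-engine output, it never re-scores spectra: an
intact-glycopeptide (IGP) table carries one row per PSM with the peptide,
glycosite, glycan composition/structure, quality scores and the TMT
reporter-ion intensity of every channel.  Global-proteome and phosphopeptide
tables follow the same layout.  All coordinates are 1-based residue indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO

from .glycans import parse_composition, GlycanParseError

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS_10PLEX",
    "DEFAULT_GROUP_MAP",
    "Sequon",
    "IgpRecord",
    "ProteinRecord",
    "PhosphoRecord",
    "AnnotationTable",
    "UniqueIgpKey",
    "LoadResult",
    "FilterSummary",
    "scan_sequons",
    "load_igp_table",
    "load_protein_table",
    "load_phospho_table",
    "load_fasta",
    "load_annotations",
    "flag_non_sequon_records",
    "apply_identification_filters",
    "unique_igp_keys",
]

#: TMT 10-plex reporter channels in mass order.
CHANNELS_10PLEX = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

#: The study design: first five channels young pools, last five aged pools.
DEFAULT_GROUP_MAP: Mapping[str, str] = {
    **{c: "young" for c in CHANNELS_10PLEX[:5]},
    **{c: "aged" for c in CHANNELS_10PLEX[5:]},
}


class Sequon(NamedTuple):
    position: int  # 1-based index of the Asn
    motif: str  # "N-X-T" or "N-X-S"


def scan_sequons(sequence: str) -> list[Sequon]:
    """Find all N-X-S/T sequons (X any residue except proline).

    Positions are 1-based indices of the Asn; overlapping motifs are all
    reported; ambiguity codes (X, B, ...) never match any of N/S/T.
    """
    seq = sequence.upper()
    out: list[Sequon] = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P":
            if seq[i + 2] == "T":
                out.append(Sequon(i + 1, "N-X-T"))
            elif seq[i + 2] == "S":
                out.append(Sequon(i + 1, "N-X-S"))
    return out


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniqueIgpKey:
    """Identity of a unique intact glycopeptide: protein, site, glycan.

    ``glycan`` is the canonical structure string when available, else the
    composition string — equality of this key defines all "unique IGP"
    counts.
    """

    protein_id: str
    glycosite: int
    glycan: str

    def __str__(self) -> str:
        return f"{self.protein_id}@{self.glycosite}:{self.glycan}"


@dataclass(frozen=True)
class IgpRecord:
    protein_id: str
    glycosite: int
    peptide: str
    glycan_composition: str
    glycan_structure: str  # canonical structure string or "unknown"
    psm_id: str
    channel_intensities: Mapping[str, float]
    peptide_fdr: float = 0.0
    glycan_fdr: float = 0.0
    by_ion_count: int = 0
    oxonium_top10_count: int = 0
    flags: tuple[str, ...] = ()

    @property
    def key(self) -> UniqueIgpKey:
        glycan = (
            self.glycan_structure
            if self.glycan_structure and self.glycan_structure != "unknown"
            else self.glycan_composition
        )
        return UniqueIgpKey(self.protein_id, self.glycosite, glycan)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    channel_intensities: Mapping[str, float]
    fdr: float = 0.0


@dataclass(frozen=True)
class PhosphoRecord:
    protein_id: str
    site: int
    residue: str  # S, T or Y
    channel_intensities: Mapping[str, float]
    fdr: float = 0.0

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")


class AnnotationTable:
    """Many-to-many protein -> annotation-category mapping."""

    def __init__(self, mapping: Mapping[str, set[str]] | None = None):
        self._map: dict[str, set[str]] = {
            k: set(v) for k, v in (mapping or {}).items()
        }

    def categories(self, protein_id: str) -> set[str]:
        return self._map.get(protein_id, set())

    def proteins_in(self, category: str) -> set[str]:
        return {p for p, cats in self._map.items() if category in cats}

    def all_categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self._map.values():
            out |= cats
        return out

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_IGP_META_COLS = (
    "protein_id",
    "glycosite",
    "peptide",
    "glycan_composition",
    "glycan_structure",
    "psm_id",
    "peptide_fdr",
    "glycan_fdr",
    "by_ion_count",
    "oxonium_top10_count",
)


@dataclass
class LoadResult:
    records: list
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.diagnostics)


def _read_tsv(path, mandatory: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(mandatory) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    return df

def _channel_columns(df: pd.DataFrame, meta: Iterable[str]) -> list[str]:
    channels = [c for c in df.columns if c not in set(meta)]
    if not channels:
        raise ValueError("no channel intensity columns found")
    return channels


def _row_intensities(row, channels: list[str]) -> dict[str, float] | str:
    out: dict[str, float] = {}
    for c in channels:
        try:
            v = float(row[c])
        except (TypeError, ValueError):
            return f"non-numeric intensity in channel {c!r}"
        if pd.isna(v):
            v = 0.0
        if v < 0:
            return f"negative intensity in channel {c!r}"
        out[c] = v
    return out


def _fdr_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    if col not in df.columns:
        warnings.warn(
            f"{path}: column {col!r} absent — defaulting to 0.0 (no FDR filtering)",
            stacklevel=3,
        )
        return pd.Series(0.0, index=df.index)
    return pd.to_numeric(df[col], errors="coerce")


def load_igp_table(path) -> LoadResult:
    """Load an intact-glycopeptide PSM table.

    Any column that is not one of the documented metadata columns is taken
    to be a TMT channel.  Rows violating the record invariants (negative
    intensity, FDR outside [0,1], unparsable composition) are rejected with
    a line-numbered diagnostic.
    """
    mandatory = ("protein_id", "glycosite", "peptide", "glycan_composition", "psm_id")
    df = _read_tsv(path, mandatory)
    channels = _channel_columns(df, _IGP_META_COLS)
    pep_fdr = _fdr_column(df, "peptide_fdr", path)
    gly_fdr = _fdr_column(df, "glycan_fdr", path)
    records: list[IgpRecord] = []
    diagnostics: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        intens = _row_intensities(row, channels)
        if isinstance(intens, str):
            diagnostics.append(f"{path}:{line}: {intens}")
            continue
        try:
            parse_composition(str(row["glycan_composition"]))
        except GlycanParseError as exc:
            diagnostics.append(f"{path}:{line}: bad composition ({exc})")
            continue
        pf, gf = float(pep_fdr[i]), float(gly_fdr[i])
        if not (0.0 <= pf <= 1.0 and 0.0 <= gf <= 1.0):
            diagnostics.append(f"{path}:{line}: FDR outside [0,1]")
            continue
        records.append(
            IgpRecord(
                protein_id=str(row["protein_id"]),
                glycosite=int(row["glycosite"]),
                peptide=str(row["peptide"]),
                glycan_composition=str(row["glycan_composition"]),
                glycan_structure=str(row.get("glycan_structure", "unknown") or "unknown"),
                psm_id=str(row["psm_id"]),
                channel_intensities=intens,
                peptide_fdr=pf,
                glycan_fdr=gf,
                by_ion_count=int(row.get("by_ion_count", 0) or 0),
                oxonium_top10_count=int(row.get("oxonium_top10_count", 0) or 0),
            )
        )
    logger.info(
        "loaded %d IGP records from %s (%d rejected)",
        len(records), path, len(diagnostics),
    )
    return LoadResult(records, diagnostics)


def load_protein_table(path) -> LoadResult:
    df = _read_tsv(path, ("protein_id",))
    channels = _channel_columns(df, ("protein_id", "fdr"))
    fdr = _fdr_column(df, "fdr", path)
    records, diagnostics = [], []
    for i, row in df.iterrows():
        intens = _row_intensities(row, channels)
        if isinstance(intens, str):
            diagnostics.append(f"{path}:{i + 2}: {intens}")
            continue
        records.append(
            ProteinRecord(str(row["protein_id"]), intens, float(fdr[i]))
        )
    return LoadResult(records, diagnostics)


def load_phospho_table(path) -> LoadResult:
    df = _read_tsv(path, ("protein_id", "site", "residue"))
    channels = _channel_columns(df, ("protein_id", "site", "residue", "fdr"))
    fdr = _fdr_column(df, "fdr", path)
    records, diagnostics = [], []
    for i, row in df.iterrows():
        intens = _row_intensities(row, channels)
        if isinstance(intens, str):
            diagnostics.append(f"{path}:{i + 2}: {intens}")
            continue
        residue = str(row["residue"])
        if residue not in ("S", "T", "Y"):
            diagnostics.append(f"{path}:{i + 2}: residue {residue!r} not S/T/Y")
            continue
        records.append(
            PhosphoRecord(str(row["protein_id"]), int(row["site"]), residue,
                          intens, float(fdr[i]))
        )
    return LoadResult(records, diagnostics)


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_annotations(path) -> AnnotationTable:
    """TSV with columns protein_id, category (one label per row)."""
    df = _read_tsv(path, ("protein_id", "category"))
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples():
        label = str(row.category).strip()
        if not label:
            raise ValueError(f"{path}: empty category label for {row.protein_id}")
        mapping.setdefault(str(row.protein_id), set()).add(label)
    return AnnotationTable(mapping)


def flag_non_sequon_records(
    records: Iterable[IgpRecord], sequences: Mapping[str, str]
) -> list[IgpRecord]:
    """Cross-check every glycosite against the sequons of its protein.

    Returns records re-emitted with a ``non-sequon-site`` flag where the
    declared glycosite is not an N-X-S/T Asn in the protein sequence (or the
    protein is absent from the FASTA).
    """
    out: list[IgpRecord] = []
    sequon_cache: dict[str, set[int]] = {}
    for rec in records:
        seq = sequences.get(rec.protein_id)
        ok = False
        if seq is not None:
            if rec.protein_id not in sequon_cache:
                sequon_cache[rec.protein_id] = {
                    s.position for s in scan_sequons(seq)
                }
            ok = rec.glycosite in sequon_cache[rec.protein_id]
        if ok:
            out.append(rec)
        else:
            out.append(
                IgpRecord(
                    **{
                        **rec.__dict__,
                        "flags": rec.flags + ("non-sequon-site",),
                    }
                )
            )
    return out


# ---------------------------------------------------------------------------
# Identification filters
# ---------------------------------------------------------------------------


def unique_igp_keys(records: Iterable[IgpRecord]) -> set[UniqueIgpKey]:
    return {r.key for r in records}


def _granularity_counts(records: list[IgpRecord]) -> dict[str, int]:
    keys = unique_igp_keys(records)
    return {
        "psms": len(records),
        "unique_igps": len(keys),
        "glycosites": len({(k.protein_id, k.glycosite) for k in keys}),
        "glycoproteins": len({k.protein_id for k in keys}),
    }


@dataclass
class FilterSummary:
    """Identification-filter outcome at two confidence levels.

    ``peptide_level`` holds records confident at the glycosite-containing
    peptide level (peptide FDR, b/y ions, oxonium prefilter); the nested
    ``glycan_level`` subset is additionally confident in the glycan
    structure (glycan FDR).
    """

    peptide_level: list[IgpRecord]
    glycan_level: list[IgpRecord]
    counts: dict[str, dict[str, int]]


def apply_identification_filters(
    records: Iterable[IgpRecord],
    peptide_fdr_max: float = 0.01,
    glycan_fdr_max: float = 0.01,
    min_by_ions: int = 5,
    min_oxonium: int = 2,
) -> FilterSummary:
    """Apply the identification filters at both confidence levels.

    Defaults reproduce the study thresholds: FDR < 1 % at the peptide and
    glycan level, at least 5 b/y ions at the glycosite-containing peptide,
    and at least two oxonium ions among the top-10 fragment ions.
    """
    records = list(records)
    peptide_level = [
        r
        for r in records
        if r.peptide_fdr <= peptide_fdr_max
        and r.by_ion_count >= min_by_ions
        and r.oxonium_top10_count >= min_oxonium
    ]
    glycan_level = [r for r in peptide_level if r.glycan_fdr <= glycan_fdr_max]
    counts = {
        "input": _granularity_counts(records),
        "peptide_level": _granularity_counts(peptide_level),
        "glycan_level": _granularity_counts(glycan_level),
    }
    return FilterSummary(peptide_level, glycan_level, counts)
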