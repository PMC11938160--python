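"""TMT reporter-ion quantification and two-group differential testing.

The quantification path mirrors a standard 10-plex TMT workflow: reporter
intensities are normalised within a TMT set by equalising channel sums (this
corrects sample-loading imbalance); glycopeptide and phosphopeptide matrices
are instead rescaled with the *global-proteome* channel factors, so that a
loading artefact measured on the unfractionated proteome is removed from the
enriched sub-proteomes; PSMs are collapsed to unique features by the
per-channel median; and features are compared between the two pooled groups
(5 young vs 5 aged channels) with a two-tailed unpaired t-test on log2
intensities plus a fold-change gate.

The differential test is exposed statsmodels-style: build a
:class:`TwoGroupDifferentialModel` from a :class:`QuantMatrix` (or a plain
DataFrame via :meth:`~TwoGroupDifferentialModel.from_dataframe`), call
``fit()``, and read estimates off the returned
:class:`DifferentialResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .igp import DEFAULT_GROUP_MAP, IgpRecord, PhosphoRecord, ProteinRecord

__all__ = [
    "QuantMatrix",
    "normalize_within_set",
    "scaling_factors",
    "apply_global_scaling",
    "aggregate_psms",
    "protein_matrix",
    "phospho_matrix",
    "TwoGroupDifferentialModel",
    "DifferentialResults",
    "FC_UP_DEFAULT",
    "FC_DOWN_DEFAULT",
    "ALPHA_DEFAULT",
]

#: Differential-call cutoffs: FC > 1.5 or < 0.67 with p < 0.05.
FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 0.67
ALPHA_DEFAULT = 0.05


@dataclass
class QuantMatrix:
    """A features x channels intensity table with group labels.

    ``state`` tracks the normalisation applied: ``raw`` ->
    ``within-set-normalized`` (channel sums equalised) or ``global-scaled``
    (proteome-derived channel factors applied).
    """

    data: pd.DataFrame
    group_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    state: str = "raw"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.group_map]
        if missing:
            raise ValueError(f"channels without group label: {missing}")
        if (self.data.values < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def group_channels(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.group_map[c] == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for c in self.data.columns:
            g = self.group_map[c]
            if g not in seen:
                seen.append(g)
        return seen


def scaling_factors(m: QuantMatrix) -> pd.Series:
    """Within-set channel factors: (mean column sum) / (column sum).

    Multiplying each channel by its factor equalises all channel sums; the
    factors of the global-proteome matrix are the cross-omic scaling factors
    applied to glyco/phospho matrices.
    """
    sums = m.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum channel(s): {list(zero.index)}")
    return sums.mean() / sums


def normalize_within_set(m: QuantMatrix) -> QuantMatrix:
    """Equalise channel sums within the TMT set (sample-loading correction)."""
    if m.state != "raw":
        raise ValueError(f"matrix already normalised (state={m.state!r})")
    factors = scaling_factors(m)
    return replace(m, data=m.data * factors, state="within-set-normalized")


def apply_global_scaling(glyco: QuantMatrix, proteome_factors: pd.Series) -> QuantMatrix:
    """Rescale an enriched-subproteome matrix with proteome channel factors."""
    if glyco.state != "raw":
        raise ValueError(f"matrix already normalised (state={glyco.state!r})")
    missing = [c for c in glyco.channels if c not in proteome_factors.index]
    if missing:
        raise ValueError(f"no scaling factor for channel(s): {missing}")
    if (proteome_factors <= 0).any():
        raise ValueError("scaling factors must be strictly positive")
    return replace(
        glyco,
        data=glyco.data * proteome_factors[glyco.channels],
        state="global-scaled",
    )


# ---------------------------------------------------------------------------
# PSM aggregation
# ---------------------------------------------------------------------------


def aggregate_psms(
    records: Iterable[IgpRecord],
    group_map: Mapping[str, str] | None = None,
) -> QuantMatrix:
    """Collapse IGP PSMs to one row per unique IGP by per-channel median.

    The PSM count per key is kept in ``meta['n_psm']``.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    group_map = dict(group_map or DEFAULT_GROUP_MAP)
    channels = [c for c in group_map if c in records[0].channel_intensities]
    rows = pd.DataFrame(
        [
            {"__key__": str(r.key), **{c: r.channel_intensities[c] for c in channels}}
            for r in records
        ]
    )
    grouped = rows.groupby("__key__", sort=True)
    data = grouped[channels].median()
    data.index.name = "key"
    meta = grouped.size().to_frame("n_psm")
    meta.index.name = "key"
    return QuantMatrix(data=data, group_map=group_map, state="raw", meta=meta)


def protein_matrix(
    records: Iterable[ProteinRecord],
    group_map: Mapping[str, str] | None = None,
) -> QuantMatrix:
    group_map = dict(group_map or DEFAULT_GROUP_MAP)
    records = list(records)
    if not records:
        raise ValueError("no protein records")
    channels = [c for c in group_map if c in records[0].channel_intensities]
    rows = pd.DataFrame(
        [
            {"__key__": r.protein_id, **{c: r.channel_intensities[c] for c in channels}}
            for r in records
        ]
    )
    data = rows.groupby("__key__", sort=True)[channels].median()
    data.index.name = "key"
    return QuantMatrix(data=data, group_map=group_map, state="raw")


def phospho_matrix(
    records: Iterable[PhosphoRecord],
    group_map: Mapping[str, str] | None = None,
) -> QuantMatrix:
    group_map = dict(group_map or DEFAULT_GROUP_MAP)
    records = list(records)
    if not records:
        raise ValueError("no phospho records")
    channels = [c for c in group_map if c in records[0].channel_intensities]
    rows = pd.DataFrame(
        [
            {
                "__key__": f"{r.protein_id}@{r.site}{r.residue}",
                **{c: r.channel_intensities[c] for c in channels},
            }
            for r in records
        ]
    )
    data = rows.groupby("__key__", sort=True)[channels].median()
    data.index.name = "key"
    return QuantMatrix(data=data, group_map=group_map, state="raw")


# ---------------------------------------------------------------------------
# Differential model
# ---------------------------------------------------------------------------


class TwoGroupDifferentialModel:
    """Two-group differential-abundance model for a normalised QuantMatrix.

    Parameters
    ----------
    matrix
        Normalised intensities (``within-set-normalized`` or
        ``global-scaled``); a raw matrix raises.
    group_a, group_b
        Reference and comparison group labels; fold changes are
        ``median(group_b) / median(group_a)`` (default aged / young).
    fc_up, fc_down, alpha
        Differential-call cutoffs (defaults 1.5, 0.67, 0.05).
    log_scale
        Run the t-test on log2 intensities (default, multiplicative noise
        model); set False for a linear-scale test.
    equal_var
        Student (default) vs Welch t-test.
    bh
        Gate calls on Benjamini-Hochberg adjusted p-values instead of raw p.
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        group_a: str = "young",
        group_b: str = "aged",
        fc_up: float = FC_UP_DEFAULT,
        fc_down: float = FC_DOWN_DEFAULT,
        alpha: float = ALPHA_DEFAULT,
        log_scale: bool = True,
        equal_var: bool = True,
        bh: bool = False,
    ):
        if matrix.state == "raw":
            raise ValueError("differential test requires a normalised matrix")
        for g in (group_a, group_b):
            if len(matrix.group_channels(g)) < 2:
                raise ValueError(f"group {g!r} needs at least 2 channels")
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.fc_up = fc_up
        self.fc_down = fc_down
        self.alpha = alpha
        self.log_scale = log_scale
        self.equal_var = equal_var
        self.bh = bh

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        group_map: Mapping[str, str] | None = None,
        normalize: bool = True,
        **kwargs,
    ) -> "TwoGroupDifferentialModel":
        m = QuantMatrix(data=data, group_map=dict(group_map or DEFAULT_GROUP_MAP))
        if normalize:
            m = normalize_within_set(m)
        else:
            m = replace(m, state="within-set-normalized")
        return cls(m, **kwargs)

    def fit(self) -> "DifferentialResults":
        m = self.matrix
        a_cols = m.group_channels(self.group_a)
        b_cols = m.group_channels(self.group_b)
        values = m.data
        a = values[a_cols].to_numpy(float)
        b = values[b_cols].to_numpy(float)

        # fold changes come from the raw group medians; a zero young-group
        # median leaves the ratio undefined and the record excluded from
        # calls (flagged, not silently dropped)
        med_a = np.median(a, axis=1)
        med_b = np.median(b, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = med_b / med_a
        undefined = med_a <= 0

        # for the log-scale test, zero intensities are imputed as half the
        # row's minimum positive value so the fill respects the feature's
        # own intensity scale (matrix-wide fallback for all-zero rows)
        allv = np.concatenate([a, b], axis=1)
        positive = allv[allv > 0]
        if positive.size == 0:
            raise ValueError("matrix contains no positive intensities")
        global_eps = positive.min() / 2.0
        row_min = np.where(allv > 0, allv, np.inf).min(axis=1)
        eps = np.where(np.isfinite(row_min), row_min / 2.0, global_eps)[:, None]
        imputed = (a == 0).any(axis=1) | (b == 0).any(axis=1)
        a = np.where(a == 0, eps, a)
        b = np.where(b == 0, eps, b)

        if self.log_scale:
            ta, tb = np.log2(a), np.log2(b)
        else:
            ta, tb = a, b
        with warnings.catch_warnings():
            # constant rows trip scipy's precision warning; their NaN
            # p-values are mapped to 1 (null) below
            warnings.simplefilter("ignore", RuntimeWarning)
            tt = stats.ttest_ind(tb, ta, axis=1, equal_var=self.equal_var)
        p = np.asarray(tt.pvalue, float)
        # constant rows (zero variance in both groups, equal means) are null
        p = np.where(np.isnan(p), 1.0, p)

        p_gate = p.copy()
        q = None
        if self.bh:
            q = stats.false_discovery_control(p, method="bh")
            p_gate = q

        call = np.full(len(values), "unchanged", dtype=object)
        call[(fc > self.fc_up) & (p_gate < self.alpha)] = "up"
        call[(fc < self.fc_down) & (p_gate < self.alpha)] = "down"
        call[undefined] = "undefined"

        frame = pd.DataFrame(
            {
                "fold_change": fc,
                "log2_fc": np.where(fc > 0, np.log2(np.where(fc > 0, fc, 1.0)), np.nan),
                "p_value": p,
                "call": call,
                f"median_{self.group_a}": med_a,
                f"median_{self.group_b}": med_b,
                "imputed": imputed,
            },
            index=values.index,
        )
        if q is not None:
            frame.insert(3, "q_value", q)
        if m.meta is not None:
            frame = frame.join(m.meta, how="left")
        return DifferentialResults(model=self, frame=frame)


@dataclass
class DifferentialResults:
    """Per-feature fold changes, p-values and calls from a fitted model."""

    model: TwoGroupDifferentialModel
    frame: pd.DataFrame

    @property
    def calls(self) -> pd.Series:
        return self.frame["call"]

    @property
    def n_up(self) -> int:
        return int((self.frame["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["call"] == "down").sum())

    def changed(self) -> pd.DataFrame:
        return self.frame[self.frame["call"].isin(["up", "down"])]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def fold_change(self, key: str) -> float:
        return float(self.frame.at[key, "fold_change"])

    def summary(self) -> str:
        m = self.model
        n = len(self.frame)
        lines = [
            "Two-group differential abundance",
            "=" * 48,
            f"features:        {n}",
            f"groups:          {m.group_b} vs {m.group_a} "
            f"({len(m.matrix.group_channels(m.group_b))} vs "
            f"{len(m.matrix.group_channels(m.group_a))} channels)",
            f"test:            two-tailed unpaired t "
            f"({'Student' if m.equal_var else 'Welch'}, "
            f"{'log2' if m.log_scale else 'linear'} scale)",
            f"cutoffs:         FC > {m.fc_up} or < {m.fc_down}, "
            f"{'BH q' if m.bh else 'p'} < {m.alpha}",
            f"up:              {self.n_up}",
            f"down:            {self.n_down}",
            f"unchanged:       {int((self.frame['call'] == 'unchanged').sum())}",
            f"undefined:       {int((self.frame['call'] == 'undefined').sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="key")
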