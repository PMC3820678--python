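"""Per-promoter mean enrichment, binding calls and differential calls.

Probe-level log2 IP/input tracks (bedGraph) are reduced to one mean
enrichment per promoter region, replicate means are averaged, and strict
thresholds turn means into bound / induced / repressed calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from combichip.promoter_catalog import PromoterRecord

logger = logging.getLogger(__name__)

FACTORS = ("CREB", "CEBPB", "CEBPA", "CJUN", "RNAP", "H3K9AC", "MEDIP")
CONDITIONS = ("undiff", "diff")

INDUCED = "induced"
REPRESSED = "repressed"
UNCHANGED = "unchanged"
STATUSES = (INDUCED, REPRESSED, UNCHANGED)

#: log2 binding thresholds per factor (strict ">")
DEFAULT_BIND_THRESHOLDS = {
    "CREB": 0.4,
    "CEBPB": 0.4,
    "CEBPA": 0.36,
    "CJUN": 0.36,
    "RNAP": 0.4,
}


@dataclass
class ThresholdConfig:
    """All decision thresholds, on the log2 scale.

    ``bind_thresholds`` maps factor name to the strict lower bound for a
    bound call.  Differential calls require the high-condition value to
    exceed ``level`` and the difference to exceed ``delta``; repression uses
    the mirrored rule.
    """

    bind_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_BIND_THRESHOLDS))
    rnap_level: float = 0.4
    rnap_delta: float = 0.3
    h3k9ac_level: float = 0.4
    h3k9ac_delta: float = 0.36
    mrna_log2fc: float = 0.5
    medip_threshold: float = 0.4

    def __post_init__(self) -> None:
        values = list(self.bind_thresholds.values()) + [
            self.rnap_level,
            self.rnap_delta,
            self.h3k9ac_level,
            self.h3k9ac_delta,
            self.mrna_log2fc,
            self.medip_threshold,
        ]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("all thresholds must be finite")
        if self.rnap_delta < 0 or self.h3k9ac_delta < 0:
            raise ValueError("deltas must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        bind = dict(DEFAULT_BIND_THRESHOLDS)
        bind.update(data.pop("bind_thresholds", {}))
        return cls(bind_thresholds=bind, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "bind_thresholds": dict(self.bind_thresholds),
            "rnap_level": self.rnap_level,
            "rnap_delta": self.rnap_delta,
            "h3k9ac_level": self.h3k9ac_level,
            "h3k9ac_delta": self.h3k9ac_delta,
            "mrna_log2fc": self.mrna_log2fc,
            "medip_threshold": self.medip_threshold,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class SignalTrack:
    """Probe-level log2 enrichment for one factor / condition / replicate."""

    factor: str
    condition: str
    replicate: int
    chrom: np.ndarray  # object dtype, per-probe chromosome
    pos: np.ndarray  # int64, probe position (midpoint)
    value: np.ndarray  # float64, log2 IP/input

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if not (len(self.chrom) == len(self.pos) == len(self.value)):
            raise ValueError("chrom/pos/value arrays must have equal length")
        if len(self.pos) and self.pos.min() < 0:
            raise ValueError("probe positions must be non-negative")
        if len(self.value) and not np.all(np.isfinite(self.value)):
            raise ValueError("log2 enrichment values must be finite")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, factor: str, condition: str, replicate: int
    ) -> "SignalTrack":
        """Read a 4-column bedGraph; probe position is the interval midpoint."""
        df = pd.read_csv(
            path,
            sep="\t",
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        )
        pos = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        return cls(
            factor=factor,
            condition=condition,
            replicate=replicate,
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=pos,
            value=df["value"].to_numpy(),
        )

    def to_bedgraph(self, path: str | Path) -> None:
        """Write 1-bp probe intervals, sorted by chromosome then position."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        with Path(path).open("w") as out:
            for i in order:
                out.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t{self.pos[i] + 1}"
                    f"\t{self.value[i]:.4f}\n"
                )


@dataclass(frozen=True)
class BindingProfile:
    promoter_id: str
    factor: str
    condition: str
    mean_enrichment: float
    bound: bool


@dataclass(frozen=True)
class DifferentialCall:
    promoter_id: str
    assay: str
    status: str
    diff_value: float
    undiff_value: float


def promoter_mean_enrichment(track: SignalTrack, promoter: PromoterRecord) -> float:
    """Arithmetic mean of in-region probe log2 enrichments; NaN if no probe."""
    mask = (
        (track.chrom == promoter.chrom)
        & (track.pos >= promoter.region_start)
        & (track.pos < promoter.region_end)
    )
    if not mask.any():
        return float("nan")
    return float(track.value[mask].mean())


def promoter_means(
    track: SignalTrack, catalog: Sequence[PromoterRecord]
) -> pd.Series:
    """Vectorised per-promoter mean enrichment over a catalog.

    Returns a float Series indexed by promoter_id; promoters with zero
    in-region probes get NaN (they drop out of that factor's universe).
    """
    ids = [p.promoter_id for p in catalog]
    out = pd.Series(np.nan, index=pd.Index(ids, name="promoter_id"), dtype=float)
    if len(track.pos) == 0 or not catalog:
        return out
    chroms = track.chrom.astype(str)
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = track.pos[sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        vals = track.value[sel][order]
        csum = np.concatenate(([0.0], np.cumsum(vals)))
        proms = [p for p in catalog if p.chrom == chrom]
        if not proms:
            continue
        starts = np.array([p.region_start for p in proms])
        ends = np.array([p.region_end for p in proms])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        counts = hi - lo
        sums = csum[hi] - csum[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out.loc[[p.promoter_id for p in proms]] = means
    return out


def average_replicates(values: Iterable[float] | pd.DataFrame) -> float | pd.Series:
    """Average per-replicate promoter means, skipping missing values.

    Accepts a list of scalars (returns a scalar) or a DataFrame with one
    column per replicate (returns a per-row Series).  All-missing input
    stays missing (NaN).
    """
    if isinstance(values, pd.DataFrame):
        return values.mean(axis=1, skipna=True)
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def call_binding(mean: float, factor: str, cfg: ThresholdConfig) -> bool:
    """True iff the mean enrichment strictly exceeds the factor threshold."""
    if factor not in cfg.bind_thresholds:
        raise KeyError(f"no binding threshold configured for factor {factor!r}")
    if math.isnan(mean):
        raise ValueError("cannot call binding on a missing mean")
    return mean > cfg.bind_thresholds[factor]


def call_differential(diff: float, undiff: float, level: float, delta: float) -> str:
    """Induced / repressed / unchanged from the two condition means.

    Induced iff ``diff > level`` and ``diff - undiff > delta``; repressed by
    the mirrored rule; otherwise unchanged.  Both comparisons are strict.
    """
    if level < 0 or delta < 0:
        raise ValueError("level and delta must be >= 0")
    if math.isnan(diff) or math.isnan(undiff):
        raise ValueError("cannot call differential status on missing values")
    if diff > level and diff - undiff > delta:
        return INDUCED
    if undiff > level and undiff - diff > delta:
        return REPRESSED
    return UNCHANGED


def call_differential_series(
    diff: pd.Series, undiff: pd.Series, level: float, delta: float
) -> pd.Series:
    """Vectorised :func:`call_differential` over aligned Series (NaN dropped)."""
    if level < 0 or delta < 0:
        raise ValueError("level and delta must be >= 0")
    df = pd.DataFrame({"diff": diff, "undiff": undiff}).dropna()
    ind = (df["diff"] > level) & (df["diff"] - df["undiff"] > delta)
    rep = (df["undiff"] > level) & (df["undiff"] - df["diff"] > delta)
    out = pd.Series(UNCHANGED, index=df.index, dtype=object)
    out[ind] = INDUCED
    out[rep] = REPRESSED
    return out


def call_methylation(medip_mean: float, cfg: ThresholdConfig) -> bool:
    """True iff the MeDIP mean strictly exceeds the configured threshold."""
    if math.isnan(medip_mean):
        raise ValueError("cannot call methylation on a missing mean")
    return medip_mean > cfg.medip_threshold


def track_means_table(
    tracks: Sequence[SignalTrack], catalog: Sequence[PromoterRecord]
) -> pd.DataFrame:
    """Replicate-averaged promoter means for every factor x condition.

    Returns a DataFrame indexed by promoter_id with MultiIndex columns
    ``(factor, condition)``.  Promoter means are computed per replicate and
    averaged on the log2 scale, skipping missing replicates.
    """
    per_rep: dict[tuple[str, str], list[pd.Series]] = {}
    for tr in tracks:
        per_rep.setdefault((tr.factor, tr.condition), []).append(
            promoter_means(tr, catalog)
        )
    cols = {}
    for key, series_list in per_rep.items():
        stacked = pd.concat(series_list, axis=1)
        cols[key] = average_replicates(stacked)
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["factor", "condition"])
    return table.sort_index(axis=1)
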