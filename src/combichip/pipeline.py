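"""End-to-end orchestration: from input files to report tables.

Stages: promoter filtering -> binding / differential calls -> pattern
classification -> group enrichment (incl. methylation stratification and
percentile summaries) -> motif combination enrichment -> summary JSON.
All stages are deterministic given their inputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from combichip import expression_mapping, motif_analysis
from combichip.combinatorial_enrichment import (
    DEFAULT_FACTOR_SET,
    all_pattern_labels,
    assign_patterns,
    euler_counts,
    group_enrichment_table,
    percentile_summary,
)
from combichip.motif_analysis import (
    CONSENSUS_MOTIFS,
    MOTIF_FOR_FACTOR,
    default_motifs,
    load_motif_table,
    motif_presence,
    scan_catalog,
)
from combichip.occupancy_signals import (
    INDUCED,
    REPRESSED,
    SignalTrack,
    ThresholdConfig,
    call_differential_series,
    track_means_table,
)
from combichip.promoter_catalog import (
    PromoterRecord,
    apply_promoter_filters,
    read_promoters,
    read_sequences,
    write_promoters_bed,
)
from combichip.synthetic_data import DatasetBundle

logger = logging.getLogger(__name__)

_TRACK_NAME = re.compile(r"^(?P<factor>[A-Za-z0-9]+)_(?P<cond>undiff|diff)_rep(?P<rep>\d+)\.bedGraph$")


@dataclass
class RunConfig:
    """File-level configuration of a full pipeline run."""

    promoters: Path
    sequences: Path
    tracks_dir: Path
    outdir: Path
    expression: Path | None = None
    motifs: Path | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    factor_set: tuple = DEFAULT_FACTOR_SET
    apply_filters: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factor_set) != 3:
            raise ValueError("factor set must have exactly 3 members")
        for attr in ("promoters", "sequences", "tracks_dir"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")


def load_tracks(tracks_dir: str | Path) -> list[SignalTrack]:
    """Load every ``FACTOR_condition_repN.bedGraph`` file in a directory."""
    tracks = []
    for path in sorted(Path(tracks_dir).glob("*.bedGraph")):
        m = _TRACK_NAME.match(path.name)
        if not m:
            raise ValueError(
                f"cannot parse track file name {path.name!r}; expected "
                "FACTOR_condition_repN.bedGraph"
            )
        tracks.append(
            SignalTrack.from_bedgraph(
                path,
                factor=m["factor"].upper(),
                condition=m["cond"],
                replicate=int(m["rep"]),
            )
        )
    if not tracks:
        raise FileNotFoundError(f"no .bedGraph tracks found in {tracks_dir}")
    return tracks


def analyze(
    catalog: Sequence[PromoterRecord],
    sequences: Mapping[str, str],
    tracks: Sequence[SignalTrack],
    expression: pd.DataFrame | None = None,
    thresholds: ThresholdConfig | None = None,
    factor_set: Sequence[str] = DEFAULT_FACTOR_SET,
    motifs=None,
) -> dict:
    """Run every analysis stage on in-memory inputs.

    Returns a dict of DataFrames / dicts keyed by output name; ``analyze``
    does no file IO, so it is also the fast path for simulations.
    """
    cfg = thresholds or ThresholdConfig()
    motifs = motifs if motifs is not None else default_motifs()
    result: dict = {}

    means = track_means_table(tracks, catalog)
    result["binding_means"] = means

    bound: dict[str, pd.DataFrame] = {}
    for cond in ("undiff", "diff"):
        cols = {}
        for f, thr in cfg.bind_thresholds.items():
            if (f, cond) in means.columns:
                cols[f] = means[(f, cond)] > thr
        bound[cond] = pd.DataFrame(cols)
    result["binding_calls"] = bound

    statuses: dict[str, pd.Series] = {}
    if ("RNAP", "diff") in means.columns and ("RNAP", "undiff") in means.columns:
        statuses["RNAP"] = call_differential_series(
            means[("RNAP", "diff")], means[("RNAP", "undiff")],
            cfg.rnap_level, cfg.rnap_delta,
        )
    if ("H3K9AC", "diff") in means.columns and ("H3K9AC", "undiff") in means.columns:
        statuses["H3K9AC"] = call_differential_series(
            means[("H3K9AC", "diff")], means[("H3K9AC", "undiff")],
            cfg.h3k9ac_level, cfg.h3k9ac_delta,
        )

    methylated = None
    if ("MEDIP", "diff") in means.columns:
        medip = means[("MEDIP", "diff")].dropna()
        methylated = medip > cfg.medip_threshold

    promoter_expression = None
    if expression is not None and len(expression):
        promoter_expression = expression_mapping.map_expression(expression, catalog)
        statuses["MRNA"] = expression_mapping.call_mrna_changes(
            promoter_expression["log2fc_diff_vs_undiff"], cfg.mrna_log2fc
        )
        for pert in ("acebp", "afos", "5aza"):
            col = f"log2fc_{pert}"
            if col in promoter_expression.columns:
                statuses[pert.upper()] = expression_mapping.call_mrna_changes(
                    promoter_expression[col], cfg.mrna_log2fc
                )
    result["promoter_expression"] = promoter_expression
    result["differential_calls"] = statuses
    result["methylated"] = methylated

    patterns = assign_patterns(bound["diff"], factor_set)
    patterns_undiff = assign_patterns(bound["undiff"], factor_set) if len(bound["undiff"].columns) else None
    result["patterns"] = patterns
    result["patterns_undiff"] = patterns_undiff
    counts, marginals = euler_counts(patterns, factor_set)
    result["euler_counts"] = counts
    result["euler_marginals"] = marginals

    for assay in ("RNAP", "MRNA", "H3K9AC"):
        if assay in statuses:
            result[f"enrichment_{assay.lower()}"] = group_enrichment_table(
                patterns, statuses[assay], factor_set
            )
    for pert in ("ACEBP", "AFOS", "5AZA"):
        if pert in statuses:
            result[f"enrichment_{pert.lower()}"] = group_enrichment_table(
                patterns, statuses[pert], factor_set, statuses_of_interest=(REPRESSED,)
            )
    # perturbation repression among differentiation-induced genes
    if "MRNA" in statuses:
        induced_ids = statuses["MRNA"].index[statuses["MRNA"] == INDUCED]
        for pert in ("ACEBP", "AFOS"):
            if pert in statuses:
                sub = statuses[pert].reindex(induced_ids).dropna()
                if len(sub):
                    result[f"enrichment_{pert.lower()}_induced"] = group_enrichment_table(
                        patterns, sub, factor_set, statuses_of_interest=(REPRESSED,)
                    )

    if methylated is not None:
        meth_status = methylated.map({True: "methylated", False: "unmethylated"})
        result["methylation_by_pattern"] = group_enrichment_table(
            patterns, meth_status, factor_set, statuses_of_interest=("methylated",)
        )
        rows = []
        common = methylated.index.intersection(bound["diff"].index)
        for f in factor_set:
            sel = bound["diff"].loc[common, f].fillna(False).astype(bool)
            if sel.sum():
                rows.append(
                    {
                        "factor": f,
                        "n_bound": int(sel.sum()),
                        "fraction_methylated": float(methylated.loc[common][sel].mean()),
                        "universe_fraction": float(methylated.loc[common].mean()),
                    }
                )
        result["methylation_by_factor"] = pd.DataFrame(rows)
        for assay in ("RNAP", "MRNA"):
            if assay in statuses:
                for label, stratum in (
                    ("methylated", methylated[methylated].index),
                    ("unmethylated", methylated[~methylated].index),
                ):
                    sub = statuses[assay].reindex(stratum).dropna()
                    if len(sub):
                        result[f"enrichment_{assay.lower()}_{label}"] = (
                            group_enrichment_table(patterns, sub, factor_set)
                        )

    # RNAP co-binding probabilities per factor (both conditions)
    if "RNAP" in cfg.bind_thresholds:
        rows = []
        for cond in ("undiff", "diff"):
            if "RNAP" not in bound[cond].columns:
                continue
            rnap_bound = bound[cond]["RNAP"].dropna().astype(bool)
            for f in factor_set:
                if f not in bound[cond].columns:
                    continue
                fb = bound[cond][f].dropna().astype(bool)
                common = fb.index[fb].intersection(rnap_bound.index)
                if len(common):
                    rows.append(
                        {
                            "condition": cond,
                            "factor": f,
                            "n_bound": len(common),
                            "fraction_rnap_bound": float(rnap_bound.loc[common].mean()),
                        }
                    )
        result["rnap_cobinding"] = pd.DataFrame(rows)

    result["percentiles"] = _percentile_report(means, patterns, statuses, factor_set)

    # motif scanning over the analysis universe
    universe = [p.promoter_id for p in catalog]
    seqs = {pid: sequences[pid] for pid in universe if pid in sequences}
    hits = scan_catalog(seqs, motifs)
    result["motif_hits"] = hits
    presence = motif_presence(hits, list(seqs), [m.name for m in motifs])
    result["motif_presence"] = presence

    combo_rows = []
    motif_names = [m for m in CONSENSUS_MOTIFS if m in presence.columns]
    combos = [
        c
        for r in (2, 3)
        for c in itertools.combinations(motif_names, r)
    ]
    for label in all_pattern_labels(factor_set):
        for combo in combos:
            res = motif_analysis.combo_enrichment(
                presence, patterns, label, combo, exclusive=True, all_motifs=motif_names
            )
            combo_rows.append(
                {
                    "pattern": res.pattern,
                    "combo": "+".join(res.combo),
                    "n_group": res.n_group,
                    "n_with_combo": res.n_with_combo,
                    "fraction": res.fraction,
                    "background_fraction": res.background_fraction,
                    "enrichment": res.enrichment,
                    "chi2": res.chi2,
                    "p_value": res.p_value,
                }
            )
    result["motif_combo_enrichment"] = pd.DataFrame(combo_rows)

    coloc_rows = []
    for label in all_pattern_labels(factor_set):
        group_ids = patterns.index[patterns == label].intersection(presence.index)
        if not len(group_ids):
            continue
        for pair in itertools.combinations(motif_names, 2):
            ratio = motif_analysis.colocalization_ratio(
                presence, pair, group_ids, presence.index
            )
            coloc_rows.append(
                {"pattern": label, "pair": "+".join(pair), "ratio": ratio}
            )
    result["motif_colocalization"] = pd.DataFrame(coloc_rows)

    result["summary"] = _summarize(result, factor_set)
    return result


def _percentile_report(means, patterns, statuses, factor_set) -> dict:
    """Percentile summaries of binding, per group (all / triple-bound / by status)."""
    out: dict = {}
    all_label = "+".join(factor_set)
    triple_ids = patterns.index[patterns == all_label]
    groups = {"all": patterns.index, all_label: triple_ids}
    if "RNAP" in statuses:
        st = statuses["RNAP"]
        groups[f"{all_label}&induced"] = triple_ids.intersection(st.index[st == INDUCED])
        groups[f"{all_label}&repressed"] = triple_ids.intersection(st.index[st == REPRESSED])
    binding = {}
    for f in factor_set:
        if (f, "diff") not in means.columns:
            continue
        col = means[(f, "diff")]
        binding[f] = {
            name: percentile_summary(col.reindex(ids).dropna(), label=name).to_dict()
            for name, ids in groups.items()
            if len(col.reindex(ids).dropna())
        }
    out["binding_by_group"] = binding
    if ("RNAP", "diff") in means.columns:
        col = means[("RNAP", "diff")]
        by_pattern = {}
        induced_by_pattern = {}
        for label in all_pattern_labels(factor_set):
            ids = patterns.index[patterns == label]
            vals = col.reindex(ids).dropna()
            if len(vals):
                by_pattern[label] = percentile_summary(vals, label=label).to_dict()
            if "RNAP" in statuses:
                st = statuses["RNAP"]
                sub = vals.reindex(ids.intersection(st.index[st == INDUCED])).dropna()
                if len(sub):
                    induced_by_pattern[label] = percentile_summary(sub, label=label).to_dict()
        out["rnap_by_pattern"] = by_pattern
        out["rnap_by_pattern_induced"] = induced_by_pattern
    return out


def _summarize(result: dict, factor_set) -> dict:
    statuses = result["differential_calls"]
    summary: dict = {
        "factor_set": list(factor_set),
        "n_universe": int(len(result["patterns"])),
        "euler_counts": {k: int(v) for k, v in result["euler_counts"].items()},
    }
    for assay in ("RNAP", "MRNA", "H3K9AC"):
        if assay in statuses:
            st = statuses[assay]
            n = len(st)
            n_ind = int((st == INDUCED).sum())
            n_rep = int((st == REPRESSED).sum())
            summary[assay.lower()] = {
                "n_called": n,
                "n_induced": n_ind,
                "n_repressed": n_rep,
                "pct_induced": round(100.0 * n_ind / n, 1) if n else None,
                "pct_repressed": round(100.0 * n_rep / n, 1) if n else None,
            }
    key = "enrichment_rnap"
    if key in result:
        tab = result[key]
        row = tab[(tab["pattern"] == "+".join(factor_set[1:])) & (tab["status"] == INDUCED)]
        if len(row):
            summary["cebp_jun_induced_enrichment"] = {
                "fraction": float(row["fraction"].iloc[0]),
                "expected": float(row["expected_fraction"].iloc[0]),
                "ratio": float(row["enrichment_ratio"].iloc[0]),
                "p_value": float(row["p_value"].iloc[0]),
            }
    if result.get("methylated") is not None:
        summary["fraction_methylated"] = float(result["methylated"].mean())
    return summary


def write_outputs(result: dict, outdir: str | Path) -> None:
    """Serialise every analysis table to TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    means = result["binding_means"].copy()
    means.columns = [f"{f}_{c}" for f, c in means.columns]
    means.to_csv(outdir / "binding_means.tsv", sep="\t", float_format="%.6f")

    for cond, df in result["binding_calls"].items():
        df.to_csv(outdir / f"binding_calls_{cond}.tsv", sep="\t")

    calls = pd.DataFrame(result["differential_calls"])
    calls.to_csv(outdir / "differential_calls.tsv", sep="\t")

    if result.get("methylated") is not None:
        result["methylated"].rename("methylated").to_csv(
            outdir / "methylation_calls.tsv", sep="\t"
        )

    result["patterns"].to_csv(outdir / "patterns.tsv", sep="\t")
    result["euler_counts"].to_csv(outdir / "euler_counts.tsv", sep="\t")
    result["euler_marginals"].rename("n_bound").to_csv(
        outdir / "euler_marginals.tsv", sep="\t"
    )

    for key, value in result.items():
        if key.startswith(("enrichment_", "methylation_by", "rnap_cobinding",
                           "motif_combo", "motif_colocalization")):
            if isinstance(value, pd.DataFrame):
                value.to_csv(outdir / f"{key}.tsv", sep="\t", index=False, float_format="%.6g")

    if result.get("promoter_expression") is not None:
        result["promoter_expression"].to_csv(
            outdir / "promoter_expression.tsv", sep="\t", float_format="%.6f"
        )

    hits = result.get("motif_hits") or []
    with (outdir / "motif_hits.tsv").open("w") as out:
        out.write("promoter_id\tmotif\toffset\tstrand\n")
        for h in hits:
            out.write(f"{h.promoter_id}\t{h.motif}\t{h.offset}\t{h.strand}\n")

    (outdir / "percentiles.json").write_text(
        json.dumps(result["percentiles"], indent=2, sort_keys=True) + "\n"
    )
    (outdir / "summary.json").write_text(
        json.dumps(result["summary"], indent=2, sort_keys=True) + "\n"
    )


def read_patterns(outdir: str | Path) -> pd.Series:
    df = pd.read_csv(Path(outdir) / "patterns.tsv", sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_differential_calls(outdir: str | Path) -> dict[str, pd.Series]:
    df = pd.read_csv(Path(outdir) / "differential_calls.tsv", sep="\t", index_col=0)
    return {c: df[c].dropna() for c in df.columns}


def read_binding_calls(outdir: str | Path) -> dict[str, pd.DataFrame]:
    out = {}
    for cond in ("undiff", "diff"):
        p = Path(outdir) / f"binding_calls_{cond}.tsv"
        if p.exists():
            out[cond] = pd.read_csv(p, sep="\t", index_col=0).astype(bool)
    return out


def read_binding_means(outdir: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(outdir) / "binding_means.tsv", sep="\t", index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.rsplit("_", 1)) for c in df.columns], names=["factor", "condition"]
    )
    return df


def read_methylation_calls(outdir: str | Path) -> pd.Series | None:
    p = Path(outdir) / "methylation_calls.tsv"
    if not p.exists():
        return None
    return pd.read_csv(p, sep="\t", index_col=0)["methylated"].astype(bool)


def run_all(cfg: RunConfig) -> dict:
    """Load inputs, filter, analyze and write the full report bundle."""
    logger.info("loading promoters from %s", cfg.promoters)
    catalog = read_promoters(cfg.promoters)
    sequences = read_sequences(cfg.sequences)

    if cfg.apply_filters:
        logger.info("applying promoter filters to %d promoters", len(catalog))
        catalog, report = apply_promoter_filters(catalog, sequences)
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(Path(cfg.outdir) / "filter_report.json")
        write_promoters_bed(catalog, Path(cfg.outdir) / "retained_promoters.bed")

    logger.info("loading tracks from %s", cfg.tracks_dir)
    tracks = load_tracks(cfg.tracks_dir)
    expression = None
    if cfg.expression is not None:
        expression = expression_mapping.read_expression_table(cfg.expression)
    motifs = load_motif_table(cfg.motifs) if cfg.motifs else None

    result = analyze(
        catalog,
        sequences,
        tracks,
        expression=expression,
        thresholds=cfg.thresholds,
        factor_set=tuple(cfg.factor_set),
        motifs=motifs,
    )
    write_outputs(result, cfg.outdir)
    logger.info("wrote outputs to %s", cfg.outdir)
    return result["summary"]


def analyze_bundle(
    bundle: DatasetBundle,
    truth: pd.DataFrame | None = None,
    factor_set: Sequence[str] = DEFAULT_FACTOR_SET,
    drop_decoys: bool = True,
) -> dict:
    """Analyze an in-memory synthetic bundle (fast path, no file IO).

    With ``drop_decoys`` the catalog is restricted to non-decoy promoters
    (what the exclusion filters would retain) using the truth table.
    """
    catalog = bundle.catalog
    if drop_decoys and truth is not None and len(truth):
        keep = set(truth.index[truth["decoy"] == ""])
        catalog = [p for p in catalog if p.promoter_id in keep]
    return analyze(
        catalog,
        bundle.sequences,
        bundle.tracks,
        expression=bundle.expression,
        thresholds=bundle.config.thresholds,
        factor_set=factor_set,
    )
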