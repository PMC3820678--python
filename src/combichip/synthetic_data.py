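"""Seeded generator for complete, truth-tagged dataset bundles.

Emits promoters (BED), sequences (FASTA), probe-level enrichment tracks
(bedGraph) for every factor x condition x replicate, an expression table and
a truth table, with planted occupancy patterns, differential statuses,
methylation labels and consensus motifs so the whole pipeline is testable
offline with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from combichip.combinatorial_enrichment import (
    DEFAULT_FACTOR_SET,
    all_pattern_labels,
)
from combichip.motif_analysis import (
    CONSENSUS_MOTIFS,
    MOTIF_FOR_FACTOR,
    MotifPattern,
    default_motifs,
)
from combichip.occupancy_signals import (
    CONDITIONS,
    FACTORS,
    INDUCED,
    REPRESSED,
    UNCHANGED,
    SignalTrack,
    ThresholdConfig,
)
from combichip.promoter_catalog import (
    REGION_LENGTH,
    UPSTREAM,
    PromoterRecord,
    make_promoter,
    write_promoters_bed,
)

_LABELS = all_pattern_labels(DEFAULT_FACTOR_SET)

#: pattern prevalences (sum to 1) over none/CREB/CEBPB/CJUN/CREB+CEBPB/
#: CREB+CJUN/CEBPB+CJUN/CREB+CEBPB+CJUN
DEFAULT_PREVALENCE = {
    "none": 0.55,
    "CREB": 0.12,
    "CEBPB": 0.08,
    "CJUN": 0.05,
    "CREB+CEBPB": 0.05,
    "CREB+CJUN": 0.04,
    "CEBPB+CJUN": 0.06,
    "CREB+CEBPB+CJUN": 0.05,
}

# Per-pattern induction probabilities chosen so the universe-wide rate is
# exactly 0.04 and the CEBPB+CJUN group fraction 0.20 gives a planted
# enrichment ratio of exactly 5.0 (CREB-bound groups are depleted, the
# groups lacking CREB are elevated).
DEFAULT_INDUCTION = {
    "none": 0.03,
    "CREB": 0.01,
    "CEBPB": 0.08,
    "CJUN": 0.05,
    "CREB+CEBPB": 0.01,
    "CREB+CJUN": 0.01,
    "CEBPB+CJUN": 0.20,
    "CREB+CEBPB+CJUN": 0.01,
}

DEFAULT_REPRESSION = {
    "none": 0.05,
    "CREB": 0.08,
    "CEBPB": 0.03,
    "CJUN": 0.04,
    "CREB+CEBPB": 0.06,
    "CREB+CJUN": 0.06,
    "CEBPB+CJUN": 0.02,
    "CREB+CEBPB+CJUN": 0.04,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic bundle; the seed is mandatory."""

    seed: int
    n_promoters: int = 20_000
    probes_per_promoter: int = 15
    replicates: int = 2
    bound_effect: float = 0.8
    baseline: float = 0.0
    probe_noise_sd: float = 0.25
    pattern_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    induction_prob: dict = field(default_factory=lambda: dict(DEFAULT_INDUCTION))
    repression_prob: dict = field(default_factory=lambda: dict(DEFAULT_REPRESSION))
    meth_prob_creb_bound: float = 0.10
    meth_prob_creb_unbound: float = 0.45
    motif_plant_prob: float = 0.6
    expr_mapped_prob: float = 0.9
    expr_two_row_prob: float = 0.1
    perturb_background_prob: float = 0.05
    perturb_target_prob: float = 0.35
    sex_decoy_frac: float = 0.0
    nrun_decoy_frac: float = 0.0
    dup_decoy_count: int = 0
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = (
            list(self.pattern_prevalence.values())
            + list(self.induction_prob.values())
            + list(self.repression_prob.values())
            + [
                self.meth_prob_creb_bound,
                self.meth_prob_creb_unbound,
                self.motif_plant_prob,
                self.expr_mapped_prob,
                self.expr_two_row_prob,
                self.perturb_background_prob,
                self.perturb_target_prob,
                self.sex_decoy_frac,
                self.nrun_decoy_frac,
            ]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        total = sum(self.pattern_prevalence.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"pattern prevalences must sum to 1, got {total}")
        if set(self.pattern_prevalence) != set(_LABELS):
            raise ValueError(f"pattern prevalence must cover exactly {sorted(_LABELS)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            data["seed"] = seed
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr:
            bind = thr.pop("bind_thresholds", {})
            tc = ThresholdConfig(**thr)
            tc.bind_thresholds.update(bind)
            cfg.thresholds = tc
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k != "thresholds"
        }
        data["thresholds"] = {
            "bind_thresholds": dict(self.thresholds.bind_thresholds),
            "rnap_level": self.thresholds.rnap_level,
            "rnap_delta": self.thresholds.rnap_delta,
            "h3k9ac_level": self.thresholds.h3k9ac_level,
            "h3k9ac_delta": self.thresholds.h3k9ac_delta,
            "mrna_log2fc": self.thresholds.mrna_log2fc,
            "medip_threshold": self.thresholds.medip_threshold,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class DatasetBundle:
    """In-memory synthetic dataset: catalog, sequences, tracks, expression."""

    catalog: list
    sequences: dict
    tracks: list
    expression: pd.DataFrame
    config: SyntheticConfig


def _motif_window(motif_index: int, motif_len: int, rng: np.random.Generator) -> int:
    """Offset (relative to TSS) inside the motif's reserved -500..0 subwindow.

    Each consensus motif plants into its own third of the window so plants
    never overwrite each other.
    """
    lo = -500 + motif_index * 167
    hi = min(lo + 167, 0)
    if hi - motif_len < lo:
        raise ValueError(f"plant window too small for motif of length {motif_len}")
    return int(rng.integers(lo, hi - motif_len + 1))


def _instantiate(motif: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(
        sorted(pos)[0] if len(pos) == 1 else sorted(pos)[rng.integers(len(pos))]
        for pos in motif.positions
    )


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def plant_motifs(
    sequence: str,
    bound_factors: Sequence[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, int, str]]]:
    """Insert the consensus motif of each bound factor into -500..0.

    Each insertion happens with probability ``cfg.motif_plant_prob``; the
    instantiated motif (or its reverse complement, random strand) overwrites
    the sequence at a recorded TSS-relative offset.  Returns the new
    sequence and ``(motif_name, offset, strand)`` records.
    """
    motifs = {m.name: m for m in default_motifs()}
    buf = bytearray(sequence.encode())
    plants: list[tuple[str, int, str]] = []
    planted_names: set[str] = set()
    tss = len(sequence) - (REGION_LENGTH - UPSTREAM)
    for factor in bound_factors:
        name = MOTIF_FOR_FACTOR.get(factor)
        if name is None or name in planted_names:
            continue
        if rng.random() >= cfg.motif_plant_prob:
            continue
        motif = motifs[name]
        offset = _motif_window(CONSENSUS_MOTIFS.index(name), len(motif), rng)
        instance = _instantiate(motif, rng)
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            instance = instance.translate(_RC_TABLE)[::-1]
        start = tss + offset
        buf[start : start + len(instance)] = instance.encode()
        plants.append((name, offset, strand))
        planted_names.add(name)
    return buf.decode(), plants


def _draw_statuses(
    rng: np.random.Generator,
    labels: np.ndarray,
    induction: Mapping[str, float],
    repression: Mapping[str, float],
) -> np.ndarray:
    p_ind = np.array([induction[lab] for lab in labels])
    p_rep = np.array([repression[lab] for lab in labels])
    u = rng.random(len(labels))
    out = np.full(len(labels), UNCHANGED, dtype=object)
    out[u < p_ind] = INDUCED
    out[(u >= p_ind) & (u < p_ind + p_rep)] = REPRESSED
    return out


def generate_dataset(cfg: SyntheticConfig) -> tuple[DatasetBundle, pd.DataFrame]:
    """Generate a full truth-tagged bundle, deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_promoters
    n_sex = int(round(cfg.sex_decoy_frac * n))
    n_nrun = int(round(cfg.nrun_decoy_frac * n))
    n_dup = int(cfg.dup_decoy_count)
    total = n + n_nrun + n_dup + n_sex

    decoy = np.array(
        [""] * n + ["nrun"] * n_nrun + ["dup"] * n_dup + ["sex"] * n_sex, dtype=object
    )
    pids = np.array([f"p{i:05d}" for i in range(total)], dtype=object)

    # genomic layout: autosomes for everything except sex decoys
    chroms = np.empty(total, dtype=object)
    tss = np.empty(total, dtype=np.int64)
    auto_i = 0
    sex_i = 0
    for i in range(total):
        if decoy[i] == "sex":
            chroms[i] = "chrX" if sex_i % 2 == 0 else "chrY"
            tss[i] = 1_000_000 + (sex_i // 2) * 10_000
            sex_i += 1
        else:
            chroms[i] = _AUTOSOMES[auto_i % len(_AUTOSOMES)]
            tss[i] = 1_000_000 + (auto_i // len(_AUTOSOMES)) * 10_000
            auto_i += 1
    strands = np.where(rng.integers(2, size=total) == 0, "+", "-").astype(object)

    # occupancy patterns: decoys are all-unbound
    label_idx = rng.choice(len(_LABELS), size=n, p=[cfg.pattern_prevalence[l] for l in _LABELS])
    labels = np.array(
        [_LABELS[j] for j in label_idx] + ["none"] * (total - n), dtype=object
    )
    bound = {
        f: np.array([f in lab.split("+") for lab in labels], dtype=bool)
        for f in DEFAULT_FACTOR_SET
    }
    bound["CEBPA"] = np.where(
        bound["CEBPB"], rng.random(total) < 0.5, rng.random(total) < 0.02
    )

    rnap_status = _draw_statuses(rng, labels, cfg.induction_prob, cfg.repression_prob)
    mrna_status = _draw_statuses(rng, labels, cfg.induction_prob, cfg.repression_prob)
    h3k9ac_status = _draw_statuses(rng, labels, cfg.induction_prob, cfg.repression_prob)
    methylated = rng.random(total) < np.where(
        bound["CREB"], cfg.meth_prob_creb_bound, cfg.meth_prob_creb_unbound
    )

    # sequences: i.i.d. uniform ACGT, then motif plants and decoy edits
    seq_arr = _BASES[rng.integers(0, 4, size=(total, REGION_LENGTH))]
    sequences: dict[str, str] = {}
    planted: list[str] = []
    for i in range(total):
        seq = seq_arr[i].tobytes().decode("ascii")
        on = [f for f in DEFAULT_FACTOR_SET if bound[f][i]]
        plants: list[tuple[str, int, str]] = []
        if on and decoy[i] == "":
            seq, plants = plant_motifs(seq, on, cfg, rng)
        sequences[pids[i]] = seq
        planted.append(";".join(f"{m}:{o}:{s}" for m, o, s in plants))
    if n_nrun:
        for i in range(n, n + n_nrun):
            s = sequences[pids[i]]
            sequences[pids[i]] = s[:100] + "N" * 161 + s[261:]
    if n_dup:
        block = _BASES[rng.integers(0, 4, size=150)].tobytes().decode("ascii")
        for i in range(n + n_nrun, n + n_nrun + n_dup):
            s = sequences[pids[i]]
            sequences[pids[i]] = s[:200] + block + s[350:]

    catalog = [
        make_promoter(
            pids[i],
            chroms[i],
            strands[i],
            int(tss[i]),
            gene_ids=(f"gene{i:05d}", f"AK{i:06d}", f"Mm.{i}"),
        )
        for i in range(total)
    ]

    # per-factor per-condition true promoter means
    eff = cfg.bound_effect
    base = cfg.baseline
    rnap_high = cfg.thresholds.rnap_level + cfg.thresholds.rnap_delta + 0.1
    h3_high = cfg.thresholds.h3k9ac_level + cfg.thresholds.h3k9ac_delta + 0.1
    rnap_base = np.where(
        rng.random(total) < np.where(bound["CREB"], 0.9, 0.5), rnap_high, base
    )
    h3_base = np.where(rng.random(total) < 0.5, h3_high, base)
    medip_mean = np.where(methylated, cfg.thresholds.medip_threshold + 0.4, base)

    def differential_means(status, high, baseline_arr):
        undiff = np.where(
            status == INDUCED, base, np.where(status == REPRESSED, high, baseline_arr)
        )
        diff = np.where(
            status == INDUCED, high, np.where(status == REPRESSED, base, baseline_arr)
        )
        return undiff, diff

    rnap_undiff, rnap_diff = differential_means(rnap_status, rnap_high, rnap_base)
    h3_undiff, h3_diff = differential_means(h3k9ac_status, h3_high, h3_base)
    means = {}
    for f in ("CREB", "CEBPB", "CEBPA", "CJUN"):
        tf_mean = np.where(bound[f], base + eff, base)
        means[(f, "undiff")] = tf_mean
        means[(f, "diff")] = tf_mean
    means[("RNAP", "undiff")] = rnap_undiff
    means[("RNAP", "diff")] = rnap_diff
    means[("H3K9AC", "undiff")] = h3_undiff
    means[("H3K9AC", "diff")] = h3_diff
    means[("MEDIP", "undiff")] = medip_mean
    means[("MEDIP", "diff")] = medip_mean

    # fixed probe layout shared by all tracks (like a real array design)
    probes = cfg.probes_per_promoter
    offsets = rng.integers(0, REGION_LENGTH, size=(total, probes))
    region_start = np.array([p.region_start for p in catalog], dtype=np.int64)
    pos_flat = (region_start[:, None] + offsets).reshape(-1)
    chrom_flat = np.repeat(chroms, probes)

    tracks: list[SignalTrack] = []
    for f in FACTORS:
        for cond in CONDITIONS:
            for rep in range(1, cfg.replicates + 1):
                noise = rng.normal(0.0, cfg.probe_noise_sd, size=(total, probes))
                values = (means[(f, cond)][:, None] + noise).reshape(-1)
                tracks.append(
                    SignalTrack(
                        factor=f,
                        condition=cond,
                        replicate=rep,
                        chrom=chrom_flat,
                        pos=pos_flat,
                        value=values,
                    )
                )

    expression = _make_expression(cfg, rng, pids, labels, bound, methylated, mrna_status, decoy)

    truth = pd.DataFrame(
        {
            "pattern": labels,
            **{f"bound_{f}": bound[f] for f in ("CREB", "CEBPB", "CEBPA", "CJUN")},
            "rnap_status": rnap_status,
            "mrna_status": mrna_status,
            "h3k9ac_status": h3k9ac_status,
            "methylated": methylated,
            "decoy": decoy,
            "planted_motifs": planted,
        },
        index=pd.Index(pids, name="promoter_id"),
    )
    bundle = DatasetBundle(
        catalog=catalog,
        sequences=sequences,
        tracks=tracks,
        expression=expression,
        config=cfg,
    )
    return bundle, truth


def _make_expression(cfg, rng, pids, labels, bound, methylated, mrna_status, decoy):
    total = len(pids)
    clean = decoy == ""
    mapped = (rng.random(total) < cfg.expr_mapped_prob) & clean
    two_rows = rng.random(total) < cfg.expr_two_row_prob
    base_expr = rng.normal(6.0, 1.5, size=total)
    fc_ind = 0.8 + np.abs(rng.normal(0.0, 0.3, size=total))
    fc_unch = np.clip(rng.normal(0.0, 0.15, size=total), -0.45, 0.45)
    fc = np.where(
        mrna_status == INDUCED, fc_ind, np.where(mrna_status == REPRESSED, -fc_ind, fc_unch)
    )
    expr_undiff = base_expr
    expr_diff = base_expr + fc

    not_creb = ~bound["CREB"]
    target_acebp = bound["CEBPB"] & not_creb
    target_afos = bound["CJUN"] & not_creb
    target_aza = (bound["CEBPB"] | bound["CJUN"]) & not_creb & methylated

    def perturb_fc(target):
        p = np.where(target, cfg.perturb_target_prob, cfg.perturb_background_prob)
        hit = rng.random(total) < p
        down = -(0.8 + np.abs(rng.normal(0.0, 0.2, size=total)))
        flat = np.clip(rng.normal(0.0, 0.15, size=total), -0.45, 0.45)
        return np.where(hit, down, flat)

    expr_control = expr_diff + rng.normal(0.0, 0.05, size=total)
    expr_acebp = expr_control + perturb_fc(target_acebp)
    expr_afos = expr_control + perturb_fc(target_afos)
    expr_aza = expr_control + perturb_fc(target_aza)

    value_mat = np.column_stack(
        [expr_undiff, expr_diff, expr_acebp, expr_afos, expr_aza, expr_control]
    )
    value_cols = ["expr_undiff", "expr_diff", "expr_acebp", "expr_afos", "expr_5aza", "expr_control"]
    jitter_a = rng.normal(0.0, 0.05, size=value_mat.shape)
    jitter_b = rng.normal(0.0, 0.05, size=value_mat.shape)

    rows = []
    for i in np.flatnonzero(mapped):
        vals_a = value_mat[i] + jitter_a[i]
        rows.append(
            {
                "row_id": f"r{i:05d}a",
                "genbank": f"AK{i:06d}",
                "symbol": f"gene{i:05d}",
                "unigene_cluster": f"Mm.{i}",
                "unigene_id": f"Mm.{i}",
                **dict(zip(value_cols, vals_a)),
            }
        )
        if two_rows[i]:
            vals_b = value_mat[i] + jitter_b[i]
            rows.append(
                {
                    "row_id": f"r{i:05d}b",
                    "genbank": f"AK{i:06d}",
                    "symbol": "",
                    "unigene_cluster": "",
                    "unigene_id": "",
                    **dict(zip(value_cols, vals_b)),
                }
            )
    columns = ["row_id", "genbank", "symbol", "unigene_cluster", "unigene_id"] + value_cols
    return pd.DataFrame(rows, columns=columns)


def write_bundle(
    bundle: DatasetBundle, truth: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Write the bundle as plain-text files; byte-identical for a given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    bed = outdir / "promoters.bed"
    write_promoters_bed(bundle.catalog, bed)
    paths["promoters"] = bed

    fasta = outdir / "sequences.fa"
    with fasta.open("w") as out:
        for p in bundle.catalog:
            seq = bundle.sequences[p.promoter_id]
            out.write(f">{p.promoter_id}\n")
            for j in range(0, len(seq), 80):
                out.write(seq[j : j + 80] + "\n")
    paths["sequences"] = fasta

    for tr in bundle.tracks:
        tp = outdir / "tracks" / f"{tr.factor}_{tr.condition}_rep{tr.replicate}.bedGraph"
        tr.to_bedgraph(tp)
    paths["tracks_dir"] = outdir / "tracks"

    expr = outdir / "expression.tsv"
    bundle.expression.to_csv(expr, sep="\t", index=False, float_format="%.4f")
    paths["expression"] = expr

    tt = outdir / "truth.tsv"
    truth.to_csv(tt, sep="\t", float_format="%.4f")
    paths["truth"] = tt

    cfgp = outdir / "config.yaml"
    bundle.config.to_yaml(cfgp)
    paths["config"] = cfgp
    return paths
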