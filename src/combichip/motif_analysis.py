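"""Degenerate consensus-motif scanning and combination enrichment.

Patterns use IUPAC one-letter codes plus an ``(X/Y)`` alternation form and
lowercase ``n`` spacers.  Scanning covers both strands of a window upstream
of the TSS (default -500..0); sequence N never matches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from combichip.combinatorial_enrichment import chi_square_gof
from combichip.promoter_catalog import DOWNSTREAM, UPSTREAM, PromoterSequence

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-500, 0)

#: consensus and composite motifs shipped by default (name, pattern)
DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("CRE", "TGACGTCA"),
    ("CEBP", "TTGCGCAA"),
    ("TRE", "TGA(C/G)TCA"),
    ("ZFP143_RBPJ", "ACTACAnnTCCCA"),
    ("CEBP_JUN_LONG", "CCCACCATGCTTTGGTCA"),
    ("CEBP_JUN_LONG_ALT", "CCCACCATGCTTTTGGTCA"),
    ("CEBP_JUN_SHORT", "GACAAGTT(T/A)GGTCA"),
)

#: the three factor-consensus motif names used for combination statistics
CONSENSUS_MOTIFS = ("CRE", "CEBP", "TRE")

#: which factor each consensus motif corresponds to
MOTIF_FOR_FACTOR = {"CREB": "CRE", "CEBPB": "CEBP", "CEBPA": "CEBP", "CJUN": "TRE"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Biopython's table maps 'X' to GATC; the printed pattern notation has no X,
# so only the standard degenerate letters are accepted here.
_IUPAC = {k: v for k, v in ambiguous_dna_values.items() if k != "X"}


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern: one allowed-base set per position."""

    name: str
    pattern: str
    positions: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def reverse_complement(self) -> "MotifPattern":
        rc = tuple(
            frozenset(_COMPLEMENT[b] for b in pos) for pos in reversed(self.positions)
        )
        return MotifPattern(name=self.name, pattern=f"revcomp({self.pattern})", positions=rc)

    def is_palindromic(self) -> bool:
        return self.positions == self.reverse_complement().positions


@dataclass(frozen=True)
class MotifHit:
    """A stranded motif match; offset is the leftmost base relative to the TSS."""

    promoter_id: str
    motif: str
    offset: int
    strand: str


def compile_pattern(text: str, name: str = "") -> MotifPattern:
    """Compile a pattern string into positional base sets.

    Supports IUPAC codes (``R`` -> {A,G} etc.), ``(C/G)``-style alternation
    and ``n``/``N`` wildcards.
    """
    positions: list[frozenset] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            close = text.find(")", i)
            if close == -1:
                raise ValueError(f"pattern {text!r}: unbalanced parenthesis at {i}")
            alts = text[i + 1 : close].split("/")
            bases = set()
            for a in alts:
                a = a.strip().upper()
                if a not in {"A", "C", "G", "T"}:
                    raise ValueError(f"pattern {text!r}: invalid alternation base {a!r}")
                bases.add(a)
            if not bases:
                raise ValueError(f"pattern {text!r}: empty alternation")
            positions.append(frozenset(bases))
            i = close + 1
        elif ch == ")":
            raise ValueError(f"pattern {text!r}: unbalanced parenthesis at {i}")
        else:
            code = ch.upper()
            if code not in _IUPAC:
                raise ValueError(f"pattern {text!r}: invalid letter {ch!r} at {i}")
            positions.append(frozenset(_IUPAC[code]))
            i += 1
    if not positions:
        raise ValueError("empty pattern")
    return MotifPattern(name=name or text, pattern=text, positions=tuple(positions))


def _to_regex(motif: MotifPattern) -> re.Pattern:
    # lookahead so overlapping matches are all reported; N never matches
    body = "".join("[" + "".join(sorted(pos)) + "]" for pos in motif.positions)
    return re.compile(f"(?={body})")


def scan_window(seq: str, motif: MotifPattern) -> list[tuple[int, str]]:
    """All stranded matches of a motif in a raw sequence window.

    Returns ``(start_index, strand)`` pairs; a position matching on both
    strands (palindrome) is reported once with strand ``+``.
    """
    seq = seq.upper()
    fwd = {m.start() for m in _to_regex(motif).finditer(seq)}
    rc = motif.reverse_complement()
    rev = {m.start() for m in _to_regex(rc).finditer(seq)}
    hits = [(i, "+") for i in fwd]
    hits.extend((i, "-") for i in rev - fwd)
    return sorted(hits)


def scan_promoter(
    seq: PromoterSequence | tuple[str, str],
    motif: MotifPattern,
    window: tuple[int, int] = DEFAULT_WINDOW,
    tss_index: int | None = None,
) -> list[MotifHit]:
    """Scan one promoter sequence for a motif within a TSS-relative window.

    ``seq`` covers -1000..+500 around the TSS on the promoter strand (the TSS
    sits at index 1000 unless ``tss_index`` overrides it).  Only matches fully
    inside ``[window[0], window[1])`` are reported, on either strand.
    """
    if isinstance(seq, PromoterSequence):
        pid, s = seq.promoter_id, seq.sequence
    else:
        pid, s = seq
    if tss_index is None:
        tss_index = UPSTREAM
    w0, w1 = window
    if w0 >= w1:
        raise ValueError(f"empty window {window}")
    if w0 < -tss_index or w1 > len(s) - tss_index:
        raise ValueError(
            f"window {window} outside promoter region [-{tss_index}, {len(s) - tss_index})"
        )
    sub = s[tss_index + w0 : tss_index + w1]
    hits = []
    for start, strand in scan_window(sub, motif):
        if start + len(motif) <= len(sub):
            hits.append(
                MotifHit(promoter_id=pid, motif=motif.name, offset=w0 + start, strand=strand)
            )
    return hits


def scan_catalog(
    sequences: Mapping[str, str] | Sequence[PromoterSequence],
    motifs: Sequence[MotifPattern],
    window: tuple[int, int] = DEFAULT_WINDOW,
    tss_index: int | None = None,
) -> list[MotifHit]:
    """Scan every promoter for every motif."""
    if not isinstance(sequences, Mapping):
        sequences = {s.promoter_id: s.sequence for s in sequences}
    hits: list[MotifHit] = []
    for pid, s in sequences.items():
        for motif in motifs:
            hits.extend(scan_promoter((pid, s), motif, window=window, tss_index=tss_index))
    return hits


def motif_presence(
    hits: Iterable[MotifHit],
    universe: Sequence[str],
    motif_names: Sequence[str],
) -> pd.DataFrame:
    """Boolean promoter x motif presence matrix over a promoter universe."""
    table = pd.DataFrame(
        False, index=pd.Index(universe, name="promoter_id"), columns=list(motif_names)
    )
    for h in hits:
        if h.promoter_id in table.index and h.motif in table.columns:
            table.loc[h.promoter_id, h.motif] = True
    return table


@dataclass(frozen=True)
class ComboEnrichmentResult:
    pattern: str
    combo: tuple
    n_group: int
    n_with_combo: int
    fraction: float
    background_fraction: float
    enrichment: float
    chi2: float
    p_value: float


def combo_enrichment(
    presence: pd.DataFrame,
    patterns: pd.Series,
    group_label: str,
    combo: Sequence[str],
    exclusive: bool = True,
    all_motifs: Sequence[str] = CONSENSUS_MOTIFS,
) -> ComboEnrichmentResult:
    """Enrichment of a motif combination in one occupancy group.

    A promoter carries the combination when it contains every motif in
    ``combo``; with ``exclusive=True`` ("containing only") it must also lack
    the remaining motifs of ``all_motifs``.  Enrichment is the in-group
    fraction over the all-promoter fraction, with a 2-cell chi-square p.
    """
    universe = presence.index.intersection(patterns.index)
    pres = presence.loc[universe]
    pat = patterns.loc[universe]
    has = pres[list(combo)].all(axis=1)
    if exclusive:
        others = [m for m in all_motifs if m not in combo]
        if others:
            has &= ~pres[others].any(axis=1)
    group = pat.index[pat == group_label]
    n_group = len(group)
    if n_group == 0:
        logger.warning("empty group %r for combo enrichment", group_label)
        return ComboEnrichmentResult(
            group_label, tuple(combo), 0, 0, float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"),
        )
    n_with = int(has.loc[group].sum())
    fraction = n_with / n_group
    background = float(has.mean())
    enrichment = fraction / background if background > 0 else (0.0 if fraction == 0 else float("nan"))
    chi2 = p = float("nan")
    if 0 < background < 1:
        chi2, p = chi_square_gof(
            [n_with, n_group - n_with],
            [n_group * background, n_group * (1 - background)],
        )
    return ComboEnrichmentResult(
        pattern=group_label,
        combo=tuple(combo),
        n_group=n_group,
        n_with_combo=n_with,
        fraction=fraction,
        background_fraction=background,
        enrichment=enrichment,
        chi2=chi2,
        p_value=p,
    )


def colocalization_ratio(
    presence: pd.DataFrame,
    pair: Sequence[str],
    group_ids: Sequence[str],
    universe_ids: Sequence[str] | None = None,
) -> float:
    """Group co-occurrence rate of a motif pair over the universe rate.

    ``(co-occurring in group / group size) / (co-occurring in universe /
    universe size)``; NaN (flagged) when the universe has no co-occurrence.
    """
    if universe_ids is None:
        universe_ids = presence.index
    universe_ids = pd.Index(universe_ids)
    group_ids = pd.Index(group_ids)
    if len(group_ids) == 0 or len(universe_ids) == 0:
        raise ValueError("group and universe must be nonempty")
    co = presence[list(pair)].all(axis=1)
    group_rate = float(co.loc[group_ids].mean())
    universe_rate = float(co.loc[universe_ids].mean())
    if universe_rate == 0:
        logger.warning("no universe co-occurrence for pair %s", tuple(pair))
        return float("nan")
    return group_rate / universe_rate


def load_motif_table(path: str | Path) -> list[MotifPattern]:
    """Load motifs from a plain-text table: ``name<TAB>pattern`` per line."""
    motifs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected name<TAB>pattern")
        motifs.append(compile_pattern(parts[1], name=parts[0]))
    return motifs


def default_motifs() -> list[MotifPattern]:
    """The built-in consensus / composite motif set, compiled."""
    return [compile_pattern(p, name=n) for n, p in DEFAULT_MOTIFS]


def write_motif_table(path: str | Path, motifs: Iterable[tuple[str, str]] = DEFAULT_MOTIFS) -> None:
    with Path(path).open("w") as out:
        out.write("# name\tpattern\n")
        for name, pattern in motifs:
            out.write(f"{name}\t{pattern}\n")
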