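"""Promoter catalog: TSS-anchored regions, sequences and exclusion filters.

The analysis universe is built from a BED6 promoter definition file and a
FASTA of promoter-strand sequences.  Promoters are excluded when they sit on
a sex chromosome, contain a long unsequenced (N) run, or share a long exact
sequence window with many other promoters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: region geometry relative to the TSS, in bp
UPSTREAM = 1000
DOWNSTREAM = 500
REGION_LENGTH = UPSTREAM + DOWNSTREAM

#: chromosome names excluded as sex chromosomes (matched case-insensitively)
SEX_CHROMOSOMES = frozenset({"chrx", "chry", "x", "y"})

#: default duplicated-window parameters: an exact 150-mer shared with >=10 others
DUP_WINDOW = 150
DUP_MIN_OTHER = 10

#: N runs strictly longer than this many bp exclude a promoter
MAX_N_RUN = 150

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_MINUS_STRANDS = {"-", "−"}  # accept both ASCII hyphen and unicode minus


@dataclass(frozen=True)
class PromoterRecord:
    """A TSS-anchored, strand-aware promoter interval.

    Coordinates are 0-based half-open.  The region spans -1000..+500 around
    the TSS *on the promoter strand*: for a ``+`` promoter it is
    ``[tss - 1000, tss + 500)``; for a ``-`` promoter the genomic interval is
    mirrored so the same relative window is covered.
    """

    promoter_id: str
    chrom: str
    strand: str
    tss: int
    region_start: int
    region_end: int
    gene_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"promoter {self.promoter_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.region_end - self.region_start != REGION_LENGTH:
            raise ValueError(
                f"promoter {self.promoter_id!r}: region length "
                f"{self.region_end - self.region_start} != {REGION_LENGTH}"
            )


@dataclass(frozen=True)
class PromoterSequence:
    """Promoter-strand sequence over the ACGTN alphabet."""

    promoter_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(
                f"promoter {self.promoter_id!r}: invalid characters {bad} in sequence"
            )


@dataclass
class FilterReport:
    """Accounting of the promoter exclusion rules.

    Per-rule exclusion sets may overlap; ``n_retained`` counts each promoter
    once (input minus the union of the exclusion sets).
    """

    n_input: int
    n_excluded_sex: int
    n_excluded_unsequenced: int
    n_excluded_duplicated: int
    n_retained: int
    excluded_sex: frozenset
    excluded_unsequenced: frozenset
    excluded_duplicated: frozenset

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_sex": self.n_excluded_sex,
            "n_excluded_unsequenced": self.n_excluded_unsequenced,
            "n_excluded_duplicated": self.n_excluded_duplicated,
            "n_retained": self.n_retained,
            "excluded_sex": sorted(self.excluded_sex),
            "excluded_unsequenced": sorted(self.excluded_unsequenced),
            "excluded_duplicated": sorted(self.excluded_duplicated),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def make_promoter(
    promoter_id: str,
    chrom: str,
    strand: str,
    tss: int,
    gene_ids: Iterable[str] = (),
) -> PromoterRecord:
    """Build a :class:`PromoterRecord` deriving the -1000..+500 region."""
    if strand in _MINUS_STRANDS:
        strand = "-"
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM
    elif strand == "-":
        # mirror image: upstream extends to higher coordinates
        start, end = tss + 1 - DOWNSTREAM, tss + 1 + UPSTREAM
    else:
        raise ValueError(f"promoter {promoter_id!r}: missing or invalid strand {strand!r}")
    return PromoterRecord(
        promoter_id=promoter_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        region_start=start,
        region_end=end,
        gene_ids=frozenset(gene_ids),
    )


def read_promoters(path: str | Path) -> list[PromoterRecord]:
    """Read promoter definitions from a BED6 file.

    The BED ``start`` field is taken as the TSS.  The ``name`` field holds the
    promoter id, optionally followed by ``|``-separated gene identifiers
    (symbol / accession / UniGene), e.g. ``p0001|Krt10|AK012345``.

    Raises
    ------
    ValueError
        On malformed lines (with the line number), missing strand, or
        duplicate promoter ids.
    """
    path = Path(path)
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, start_s, _end_s, name, _score, strand = fields[:6]
            try:
                tss = int(start_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer start {start_s!r}") from exc
            if strand not in {"+", "-"} and strand not in _MINUS_STRANDS:
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            tokens = name.split("|")
            promoter_id, gene_ids = tokens[0], tokens[1:]
            if promoter_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate promoter id {promoter_id!r}")
            seen.add(promoter_id)
            records.append(make_promoter(promoter_id, chrom, strand, tss, gene_ids))
    return records


def longest_unsequenced_run(seq: PromoterSequence | str) -> int:
    """Length of the longest maximal run of N in a promoter sequence."""
    if isinstance(seq, PromoterSequence):
        s = seq.sequence
    else:
        s = seq
        if not _VALID_SEQ.match(s):
            bad = sorted(set(s) - set("ACGTN"))
            raise ValueError(f"invalid characters {bad} in sequence")
    if not s:
        raise ValueError("empty sequence")
    best = 0
    for run in re.finditer(r"N+", s):
        best = max(best, run.end() - run.start())
    return best


_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp_bytes(s: bytes) -> bytes:
    return s.translate(_RC)[::-1]


def duplicated_window_index(
    sequences: Mapping[str, str] | Sequence[PromoterSequence],
    window: int = DUP_WINDOW,
    min_other: int = DUP_MIN_OTHER,
) -> set[str]:
    """Promoters sharing an exact length-``window`` substring with many others.

    A promoter is flagged when any of its length-``window`` windows (on either
    strand; windows containing N are skipped as unsequenced) occurs in at
    least ``min_other`` *other* promoters.  Exact 150-mer hashing at stride 1,
    canonicalized over strands; deterministic and order-independent.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    items: list[tuple[str, str]]
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(s.promoter_id, s.sequence) for s in sequences]
    for pid, s in items:
        if len(s) < window:
            raise ValueError(
                f"promoter {pid!r}: sequence length {len(s)} shorter than window {window}"
            )
    # canonical window -> distinct promoters carrying it
    owners: dict[bytes, set[str]] = {}
    for pid, s in items:
        fwd = s.upper().encode()
        rev = _revcomp_bytes(fwd)
        n = len(fwd)
        local: set[bytes] = set()
        for i in range(n - window + 1):
            k = fwd[i : i + window]
            if b"N" in k:
                continue
            r = rev[n - window - i : n - i]
            local.add(k if k <= r else r)
        for key in local:
            owners.setdefault(key, set()).add(pid)
    flagged: set[str] = set()
    for pids in owners.values():
        if len(pids) >= min_other + 1:
            flagged.update(pids)
    return flagged


def apply_promoter_filters(
    catalog: Sequence[PromoterRecord],
    sequences: Mapping[str, str] | Sequence[PromoterSequence],
    max_n_run: int = MAX_N_RUN,
    dup_window: int = DUP_WINDOW,
    dup_min_other: int = DUP_MIN_OTHER,
) -> tuple[list[PromoterRecord], FilterReport]:
    """Apply the three exclusion rules and return retained promoters + report.

    Rules: (1) sex-chromosome location; (2) an unsequenced (N) run strictly
    longer than ``max_n_run`` bp; (3) an exact ``dup_window``-bp window shared
    with >= ``dup_min_other`` other promoters.
    """
    if not isinstance(sequences, Mapping):
        sequences = {s.promoter_id: s.sequence for s in sequences}
    missing = [p.promoter_id for p in catalog if p.promoter_id not in sequences]
    if missing:
        raise KeyError(f"promoters lacking sequence: {missing[:5]}" +
                       (" ..." if len(missing) > 5 else ""))

    sex = {p.promoter_id for p in catalog if p.chrom.lower() in SEX_CHROMOSOMES}
    unseq = {
        p.promoter_id
        for p in catalog
        if longest_unsequenced_run(sequences[p.promoter_id]) > max_n_run
    }
    catalog_seqs = {p.promoter_id: sequences[p.promoter_id] for p in catalog}
    dup = duplicated_window_index(catalog_seqs, window=dup_window, min_other=dup_min_other)

    excluded = sex | unseq | dup
    retained = [p for p in catalog if p.promoter_id not in excluded]
    report = FilterReport(
        n_input=len(catalog),
        n_excluded_sex=len(sex),
        n_excluded_unsequenced=len(unseq),
        n_excluded_duplicated=len(dup),
        n_retained=len(retained),
        excluded_sex=frozenset(sex),
        excluded_unsequenced=frozenset(unseq),
        excluded_duplicated=frozenset(dup),
    )
    return retained, report


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read promoter sequences from FASTA keyed by promoter_id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split("|")[0]
        seqs[pid] = str(rec.seq).upper()
    return seqs


def write_promoters_bed(records: Sequence[PromoterRecord], path: str | Path) -> None:
    """Write promoters as BED6 (TSS as the 1-bp BED interval, ids in name)."""
    with Path(path).open("w") as out:
        for p in records:
            name = "|".join([p.promoter_id, *sorted(p.gene_ids)])
            out.write(
                f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{name}\t0\t{p.strand}\n"
            )
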