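"""FASTQ parsing, amplicon QC and variant counting for sorted pools.

The QC rule is deliberately minimal, matching the sort-seq amplicon design:
a read is accepted iff it has the exact amplicon length, Phred > 20 at every
constant-region position and at the three bases of the consensus-tyrosine
TAC codon, an exact match to the constant flanks, and TAC (not a synonymous
TAT) at the tyrosine codon.  Base qualities inside the variable region are
intentionally *not* filtered — sequencing errors there produce spurious
low-count variants which the downstream CPM > 10 filter removes.

Counting is exact and streaming-order independent.  Two equivalent paths
exist: a per-read reference path (`qc_and_extract`) and a vectorized bulk
path (`count_fastq`) used for million-read pools; tests assert they agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

from .library_design import LibraryLayout, translate_variant

QC_REASONS = (
    "length",
    "ambiguous_base",
    "low_quality",
    "constant_mismatch",
    "tyrosine_codon",
)

SORT_GROUPS = ("INPUT", "INPUT_KA", "INPUT_KD", "KAH", "KAL", "KDH", "KDL")

_VALID_BASES = frozenset(b"ACGTN")


@dataclass
class ReadRecord:
    """One FASTQ read with Phred+33-decoded qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


class FastqFormatError(ValueError):
    """Malformed FASTQ input; the message carries the failing record index."""


def parse_fastq(source: str | Path | IO[str]) -> Iterator[ReadRecord]:
    """Lazily parse strict 4-line FASTQ (Phred+33).

    Aborts with :class:`FastqFormatError` (including the 1-based record
    number) on a truncated record, a bad header/separator, a base outside
    A/C/G/T/N, or a sequence/quality length mismatch.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from parse_fastq(handle)
        return
    record_no = 0
    while True:
        header = source.readline()
        if header == "":
            return
        record_no += 1
        header = header.rstrip("\n")
        seq = source.readline().rstrip("\n")
        plus = source.readline().rstrip("\n")
        qual = source.readline().rstrip("\n")
        if not header.startswith("@"):
            raise FastqFormatError(f"record {record_no}: header does not start with '@'")
        if plus == "" and qual == "":
            raise FastqFormatError(f"record {record_no}: truncated record")
        if not plus.startswith("+"):
            raise FastqFormatError(f"record {record_no}: separator line is not '+'")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {record_no}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        if any(ord(b) not in _VALID_BASES for b in seq):
            raise FastqFormatError(f"record {record_no}: base outside A/C/G/T/N")
        phred = [ord(c) - 33 for c in qual]
        if any(q < 0 or q > 93 for q in phred):
            raise FastqFormatError(f"record {record_no}: quality character out of range")
        yield ReadRecord(id=header[1:], sequence=seq, qualities=phred)


def qc_and_extract(
    read: ReadRecord, layout: LibraryLayout, min_phred: int = 20
) -> tuple[str | None, str | None]:
    """Apply the amplicon QC filter to one read.

    Returns ``(variable_region_9mer, None)`` on acceptance, or
    ``(None, reason)`` with reason one of :data:`QC_REASONS`.  The Phred
    threshold is strict: a base scoring exactly ``min_phred`` fails.
    """
    if len(read.sequence) != layout.read_length:
        return None, "length"
    scored = layout.scored_positions()
    seq = read.sequence
    for i in scored:
        if seq[i] not in "ACGT":
            return None, "ambiguous_base"
    for i in scored:
        if read.qualities[i] <= min_phred:
            return None, "low_quality"
    template = layout.constant_read_template()
    for i in layout.constant_positions():
        if seq[i] != template[i]:
            return None, "constant_mismatch"
    if seq[layout.tyrosine_codon_slice] != "TAC":
        return None, "tyrosine_codon"
    variable = seq[layout.variable_slice]
    if any(b not in "ACGT" for b in variable):
        return None, "ambiguous_base"
    return variable, None


@dataclass
class PoolCounts:
    """Per-variant read counts for one sorted pool at DNA or AA level."""

    group: str
    counts: dict[str, int]
    total_reads: int
    level: str = "dna"
    qc_stats: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_reads != sum(self.counts.values()):
            raise ValueError("total_reads must equal the sum of counts")
        if self.level not in ("dna", "aa"):
            raise ValueError("level must be 'dna' or 'aa'")

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype="int64").sort_index()

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "variant": sorted(self.counts),
                "level": self.level,
                "count": [self.counts[v] for v in sorted(self.counts)],
            }
        )
        df.insert(0, "group", self.group)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolCounts":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str})
        if df.empty:
            raise ValueError(f"empty counts table: {path}")
        groups = df["group"].unique()
        levels = df["level"].unique()
        if len(groups) != 1 or len(levels) != 1:
            raise ValueError("counts table must hold a single group and level")
        counts = dict(zip(df["variant"], df["count"].astype(int)))
        return cls(
            group=str(groups[0]),
            counts=counts,
            total_reads=int(df["count"].sum()),
            level=str(levels[0]),
        )

    def qc_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.qc_stats, indent=2, sort_keys=True) + "\n")


def count_variants(variants: Iterable[str], group: str = "INPUT") -> PoolCounts:
    """Exact multiset counts of accepted variable-region sequences."""
    counts: dict[str, int] = {}
    total = 0
    for v in variants:
        counts[v] = counts.get(v, 0) + 1
        total += 1
    return PoolCounts(group=group, counts=counts, total_reads=total, level="dna")


def count_reads(
    reads: Iterable[ReadRecord],
    layout: LibraryLayout,
    group: str = "INPUT",
    min_phred: int = 20,
) -> PoolCounts:
    """Reference per-read path: QC each record, count accepted 9-mers."""
    counts: dict[str, int] = {}
    stats = {reason: 0 for reason in QC_REASONS}
    accepted = 0
    parsed = 0
    for read in reads:
        parsed += 1
        variant, reason = qc_and_extract(read, layout, min_phred=min_phred)
        if variant is None:
            stats[reason] += 1
        else:
            counts[variant] = counts.get(variant, 0) + 1
            accepted += 1
    stats["accepted"] = accepted
    stats["parsed"] = parsed
    return PoolCounts(
        group=group, counts=counts, total_reads=accepted, level="dna", qc_stats=stats
    )


def count_fastq(
    path: str | Path,
    layout: LibraryLayout,
    group: str = "INPUT",
    min_phred: int = 20,
) -> PoolCounts:
    """Vectorized QC + counting over a whole FASTQ pool.

    Produces exactly the same counts and QC tallies as streaming every
    record through :func:`qc_and_extract`, but works on numpy byte matrices
    so million-read pools take seconds.
    """
    data = Path(path).read_bytes()
    stats = {reason: 0 for reason in QC_REASONS}
    if not data.strip():
        stats.update(accepted=0, parsed=0)
        return PoolCounts(group=group, counts={}, total_reads=0, level="dna", qc_stats=stats)
    lines = data.rstrip(b"\n").split(b"\n")
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"record {len(lines) // 4 + 1}: truncated record"
        )
    headers = lines[0::4]
    seq_lines = lines[1::4]
    plus_lines = lines[2::4]
    qual_lines = lines[3::4]
    for i, (h, p) in enumerate(zip(headers, plus_lines)):
        if not h.startswith(b"@"):
            raise FastqFormatError(f"record {i + 1}: header does not start with '@'")
        if not p.startswith(b"+"):
            raise FastqFormatError(f"record {i + 1}: separator line is not '+'")
    n = len(seq_lines)
    parsed = n

    seq_len = np.fromiter((len(s) for s in seq_lines), dtype=np.intp, count=n)
    qual_len = np.fromiter((len(q) for q in qual_lines), dtype=np.intp, count=n)
    mismatched = np.nonzero(seq_len != qual_len)[0]
    if len(mismatched):
        i = int(mismatched[0])
        raise FastqFormatError(
            f"record {i + 1}: sequence length {seq_len[i]} != quality length {qual_len[i]}"
        )

    L = layout.read_length
    good_len = seq_len == L
    stats["length"] = int(n - good_len.sum())
    idx = np.nonzero(good_len)[0]
    counts: dict[str, int] = {}
    accepted = 0
    if len(idx):
        seqs = np.frombuffer(
            b"".join(seq_lines[i] for i in idx), dtype=np.uint8
        ).reshape(len(idx), L)
        quals = (
            np.frombuffer(
                b"".join(qual_lines[i] for i in idx), dtype=np.uint8
            ).reshape(len(idx), L)
            - 33
        )
        bad_chars = ~np.isin(seqs, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad_chars.any():
            i = int(idx[np.nonzero(bad_chars.any(axis=1))[0][0]])
            raise FastqFormatError(f"record {i + 1}: base outside A/C/G/T/N")
        if (quals < 0).any() or (quals > 93).any():
            raise FastqFormatError("quality character out of range")

        scored = layout.scored_positions()
        const = layout.constant_positions()
        template = np.frombuffer(
            layout.constant_read_template().encode(), dtype=np.uint8
        )
        tyr = layout.tyrosine_codon_slice
        tac = np.frombuffer(b"TAC", dtype=np.uint8)
        acgt = np.frombuffer(b"ACGT", dtype=np.uint8)

        alive = np.ones(len(idx), dtype=bool)

        ambiguous_scored = ~np.isin(seqs[:, scored], acgt).all(axis=1)
        stats["ambiguous_base"] += int((alive & ambiguous_scored).sum())
        alive &= ~ambiguous_scored

        low_q = ~(quals[:, scored] > min_phred).all(axis=1)
        stats["low_quality"] += int((alive & low_q).sum())
        alive &= ~low_q

        const_bad = ~(seqs[:, const] == template[const]).all(axis=1)
        stats["constant_mismatch"] += int((alive & const_bad).sum())
        alive &= ~const_bad

        tyr_bad = ~(seqs[:, tyr] == tac).all(axis=1)
        stats["tyrosine_codon"] += int((alive & tyr_bad).sum())
        alive &= ~tyr_bad

        variable = seqs[np.nonzero(alive)[0]][:, layout.variable_slice]
        ambiguous_var = ~np.isin(variable, acgt).all(axis=1)
        stats["ambiguous_base"] += int(ambiguous_var.sum())
        variable = variable[~ambiguous_var]

        if len(variable):
            keys = np.ascontiguousarray(variable).view(
                f"S{layout.variable_region_length_nt}"
            ).ravel()
            uniq, cnt = np.unique(keys, return_counts=True)
            counts = {k.decode(): int(c) for k, c in zip(uniq, cnt)}
            accepted = int(cnt.sum())

    stats["accepted"] = accepted
    stats["parsed"] = parsed
    return PoolCounts(
        group=group, counts=counts, total_reads=accepted, level="dna", qc_stats=stats
    )


def aggregate_to_aa(dna_counts: PoolCounts) -> PoolCounts:
    """Collapse synonymous DNA variants to amino-acid counts.

    Stop-containing variants are kept (their '*' marks them) and stay in
    the pool total so frequency denominators are conserved; downstream
    selection never treats them as candidates.  Totals are conserved
    exactly.
    """
    if dna_counts.level != "dna":
        raise ValueError("aggregate_to_aa expects DNA-level counts")
    counts: dict[str, int] = {}
    for dna, c in dna_counts.counts.items():
        aa = translate_variant(dna)
        counts[aa] = counts.get(aa, 0) + c
    return PoolCounts(
        group=dna_counts.group,
        counts=counts,
        total_reads=dna_counts.total_reads,
        level="aa",
        qc_stats=dict(dna_counts.qc_stats),
    )
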