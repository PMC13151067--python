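"""FASTQ → peptide count tables for multi-round selection campaigns.

Reads are demultiplexed by the (i5, i7) index pair carried in the Illumina
read header (``1:N:0:i7+i5``), the variable region is extracted between the
schema's constant flanks, quality-filtered on mean Phred, translated with
suppression, scaffold-filtered, and aggregated to per-(strategy, round)
peptide counts.  Every read is accounted for: kept plus the per-reason drop
counters always equal the total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .schema import (
    LibrarySchema,
    SequenceRejected,
    format_tokens,
    translate_with_suppression,
)

__all__ = [
    "DROP_REASONS",
    "DemuxSheet",
    "IngestStats",
    "demultiplex",
    "extract_variable_region",
    "build_pool_table",
    "ingest_fastq",
    "read_fastq",
]

DROP_REASONS = (
    "index-unmatched",
    "flank-unmatched",
    "low-quality",
    "frame",
    "stop",
    "scaffold-fail",
    "ambiguous",
)


class FastqParseError(ValueError):
    """Malformed FASTQ input, reported with the failing record number."""


@dataclass(frozen=True)
class DemuxSheet:
    """(i5, i7) index pair → (strategy, round), with a Hamming mismatch
    tolerance of 0 or 1 per pair."""

    assignments: dict[tuple[str, str], tuple[str, int]]
    tolerance: int = 0

    def __post_init__(self) -> None:
        if self.tolerance not in (0, 1):
            raise ValueError(f"tolerance must be 0 or 1, got {self.tolerance}")
        if len(set(self.assignments)) != len(self.assignments):
            raise ValueError("index pairs must be unique")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tolerance: int = 0) -> "DemuxSheet":
        assignments = {
            (row.i5, row.i7): (row.strategy, int(row.round))
            for row in df.itertuples()
        }
        if len(assignments) != len(df):
            raise ValueError("duplicate index pairs in demux sheet")
        return cls(assignments, tolerance)

    @classmethod
    def from_tsv(cls, path, tolerance: int = 0) -> "DemuxSheet":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"), tolerance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i5, i7, strategy, rnd)
            for (i5, i7), (strategy, rnd) in self.assignments.items()
        ]
        return pd.DataFrame(rows, columns=["i5", "i7", "strategy", "round"])


@dataclass
class IngestStats:
    """Read bookkeeping; ``kept + sum(dropped) == total`` always."""

    total: int = 0
    kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def drop(self, reason: str) -> None:
        if reason not in DROP_REASONS:
            raise ValueError(f"unknown drop reason {reason!r}")
        self.total += 1
        self.dropped[reason] += 1

    def keep(self) -> None:
        self.total += 1
        self.kept += 1

    def validate(self) -> None:
        if self.kept + sum(self.dropped.values()) != self.total:
            raise AssertionError("ingest statistics do not conserve reads")

    def merge(self, other: "IngestStats") -> "IngestStats":
        out = IngestStats(
            total=self.total + other.total,
            kept=self.kept + other.kept,
            dropped=self.dropped + other.dropped,
        )
        out.validate()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total), ("kept", self.kept)]
        rows += [(f"dropped:{r}", self.dropped.get(r, 0)) for r in DROP_REASONS]
        return pd.DataFrame(rows, columns=["category", "reads"])


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Parse a FASTQ file into (title, sequence, quality) tuples."""
    try:
        with open(path) as fh:
            return list(FastqGeneralIterator(fh))
    except ValueError as exc:
        raise FastqParseError(f"{path}: {exc}") from exc


def _index_pair_of(title: str) -> tuple[str, str] | None:
    """Extract (i5, i7) from an Illumina-style ``... 1:N:0:i7+i5`` title."""
    fields = title.split()
    if len(fields) < 2:
        return None
    tag = fields[1].split(":")
    if len(tag) != 4 or "+" not in tag[3]:
        return None
    i7, _, i5 = tag[3].partition("+")
    return (i5, i7)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: list[tuple[str, str, str]], sheet: DemuxSheet
) -> tuple[dict[tuple[str, int], list[tuple[str, str, str]]], IngestStats]:
    """Assign each read to the unique sample whose index pair is nearest
    within tolerance; ties between equally near samples are unassignable
    and counted as index-unmatched."""
    stats = IngestStats()
    samples: dict[tuple[str, int], list[tuple[str, str, str]]] = {
        sample: [] for sample in sheet.assignments.values()
    }
    pairs = list(sheet.assignments.items())
    for record in reads:
        observed = _index_pair_of(record[0])
        if observed is None:
            stats.drop("index-unmatched")
            continue
        best: tuple[str, int] | None = None
        best_d = sheet.tolerance + 1
        tied = False
        for (i5, i7), sample in pairs:
            d = _hamming(observed[0], i5) + _hamming(observed[1], i7)
            if d < best_d:
                best, best_d, tied = sample, d, False
            elif d == best_d and best is not None:
                tied = True
        if best is None or tied:
            stats.drop("index-unmatched")
            continue
        stats.keep()
        samples[best].append(record)
    stats.validate()
    return samples, stats


def _find_with_mismatch(haystack: str, needle: str, max_mm: int) -> int:
    """Leftmost start of ``needle`` in ``haystack`` allowing ``max_mm``
    substitutions; -1 if absent."""
    if max_mm == 0:
        return haystack.find(needle)
    n, m = len(haystack), len(needle)
    for start in range(n - m + 1):
        if _hamming(haystack[start : start + m], needle) <= max_mm:
            return start
    return -1


def extract_variable_region(
    seq: str,
    qual: str,
    schema: LibrarySchema,
    min_quality: float = 20.0,
    flank_mismatch: int = 0,
) -> str:
    """Return the expected-length window between the schema's flanks.

    Raises :class:`~macropan.schema.SequenceRejected` with reason
    ``"flank-unmatched"`` (either flank absent at its expected place) or
    ``"low-quality"`` (window mean Phred below threshold).
    """
    start5 = _find_with_mismatch(seq, schema.flank5, flank_mismatch)
    if start5 < 0:
        raise SequenceRejected("flank-unmatched", "5' flank not found")
    lo = start5 + len(schema.flank5)
    hi = lo + schema.variable_region_nt
    window = seq[lo:hi]
    if len(window) < schema.variable_region_nt:
        raise SequenceRejected("flank-unmatched", "read too short for window")
    after = seq[hi : hi + len(schema.flank3)]
    if (
        len(after) < len(schema.flank3)
        or _hamming(after, schema.flank3) > flank_mismatch
    ):
        raise SequenceRejected("flank-unmatched", "3' flank not found after window")
    window_qual = qual[lo:hi]
    mean_q = sum(ord(c) - 33 for c in window_qual) / len(window_qual)
    if mean_q < min_quality:
        raise SequenceRejected("low-quality", f"mean Q {mean_q:.1f}")
    return window


def build_pool_table(
    samples: dict[tuple[str, int], list[tuple[str, str, str]]],
    schema: LibrarySchema,
    min_quality: float = 20.0,
    flank_mismatch: int = 0,
) -> tuple[pd.DataFrame, IngestStats]:
    """Extract, translate and scaffold-filter demultiplexed reads, and
    aggregate identical peptides to counts.

    Returns a (strategy, round, peptide, count) table sorted by sample and
    descending count, plus the conservation-checked statistics.
    """
    stats = IngestStats()
    rows = []
    for (strategy, rnd), records in sorted(samples.items()):
        counter: Counter[str] = Counter()
        for _, seq, qual in records:
            try:
                window = extract_variable_region(
                    seq, qual, schema, min_quality, flank_mismatch
                )
                tokens = translate_with_suppression(
                    window, schema.code, schema.suppression
                )
            except SequenceRejected as rej:
                stats.drop(rej.reason)
                continue
            if not schema.matches_scaffold(tokens):
                stats.drop("scaffold-fail")
                continue
            stats.keep()
            counter[format_tokens(tokens)] += 1
        for pep, cnt in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((strategy, rnd, pep, cnt))
    stats.validate()
    table = pd.DataFrame(rows, columns=["strategy", "round", "peptide", "count"])
    return table, stats


def ingest_fastq(
    reads: list[tuple[str, str, str]],
    schema: LibrarySchema,
    sheet: DemuxSheet,
    min_quality: float = 20.0,
    flank_mismatch: int = 0,
) -> tuple[pd.DataFrame, IngestStats]:
    """Demultiplex + extract + translate + count in one call.

    The returned statistics merge both stages, so ``kept`` counts reads
    that survived all filters and ``total`` equals the input reads.
    """
    samples, demux_stats = demultiplex(reads, sheet)
    table, build_stats = build_pool_table(samples, schema, min_quality, flank_mismatch)
    stats = IngestStats(
        total=demux_stats.total,
        kept=build_stats.kept,
        dropped=demux_stats.dropped + build_stats.dropped,
    )
    stats.validate()
    return table, stats
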