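"""gp8-targeted read processing: orient, trim, size-filter, quality-filter,
collapse, and translate displayed-peptide inserts.

The workflow mirrors targeted amplicon processing of a p8-type display
library: each usable read carries the degenerate 27-nt insert between fixed
gp8 flanks, on either the sense strand or (for roughly half of single-end
reads) the anti-sense strand.  Anti-sense hits are reverse-complemented into
sense orientation so that all downstream analysis operates on one strand.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import reverse_complement, translate
from .synthetic import LibraryDesign

DEFAULT_Q_MIN = 34
DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"sequence/quality length mismatch in {self.read_id}")


@dataclass(frozen=True)
class InsertRecord:
    """A 27-nt insert extracted from one read, stored in sense orientation."""

    insert: str
    insert_qualities: tuple[int, ...]
    strand_of_origin: str  # "sense" | "antisense"
    source_read_id: str


@dataclass(frozen=True)
class Rejection:
    reason: str  # no_match | size_mismatch | ambiguous | low_quality | stop_codon | ambiguous_base


@dataclass(frozen=True)
class NucleotideVariant:
    insert: str
    read_count: int


@dataclass(frozen=True)
class PeptideRecord:
    peptide: str
    read_count: int
    n_nucleotide_variants: int


@dataclass
class ProcessingStats:
    """Per-category read tallies; the rejection categories plus successes
    partition the input reads exactly."""

    reads_in: int = 0
    sense_matched: int = 0
    antisense_matched: int = 0
    no_match: int = 0
    size_rejected: int = 0
    ambiguous_rejected: int = 0
    quality_rejected: int = 0
    stop_rejected: int = 0
    ambiguous_base_rejected: int = 0
    passed: int = 0

    @property
    def fraction_passing(self) -> float:
        return self.passed / self.reads_in if self.reads_in else 0.0

    def check_partition(self) -> None:
        matched = self.sense_matched + self.antisense_matched
        if self.no_match + self.size_rejected + self.ambiguous_rejected + matched != self.reads_in:
            raise AssertionError("orientation categories do not partition reads_in")
        post = (
            self.quality_rejected
            + self.stop_rejected
            + self.ambiguous_base_rejected
            + self.passed
        )
        if post != matched:
            raise AssertionError("post-trim categories do not partition matched reads")

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        payload["fraction_passing"] = self.fraction_passing
        Path(path).write_text(json.dumps(payload, indent=2))


def _mismatch_positions(seq: str, flank: str, max_mismatch: int) -> list[int]:
    """Start positions where ``flank`` matches ``seq`` with <= max_mismatch
    substitutions, leftmost first."""
    n, m = len(seq), len(flank)
    if n < m:
        return []
    if max_mismatch == 0:
        out, start = [], 0
        while True:
            i = seq.find(flank, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    fl = np.frombuffer(flank.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mm = (windows != fl).sum(axis=1)
    return np.nonzero(mm <= max_mismatch)[0].tolist()


def _linked_match(
    seq: str, upstream: str, downstream: str, insert_len: int, max_mismatch: int
) -> tuple[int | None, bool]:
    """Locate ``upstream`` + exactly ``insert_len`` nt + ``downstream``.

    Returns (insert start or None, flanks-present-at-wrong-spacing flag).
    Leftmost upstream candidate wins.
    """
    ups = _mismatch_positions(seq, upstream, max_mismatch)
    if not ups:
        return None, False
    downs = _mismatch_positions(seq, downstream, max_mismatch)
    down_set = set(downs)
    for i in ups:
        j = i + len(upstream) + insert_len
        if j in down_set:
            return i + len(upstream), False
    wrong_spacing = any(d > i + len(upstream) for i in ups for d in downs)
    return None, wrong_spacing


def orient_and_trim(
    read: ReadRecord,
    design: LibraryDesign,
    max_mismatch_per_flank: int = DEFAULT_MAX_MISMATCH,
    sense_only: bool = False,
) -> InsertRecord | Rejection:
    """Extract the 27-nt insert from a read on either strand.

    Sense flanks are tried first, then anti-sense flanks; an anti-sense hit is
    returned reverse-complemented (with reversed qualities) so the insert is
    always in sense orientation.  A read matching both strand patterns is
    rejected as ambiguous.
    """
    ins_len = design.insert_length_nt
    s_start, s_size = _linked_match(
        read.sequence,
        design.sense_upstream_flank,
        design.sense_downstream_flank,
        ins_len,
        max_mismatch_per_flank,
    )
    if sense_only:
        a_start, a_size = None, False
    else:
        a_start, a_size = _linked_match(
            read.sequence,
            design.antisense_upstream_flank,
            design.antisense_downstream_flank,
            ins_len,
            max_mismatch_per_flank,
        )
    if s_start is not None and a_start is not None:
        return Rejection("ambiguous")
    if s_start is not None:
        insert = read.sequence[s_start : s_start + ins_len]
        quals = read.qualities[s_start : s_start + ins_len]
        return InsertRecord(insert, tuple(quals), "sense", read.read_id)
    if a_start is not None:
        insert = reverse_complement(read.sequence[a_start : a_start + ins_len])
        quals = tuple(reversed(read.qualities[a_start : a_start + ins_len]))
        return InsertRecord(insert, quals, "antisense", read.read_id)
    return Rejection("size_mismatch" if (s_size or a_size) else "no_match")


def quality_filter(
    record: InsertRecord, q_min: int = DEFAULT_Q_MIN, min_fraction: float = 1.0
) -> bool:
    """True iff at least ``min_fraction`` of insert bases have Q >= q_min
    (default: every base)."""
    if not record.insert_qualities:
        raise ValueError("insert has no quality values")
    ok = sum(1 for q in record.insert_qualities if q >= q_min)
    return ok >= min_fraction * len(record.insert_qualities)


def collapse_nucleotide(inserts: Iterable[InsertRecord]) -> list[NucleotideVariant]:
    """Collapse identical 27-mers; read support is conserved."""
    counts = Counter(rec.insert for rec in inserts)
    return [
        NucleotideVariant(insert, n)
        for insert, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def translate_insert(variant: NucleotideVariant) -> str | Rejection:
    """Translate a 27-nt insert (frame 0, standard code); rejects inserts with
    ambiguous bases or an in-frame stop."""
    if len(variant.insert) % 3 != 0:
        raise ValueError(f"insert length {len(variant.insert)} not a multiple of 3")
    if "N" in variant.insert:
        return Rejection("ambiguous_base")
    peptide = translate(variant.insert)
    if "*" in peptide:
        return Rejection("stop_codon")
    return peptide


def collapse_peptides(variants: Iterable[NucleotideVariant]) -> list[PeptideRecord]:
    """Collapse synonymous nucleotide variants into peptide records carrying
    total read support and the number of distinct encodings."""
    support: dict[str, int] = {}
    encodings: dict[str, set[str]] = {}
    for v in variants:
        peptide = translate_insert(v)
        if isinstance(peptide, Rejection):
            raise ValueError(f"variant {v.insert} does not translate cleanly")
        support[peptide] = support.get(peptide, 0) + v.read_count
        encodings.setdefault(peptide, set()).add(v.insert)
    return [
        PeptideRecord(p, support[p], len(encodings[p]))
        for p in sorted(support, key=lambda p: (-support[p], p))
    ]


def iter_fastq(path: str | Path) -> Iterable[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )


def process_reads(
    reads: Iterable[ReadRecord],
    design: LibraryDesign | None = None,
    q_min: int = DEFAULT_Q_MIN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    sense_only: bool = False,
    quality_scope: str = "insert",
    min_quality_fraction: float = 1.0,
) -> tuple[list[PeptideRecord], ProcessingStats]:
    """Run the full trim -> quality-filter -> collapse -> translate workflow
    over an in-memory read stream."""
    if design is None:
        design = LibraryDesign()
    if quality_scope not in ("insert", "read"):
        raise ValueError("quality_scope must be 'insert' or 'read'")
    stats = ProcessingStats()
    kept: list[InsertRecord] = []
    for read in reads:
        stats.reads_in += 1
        if quality_scope == "read":
            whole = InsertRecord(read.sequence, tuple(read.qualities), "sense", read.read_id)
            if not quality_filter(whole, q_min, min_quality_fraction):
                # full-read mode rejects before trimming; count as matched+rejected
                # only if the read orients, otherwise as its orientation outcome
                result = orient_and_trim(read, design, max_mismatch, sense_only)
                if isinstance(result, Rejection):
                    _tally_orientation(stats, result)
                else:
                    _tally_strand(stats, result)
                    stats.quality_rejected += 1
                continue
        result = orient_and_trim(read, design, max_mismatch, sense_only)
        if isinstance(result, Rejection):
            _tally_orientation(stats, result)
            continue
        _tally_strand(stats, result)
        if quality_scope == "insert" and not quality_filter(
            result, q_min, min_quality_fraction
        ):
            stats.quality_rejected += 1
            continue
        kept.append(result)

    variants = collapse_nucleotide(kept)
    clean: list[NucleotideVariant] = []
    for v in variants:
        out = translate_insert(v)
        if isinstance(out, Rejection):
            if out.reason == "stop_codon":
                stats.stop_rejected += v.read_count
            else:
                stats.ambiguous_base_rejected += v.read_count
            continue
        clean.append(v)
    peptides = collapse_peptides(clean)
    stats.passed = sum(v.read_count for v in clean)
    stats.check_partition()
    return peptides, stats


def _tally_orientation(stats: ProcessingStats, rej: Rejection) -> None:
    if rej.reason == "no_match":
        stats.no_match += 1
    elif rej.reason == "size_mismatch":
        stats.size_rejected += 1
    elif rej.reason == "ambiguous":
        stats.ambiguous_rejected += 1
    else:  # pragma: no cover - defensive
        raise ValueError(f"unexpected orientation rejection {rej.reason}")


def _tally_strand(stats: ProcessingStats, rec: InsertRecord) -> None:
    if rec.strand_of_origin == "sense":
        stats.sense_matched += 1
    else:
        stats.antisense_matched += 1


def process_fastq(
    path: str | Path,
    design: LibraryDesign | None = None,
    q_min: int = DEFAULT_Q_MIN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    **kwargs,
) -> tuple[list[PeptideRecord], ProcessingStats]:
    """Process one Phred+33 FASTQ file into collapsed peptide records."""
    return process_reads(
        iter_fastq(path), design, q_min=q_min, max_mismatch=max_mismatch, **kwargs
    )


def write_peptides_tsv(records: Sequence[PeptideRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.peptide, r.read_count, r.n_nucleotide_variants) for r in records],
        columns=["peptide", "read_count", "n_nucleotide_variants"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideRecord(row.peptide, int(row.read_count), int(row.n_nucleotide_variants))
        for row in df.itertuples()
    ]
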