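"""Sequence and peak I/O, negative-set construction, and train/test splitting.

This module covers the preprocessing stage of a ChIP-seq motif study: read
peaks in UCSC narrowPeak format, keep the most significant ones, pull the
peak sequences out of a genome FASTA, build matched negative sets (flanking
or genome-wide), drop sequences with ambiguous nucleotides, and split each
class 2:1 into training and test data.

Coordinates are 0-based half-open throughout (the BED/narrowPeak convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._seq import is_unambiguous

__all__ = [
    "SequenceRecord",
    "PeakRecord",
    "LabeledDataSet",
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "filter_peaks_min_pvalue",
    "extract_peak_sequences",
    "flanking_negatives",
    "genomewide_negatives",
    "filter_ambiguous",
    "split_train_test",
    "make_labeled_dataset",
]


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally tagged with its genomic origin.

    ``source_coords`` is ``(chrom, start, end, strand)`` with 0-based
    half-open coordinates when the sequence was cut out of a genome.
    """

    id: str
    seq: str
    source_coords: tuple[str, int, int, str] | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PeakRecord:
    """One narrowPeak line: genomic interval plus significance columns.

    ``p_exponent`` / ``q_exponent`` are the file's −log10(p) and −log10(q)
    columns; larger means more significant.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    p_exponent: float = -1.0
    q_exponent: float = -1.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LabeledDataSet:
    """Positive/negative sequence sets with a train/test split manifest."""

    positives: list[SequenceRecord]
    negatives: list[SequenceRecord]
    split: dict[str, str] = field(default_factory=dict)

    def subset(self, label: str, part: str) -> list[SequenceRecord]:
        pool = self.positives if label == "positive" else self.negatives
        return [r for r in pool if self.split.get(r.id) == part]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, uppercased.

    File order is preserved.  Records with empty sequences or missing
    headers are rejected.  Ambiguous symbols are *not* rejected here; use
    :func:`filter_ambiguous` for that.
    """
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ValueError(f"{path}: record {i + 1} has an empty header")
        if not seq:
            raise ValueError(f"{path}: record {i + 1} ({rec.id!r}) has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 70 columns."""
    bio = (_BioRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(bio)


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Parse a 10-column UCSC narrowPeak (BED6+4) file."""
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                peaks.append(
                    PeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=float(fields[4]),
                        strand=fields[5],
                        signal=float(fields[6]),
                        p_exponent=float(fields[7]),
                        q_exponent=float(fields[8]),
                        summit=int(fields[9]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def filter_peaks_min_pvalue(peaks: Sequence[PeakRecord]) -> list[PeakRecord]:
    """Keep only the peaks with the minimal p-value in the input.

    narrowPeak stores −log10(p), so the minimal p-value corresponds to the
    maximal ``p_exponent``.  Input order is preserved.
    """
    if not peaks:
        raise ValueError("filter_peaks_min_pvalue: empty peak list")
    best = max(p.p_exponent for p in peaks)
    return [p for p in peaks if p.p_exponent == best]


def _genome_lookup(genome_fasta):
    """Accept a pyfaidx.Fasta, a path, or a plain {chrom: str} dict."""
    if isinstance(genome_fasta, (str, Path)):
        from pyfaidx import Fasta

        return Fasta(str(genome_fasta))
    return genome_fasta


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    region = genome[chrom][start:end]
    return str(region).upper()


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_peak_sequences(
    peaks: Sequence[PeakRecord], genome_fasta
) -> list[SequenceRecord]:
    """Cut peak intervals out of the genome (forward strand)."""
    genome = _genome_lookup(genome_fasta)
    out = []
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.name} ({p.chrom}): chromosome not in genome")
        clen = _chrom_len(genome, p.chrom)
        if p.start < 0 or p.end > clen:
            raise ValueError(
                f"peak {p.name} {p.chrom}:{p.start}-{p.end} outside chromosome bounds (len {clen})"
            )
        out.append(
            SequenceRecord(
                id=f"{p.chrom}:{p.start}-{p.end}",
                seq=_fetch(genome, p.chrom, p.start, p.end),
                source_coords=(p.chrom, p.start, p.end, "+"),
            )
        )
    return out


def _overlaps(chrom: str, start: int, end: int, peaks: Sequence[PeakRecord]) -> bool:
    return any(p.chrom == chrom and start < p.end and p.start < end for p in peaks)


def flanking_negatives(
    peaks: Sequence[PeakRecord], genome_fasta
) -> list[SequenceRecord]:
    """Adjacent same-length flanks of each peak, minus any that touch a peak.

    For a peak [s, e) the candidate negatives are [s−(e−s), s) and
    [e, e+(e−s)).  Candidates that run off the chromosome or that overlap
    *any* input peak are discarded, so positives and negatives are disjoint.
    """
    genome = _genome_lookup(genome_fasta)
    out: list[SequenceRecord] = []
    for p in peaks:
        length = len(p)
        clen = _chrom_len(genome, p.chrom)
        for s, e in ((p.start - length, p.start), (p.end, p.end + length)):
            if s < 0 or e > clen:
                continue
            if _overlaps(p.chrom, s, e, peaks):
                continue
            out.append(
                SequenceRecord(
                    id=f"{p.chrom}:{s}-{e}",
                    seq=_fetch(genome, p.chrom, s, e),
                    source_coords=(p.chrom, s, e, "+"),
                )
            )
    return out


def genomewide_negatives(
    peaks: Sequence[PeakRecord],
    genome_fasta,
    exclusion_peaks: Sequence[PeakRecord] | None = None,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> list[SequenceRecord]:
    """Sample two length-matched negatives per positive from the whole genome.

    A draw is rejected and redrawn if the sampled sequence contains an
    ambiguous nucleotide or overlaps a peak in the exclusion set (defaults
    to the input peaks themselves).  Chromosomes are chosen proportionally
    to the number of valid start positions, starts uniformly within them.
    """
    genome = _genome_lookup(genome_fasta)
    if exclusion_peaks is None:
        exclusion_peaks = peaks
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys()) if hasattr(genome, "keys") else list(genome)
    out: list[SequenceRecord] = []
    for p in peaks:
        length = len(p)
        valid = np.array(
            [max(0, _chrom_len(genome, c) - length + 1) for c in chroms], dtype=float
        )
        if valid.sum() == 0:
            raise ValueError(f"no chromosome can host a length-{length} sample")
        probs = valid / valid.sum()
        for k in range(2):
            for attempt in range(max_redraws):
                ci = rng.choice(len(chroms), p=probs)
                chrom = chroms[ci]
                start = int(rng.integers(0, int(valid[ci])))
                end = start + length
                seq = _fetch(genome, chrom, start, end)
                if not is_unambiguous(seq):
                    continue
                if _overlaps(chrom, start, end, exclusion_peaks):
                    continue
                out.append(
                    SequenceRecord(
                        id=f"gw:{chrom}:{start}-{end}#{len(out)}",
                        seq=seq,
                        source_coords=(chrom, start, end, "+"),
                    )
                )
                break
            else:
                raise RuntimeError(
                    f"genomewide_negatives: exceeded {max_redraws} redraws for peak {p.name}"
                )
    return out


def filter_ambiguous(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Drop records containing any non-ACGT symbol."""
    kept = [r for r in records if is_unambiguous(r.seq)]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "filter_ambiguous: dropped %d of %d records", n_dropped, len(records)
        )
    return kept


def split_train_test(
    records: Sequence[SequenceRecord],
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> dict[str, str]:
    """Seeded uniform shuffle, then the first ⌈train·n/(train+test)⌉ go to train.

    Returns a mapping id → ``"train"``/``"test"``.
    """
    train_parts, test_parts = ratio
    n = len(records)
    if n < train_parts + test_parts:
        raise ValueError(f"need at least {train_parts + test_parts} records, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = math.ceil(train_parts * n / (train_parts + test_parts))
    split = {}
    for rank, idx in enumerate(order):
        split[records[idx].id] = "train" if rank < n_train else "test"
    return split


def make_labeled_dataset(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> LabeledDataSet:
    """Bundle both classes and split each 2:1 (per-class, seeded)."""
    split = split_train_test(positives, ratio, seed)
    split.update(split_train_test(negatives, ratio, seed + 1))
    return LabeledDataSet(list(positives), list(negatives), split)
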