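"""Sequencing QC metrics: base-quality fractions, GC content, coverage
breadth/depth summaries, and depth summaries stratified by GC window."""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO


class QcError(ValueError):
    pass


@dataclass
class ReadQualitySummary:
    n_reads: int
    n_bases: int
    q20_fraction: float
    q30_fraction: float
    gc_fraction: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fastq_quality_summary(path: str | Path, phred_offset: int = 33) -> ReadQualitySummary:
    """Q20/Q30 base fractions and GC content of a FASTQ(.gz) file.

    GC is computed over A/C/G/T calls only (N excluded from the denominator).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n_reads = n_bases = n_q20 = n_q30 = n_gc = n_acgt = 0
    if phred_offset != 33:
        raise QcError("only Phred+33 FASTQ is supported")
    with opener(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                quals = rec.letter_annotations["phred_quality"]
                seq = str(rec.seq).upper()
                n_reads += 1
                n_bases += len(seq)
                n_q20 += sum(q >= 20 for q in quals)
                n_q30 += sum(q >= 30 for q in quals)
                n_gc += seq.count("G") + seq.count("C")
                n_acgt += sum(seq.count(b) for b in "ACGT")
        except ValueError as exc:
            raise QcError(f"{path}: malformed FASTQ near record {n_reads + 1}: {exc}") from exc
    if n_bases == 0:
        raise QcError(f"{path}: no bases parsed")
    return ReadQualitySummary(
        n_reads=n_reads,
        n_bases=n_bases,
        q20_fraction=n_q20 / n_bases,
        q30_fraction=n_q30 / n_bases,
        gc_fraction=(n_gc / n_acgt) if n_acgt else float("nan"),
    )


def _chrom_sequence(reference, chrom: str) -> str:
    if isinstance(reference, (str, Path)):
        for rec in SeqIO.parse(str(reference), "fasta"):
            if rec.id == chrom:
                return str(rec.seq)
        raise QcError(f"chromosome {chrom!r} not in reference {reference}")
    if isinstance(reference, Mapping):
        if chrom not in reference:
            raise QcError(f"chromosome {chrom!r} not in reference mapping")
        return str(reference[chrom])
    raise QcError(f"unsupported reference source {type(reference)}")


def window_gc(reference, chrom: str, pos: int, window: int = 200) -> float:
    """GC percent of the ``window``-base window centered on 1-based ``pos``.

    For even windows the extra base goes 3' of the variant. A window running
    off the sequence end is computed on the truncated window with a warning.
    N bases are excluded from the denominator.
    """
    seq = _chrom_sequence(reference, chrom)
    if not (1 <= pos <= len(seq)):
        raise QcError(f"{chrom}:{pos} outside reference of length {len(seq)}")
    pos0 = pos - 1
    left = (window - 1) // 2
    start = pos0 - left
    end = start + window
    if start < 0 or end > len(seq):
        warnings.warn(f"{chrom}:{pos}: window truncated at sequence edge", stacklevel=2)
        start, end = max(start, 0), min(end, len(seq))
    win = seq[start:end].upper()
    denom = sum(win.count(b) for b in "ACGT")
    if denom == 0:
        raise QcError(f"{chrom}:{pos}: window has no A/C/G/T bases")
    return 100.0 * (win.count("G") + win.count("C")) / denom


@dataclass
class CoverageSummary:
    region: str
    n_bases: int
    mean_depth: float
    threshold: int
    breadth_at_threshold: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def coverage_breadth(
    depths: Sequence[float], threshold: int = 20, region: str = ""
) -> CoverageSummary:
    """Mean depth and fraction of bases at or above ``threshold``."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise QcError(f"{region or 'region'}: empty depth vector")
    return CoverageSummary(
        region=region,
        n_bases=int(d.size),
        mean_depth=float(d.mean()),
        threshold=threshold,
        breadth_at_threshold=float((d >= threshold).mean()),
    )


@dataclass
class GcDepthBinSummary:
    edges: list[float]                      # e.g. [28, 45, 55, 68]
    counts: list[int]                       # per (low, high] bin
    mean_depths: list[float | None]         # None where the bin is empty
    overflow: list[tuple[float, float]]     # (gc, depth) outside the edges

    @property
    def n_total(self) -> int:
        return sum(self.counts) + len(self.overflow)


def depth_by_gc_bins(
    gc_values: Sequence[float],
    depths: Sequence[float],
    edges: Sequence[float] = (28.0, 45.0, 55.0, 68.0),
) -> GcDepthBinSummary:
    """Per-GC-bin variant counts and mean variant-site depth.

    Bin membership is (low, high], except the first bin which is closed on
    both sides. Values outside [first, last] go to an overflow bucket.
    """
    if len(gc_values) != len(depths):
        raise QcError("gc_values and depths differ in length")
    edges = list(edges)
    if sorted(edges) != edges or len(edges) < 2:
        raise QcError("edges must be an increasing list of >= 2 values")
    n_bins = len(edges) - 1
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    overflow: list[tuple[float, float]] = []
    for gc, depth in zip(gc_values, depths):
        if gc < edges[0] or gc > edges[-1]:
            overflow.append((gc, depth))
            continue
        if gc == edges[0]:
            k = 0
        else:
            k = next(i for i in range(n_bins) if edges[i] < gc <= edges[i + 1])
        counts[k] += 1
        sums[k] += depth
    means = [s / c if c else None for s, c in zip(sums, counts)]
    return GcDepthBinSummary(edges=edges, counts=counts, mean_depths=means, overflow=overflow)
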