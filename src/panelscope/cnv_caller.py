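"""Copy-number-loss calling from binned depth against a reference pool.

Pipeline: per-sample library-size normalization (panel-wide median), per-bin
ratio against the pool's median normalized depth (fold depth), z-score against
the pool's fold distribution, then maximal runs of significantly low bins
become loss events with a width-weighted median fold, log2 ratio, and an
integer copy-number estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from panelscope.panel_model import Bin, PanelDefinition, bin_panel

SEX_CHROMS = {"chrX", "X", "chrY", "Y"}


class CnvError(ValueError):
    pass


@dataclass
class CnvParams:
    """Caller parameters.

    ``min_consecutive_bins`` defaults to 3 so that the smallest callable span
    at the 50-bp bin length is 150 bp. ``min_pool_sd`` floors the pool's
    per-bin fold standard deviation so that noise-free pools still yield
    finite z-scores.
    """

    z_threshold: float = 3.0
    fold_ceiling: float = 0.75
    min_consecutive_bins: int = 3
    min_pool_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.fold_ceiling <= 0 or self.min_consecutive_bins <= 0:
            raise CnvError("caller parameters must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "CnvParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BinDepths:
    """Mean depth of coverage per panel bin for one sample."""

    sample_id: str
    depths: np.ndarray
    sex: str = "unknown"  # {male, female, unknown}

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths < 0):
            raise CnvError(f"{self.sample_id}: negative bin depths")
        if self.sex not in {"male", "female", "unknown"}:
            raise CnvError(f"{self.sample_id}: invalid sex {self.sex!r}")


def _recenter_sex_chroms(values: np.ndarray, bins: Sequence[Bin]) -> np.ndarray:
    """Divide sex-chromosome bins by their per-chromosome median.

    Removes the baseline half-depth of a male X against a mixed pool without
    touching autosomes; a no-op when the chromosome is already centered at 1.
    """
    out = values.copy()
    chroms = np.array([b.chrom for b in bins])
    for chrom in sorted(set(chroms) & SEX_CHROMS):
        sel = chroms == chrom
        med = np.median(out[sel][out[sel] > 0]) if np.any(out[sel] > 0) else 0.0
        if med > 0:
            out[sel] = out[sel] / med
    return out


@dataclass
class ReferencePool:
    """Reference samples' normalized per-bin fold distribution."""

    members: list[BinDepths]
    bins: list[Bin]
    pool_median: np.ndarray = field(init=False)
    fold_mean: np.ndarray = field(init=False)
    fold_sd: np.ndarray = field(init=False)
    informative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise CnvError(f"reference pool needs >= 3 members, got {len(self.members)}")
        n_bins = len(self.bins)
        for m in self.members:
            if len(m.depths) != n_bins:
                raise CnvError(f"pool member {m.sample_id}: {len(m.depths)} depths for {n_bins} bins")
        norm = []
        for m in self.members:
            med = np.median(m.depths)
            if med <= 0:
                raise CnvError(f"pool member {m.sample_id}: zero median depth")
            v = m.depths / med
            norm.append(_recenter_sex_chroms(v, self.bins))
        norm = np.array(norm)
        self.pool_median = np.median(norm, axis=0)
        self.informative = self.pool_median > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(self.informative, norm / self.pool_median, np.nan)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-nan uninformative bins
            self.fold_mean = np.where(self.informative, np.nanmean(fold, axis=0), np.nan)
            self.fold_sd = np.where(self.informative, np.nanstd(fold, axis=0, ddof=1), np.nan)


@dataclass
class FoldDepthTrack:
    """Per-bin normalized fold depth and z-score of one sample vs the pool."""

    sample_id: str
    sex: str
    fold: np.ndarray
    z: np.ndarray
    informative: np.ndarray
    bins: list[Bin]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ordinal": [b.ordinal for b in self.bins],
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "fold": self.fold,
                "z": self.z,
                "informative": self.informative,
            }
        )


@dataclass
class CnvLossEvent:
    chrom: str
    start: int
    end: int
    first_bin: int
    last_bin: int
    n_bins: int
    span_bp: int
    median_fold: float
    log2_ratio: float
    copy_number_estimate: float
    copy_number: int
    genes: list[str]
    labels: list[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["log2_ratio"]):
            d["log2_ratio"] = "-inf"
        return d


def normalize_fold_depth(
    sample: BinDepths, pool: ReferencePool, params: CnvParams | None = None
) -> FoldDepthTrack:
    """Library-size-normalize a sample and express each bin as fold of the pool.

    Bins where the pool's median normalized depth is zero are flagged
    uninformative and excluded from calling.
    """
    params = params or CnvParams()
    if len(sample.depths) != len(pool.bins):
        raise CnvError(
            f"{sample.sample_id}: {len(sample.depths)} depths for {len(pool.bins)} panel bins"
        )
    med = np.median(sample.depths)
    if med <= 0:
        raise CnvError(f"{sample.sample_id}: zero median depth; cannot normalize")
    norm = _recenter_sex_chroms(sample.depths / med, pool.bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(pool.informative, norm / pool.pool_median, np.nan)
    sd = np.maximum(pool.fold_sd, params.min_pool_sd)
    with np.errstate(invalid="ignore"):
        z = np.where(pool.informative, (fold - pool.fold_mean) / sd, np.nan)
    return FoldDepthTrack(
        sample_id=sample.sample_id,
        sex=sample.sex,
        fold=fold,
        z=z,
        informative=pool.informative.copy(),
        bins=list(pool.bins),
    )


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches half."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _round_cn(estimate: float) -> int:
    # nearest integer, ties toward the lower copy number
    return max(0, math.ceil(estimate - 0.5))


def estimate_copy_number(
    fold_values: Sequence[float], widths: Sequence[float], ploidy: int = 2
) -> tuple[float, float, float, int]:
    """(median_fold, log2_ratio, copy_number_estimate, copy_number) for an event.

    ``median_fold`` is the width-weighted median of the per-bin folds; copy
    number is ``ploidy x median_fold`` rounded to the nearest integer with
    ties toward the lower copy number. A zero fold yields a -inf log2 ratio.
    """
    median_fold = weighted_median(fold_values, widths)
    log2_ratio = math.log2(median_fold) if median_fold > 0 else float("-inf")
    estimate = ploidy * median_fold
    return median_fold, log2_ratio, estimate, _round_cn(estimate)


def call_loss_events(
    track: FoldDepthTrack,
    panel: PanelDefinition,
    params: CnvParams | None = None,
) -> list[CnvLossEvent]:
    """Report maximal runs of significantly low bins as loss events.

    A bin is significant iff it is informative, ``z < -z_threshold`` and
    ``fold < fold_ceiling``. Runs must be consecutive in panel ordinal, stay
    on one chromosome, contain at least ``min_consecutive_bins`` bins and span
    at least ``min_consecutive_bins * bin_length`` genomic bases.
    """
    params = params or CnvParams()
    bins = track.bins
    with np.errstate(invalid="ignore"):
        sig = (
            track.informative
            & (np.nan_to_num(track.z, nan=np.inf) < -params.z_threshold)
            & (np.nan_to_num(track.fold, nan=np.inf) < params.fold_ceiling)
        )
    events: list[CnvLossEvent] = []
    i, n = 0, len(bins)
    min_span = params.min_consecutive_bins * panel.bin_length
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and bins[j + 1].chrom == bins[i].chrom:
            j += 1
        run = bins[i : j + 1]
        n_bins = len(run)
        span = run[-1].end - run[0].start
        if n_bins >= params.min_consecutive_bins and span >= min_span:
            folds = track.fold[i : j + 1]
            widths = [b.width for b in run]
            ploidy = 1 if (track.sex == "male" and run[0].chrom in SEX_CHROMS) else 2
            median_fold, log2_ratio, estimate, cn = estimate_copy_number(folds, widths, ploidy)
            genes, labels = [], []
            for b in run:
                r = panel.regions[b.region_index]
                if r.gene and r.gene not in genes:
                    genes.append(r.gene)
                lbl = f"{r.gene}:{r.label}" if r.label else r.gene
                if lbl and lbl not in labels:
                    labels.append(lbl)
            events.append(
                CnvLossEvent(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    first_bin=run[0].ordinal,
                    last_bin=run[-1].ordinal,
                    n_bins=n_bins,
                    span_bp=span,
                    median_fold=median_fold,
                    log2_ratio=log2_ratio,
                    copy_number_estimate=estimate,
                    copy_number=cn,
                    genes=genes,
                    labels=labels,
                )
            )
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# depth I/O
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-base depth table: columns (chrom, pos[1-based], depth)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "pos", "depth"])
    if df.empty:
        raise CnvError(f"{path}: empty depth table")
    return df


def mean_bin_depths(depth: pd.DataFrame, bins: Sequence[Bin]) -> np.ndarray:
    """Mean per-base depth over each bin; bases absent from the table count as 0."""
    sums = np.zeros(len(bins))
    widths = np.array([b.width for b in bins], dtype=float)
    idx_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in bins}:
        ords = np.array([i for i, b in enumerate(bins) if b.chrom == chrom])
        starts = np.array([bins[i].start for i in ords])
        ends = np.array([bins[i].end for i in ords])
        idx_by_chrom[chrom] = (ords, starts, ends)
    for chrom, g in depth.groupby("chrom"):
        if chrom not in idx_by_chrom:
            continue
        ords, starts, ends = idx_by_chrom[chrom]
        pos0 = g["pos"].to_numpy() - 1  # 0-based
        k = np.searchsorted(starts, pos0, side="right") - 1
        ok = (k >= 0) & (pos0 < ends[np.clip(k, 0, None)])
        np.add.at(sums, ords[k[ok]], g["depth"].to_numpy()[ok])
    return sums / widths


def bin_depths_from_tsv(
    path: str | Path, panel: PanelDefinition, bins: Sequence[Bin] | None = None,
    sample_id: str | None = None, sex: str = "unknown",
) -> BinDepths:
    bins = bins if bins is not None else bin_panel(panel)
    df = read_depth_tsv(path)
    return BinDepths(
        sample_id=sample_id or Path(path).stem.replace(".depth", ""),
        depths=mean_bin_depths(df, bins),
        sex=sex,
    )


def read_pool_dir(
    pool_dir: str | Path, panel: PanelDefinition, bins: Sequence[Bin] | None = None
) -> ReferencePool:
    """Load a reference pool from a directory of depth TSVs.

    An optional ``manifest.tsv`` (columns: filename, sample_id, sex) selects
    and annotates members; otherwise every ``*.tsv`` file is a member of
    unknown sex.
    """
    pool_dir = Path(pool_dir)
    bins = bins if bins is not None else bin_panel(panel)
    manifest = pool_dir / "manifest.tsv"
    members: list[BinDepths] = []
    if manifest.exists():
        mf = pd.read_csv(manifest, sep="\t", comment="#")
        for _, row in mf.iterrows():
            members.append(
                bin_depths_from_tsv(
                    pool_dir / row["filename"], panel, bins,
                    sample_id=str(row.get("sample_id", row["filename"])),
                    sex=str(row.get("sex", "unknown")),
                )
            )
    else:
        for p in sorted(pool_dir.glob("*.tsv")):
            members.append(bin_depths_from_tsv(p, panel, bins))
    return ReferencePool(members=members, bins=list(bins))


def cnv_pipeline(
    sample: BinDepths,
    pool: ReferencePool,
    panel: PanelDefinition,
    params: CnvParams | None = None,
) -> dict:
    """normalize -> call -> estimate; returns events plus the per-bin audit track."""
    params = params or CnvParams()
    track = normalize_fold_depth(sample, pool, params)
    events = call_loss_events(track, panel, params)
    return {
        "sample_id": sample.sample_id,
        "params": asdict(params),
        "events": [e.to_dict() for e in events],
        "audit_track": track.to_frame().to_dict(orient="list"),
    }


def events_to_tsv(events: Iterable[CnvLossEvent], path: str | Path) -> None:
    """Write events with 1-based inclusive coordinates for human readers."""
    rows = []
    for e in events:
        d = e.to_dict()
        d["start"] = e.start + 1  # 1-based inclusive
        rows.append(d)
    cols = [
        "chrom", "start", "end", "span_bp", "n_bins", "median_fold", "log2_ratio",
        "copy_number_estimate", "copy_number", "genes", "labels",
    ]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    if rows:
        df["genes"] = df["genes"].map(",".join)
        df["labels"] = df["labels"].map(",".join)
    df.to_csv(path, sep="\t", index=False)


def events_to_bed(events: Iterable[CnvLossEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{','.join(e.genes)}|CN{e.copy_number}\n")
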