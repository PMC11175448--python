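"""Panel data model: gene-annotated target regions and their fixed-length binning.

A panel is an ordered set of target intervals (BED, 0-based half-open), each
annotated with a gene symbol and a free-text label (typically an exon number).
For copy-number analysis the target space is tiled left-to-right with
fixed-length bins (default 50 bp); a short terminal remainder of a region is
kept as a flagged partial bin rather than dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_BIN_LENGTH = 50


class PanelError(ValueError):
    """Raised on malformed panel input or invariant violation."""


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One target interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise PanelError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise PanelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bin:
    """One fixed-length tile of a target region.

    ``ordinal`` is the bin's index in the panel-wide sequence (genome order);
    ``region_index`` points back at the region the bin tiles. A bin shorter
    than the panel bin length is a flagged terminal partial bin.
    """

    chrom: str
    start: int
    end: int
    region_index: int
    ordinal: int
    is_partial: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PanelDefinition:
    """Ordered target regions plus the bin length used for CNV analysis."""

    regions: list[TargetRegion]
    bin_length: int = DEFAULT_BIN_LENGTH
    name: str = "panel"

    def __post_init__(self) -> None:
        if self.bin_length < 1:
            raise PanelError(f"bin_length must be >= 1, got {self.bin_length}")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions if r.gene}

    @property
    def n_target_bases(self) -> int:
        return sum(r.length for r in self.regions)

    def regions_for_gene(self, gene: str) -> list[TargetRegion]:
        return [r for r in self.regions if r.gene == gene]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bin_length": self.bin_length,
            "regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end, "gene": r.gene, "label": r.label}
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDefinition":
        return cls(
            regions=[TargetRegion(**r) for r in d["regions"]],
            bin_length=int(d.get("bin_length", DEFAULT_BIN_LENGTH)),
            name=d.get("name", "panel"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


def merge_same_gene_overlaps(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping or book-ended intervals that share a gene symbol.

    Intervals of different genes are never merged even if they overlap.
    Labels of merged intervals are joined with ','.
    """
    by_key: dict[tuple[str, str], list[TargetRegion]] = {}
    for r in regions:
        by_key.setdefault((r.chrom, r.gene), []).append(r)
    out: list[TargetRegion] = []
    for (chrom, gene), group in by_key.items():
        group.sort(key=lambda r: (r.start, r.end))
        cur_start, cur_end = group[0].start, group[0].end
        labels = [group[0].label] if group[0].label else []
        for r in group[1:]:
            if r.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, r.end)
                if r.label and r.label not in labels:
                    labels.append(r.label)
            else:
                out.append(TargetRegion(chrom, cur_start, cur_end, gene, ",".join(labels)))
                cur_start, cur_end = r.start, r.end
                labels = [r.label] if r.label else []
        out.append(TargetRegion(chrom, cur_start, cur_end, gene, ",".join(labels)))
    return sorted(out, key=lambda r: (r.chrom, r.start, r.end))


def read_panel_bed(
    path: str | Path, bin_length: int = DEFAULT_BIN_LENGTH, name: str | None = None
) -> PanelDefinition:
    """Read a panel from BED (0-based half-open; column 4 parsed as ``gene|label``).

    Overlapping intervals of the same gene are merged. Raises
    :class:`PanelError` naming the offending line on malformed input.
    """
    path = Path(path)
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise PanelError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise PanelError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            gene, label = "", ""
            if len(fields) >= 4 and fields[3] not in (".", ""):
                gene, _, label = fields[3].partition("|")
            regions.append(TargetRegion(chrom, start, end, gene, label))
    return PanelDefinition(
        regions=merge_same_gene_overlaps(regions),
        bin_length=bin_length,
        name=name or path.stem,
    )


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            name = f"{r.gene}|{r.label}" if r.label else r.gene
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def bin_panel(panel: PanelDefinition) -> list[Bin]:
    """Tile every region left-to-right with bins of ``panel.bin_length``.

    The terminal remainder of a region shorter than the bin length is kept as
    a partial bin. The union of bins equals the union of regions base-exactly,
    and panel-wide ordinals are strictly increasing in genome order.
    """
    bins: list[Bin] = []
    ordinal = 0
    for region_index, region in enumerate(panel.regions):
        pos = region.start
        while pos < region.end:
            end = min(pos + panel.bin_length, region.end)
            bins.append(
                Bin(
                    chrom=region.chrom,
                    start=pos,
                    end=end,
                    region_index=region_index,
                    ordinal=ordinal,
                    is_partial=(end - pos) < panel.bin_length,
                )
            )
            ordinal += 1
            pos = end
    return bins


def _data_path(filename: str):
    return resources.files("panelscope").joinpath("data", filename)


def load_bundled_panel(bin_length: int = DEFAULT_BIN_LENGTH) -> PanelDefinition:
    """Load the bundled 82-gene panel fixture shipped with the package."""
    with resources.as_file(_data_path("ird_panel.bed")) as p:
        return read_panel_bed(p, bin_length=bin_length, name="ird_panel")


def load_bundled_gene_list() -> list[str]:
    """Gene symbols of the bundled panel (one per line in the shipped TSV)."""
    text = _data_path("ird_panel_genes.tsv").read_text()
    genes = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes
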