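"""Construction of the bundled 82-gene panel fixture.

The gene list is the published panel content; exon coordinates are synthetic
but deterministic, with the exon-count structure needed by the validation
scenarios preserved (gene exon counts, the 153/90-base exon pair used for
sub-exon resolution checks, the extra intronic target, and the long
low-complexity terminal-exon target). The shipped ``data/ird_panel.bed`` is
generated from :func:`build_bundled_panel` by ``scripts/make_fixture.py``.
"""

from __future__ import annotations

from panelscope.panel_model import PanelDefinition, TargetRegion

# 82 gene symbols of the panel, alphabetical.
PANEL_GENES: tuple[str, ...] = (
    "ABCA4", "ADGRV1", "AIPL1", "BEST1", "C8orf37", "CA4", "CACNA1F", "CDH23",
    "CDHR1", "CEP290", "CERKL", "CFAP410", "CHM", "CLRN1", "CNGA1", "CNGA3",
    "CNGB1", "CNGB3", "CRB1", "CRX", "CYP4V2", "DHDDS", "DRAM2", "EYS",
    "FAM161A", "FSCN2", "GNAT2", "GRK1", "GUCA1A", "GUCY2D", "IDH3B", "IMPDH1",
    "IMPG2", "IQCB1", "KCNV2", "KLHL7", "LRAT", "MAK", "MERTK", "MYO7A",
    "NMNAT1", "NR2E3", "NRL", "NYX", "PCARE", "PDE6A", "PDE6B", "PDE6C",
    "PDE6G", "POC1B", "PRCD", "PROM1", "PRPF3", "PRPF31", "PRPF6", "PRPF8",
    "PRPH2", "RBP3", "RDH12", "RDH5", "RGR", "RGS9BP", "RHO", "RLBP1", "ROM1",
    "RP1", "RP1L1", "RP2", "RP9", "RPE65", "RPGR", "RPGRIP1", "RS1", "SAG",
    "SEMA4A", "SNRNP200", "SPATA7", "TOPORS", "TTC8", "TULP1", "USH2A",
    "ZNF513",
)

X_LINKED_GENES: frozenset[str] = frozenset({"RPGR", "RP2", "CHM", "RS1", "NYX", "CACNA1F"})

# Exon counts fixed where the validation scenarios depend on them.
_EXON_COUNTS: dict[str, int] = {
    "RP1L1": 6,     # deletion analog spans exons 3-4
    "PDE6B": 10,    # deletion analog spans exons 2-3
    "EYS": 12,      # deletion analog spans exons 6-8
    "PRPF31": 14,   # deletion analogs span exons 1-14 and 2-3
    "CEP290": 28,   # plus an intronic target between exons 26 and 27
    "RPGR": 15,     # plus the long terminal-exon target
}

# Exon lengths fixed for sub-exon-scale scenarios; PDE6B exons 2 and 3 are
# 153 and 90 bases (one not bin-aligned, one shorter than two bins).
_EXON_LENGTHS: dict[tuple[str, int], int] = {
    ("PDE6B", 2): 153,
    ("PDE6B", 3): 90,
}

_INTRON = 1500
_GENE_SPACING = 1_000_000
ORF15_LENGTH = 1706  # printed span of the terminal-exon coding target


def _exon_count(gene: str, gene_index: int) -> int:
    if gene in _EXON_COUNTS:
        return _EXON_COUNTS[gene]
    return 4 + (gene_index * 7) % 10  # 4..13, deterministic


def _exon_length(gene: str, gene_index: int, exon_number: int) -> int:
    if (gene, exon_number) in _EXON_LENGTHS:
        return _EXON_LENGTHS[(gene, exon_number)]
    return 120 + ((gene_index + exon_number) * 13) % 90  # 120..209


def build_bundled_panel(bin_length: int = 50) -> PanelDefinition:
    """Deterministically build the 82-gene fixture panel."""
    # chromosome assignment: X-linked genes on chrX, the rest round-robin chr1..chr22
    autosomal = [g for g in PANEL_GENES if g not in X_LINKED_GENES]
    chrom_of: dict[str, str] = {g: "chrX" for g in X_LINKED_GENES}
    for i, g in enumerate(autosomal):
        chrom_of[g] = f"chr{(i % 22) + 1}"

    next_start: dict[str, int] = {}
    regions: list[TargetRegion] = []
    for gene_index, gene in enumerate(PANEL_GENES):
        chrom = chrom_of[gene]
        pos = next_start.get(chrom, 1_000_000)
        n_exons = _exon_count(gene, gene_index)
        for exon in range(1, n_exons + 1):
            length = _exon_length(gene, gene_index, exon)
            regions.append(TargetRegion(chrom, pos, pos + length, gene, f"ex{exon}"))
            pos += length + _INTRON
            if gene == "CEP290" and exon == 26:
                # extra intronic target between exons 26 and 27
                regions.append(TargetRegion(chrom, pos, pos + 200, gene, "int26-27"))
                pos += 200 + _INTRON
        if gene == "RPGR":
            regions.append(TargetRegion(chrom, pos, pos + ORF15_LENGTH, gene, "ORF15"))
            pos += ORF15_LENGTH + _INTRON
        next_start[chrom] = pos + _GENE_SPACING
    return PanelDefinition(regions=regions, bin_length=bin_length, name="ird_panel")


def exon_span(panel: PanelDefinition, gene: str, first_exon: int, last_exon: int) -> tuple[str, int, int]:
    """Genomic interval (chrom, start, end) from the start of ``ex<first>`` to the end of ``ex<last>``."""
    wanted = {f"ex{i}" for i in range(first_exon, last_exon + 1)}
    hits = [r for r in panel.regions_for_gene(gene) if r.label in wanted]
    if len(hits) != len(wanted):
        missing = wanted - {r.label for r in hits}
        raise ValueError(f"{gene}: exon labels not found in panel: {sorted(missing)}")
    return hits[0].chrom, min(r.start for r in hits), max(r.end for r in hits)
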