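"""Seeded generators for panel-shaped synthetic inputs.

Depth is negative-binomially dispersed around a target mean, modulated by a
unimodal GC response (capture efficiency peaks at mid GC and falls off toward
the extremes) and a ploidy factor (heterozygous deletion halves depth,
homozygous zeroes it, male non-PAR X runs at half baseline). Allele depths at
variant sites are binomial around the theoretical VAF. All generators are
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from panelscope.panel_model import PanelDefinition, TargetRegion
from panelscope.panel_fixture import X_LINKED_GENES

_GC_SEED = 20240613  # fixes the per-region GC landscape independently of sample seeds


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlannedDeletion:
    chrom: str
    start: int
    end: int
    zygosity: str  # {het, hom}
    gene: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.zygosity not in {"het", "hom"}:
            raise SimulationError(f"deletion zygosity must be het/hom, got {self.zygosity!r}")

    @property
    def copy_number(self) -> int:
        return 1 if self.zygosity == "het" else 0


@dataclass(frozen=True)
class PlannedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # {het, hom, hemi}
    gene: str = ""

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "indel"


@dataclass
class TruthSet:
    variants: list[PlannedVariant] = field(default_factory=list)
    cnv_losses: list[PlannedDeletion] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "variants": [asdict(v) for v in self.variants],
                    "cnv_losses": [
                        dict(asdict(d), copy_number=d.copy_number) for d in self.cnv_losses
                    ],
                },
                indent=1,
            )
        )


@dataclass
class SimulationConfig:
    seed: int = 0
    mean_depth: float = 500.0
    dispersion: float = 0.003   # NB overdispersion; 0 means noise-free exact means
    gc_optimum: float = 0.50
    gc_width: float = 0.12
    gc_floor: float = 0.20
    sex: str = "female"
    pool_size: int = 8
    hom_error: float = 0.005    # base error pulling hom/hemi VAF below 1.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise SimulationError("mean_depth must be positive")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


def gc_response(gc: np.ndarray | float, config: SimulationConfig) -> np.ndarray | float:
    """Unimodal (Gaussian-shaped) capture-efficiency multiplier, 1.0 at the optimum."""
    rel = np.exp(-((np.asarray(gc) - config.gc_optimum) ** 2) / (2 * config.gc_width**2))
    return config.gc_floor + (1 - config.gc_floor) * rel


def region_gc(panel: PanelDefinition) -> np.ndarray:
    """Deterministic per-region GC fraction in [0.28, 0.68], fixed per panel."""
    rng = np.random.default_rng(_GC_SEED + len(panel.regions))
    return 0.28 + 0.40 * rng.random(len(panel.regions))


def _ploidy_factor(region: TargetRegion, pos0: np.ndarray,
                   deletions: Sequence[PlannedDeletion], sex: str) -> np.ndarray:
    factor = np.ones(len(pos0))
    if sex == "male" and (region.chrom in {"chrX", "X", "chrY", "Y"} or region.gene in X_LINKED_GENES):
        factor *= 0.5
    for d in deletions:
        if d.chrom != region.chrom:
            continue
        mask = (pos0 >= d.start) & (pos0 < d.end)
        factor[mask] *= 0.5 if d.zygosity == "het" else 0.0
    return factor


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial (gamma-Poisson) draw; dispersion 0 -> exact rounded means."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return np.round(mu)
    out = np.zeros_like(mu)
    pos = mu > 0
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu[pos] * dispersion)
    out[pos] = rng.poisson(lam)
    return out


def simulate_depth_profile(
    config: SimulationConfig,
    panel: PanelDefinition,
    deletions: Sequence[PlannedDeletion] = (),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Per-base depth over the panel's target bases plus the planted truth.

    Returns a DataFrame with columns (chrom, pos[1-based], depth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = region_gc(panel)
    # normalize the GC response to unit mean over regions so the panel-wide
    # average depth stays at mean_depth regardless of the GC landscape
    response = np.asarray(gc_response(gc, config), dtype=float)
    response = response / response.mean()
    target = {(r.chrom, r.start, r.end) for r in panel.regions}
    for d in deletions:
        if not any(c == d.chrom and s < d.end and d.start < e for c, s, e in target):
            raise SimulationError(f"deletion {d.chrom}:{d.start}-{d.end} overlaps no panel region")
    frames = []
    for i, region in enumerate(panel.regions):
        pos0 = np.arange(region.start, region.end)
        mu = (
            config.mean_depth
            * response[i]
            * _ploidy_factor(region, pos0, deletions, config.sex)
        )
        depth = _nb_draw(rng, mu, config.dispersion)
        frames.append(pd.DataFrame({"chrom": region.chrom, "pos": pos0 + 1, "depth": depth.astype(int)}))
    df = pd.concat(frames, ignore_index=True)
    return df, TruthSet(cnv_losses=list(deletions))


def write_depth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def simulate_reference_pool(
    config: SimulationConfig,
    panel: PanelDefinition,
    n: int | None = None,
    out_dir: str | Path | None = None,
    sexes: Sequence[str] | None = None,
) -> list[tuple[str, str, pd.DataFrame]]:
    """n deletion-free profiles (sample_id, sex, depth frame); optionally written
    as TSVs plus a manifest under ``out_dir``. Member seeds are spawned from the
    master seed, so regeneration is byte-identical."""
    n = n if n is not None else config.pool_size
    if n < 3:
        raise SimulationError(f"reference pool needs n >= 3, got {n}")
    sexes = list(sexes) if sexes is not None else [config.sex] * n
    if len(sexes) != n:
        raise SimulationError("sexes must have length n")
    children = np.random.SeedSequence(config.seed).spawn(n)
    members = []
    for i, (ss, sex) in enumerate(zip(children, sexes)):
        member_cfg = SimulationConfig(**{**asdict(config), "sex": sex})
        df, _ = simulate_depth_profile(member_cfg, panel, rng=np.random.default_rng(ss))
        members.append((f"ref{i:02d}", sex, df))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.tsv", "w") as mf:
            mf.write("filename\tsample_id\tsex\n")
            for sample_id, sex, df in members:
                write_depth_tsv(df, out_dir / f"{sample_id}.tsv")
                mf.write(f"{sample_id}.tsv\t{sample_id}\t{sex}\n")
    return members


_VCF_HEADER = """##fileformat=VCFv4.2
##source=panelscope-simulator
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _site_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    return int(_nb_draw(rng, np.array([config.mean_depth]), config.dispersion)[0])


def _theoretical_vaf(variant: PlannedVariant, config: SimulationConfig) -> float:
    if variant.zygosity == "het":
        return 0.5
    return 1.0 - config.hom_error  # hom and hemi


def simulate_variant_vcf(
    config: SimulationConfig,
    variants: Sequence[PlannedVariant],
    out_path: str | Path,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
) -> Path:
    """Write one replicate's VCF: AD ~ Binomial(DP, p) per planted variant.

    Sites whose drawn depth is zero are omitted (models dropout).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out_path = Path(out_path)
    contigs = sorted({v.chrom for v in variants})
    lines = [_VCF_HEADER.rstrip("\n")]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        dp = _site_depth(rng, config)
        if dp == 0:
            continue
        p = _theoretical_vaf(v, config)
        alt_depth = int(rng.binomial(dp, p))
        gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[v.zygosity]
        info = f"GENE={v.gene}" if v.gene else "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
            f"\tGT:AD:DP\t{gt}:{dp - alt_depth},{alt_depth}:{dp}"
        )
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def simulate_replicate_cohort(
    config: SimulationConfig,
    variants: Sequence[PlannedVariant],
    out_dir: str | Path,
    operators: int = 2,
    lots: int = 3,
    days: int = 3,
    replicates: int = 8,
) -> dict[tuple[int, int, int, int], Path]:
    """Full replicate design, one VCF per (operator, lot, day, replicate)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = [
        (o, l, d, r)
        for o in range(operators)
        for l in range(lots)
        for d in range(days)
        for r in range(replicates)
    ]
    children = np.random.SeedSequence(config.seed).spawn(len(keys))
    paths = {}
    for key, ss in zip(keys, children):
        o, l, d, r = key
        name = f"op{o}_lot{l}_day{d}_rep{r}.vcf"
        paths[key] = simulate_variant_vcf(
            config, variants, out_dir / name,
            sample_id=f"op{o}-lot{l}-day{d}-rep{r}",
            rng=np.random.default_rng(ss),
        )
    return paths


def simulate_condition_cohort(
    config: SimulationConfig,
    control: dict[str, Iterable[str]],
    dropout: dict[str, float],
    condition_label: str = "condition",
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Thin a control call set by a seeded per-class dropout probability."""
    rng = np.random.default_rng(config.seed)
    ctrl = {c: set(v) for c, v in control.items()}
    cond: dict[str, set[str]] = {}
    for vclass, variants in ctrl.items():
        p = dropout.get(vclass, 0.0)
        if not 0.0 <= p <= 1.0:
            raise SimulationError(f"dropout for {vclass} outside [0,1]: {p}")
        kept = {v for v in sorted(variants) if rng.random() >= p}
        cond[vclass] = kept
    return ctrl, cond


def table2_analog_deletions(panel: PanelDefinition) -> list[PlannedDeletion]:
    """The five-heterozygous-deletion validation cohort mapped onto the fixture
    panel, preserving each event's gene and deleted-exon range."""
    from panelscope.panel_fixture import exon_span

    spec = [
        ("S884", "RP1L1", 3, 4),
        ("S952", "PDE6B", 2, 3),
        ("S983", "EYS", 6, 8),
        ("S1042", "PRPF31", 1, 14),
        ("S1145", "PRPF31", 2, 3),
    ]
    out = []
    for patient, gene, lo, hi in spec:
        chrom, start, end = exon_span(panel, gene, lo, hi)
        out.append(
            PlannedDeletion(chrom=chrom, start=start, end=end, zygosity="het",
                            gene=gene, label=f"{patient}:ex{lo}-{hi}")
        )
    return out


def default_precision_variants(panel: PanelDefinition) -> list[PlannedVariant]:
    """The 15-variant precision truth set: 11 SNVs in five genes and 4 indels
    in four genes, placed at deterministic in-panel positions."""
    snv_genes = ["ABCA4", "RHO", "RP1L1", "RPGRIP1", "USH2A"]
    indel_genes = ["ADGRV1", "EYS", "MYO7A", "POC1B"]
    variants: list[PlannedVariant] = []
    counts = {g: 0 for g in snv_genes}
    # 11 SNVs spread over the five genes (3+2+2+2+2)
    per_gene = {"ABCA4": 3, "RHO": 2, "RP1L1": 2, "RPGRIP1": 2, "USH2A": 2}
    bases = ("A", "C", "G", "T")
    for gene, n in per_gene.items():
        regions = panel.regions_for_gene(gene)
        for j in range(n):
            r = regions[j % len(regions)]
            pos = r.start + 10 + 7 * j
            ref = bases[(pos) % 4]
            alt = bases[(pos + 1) % 4]
            zyg = "hom" if gene == "RPGRIP1" and j == 0 else "het"
            variants.append(PlannedVariant(r.chrom, pos + 1, ref, alt, zyg, gene))
            counts[gene] += 1
    indel_specs = [("ADGRV1", "ATG", "A"), ("EYS", "CA", "C"),
                   ("MYO7A", "G", "GTTCA"), ("POC1B", "TGCAGCAGCA", "T")]
    for gene, ref, alt in indel_specs:
        r = panel.regions_for_gene(gene)[0]
        pos = r.start + 25
        variants.append(PlannedVariant(r.chrom, pos + 1, ref, alt, "het", gene))
    assert len(variants) == 15
    return variants
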