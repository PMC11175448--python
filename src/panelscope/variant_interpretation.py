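"""Small-variant interpretation: depth gate, VAF-based zygosity, evidence-code
combination into the five-tier classification, and report rendering.

Evidence codes are inputs (curated upstream); this module owns only the
combination logic and the downstream genotype/report semantics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

SEX_CHROMS_X = {"chrX", "X"}
SEX_CHROMS_Y = {"chrY", "Y"}

TIERS = ("Pathogenic", "Likely pathogenic", "Uncertain significance", "Likely benign", "Benign")


class InterpretationError(ValueError):
    pass


@dataclass(frozen=True)
class VariantObservation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    gene: str = ""
    transcript: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InterpretationError(f"{self.key}: ref == alt")
        if not (0 <= self.alt_depth <= self.total_depth):
            raise InterpretationError(
                f"{self.key}: alt_depth {self.alt_depth} outside [0, total_depth {self.total_depth}]"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            raise InterpretationError(f"{self.key}: total_depth is 0, VAF undefined")
        return self.alt_depth / self.total_depth

    @property
    def variant_class(self) -> str:
        r, a = self.ref, self.alt
        if len(r) == 1 and len(a) == 1:
            return "SNV"
        if len(r) == 1 and len(a) > 1 and a.startswith(r):
            return "insertion"
        if len(a) == 1 and len(r) > 1 and r.startswith(a):
            return "deletion"
        return "complex"


def _check_normalized(chrom: str, pos: int, ref: str, alt: str) -> None:
    # a minimal, left-aligned record never has a trimmable shared suffix,
    # nor a shared prefix beyond the single anchor base
    if len(ref) > 1 and len(alt) > 1:
        if ref[-1] == alt[-1]:
            raise InterpretationError(
                f"{chrom}:{pos}:{ref}:{alt}: record is not normalized (trimmable shared suffix)"
            )
        if ref[1] == alt[1] and ref[0] == alt[0]:
            raise InterpretationError(
                f"{chrom}:{pos}:{ref}:{alt}: record is not normalized (shared prefix beyond anchor)"
            )


def read_variants_vcf(path: str | Path, sample: str | None = None) -> list[VariantObservation]:
    """Read per-ALT observations from a VCF with AD/DP genotype fields.

    Multi-allelic records are split per ALT; AD is apportioned accordingly.
    A multi-sample VCF requires an explicit ``sample`` selector.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise InterpretationError(f"{path}: VCF has no sample columns")
    if sample is None:
        if len(samples) > 1:
            raise InterpretationError(
                f"{path}: multi-sample VCF ({len(samples)} samples); pass an explicit sample selector"
            )
        sample = samples[0]
    elif sample not in samples:
        raise InterpretationError(f"{path}: sample {sample!r} not in VCF ({samples})")

    out: list[VariantObservation] = []
    for rec in vcf:
        call = rec.samples[sample]
        ad = call.get("AD")
        dp = call.get("DP")
        where = f"{rec.chrom}:{rec.pos}"
        if ad is None or all(v is None for v in ad):
            raise InterpretationError(f"{path}: record {where} lacks AD")
        if dp is None:
            dp = sum(v or 0 for v in ad)
        if dp == 0:
            raise InterpretationError(f"{path}: record {where} has DP=0")
        gene = ""
        if "GENE" in rec.header.info:
            gene = rec.info.get("GENE", "") or ""
            if isinstance(gene, tuple):
                gene = gene[0] or ""
        for i, alt in enumerate(rec.alts or ()):
            _check_normalized(rec.chrom, rec.pos, rec.ref, alt)
            out.append(
                VariantObservation(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_depth=int(ad[i + 1] or 0),
                    total_depth=int(dp),
                    gene=str(gene),
                    sample_id=sample,
                )
            )
    return out


def depth_gate(obs: VariantObservation, min_depth: int = 20) -> bool:
    """True iff the site's total depth reaches the calling threshold (inclusive)."""
    return obs.total_depth >= min_depth


@dataclass(frozen=True)
class ZygosityThresholds:
    t_low: float = 0.20   # below: ambiguous / sub-germline signal
    t_hom: float = 0.80   # at or above: homozygous (hemizygous on male X/Y)


@dataclass
class ZygosityCall:
    zygosity: str  # {heterozygous, homozygous, hemizygous, ambiguous}
    vaf: float
    thresholds: ZygosityThresholds
    sex: str
    flags: list[str] = field(default_factory=list)


def zygosity_from_vaf(
    vaf: float,
    chrom: str = "chr1",
    sex: str = "unknown",
    thresholds: ZygosityThresholds | None = None,
) -> ZygosityCall:
    """Assign zygosity from a VAF in [0, 1].

    ``vaf < t_low`` is ambiguous (reported, flagged); ``[t_low, t_hom)`` is
    heterozygous; ``>= t_hom`` is homozygous, or hemizygous on the
    non-pseudoautosomal X/Y of a male sample. Unknown sex on X/Y degrades
    hemizygous to homozygous with a flag.
    """
    if not 0.0 <= vaf <= 1.0:
        raise InterpretationError(f"VAF {vaf} outside [0, 1]")
    thresholds = thresholds or ZygosityThresholds()
    flags: list[str] = []
    on_xy = chrom in SEX_CHROMS_X or chrom in SEX_CHROMS_Y
    if vaf < thresholds.t_low:
        zyg = "ambiguous"
        flags.append(f"vaf {vaf:.3f} below reporting threshold {thresholds.t_low}")
    elif vaf < thresholds.t_hom:
        zyg = "heterozygous"
    else:
        if on_xy and sex == "male":
            zyg = "hemizygous"
        else:
            zyg = "homozygous"
            if on_xy and sex == "unknown":
                flags.append("sex unknown on X/Y: hemizygosity cannot be resolved")
    return ZygosityCall(zygosity=zyg, vaf=vaf, thresholds=thresholds, sex=sex, flags=flags)


def classify_zygosity(
    obs: VariantObservation,
    sex: str = "unknown",
    thresholds: ZygosityThresholds | None = None,
) -> ZygosityCall:
    """Assign zygosity to an observation from its VAF (see :func:`zygosity_from_vaf`)."""
    return zygosity_from_vaf(obs.vaf, chrom=obs.chrom, sex=sex, thresholds=thresholds)


# ---------------------------------------------------------------------------
# ACMG/AMP evidence combination
# ---------------------------------------------------------------------------

_PATH_CODES = {"PVS1"} | {f"PS{i}" for i in range(1, 5)} | {f"PM{i}" for i in range(1, 7)} | {
    f"PP{i}" for i in range(1, 6)
}
_BENIGN_CODES = {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
VALID_CODES = _PATH_CODES | _BENIGN_CODES

_STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")

_DEFAULT_STRENGTH = {"PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
                     "BA": "stand_alone", "BS": "strong", "BP": "supporting"}

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)(?:_(\w+))?$")


@dataclass(frozen=True)
class EvidenceCode:
    base: str                # e.g. "PM2"
    strength: str            # effective strength, possibly modified

    @property
    def is_benign(self) -> bool:
        return self.base.startswith("B")


@dataclass
class EvidenceSet:
    codes: list[EvidenceCode]

    @classmethod
    def parse(cls, items: Iterable[str], allow_modifiers: bool = True) -> "EvidenceSet":
        """Parse strings like ``PM2`` or ``PS4_moderate`` into an evidence set."""
        codes: list[EvidenceCode] = []
        seen: set[str] = set()
        for item in items:
            m = _CODE_RE.match(item.strip())
            if not m:
                raise InterpretationError(f"unknown evidence code {item!r}")
            prefix, number, modifier = m.groups()
            base = prefix + number
            if base not in VALID_CODES:
                raise InterpretationError(f"unknown evidence code {item!r}")
            if base in seen:
                raise InterpretationError(f"duplicate evidence code {base}")
            seen.add(base)
            strength = _DEFAULT_STRENGTH[prefix]
            if modifier:
                if not allow_modifiers:
                    raise InterpretationError(f"strength modifiers disabled: {item!r}")
                modifier = modifier.lower()
                if modifier not in _STRENGTHS:
                    raise InterpretationError(f"invalid strength modifier in {item!r}")
                if modifier == "stand_alone" and prefix not in ("BA", "BS"):
                    raise InterpretationError(f"stand_alone modifier invalid for {base}")
                strength = modifier
            codes.append(EvidenceCode(base, strength))
        return cls(codes)


@dataclass
class TierCall:
    tier: str
    fired_rules: list[str]
    evidence: list[str]


def acmg_combine(evidence: EvidenceSet | Iterable[str]) -> TierCall:
    """Combine evidence codes into one of the five tiers.

    Counts codes by effective strength on each side, applies the published
    combining rules, and forces Uncertain significance when a pathogenic-side
    and a benign-side rule both match.
    """
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet.parse(evidence)

    pvs = sum(1 for c in evidence.codes if not c.is_benign and c.strength == "very_strong")
    ps = sum(1 for c in evidence.codes if not c.is_benign and c.strength == "strong")
    pm = sum(1 for c in evidence.codes if not c.is_benign and c.strength == "moderate")
    pp = sum(1 for c in evidence.codes if not c.is_benign and c.strength == "supporting")
    ba = sum(1 for c in evidence.codes if c.is_benign and c.strength == "stand_alone")
    bs = sum(1 for c in evidence.codes if c.is_benign and c.strength == "strong")
    bp = sum(1 for c in evidence.codes if c.is_benign and c.strength == "supporting")
    # benign moderate has no slot in the published table; counted as supporting
    bp += sum(1 for c in evidence.codes if c.is_benign and c.strength == "moderate")

    fired: list[str] = []
    path_tier = None
    if pvs >= 2:
        fired.append("pathogenic: >=2 very strong")
        path_tier = "Pathogenic"
    elif pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2):
        fired.append("pathogenic: 1 very strong + corroboration")
        path_tier = "Pathogenic"
    elif ps >= 2:
        fired.append("pathogenic: >=2 strong")
        path_tier = "Pathogenic"
    elif ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)):
        fired.append("pathogenic: 1 strong + moderates/supportings")
        path_tier = "Pathogenic"
    elif pvs >= 1 and pm >= 1:
        fired.append("likely pathogenic: 1 very strong + 1 moderate")
        path_tier = "Likely pathogenic"
    elif ps >= 1 and pm >= 1:
        fired.append("likely pathogenic: 1 strong + 1-2 moderate")
        path_tier = "Likely pathogenic"
    elif ps >= 1 and pp >= 2:
        fired.append("likely pathogenic: 1 strong + >=2 supporting")
        path_tier = "Likely pathogenic"
    elif pm >= 3:
        fired.append("likely pathogenic: >=3 moderate")
        path_tier = "Likely pathogenic"
    elif pm >= 2 and pp >= 2:
        fired.append("likely pathogenic: 2 moderate + >=2 supporting")
        path_tier = "Likely pathogenic"
    elif pm >= 1 and pp >= 4:
        fired.append("likely pathogenic: 1 moderate + >=4 supporting")
        path_tier = "Likely pathogenic"

    benign_tier = None
    if ba >= 1:
        fired.append("benign: stand-alone")
        benign_tier = "Benign"
    elif bs >= 2:
        fired.append("benign: >=2 strong")
        benign_tier = "Benign"
    elif bs >= 1 and bp >= 1:
        fired.append("likely benign: 1 strong + 1 supporting")
        benign_tier = "Likely benign"
    elif bp >= 2:
        fired.append("likely benign: >=2 supporting")
        benign_tier = "Likely benign"

    if path_tier and benign_tier:
        fired.append("conflict: pathogenic and benign rules both matched")
        tier = "Uncertain significance"
    else:
        tier = path_tier or benign_tier or "Uncertain significance"
    return TierCall(tier=tier, fired_rules=fired, evidence=[c.base for c in evidence.codes])


def read_evidence(path: str | Path) -> dict[str, list[str]]:
    """Evidence-code assignments keyed by variant ``chrom:pos:ref:alt``.

    JSON object of key -> list of codes, or TSV with columns (variant, codes)
    where codes are comma-separated.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {k: list(v) for k, v in data.items()}
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InterpretationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        out[parts[0]] = [c for c in parts[1].split(",") if c]
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def interpret_variants(
    observations: Sequence[VariantObservation],
    evidence: Mapping[str, Iterable[str]] | None = None,
    sex: str = "unknown",
    min_depth: int = 20,
    thresholds: ZygosityThresholds | None = None,
) -> list[dict]:
    """Full per-variant interpretation records (gate, zygosity, tier)."""
    evidence = evidence or {}
    records = []
    for obs in observations:
        rec: dict = {
            "variant": obs.key,
            "gene": obs.gene,
            "class": obs.variant_class,
            "alt_depth": obs.alt_depth,
            "total_depth": obs.total_depth,
            "vaf": obs.vaf,
            "depth_gate": "pass" if depth_gate(obs, min_depth) else "fail",
        }
        if rec["depth_gate"] == "pass":
            z = classify_zygosity(obs, sex=sex, thresholds=thresholds)
            tier = acmg_combine(list(evidence.get(obs.key, [])))
            rec.update(
                zygosity=z.zygosity, zygosity_flags=z.flags,
                tier=tier.tier, fired_rules=tier.fired_rules, evidence=tier.evidence,
            )
        else:
            rec.update(zygosity=None, zygosity_flags=["QC-failed site: depth below gate"],
                       tier=None, fired_rules=[], evidence=[])
        records.append(rec)
    return records


def render_reports(
    records: Sequence[dict],
    qc_status: Mapping | None = None,
    cnv_events: Sequence[dict] | None = None,
    metadata: Mapping | None = None,
) -> tuple[dict, dict]:
    """(summary_report, sequencing_report).

    The summary carries only Pathogenic / Likely pathogenic small variants,
    detected copy-number losses, and the QC status; the sequencing report
    carries every observation with full audit fields.
    """
    qc_status = dict(qc_status or {"status": "not assessed"})
    cnv_events = list(cnv_events or [])
    metadata = dict(metadata or {})
    reportable = [r for r in records if r.get("tier") in ("Pathogenic", "Likely pathogenic")]
    qc_failed_sites = [r["variant"] for r in records if r["depth_gate"] == "fail"]
    summary = {
        "report": "summary",
        "qc": qc_status,
        "variants": reportable,
        "cnv_losses": cnv_events,
        "qc_failed_sites": qc_failed_sites,
        "metadata": metadata,
    }
    sequencing = {
        "report": "sequencing",
        "qc": qc_status,
        "variants": list(records),
        "cnv_losses": cnv_events,
        "metadata": metadata,
    }
    return summary, sequencing


def report_to_markdown(report: dict) -> str:
    lines = [f"# {report['report'].capitalize()} report", ""]
    qc = report.get("qc", {})
    lines.append(f"QC status: **{qc.get('status', 'not assessed')}**")
    lines.append("")
    lines.append("| variant | gene | class | zygosity | VAF | tier |")
    lines.append("|---|---|---|---|---|---|")
    for r in report["variants"]:
        vaf = f"{r['vaf']:.3f}" if r.get("vaf") is not None else ""
        lines.append(
            f"| {r['variant']} | {r.get('gene','')} | {r.get('class','')} "
            f"| {r.get('zygosity') or 'n/a'} | {vaf} | {r.get('tier') or 'n/a'} |"
        )
    if report.get("cnv_losses"):
        lines += ["", "## Copy-number losses", "",
                  "| location | genes | copy number | log2 ratio |", "|---|---|---|---|"]
        for e in report["cnv_losses"]:
            lines.append(
                f"| {e['chrom']}:{e['start'] + 1}-{e['end']} | {','.join(e['genes'])} "
                f"| {e['copy_number']} | {e['log2_ratio']} |"
            )
    if report.get("metadata"):
        lines += ["", "## Provenance", ""]
        for k, v in sorted(report["metadata"].items()):
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
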