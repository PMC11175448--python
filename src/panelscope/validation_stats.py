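"""Analytical-validation statistics: exact binomial intervals, PPA/NPA
concordance, zygosity concordance, replicate-design precision agreement, and
condition-vs-control detection rates."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    pass


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided equal-tailed binomial confidence interval.

    Boundary cases are closed-form: x=0 gives low=0, high=1-(a/2)^(1/n);
    x=n gives low=(a/2)^(1/n), high=1.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValidationError(f"x={x} outside [0, n={n}]")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0,1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


@dataclass
class ConcordanceResult:
    tp: int
    fp: int
    fn: int
    tn: int
    level: float = 0.95
    ppa: float | None = field(init=False)
    npa: float | None = field(init=False)
    ppa_ci: tuple[float, float] | None = field(init=False)
    npa_ci: tuple[float, float] | None = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValidationError("all concordance counts are zero")
        if self.tp + self.fn > 0:
            self.ppa = self.tp / (self.tp + self.fn)
            self.ppa_ci = clopper_pearson(self.tp, self.tp + self.fn, self.level)
        else:
            self.ppa, self.ppa_ci = None, None
        if self.tn + self.fp > 0:
            self.npa = self.tn / (self.tn + self.fp)
            self.npa_ci = clopper_pearson(self.tn, self.tn + self.fp, self.level)
        else:
            self.npa, self.npa_ci = None, None

    def to_dict(self) -> dict:
        def pct(v):
            return None if v is None else 100.0 * v

        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "ppa_percent": pct(self.ppa),
            "ppa_ci_percent": None if self.ppa_ci is None else [pct(v) for v in self.ppa_ci],
            "npa_percent": pct(self.npa),
            "npa_ci_percent": None if self.npa_ci is None else [pct(v) for v in self.npa_ci],
            "level": self.level,
        }


def concordance(tp: int, fp: int, fn: int, tn: int, level: float = 0.95) -> ConcordanceResult:
    """PPA/NPA with exact CIs; undefined ratios are reported as None, never 0."""
    return ConcordanceResult(tp=tp, fp=fp, fn=fn, tn=tn, level=level)


_ZYG_MAP = {
    "hom": "hom_hemi", "hemi": "hom_hemi", "hom_hemi": "hom_hemi",
    "homozygous": "hom_hemi", "hemizygous": "hom_hemi",
    "het": "het", "heterozygous": "het",
}


def zygosity_concordance(pairs: Iterable[tuple[str, str]]) -> dict:
    """2x2 contingency of called vs truth zygosity (hom/hemi pooled) + rate."""
    table = {("hom_hemi", "hom_hemi"): 0, ("hom_hemi", "het"): 0,
             ("het", "hom_hemi"): 0, ("het", "het"): 0}
    n = agree = 0
    for called, truth in pairs:
        try:
            c, t = _ZYG_MAP[called.lower()], _ZYG_MAP[truth.lower()]
        except KeyError as exc:
            raise ValidationError(f"unpaired or unknown zygosity label {exc}") from exc
        table[(c, t)] += 1
        n += 1
        agree += c == t
    if n == 0:
        raise ValidationError("no zygosity pairs supplied")
    return {
        "table": {f"called_{c}|truth_{t}": v for (c, t), v in table.items()},
        "n": n,
        "concordance_rate_percent": 100.0 * agree / n,
    }


@dataclass
class ReplicateDesign:
    """Full factorial replicate design (operator x lot x day x replicate)."""

    operators: int = 2
    lots: int = 3
    days: int = 3
    replicates: int = 8

    @property
    def n_total(self) -> int:
        return self.operators * self.lots * self.days * self.replicates

    def cells(self) -> list[tuple[int, int, int]]:
        """Same-condition cells (operator, lot, day), each holding ``replicates`` runs."""
        return list(itertools.product(range(self.operators), range(self.lots), range(self.days)))

    def keys(self) -> list[tuple[int, int, int, int]]:
        return [c + (r,) for c in self.cells() for r in range(self.replicates)]


def precision_agreement(
    design: ReplicateDesign,
    expected: Mapping[str, str],
    detected: Mapping[tuple[int, int, int, int], Iterable[str]],
    vafs: Mapping[tuple[int, int, int, int], Mapping[str, float]] | None = None,
) -> dict:
    """Repeatability/reproducibility agreement over a replicate design.

    ``expected`` maps variant key -> class ('SNV' or 'indel'); ``detected``
    maps each design key (operator, lot, day, replicate) to the set of variant
    keys found. Agreement = detected / expected observations, per class;
    repeatability per same-condition octet, reproducibility over the whole
    design. Optional per-replicate VAFs yield per-variant mean/sd.
    """
    keys = design.keys()
    missing = [k for k in keys if k not in detected]
    if missing:
        raise ValidationError(f"missing design cells: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    classes = sorted(set(expected.values()))
    per_class_vars = {c: [v for v, vc in expected.items() if vc == c] for c in classes}

    def agreement(subset_keys: list[tuple[int, int, int, int]]) -> dict:
        out = {}
        for c in classes:
            variants = per_class_vars[c]
            n_expected = len(variants) * len(subset_keys)
            n_found = sum(1 for k in subset_keys for v in variants if v in set(detected[k]))
            out[c] = {
                "expected": n_expected,
                "detected": n_found,
                "agreement_percent": 100.0 * n_found / n_expected if n_expected else None,
            }
        return out

    repeatability = {
        f"operator{o}_lot{l}_day{d}": agreement([(o, l, d, r) for r in range(design.replicates)])
        for (o, l, d) in design.cells()
    }
    reproducibility = agreement(keys)

    vaf_stats = {}
    if vafs is not None:
        for v in expected:
            vals = [vafs[k][v] for k in keys if k in vafs and v in vafs[k]]
            if vals:
                arr = np.asarray(vals)
                vaf_stats[v] = {
                    "n": int(arr.size),
                    "mean_percent": float(100.0 * arr.mean()),
                    "sd_percent": float(100.0 * arr.std(ddof=1)) if arr.size > 1 else 0.0,
                }
    return {
        "design": {"operators": design.operators, "lots": design.lots,
                   "days": design.days, "replicates": design.replicates,
                   "n_total": design.n_total},
        "repeatability": repeatability,
        "reproducibility": reproducibility,
        "vaf_stats": vaf_stats,
    }


@dataclass
class DetectionRateResult:
    condition: str
    variant_class: str
    n_control: int
    n_condition: int
    gained: list[str]

    @property
    def rate(self) -> float:
        return self.n_condition / self.n_control

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "class": self.variant_class,
            "n_control": self.n_control,
            "n_condition": self.n_condition,
            "rate_percent": self.rate_percent,
            "gained": self.gained,
        }


def detection_rate(
    control: Mapping[str, Iterable[Hashable]],
    condition: Mapping[str, Iterable[Hashable]],
    condition_label: str = "condition",
) -> list[DetectionRateResult]:
    """Per-class fraction of control-detected variants also found under a condition.

    Variants found only under the condition are reported as ``gained`` and do
    not enter the rate.
    """
    results = []
    for vclass, ctrl in control.items():
        ctrl_set = set(ctrl)
        if not ctrl_set:
            raise ValidationError(f"{vclass}: empty control set")
        cond_set = set(condition.get(vclass, ()))
        results.append(
            DetectionRateResult(
                condition=condition_label,
                variant_class=vclass,
                n_control=len(ctrl_set),
                n_condition=len(ctrl_set & cond_set),
                gained=sorted(str(v) for v in cond_set - ctrl_set),
            )
        )
    return results
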