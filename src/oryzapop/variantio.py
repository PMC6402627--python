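"""Variant I/O and quality control.

Reads biallelic-SNP VCFs into an in-memory genotype matrix, profiles
call sets by the transition:transversion ratio along annotation bins,
applies hard annotation filters plus a missing-data filter, and computes
per-sample summary statistics (depth, call rate, heterozygosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Genotype code for a missing (no-call) genotype.
MISSING = -1

#: Canonical annotation order; also the fixed attribution order for filters.
ANNOTATION_NAMES = ("DP", "QD", "MQ", "MQRankSum", "ReadPosRankSum", "FS")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP variants with diploid genotype codes.

    Genotype codes: 0 = hom ref, 1 = het, 2 = hom alt, -1 = missing.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # (n_samples, n_variants) int8
    annotations: dict = field(default_factory=dict)  # name -> float array (nan = absent)
    functional_class: np.ndarray | None = None  # noncoding | synonymous | nonsynonymous

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_samples, self.n_variants):
            raise ValueError("genotype matrix shape mismatch")
        codes = np.unique(self.genotypes)
        if not np.all(np.isin(codes, [MISSING, 0, 1, 2])):
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        for a in np.concatenate([self.ref, self.alt]):
            if a not in _BASES:
                raise ValueError(f"non-ACGT allele {a!r}")

    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset to the variants selected by ``index`` (bool mask or indices)."""
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            annotations={k: v[index] for k, v in self.annotations.items()},
            functional_class=(
                None if self.functional_class is None else self.functional_class[index]
            ),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            genotypes=self.genotypes[index, :],
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)


def read_vcf(path) -> tuple[GenotypeMatrix, dict]:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are excluded and counted in the
    returned warnings dict. INFO annotations DP/QD/MQ/MQRankSum/
    ReadPosRankSum/FS are parsed where present (NaN when absent); the
    custom FC key carries the functional class when available.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows, fc = [], [], [], [], [], []
    ann = {name: [] for name in ANNOTATION_NAMES}
    warnings = {"multiallelic": 0, "non_snp": 0}
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            warnings["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.REF not in _BASES or v.ALT[0] not in _BASES:
            warnings["non_snp"] += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(code_map[v.gt_types])
        for name in ANNOTATION_NAMES:
            val = v.INFO.get(name)
            ann[name].append(np.nan if val is None else float(val))
        fc.append(v.INFO.get("FC"))
    n = len(pos)
    matrix = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=(
            np.stack(rows, axis=1).astype(np.int8) if n else np.zeros((len(samples), 0), np.int8)
        ),
        annotations={k: np.array(v, dtype=float) for k, v in ann.items()},
        functional_class=(
            np.array([x if x is not None else "" for x in fc], dtype=object)
            if any(x is not None for x in fc)
            else None
        ),
    )
    return matrix, warnings


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT alleles ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def tstv_ratio(ref, alt) -> float:
    """Ts:Tv over a set of substitutions; NaN when there are no transversions."""
    kinds = [classify_substitution(r, a) for r, a in zip(ref, alt)]
    ts = sum(k == "transition" for k in kinds)
    tv = len(kinds) - ts
    return ts / tv if tv else math.nan


def tstv_profile(matrix: GenotypeMatrix, annotation_name: str, n_bins: int) -> pd.DataFrame:
    """Bin SNPs along one annotation's observed range; per bin report the
    SNP count and Ts:Tv. Variants lacking the annotation go into a separate
    terminal row with NaN bin bounds.
    """
    if annotation_name not in matrix.annotations:
        raise KeyError(f"unknown annotation {annotation_name!r}")
    values = matrix.annotations[annotation_name]
    present = ~np.isnan(values)
    if not present.any():
        raise ValueError(f"annotation {annotation_name!r} absent for all variants")
    vals = values[present]
    edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
    # right-closed last bin so the max lands in the final interval
    which = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = np.flatnonzero(present)[which == b]
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": len(sel),
                "tstv": tstv_ratio(matrix.ref[sel], matrix.alt[sel]) if len(sel) else math.nan,
            }
        )
    missing_idx = np.flatnonzero(~present)
    rows.append(
        {
            "bin_low": math.nan,
            "bin_high": math.nan,
            "count": len(missing_idx),
            "tstv": tstv_ratio(matrix.ref[missing_idx], matrix.alt[missing_idx])
            if len(missing_idx)
            else math.nan,
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Interval:
    """Keep-interval for one annotation; infinite bounds pass everything."""

    low: float = -math.inf
    high: float = math.inf
    low_closed: bool = True
    high_closed: bool = True

    def contains(self, x: float) -> bool:
        if math.isnan(x):
            return True  # absent annotation cannot fail a hard filter
        lo = x >= self.low if self.low_closed else x > self.low
        hi = x <= self.high if self.high_closed else x < self.high
        return lo and hi


@dataclass
class FilterSpec:
    """Hard filter thresholds per annotation plus a missing-data cap.

    Attribution of removed variants follows the fixed order DP, QD, MQ,
    MQRankSum, ReadPosRankSum, FS, then missingness: the first failing
    filter claims the variant.
    """

    intervals: dict = field(default_factory=dict)  # name -> Interval
    max_missing_fraction: float = 1.0

    def __post_init__(self):
        for name, iv in self.intervals.items():
            if name not in ANNOTATION_NAMES:
                raise ValueError(f"unknown annotation {name!r}")
            if iv.low > iv.high:
                raise ValueError(f"ill-ordered interval for {name}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


#: Two named presets mirroring a permissive full call set and a strict one.
#: Thresholds are editable configuration, meant to be tuned with tstv_profile.
FILTER_PRESETS = {
    "full": FilterSpec(
        intervals={
            "QD": Interval(low=2.0),
            "MQ": Interval(low=40.0),
            "FS": Interval(high=60.0),
        },
        max_missing_fraction=0.5,
    ),
    "strict": FilterSpec(
        intervals={
            "DP": Interval(low=100.0),
            "QD": Interval(low=5.0),
            "MQ": Interval(low=50.0),
            "MQRankSum": Interval(low=-4.0, high=4.0),
            "ReadPosRankSum": Interval(low=-4.0, high=4.0),
            "FS": Interval(high=30.0),
        },
        max_missing_fraction=0.2,
    ),
}


def apply_filters(matrix: GenotypeMatrix, spec: FilterSpec) -> tuple[GenotypeMatrix, dict]:
    """Remove variants failing the spec; return survivors and removal counts
    attributed to the first failing filter in declared order.
    """
    n = matrix.n_variants
    removed_by = {name: 0 for name in ANNOTATION_NAMES}
    removed_by["missingness"] = 0
    keep = np.ones(n, dtype=bool)
    missing_frac = (matrix.genotypes == MISSING).mean(axis=0) if matrix.n_samples else np.zeros(n)
    for i in range(n):
        for name in ANNOTATION_NAMES:
            iv = spec.intervals.get(name)
            if iv is not None and name in matrix.annotations:
                if not iv.contains(matrix.annotations[name][i]):
                    removed_by[name] += 1
                    keep[i] = False
                    break
        else:
            if missing_frac[i] > spec.max_missing_fraction:
                removed_by["missingness"] += 1
                keep[i] = False
    return matrix.take_variants(keep), removed_by


def sample_stats(
    matrix: GenotypeMatrix, depths=None, coverage_threshold: float = 4.0
) -> pd.DataFrame:
    """Per-sample mean depth, call rate and heterozygosity.

    Heterozygosity is het calls over called genotypes (NaN when a sample
    has no calls). ``low_coverage`` flags samples with depth strictly
    below the threshold.
    """
    g = matrix.genotypes
    called = (g != MISSING).sum(axis=1)
    het = (g == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    call_rate = called / matrix.n_variants if matrix.n_variants else np.zeros(matrix.n_samples)
    depths = np.full(matrix.n_samples, np.nan) if depths is None else np.asarray(depths, float)
    return pd.DataFrame(
        {
            "sample": matrix.samples,
            "mean_depth": depths,
            "call_rate": call_rate,
            "heterozygosity": het_frac,
            "low_coverage": depths < coverage_threshold,
        }
    )
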