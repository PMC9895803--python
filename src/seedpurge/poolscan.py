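"""Two-pool linkage scanning for bulked-segregant variant calls.

In a bulked-segregant design, plants are pooled by phenotype (here a
"green" wild-type pool and an "albino" mutant pool) and each pool is
sequenced. At a variant fully linked to a recessive causal allele, every
albino-pool read carries the mutant allele and every green-pool read the
wild-type allele; unlinked polymorphisms segregate independently of the
phenotype and show similar allele frequencies in both pools.

The per-site statistic is the *linkage percent*: the percentage of reads
concordant with the phenotype model,

    100 * (green_wt + albino_mut) / (green_wt + green_mut + albino_wt + albino_mut).

Fully linked sites score 100; sites with equal allele frequencies in both
pools have expectation near 50. Candidate causal variants are sites that
pass a per-pool depth filter and score at or above a linkage threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
import pysam

from ._round import round_half_up

logger = logging.getLogger(__name__)

VariantClass = Literal["SNP", "insertion", "deletion"]


class ZeroDepthError(ValueError):
    """Raised when a linkage percent is requested for a site with no reads."""


@dataclass(frozen=True)
class PoolAlleleDepths:
    """The four read counts at one site: wild-type/mutant per pool."""

    green_wt: int
    green_mut: int
    albino_wt: int
    albino_mut: int

    def __post_init__(self) -> None:
        for name in ("green_wt", "green_mut", "albino_wt", "albino_mut"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def green_total(self) -> int:
        return self.green_wt + self.green_mut

    @property
    def albino_total(self) -> int:
        return self.albino_wt + self.albino_mut

    @property
    def total(self) -> int:
        return self.green_total + self.albino_total


@dataclass(frozen=True)
class PooledVariant:
    """A biallelic variant lifted into the two-pool model."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depths: PoolAlleleDepths

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def var_class(self) -> VariantClass:
        return classify_variant(self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Depth filter and candidacy rule.

    ``min_reads``/``max_reads`` are strict (exclusive) bounds on pool read
    totals; with ``per_pool`` both pools must satisfy them individually,
    otherwise the bound applies to the summed depth.
    """

    min_reads: int = 3
    max_reads: int = 100
    linkage_threshold: float = 100.0
    per_pool: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_reads < self.max_reads):
            raise ValueError("require 0 <= min_reads < max_reads")
        if not (0.0 <= self.linkage_threshold <= 100.0):
            raise ValueError("linkage_threshold must be in [0, 100]")


@dataclass(frozen=True)
class LinkageRecord:
    variant: PooledVariant
    linkage_percent: float
    passed_depth: bool
    candidate: bool


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a ref/alt allele pair as SNP, insertion or deletion."""
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if len(ref) == len(alt):
        if len(ref) != 1:
            raise ValueError(f"equal-length multi-base alleles (MNP) not supported: {ref}>{alt}")
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def linkage_percent(depths: PoolAlleleDepths) -> float:
    """Percent of reads concordant with the phenotype model, in [0, 100].

    Raises :class:`ZeroDepthError` when the site has no reads at all:
    the statistic is undefined there, not zero.
    """
    total = depths.total
    if total == 0:
        raise ZeroDepthError("linkage percent undefined at a site with zero total depth")
    return 100.0 * (depths.green_wt + depths.albino_mut) / total


def format_linkage(value: float) -> str:
    """Two-decimal half-up display, e.g. 74.07, 100.00."""
    return f"{round_half_up(value, 2):.2f}"


def depth_filter(depths: PoolAlleleDepths, cfg: FilterConfig = FilterConfig()) -> bool:
    """Strict depth window: min_reads < total < max_reads (per pool by default)."""
    if cfg.per_pool:
        return all(
            cfg.min_reads < t < cfg.max_reads
            for t in (depths.green_total, depths.albino_total)
        )
    return cfg.min_reads < depths.total < cfg.max_reads


def score_variant(variant: PooledVariant, cfg: FilterConfig = FilterConfig()) -> LinkageRecord:
    passed = depth_filter(variant.depths, cfg)
    pct = linkage_percent(variant.depths) if variant.depths.total > 0 else float("nan")
    candidate = bool(passed and pct >= cfg.linkage_threshold)
    return LinkageRecord(variant, pct, passed, candidate)


def select_candidates(
    variants: Iterable[PooledVariant], cfg: FilterConfig = FilterConfig()
) -> list[LinkageRecord]:
    """Score all variants; sort by linkage percent descending, ties by (chrom, pos)."""
    records = [score_variant(v, cfg) for v in variants]
    records.sort(key=lambda r: (-r.linkage_percent, r.variant.chrom, r.variant.pos))
    return records


def summarize_classes(variants: Sequence[PooledVariant]) -> dict[str, int]:
    """Counts per variant class; values sum to the input length."""
    counts = {"SNP": 0, "insertion": 0, "deletion": 0}
    for v in variants:
        counts[v.var_class] += 1
    return counts


def read_pooled_vcf(
    path: str,
    green_sample_name: str = "green",
    albino_sample_name: str = "albino",
) -> tuple[list[PooledVariant], int]:
    """Read a two-sample VCF with per-sample AD into PooledVariants.

    AD[0] maps to wild-type counts and AD[1] to mutated (ALT) counts.
    Multi-allelic records are skipped with a warning; the number skipped is
    returned alongside the variants.

    Returns (variants, n_skipped_multiallelic).
    """
    variants: list[PooledVariant] = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for name in (green_sample_name, albino_sample_name):
            if name not in samples:
                raise KeyError(f"sample {name!r} not in VCF (has {samples})")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                logger.warning(
                    "skipping multi-allelic record %s:%d (%s>%s)",
                    rec.chrom, rec.pos, rec.ref, ",".join(rec.alts or ()),
                )
                continue
            try:
                g_ad = rec.samples[green_sample_name]["AD"]
                a_ad = rec.samples[albino_sample_name]["AD"]
            except KeyError as exc:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks the AD FORMAT field"
                ) from exc
            if g_ad is None or a_ad is None or None in g_ad[:2] or None in a_ad[:2]:
                raise ValueError(f"record {rec.chrom}:{rec.pos} has missing AD values")
            depths = PoolAlleleDepths(
                green_wt=int(g_ad[0]), green_mut=int(g_ad[1]),
                albino_wt=int(a_ad[0]), albino_mut=int(a_ad[1]),
            )
            variants.append(
                PooledVariant(rec.chrom, rec.pos, rec.ref, str(rec.alts[0]), depths)
            )
    if skipped:
        logger.warning("skipped %d multi-allelic record(s)", skipped)
    return variants, skipped


def records_to_frame(records: Sequence[LinkageRecord]) -> pd.DataFrame:
    """Candidate table with one row per scored variant."""
    rows = []
    for r in records:
        v, d = r.variant, r.variant.depths
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "var_class": v.var_class,
                "green_wt": d.green_wt, "green_mut": d.green_mut,
                "albino_wt": d.albino_wt, "albino_mut": d.albino_mut,
                "linkage_percent": round_half_up(r.linkage_percent, 2),
                "passed_depth": r.passed_depth, "candidate": r.candidate,
            }
        )
    columns = [
        "chrom", "pos", "ref", "alt", "var_class", "green_wt", "green_mut",
        "albino_wt", "albino_mut", "linkage_percent", "passed_depth", "candidate",
    ]
    return pd.DataFrame(rows, columns=columns)
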