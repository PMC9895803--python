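"""Synthetic two-pool sequencing data emulating the albino breeder-seed study.

The generator reproduces the statistical structure of the study design: a
pool of 13 green plants and a pool of 10 albino plants from a selfing rice
population segregating one recessive lethal albino allele, sequenced to a
mean depth of ~10x per pool, with 216 unlinked background polymorphisms.

The population model: albino plants are homozygous mutant at the causal
site by definition of the phenotype. A green plant is a heterozygous
carrier with probability (h/2)/(1 - h/4) — the conditional probability of
being a carrier given a green phenotype, one selfing generation after the
population-wide heterozygote frequency was h. Background sites are in
Hardy-Weinberg proportions at a per-site allele frequency drawn once and
shared by both pools (unlinked sites have the same expected frequency in
both phenotype classes).

The sequencing model: per site and pool, total read depth is Poisson with
the configured mean, truncated to >= 1; mutant-allele read counts are
binomial at the realized pool allele frequency, with a symmetric per-read
allele-flip error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .consequence import GeneModel, SequenceVariant
from .poolscan import PoolAlleleDepths, PooledVariant

CAUSAL_CHROM = "chr4"
CAUSAL_POS = 1993  # anchor base 5' of the single-C insertion in the fixture gene
CAUSAL_REF = "G"
CAUSAL_ALT = "GC"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters; defaults are the study's own conditions."""

    n_green: int = 13
    n_albino: int = 10
    depth_mean: float = 10.0
    error_rate: float = 0.001
    n_background: int = 216
    carrier_freq: float = 0.0544  # h = 4 * 1.36% albino incidence
    causal_chrom: str = CAUSAL_CHROM
    causal_pos: int = CAUSAL_POS
    causal_ref: str = CAUSAL_REF
    causal_alt: str = CAUSAL_ALT
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_green, self.n_albino, self.n_background + 1) < 1:
            raise ValueError("plant counts must be >= 1 and n_background >= 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0.0 <= self.carrier_freq <= 1.0):
            raise ValueError("carrier_freq must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.background_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("background_freq_range must be within [0, 1]")

    @property
    def green_carrier_prob(self) -> float:
        """P(carrier | green phenotype) after one selfing generation."""
        h = self.carrier_freq
        return (h / 2.0) / (1.0 - h / 4.0) if h > 0 else 0.0


@dataclass(frozen=True)
class PlantGenotype:
    """One plant: phenotype plus allele dosage at the causal and background sites."""

    plant_id: str
    phenotype: str  # "green" | "albino"
    dosages: tuple[int, ...]  # index 0 = causal site, then background sites

    @property
    def causal_dosage(self) -> int:
        return self.dosages[0]


@dataclass(frozen=True)
class SimulatedDataset:
    config: SimConfig
    plants: list[PlantGenotype]
    variants: list[PooledVariant]
    truth: pd.DataFrame  # chrom, pos, ref, alt, green_freq, albino_freq, linked


def sample_population(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[PlantGenotype]:
    """Draw plant genotypes for both pools.

    Albino plants are homozygous mutant at the causal site; green plants are
    heterozygous with the conditional carrier probability. Background
    dosages are Binomial(2, f_site) with f_site ~ Uniform over
    ``background_freq_range``, the same f_site for all plants.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    lo, hi = config.background_freq_range
    site_freqs = rng.uniform(lo, hi, size=config.n_background)
    plants: list[PlantGenotype] = []
    p_carrier = config.green_carrier_prob
    for i in range(config.n_green):
        causal = 1 if rng.random() < p_carrier else 0
        bg = rng.binomial(2, site_freqs)
        plants.append(PlantGenotype(f"green_{i+1}", "green", (causal, *map(int, bg))))
    for i in range(config.n_albino):
        bg = rng.binomial(2, site_freqs)
        plants.append(PlantGenotype(f"albino_{i+1}", "albino", (2, *map(int, bg))))
    return plants


def _truncated_poisson(mean: float, rng: np.random.Generator) -> int:
    """Poisson(mean) conditioned on being >= 1."""
    while True:
        d = int(rng.poisson(mean))
        if d >= 1:
            return d


def simulate_pool_depths(
    green_freq: float,
    albino_freq: float,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PoolAlleleDepths:
    """Sample the four read counts at one site given realized pool allele frequencies."""
    rng = rng or np.random.default_rng(config.rng_seed)
    e = config.error_rate
    counts = {}
    for pool, f in (("green", green_freq), ("albino", albino_freq)):
        total = _truncated_poisson(config.depth_mean, rng)
        p_mut = f * (1.0 - e) + (1.0 - f) * e
        mut = int(rng.binomial(total, p_mut))
        counts[f"{pool}_mut"] = mut
        counts[f"{pool}_wt"] = total - mut
    return PoolAlleleDepths(
        green_wt=counts["green_wt"], green_mut=counts["green_mut"],
        albino_wt=counts["albino_wt"], albino_mut=counts["albino_mut"],
    )


_BASES = np.array(list("ACGT"))


def _draw_background_sites(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, str, str]]:
    """Unlinked site coordinates and alleles, spread over 12 chromosomes.

    The class mix (SNP / insertion / deletion) mirrors the study's observed
    composition (105:40:72).
    """
    sites: list[tuple[str, int, str, str]] = []
    used: set[tuple[str, int]] = {(config.causal_chrom, config.causal_pos)}
    class_p = np.array([105, 40, 72], dtype=float)
    class_p /= class_p.sum()
    while len(sites) < config.n_background:
        chrom = f"chr{rng.integers(1, 13)}"
        pos = int(rng.integers(1, 30_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        kind = rng.choice(3, p=class_p)
        ref = str(rng.choice(_BASES))
        if kind == 0:  # SNP
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif kind == 1:  # insertion
            alt = ref + str(rng.choice(_BASES))
        else:  # deletion
            ref = ref + str(rng.choice(_BASES))
            alt = ref[0]
        sites.append((chrom, pos, ref, alt))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Full simulation: population, per-site pool frequencies, read depths."""
    rng = np.random.default_rng(config.rng_seed)
    plants = sample_population(config, rng)
    background = _draw_background_sites(config, rng)
    site_list = [
        (config.causal_chrom, config.causal_pos, config.causal_ref, config.causal_alt)
    ] + background

    greens = [p for p in plants if p.phenotype == "green"]
    albinos = [p for p in plants if p.phenotype == "albino"]
    variants: list[PooledVariant] = []
    truth_rows = []
    for idx, (chrom, pos, ref, alt) in enumerate(site_list):
        g_f = sum(p.dosages[idx] for p in greens) / (2.0 * len(greens))
        a_f = sum(p.dosages[idx] for p in albinos) / (2.0 * len(albinos))
        depths = simulate_pool_depths(g_f, a_f, config, rng)
        variants.append(PooledVariant(chrom, pos, ref, alt, depths))
        truth_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "green_freq": g_f, "albino_freq": a_f, "linked": idx == 0,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(config, plants, variants, truth)


def write_simulated_vcf(
    variants: Sequence[PooledVariant],
    path: str | Path,
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write a two-sample VCF 4.2 (samples 'green', 'albino', GT + AD FORMAT).

    When ``truth`` is given, a TSV truth table is written next to the VCF
    with the suffix ``.truth.tsv``.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    contigs = sorted({v.chrom for v in variants}) or ["chr1"]
    for c in contigs:
        header.contigs.add(c, length=40_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample("green")
    header.add_sample("albino")
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.samples["green"]["AD"] = (v.depths.green_wt, v.depths.green_mut)
            rec.samples["albino"]["AD"] = (v.depths.albino_wt, v.depths.albino_mut)
            out.write(rec)
    if truth is not None:
        truth.to_csv(path.with_suffix(path.suffix + ".truth.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene fixture: a synthetic single-exon gene in which a single-C insertion
# inside codon 332 (CGG, Arg) turns it into CCG (Pro) and brings a TAG stop
# into frame 8 codons downstream, so the new stop codon's first base sits 23
# nucleotides 3' of the insertion junction. Verified by manual translation
# (see tests).
# ---------------------------------------------------------------------------

FIXTURE_GENE_ID = "SWLFIX1"
FIXTURE_CHROM = "chr4"
_FIXTURE_FLANK5 = 1000
_FIXTURE_FLANK3 = 500

# codon 1 ATG; codons 2..330 GCA (Ala); codon 331 GCG so the insertion anchor
# base is G (GC -> GCC in VCF terms); codon 332 CGG (Arg); codons 333..338
# CAC (His); codon 339 CAT; codon 340 AGC; codons 341..345 GCT; stop TAA.
# In the +1 shifted frame the same bases read GCA, CCA x6, then TAG.
FIXTURE_CDS = (
    "ATG" + "GCA" * 329 + "GCG" + "CGG"
    + "CAC" * 6 + "CA" + "TAGC" + "GCT" * 5 + "TAA"
)


def _fixture_flank(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=n))


@dataclass(frozen=True)
class GeneFixture:
    model: GeneModel
    reference: str  # full chromosome sequence
    variant: SequenceVariant
    cds: str


def make_gene_fixture() -> GeneFixture:
    """Deterministic gene fixture with the codon-332 frameshift insertion."""
    reference = (
        _fixture_flank(_FIXTURE_FLANK5, seed=42)
        + FIXTURE_CDS
        + _fixture_flank(_FIXTURE_FLANK3, seed=43)
    )
    start = _FIXTURE_FLANK5 + 1
    model = GeneModel(
        gene_id=FIXTURE_GENE_ID,
        chrom=FIXTURE_CHROM,
        strand="+",
        exons=((start, start + len(FIXTURE_CDS) - 1),),
    )
    # anchor = last base of codon 331 (CDS position 993) = genomic 1993
    anchor = start - 1 + 993
    variant = SequenceVariant(FIXTURE_CHROM, anchor, "G", "GC")
    assert reference[anchor - 1] == "G"
    return GeneFixture(model, reference, variant, FIXTURE_CDS)


def write_gene_fixture(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the fixture as FASTA + GFF3; returns (fasta_path, gff_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = make_gene_fixture()
    fasta = out_dir / "fixture_gene.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{fx.model.chrom}\n")
        seq = fx.reference
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    gff = out_dir / "fixture_gene.gff3"
    start, end = fx.model.span
    gid = fx.model.gene_id
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"{fx.model.chrom}\tseedpurge\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
        fh.write(
            f"{fx.model.chrom}\tseedpurge\tmRNA\t{start}\t{end}\t.\t+\t.\t"
            f"ID={gid}.1;Parent={gid}\n"
        )
        fh.write(
            f"{fx.model.chrom}\tseedpurge\tCDS\t{start}\t{end}\t.\t+\t0\t"
            f"ID={gid}.1.cds;Parent={gid}.1\n"
        )
    return fasta, gff
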