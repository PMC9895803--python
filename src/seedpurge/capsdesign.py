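"""CAPS (cleaved amplified polymorphic sequence) assay design and genotype calls.

A CAPS assay genotypes a variant by digesting a PCR amplicon with a
restriction enzyme whose recognition site is present in exactly one allele.
Homozygous wild-type (G) plants show the undigested band pattern,
homozygous mutant (A) plants the digested one, and heterozygotes (H) the
union of both. The study's assay: a 300-bp amplicon, Cfr10I (R/CCGGY, a
site created by the causal C insertion), giving G = {300}, A = {100, 200},
H = {100, 200, 300}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .consequence import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition pattern and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int  # 0-based offset of the cut within the recognition site

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in recognition pattern: {bad}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset must lie within the recognition site")

    @property
    def is_palindromic(self) -> bool:
        return iupac_revcomp(self.recognition.upper()) == self.recognition.upper()


@dataclass(frozen=True)
class Amplicon:
    """One allele's PCR product."""

    label: str  # "wild" | "mutant"
    sequence: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("amplicon sequence must be uppercase ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    """Predicted digest of a wild/mutant amplicon pair."""

    enzyme: EnzymeSpec
    wild_cuts: tuple[int, ...]
    mutant_cuts: tuple[int, ...]
    wild_fragments: tuple[int, ...]
    mutant_fragments: tuple[int, ...]
    bands: dict[str, tuple[int, ...]]  # genotype G/H/A -> sorted band sizes
    diagnostic: bool


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
    return re.compile(f"(?=({body}))")


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """All 0-based start positions of the recognition site, both strands.

    A bottom-strand site is reported by the top-strand start position of its
    footprint. For palindromic patterns (e.g. RCCGGY) the two strands yield
    the same set, deduplicated here.
    """
    seq = sequence.upper()
    fwd = {m.start() for m in _pattern_regex(enzyme.recognition).finditer(seq)}
    if enzyme.is_palindromic:
        return sorted(fwd)
    rc = iupac_revcomp(enzyme.recognition)
    rev = {m.start() for m in _pattern_regex(rc).finditer(seq)}
    return sorted(fwd | rev)


def find_diagnostic_sites(
    wild: Amplicon, mutant: Amplicon, enzyme: EnzymeSpec
) -> list[tuple[int, str]]:
    """Sites present in exactly one allele, as (position, allele_label) pairs."""
    w = set(find_sites(wild.sequence, enzyme))
    m = set(find_sites(mutant.sequence, enzyme))
    out = [(p, "wild") for p in w - m] + [(p, "mutant") for p in m - w]
    return sorted(out)


def cut_positions(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand cut coordinates for every site, clipped to the interior."""
    cuts = set()
    seq = sequence.upper()
    for m in _pattern_regex(enzyme.recognition).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc = iupac_revcomp(enzyme.recognition)
        for m in _pattern_regex(rc).finditer(seq):
            cuts.add(m.start() + len(enzyme.recognition) - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_fragments(amplicon_length: int, cuts: Sequence[int]) -> list[int]:
    """Fragment lengths from cut positions; lengths sum to the amplicon length."""
    cuts = list(cuts)
    if len(set(cuts)) != len(cuts):
        raise ValueError("duplicate cut positions")
    if any(not (0 < c < amplicon_length) for c in cuts):
        raise ValueError("cut positions must lie strictly inside the amplicon")
    bounds = [0, *sorted(cuts), amplicon_length]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def predict_bands(
    wild_fragments: Iterable[int], mutant_fragments: Iterable[int], genotype: str
) -> tuple[int, ...]:
    """Expected gel bands for a genotype: G = wild, A = mutant, H = union."""
    w, m = sorted(set(wild_fragments)), sorted(set(mutant_fragments))
    if genotype == "G":
        return tuple(w)
    if genotype == "A":
        return tuple(m)
    if genotype == "H":
        return tuple(sorted(set(w) | set(m)))
    raise ValueError(f"genotype must be G, H or A, got {genotype!r}")


def design_assay(wild: Amplicon, mutant: Amplicon, enzyme: EnzymeSpec) -> DigestResult:
    """Digest both alleles and tabulate per-genotype band patterns."""
    w_cuts = tuple(cut_positions(wild.sequence, enzyme))
    m_cuts = tuple(cut_positions(mutant.sequence, enzyme))
    w_frag = tuple(digest_fragments(wild.length, w_cuts))
    m_frag = tuple(digest_fragments(mutant.length, m_cuts))
    bands = {g: predict_bands(w_frag, m_frag, g) for g in "GHA"}
    return DigestResult(
        enzyme=enzyme, wild_cuts=w_cuts, mutant_cuts=m_cuts,
        wild_fragments=w_frag, mutant_fragments=m_frag,
        bands=bands, diagnostic=bands["G"] != bands["A"],
    )


def call_genotype(
    observed_bands: Iterable[int],
    expected: Mapping[str, Sequence[int]],
    tolerance: float = 10.0,
) -> str:
    """Match observed band sizes to the nearest expected G/H/A pattern.

    A pattern matches when it has the same number of bands and each
    observed band is within ``tolerance`` bp of the corresponding expected
    band (both sorted). Returns 'ambiguous' unless exactly one genotype
    matches.
    """
    obs = sorted(set(observed_bands))
    matches = []
    for genotype, pattern in expected.items():
        pat = sorted(set(pattern))
        if len(pat) == len(obs) and all(abs(o - p) <= tolerance for o, p in zip(obs, pat)):
            matches.append(genotype)
    return matches[0] if len(matches) == 1 else "ambiguous"


def load_enzymes(path: Optional[str | Path] = None) -> dict[str, EnzymeSpec]:
    """Load enzyme definitions from YAML (bundled table by default)."""
    if path is None:
        text = resources.files("seedpurge").joinpath("data/enzymes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {
        name: EnzymeSpec(name=name, recognition=spec["recognition"],
                         cut_offset=int(spec["cut_offset"]))
        for name, spec in raw.items()
    }


def caps_fixture() -> tuple[Amplicon, Amplicon]:
    """Synthetic 300-bp amplicon pair modelling the study's assay.

    The wild allele has no Cfr10I site; a single-C insertion at position 100
    creates one (ACCGGC), placing the cut 100 bp from the amplicon start so
    the mutant digests to 100 + 200 bp. Both alleles are modelled at 300 bp
    (the mutant trimmed by one terminal base), matching the gel-resolution
    band sizes the assay reports.
    """
    base = ("ACT" * 33)  # 99 bp, no CCGG anywhere
    wild = base + "ACGGC" + ("ACT" * 66)[: 300 - 104]
    assert len(wild) == 300
    mutant = (wild[:100] + "C" + wild[100:])[:300]
    cfr10i = load_enzymes()["Cfr10I"]
    w, m = Amplicon("wild", wild), Amplicon("mutant", mutant)
    assert find_sites(wild, cfr10i) == []
    assert find_sites(mutant, cfr10i) == [99]
    return w, m
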