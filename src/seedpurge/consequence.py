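"""Coding-consequence prediction for variants on gene models.

Projects a genomic variant through a (possibly multi-exon, either-strand)
gene model onto the spliced coding sequence, translates wild-type and
mutant CDS with the standard nuclear code, and reports the consequence
class, the first changed residue (e.g. R332P), the genomic position of any
premature stop codon, and an impact tier.

Coordinates are 1-based inclusive genomic throughout; an insertion is
anchored to the base immediately 5' of the inserted sequence (the VCF
convention), so "insertion between bases p and p+1" has pos = p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import gffutils
from Bio.Seq import Seq

from .poolscan import classify_variant

ConsequenceClass = Literal[
    "frameshift", "missense", "synonymous", "in_frame_indel", "noncoding", "no_effect"
]
Impact = Literal["high", "moderate", "low", "modifier"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidGeneModelError(ValueError):
    """Gene model violates CDS structural requirements."""


@dataclass(frozen=True)
class SequenceVariant:
    """A simple sequence variant in genomic coordinates."""

    chrom: str
    pos: int  # 1-based; 5'-flanking base for insertions, first affected base otherwise
    ref: str
    alt: str

    @property
    def var_class(self) -> str:
        return classify_variant(self.ref, self.alt)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one protein-coding transcript.

    ``exons`` are 1-based inclusive genomic intervals, sorted by start and
    non-overlapping; they are taken to be coding (CDS segments).
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_to_cds(self, gpos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, or None if intronic/outside."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for start, end in exons:
            if start <= gpos <= end:
                if self.strand == "+":
                    return offset + (gpos - start) + 1
                return offset + (end - gpos) + 1
            offset += end - start + 1
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        """Genomic position of a 1-based CDS coordinate."""
        if not (1 <= cpos <= self.cds_length):
            raise ValueError(f"CDS position {cpos} outside 1..{self.cds_length}")
        remaining = cpos - 1
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for start, end in exons:
            length = end - start + 1
            if remaining < length:
                return start + remaining if self.strand == "+" else end - remaining
            remaining -= length
        raise AssertionError("unreachable")

    def extract_cds(self, reference: str) -> str:
        """Spliced CDS in transcript orientation from a full chromosome sequence."""
        parts = [reference[start - 1 : end] for start, end in self.exons]
        cds = "".join(parts).upper()
        return revcomp(cds) if self.strand == "-" else cds

    def validate_cds(self, reference: str) -> None:
        cds = self.extract_cds(reference)
        if len(cds) % 3 != 0:
            raise InvalidGeneModelError("spliced CDS length not divisible by 3")
        if not cds.startswith("ATG"):
            raise InvalidGeneModelError("CDS does not begin with ATG")
        protein = str(Seq(cds).translate())
        if not protein.endswith("*"):
            raise InvalidGeneModelError("CDS does not end with a stop codon")
        if "*" in protein[:-1]:
            raise InvalidGeneModelError("internal stop codon in wild-type CDS")


@dataclass(frozen=True)
class ConsequenceReport:
    consequence_class: ConsequenceClass
    aa_change: str  # e.g. "R332P"; empty when no residue changes
    premature_stop: Optional[int]  # genomic position of the new stop codon's first base
    impact: Impact

    def describe(self, gene_id: str = "") -> str:
        parts = [gene_id, self.consequence_class] if gene_id else [self.consequence_class]
        if self.aa_change:
            parts.append(self.aa_change)
        if self.premature_stop is not None:
            parts.append(f"premature-stop@{self.premature_stop}")
        parts.append(f"impact={self.impact}")
        return " ".join(parts)


def gene_model_from_gff(gff_path: str, gene_id: str | None = None) -> GeneModel:
    """Build a GeneModel from the CDS features of a GFF3 file."""
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    cds = [f for f in db.features_of_type("CDS")]
    if gene_id is not None:
        cds = [f for f in cds if gene_id in f.attributes.get("Parent", []) + f.attributes.get("ID", [])
               or any(gene_id in v for v in f.attributes.get("Parent", []))]
    if not cds:
        raise ValueError(f"no CDS features found in {gff_path}")
    chrom = cds[0].seqid
    strand = cds[0].strand
    exons = tuple(sorted((f.start, f.end) for f in cds))
    gid = gene_id or cds[0].attributes.get("Parent", ["gene"])[0]
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=exons)


def _project_insertion(model: GeneModel, cds: str, v: SequenceVariant) -> Optional[str]:
    """Mutant CDS for an insertion, or None if the inserted bases fall outside the CDS."""
    inserted = v.alt[len(v.ref):]
    anchor = model.genomic_to_cds(v.pos)
    after = model.genomic_to_cds(v.pos + 1)
    if model.strand == "+":
        # insert between CDS(pos) and CDS(pos+1); an anchor outside the CDS
        # (5' of the ATG, or intronic) leaves the coding sequence untouched
        if anchor is None:
            return None
        return cds[:anchor] + inserted.upper() + cds[anchor:]
    # minus strand: genomic (pos, pos+1) junction maps to CDS (after, anchor)
    if after is None:
        return None
    cut = after
    return cds[:cut] + revcomp(inserted.upper()) + cds[cut:]


def apply_variant_to_cds(model: GeneModel, reference: str, v: SequenceVariant) -> Optional[str]:
    """Return the mutant spliced CDS, or None when the variant does not touch the CDS.

    Raises ValueError if the variant lies outside the gene span entirely.
    """
    if v.chrom != model.chrom:
        raise ValueError(f"variant on {v.chrom} but gene on {model.chrom}")
    span = model.span
    if not (span[0] - 1 <= v.pos <= span[1]):
        raise ValueError(f"variant at {v.pos} outside gene span {span}")
    cds = model.extract_cds(reference)
    vclass = v.var_class
    if vclass == "insertion":
        return _project_insertion(model, cds, v)
    if vclass == "SNP":
        cpos = model.genomic_to_cds(v.pos)
        if cpos is None:
            return None
        base = v.alt if model.strand == "+" else revcomp(v.alt)
        ref_base = v.ref if model.strand == "+" else revcomp(v.ref)
        if cds[cpos - 1] != ref_base.upper():
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: CDS has {cds[cpos-1]}, variant says {ref_base}"
            )
        return cds[: cpos - 1] + base.upper() + cds[cpos:]
    # deletion: ref = anchor base + deleted bases
    del_start, del_end = v.pos + 1, v.pos + len(v.ref) - 1
    cpositions = [model.genomic_to_cds(g) for g in range(del_start, del_end + 1)]
    if all(c is None for c in cpositions):
        return None
    if any(c is None for c in cpositions):
        raise ValueError("deletion partially overlaps the CDS; not supported")
    keep = set(cpositions)
    return "".join(b for i, b in enumerate(cds, start=1) if i not in keep)


def _translate(cds: str) -> str:
    """Translate to the first stop (exclusive); standard nuclear code."""
    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = protein.find("*")
    return protein if stop == -1 else protein[:stop]


def translate_and_compare(wild_cds: str, mutant_cds: str) -> tuple[str, Optional[int], bool]:
    """Compare translations of wild-type and mutant CDS.

    Returns (aa_change, premature_stop_cds_pos, premature) where
    ``premature_stop_cds_pos`` is the 1-based position, in MUTANT CDS
    coordinates, of the first base of the mutant's stop codon when the
    mutant protein terminates before the wild-type terminal codon.
    """
    for name, cds in (("wild-type", wild_cds), ("mutant", mutant_cds)):
        if not cds.startswith("ATG"):
            raise ValueError(f"{name} CDS does not begin with ATG")
    wild_prot = _translate(wild_cds)
    mut_prot = _translate(mutant_cds)
    aa_change = ""
    for i, (w, m) in enumerate(zip(wild_prot, mut_prot), start=1):
        if w != m:
            aa_change = f"{w}{i}{m}"
            break
    else:
        if len(mut_prot) < len(wild_prot):
            # truncation with no substitution before it
            i = len(mut_prot) + 1
            if i <= len(wild_prot):
                aa_change = f"{wild_prot[i - 1]}{i}*"
    premature = len(mut_prot) < len(wild_prot)
    stop_cds_pos = 3 * len(mut_prot) + 1 if premature else None
    return aa_change, stop_cds_pos, premature


def _mutant_to_wild_cds(mpos: int, v_cds_anchor: int, indel_delta: int) -> int:
    """Map a mutant-CDS coordinate back to wild-CDS coordinates across one indel."""
    if mpos <= v_cds_anchor:
        return mpos
    return mpos - indel_delta


def predict_consequence(model: GeneModel, reference: str, v: SequenceVariant) -> ConsequenceReport:
    """Full consequence call for one variant on one gene model."""
    model.validate_cds(reference)
    wild_cds = model.extract_cds(reference)
    mutant_cds = apply_variant_to_cds(model, reference, v)
    if mutant_cds is None:
        return ConsequenceReport("noncoding", "", None, "modifier")
    if mutant_cds == wild_cds:
        return ConsequenceReport("no_effect", "", None, "low")

    delta = len(mutant_cds) - len(wild_cds)
    aa_change, stop_cds_pos, premature = translate_and_compare(wild_cds, mutant_cds)

    if delta != 0:
        cls: ConsequenceClass = "frameshift" if delta % 3 != 0 else "in_frame_indel"
    else:
        cls = "missense" if aa_change else "synonymous"

    premature_stop_genomic: Optional[int] = None
    if premature and stop_cds_pos is not None:
        if delta != 0:
            # anchor in wild-CDS coordinates: last conserved base before the indel
            if model.strand == "+":
                anchor_c = model.genomic_to_cds(v.pos) or 0
            else:
                anchor_c = model.genomic_to_cds(v.pos + len(v.ref)) or 0
            wild_c = _mutant_to_wild_cds(stop_cds_pos, anchor_c, delta)
        else:
            wild_c = stop_cds_pos
        wild_c = min(max(wild_c, 1), model.cds_length)
        premature_stop_genomic = model.cds_to_genomic(wild_c)

    impact = classify_impact(cls, premature)
    return ConsequenceReport(cls, aa_change, premature_stop_genomic, impact)


def classify_impact(consequence_class: ConsequenceClass, premature_stop: bool = False) -> Impact:
    """Impact tier: frameshift/premature stop high, missense or in-frame indel
    moderate, synonymous (or no effect) low, noncoding modifier."""
    if consequence_class == "frameshift" or premature_stop:
        return "high"
    if consequence_class in ("missense", "in_frame_indel"):
        return "moderate"
    if consequence_class in ("synonymous", "no_effect"):
        return "low"
    return "modifier"
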