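"""X/Y clone comparison, identity, XY-pattern variant screening, and
missense annotation.

Sequences are assumed pre-aligned to a common reference with no indels;
only substitution variants are called.  Indel/repeat screening is noted as
not implemented in variant reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "VariantCall",
    "CdsModel",
    "Consequence",
    "sequence_identity",
    "call_variants",
    "screen_xy_pattern",
    "annotate_missense",
]


@dataclass
class VariantCall:
    """A substitution site with per-individual unordered genotypes."""

    chrom: str
    pos_bp: int  # 1-based from the 5' end of the reference clone
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)
    source: str = "cloned"

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or any(
            len(a) != 1 for a in self.alt_alleles
        ):
            raise ValueError("snp alleles must be single bases")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alt allele equals ref")

    @property
    def alt_allele(self) -> str:
        return self.alt_alleles[0]


@dataclass
class CdsModel:
    """Exon intervals of one coding transcript, 1-based closed, on a strand."""

    transcript_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        for s, e in ex:
            if s > e or s < 1:
                raise ValueError(f"bad exon interval ({s}, {e})")
        self.exons = ex  # stored in genomic order; strand governs CDS order

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genomic_to_cds(self, pos_bp: int) -> int | None:
        """0-based CDS offset of a genomic position, or None if intronic."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            if s <= pos_bp <= e:
                if self.strand == "+":
                    return offset + (pos_bp - s)
                return offset + (e - pos_bp)
            offset += e - s + 1
        return None

    def cds_sequence(self, genome: str) -> str:
        parts = [genome[s - 1 : e] for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class Consequence:
    kind: str  # missense | synonymous | stop_gained | stop_lost | non-coding
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    protein_pos: int | None = None


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two pre-aligned equal-length
    sequences, case-insensitive; positions where either base is N are
    excluded from both numerator and denominator."""
    if len(a) != len(b):
        raise ValueError(
            f"alignment required: lengths differ ({len(a)} vs {len(b)})"
        )
    a, b = a.upper(), b.upper()
    matches = total = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        total += 1
        matches += x == y
    if total == 0:
        raise ValueError("identity undefined: no non-N positions")
    return matches / total


# ---------------------------------------------------------------------------
# Variant calling from clone pairs
# ---------------------------------------------------------------------------

def call_variants(
    pairs: dict[str, tuple[str, str]],
    ref: str,
    chrom: str = "ref",
) -> list[VariantCall]:
    """Call substitution variants from per-male (X clone, Y clone) pairs.

    Every position where any clone differs from *ref* becomes a
    :class:`VariantCall`; each male's genotype is the unordered pair of his
    X and Y bases, so males carrying only reference bases at another male's
    variant site are ref/ref there.
    """
    ref = ref.upper()
    norm = {}
    for male, (x, y) in pairs.items():
        if len(x) != len(ref) or len(y) != len(ref):
            raise ValueError(
                f"male {male}: clone length differs from reference"
            )
        norm[male] = (x.upper(), y.upper())
    sites: dict[int, set[str]] = {}
    for x, y in norm.values():
        for i, (bx, by, br) in enumerate(zip(x, y, ref)):
            for base in (bx, by):
                if base != br and base != "N":
                    sites.setdefault(i, set()).add(base)
    calls = []
    for i in sorted(sites):
        genotypes = {
            male: tuple(sorted((x[i], y[i]))) for male, (x, y) in norm.items()
        }
        calls.append(
            VariantCall(
                chrom,
                i + 1,
                ref[i],
                tuple(sorted(sites[i])),
                genotypes,
                source="cloned",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# XY-pattern screen
# ---------------------------------------------------------------------------

def screen_xy_pattern(
    calls: list[VariantCall], sexes: dict[str, str]
) -> tuple[list[VariantCall], dict[int, tuple[int, int]]]:
    """Variants heterozygous in *every* genotyped male and, when female
    genotypes are present, homozygous in every female.

    Returns the candidate list plus per-variant ``{pos: (n_het_males,
    n_males)}`` counts.  A variant with no genotyped male raises.
    """
    candidates = []
    counts: dict[int, tuple[int, int]] = {}
    for call in calls:
        male_gts = [
            g
            for iid, g in call.genotypes.items()
            if sexes.get(iid) == "male"
        ]
        female_gts = [
            g
            for iid, g in call.genotypes.items()
            if sexes.get(iid) == "female"
        ]
        if not male_gts:
            raise ValueError(
                f"screen undefined at pos {call.pos_bp}: no genotyped males"
            )
        n_het = sum(g[0] != g[1] for g in male_gts)
        counts[call.pos_bp] = (n_het, len(male_gts))
        if n_het == len(male_gts) and all(g[0] == g[1] for g in female_gts):
            candidates.append(call)
    return candidates, counts


# ---------------------------------------------------------------------------
# Missense annotation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def annotate_missense(
    v: VariantCall, cds: CdsModel, genome: str
) -> Consequence:
    """Codon-level consequence of a substitution under the standard genetic
    code.

    Intronic/intergenic positions return a ``non-coding`` record.  The
    genome must match the variant's reference allele and the CDS length must
    be a whole number of codons past the frame offset; violations raise.
    """
    genome = genome.upper()
    if genome[v.pos_bp - 1] != v.ref_allele:
        raise ValueError(
            f"model error: genome has {genome[v.pos_bp - 1]!r} at position "
            f"{v.pos_bp}, variant ref is {v.ref_allele!r}"
        )
    cds_idx = cds.genomic_to_cds(v.pos_bp)
    if cds_idx is None:
        return Consequence("non-coding")
    cds_idx -= cds.frame_offset
    if cds_idx < 0:
        return Consequence("non-coding")
    cds_seq = cds.cds_sequence(genome)[cds.frame_offset :]
    if len(cds_seq) % 3 != 0:
        raise ValueError(
            "model error: CDS length is not a whole number of codons"
        )
    codon_i = cds_idx // 3
    within = cds_idx % 3
    codon_ref = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt = v.alt_allele
    if cds.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    codon_alt = codon_ref[:within] + alt + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        kind = "synonymous"
    elif aa_alt == "*":
        kind = "stop_gained"
    elif aa_ref == "*":
        kind = "stop_lost"
    else:
        kind = "missense"
    return Consequence(kind, codon_ref, codon_alt, aa_ref, aa_alt, codon_i + 1)
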