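"""Reference panels built from published genotype-count tables.

The only real data the pipeline consumes are printed genotype counts for a
wild panel of 58 females and 47 males at two tightly linked SNPs, plus the
per-sex sample sizes of two congeneric species panels.  These builders expand
those counts into :class:`~protosex.data_model.GenotypeMatrix` objects so
every downstream statistic can be recomputed from first principles.
"""

from __future__ import annotations

from .data_model import GenotypeMatrix, Individual, Marker

__all__ = [
    "SNP_7271",
    "SNP_7412",
    "wild_panel",
    "species_panel_perfect_split",
]

#: exonic C/G SNP; heterozygous in every male, C-homozygous in every female
SNP_7271 = Marker("SNP7271", "SD3-14k", 7271, "snp", frozenset({"C", "G"}))

#: intronic G/C SNP 141 bp away, in strong but imperfect LD with SNP7271
SNP_7412 = Marker("SNP7412", "SD3-14k", 7412, "snp", frozenset({"C", "G"}))

# printed wild-panel genotype distribution at SNP7412:
#   females: 53 GG, 5 CG;  males: 4 GG, 40 CG, 2 CC, 1 undetermined
_FEMALE_7412 = [("G", "G")] * 53 + [("C", "G")] * 5
_MALE_7412 = [("G", "G")] * 4 + [("C", "G")] * 40 + [("C", "C")] * 2 + [None]


def wild_panel() -> GenotypeMatrix:
    """The 105-fish wild panel at SNP7271 and SNP7412.

    Every female is C/C and every male C/G at SNP7271; SNP7412 genotypes
    follow the printed distribution (one male undetermined).  The joint
    two-locus genotypes are fully determined because the SNP7271 genotype is
    a function of sex.
    """
    individuals = []
    genotypes = []
    for i, g7412 in enumerate(_FEMALE_7412):
        individuals.append(Individual(f"F{i + 1:03d}", "female", "wild"))
        genotypes.append([("C", "C"), g7412])
    for i, g7412 in enumerate(_MALE_7412):
        individuals.append(Individual(f"M{i + 1:03d}", "male", "wild"))
        genotypes.append([("C", "G"), g7412])
    return GenotypeMatrix(individuals, [SNP_7271, SNP_7412], genotypes)


def species_panel_perfect_split(
    species: str, n_females: int, n_males: int, marker: Marker = SNP_7271
) -> GenotypeMatrix:
    """A one-marker panel with the perfect recessive split: all females
    homozygous major, all males heterozygous.

    Mirrors the congener panels (8 females / 8 males and 6 females / 7 males)
    used for the trans-species association test.
    """
    a, b = sorted(marker.alleles)
    individuals = []
    genotypes = []
    for i in range(n_females):
        individuals.append(Individual(f"{species}_F{i + 1}", "female", species))
        genotypes.append([(a, a)])
    for i in range(n_males):
        individuals.append(Individual(f"{species}_M{i + 1}", "male", species))
        genotypes.append([(a, b)])
    return GenotypeMatrix(individuals, [marker], genotypes)
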