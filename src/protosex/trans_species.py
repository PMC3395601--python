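"""Trans-species polymorphism detection and per-species / pooled
sex-association tests.

A polymorphism is *conserved* across species only when the homologous
position carries the identical allele pair; a conserved variant earns the
``conserved_associated`` verdict only with perfect genotype-sex
correspondence (zero recessive-model discordance) in every species where it
segregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .association import (
    CountTable2x2,
    DegenerateTableWarning,
    fisher_exact,
    major_allele,
    recessive_discordance,
)
from .data_model import GenotypeMatrix, Interval

__all__ = [
    "SpeciesPanel",
    "VariantConservation",
    "ConservationReport",
    "shared_polymorphisms",
    "per_species_association",
    "pooled_association",
    "conservation_report",
]


@dataclass
class SpeciesPanel:
    species: str
    matrix: GenotypeMatrix
    region: Interval | None = None

    def __post_init__(self) -> None:
        if self.region is not None:
            for m in self.matrix.markers:
                if not self.region.contains(m.pos_bp):
                    raise ValueError(
                        f"marker {m.id} outside declared region"
                    )
        for ind in self.matrix.individuals:
            if ind.sex == "unknown":
                raise ValueError(
                    f"{self.species}: individual {ind.id} has unknown sex"
                )


@dataclass
class VariantConservation:
    chrom: str
    pos_bp: int
    alleles: frozenset[str]
    present_in: list[str]
    associated_in: list[str] = field(default_factory=list)
    per_species_p: dict[str, float | None] = field(default_factory=dict)
    pooled_p: float | None = None
    verdict: str = "private"


@dataclass
class ConservationReport:
    variants: list[VariantConservation]

    def conserved_associated(self) -> list[VariantConservation]:
        return [v for v in self.variants if v.verdict == "conserved_associated"]


def _is_polymorphic(matrix: GenotypeMatrix, marker_id: str) -> bool:
    seen: set[str] = set()
    for g in matrix.column(marker_id):
        if g is not None:
            seen.update(g)
    return len(seen) >= 2


def shared_polymorphisms(
    panels: list[SpeciesPanel],
) -> dict[tuple[str, int], list[str]]:
    """Map each variant position to the species in which both alleles
    segregate; returns only positions polymorphic in two or more species.

    Markers occupying the same position in different panels must declare the
    same allele pair, otherwise a coordinate-conflict error is raised.
    """
    allele_defs: dict[tuple[str, int], frozenset[str]] = {}
    poly: dict[tuple[str, int], list[str]] = {}
    for panel in panels:
        for m in panel.matrix.markers:
            key = (m.chrom, m.pos_bp)
            if key in allele_defs and allele_defs[key] != m.alleles:
                raise ValueError(
                    f"coordinate conflict at {key}: alleles "
                    f"{sorted(allele_defs[key])} vs {sorted(m.alleles)}"
                )
            allele_defs.setdefault(key, m.alleles)
            if _is_polymorphic(panel.matrix, m.id):
                poly.setdefault(key, []).append(panel.species)
    return {k: v for k, v in poly.items() if len(v) >= 2}


def _marker_at(panel: SpeciesPanel, chrom: str, pos_bp: int) -> str | None:
    for m in panel.matrix.markers:
        if m.chrom == chrom and m.pos_bp == pos_bp:
            return m.id
    return None


def per_species_association(
    panels: list[SpeciesPanel], chrom: str, pos_bp: int
) -> dict[str, float | None]:
    """Two-sided genotypic 2x2 exact p per species (homozygous-major vs
    other by sex).  Species where the site is absent or monomorphic map to
    None."""
    out: dict[str, float | None] = {}
    for panel in panels:
        mid = _marker_at(panel, chrom, pos_bp)
        if mid is None or not _is_polymorphic(panel.matrix, mid):
            out[panel.species] = None
            continue
        maj = major_allele(panel.matrix, mid)
        a = b = c = d = 0
        j = panel.matrix.marker_index(mid)
        for ind, row in zip(panel.matrix.individuals, panel.matrix.genotypes):
            g = row[j]
            if g is None:
                continue
            hom = g[0] == g[1] == maj
            if ind.sex == "female":
                a, b = a + hom, b + (not hom)
            else:
                c, d = c + hom, d + (not hom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateTableWarning)
            out[panel.species] = fisher_exact(
                CountTable2x2(a, b, c, d), "two_sided"
            )
    return out


def pooled_association(
    panels: list[SpeciesPanel], chrom: str, pos_bp: int
) -> float:
    """Allele-count 2x2 exact test pooled over every species carrying the
    site: allele counts are summed by sex across species and tested
    two-sided."""
    a = b = c = d = 0
    n_present = 0
    for panel in panels:
        mid = _marker_at(panel, chrom, pos_bp)
        if mid is None:
            continue
        n_present += 1
        maj = major_allele(panel.matrix, mid)
        j = panel.matrix.marker_index(mid)
        for ind, row in zip(panel.matrix.individuals, panel.matrix.genotypes):
            g = row[j]
            if g is None:
                continue
            n_maj = sum(x == maj for x in g)
            if ind.sex == "female":
                a, b = a + n_maj, b + (2 - n_maj)
            else:
                c, d = c + n_maj, d + (2 - n_maj)
    if n_present == 0:
        raise ValueError(f"no panel carries position {(chrom, pos_bp)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateTableWarning)
        return fisher_exact(CountTable2x2(a, b, c, d), "two_sided")


def conservation_report(panels: list[SpeciesPanel]) -> ConservationReport:
    """Classify every variant position across species panels.

    Verdicts: ``conserved_associated`` (polymorphic in >= 2 species with
    zero recessive-model discordance in every species where polymorphic),
    ``conserved_unassociated`` (shared but imperfect somewhere), and
    ``private`` (polymorphic in exactly one species).
    """
    # every position polymorphic anywhere
    positions: dict[tuple[str, int], frozenset[str]] = {}
    poly_in: dict[tuple[str, int], list[str]] = {}
    for panel in panels:
        for m in panel.matrix.markers:
            key = (m.chrom, m.pos_bp)
            if _is_polymorphic(panel.matrix, m.id):
                positions.setdefault(key, m.alleles)
                poly_in.setdefault(key, []).append(panel.species)
    shared = shared_polymorphisms(panels)  # also validates allele defs

    variants = []
    for key in sorted(positions):
        chrom, pos = key
        present = sorted(poly_in[key])
        per_p = per_species_association(panels, chrom, pos)
        pooled = pooled_association(panels, chrom, pos)
        associated = []
        for panel in panels:
            if panel.species not in present:
                continue
            mid = _marker_at(panel, chrom, pos)
            discordant, _ = recessive_discordance(panel.matrix, mid)
            if not discordant:
                associated.append(panel.species)
        if key in shared:
            verdict = (
                "conserved_associated"
                if sorted(associated) == present
                else "conserved_unassociated"
            )
        else:
            verdict = "private"
        variants.append(
            VariantConservation(
                chrom,
                pos,
                positions[key],
                present,
                sorted(associated),
                per_p,
                pooled,
                verdict,
            )
        )
    return ConservationReport(variants)
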