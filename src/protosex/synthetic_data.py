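"""Forward-time simulators producing every input the pipeline consumes.

Four generators cover the analysis surface: a wild population whose sex is
set by heterozygosity at one causal SNP (with free X-Y recombination), F1
families segregating the causal SNP over a genetic map, X/Y clone pairs at a
target identity, and multi-species panels sharing (or not) one trans-species
SNP.  All generators are deterministic given their integer seed; sub-streams
are split off a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import GenotypeMatrix, Individual, Marker, MarkerMap

__all__ = [
    "WildSimParams",
    "FamilySimParams",
    "ClonePairParams",
    "WildTruth",
    "FamilyTruth",
    "simulate_wild_population",
    "simulate_family",
    "simulate_clone_pair",
    "simulate_species_panels",
    "default_family_map",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class WildSimParams:
    n_females: int = 58
    n_males: int = 47
    n_markers: int = 30
    region_length_bp: int = 17_500
    causal_pos_bp: int = 7_271
    founder_haplotypes: int = 16
    generations: int = 200
    recomb_rate_per_bp_per_meiosis: float = 1e-5
    male_female_recomb_ratio: float = 0.5
    mutation_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.causal_pos_bp <= self.region_length_bp):
            raise ValueError("causal_pos_bp must lie within the region")
        for name in ("recomb_rate_per_bp_per_meiosis", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.male_female_recomb_ratio <= 1.0):
            raise ValueError("male_female_recomb_ratio must be in (0, 1]")
        if self.generations > 0 and (self.n_males < 1 or self.n_females < 1):
            raise ValueError(
                "forward simulation needs at least one breeding pair per "
                "generation"
            )


@dataclass
class FamilySimParams:
    n_offspring: int
    map: MarkerMap
    causal_marker: str
    informative_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.map.marker_index(self.causal_marker)  # raises if absent
        if not (0.0 <= self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in [0, 1]")


@dataclass
class ClonePairParams:
    length_bp: int
    target_identity: float = 0.994
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")


# ---------------------------------------------------------------------------
# Wild population
# ---------------------------------------------------------------------------

@dataclass
class WildTruth:
    """Phased truth for a simulated wild sample."""

    markers: list[Marker]
    causal_index: int
    #: per-individual (maternal haplotype, paternal haplotype) 0/1 arrays
    haplotypes: list[tuple[np.ndarray, np.ndarray]]
    #: per-marker (allele coded 0, allele coded 1); causal is ("C", "G")
    allele_codes: list[tuple[str, str]] = field(default_factory=list)


def _marker_positions(params: WildSimParams) -> np.ndarray:
    """Evenly spaced neutral markers plus the causal site, sorted."""
    n_neutral = params.n_markers - 1
    step = params.region_length_bp / (n_neutral + 1)
    pos = {int(round((i + 1) * step)) for i in range(n_neutral)}
    pos.discard(params.causal_pos_bp)
    return np.array(sorted(pos | {params.causal_pos_bp}))


def _gamete(
    haps: tuple[np.ndarray, np.ndarray],
    positions: np.ndarray,
    expected_crossovers: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine two haplotypes: Poisson crossover count, uniform positions
    in bp, no interference (Haldane)."""
    which = rng.integers(0, 2)
    n_xo = rng.poisson(expected_crossovers) if expected_crossovers > 0 else 0
    if n_xo == 0:
        return haps[which].copy()
    xo = np.sort(rng.uniform(0, positions[-1] + 1, size=n_xo))
    segment = np.searchsorted(xo, positions, side="left")
    choose = (segment + which) % 2
    out = np.where(choose == 0, haps[0], haps[1])
    return out


def simulate_wild_population(
    params: WildSimParams,
) -> tuple[GenotypeMatrix, WildTruth]:
    """Discrete-generation forward simulation of an XY wild population.

    Founder X haplotypes carry the ancestral causal allele (C), founder Y
    haplotypes the derived allele (G); X and Y recombine freely along the
    region (no suppression), fathers are always causal-site heterozygotes and
    mothers homozygotes, and offspring sex is read off the causal genotype
    (heterozygote = male).  Neutral markers mutate between their two alleles
    and drift; the causal genotype-sex correspondence is exact by
    construction.

    Returns the unphased sample matrix together with the phased truth.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    positions = _marker_positions(params)
    n_mark = len(positions)
    causal_idx = int(np.searchsorted(positions, params.causal_pos_bp))

    # per-marker allele pair; causal is C/G (C ancestral/X, G derived/Y)
    allele_pairs = []
    for j in range(n_mark):
        if j == causal_idx:
            allele_pairs.append(("C", "G"))
        else:
            a, b = rng.choice(4, size=2, replace=False)
            allele_pairs.append((str(_BASES[a]), str(_BASES[b])))

    # founder haplotypes: alleles coded 0/1 per site
    def founder_pool(n: int, y_type: bool) -> np.ndarray:
        freqs = rng.uniform(0.2, 0.8, size=n_mark)
        pool = (rng.random((n, n_mark)) < freqs).astype(np.int8)
        pool[:, causal_idx] = 1 if y_type else 0
        return pool

    x_pool = founder_pool(params.founder_haplotypes, y_type=False)
    y_pool = founder_pool(params.founder_haplotypes, y_type=True)

    def draw(pool: np.ndarray) -> np.ndarray:
        return pool[rng.integers(0, len(pool))].copy()

    females = [(draw(x_pool), draw(x_pool)) for _ in range(params.n_females)]
    males = [(draw(x_pool), draw(y_pool)) for _ in range(params.n_males)]

    rate = params.recomb_rate_per_bp_per_meiosis * params.region_length_bp
    xo_female = rate
    xo_male = rate * params.male_female_recomb_ratio
    mut = params.mutation_rate

    def mutate(g: np.ndarray) -> np.ndarray:
        if mut > 0:
            flip = rng.random(n_mark) < mut
            flip[causal_idx] = False  # causal allele defines the system
            g = np.where(flip, 1 - g, g)
        return g

    for _ in range(params.generations):
        next_f: list[tuple[np.ndarray, np.ndarray]] = []
        next_m: list[tuple[np.ndarray, np.ndarray]] = []
        while len(next_f) < params.n_females or len(next_m) < params.n_males:
            mother = females[rng.integers(0, len(females))]
            father = males[rng.integers(0, len(males))]
            egg = mutate(_gamete(mother, positions, xo_female, rng))
            sperm = mutate(_gamete(father, positions, xo_male, rng))
            child = (egg, sperm)
            if sperm[causal_idx] == 1:  # carries Y allele -> male
                if len(next_m) < params.n_males:
                    next_m.append(child)
            else:
                if len(next_f) < params.n_females:
                    next_f.append(child)
        females, males = next_f, next_m

    markers = [
        Marker(
            f"snp{positions[j]}" if j != causal_idx else f"causal{positions[j]}",
            "simregion",
            int(positions[j]),
            "snp",
            frozenset(allele_pairs[j]),
        )
        for j in range(n_mark)
    ]

    individuals: list[Individual] = []
    genotypes: list[list[tuple[str, str]]] = []
    haplotypes: list[tuple[np.ndarray, np.ndarray]] = []
    for i, (egg, sperm) in enumerate(females):
        individuals.append(Individual(f"W_F{i + 1:03d}", "female", "wild"))
        haplotypes.append((egg, sperm))
    for i, (egg, sperm) in enumerate(males):
        individuals.append(Individual(f"W_M{i + 1:03d}", "male", "wild"))
        haplotypes.append((egg, sperm))
    for egg, sperm in haplotypes:
        row = []
        for j in range(n_mark):
            pair = allele_pairs[j]
            row.append(tuple(sorted((pair[egg[j]], pair[sperm[j]]))))
        genotypes.append(row)

    matrix = GenotypeMatrix(individuals, markers, genotypes)
    return matrix, WildTruth(markers, causal_idx, haplotypes, allele_pairs)


# ---------------------------------------------------------------------------
# F1 family
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    """Per-offspring transmitted paternal haplotype labels and crossovers."""

    #: per offspring id: array of "X"/"Y" per marker
    paternal_labels: dict[str, np.ndarray]
    #: per offspring id: crossover positions on the male cM scale
    crossovers_cm: dict[str, np.ndarray]
    father_x: dict[str, str]
    father_y: dict[str, str]


def default_family_map(
    n_markers: int = 8,
    spacing_bp: int = 2_500,
    cm_per_marker_female: float = 0.5,
    male_female_ratio: float = 0.5,
    chrom: str = "simregion",
) -> MarkerMap:
    """An evenly spaced biallelic map with reduced male recombination."""
    markers = [
        Marker(
            f"m{j + 1}",
            chrom,
            (j + 1) * spacing_bp,
            "snp",
            frozenset({"A", "C"}),
        )
        for j in range(n_markers)
    ]
    cmf = [j * cm_per_marker_female for j in range(n_markers)]
    cmm = [c * male_female_ratio for c in cmf]
    return MarkerMap(markers, cmf, cmm)


def _haldane_labels(
    cm: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Transmitted-haplotype indicator (0/1 per marker) under Haldane:
    Poisson crossover count on the map length, uniform positions in cM."""
    length = cm[-1] - cm[0]
    start = rng.integers(0, 2)
    n_xo = rng.poisson(length / 100.0) if length > 0 else 0
    if n_xo == 0:
        return np.full(len(cm), start), np.empty(0)
    xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
    segment = np.searchsorted(xo, cm, side="left")
    return (segment + start) % 2, xo


def simulate_family(
    params: FamilySimParams,
    father_phase: tuple[dict[str, str], dict[str, str]] | None = None,
    mother_genotypes: dict[str, tuple[str, str]] | None = None,
) -> tuple[GenotypeMatrix, FamilyTruth]:
    """Simulate an F1 family segregating an XY causal marker.

    Offspring receive a paternal gamete generated by a Poisson/Haldane
    crossover process on the male map and a maternal gamete on the female
    map; offspring sex is assigned by the paternal allele at the causal
    marker (Y-type allele = male).

    *father_phase* is a pair of ``{marker_id: allele}`` dicts (X haplotype,
    Y haplotype); by default the father is heterozygous at a fraction
    ``informative_fraction`` of markers (and always at the causal marker),
    and the mother is homozygous for the X-type allele everywhere.
    """
    mmap = params.map
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    ids = [m.id for m in mmap.markers]
    causal_j = mmap.marker_index(params.causal_marker)

    if father_phase is None:
        fx: dict[str, str] = {}
        fy: dict[str, str] = {}
        for j, m in enumerate(mmap.markers):
            a, b = sorted(m.alleles)[:2]
            het = j == causal_j or rng.random() < params.informative_fraction
            fx[m.id] = a
            fy[m.id] = b if het else a
        father_phase = (fx, fy)
    fx, fy = father_phase
    if fx[params.causal_marker] == fy[params.causal_marker]:
        raise ValueError(
            "invalid parent: father is homozygous at the causal marker"
        )
    if mother_genotypes is None:
        mother_genotypes = {mid: (fx[mid], fx[mid]) for mid in ids}

    cmf = np.asarray(mmap.cm_female, dtype=float)
    cmm = np.asarray(mmap.cm_male, dtype=float)

    individuals = [
        Individual("father", "male", "family", "father"),
        Individual("mother", "female", "family", "mother"),
    ]
    genotypes: list[list[tuple[str, str]]] = [
        [tuple(sorted((fx[mid], fy[mid]))) for mid in ids],
        [tuple(sorted(mother_genotypes[mid])) for mid in ids],
    ]
    labels: dict[str, np.ndarray] = {}
    xovers: dict[str, np.ndarray] = {}
    for k in range(params.n_offspring):
        pat, xo = _haldane_labels(cmm, rng)
        mat, _ = _haldane_labels(cmf, rng)
        oid = f"off{k + 1:04d}"
        sex = "male" if pat[causal_j] == 1 else "female"
        individuals.append(Individual(oid, sex, "family", "offspring"))
        row = []
        for j, mid in enumerate(ids):
            p_allele = fy[mid] if pat[j] == 1 else fx[mid]
            m_allele = mother_genotypes[mid][mat[j]]
            row.append(tuple(sorted((p_allele, m_allele))))
        genotypes.append(row)
        labels[oid] = np.where(pat == 1, "Y", "X")
        xovers[oid] = xo
    matrix = GenotypeMatrix(individuals, mmap.markers, genotypes)
    return matrix, FamilyTruth(labels, xovers, dict(fx), dict(fy))


# ---------------------------------------------------------------------------
# X/Y clone pairs
# ---------------------------------------------------------------------------

def simulate_clone_pair(params: ClonePairParams) -> tuple[str, str]:
    """A random X-clone sequence and a Y copy with
    ``floor((1 - identity) * L)`` substitutions at distinct positions
    (no indels)."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    x = rng.choice(4, size=params.length_bp)
    n_sub = int((1.0 - params.target_identity) * params.length_bp)
    y = x.copy()
    if n_sub > 0:
        sites = rng.choice(params.length_bp, size=n_sub, replace=False)
        y[sites] = (y[sites] + rng.integers(1, 4, size=n_sub)) % 4
    return "".join(_BASES[x]), "".join(_BASES[y])


# ---------------------------------------------------------------------------
# Species panels
# ---------------------------------------------------------------------------

def simulate_species_panels(
    n_species: int,
    sizes: Sequence[tuple[int, int]],
    shared_snp: bool = True,
    seed: int = 0,
    n_private_snps: int = 3,
    region_chrom: str = "sd-region",
    shared_pos_bp: int = 7_271,
) -> list[tuple[str, GenotypeMatrix]]:
    """Per-species genotype panels with one (optional) trans-species SNP.

    With ``shared_snp`` every species carries the same C/G SNP at
    ``shared_pos_bp`` in perfect sex association (females homozygous C,
    males heterozygous); otherwise each species gets its own perfectly
    associated SNP at a species-specific position.  Each species additionally
    carries ``n_private_snps`` private neutral SNPs that are sex-associated
    only by chance.
    """
    if len(sizes) != n_species:
        raise ValueError("sizes must have one (n_females, n_males) per species")
    for nf, nm in sizes:
        if nf < 1 or nm < 1:
            raise ValueError("need at least one individual per sex per species")
    ss = np.random.SeedSequence(seed)
    panels: list[tuple[str, GenotypeMatrix]] = []
    for s, ((nf, nm), child_ss) in enumerate(zip(sizes, ss.spawn(n_species))):
        rng = np.random.default_rng(child_ss)
        species = f"species{s + 1}"
        causal_pos = shared_pos_bp if shared_snp else shared_pos_bp + 1000 * (s + 1)
        causal = Marker(
            f"causal_{causal_pos}", region_chrom, causal_pos, "snp",
            frozenset({"C", "G"}),
        )
        privates = []
        for k in range(n_private_snps):
            pos = shared_pos_bp + 13 + 100 * s + k  # disjoint across species
            a, b = rng.choice(4, size=2, replace=False)
            privates.append(
                Marker(
                    f"{species}_snp{pos}", region_chrom, int(pos), "snp",
                    frozenset({str(_BASES[a]), str(_BASES[b])}),
                )
            )
        markers = sorted([causal] + privates, key=lambda m: m.pos_bp)
        freqs = rng.uniform(0.2, 0.8, size=len(privates))
        individuals = []
        genotypes = []
        for i in range(nf + nm):
            female = i < nf
            individuals.append(
                Individual(
                    f"{species}_{'F' if female else 'M'}{i + 1}",
                    "female" if female else "male",
                    species,
                )
            )
            row = []
            p_idx = 0
            for m in markers:
                if m is causal:
                    row.append(("C", "C") if female else ("C", "G"))
                else:
                    a, b = sorted(m.alleles)
                    f = freqs[p_idx]
                    p_idx += 1
                    g = tuple(
                        sorted(a if rng.random() < f else b for _ in range(2))
                    )
                    row.append(g)
            genotypes.append(row)
        panels.append((species, GenotypeMatrix(individuals, markers, genotypes)))
    return panels
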