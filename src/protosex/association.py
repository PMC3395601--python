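"""Exact per-marker sex association under a recessive penetrance model.

The test statistic throughout is Fisher's exact test on a 2x2 genotype-count
table (rows: females, males; columns: homozygous-major vs other genotypes),
with the two-sided p-value defined by the point-probability rule: the sum of
probabilities of all tables with the same margins whose point probability
does not exceed the observed table's (relative tie tolerance 1e-7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .data_model import GenotypeMatrix

__all__ = [
    "CountTable2x2",
    "AssocResult",
    "FilterResult",
    "DegenerateTableWarning",
    "apply_marker_filters",
    "major_allele",
    "build_table",
    "fisher_exact",
    "recessive_discordance",
    "bonferroni",
    "permutation_correction",
    "associate",
]

#: relative tolerance when comparing point probabilities for the two-sided rule
TIE_RTOL = 1e-7


class DegenerateTableWarning(UserWarning):
    """A table with an all-zero row or column was tested; p = 1 by convention."""


@dataclass(frozen=True)
class CountTable2x2:
    """Integer 2x2 contingency table: rows are sexes, columns genotype classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class FilterResult:
    marker_id: str
    maf: float
    call_rate: float
    passed: bool
    reason: str | None = None


@dataclass
class AssocResult:
    marker_id: str
    maf: float
    call_rate: float
    model: str
    p_one_sided: float | None = None
    p_two_sided: float | None = None
    p_bonferroni: float | None = None
    p_permutation: float | None = None
    filtered: bool = False
    filter_reason: str | None = None
    table: CountTable2x2 | None = None


# ---------------------------------------------------------------------------
# Marker filters
# ---------------------------------------------------------------------------

def _allele_counts(matrix: GenotypeMatrix, j: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for row in matrix.genotypes:
        g = row[j]
        if g is None:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    return counts


def major_allele(matrix: GenotypeMatrix, marker_id: str) -> str:
    """Most frequent allele across the whole sample; ties broken
    lexicographically (smaller allele wins)."""
    counts = _allele_counts(matrix, matrix.marker_index(marker_id))
    if not counts:
        raise ValueError(f"marker {marker_id}: no genotyped individuals")
    return min(counts, key=lambda a: (-counts[a], a))


def apply_marker_filters(
    matrix: GenotypeMatrix,
    maf_min: float = 0.1,
    call_rate_min: float = 0.99,
) -> dict[str, FilterResult]:
    """Per-marker MAF and call-rate filters with strict inequalities
    (MAF > maf_min, call rate > call_rate_min).

    MAF is computed from non-missing alleles; call rate is the fraction of
    individuals genotyped.  Failing markers are carried with reason codes,
    never dropped silently.  Monomorphic markers get MAF 0 and are filtered.
    """
    out: dict[str, FilterResult] = {}
    n = matrix.n_individuals
    for j, m in enumerate(matrix.markers):
        counts = _allele_counts(matrix, j)
        n_called = sum(1 for row in matrix.genotypes if row[j] is not None)
        call_rate = n_called / n if n else 0.0
        total_alleles = sum(counts.values())
        if len(counts) >= 2 and total_alleles:
            # frequency of the second-most-common allele
            maf = sorted(counts.values())[-2] / total_alleles
        else:
            maf = 0.0
        reasons = []
        if not (maf > maf_min):
            reasons.append(f"maf<={maf_min:g}")
        if not (call_rate > call_rate_min):
            reasons.append(f"call_rate<={call_rate_min:g}")
        out[m.id] = FilterResult(
            m.id, maf, call_rate, not reasons, ";".join(reasons) or None
        )
    return out


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def build_table(
    matrix: GenotypeMatrix, marker_id: str, model: str = "genotypic_2x2"
) -> CountTable2x2:
    """Build the sex-association 2x2 table for one biallelic marker.

    ``genotypic_2x2`` / ``recessive``: columns are {homozygous-major, other
    genotypes} — the recessive penetrance collapse (homozygosity for the
    major allele is required for the female phenotype).  ``allelic``: columns
    are allele counts.  Rows are (females, males); unknown-sex and
    missing-genotype individuals are excluded.
    """
    j = matrix.marker_index(marker_id)
    marker = matrix.markers[j]
    if len(marker.alleles) > 2:
        raise ValueError(f"marker {marker_id} is not biallelic")
    maj = major_allele(matrix, marker_id)
    a = b = c = d = 0
    for ind, row in zip(matrix.individuals, matrix.genotypes):
        g = row[j]
        if g is None or ind.sex == "unknown":
            continue
        if model in ("genotypic_2x2", "recessive"):
            hom_major = g[0] == g[1] == maj
            if ind.sex == "female":
                a, b = a + hom_major, b + (not hom_major)
            else:
                c, d = c + hom_major, d + (not hom_major)
        elif model == "allelic":
            n_maj = sum(x == maj for x in g)
            if ind.sex == "female":
                a, b = a + n_maj, b + (2 - n_maj)
            else:
                c, d = c + n_maj, d + (2 - n_maj)
        else:
            raise ValueError(f"unknown model {model!r}")
    if a + b + c + d == 0:
        raise ValueError(f"marker {marker_id}: zero informative individuals")
    return CountTable2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: CountTable2x2, alternative: str = "two_sided") -> float:
    """Exact hypergeometric test of a 2x2 table, computed in log space.

    ``one_sided`` sums the tail in the observed direction of association;
    ``two_sided`` uses the point-probability rule with relative tie tolerance
    ``TIE_RTOL``.  Degenerate margins (an all-zero row or column) return
    p = 1 with a :class:`DegenerateTableWarning`.
    """
    if alternative not in ("one_sided", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn(
            "degenerate margins: p = 1 by convention", DegenerateTableWarning
        )
        return 1.0
    k_lo = max(0, c1 - (n - r1))
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    logp = hypergeom.logpmf(ks, n, r1, c1)
    obs = a - k_lo
    if alternative == "one_sided":
        # observed direction: compare a with its conditional expectation
        expect = r1 * c1 / n
        tail = ks >= a if a >= expect else ks <= a
        return float(np.exp(logsumexp(logp[tail])))
    thresh = logp[obs] + np.log1p(TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(logp[logp <= thresh]))))


# ---------------------------------------------------------------------------
# Recessive-model discordance
# ---------------------------------------------------------------------------

def recessive_discordance(
    matrix: GenotypeMatrix, marker_id: str
) -> tuple[list[str], list[str]]:
    """Individuals whose predicted sex (female iff homozygous-major)
    disagrees with phenotypic sex.

    Returns ``(discordant_ids, excluded_ids)`` where excluded individuals are
    those with a missing genotype or unknown sex at this marker.
    """
    j = matrix.marker_index(marker_id)
    maj = major_allele(matrix, marker_id)
    discordant: list[str] = []
    excluded: list[str] = []
    for ind, row in zip(matrix.individuals, matrix.genotypes):
        g = row[j]
        if g is None or ind.sex == "unknown":
            excluded.append(ind.id)
            continue
        predicted = "female" if g[0] == g[1] == maj else "male"
        if predicted != ind.sex:
            discordant.append(ind.id)
    return discordant, excluded


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------

def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], float]:
    """Bonferroni adjustment: adjusted p = min(1, m*p); threshold alpha/m."""
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    return [min(1.0, m * p) for p in p_values], alpha / m


def permutation_correction(
    matrix: GenotypeMatrix,
    marker_ids: Sequence[str],
    n_perm: int,
    seed: int,
) -> dict[str, float]:
    """Family-wise (max-T / min-P) permutation correction.

    Sex labels are permuted over the known-sex individuals; per permutation
    the minimum two-sided p across markers is recorded, and each marker's
    corrected p is ``(1 + #{permutation minima <= observed p}) / (n_perm + 1)``.
    Deterministic given *seed*.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    known = [
        i for i, ind in enumerate(matrix.individuals) if ind.sex != "unknown"
    ]
    sexes = np.array(
        [matrix.individuals[i].sex == "female" for i in known], dtype=bool
    )
    if sexes.sum() < 2 or (~sexes).sum() < 2:
        raise ValueError("need at least 2 individuals of each sex to permute")

    # code genotypes: 1 = homozygous-major, 0 = other, -1 = missing
    codes = np.full((len(known), len(marker_ids)), -1, dtype=np.int8)
    for jj, mid in enumerate(marker_ids):
        col = matrix.marker_index(mid)
        maj = major_allele(matrix, mid)
        for ii, i in enumerate(known):
            g = matrix.genotypes[i][col]
            if g is not None:
                codes[ii, jj] = 1 if g[0] == g[1] == maj else 0

    cache: dict[tuple[int, int, int, int], float] = {}

    def p_of(a: int, b: int, c: int, d: int) -> float:
        key = (a, b, c, d)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateTableWarning)
                cache[key] = fisher_exact(
                    CountTable2x2(a, b, c, d), "two_sided"
                )
        return cache[key]

    def all_p(female: np.ndarray) -> np.ndarray:
        ps = np.empty(len(marker_ids))
        for jj in range(len(marker_ids)):
            col = codes[:, jj]
            called = col >= 0
            hom = col == 1
            a = int(np.sum(called & female & hom))
            b = int(np.sum(called & female & ~hom))
            c = int(np.sum(called & ~female & hom))
            d = int(np.sum(called & ~female & ~hom))
            ps[jj] = p_of(a, b, c, d) if a + b + c + d else 1.0
        return ps

    observed = all_p(sexes)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    perm_sex = sexes.copy()
    for t in range(n_perm):
        rng.shuffle(perm_sex)
        minima[t] = all_p(perm_sex).min()
    corrected = {}
    for jj, mid in enumerate(marker_ids):
        corrected[mid] = (1 + int(np.sum(minima <= observed[jj]))) / (n_perm + 1)
    return corrected


# ---------------------------------------------------------------------------
# End-to-end per-marker association
# ---------------------------------------------------------------------------

def associate(
    matrix: GenotypeMatrix,
    model: str = "recessive",
    maf_min: float = 0.1,
    call_rate_min: float = 0.99,
    n_perm: int = 0,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[AssocResult]:
    """Run filters, per-marker exact tests, Bonferroni, and (optionally)
    permutation correction over every marker of *matrix*."""
    filters = apply_marker_filters(matrix, maf_min, call_rate_min)
    passing = [m.id for m in matrix.markers if filters[m.id].passed]
    results: list[AssocResult] = []
    for m in matrix.markers:
        f = filters[m.id]
        res = AssocResult(
            m.id, f.maf, f.call_rate, model,
            filtered=not f.passed, filter_reason=f.reason,
        )
        if f.passed:
            res.table = build_table(matrix, m.id, model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateTableWarning)
                res.p_one_sided = fisher_exact(res.table, "one_sided")
                res.p_two_sided = fisher_exact(res.table, "two_sided")
        results.append(res)
    tested = [r for r in results if not r.filtered]
    if tested:
        adjusted, _ = bonferroni([r.p_two_sided for r in tested], alpha)
        for r, p_adj in zip(tested, adjusted):
            r.p_bonferroni = p_adj
    if n_perm > 0 and passing:
        corrected = permutation_correction(matrix, passing, n_perm, seed)
        for r in tested:
            r.p_permutation = corrected[r.marker_id]
    return results
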