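"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity, then summarized as D, D', r2 and a LOD
score against the no-association model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .association import major_allele
from .data_model import GenotypeMatrix

__all__ = [
    "HaplotypeFreqs",
    "LDPair",
    "joint_genotype_counts",
    "em_haplotypes",
    "ld_stats",
    "ld_matrix",
]

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes AB, Ab, aB, ab, where
    A/B are the major alleles at each locus, plus EM diagnostics."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    n_used: int = 0
    defined: bool = True
    #: log-likelihood after each EM iteration (non-decreasing)
    loglik_trace: list[float] | None = None

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


@dataclass
class LDPair:
    marker_i: str
    marker_j: str
    distance_bp: int
    D: float
    Dprime: float
    r2: float
    LOD: float
    n_used: int = 0
    defined: bool = True


# ---------------------------------------------------------------------------
# Genotype cross-tabulation
# ---------------------------------------------------------------------------

def joint_genotype_counts(
    matrix: GenotypeMatrix, marker_i: str, marker_j: str
) -> np.ndarray:
    """3x3 joint genotype counts indexed by minor-allele dosage at each
    locus (0, 1, 2); pairwise-complete individuals only."""
    ji, jj = matrix.marker_index(marker_i), matrix.marker_index(marker_j)
    for mid in (marker_i, marker_j):
        if len(matrix.markers[matrix.marker_index(mid)].alleles) > 2:
            raise ValueError(f"marker {mid} is not biallelic")
    maj_i, maj_j = major_allele(matrix, marker_i), major_allele(matrix, marker_j)
    counts = np.zeros((3, 3), dtype=np.int64)
    for row in matrix.genotypes:
        gi, gj = row[ji], row[jj]
        if gi is None or gj is None:
            continue
        di = sum(a != maj_i for a in gi)
        dj = sum(a != maj_j for a in gj)
        counts[di, dj] += 1
    return counts


def _genotype_logprobs(p: np.ndarray, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype counts given haplotype
    frequencies p = (AB, Ab, aB, ab), under random union of gametes."""
    pAB, pAb, paB, pab = p
    # genotype probability matrix indexed by (dosage_a, dosage_b)
    g = np.empty((3, 3))
    g[0, 0] = pAB * pAB
    g[0, 1] = 2 * pAB * pAb
    g[0, 2] = pAb * pAb
    g[1, 0] = 2 * pAB * paB
    g[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    g[1, 2] = 2 * pAb * pab
    g[2, 0] = paB * paB
    g[2, 1] = 2 * paB * pab
    g[2, 2] = pab * pab
    mask = counts > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(counts[mask] * np.log(g[mask])))


def em_haplotypes(counts: np.ndarray) -> HaplotypeFreqs:
    """EM estimation of two-locus haplotype frequencies from 3x3 joint
    genotype counts (minor-allele dosage indexing).

    The only latent structure is the phase of double heterozygotes, which is
    initialized at a 50/50 split.  Convergence: max frequency change below
    ``EM_TOL`` or ``EM_MAX_ITER`` iterations.  If either locus is monomorphic
    in the pairwise-complete subset, a flagged null result is returned.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (3, 3) or counts.min() < 0:
        raise ValueError("expected a non-negative 3x3 count matrix")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("need at least one individual genotyped at both loci")

    # allele dosage margins; monomorphic -> undefined
    dos_a = counts.sum(axis=1) @ np.array([0, 1, 2])
    dos_b = counts.sum(axis=0) @ np.array([0, 1, 2])
    if dos_a in (0, 2 * n) or dos_b in (0, 2 * n):
        return HaplotypeFreqs(
            np.nan, np.nan, np.nan, np.nan, n_used=n, defined=False
        )

    # fixed (phase-unambiguous) haplotype contributions
    fixed = np.zeros(4)  # AB, Ab, aB, ab
    for da in range(3):
        for db in range(3):
            m = counts[da, db]
            if m == 0 or (da == 1 and db == 1):
                continue
            if da == 1:
                a_h = ["A", "a"]
            else:
                a_h = ["A", "A"] if da == 0 else ["a", "a"]
            if db == 1:
                b_h = ["B", "b"]
            else:
                b_h = ["B", "B"] if db == 0 else ["b", "b"]
            for ah, bh in zip(a_h, b_h):
                idx = (0 if ah == "A" else 2) + (0 if bh == "B" else 1)
                fixed[idx] += m
    n_dh = counts[1, 1]

    # seed with the 50/50 double-het split
    c0 = fixed + n_dh * np.array([0.5, 0.5, 0.5, 0.5])
    p = c0 / (2 * n)
    loglik = _genotype_logprobs(p, counts)
    trace = [loglik]
    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        # E-step: split double heterozygotes between the two phasings
        w_cis = p[0] * p[3]
        w_trans = p[1] * p[2]
        tot = w_cis + w_trans
        f_cis = 0.5 if tot == 0 else w_cis / tot
        c = fixed + n_dh * np.array(
            [f_cis, 1 - f_cis, 1 - f_cis, f_cis]
        )
        new_p = c / (2 * n)
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        loglik = _genotype_logprobs(p, counts)
        trace.append(loglik)
        if delta < EM_TOL:
            converged = True
            break
    return HaplotypeFreqs(
        float(p[0]), float(p[1]), float(p[2]), float(p[3]),
        loglik=loglik, n_iter=it, converged=converged, n_used=n,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def ld_stats(
    h: HaplotypeFreqs,
    marker_i: str = "A",
    marker_j: str = "B",
    distance_bp: int = 0,
    counts: np.ndarray | None = None,
) -> LDPair:
    """D, D', r2 and LOD from estimated haplotype frequencies.

    D = p_AB - p_A p_B; D' = |D| / Dmax; r2 = D^2 / (p_A p_a p_B p_b);
    LOD compares the fitted likelihood with the D = 0 model at the same
    allele frequencies (requires *counts*; LOD is NaN without them).
    Any allele frequency of 0 yields a flagged null result.
    """
    if not h.defined:
        return LDPair(
            marker_i, marker_j, distance_bp,
            np.nan, np.nan, np.nan, np.nan, h.n_used, defined=False,
        )
    pA, pB = h.p_A, h.p_B
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        return LDPair(
            marker_i, marker_j, distance_bp,
            np.nan, np.nan, np.nan, np.nan, h.n_used, defined=False,
        )
    D = h.p_AB - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        dmax = 1.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * pa * pB * pb)
    if counts is not None:
        p0 = np.array([pA * pB, pA * pb, pa * pB, pa * pb])
        lod = (h.loglik - _genotype_logprobs(p0, counts)) / np.log(10)
    else:
        lod = float("nan")
    return LDPair(
        marker_i, marker_j, distance_bp, float(D), float(dprime),
        float(r2), float(lod), h.n_used,
    )


def ld_pair(
    matrix: GenotypeMatrix, marker_i: str, marker_j: str
) -> LDPair:
    """Convenience: cross-tabulate, run EM, and summarize one marker pair."""
    counts = joint_genotype_counts(matrix, marker_i, marker_j)
    h = em_haplotypes(counts)
    mi = matrix.markers[matrix.marker_index(marker_i)]
    mj = matrix.markers[matrix.marker_index(marker_j)]
    return ld_stats(
        h, marker_i, marker_j, abs(mj.pos_bp - mi.pos_bp), counts
    )


def ld_matrix(
    matrix: GenotypeMatrix, marker_ids: Sequence[str] | None = None
) -> list[LDPair]:
    """All unordered marker pairs, ordered by (i, j) index."""
    if marker_ids is None:
        marker_ids = [m.id for m in matrix.markers]
    if len(marker_ids) < 2:
        raise ValueError("need at least 2 markers")
    return [
        ld_pair(matrix, mi, mj) for mi, mj in combinations(marker_ids, 2)
    ]
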