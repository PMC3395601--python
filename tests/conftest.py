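from fractions import Fraction
from math import comb

import numpy as np
import pytest

from protosex.data_model import GenotypeMatrix, Individual, Marker
from protosex.fixtures import wild_panel


@pytest.fixture(scope="session")
def wild():
    """105-fish wild panel reconstructed from the printed genotype counts."""
    return wild_panel()


@pytest.fixture
def toy_matrix():
    """2 individuals x 2 markers, one het, one hom, one missing."""
    markers = [
        Marker("mA", "chr1", 100, "snp", frozenset({"C", "G"})),
        Marker("mB", "chr1", 200, "snp", frozenset({"A", "T"})),
    ]
    individuals = [
        Individual("i1", "female", "wild"),
        Individual("i2", "male", "wild"),
    ]
    genotypes = [
        [("C", "C"), ("A", "T")],
        [("C", "G"), None],
    ]
    return GenotypeMatrix(individuals, markers, genotypes)


# ---------------------------------------------------------------------------
# Independent Fisher oracle: exact integer enumeration over fixed margins
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d, alternative="two_sided"):
    """Exhaustive-enumeration Fisher p-value in exact rational arithmetic.

    Point probability of table k (same margins): C(r1,k)*C(r2,c1-k)/C(n,c1);
    numerators are compared as exact integers, with the documented relative
    tie tolerance 1e-7 applied via integer cross-multiplication.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    denom = comb(n, c1)
    w_obs = nums[a]
    if alternative == "one_sided":
        expect = Fraction(r1 * c1, n)
        if a >= expect:
            total = sum(v for k, v in nums.items() if k >= a)
        else:
            total = sum(v for k, v in nums.items() if k <= a)
        return float(Fraction(total, denom))
    # two-sided point-probability rule: w_k <= w_obs * (1 + 1e-7)
    total = sum(
        v for v in nums.values() if v * 10**7 <= w_obs * (10**7 + 1)
    )
    return float(Fraction(total, denom))


@pytest.fixture(scope="session")
def fisher_bruteforce():
    return fisher_oracle


# ---------------------------------------------------------------------------
# Independent likelihood grid-search oracle for two-locus haplotype EM
# ---------------------------------------------------------------------------

def _loglik(p, counts):
    pAB, pAb, paB, pab = p
    g = np.array(
        [
            [pAB * pAB, 2 * pAB * pAb, pAb * pAb],
            [2 * pAB * paB, 2 * pAB * pab + 2 * pAb * paB, 2 * pAb * pab],
            [paB * paB, 2 * paB * pab, pab * pab],
        ]
    )
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.sum(counts[mask] * np.log(g[mask])))


def grid_search_loglik(counts, rounds=5, n_grid=24):
    """Maximize the genotype log-likelihood over the haplotype-frequency
    simplex by iteratively refined 3-D grid search (independent of EM)."""
    counts = np.asarray(counts, dtype=float)
    center = np.full(3, 0.5)  # (pAB, pAb, paB); pab implied
    width = 1.0
    best = (-np.inf, None)
    for _ in range(rounds):
        axis = np.linspace(-width / 2, width / 2, n_grid)
        # clip to [0, 1] so that simplex boundaries are hit exactly
        xs = np.clip(center[0] + axis, 0.0, 1.0)
        ys = np.clip(center[1] + axis, 0.0, 1.0)
        zs = np.clip(center[2] + axis, 0.0, 1.0)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        W = 1.0 - X - Y - Z
        valid = (X >= 0) & (Y >= 0) & (Z >= 0) & (W >= 0)
        pts = np.stack(
            [X[valid], Y[valid], Z[valid], W[valid]], axis=1
        )
        # points just past the pab = 0 plane, projected back onto it,
        # so that boundary optima are hit exactly
        over = (X >= 0) & (Y >= 0) & (Z >= 0) & (W < 0) & (W >= -width)
        if over.any():
            tot = X[over] + Y[over] + Z[over]
            proj = np.stack(
                [X[over] / tot, Y[over] / tot, Z[over] / tot,
                 np.zeros(int(over.sum()))],
                axis=1,
            )
            pts = np.concatenate([pts, proj], axis=0)
        if not len(pts):
            break
        # vectorized log-likelihood over all grid points
        pAB, pAb, paB, pab = pts.T
        g = np.stack(
            [
                pAB * pAB,
                2 * pAB * pAb,
                pAb * pAb,
                2 * pAB * paB,
                2 * pAB * pab + 2 * pAb * paB,
                2 * pAb * pab,
                paB * paB,
                2 * paB * pab,
                pab * pab,
            ],
            axis=1,
        )
        flat = counts.reshape(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                (g > 0) | (flat == 0), flat * np.log(np.maximum(g, 1e-300)), -np.inf
            ).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), pts[i])
        center = pts[i][:3]
        width = width * 3.0 / n_grid  # shrink around the best point
    return best


@pytest.fixture(scope="session")
def em_grid_oracle():
    return grid_search_loglik
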