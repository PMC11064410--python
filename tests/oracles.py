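"""Independent reference implementations used only to check the package.

These deliberately take the straightforward dense / exact-arithmetic
route: the kinship oracle materializes the full sites-x-samples matrix
and loops over sample pairs, and the HWE oracle enumerates heterozygote
configurations with exact rational arithmetic.  Neither shares code with
the streaming implementations they pin down.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def dense_kinship(G: np.ndarray, method: str) -> np.ndarray:
    """Dense-formula kinship on a sites-x-samples dosage matrix.

    Missing genotypes are np.nan.  Every site must be polymorphic among
    called genotypes (the caller applies the monomorphic gate).
    """
    G = np.asarray(G, dtype=float)
    m, n = G.shape
    called = ~np.isnan(G)
    p = np.nansum(G, axis=1) / (2.0 * called.sum(axis=1))
    K = np.zeros((n, n))

    if method == "Centered_IBS":
        Z = np.where(called, G - 2.0 * p[:, None], 0.0)
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        for i in range(n):
            for j in range(n):
                K[i, j] = float(np.sum(Z[:, i] * Z[:, j])) / denom
        return K

    if method == "IBSKinshipImpute":
        Gi = np.where(called, G, 2.0 * p[:, None])
        for i in range(n):
            for j in range(n):
                K[i, j] = float(np.mean(1.0 - np.abs(Gi[:, i] - Gi[:, j]) / 2.0))
        return K

    # pairwise-complete methods
    for i in range(n):
        for j in range(n):
            both = called[:, i] & called[:, j]
            gi, gj, ps = G[both, i], G[both, j], p[both]
            if method == "Normalized_IBS":
                K[i, j] = float(
                    np.mean((gi - 2 * ps) * (gj - 2 * ps) / (2 * ps * (1 - ps)))
                )
            elif method == "IBSKinship":
                K[i, j] = float(np.mean(1.0 - np.abs(gi - gj) / 2.0))
            elif method == "p_distance":
                K[i, j] = 1.0 - float(np.mean(np.abs(gi - gj) / 2.0))
            else:
                raise ValueError(method)
    return K


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational two-sided HWE test by full enumeration.

    P(h | n, n_rare) is computed as a Fraction from factorials; the
    p-value sums the probabilities of all heterozygote counts whose exact
    probability is <= the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_alt = 2 * n_aa + n_Aa
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    n_common = 2 * n - n_rare

    def prob(h: int) -> Fraction:
        return Fraction(
            factorial(n) * factorial(n_rare) * factorial(n_common) * 2 ** h,
            factorial((n_rare - h) // 2) * factorial(h)
            * factorial((n_common - h) // 2) * factorial(2 * n),
        )

    hets = range(n_rare % 2, min(n_rare, n_common) + 1, 2)
    probs = {h: prob(h) for h in hets}
    assert sum(probs.values()) == 1
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))
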