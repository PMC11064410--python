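"""Streaming kinship / genetic-relationship-matrix estimation.

All five estimators share one single-pass design: each filtered site
updates two symmetric [n_samples x n_samples] running arrays — a pairwise
numerator and a pairwise weight — after which the site's genotypes are
discarded.  Peak memory is therefore a function of the sample count only,
independent of the number of SNPs streamed.

Estimators
----------
Centered_IBS
    VanRaden centered relationship: K = Z Z' / sum_s 2 p_s (1 - p_s) with
    z = g - 2p and missing dosages mean-imputed (z = 0).
Normalized_IBS
    GCTA-style per-site standardized cross-product
    (g_i - 2p)(g_j - 2p) / (2p(1-p)), averaged over pairwise-complete sites.
IBSKinship
    Proportion of alleles identical by state, pairwise-complete sites.
IBSKinshipImpute
    IBS after mean-imputing missing dosages to 2p; every kept site
    contributes for every pair.
p_distance
    1 - mean proportion of differing alleles (reported as a similarity so
    all five estimators feed PCA identically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .site_filter import SiteStats
from .vcf_io import MISSING, SiteRecord

__all__ = [
    "KINSHIP_METHODS",
    "KinshipAccumulator",
    "KinshipMatrix",
    "update_accumulator",
    "finalize_kinship",
    "write_kinship",
    "read_kinship",
]

KINSHIP_METHODS = (
    "Normalized_IBS",
    "Centered_IBS",
    "IBSKinship",
    "IBSKinshipImpute",
    "p_distance",
)

#: methods whose finalized entries lie in [0, 1] with unit diagonal
_IBS_LIKE = ("IBSKinship", "IBSKinshipImpute", "p_distance")


@dataclass
class KinshipAccumulator:
    """The two running [n x n] arrays plus method-specific scalars."""

    n_samples: int
    method: str
    numer: np.ndarray = field(init=False)
    weight: np.ndarray = field(init=False)
    denom_scalar: float = field(init=False, default=0.0)  # Centered_IBS only
    m_used: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.method not in KINSHIP_METHODS:
            raise ValueError(f"unknown kinship method {self.method!r}")
        n = self.n_samples
        self.numer = np.zeros((n, n), dtype=np.float64)
        self.weight = np.zeros((n, n), dtype=np.float64)
        self.denom_scalar = 0.0
        self.m_used = 0


@dataclass(frozen=True)
class KinshipMatrix:
    values: np.ndarray
    sample_ids: Tuple[str, ...]
    method: str
    m_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix must be square")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length must match matrix dimension")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))


# per-site pairwise contributions (scalar forms; the accumulator applies
# them vectorized over all pairs)

def contrib_centered_ibs(g_i: float, g_j: float, p: float) -> float:
    """(g_i - 2p)(g_j - 2p); missing dosages are mean-imputed upstream (z=0)."""
    return (g_i - 2.0 * p) * (g_j - 2.0 * p)


def contrib_normalized_ibs(g_i: float, g_j: float, p: float) -> float:
    """(g_i - 2p)(g_j - 2p) / (2p(1-p)) for a pairwise-complete site."""
    return (g_i - 2.0 * p) * (g_j - 2.0 * p) / (2.0 * p * (1.0 - p))


def contrib_ibs(g_i: float, g_j: float) -> float:
    """Shared-allele fraction (2 - |g_i - g_j|) / 2 in {0, 0.5, 1}."""
    return (2.0 - abs(g_i - g_j)) / 2.0


def contrib_ibs_impute(g_i: float, g_j: float, p: float) -> float:
    """IBS on real-valued dosages after mean-imputation of missing to 2p."""
    return (2.0 - abs(g_i - g_j)) / 2.0


def contrib_pdistance(g_i: float, g_j: float) -> float:
    """Per-site allele-difference proportion |g_i - g_j| / 2."""
    return abs(g_i - g_j) / 2.0


def update_accumulator(
    acc: KinshipAccumulator, rec: SiteRecord, stats: SiteStats, method: str | None = None
) -> KinshipAccumulator:
    """Consume one filtered site: add its pairwise contributions to the
    running arrays and discard the site.  p is the site's ALT frequency
    among called genotypes; p in (0,1) is guaranteed by the monomorphic
    gate upstream."""
    if method is None:
        method = acc.method
    if method != acc.method:
        raise ValueError(f"accumulator method {acc.method!r} != requested {method!r}")
    d = rec.dosages
    if d.size != acc.n_samples:
        raise ValueError(
            f"site has {d.size} samples but accumulator expects {acc.n_samples}"
        )
    p = stats.alt_freq
    if not (0.0 < p < 1.0):
        raise ValueError("monomorphic site reached the accumulator (p not in (0,1))")
    called = d != MISSING
    g = d.astype(np.float64)

    if method == "Centered_IBS":
        z = np.where(called, g - 2.0 * p, 0.0)
        acc.numer += np.outer(z, z)
        acc.denom_scalar += 2.0 * p * (1.0 - p)
        acc.weight += np.outer(called, called)  # bookkeeping only
    elif method == "Normalized_IBS":
        z = np.where(called, g - 2.0 * p, 0.0)
        acc.numer += np.outer(z, z) / (2.0 * p * (1.0 - p))
        acc.weight += np.outer(called, called)
    elif method == "IBSKinship":
        gc = np.where(called, g, 0.0)
        pair = np.outer(called, called)
        acc.numer += np.where(pair, 1.0 - np.abs(gc[:, None] - gc[None, :]) / 2.0, 0.0)
        acc.weight += pair
    elif method == "IBSKinshipImpute":
        gi = np.where(called, g, 2.0 * p)
        acc.numer += 1.0 - np.abs(gi[:, None] - gi[None, :]) / 2.0
        acc.weight += 1.0
    elif method == "p_distance":
        gc = np.where(called, g, 0.0)
        pair = np.outer(called, called)
        acc.numer += np.where(pair, np.abs(gc[:, None] - gc[None, :]) / 2.0, 0.0)
        acc.weight += pair
    acc.m_used += 1
    return acc


def finalize_kinship(acc: KinshipAccumulator, sample_ids: Tuple[str, ...]) -> KinshipMatrix:
    """Apply the method's normalization to the accumulated arrays."""
    if acc.m_used < 1:
        raise ValueError("no sites contributed to the kinship accumulator")
    method = acc.method
    if method == "Centered_IBS":
        values = acc.numer / acc.denom_scalar
    else:
        zero = acc.weight == 0
        if zero.any():
            i, j = np.argwhere(zero)[0]
            raise ValueError(
                f"sample pair ({sample_ids[i]}, {sample_ids[j]}) shares no called "
                "site (too much missingness)"
            )
        ratio = acc.numer / acc.weight
        values = 1.0 - ratio if method == "p_distance" else ratio
    values = (values + values.T) / 2.0  # exact symmetry
    return KinshipMatrix(values=values, sample_ids=tuple(sample_ids),
                         method=method, m_used=acc.m_used)


# ---------------------------------------------------------------------------
# text round-trip: line 1 = tab-separated sample IDs; lines 2..n+1 =
# sample ID + n floats at full double precision (%.17g), so read(write(K))
# is bit-exact and re-clustering from the file reproduces the direct run.

def write_kinship(K: KinshipMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(K.sample_ids) + "\n")
        for sid, row in zip(K.sample_ids, K.values):
            fh.write(sid + "\t" + "\t".join("%.17g" % v for v in row) + "\n")


def read_kinship(path) -> KinshipMatrix:
    """Read the tab-separated kinship format (also accepts any externally
    authored square matrix in the same layout)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: line 1: empty kinship header")
        ids = tuple(header.rstrip("\n").split("\t"))
        n = len(ids)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected sample ID + {n} values, "
                    f"got {len(parts)} fields"
                )
            if parts[0] != ids[len(rows)]:
                raise ValueError(
                    f"{path}: line {lineno}: row ID {parts[0]!r} does not match "
                    f"header ID {ids[len(rows)]!r}"
                )
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell") from exc
        if len(rows) != n:
            raise ValueError(
                f"{path}: header names {n} samples but {len(rows)} data rows found"
            )
    values = np.array(rows, dtype=np.float64)
    return KinshipMatrix(values=values, sample_ids=ids, method="external",
                         m_used=0)
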