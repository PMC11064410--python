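"""Per-site statistics and SNP filtering.

Non-biallelic sites (monomorphic-in-sample or multiallelic) and indels are
discarded unconditionally; optional thresholds then remove sites with low
minor allele frequency (MAF), high per-marker missingness, or gross
departure from Hardy-Weinberg equilibrium (HWE, two-sided exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .vcf_io import MISSING, SiteRecord

__all__ = [
    "SiteStats",
    "FilterThresholds",
    "classify_and_gate",
    "site_stats",
    "hwe_exact_test",
    "passes_filters",
]


@dataclass(frozen=True)
class SiteStats:
    """Genotype counts and derived statistics for one biallelic SNP."""

    n_samples: int
    n_called: int
    n_AA: int  # hom REF
    n_Aa: int  # het
    n_aa: int  # hom ALT
    alt_freq: float
    maf: float
    missing_rate: float
    hwe_p: float


@dataclass(frozen=True)
class FilterThresholds:
    """Optional site filters: a site is kept iff maf >= maf_min AND
    missing_rate <= miss_max AND hwe_p >= hwe_min.  Defaults drop
    near-monomorphic noise and leave the HWE filter inert (hwe_min = 0)."""

    maf_min: float = 0.001
    miss_max: float = 0.25
    hwe_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.miss_max <= 1.0):
            raise ValueError("miss_max must be in [0, 1]")
        if not (0.0 <= self.hwe_min <= 1.0):
            raise ValueError("hwe_min must be in [0, 1]")


def classify_and_gate(rec: SiteRecord) -> bool:
    """Mandatory gate: keep only biallelic SNPs with both alleles observed."""
    return rec.site_class == "BIALLELIC_SNP"


def site_stats(rec: SiteRecord) -> SiteStats:
    """Count genotypes at a biallelic SNP and derive MAF, missingness and
    the HWE exact p-value (computed on called genotypes only)."""
    d = rec.dosages
    n_samples = int(d.size)
    called = d[d != MISSING]
    n_called = int(called.size)
    if n_called == 0:
        raise ValueError(
            f"degenerate site {rec.chrom}:{rec.pos}: no called genotypes"
        )
    n_aa = int(np.count_nonzero(called == 2))
    n_Aa = int(np.count_nonzero(called == 1))
    n_AA = n_called - n_Aa - n_aa
    alt_freq = (n_Aa + 2 * n_aa) / (2 * n_called)
    return SiteStats(
        n_samples=n_samples,
        n_called=n_called,
        n_AA=n_AA,
        n_Aa=n_Aa,
        n_aa=n_aa,
        alt_freq=alt_freq,
        maf=min(alt_freq, 1.0 - alt_freq),
        missing_rate=(n_samples - n_called) / n_samples,
        hwe_p=hwe_exact_test(n_AA, n_Aa, n_aa),
    )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts: with n genotypes and n_rare
    copies of the rarer allele, the heterozygote count h ranges over values
    of the same parity as n_rare, with

        P(h | n, n_rare) = n! * n_rare! * n_common! * 2**h
                           / ( ((n_rare-h)/2)! * h! * ((n_common-h)/2)! * (2n)! )

    The p-value is the summed probability of all configurations no more
    likely than the observed one.  Returns 1.0 for monomorphic input.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_alt = 2 * n_aa + n_Aa
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        rare_hom = (n_rare - h) // 2
        common_hom = (2 * n - n_rare - h) // 2
        return (
            gammaln(n + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            + h * np.log(2.0)
            - gammaln(rare_hom + 1)
            - gammaln(h + 1)
            - gammaln(common_hom + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_Aa)]
    # tolerance admits float ties between symmetric configurations
    p = float(probs[probs <= obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def passes_filters(stats: SiteStats, thr: FilterThresholds) -> bool:
    """Boundary values are retained (>= / <= comparisons)."""
    return (
        stats.maf >= thr.maf_min
        and stats.missing_rate <= thr.miss_max
        and stats.hwe_p >= thr.hwe_min
    )
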