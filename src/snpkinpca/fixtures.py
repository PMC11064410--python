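"""Synthetic structured-population VCF generation.

Stands in for real consortium genotype panels: subpopulation allele
frequencies diverge from a shared ancestral frequency under the
Balding-Nichols model — pop frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) —
so PCA-separable structure is controlled by a single parameter F.
Sites are i.i.d. (no linkage disequilibrium); genotypes are
Binomial(2, pop_freq).  Contaminant indel / multiallelic / monomorphic
records and missing genotypes can be injected at stated fractions so
every filtering rule has constructed truth.

Defaults state the standard test world used throughout: 4 populations of
50 samples, 2000 SNPs, F = 0.2 — strong differentiation relative to
binomial sampling noise at this site count.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["PopulationModel", "simulate_structured_vcf", "make_toy_vcf"]

_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


@dataclass(frozen=True)
class PopulationModel:
    n_pops: int = 4
    samples_per_pop: int = 50
    n_sites: int = 2000
    ancestral_beta: Tuple[float, float] = (1.0, 1.0)
    divergence: float = 0.2      # Balding-Nichols F
    missing_rate: float = 0.0
    indel_rate: float = 0.0
    multiallelic_rate: float = 0.0
    monomorphic_rate: float = 0.0
    seed: int = 12345

    def __post_init__(self) -> None:
        for name in ("missing_rate", "indel_rate", "multiallelic_rate", "monomorphic_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.indel_rate + self.multiallelic_rate + self.monomorphic_rate >= 1.0:
            raise ValueError("contamination fractions must sum to < 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence F must be in [0, 1)")


def _pop_freqs(rng: np.random.Generator, p_anc: np.ndarray, n_pops: int, F: float) -> np.ndarray:
    """Per-population frequencies for each site (sites x pops)."""
    if F == 0.0:
        return np.tile(p_anc[:, None], (1, n_pops))
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return rng.beta(a[:, None], b[:, None], size=(p_anc.size, n_pops))


def _gt_string(dosage: int, missing: bool) -> str:
    if missing:
        return "./."
    return ("0/0", "0/1", "1/1")[dosage]


def simulate_structured_vcf(model: PopulationModel, path: str) -> Tuple[str, str]:
    """Write a structured-population VCF and its truth table.

    Returns (vcf_path, truth_path); the truth file maps each sample ID to
    its generative population, one "sample_id<TAB>pop" row per sample.
    Output is byte-identical for a given (model, seed).
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_pops * model.samples_per_pop
    sample_ids = [
        f"pop{p}_s{i}" for p in range(model.n_pops) for i in range(model.samples_per_pop)
    ]
    pop_of = np.repeat(np.arange(model.n_pops), model.samples_per_pop)

    m = model.n_sites
    n_indel = int(round(model.indel_rate * m))
    n_multi = int(round(model.multiallelic_rate * m))
    n_mono = int(round(model.monomorphic_rate * m))
    kinds = np.array(
        ["indel"] * n_indel + ["multi"] * n_multi + ["mono"] * n_mono
        + ["snp"] * (m - n_indel - n_multi - n_mono)
    )
    rng.shuffle(kinds)

    a, b = model.ancestral_beta
    # clip away near-fixed ancestral frequencies so most SNP records segregate
    p_anc = np.clip(rng.beta(a, b, size=m), 0.05, 0.95)
    freqs = _pop_freqs(rng, p_anc, model.n_pops, model.divergence)

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for s in range(m):
            pos = s + 1
            kind = kinds[s]
            if kind == "mono":
                dosages = np.zeros(n, dtype=int)
                ref, alt = "A", "T"
            else:
                dosages = rng.binomial(2, freqs[s, pop_of])
                if kind == "indel":
                    ref, alt = "A", "AT"
                elif kind == "multi":
                    ref, alt = "A", "C,T"
                else:
                    ref, alt = "A", "C"
            missing = (
                rng.random(n) < model.missing_rate
                if model.missing_rate > 0 else np.zeros(n, dtype=bool)
            )
            gts = "\t".join(
                _gt_string(int(d), bool(miss)) for d, miss in zip(dosages, missing)
            )
            fh.write(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")

    truth_path = f"{path}.truth"
    with open(truth_path, "wt", encoding="utf-8") as fh:
        for sid, p in zip(sample_ids, pop_of):
            fh.write(f"{sid}\tpop{p}\n")
    return str(path), truth_path


def make_toy_vcf(
    sample_ids: Sequence[str],
    records: Sequence[Dict],
    path: str,
) -> str:
    """Write a VCF verbatim from explicit record specs.

    Each record is a dict with keys chrom, pos, ref, alt (comma-joined
    string) and gts (one GT string per sample) — the substrate for parser
    and filter unit tests.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for rec in records:
            gts: List[str] = list(rec["gts"])
            if len(gts) != len(sample_ids):
                raise ValueError(
                    f"record at {rec.get('chrom')}:{rec.get('pos')} has {len(gts)} "
                    f"GT fields for {len(sample_ids)} samples"
                )
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return str(path)
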