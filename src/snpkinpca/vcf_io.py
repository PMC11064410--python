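"""Streaming VCF input.

Reads a multi-sample VCF (plain or gzip) one site at a time and encodes
each sample's GT field as an ALT-allele dosage in {0, 1, 2, MISSING}.
The reader never materializes a genotype matrix across sites: peak state
is one :class:`SiteRecord` plus the :class:`SamplePanel`, which is what
keeps downstream kinship estimation memory-bounded by sample count only.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MISSING",
    "SamplePanel",
    "SiteRecord",
    "VcfFormatError",
    "encode_genotype",
    "open_vcf_stream",
    "read_vcf_header",
    "read_subsample_list",
    "read_group_labels",
]

#: Sentinel dosage for an uncallable genotype (missing, half-missing or haploid).
MISSING: int = -1

_BASES = frozenset("ACGT")

SITE_CLASSES = ("BIALLELIC_SNP", "INDEL", "MULTIALLELIC", "MONOMORPHIC")


class VcfFormatError(ValueError):
    """Raised for malformed VCF content; message names the offending line."""


@dataclass(frozen=True)
class SamplePanel:
    """The sample dimension of an analysis.

    Holds the VCF header sample order, a boolean inclusion mask (subset
    analysis) and optional prior group labels used for concordance scoring.
    """

    sample_ids: Tuple[str, ...]
    subset_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    group_labels: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError("SamplePanel requires at least one sample ID")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in panel")
        mask = self.subset_mask
        if mask is None:
            mask = np.ones(len(self.sample_ids), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self.sample_ids),):
            raise ValueError("subset_mask must have one entry per sample")
        object.__setattr__(self, "subset_mask", mask)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if self.group_labels is not None:
            unknown = sorted(set(self.group_labels) - set(self.sample_ids))
            if unknown:
                raise ValueError(
                    f"group labels refer to unknown sample IDs: {', '.join(unknown)}"
                )

    @property
    def n_total(self) -> int:
        return len(self.sample_ids)

    @property
    def included_ids(self) -> Tuple[str, ...]:
        """Included sample IDs, in VCF header order."""
        return tuple(s for s, m in zip(self.sample_ids, self.subset_mask) if m)

    @property
    def n_included(self) -> int:
        return int(self.subset_mask.sum())

    def group_of(self, sample_id: str) -> str:
        """Prior group of a sample; samples without a label map to "NA"."""
        if self.group_labels is None:
            return "NA"
        return self.group_labels.get(sample_id, "NA")

    def with_subset(self, keep_ids: Sequence[str]) -> "SamplePanel":
        """Restrict the panel to ``keep_ids`` (analysis order stays header order)."""
        keep = set(keep_ids)
        missing = sorted(keep - set(self.sample_ids))
        if missing:
            raise ValueError(
                f"subset sample IDs absent from VCF header: {', '.join(missing)}"
            )
        mask = np.array([s in keep for s in self.sample_ids], dtype=bool)
        if not mask.any():
            raise ValueError("subset selects no samples")
        return replace(self, subset_mask=mask)

    def with_groups(self, group_labels: Dict[str, str]) -> "SamplePanel":
        return replace(self, group_labels=dict(group_labels))


@dataclass(frozen=True)
class SiteRecord:
    """One VCF site restricted to the panel-included samples.

    ``dosages`` holds one value per included sample: the ALT-allele count
    of the diploid genotype, or :data:`MISSING`.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    dosages: np.ndarray
    site_class: str

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.int8)
        object.__setattr__(self, "dosages", d)
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")


def encode_genotype(gt_string: str, n_alt: int = 1) -> int:
    """Encode a VCF GT subfield as an ALT-allele dosage.

    '/' and '|' separators are equivalent. Any '.' allele, and haploid
    calls, yield :data:`MISSING` (the diploid dosage model cannot represent
    a single allele unambiguously).
    """
    alleles = gt_string.replace("|", "/").split("/")
    if len(alleles) != 2:
        # haploid (or polyploid) call; caller emits the one-time warning
        return MISSING
    dosage = 0
    for a in alleles:
        if a == ".":
            return MISSING
        try:
            idx = int(a)
        except ValueError as exc:
            raise VcfFormatError(f"unparseable GT allele {a!r} in {gt_string!r}") from exc
        if idx < 0 or idx > n_alt:
            raise VcfFormatError(
                f"GT allele index {idx} exceeds number of ALT alleles ({n_alt})"
            )
        if idx > 0:
            dosage += 1
    return dosage


def _classify(ref: str, alts: Tuple[str, ...], dosages: np.ndarray) -> str:
    if len(alts) > 1:
        return "MULTIALLELIC"
    if not alts:
        return "MONOMORPHIC"
    alt = alts[0]
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        return "INDEL"
    called = dosages[dosages != MISSING]
    if called.size == 0:
        return "MONOMORPHIC"
    n_alt_alleles = int(called.sum())
    n_ref_alleles = 2 * called.size - n_alt_alleles
    if n_alt_alleles == 0 or n_ref_alleles == 0:
        return "MONOMORPHIC"
    return "BIALLELIC_SNP"


def _open_text(path) -> io.TextIOBase:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_vcf_header(path) -> SamplePanel:
    """Read only the #CHROM header line and return the full sample panel."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 10 or fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VcfFormatError(
                        f"garbled #CHROM header at line {lineno}: expected 9 fixed "
                        "columns followed by at least one sample"
                    )
                return SamplePanel(sample_ids=tuple(fields[9:]))
            raise VcfFormatError(
                f"line {lineno}: expected '##' meta line or '#CHROM' header, "
                f"got {line[:40]!r}"
            )
    raise VcfFormatError("no #CHROM header line found")


def open_vcf_stream(path, panel: Optional[SamplePanel] = None) -> Iterator[SiteRecord]:
    """Yield one :class:`SiteRecord` per VCF data line, in file order.

    Dosages are restricted and ordered to the panel-included samples.
    gzip input is detected by magic bytes and decompressed transparently.
    Memory held at any time is a single site; the returned object is a
    generator and exposes no all-sites container.
    """
    header = read_vcf_header(path)
    if panel is None:
        panel = header
    elif panel.sample_ids != header.sample_ids:
        raise VcfFormatError(
            "panel sample IDs do not match the VCF header columns"
        )
    keep_idx = np.flatnonzero(panel.subset_mask)
    return _iter_sites(path, panel, keep_idx)


def _iter_sites(path, panel: SamplePanel, keep_idx: np.ndarray) -> Iterator[SiteRecord]:
    n_total = panel.n_total
    warned_haploid = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 + n_total:
                raise VcfFormatError(
                    f"line {lineno}: expected {9 + n_total} columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VcfFormatError(f"line {lineno}: bad POS {pos_s!r}") from exc
            alts: Tuple[str, ...] = () if alt_s == "." else tuple(alt_s.split(","))
            n_alt = max(len(alts), 1)
            dosages = np.empty(keep_idx.size, dtype=np.int8)
            for out_i, col in enumerate(keep_idx):
                gt = fields[9 + col].split(":", 1)[0]
                try:
                    d = encode_genotype(gt, n_alt=n_alt)
                except VcfFormatError as exc:
                    raise VcfFormatError(f"line {lineno}: {exc}") from exc
                if d == MISSING and not warned_haploid and "/" not in gt and "|" not in gt and gt != ".":
                    warnings.warn(
                        f"haploid GT call {gt!r} at line {lineno} treated as missing "
                        "(further haploid calls silently missing)",
                        stacklevel=2,
                    )
                    warned_haploid = True
                dosages[out_i] = d
            yield SiteRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                dosages=dosages,
                site_class=_classify(ref, alts, dosages),
            )


def read_subsample_list(path, panel: SamplePanel) -> SamplePanel:
    """Apply a one-ID-per-line subset file to a panel.

    Analysis order follows the VCF header order, not list order; blank
    lines are ignored; an ID absent from the header is an error.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        ids = [ln.strip() for ln in fh if ln.strip()]
    if not ids:
        raise ValueError(f"subsample list {path} selects no samples")
    return panel.with_subset(ids)


def read_group_labels(path) -> Dict[str, str]:
    """Read a two-column "sample_id<TAB>group" table.

    A sample listed twice with conflicting groups is an error; samples
    absent from the file carry label "NA" downstream.
    """
    labels: Dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path} line {lineno}: expected 'sample_id group', got {line.rstrip()!r}"
                )
            sid, grp = parts
            if sid in labels and labels[sid] != grp:
                raise ValueError(
                    f"{path} line {lineno}: sample {sid!r} listed with conflicting "
                    f"groups {labels[sid]!r} and {grp!r}"
                )
            labels[sid] = grp
    return labels
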