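"""PCA by eigendecomposition of the kinship matrix.

Sample coordinates are the raw unit-norm eigenvectors of K (the
smartpca/GCTA convention); an optional flag scales column i by sqrt(λ_i).
Negative eigenvalues — possible with missing-data kinship — are reported
in the eigenvalue file but clipped to zero for variance-explained
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .vcf_io import SamplePanel
from .kinship import KinshipMatrix

__all__ = ["PCAResult", "eigen_pca", "write_pca_outputs"]


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # all n, descending
    scores: np.ndarray       # n x k, unit-norm columns
    var_explained: np.ndarray  # per retained PC, fraction of sum of max(λ,0)
    k: int


def _sign_convention(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.|, lowest-index entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax returns the lowest tied index
        if col[i] < 0:
            out[:, j] = -col
    return out


def eigen_pca(K: KinshipMatrix, k: int = 10) -> PCAResult:
    """Full symmetric eigendecomposition of K; returns the top-k
    eigenvectors as per-sample PC scores under a deterministic sign
    convention."""
    A = K.values
    n = A.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    asym = np.max(np.abs(A - A.T)) if n else 0.0
    if asym > 1e-8:
        raise ValueError(f"kinship matrix is asymmetric (max |K - K'| = {asym:g})")
    A = (A + A.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(A)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = np.clip(eigvals, 0.0, None)
    total = pos.sum()
    var = pos[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        eigenvalues=eigvals,
        scores=_sign_convention(eigvecs[:, :k]),
        var_explained=var,
        k=k,
    )


def write_pca_outputs(res: PCAResult, panel: SamplePanel, prefix: str) -> Tuple[str, str]:
    """Write <prefix>.eigenval (one eigenvalue per line, all n) and
    <prefix>.eigenvec (header; rows = sample_id, group-or-NA, PC1..PCk)."""
    eigenval_path = f"{prefix}.eigenval"
    eigenvec_path = f"{prefix}.eigenvec"
    with open(eigenval_path, "wt", encoding="utf-8") as fh:
        for v in res.eigenvalues:
            fh.write("%.6g\n" % v)
    ids = panel.included_ids
    with open(eigenvec_path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\t" + "\t".join(f"PC{i+1}" for i in range(res.k)) + "\n")
        for row_i, sid in enumerate(ids):
            coords = "\t".join("%.6g" % v for v in res.scores[row_i])
            fh.write(f"{sid}\t{panel.group_of(sid)}\t{coords}\n")
    return eigenval_path, eigenvec_path
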