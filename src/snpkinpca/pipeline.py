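"""Five-stage pipeline: SNP filtering -> kinship -> PCA -> clustering ->
visualization, orchestrated from a single configuration.

Either a VCF or a previously written kinship matrix is the input; the
latter skips straight to PCA so clustering parameters can be adjusted
without re-streaming genotypes.  A run log records every effective
parameter and the per-rule site discard counts, which always reconcile:
sites_read = sites_used + sum of discards.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import clustering as clu
from .kinship import (
    KINSHIP_METHODS,
    KinshipAccumulator,
    finalize_kinship,
    read_kinship,
    update_accumulator,
    write_kinship,
)
from .pca import eigen_pca, write_pca_outputs
from .site_filter import FilterThresholds, classify_and_gate, passes_filters, site_stats
from .vcf_io import (
    SamplePanel,
    open_vcf_stream,
    read_group_labels,
    read_subsample_list,
    read_vcf_header,
)
from .viz import plot_scatter_2d, plot_scatter_3d

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

DISCARD_RULES = ("indel", "multiallelic", "monomorphic", "maf", "miss", "hwe")


class PipelineError(RuntimeError):
    """A stage failure; the message carries the stage name."""


@dataclass
class RunConfig:
    in_vcf: Optional[str] = None
    in_kinship: Optional[str] = None
    out_prefix: str = "snpkinpca"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    kinship_method: str = "Normalized_IBS"
    pc_num: int = 10
    scale_by_eigenvalue: bool = False   # scores column i *= sqrt(max(lambda_i, 0))
    cluster_method: str = "EM"          # EM | Kmeans | DBSCAN
    cluster_pc_num: int = 3
    best_k_min: int = 2
    best_k_max: int = 10
    em_restarts: int = 1000
    dbscan_eps: Optional[float] = None
    dbscan_min_pts: int = 4
    subsample_path: Optional[str] = None
    group_path: Optional[str] = None
    seed: int = 12345
    threads: int = 1                    # accepted for compatibility; ignored

    def __post_init__(self) -> None:
        if (self.in_vcf is None) == (self.in_kinship is None):
            raise ValueError("exactly one of in_vcf / in_kinship must be given")
        if self.kinship_method not in KINSHIP_METHODS:
            raise ValueError(f"unknown kinship method {self.kinship_method!r}")
        if self.cluster_method not in ("EM", "Kmeans", "DBSCAN"):
            raise ValueError(f"unknown cluster method {self.cluster_method!r}")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


def _stream_kinship(cfg: RunConfig, panel: SamplePanel, counts: Dict[str, int]):
    acc = KinshipAccumulator(n_samples=panel.n_included, method=cfg.kinship_method)
    for rec in open_vcf_stream(cfg.in_vcf, panel):
        counts["sites_read"] += 1
        if not classify_and_gate(rec):
            counts[{"INDEL": "indel", "MULTIALLELIC": "multiallelic",
                    "MONOMORPHIC": "monomorphic"}[rec.site_class]] += 1
            continue
        stats = site_stats(rec)
        if stats.maf < cfg.thresholds.maf_min:
            counts["maf"] += 1
            continue
        if stats.missing_rate > cfg.thresholds.miss_max:
            counts["miss"] += 1
            continue
        if stats.hwe_p < cfg.thresholds.hwe_min:
            counts["hwe"] += 1
            continue
        update_accumulator(acc, rec, stats)
        counts["sites_used"] += 1
    if counts["sites_used"] == 0:
        raise ValueError("no sites survive filters")
    return finalize_kinship(acc, panel.included_ids)


def run_pipeline(cfg: RunConfig) -> Dict[str, str]:
    """Run the configured pipeline; returns a manifest of output files.

    Identical configuration and seed yield byte-identical numeric outputs.
    """
    out_dir = os.path.dirname(os.path.abspath(cfg.out_prefix))
    os.makedirs(out_dir, exist_ok=True)
    counts = {"sites_read": 0, "sites_used": 0, **{r: 0 for r in DISCARD_RULES}}
    outputs: Dict[str, str] = {}

    if cfg.in_vcf is not None:
        panel = _stage("vcf_io", read_vcf_header, cfg.in_vcf)
        if cfg.subsample_path:
            panel = _stage("vcf_io", read_subsample_list, cfg.subsample_path, panel)
        if cfg.group_path:
            labels = _stage("vcf_io", read_group_labels, cfg.group_path)
            panel = _stage("vcf_io", panel.with_groups, labels)
        K = _stage("kinship", _stream_kinship, cfg, panel, counts)
        kin_path = f"{cfg.out_prefix}.kinship.matrix"
        _stage("kinship", write_kinship, K, kin_path)
        outputs["kinship"] = kin_path
    else:
        K = _stage("kinship", read_kinship, cfg.in_kinship)
        panel = SamplePanel(sample_ids=K.sample_ids)
        if cfg.subsample_path:
            raise PipelineError("[kinship] -InSubSample applies to VCF input only")
        if cfg.group_path:
            labels = _stage("vcf_io", read_group_labels, cfg.group_path)
            panel = _stage("vcf_io", panel.with_groups, labels)

    n = len(K.sample_ids)
    pc_num = min(cfg.pc_num, n)
    res = _stage("pca", eigen_pca, K, pc_num)
    if cfg.scale_by_eigenvalue:
        import dataclasses

        scale = np.sqrt(np.clip(res.eigenvalues[:res.k], 0.0, None))
        res = dataclasses.replace(res, scores=res.scores * scale)
    eigenval, eigenvec = _stage("pca", write_pca_outputs, res, panel, cfg.out_prefix)
    outputs["eigenval"] = eigenval
    outputs["eigenvec"] = eigenvec

    points = res.scores[:, : min(cfg.cluster_pc_num, res.k)]
    cluster = _stage("clustering", _cluster, cfg, points, n)
    prior = [panel.group_of(s) for s in panel.included_ids]
    conc = None
    if panel.group_labels is not None:
        conc = _stage("clustering", clu.concordance, cluster.labels, prior)
    cluster_path = f"{cfg.out_prefix}.cluster"
    _stage("clustering", _write_cluster, cluster, panel, conc, cluster_path)
    outputs["cluster"] = cluster_path

    if res.k >= 2:
        outputs["plot2d"] = _stage(
            "viz", plot_scatter_2d, res, cluster, panel, f"{cfg.out_prefix}.pca2d.svg"
        )
    if res.k >= 3:
        outputs["plot3d"] = _stage(
            "viz", plot_scatter_3d, res, cluster, panel, f"{cfg.out_prefix}.pca3d.svg"
        )

    log_path = f"{cfg.out_prefix}.log"
    _write_log(cfg, counts, cluster, conc, outputs, log_path)
    outputs["log"] = log_path
    return outputs


def _cluster(cfg: RunConfig, points: np.ndarray, n: int) -> clu.ClusterResult:
    if cfg.cluster_method == "DBSCAN":
        return clu.dbscan_cluster(points, eps=cfg.dbscan_eps, min_pts=cfg.dbscan_min_pts)
    k_max = min(cfg.best_k_max, n - 1)
    K, centroids = clu.best_k_kmeans(points, cfg.best_k_min, k_max, seed=cfg.seed)
    if cfg.cluster_method == "Kmeans":
        return clu.kmeans_cluster(points, K, seed=cfg.seed)
    return clu.em_gaussian_cluster(
        points, K, init_centroids=centroids, n_restarts=cfg.em_restarts, seed=cfg.seed
    )


def _write_cluster(cluster, panel: SamplePanel, conc, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tcluster\n")
        for sid, lab in zip(panel.included_ids, cluster.labels):
            fh.write(f"{sid}\t{panel.group_of(sid)}\t{int(lab)}\n")
        c = "NA" if conc is None else "%.6g" % conc
        fh.write(f"#K={cluster.K} method={cluster.method} concordance={c}\n")


def _write_log(cfg, counts, cluster, conc, outputs, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# effective parameters\n")
        for k, v in vars(cfg).items():
            if k == "thresholds":
                fh.write(f"maf_min={v.maf_min}\nmiss_max={v.miss_max}\nhwe_min={v.hwe_min}\n")
            else:
                fh.write(f"{k}={v}\n")
        fh.write("# site counts\n")
        for k, v in counts.items():
            fh.write(f"{k}={v}\n")
        discards = sum(counts[r] for r in DISCARD_RULES)
        fh.write(f"discarded_total={discards}\n")
        c = "NA" if conc is None else "%.6g" % conc
        fh.write(f"# result\nK={cluster.K} method={cluster.method} concordance={c}\n")
        fh.write("# outputs\n")
        for k, v in outputs.items():
            fh.write(f"{k}={v}\n")
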