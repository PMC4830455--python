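"""End-to-end pipeline: scan pair in, change map and rates out.

Stages: downsample -> threshold -> register (on intensity volumes) ->
resample + re-threshold -> subtract -> summarize -> rates.  Registration is
estimated on the raw working-resolution intensities and the moving scan is
re-thresholded after linear resampling, so the binary volumes entering the
subtraction both come from the same global threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from coralct import __version__
from coralct.differencing import filter_small_clusters, subtract_binary, summarize
from coralct.preprocess import PreprocessConfig, apply_threshold, downsample_mean
from coralct.rates import BlockMeta, compute_rates, ct_volume
from coralct.registration import RegistrationConfig, register, resample
from coralct.volume_io import VolumeGrid, read_volume, write_change_map

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_volumes"]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    min_cluster_size: int = 0
    out_dir: Path | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
        self.registration = dataclasses.replace(self.registration, seed=self.seed)


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, Path):
            return str(o)
        return o
    return hashlib.sha256(json.dumps(enc(cfg), sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def run_pipeline_volumes(pre: VolumeGrid, post: VolumeGrid, meta: BlockMeta,
                         cfg: PipelineConfig | None = None) -> dict:
    """Run the full analysis on in-memory volumes; returns a report dict.

    The report carries the recovered transform, change summary, rates, and
    provenance (version, config hash, seed).  Outputs are only written when
    ``cfg.out_dir`` is set.
    """
    cfg = cfg or PipelineConfig()
    stages = {}
    t0 = time.perf_counter()

    pre_ds = downsample_mean(pre, cfg.preprocess.downsample_factor)
    post_ds = downsample_mean(post, cfg.preprocess.downsample_factor)
    pre_bin = apply_threshold(pre_ds, cfg.preprocess.threshold)
    stages["preprocess_s"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    reg = register(pre_ds, post_ds, cfg.registration)
    stages["register_s"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    post_aligned = resample(post_ds, reg.transform, interpolation="linear",
                            out_shape=pre_ds.shape)
    post_bin = apply_threshold(post_aligned, cfg.preprocess.threshold)
    cm = subtract_binary(pre_bin, post_bin)
    cm = filter_small_clusters(cm, cfg.min_cluster_size)
    summary = summarize(cm)
    stages["difference_s"] = time.perf_counter() - t2

    vol_pre = ct_volume(pre_bin)
    rates = compute_rates(summary, vol_pre, meta)

    report = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "block_id": meta.block_id,
        "transform": reg.transform.to_dict(),
        "registration": {"final_metric": reg.final_metric,
                         "iterations_used": reg.iterations_used,
                         "converged": reg.converged},
        "summary": {"n_accreted": summary.n_accreted, "n_eroded": summary.n_eroded,
                    "vol_accreted_m3": summary.vol_accreted,
                    "vol_eroded_m3": summary.vol_eroded,
                    "voxel_edge_um": summary.voxel_edge},
        "vol_pre_m3": vol_pre,
        "rates": {"bioerosion_kg_m2_yr": rates.bioerosion_rate,
                  "accretion_mm_yr": rates.accretion_rate,
                  "net_change_pct_yr": rates.net_change_pct_per_yr},
        "timing_s": stages,
    }
    if cfg.out_dir is not None:
        _write_outputs(cfg, cm, reg, report)
    return report


def _write_outputs(cfg: PipelineConfig, cm, reg, report: dict) -> None:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    tmp = []
    try:
        p = out / "change_map.nii.gz"
        write_change_map(cm, p)
        tmp.append(p)
        reg.transform.save(out / "transform.json")
        tmp.append(out / "transform.json")
        (out / "report.json").write_text(json.dumps(report, indent=1))
    except Exception:
        for p in tmp:  # remove partial outputs on failure
            p.unlink(missing_ok=True)
        raise


def run_pipeline(pre_path, post_path, meta: BlockMeta,
                 cfg: PipelineConfig | None = None,
                 voxel_edge: float | None = None) -> dict:
    """File-based variant of :func:`run_pipeline_volumes`."""
    pre = read_volume(pre_path, voxel_edge=voxel_edge)
    post = read_volume(post_path, voxel_edge=voxel_edge)
    return run_pipeline_volumes(pre, post, meta, cfg)
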