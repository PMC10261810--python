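"""End-to-end pipeline: samples -> summaries -> tests -> risk -> clustering.

A :class:`PipelineConfig` fully determines a run; with a fixed seed every
output table is bit-reproducible. Outputs are CSV/JSON/Newick/PNG files in
an output directory, each text artifact carrying a provenance comment with
the config hash and seed.

Exposure handling offers two modes:

``calibrated`` (default)
    Back-solves a per-product scalar exposure multiplier so the simulated
    median total intake matches a supplied (or bundled reference) median
    EDI; used when intake-rate/body-weight values are unpublished.

``config``
    Full distributional exposure parameters per product via
    :class:`pcbrisk.exposure.ExposureConfig` mappings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .congeners import (
    CONGENERS,
    EU_LIMIT_NG_G_FAT,
    ILCR_THRESHOLD,
    SLOPE_FACTOR,
    TDI_NG_KG_DAY,
    Congener,
)
from .clustering import build_profile_matrix, export_tree, hierarchical_cluster, render_heatmap
from .datasets import edi_median_totals, product_moment_specs, qc_reference
from .errors import ConfigError
from .exposure import (
    ExposureConfig,
    calibrate_exposure,
    compare_tdi,
    compute_ilcr,
    congener_contributions,
    run_mcs,
)
from .io import apply_censoring, load_yaml, read_samples, write_samples
from .simulate import generate_survey
from .stats import check_regulatory_limit, compare_groups, summarize, summary_frame, total_ndl

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("pcbrisk.pipeline")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full run.

    ``input_path=None`` generates a synthetic survey from the bundled
    reference moment specs (``n_per_product`` samples per product type).
    ``edi_median_targets`` drives the calibrated exposure mode; ``None``
    uses the bundled reference medians.
    """

    input_path: str | None = None
    n_per_product: int = 40
    seed: int = 1
    n_iter: int = 10_000
    outdir: str = "pcbrisk_out"
    exposure_mode: str = "calibrated"  # "calibrated" | "config"
    exposure: Mapping[str, Mapping] | None = None  # per product, for "config"
    edi_median_targets: Mapping[str, float] | None = None
    censoring_rule: str = "half_lod"
    eu_limit: float = EU_LIMIT_NG_G_FAT
    tdi: float = TDI_NG_KG_DAY
    ilcr_threshold: float = ILCR_THRESHOLD
    slope_factor: float = SLOPE_FACTOR
    heatmap_group_by: str = "product"

    def __post_init__(self) -> None:
        if self.exposure_mode not in ("calibrated", "config"):
            raise ConfigError(f"unknown exposure_mode {self.exposure_mode!r}")
        if self.exposure_mode == "config" and not self.exposure:
            raise ConfigError("exposure_mode='config' requires an exposure mapping")
        for name in ("eu_limit", "tdi", "ilcr_threshold", "slope_factor"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**load_yaml(path))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure"] = dict(self.exposure) if self.exposure else None
        d["edi_median_targets"] = (
            dict(self.edi_median_targets) if self.edi_median_targets else None
        )
        return d

    def digest(self) -> str:
        """Short hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclasses.dataclass
class RunReport:
    """Handles to every artifact of one pipeline run."""

    config: PipelineConfig
    samples: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    group_tests: pd.DataFrame
    edi_percentiles: pd.DataFrame
    contributions: pd.DataFrame
    risk: pd.DataFrame
    newick: str
    paths: dict[str, str]
    provenance: dict[str, object]


def _provenance_line(config: PipelineConfig) -> str:
    return f"pcbrisk {__version__} config={config.digest()} seed={config.seed}"


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(f"# {_provenance_line(config)}\n")
        frame.to_csv(handle, index=index)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # -- stage 1: obtain samples ----------------------------------------
    if config.input_path is None:
        log.info("stage=samples mode=synthetic n_per_product=%d seed=%d",
                 config.n_per_product, config.seed)
        samples = generate_survey(
            product_moment_specs(), n_per_product=config.n_per_product, seed=config.seed
        )
    else:
        log.info("stage=samples mode=read path=%s", config.input_path)
        samples = read_samples(config.input_path)
        lods = qc_reference()["lod_ng_g"]
        loqs = qc_reference()["loq_ng_g"]
        samples = apply_censoring(
            samples, lod=lods.to_dict(), loq=loqs.to_dict(), rule=config.censoring_rule
        )
    p = outdir / "samples.csv"
    write_samples(samples, p, provenance=_provenance_line(config))
    paths["samples"] = str(p)

    # -- stage 2: summaries and limit check -----------------------------
    summaries: dict[str, pd.DataFrame] = {}
    limit_rows = []
    for level in ("overall", "product", "brand"):
        groups = summarize(samples, level=level)
        frame = summary_frame(groups)
        summaries[level] = frame
        p = outdir / f"summary_{level}.csv"
        _write_csv(frame, p, config)
        paths[f"summary_{level}"] = str(p)
        for g in groups:
            ok, margin = check_regulatory_limit(g, limit=config.eu_limit)
            limit_rows.append(
                {"level": level, "group": g.value, "mean_total": g.total.mean,
                 "limit": config.eu_limit, "compliant": ok, "margin": margin}
            )
        log.info("stage=summarize level=%s groups=%d", level, len(groups))
    limits = pd.DataFrame(limit_rows)
    p = outdir / "regulatory_limits.csv"
    _write_csv(limits, p, config, index=False)
    paths["regulatory_limits"] = str(p)

    # -- stage 3: group comparisons -------------------------------------
    test_rows = []
    for factor in ("product", "brand"):
        if samples[factor].nunique() < 2:
            log.info("stage=compare factor=%s skipped (single group)", factor)
            continue
        for target in [*CONGENERS, "total"]:
            res = compare_groups(samples, factor=factor, congener=target)
            test_rows.append(
                {"factor": factor, "congener": res.congener, "test": res.test_name,
                 "statistic": res.statistic, "p_value": res.p_value,
                 "significant": res.significant}
            )
    group_tests = pd.DataFrame(test_rows)
    p = outdir / "group_tests.csv"
    _write_csv(group_tests, p, config, index=False)
    paths["group_tests"] = str(p)
    log.info("stage=compare tests=%d", len(group_tests))

    # -- stage 4: Monte Carlo exposure and risk -------------------------
    targets = dict(config.edi_median_targets or edi_median_totals())
    pctl_frames, contrib_rows, risk_rows = [], [], []
    for product, group in samples.groupby("product", sort=False):
        conc_specs = {
            c: _specs_from_samples(group, c) for c in CONGENERS
        }
        if config.exposure_mode == "calibrated":
            conc_median = float(np.median(total_ndl(group)))
            mult = calibrate_exposure(conc_median, targets[product])
            exp_cfg = ExposureConfig.from_multiplier(mult, sf=config.slope_factor)
            log.info("stage=risk product=%s multiplier=%.4g", product, mult)
        else:
            exp_cfg = ExposureConfig.from_dict(config.exposure[product])
        dist = run_mcs(conc_specs, exp_cfg, n_iter=config.n_iter, seed=config.seed)
        tab = dist.percentiles.copy()
        tab.insert(0, "product", product)
        pctl_frames.append(tab.reset_index())
        for cong, frac in congener_contributions(dist).items():
            contrib_rows.append({"product": product, "congener": cong.value, "fraction": frac})
        risk = compute_ilcr(dist.total, sf=exp_cfg.sf, threshold=config.ilcr_threshold)
        risk_rows.append(
            {"product": product, "mean_edi": dist.mean_total(),
             "median_edi": float(np.median(dist.total)),
             "below_tdi_mean": compare_tdi(dist.mean_total(), tdi=config.tdi),
             "ilcr_mean": risk.ilcr_mean,
             "ilcr_p95": float(risk.ilcr_percentiles.loc[95]),
             "classification": risk.classification}
        )
    edi_percentiles = pd.concat(pctl_frames, ignore_index=True)
    contributions = pd.DataFrame(contrib_rows)
    risk_table = pd.DataFrame(risk_rows)
    for name, frame in (("edi_percentiles", edi_percentiles),
                        ("congener_contributions", contributions),
                        ("risk", risk_table)):
        p = outdir / f"{name}.csv"
        _write_csv(frame, p, config, index=False)
        paths[name] = str(p)
    log.info("stage=risk products=%d n_iter=%d", len(risk_rows), config.n_iter)

    # -- stage 5: congener-profile clustering ---------------------------
    matrix = build_profile_matrix(samples, group_by=config.heatmap_group_by)
    tree = hierarchical_cluster(matrix)
    newick = export_tree(tree)
    p = outdir / "congener_tree.nwk"
    p.write_text(f"[{_provenance_line(config)}]\n{newick}\n", encoding="utf-8")
    paths["tree"] = str(p)
    p = outdir / "heatmap.png"
    render_heatmap(matrix, str(p), row_tree=tree)
    paths["heatmap"] = str(p)
    log.info("stage=cluster leaf_order=%s", ",".join(tree.leaf_order))

    # -- stage 6: report -------------------------------------------------
    provenance = {
        "tool": "pcbrisk",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    report = {
        "provenance": provenance,
        "regulatory_limits": limits.to_dict(orient="records"),
        "risk": risk_table.to_dict(orient="records"),
        "cluster_leaf_order": list(tree.leaf_order),
        "artifacts": paths,
    }
    p = outdir / "report.json"
    p.write_text(json.dumps(report, indent=2, default=float), encoding="utf-8")
    paths["report"] = str(p)
    log.info("stage=report artifacts=%d", len(paths))

    return RunReport(
        config=config,
        samples=samples,
        summaries=summaries,
        group_tests=group_tests,
        edi_percentiles=edi_percentiles,
        contributions=contributions,
        risk=risk_table,
        newick=newick,
        paths=paths,
        provenance=provenance,
    )


def _specs_from_samples(group: pd.DataFrame, congener: Congener):
    """Concentration model for the MCS: moments observed in the sample table."""
    from .distributions import MomentSpec

    x = group[congener.value].to_numpy(dtype=float)
    return MomentSpec(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )
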