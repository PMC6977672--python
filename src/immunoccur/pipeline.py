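"""End-to-end pipeline: synthetic inputs -> census, meta-analysis, DE,
trajectory shapes, qPCR and correlation tables, with a reproducibility
header on every output."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog
from .correlation import correlate_panel
from .dataset_io import cohort_census, filter_eligible
from .occurrence import DEFAULT_GROUP_PAIRS, run_meta_analysis
from .qpcr import qpcr_summary
from .simulate import (
    AdTimecourseSpec,
    CohortSpec,
    generate_ad_timecourse,
    generate_aging_cohort,
    panel_log2_expression,
)
from .timecourse import de_contrast, trajectory_shape

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "out_dir",
    "seed",
    "cutoff",
    "baseline",
    "pooling_model",
    "vshape_margin",
    "stages",
    "cohort",
    "timecourse",
    "correlate_genes",
    "log_level",
}
_STAGES = ("census", "meta", "de", "qpcr", "correlate")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 20200106
    cutoff: float = 1.0
    baseline: str = "mean"
    pooling_model: str = "fixed"
    vshape_margin: float = 1.0
    stages: tuple[str, ...] = _STAGES
    cohort: dict = field(default_factory=dict)
    timecourse: dict = field(default_factory=dict)
    correlate_genes: tuple[str, ...] = (
        "AttB", "AttC", "CecA1", "Drs", "Mtk", "LysS",
    )
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in data:
            raise ValueError("config requires out_dir")
        kwargs: dict[str, Any] = dict(data)
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        for key in ("stages", "correlate_genes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        bad = set(kwargs.get("stages", ())) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def resolved(self) -> dict[str, Any]:
        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "cutoff": self.cutoff,
            "baseline": self.baseline,
            "pooling_model": self.pooling_model,
            "vshape_margin": self.vshape_margin,
            "stages": list(self.stages),
            "cohort": dict(self.cohort),
            "timecourse": dict(self.timecourse),
            "correlate_genes": list(self.correlate_genes),
            "log_level": self.log_level,
        }
        return d


def _config_hash(resolved: Mapping[str, Any]) -> str:
    # hash the scientific parameters only, not filesystem locations
    params = {k: v for k, v in resolved.items() if k not in ("out_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str, index: bool = False) -> None:
    """TSV with a reproducibility comment header (version, seed, config)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# immunoccur {__version__} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages on synthetic inputs; returns the map of
    stage outputs written under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    cfg_hash = _config_hash(resolved)
    with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    catalog = load_catalog("default")
    outputs: dict[str, Path] = {}

    needs_cohort = {"census", "meta"} & set(config.stages)
    needs_tc = {"de", "qpcr", "correlate"} & set(config.stages)

    cohort = truth = None
    if needs_cohort:
        spec = CohortSpec(seed=config.seed, **config.cohort)
        cohort, truth = generate_aging_cohort(spec, catalog)
        cohort = filter_eligible(cohort)

    bundle = None
    if needs_tc:
        tc_spec = AdTimecourseSpec(seed=config.seed, **config.timecourse)
        bundle = generate_ad_timecourse(tc_spec, catalog)

    for stage in config.stages:
        logger.info("running stage %s", stage)
        if stage == "census":
            census = cohort_census(cohort)
            df = pd.DataFrame([census.as_dict()])
            outputs["census"] = out / "census.tsv"
            write_table(df, outputs["census"], config.seed, cfg_hash)
        elif stage == "meta":
            meta = run_meta_analysis(
                cohort,
                catalog,
                cutoff=config.cutoff,
                baseline=config.baseline,
                model=config.pooling_model,
            )
            outputs["class_rd"] = out / "class_rd.tsv"
            write_table(meta.class_rates, outputs["class_rd"], config.seed, cfg_hash)
            for older, younger in DEFAULT_GROUP_PAIRS:
                name = f"forest_{older}_vs_{younger}.tsv"
                outputs[name] = out / name
                write_table(
                    meta.forest_table(older, younger), outputs[name], config.seed, cfg_hash
                )
        elif stage == "de":
            profiles = {}
            for tp in bundle.counts.meta["timepoint_days"].unique():
                res = de_contrast(bundle.counts, int(tp))
                name = f"de_day{int(tp)}.tsv"
                outputs[name] = out / name
                write_table(res, outputs[name], config.seed, cfg_hash)
                profiles[int(tp)] = res.set_index("gene")["log2FC"]
            prof = pd.DataFrame(profiles)
            shapes = trajectory_shape(
                prof,
                gene_set=list(catalog.members("AMP")) + ["LysS"],
                margin=config.vshape_margin,
            )
            outputs["trajectory_shapes"] = out / "trajectory_shapes.tsv"
            write_table(shapes, outputs["trajectory_shapes"], config.seed, cfg_hash)
        elif stage == "qpcr":
            summary = qpcr_summary(bundle.ct_records)
            outputs["qpcr_results"] = out / "qpcr_results.tsv"
            write_table(summary, outputs["qpcr_results"], config.seed, cfg_hash)
        elif stage == "correlate":
            expr = panel_log2_expression(bundle, config.correlate_genes)
            matrix = correlate_panel(expr, bundle.phenotypes)
            outputs["corr"] = out / "corr.tsv"
            write_table(matrix.to_long(), outputs["corr"], config.seed, cfg_hash)
    return outputs
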