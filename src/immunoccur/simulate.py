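"""Synthetic data with the statistical structure the analyses assume.

Two generators cover every input the pipeline consumes:

* :func:`generate_aging_cohort` emulates the multi-study GEO mining input —
  several independent datasets, each with its own per-gene platform baseline,
  log2-normal sample noise, and a planted per-class log2 shift per age step
  (young -> middle-aged -> old). Default: AMPs shift +2 log2 units per step,
  all other classes flat, noise sd 0.5, six datasets of 4 samples per group.

* :func:`generate_ad_timecourse` emulates a WT/AD head RNA-seq design at
  days 3/10/20/30 in triplicate: negative-binomial counts with planted
  AD-vs-WT log2 trajectories (the AMP panel V-shaped with its minimum at
  day 10; LysS elevated at every timepoint), qPCR Ct tables back-computed
  from expression with a flat RpL32 reference, and Abeta42 / apoptosis
  phenotype series that stay low in WT and rise in AD, with the designated
  genes coupled to Abeta42 through a shared latent factor.

Everything is deterministic given a seed; each output table draws from its
own named PRNG substream so adding one table never perturbs another.
Ground-truth planted effects are returned (and written) as sidecar tables so
recovery tests compare generated truth against estimates directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, load_catalog
from .dataset_io import AGE_GROUPS, Cohort, ExpressionDataset, SampleMeta, write_dataset
from .timecourse import CountMatrix

DEFAULT_SEED = 20200106

#: qPCR panel: the 14 AMPs plus LysS, with RpL32 as reference.
QPCR_PANEL_CLASSES = ("AMP", "lysozyme")

#: Genes whose AD expression co-varies with Abeta42 via the shared latent.
DEFAULT_COUPLED_GENES = ("AttB", "AttC", "CecA1", "Drs", "Mtk", "LysS")


@dataclass
class CohortSpec:
    """Design of a synthetic multi-study aging cohort."""

    n_datasets: int = 6
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"young": 4, "middle_aged": 4, "old": 4}
    )
    #: log2 shift per age step (young=0, middle_aged=1, old=2) per class.
    class_effects: Mapping[str, float] = field(default_factory=lambda: {"AMP": 2.0})
    noise_sd: float = 0.5
    platform_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    group_ages: Mapping[str, int] = field(
        default_factory=lambda: {"young": 3, "middle_aged": 20, "old": 40}
    )
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.platform_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(n < 1 for n in self.samples_per_group.values()):
            raise ValueError("samples_per_group entries must be >= 1")


_AGE_STEP = {g: i for i, g in enumerate(AGE_GROUPS)}


def generate_aging_cohort(
    spec: CohortSpec, catalog: Optional[GeneCatalog] = None
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort of log2-scale expression datasets plus planted truth.

    Per dataset, each gene gets a platform-specific baseline around a global
    gene mean; each sample's value is baseline + class_effect * age_step +
    Gaussian noise. The truth table records the per-gene log2 shift per step.
    """
    catalog = catalog or load_catalog("default")
    genes = [rec.symbol for rec in catalog.records]
    effects = np.array(
        [spec.class_effects.get(rec.immune_class, 0.0) for rec in catalog.records]
    )
    rng_base = np.random.default_rng([spec.seed, 0])
    gene_means = rng_base.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    datasets = []
    for d in range(spec.n_datasets):
        rng = np.random.default_rng([spec.seed, 1, d])
        dataset_id = f"SYN{d + 1:03d}"
        baselines = gene_means + rng.normal(0.0, spec.platform_sd, size=len(genes))
        columns: dict[str, np.ndarray] = {}
        samples: list[SampleMeta] = []
        for group in AGE_GROUPS:
            n = spec.samples_per_group.get(group, 0)
            step = _AGE_STEP[group]
            for i in range(n):
                sid = f"{dataset_id}_{group}_{i + 1}"
                values = (
                    baselines
                    + effects * step
                    + rng.normal(0.0, spec.noise_sd, size=len(genes))
                )
                columns[sid] = values
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        dataset_id=dataset_id,
                        age_days=spec.group_ages[group],
                    )
                )
        matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_id, matrix=matrix, scale="log2", samples=samples
            )
        )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "immune_class": [rec.immune_class for rec in catalog.records],
            "log2_shift_per_age_step": effects,
        }
    )
    return Cohort(datasets=datasets, catalog=catalog), truth


def write_cohort(cohort: Cohort, truth: pd.DataFrame, out_dir: str | Path) -> None:
    """Write every dataset (matrix + metadata TSV) and the truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in cohort.datasets:
        write_dataset(ds, out / f"{ds.dataset_id}_matrix.tsv", out / f"{ds.dataset_id}_meta.tsv")
    truth.to_csv(out / "truth_aging.tsv", sep="\t", index=False)


@dataclass
class AdTimecourseSpec:
    """Design of the synthetic WT/AD time-course experiment."""

    timepoints: tuple[int, ...] = (3, 10, 20, 30)
    replicates: int = 3
    n_background_genes: int = 185
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.1
    #: AD-vs-WT log2FC per timepoint for every AMP gene (V shape, min day 10).
    amp_trajectory: tuple[float, ...] = (-0.5, -2.0, 0.0, 0.5)
    #: AD-vs-WT log2FC per timepoint for LysS (rounded from the reported
    #: 2.891 / 3.929 / 3.412 / 4.576).
    lyss_trajectory: tuple[float, ...] = (2.9, 3.9, 3.4, 4.6)
    #: WT aging trend added to AMP genes (log2 vs day 3), rising with age.
    wt_amp_trend: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    abeta_wt_mean: float = 8.0
    abeta_wt_sd: float = 1.5
    abeta_ad_means: tuple[float, ...] = (15.0, 40.0, 150.0, 160.0)
    abeta_ad_sds: tuple[float, ...] = (3.0, 8.0, 15.0, 25.0)
    apoptosis_wt_mean: float = 0.12
    apoptosis_wt_sd: float = 0.02
    apoptosis_ad_means: tuple[float, ...] = (0.25, 0.6, 1.4, 1.5)
    apoptosis_ad_sds: tuple[float, ...] = (0.05, 0.1, 0.12, 0.3)
    coupled_genes: tuple[str, ...] = DEFAULT_COUPLED_GENES
    #: log2 units of coupled-gene AD expression per latent-factor sd.
    coupling_coef: float = 0.5
    ct_intercept: float = 34.0
    ct_reference: float = 16.0
    ct_noise_sd: float = 0.15
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("amp_trajectory", "lyss_trajectory", "wt_amp_trend",
                     "abeta_ad_means", "abeta_ad_sds",
                     "apoptosis_ad_means", "apoptosis_ad_sds"):
            if len(getattr(self, name)) != len(self.timepoints):
                raise ValueError(f"{name} must have one value per timepoint")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per arm")


@dataclass
class AdTimecourseBundle:
    """Everything :func:`generate_ad_timecourse` produces."""

    counts: CountMatrix
    ct_records: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # gene x timepoint planted AD-vs-WT log2FC


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_ad_timecourse(
    spec: AdTimecourseSpec, catalog: Optional[GeneCatalog] = None
) -> AdTimecourseBundle:
    catalog = catalog or load_catalog("default")
    amp_genes = list(catalog.members("AMP"))
    panel = amp_genes + ["LysS"]
    background = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = panel + background
    n_genes = len(genes)
    tps = spec.timepoints

    rng_base = np.random.default_rng([spec.seed, 10])
    baseline = rng_base.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_genes)

    # planted AD-vs-WT log2FC per gene x timepoint
    traj = np.zeros((n_genes, len(tps)))
    for g in amp_genes:
        traj[genes.index(g)] = spec.amp_trajectory
    traj[genes.index("LysS")] = spec.lyss_trajectory
    wt_trend = np.zeros((n_genes, len(tps)))
    for g in amp_genes:
        wt_trend[genes.index(g)] = spec.wt_amp_trend

    # shared latent factor per AD (timepoint, replicate) drives Abeta42 and
    # the coupled genes
    rng_latent = np.random.default_rng([spec.seed, 11])
    latent = rng_latent.standard_normal((len(tps), spec.replicates))
    coupled_idx = [genes.index(g) for g in spec.coupled_genes if g in genes]

    rng_counts = np.random.default_rng([spec.seed, 12])
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    log2_expr: dict[tuple[str, int, int], np.ndarray] = {}
    for ti, tp in enumerate(tps):
        for cond in ("WT", "AD"):
            for rep in range(1, spec.replicates + 1):
                log2_mean = baseline + wt_trend[:, ti]
                if cond == "AD":
                    log2_mean = log2_mean + traj[:, ti]
                    z = latent[ti, rep - 1]
                    log2_mean = log2_mean.copy()
                    log2_mean[coupled_idx] += spec.coupling_coef * z
                counts = _nb_draw(rng_counts, 2.0**log2_mean, spec.nb_dispersion)
                sid = f"{cond}_d{tp}_r{rep}"
                columns[sid] = counts
                log2_expr[(cond, tp, rep)] = log2_mean
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "timepoint_days": tp,
                        "replicate": rep,
                    }
                )
    counts_df = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    counts = CountMatrix(counts=counts_df, meta=meta)

    # qPCR Ct: Ct = intercept - log2(expression) + noise; RpL32 flat
    rng_ct = np.random.default_rng([spec.seed, 13])
    ct_rows = []
    for (cond, tp, rep), expr in sorted(log2_expr.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2])):
        sid = f"{cond}_d{tp}_r{rep}"
        for g in panel:
            ct = spec.ct_intercept - expr[genes.index(g)] + rng_ct.normal(0, spec.ct_noise_sd)
            ct_rows.append(
                {
                    "sample_id": sid,
                    "gene": g,
                    "Ct": round(float(ct), 4),
                    "condition": cond,
                    "timepoint_days": tp,
                    "replicate": rep,
                }
            )
        ct_rows.append(
            {
                "sample_id": sid,
                "gene": "RpL32",
                "Ct": round(float(spec.ct_reference + rng_ct.normal(0, spec.ct_noise_sd)), 4),
                "condition": cond,
                "timepoint_days": tp,
                "replicate": rep,
            }
        )
    ct_records = pd.DataFrame(ct_rows)

    # phenotypes: WT low and flat; AD rising, sharpest separation at day 20;
    # Abeta42 loads fully on the latent, apoptosis partially (r > 0 with it)
    rng_ph = np.random.default_rng([spec.seed, 14])
    ph_rows = []
    for ti, tp in enumerate(tps):
        for rep in range(1, spec.replicates + 1):
            z = latent[ti, rep - 1]
            eps = rng_ph.standard_normal()
            wt_ab = spec.abeta_wt_mean + spec.abeta_wt_sd * rng_ph.standard_normal()
            wt_ap = spec.apoptosis_wt_mean + spec.apoptosis_wt_sd * rng_ph.standard_normal()
            ad_ab = spec.abeta_ad_means[ti] + spec.abeta_ad_sds[ti] * z
            ad_ap = spec.apoptosis_ad_means[ti] + spec.apoptosis_ad_sds[ti] * (
                0.8 * z + 0.6 * eps
            )
            for cond, ab, ap in (("WT", wt_ab, wt_ap), ("AD", ad_ab, ad_ap)):
                ph_rows.append(
                    {
                        "condition": cond,
                        "timepoint_days": tp,
                        "replicate": rep,
                        "analyte": "Abeta42",
                        "value": max(0.0, round(float(ab), 4)),
                    }
                )
                ph_rows.append(
                    {
                        "condition": cond,
                        "timepoint_days": tp,
                        "replicate": rep,
                        "analyte": "apoptosis_abs",
                        "value": max(0.0, round(float(ap), 4)),
                    }
                )
    phenotypes = pd.DataFrame(ph_rows)

    truth = pd.DataFrame(traj, index=pd.Index(genes, name="gene"), columns=list(tps))
    return AdTimecourseBundle(
        counts=counts, ct_records=ct_records, phenotypes=phenotypes, truth=truth
    )


def write_ad_timecourse(bundle: AdTimecourseBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.counts.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    bundle.counts.meta.to_csv(out / "counts_meta.tsv", sep="\t", index=False)
    bundle.ct_records.to_csv(out / "ct_records.tsv", sep="\t", index=False)
    bundle.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    bundle.truth.to_csv(out / "truth_timecourse.tsv", sep="\t")


def panel_log2_expression(bundle: AdTimecourseBundle, genes: Sequence[str]) -> pd.DataFrame:
    """log2(normalized count + 1) for selected genes, indexed by
    (condition, timepoint_days, replicate) — the correlation panel input."""
    from .timecourse import normalize

    norm = np.log2(normalize(bundle.counts.counts) + 1.0)
    meta = bundle.counts.meta.set_index("sample_id")
    idx = pd.MultiIndex.from_frame(
        meta.loc[norm.columns, ["condition", "timepoint_days", "replicate"]]
    )
    wide = norm.loc[[g for g in genes if g in norm.index]].T
    wide.index = idx
    return wide
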