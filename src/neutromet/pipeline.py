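"""Configuration-driven orchestration of the full pipeline.

``run_pipeline`` drives: cohort input (a directory of spectra + metadata,
or the synthetic generator), TSP referencing, line-width QC with
exclusion of failed spectra, Bernstein baseline correction, residual-water
exclusion, bin integration, total-area normalisation, CRS filtering, PCA,
the replicated PLS-DA validation, the univariate screen, and — for
titration cohorts — the detection-limit report. Every run writes a
machine-readable manifest (config echo, package version, seeds, QC
exclusions) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InvariantError
from .evaluate import replicated_evaluation, univariate_screen
from .features import crs_select, integrate_bins, pareto_scale, ta_normalise
from .io import (
    FeatureTable,
    PatternFile,
    Spectrum,
    read_pattern,
    read_spectrum,
    write_feature_table,
    write_pattern,
)
from .models import fit_pca
from .preprocess import (
    DEFAULT_TSP_WINDOW,
    DEFAULT_WATER_REGION,
    correct_baseline,
    exclude_region,
    qc_spectrum,
    reference_to_tsp,
)
from .synthetic import (
    SpectrumSet,
    SyntheticConfig,
    generate_titration_cohort,
    write_library,
)
from .version import __version__

logger = logging.getLogger("neutromet")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "spectra_dir"
    output_dir: str = "neutromet_out"
    spectra_dir: Optional[str] = None
    metadata: Optional[str] = None
    pattern: Optional[str] = None
    # preprocessing
    reference_window: Tuple[float, float] = DEFAULT_TSP_WINDOW
    baseline_degree: int = 5
    baseline_anchors: int = 16
    water_region: Tuple[float, float] = DEFAULT_WATER_REGION
    exclude_water: bool = True
    linewidth_threshold_hz: float = 1.0
    run_qc: bool = True
    # features
    crs: bool = True
    # evaluation
    n_replicates: int = 10
    train_fraction: float = 0.7
    max_components: int = 5
    alpha: float = 0.05
    label_key: str = "group"
    group_pools: Optional[dict] = None  # new label -> list of pooled label values
    eval_filter: Optional[dict] = None  # design column -> allowed values
    seed: int = 0
    timestamps: bool = True
    write_corrected_spectra: bool = False
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if self.mode not in ("synthetic", "spectra_dir"):
            raise ConfigError(f"mode must be 'synthetic' or 'spectra_dir', got {self.mode!r}")
        if self.mode == "spectra_dir":
            for name in ("spectra_dir", "metadata", "pattern"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"{name} is required in spectra_dir mode")
                if not Path(value).exists():
                    raise ConfigError(f"{name} path does not exist: {value}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        syn = data.pop("synthetic", None)
        if isinstance(syn, SyntheticConfig):
            pass
        elif syn is not None:
            syn = SyntheticConfig(**syn)
        else:
            syn = SyntheticConfig()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=syn, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["synthetic"]["library"] = [m["name"] for m in out["synthetic"]["library"]]
        return out


# --------------------------------------------------------------------------
# spectra_dir input
# --------------------------------------------------------------------------


def _load_cohort(config: PipelineConfig) -> SpectrumSet:
    meta = pd.read_csv(config.metadata, sep=None, engine="python")
    if "sample_id" not in meta.columns or "file" not in meta.columns:
        raise ConfigError("metadata must have 'sample_id' and 'file' columns")
    spectra = []
    base = Path(config.spectra_dir)
    for _, row in meta.iterrows():
        s = read_spectrum(base / str(row["file"]))
        for key in meta.columns:
            if key != "file":
                s.meta[key] = row[key]
        spectra.append(s)
    design = meta.drop(columns=["file"]).copy()
    return SpectrumSet(spectra, design)


# --------------------------------------------------------------------------
# detection-limit report
# --------------------------------------------------------------------------


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window)
    return np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones_like(y), kernel, mode="same"
    )


def estimate_noise_sd(s: Spectrum, region: Tuple[float, float] = (9.55, 9.95)) -> float:
    """Noise SD from first differences in a signal-free region.

    Differencing removes any smooth (baseline) component; for i.i.d.
    noise, SD(diff)/sqrt(2) estimates the point noise SD.
    """
    lo, hi = sorted(region)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 8:
        raise InvariantError(f"noise region [{lo}, {hi}] has too few axis points")
    return float(np.std(np.diff(s.intensity[mask])) / np.sqrt(2.0))


def detection_limit_report(
    cohort: SpectrumSet,
    pattern: PatternFile,
    snr_threshold: float = 3.0,
    noise_region: Tuple[float, float] = (9.55, 9.95),
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Bins detected above a signal-to-noise threshold, per condition.

    For each (cell_count, n_scans) condition, a bin counts as detected
    when its mean SNR across replicates exceeds ``snr_threshold``; SNR is
    the lightly smoothed peak height inside the bin over the noise SD
    estimated from a signal-free region.
    """
    for col in ("cell_count", "n_scans"):
        if col not in cohort.design.columns:
            raise InvariantError(f"cohort design lacks required column {col!r}")
    bins = list(pattern.bins)
    snr_rows = np.empty((len(cohort), len(bins)))
    for i, s in enumerate(cohort.spectra):
        sigma = estimate_noise_sd(s, noise_region)
        smoothed = _smooth(s.intensity, smooth_window)
        for j, b in enumerate(bins):
            mask = (s.ppm >= b.right_ppm) & (s.ppm <= b.left_ppm)
            height = float(smoothed[mask].max()) if mask.any() else 0.0
            if sigma > 0:
                snr_rows[i, j] = height / sigma
            else:
                snr_rows[i, j] = np.inf if height > 0 else 0.0
    frame = cohort.design[["cell_count", "n_scans"]].copy()
    rows = []
    for (cells, ns), idx in frame.groupby(["cell_count", "n_scans"]).groups.items():
        mean_snr = snr_rows[np.asarray(idx)].mean(axis=0)
        detected = [b.bin_id for b, v in zip(bins, mean_snr) if v > snr_threshold]
        rows.append(
            {
                "cell_count": int(cells),
                "n_scans": int(ns),
                "n_detected": len(detected),
                "n_bins": len(bins),
                "detected_bins": ";".join(detected),
            }
        )
    return pd.DataFrame(rows).sort_values(["n_scans", "cell_count"]).reset_index(drop=True)


def detection_monotonicity(report: pd.DataFrame) -> dict:
    """Fraction of adjacent condition steps with non-decreasing detected
    counts, along the cell-count axis (fixed NS) and the NS axis (fixed
    cell count)."""
    ok_cells = total_cells = ok_ns = total_ns = 0
    for _, sub in report.groupby("n_scans"):
        counts = sub.sort_values("cell_count")["n_detected"].to_numpy()
        steps = np.diff(counts)
        ok_cells += int(np.sum(steps >= 0))
        total_cells += steps.size
    for _, sub in report.groupby("cell_count"):
        counts = sub.sort_values("n_scans")["n_detected"].to_numpy()
        steps = np.diff(counts)
        ok_ns += int(np.sum(steps >= 0))
        total_ns += steps.size
    return {
        "frac_nondecreasing_cell_count": ok_cells / total_cells if total_cells else 1.0,
        "frac_nondecreasing_ns": ok_ns / total_ns if total_ns else 1.0,
    }


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def preprocess_cohort(
    cohort: SpectrumSet, config: PipelineConfig, pattern: Optional[PatternFile] = None
) -> tuple:
    """Reference, baseline-correct, QC and water-exclude every spectrum.

    Returns (SpectrumSet of passing corrected spectra, QC DataFrame,
    list of failed sample_ids). Baseline anchors avoid the pattern bins,
    the water region and the TSP singlet.
    """
    exclude = [(-0.05, 0.05), tuple(config.water_region)]
    if pattern is not None:
        exclude += [(b.right_ppm, b.left_ppm) for b in pattern.bins]
    corrected, qc_rows, failed, keep_idx = [], [], [], []
    for i, s in enumerate(cohort.spectra):
        # baseline first: the referencing peak-prominence test and the
        # line-width half-height both assume a locally flat baseline
        s2 = correct_baseline(
            s,
            degree=config.baseline_degree,
            n_anchors=config.baseline_anchors,
            anchor_mode="auto",
            exclude=exclude,
        )
        s2 = reference_to_tsp(s2, config.reference_window)
        report = qc_spectrum(s2, threshold_hz=config.linewidth_threshold_hz)
        qc_rows.append(
            {
                "sample_id": report.sample_id or s.meta.get("sample_id", f"sample_{i}"),
                "linewidth_hz": report.linewidth_hz,
                "linewidth_pass": report.linewidth_pass,
                "baseline_rms_signal_free": report.baseline_rms_signal_free,
                "notes": "; ".join(report.notes),
            }
        )
        if config.run_qc and not report.linewidth_pass:
            failed.append(qc_rows[-1]["sample_id"])
            continue
        if config.exclude_water:
            s2 = exclude_region(s2, config.water_region)
        corrected.append(s2)
        keep_idx.append(i)
    if not corrected:
        raise InvariantError("no spectra passed QC")
    passed = SpectrumSet(corrected, cohort.design.iloc[keep_idx].reset_index(drop=True))
    return passed, pd.DataFrame(qc_rows), failed


def _evaluation_labels(table: FeatureTable, config: PipelineConfig):
    """Derive classification labels, honouring eval_filter and group_pools."""
    meta = table.sample_meta
    mask = np.ones(len(meta), dtype=bool)
    if config.eval_filter:
        for col, allowed in config.eval_filter.items():
            if col not in meta.columns:
                raise ConfigError(f"eval_filter column {col!r} not in sample metadata")
            mask &= meta[col].isin(list(allowed)).to_numpy()
    if config.label_key not in meta.columns:
        raise ConfigError(f"label_key {config.label_key!r} not in sample metadata")
    raw_labels = meta[config.label_key].astype(str)
    if config.group_pools:
        pool_of = {}
        for new_label, values in config.group_pools.items():
            for v in values:
                pool_of[str(v)] = str(new_label)
        pooled = raw_labels.map(pool_of)
        mask &= pooled.notna().to_numpy()
        labels = pooled
    else:
        labels = raw_labels
    idx = np.flatnonzero(mask)
    sub = FeatureTable(
        table.values[idx],
        meta.iloc[idx].reset_index(drop=True),
        list(table.bins),
        table.state,
    )
    return sub, [labels.iloc[i] for i in idx]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = config.timestamps

    def stage(name):
        logger.info("stage: %s", name)

    if config.mode == "synthetic":
        stage("simulate")
        cohort = generate_titration_cohort(config.synthetic)
        from .synthetic import default_pattern

        pattern = read_pattern(config.pattern) if config.pattern else default_pattern()
        write_library(config.synthetic.library, out / "library.csv")
    else:
        stage("load")
        cohort = _load_cohort(config)
        pattern = read_pattern(config.pattern)
    write_pattern(pattern, out / "pattern.tsv", timestamps=ts)
    cohort.design.to_csv(out / "design.tsv", sep="\t", index=False)

    stage("preprocess")
    passed, qc_frame, failed = preprocess_cohort(cohort, config, pattern)
    qc_frame.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    if config.write_corrected_spectra:
        from .io import write_tabular_spectrum

        spec_dir = out / "corrected_spectra"
        spec_dir.mkdir(exist_ok=True)
        for s in passed.spectra:
            write_tabular_spectrum(
                s, spec_dir / f"{s.meta.get('sample_id', 'spectrum')}.tsv", timestamps=ts
            )

    stage("bin")
    raw = integrate_bins(passed, pattern)
    write_feature_table(raw, out / "feature_raw.tsv", timestamps=ts)
    norm = ta_normalise(raw)
    write_feature_table(norm, out / "feature_normalised.tsv", timestamps=ts)

    if config.crs:
        stage("crs")
        filtered, crs_result = crs_select(norm, pattern)
        crs_result.to_frame().to_csv(out / "crs_result.tsv", sep="\t", index=False)
        write_feature_table(filtered, out / "feature_crs.tsv", timestamps=ts)
        eval_table = filtered
    else:
        crs_result = None
        eval_table = norm

    stage("pca")
    scaled = pareto_scale(eval_table)
    k = min(5, scaled.n_samples - 1, scaled.n_bins)
    pca = fit_pca(scaled.values, k)
    scores = pd.concat(
        [
            scaled.sample_meta.reset_index(drop=True),
            pd.DataFrame(pca.scores, columns=[f"PC{i + 1}" for i in range(k)]),
        ],
        axis=1,
    )
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    loadings = pd.DataFrame(
        pca.loadings, index=scaled.bin_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings.insert(0, "explained_variance_ratio", np.nan)
    loadings.iloc[: len(pca.explained_variance_ratio), 0] = pca.explained_variance_ratio
    loadings.to_csv(out / "pca_loadings.tsv", sep="\t")

    report_summary = None
    if config.mode == "synthetic" and config.group_pools is None:
        # default titration comparison: low (<=200k) vs standard (400-800k)
        # cell counts at the highest NS acquired
        cells = config.synthetic.cell_counts
        low = [f"c{c}" for c in cells if c <= 200_000]
        standard = [f"c{c}" for c in cells if 200_000 < c <= 800_000]
        if low and standard:
            config = dataclasses.replace(
                config,
                group_pools={"low": low, "standard": standard},
                eval_filter=config.eval_filter
                or {"n_scans": [max(config.synthetic.ns_values)]},
            )
    eval_sub, labels = _evaluation_labels(eval_table, config)
    label_counts = pd.Series(labels).value_counts()
    if len(label_counts) >= 2 and label_counts.min() >= 4:
        stage("evaluate")
        report = replicated_evaluation(
            eval_sub,
            labels,
            n_replicates=config.n_replicates,
            train_fraction=config.train_fraction,
            max_components=config.max_components,
            seed=config.seed,
        )
        report.replicates.to_csv(out / "validation_replicates.tsv", sep="\t", index=False)
        report.aggregate.to_csv(out / "validation_aggregate.tsv", sep="\t")
        report.vip_table().to_csv(out / "vip.tsv", sep="\t", index=False)
        report_summary = {
            "accuracy_mean": float(report.aggregate.loc["accuracy", "mean"]),
            "accuracy_sd": float(report.aggregate.loc["accuracy", "sd"]),
            "ber_by_component": [
                None if np.isnan(v) else float(v) for v in report.ber_by_component
            ],
        }
        stage("univariate")
        uni = univariate_screen(eval_sub, labels, alpha=config.alpha)
        uni.table.to_csv(out / "univariate.tsv", sep="\t", index=False)
        if uni.pairwise is not None:
            uni.pairwise.to_csv(out / "univariate_pairwise.tsv", sep="\t", index=False)
    else:
        logger.warning("skipping evaluation: need >= 2 groups with >= 4 samples each")

    if config.mode == "synthetic":
        stage("detect-limit")
        det = detection_limit_report(passed, pattern)
        det.to_csv(out / "detection_limit.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_spectra": len(cohort),
        "qc_failed_samples": failed,
        "evaluation": report_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
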