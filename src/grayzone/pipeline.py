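"""End-to-end pipeline: cohort -> ROC -> both gray zones -> reports.

A single :class:`PipelineConfig` (CSV input or a synthetic cohort recipe)
drives the full analysis and writes a reproducible bundle of plain-text
outputs to one directory:

    cohort.csv          the analysed cohort (written only when synthetic)
    roc.csv             threshold, Se, Sp, LR+, LR- per observed cutoff
    zones.json          both zones with LR targets and UI diagnostics
    zone_table.csv      per-approach limits, inside counts, outside metrics
    comparison.csv      metric-by-metric approach comparison
    histogram_grey_zone.csv, histogram_uncertain_interval.csv
    descriptives.csv    per-class quartiles and Mann-Whitney test
    manifest.json       package/library versions, seed, config hash
    run.log             timestamped step log

Every number in the bundle is regenerable from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import MarkerDataset
from .greyzone import (
    DEFAULT_NPV_TARGET,
    DEFAULT_PPV_TARGET,
    GrayZone,
    grey_zone_bounds,
    lr_targets,
    pretest_from_counts,
)
from .performance import (
    ZoneReport,
    bootstrap_compare,
    compare_zone_metrics,
    descriptive_summary,
    reports_to_table,
    trichotomize,
    zone_report,
)
from .roc import empirical_roc
from .simulate import CohortConfig, generate_cohort
from .uncertain import DEFAULT_UI_TARGET, UiSpec, uncertain_interval_bounds

logger = logging.getLogger("grayzone")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """One fully-specified run: input source, targets, output directory."""

    outdir: Path
    input_csv: Path | None = None
    cohort: CohortConfig | None = None
    marker_name: str | None = None  # marker to select from a multi-marker CSV
    ppv_target: float = DEFAULT_PPV_TARGET
    npv_target: float = DEFAULT_NPV_TARGET
    pretest_prob: float | None = None  # None -> sample prevalence
    ui_se_target: float = DEFAULT_UI_TARGET
    ui_sp_target: float = DEFAULT_UI_TARGET
    bins: int = 50
    log_bins: bool = True  # log-spaced histogram bins for skewed markers
    bootstrap_reps: int = 0  # 0 disables the paired bootstrap comparison
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.cohort is None):
            raise ValueError("exactly one of input_csv or cohort must be set")
        if self.cohort is None and self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("bootstrap comparison needs a seed")
        object.__setattr__(self, "outdir", Path(self.outdir))
        if self.input_csv is not None:
            object.__setattr__(self, "input_csv", Path(self.input_csv))

    def to_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "input_csv": None if self.input_csv is None else str(self.input_csv),
            "cohort": None if self.cohort is None else self.cohort.to_dict(),
            "marker_name": self.marker_name,
            "ppv_target": self.ppv_target,
            "npv_target": self.npv_target,
            "pretest_prob": self.pretest_prob,
            "ui_se_target": self.ui_se_target,
            "ui_sp_target": self.ui_sp_target,
            "bins": self.bins,
            "log_bins": self.log_bins,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            cohort = CohortConfig.from_dict(cohort)
        input_csv = raw.pop("input_csv", None)
        return cls(
            outdir=Path(raw.pop("outdir", "grayzone_out")),
            input_csv=None if input_csv is None else Path(input_csv),
            cohort=cohort,
            **raw,
        )


@dataclasses.dataclass(frozen=True)
class HistogramData:
    """Per-class binned counts with the zone limits as annotations."""

    edges: np.ndarray
    counts_neg: np.ndarray
    counts_pos: np.ndarray
    zone: GrayZone
    n_gray: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1],
            "bin_right": self.edges[1:],
            "count_normal": self.counts_neg,
            "count_no_reflow": self.counts_pos,
            "zone_lower": self.zone.lower,
            "zone_upper": self.zone.upper,
            "zone_method": self.zone.method,
        })


def histogram_with_zones(
    dataset: MarkerDataset,
    zone: GrayZone,
    bins: int = 50,
    log_bins: bool = False,
) -> HistogramData:
    """Shared-edge per-class histogram spanning [min, max], zone-annotated."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = float(dataset.values.min()), float(dataset.values.max())
    if log_bins and lo > 0 and hi > lo:
        edges = np.geomspace(lo, hi, bins + 1)
    elif hi > lo:
        edges = np.linspace(lo, hi, bins + 1)
    else:  # all values identical
        edges = np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    counts_neg, _ = np.histogram(dataset.neg_values, bins=edges)
    counts_pos, _ = np.histogram(dataset.pos_values, bins=edges)
    n_gray = int(np.sum(trichotomize(dataset, zone) == "gray"))
    return HistogramData(edges=edges, counts_neg=counts_neg,
                         counts_pos=counts_pos, zone=zone, n_gray=n_gray)


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    """In-memory handles on the bundle a pipeline run produced."""

    outdir: Path
    dataset: MarkerDataset
    grey_zone: GrayZone
    uncertain_zone: GrayZone
    report_grey: ZoneReport
    report_uncertain: ZoneReport
    comparisons: pd.DataFrame
    manifest: dict


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("grayzone", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            out[pkg] = metadata.version(pkg)
        except metadata.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the output bundle."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        if config.cohort is not None:
            logger.info("generating synthetic cohort (seed=%s)", config.cohort.seed)
            dataset = generate_cohort(config.cohort)
            dataset.write_csv(outdir / "cohort.csv")
        else:
            logger.info("reading cohort from %s", config.input_csv)
            dataset = MarkerDataset.read_csv(config.input_csv, config.marker_name)
        dataset.require_both_classes()

        desc = descriptive_summary(dataset)
        pd.DataFrame([dataclasses.asdict(desc)]).to_csv(
            outdir / "descriptives.csv", index=False)

        roc = empirical_roc(dataset)
        roc.to_csv(outdir / "roc.csv")
        logger.info("empirical AUC = %.4f", roc.auc)

        if config.pretest_prob is None:
            bayes = pretest_from_counts(dataset.n_pos, dataset.n_neg,
                                        config.ppv_target, config.npv_target)
        else:
            bayes = dataclasses.replace(
                pretest_from_counts(dataset.n_pos, dataset.n_neg,
                                    config.ppv_target, config.npv_target),
                pretest_prob=config.pretest_prob)
        targets = lr_targets(bayes)
        gz = grey_zone_bounds(roc, targets)
        logger.info("grey zone: [%.4f, %.4f) (LR+>=%.3f, LR-<=%.3f)",
                    gz.lower, gz.upper,
                    targets.lr_pos_target, targets.lr_neg_target)

        ui_spec = UiSpec(config.ui_se_target, config.ui_sp_target)
        uz, ui_diag = uncertain_interval_bounds(dataset, ui_spec)
        logger.info("uncertain interval: [%.4f, %.4f) (intersection %.4f)",
                    uz.lower, uz.upper, ui_diag.intersection)

        report_g = zone_report(dataset, gz)
        report_u = zone_report(dataset, uz)
        table = reports_to_table(
            {"uncertain_interval": report_u, "grey_zone": gz and report_g})
        table.to_csv(outdir / "zone_table.csv", index=False)

        comparisons = []
        for metric in ("accuracy", "sensitivity", "specificity"):
            try:
                comparisons.append(dataclasses.asdict(
                    compare_zone_metrics(report_u, report_g, metric)))
            except ValueError:
                logger.warning("metric %s undefined; comparison skipped", metric)
            if config.bootstrap_reps > 0:
                try:
                    comparisons.append(dataclasses.asdict(bootstrap_compare(
                        dataset, uz, gz, metric,
                        n_boot=config.bootstrap_reps,
                        seed=config.seed or 0)))
                except ValueError:
                    logger.warning("bootstrap for %s skipped", metric)
        cmp_frame = pd.DataFrame(
            comparisons,
            columns=["metric", "estimate_a", "estimate_b", "p_value", "method"])
        cmp_frame.to_csv(outdir / "comparison.csv", index=False)

        for zone in (gz, uz):
            hist = histogram_with_zones(dataset, zone, config.bins,
                                        log_bins=config.log_bins)
            hist.to_frame().to_csv(outdir / f"histogram_{zone.method}.csv",
                                   index=False)

        zones_payload = {
            "grey_zone": {**gz.to_dict(),
                          "lr_pos_target": targets.lr_pos_target,
                          "lr_neg_target": targets.lr_neg_target,
                          "pretest_prob": bayes.pretest_prob},
            "uncertain_interval": {**uz.to_dict(),
                                   **dataclasses.asdict(ui_diag)},
            "auc": roc.auc,
        }
        (outdir / "zones.json").write_text(json.dumps(zones_payload, indent=2))

        cfg_dict = config.to_dict()
        manifest = {
            "versions": _versions(),
            "seed": config.seed if config.seed is not None else (
                config.cohort.seed if config.cohort else None),
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "n": dataset.n,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("bundle written to %s", outdir)
        return PipelineResult(
            outdir=outdir, dataset=dataset,
            grey_zone=gz, uncertain_zone=uz,
            report_grey=report_g, report_uncertain=report_u,
            comparisons=cmp_frame, manifest=manifest,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
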