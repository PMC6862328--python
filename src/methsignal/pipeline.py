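"""End-to-end orchestration: counts -> divergence -> fits -> DMPs -> classifier.

`run_pipeline` executes the full flow on in-memory samples (or a file
manifest) and writes stage artifacts; `predict_external` pushes an
independent dataset through a trained pipeline with the training run's
decision thresholds frozen.  Per-sample distribution fits (and hence
critical values and tail probabilities) *are* recomputed for external
individuals — the background model is an individual property — while the
group-level decisions (TV cutoff, optimal divergence cutoff, trained
classifier) are carried over unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import dist_fit, divergence, signal_detect
from .dist_fit import CriticalValue, FAMILIES
from .meth_io import MethSample, pool_reference, read_cov

__all__ = ["PipelineConfig", "PipelineResult", "ExternalPrediction", "run_pipeline", "predict_external"]


class PipelineValidationError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Settings for one signal-detection run.

    ``samples`` are the control and treatment individuals;
    ``reference_samples`` the independent control-process individuals
    pooled into the virtual reference.  They must be disjoint: measuring
    divergence of a control individual against a reference containing its
    own counts would bias the background distribution.
    """

    samples: list[MethSample] = field(default_factory=list)
    reference_samples: list[MethSample] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    prior_mode: str = "uniform"
    min_coverage: int = 10
    alpha: float = 0.05
    tv_quantile: float = 0.95
    tv_group: str = "control"  # or "pooled"
    cutoff_method: str = "youden"  # youden | classifier_posterior | gamma_mixture
    pooling_statistic: str = "sum"
    families: Sequence[str] = FAMILIES
    classifier_spec: clf.ClassifierSpec = field(default_factory=clf.ClassifierSpec)
    cv_resamples: int = 999
    train_fraction: float = 0.6
    tailp_per_site: bool = True
    seed: int = 1
    output_dir: Path | None = None

    def validate(self) -> None:
        if not self.samples:
            raise PipelineValidationError("sample manifest is empty")
        if not self.reference_samples:
            raise PipelineValidationError("no reference samples")
        ids = {s.sample_id for s in self.samples}
        ref_ids = {s.sample_id for s in self.reference_samples}
        overlap = ids & ref_ids
        if overlap:
            raise PipelineValidationError(
                f"reference members must be disjoint from the analyzed samples: {sorted(overlap)}"
            )
        groups = {s.group for s in self.samples}
        if not groups <= {"control", "treatment"}:
            raise PipelineValidationError(f"sample groups must be control/treatment, got {groups}")
        if self.tv_group not in ("control", "pooled"):
            raise PipelineValidationError("tv_group must be 'control' or 'pooled'")
        if self.cutoff_method not in ("youden", "classifier_posterior", "gamma_mixture"):
            raise PipelineValidationError(f"unknown cutoff method {self.cutoff_method!r}")


@dataclass
class PipelineResult:
    """All stage artifacts of one training run."""

    config: PipelineConfig
    reference: MethSample
    tracks: dict[str, pd.DataFrame]
    groups: dict[str, str]
    critical_values: dict[str, CriticalValue]
    tv_cut: float
    pdmps: pd.DataFrame
    cutpoint: signal_detect.CutpointResult
    dmps: signal_detect.DMPSet
    features: pd.DataFrame
    model: clf.TrainedClassifier
    report: clf.PerformanceReport


@dataclass
class ExternalPrediction:
    """Frozen-threshold evaluation of a trained pipeline on external data."""

    tracks: dict[str, pd.DataFrame]
    critical_values: dict[str, CriticalValue]
    pdmps: pd.DataFrame
    dmps: signal_detect.DMPSet
    features: pd.DataFrame
    predicted: np.ndarray
    posterior: np.ndarray
    report: dict[str, float] | None
    n_track_sites: int
    empty: bool = False


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _fit_sample_models(
    tracks: Mapping[str, pd.DataFrame],
    families: Sequence[str],
    alpha: float,
) -> dict[str, CriticalValue]:
    out: dict[str, CriticalValue] = {}
    for sample_id, track in tracks.items():
        hdiv = track["hdiv"].to_numpy()
        ecdf = dist_fit.subsample_ecdf(dist_fit.empirical_cdf(hdiv[hdiv > 0]))
        model = dist_fit.select_best_model(ecdf, families)
        out[sample_id] = CriticalValue(
            sample_id=sample_id,
            alpha=alpha,
            h_crit=dist_fit.critical_value(model, alpha),
            model=model,
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run divergence, fitting, detection and classification stages."""
    config.validate()
    seeds = _derive_seeds(config.seed, 3)

    reference = pool_reference(config.reference_samples, statistic=config.pooling_statistic)
    tracks = {
        s.sample_id: divergence.divergence_track(
            s, reference, prior_mode=config.prior_mode, min_coverage=config.min_coverage
        )
        for s in config.samples
    }
    groups = {s.sample_id: s.group for s in config.samples}

    critical_values = _fit_sample_models(tracks, config.families, config.alpha)

    if config.tv_group == "control":
        tv_tracks = [tracks[sid] for sid, g in groups.items() if g == "control"]
        if not tv_tracks:
            tv_tracks = list(tracks.values())
    else:
        tv_tracks = list(tracks.values())
    tv_cut = signal_detect.tv_quantile_cutoff(tv_tracks, q=config.tv_quantile)

    pdmps = signal_detect.select_potential_dmps(
        tracks, groups, critical_values, tv_cut, tailp_per_site=config.tailp_per_site
    )
    if len(pdmps) == 0:
        raise RuntimeError("no potential DMPs passed the critical-value and TV filters")

    if config.cutoff_method == "youden":
        cutpoint = signal_detect.youden_cutpoint(pdmps)
    elif config.cutoff_method == "classifier_posterior":
        cutpoint = signal_detect.classifier_posterior_cutpoint(
            pdmps, config.chrom_lengths, spec=config.classifier_spec, seed=seeds[0]
        )
    else:
        cutpoint = signal_detect.gamma_mixture_cutpoint(
            pdmps["hdiv"].to_numpy(), seed=seeds[0]
        )

    dmps = signal_detect.call_dmps(pdmps, cutpoint)
    if len(dmps) == 0:
        raise RuntimeError("optimal cutoff left no DMPs")
    features = clf.build_feature_frame(dmps.members, config.chrom_lengths)
    model = clf.train_classifier(features, config.classifier_spec, seed=seeds[1])
    report = clf.monte_carlo_cv(
        features,
        config.classifier_spec,
        n_resamples=config.cv_resamples,
        train_fraction=config.train_fraction,
        seed=seeds[2],
    )
    result = PipelineResult(
        config=config,
        reference=reference,
        tracks=tracks,
        groups=groups,
        critical_values=critical_values,
        tv_cut=tv_cut,
        pdmps=pdmps,
        cutpoint=cutpoint,
        dmps=dmps,
        features=features,
        model=model,
        report=report,
    )
    if config.output_dir is not None:
        write_artifacts(result, Path(config.output_dir))
    return result


def predict_external(
    result: PipelineResult,
    external_samples: Sequence[MethSample],
    reference_samples: Sequence[MethSample] | None = None,
    evaluate: bool = True,
) -> ExternalPrediction:
    """Apply a trained pipeline to external individuals.

    The TV cutoff, the optimal divergence cutoff and the classifier are
    frozen from training; per-sample background models are re-fitted for
    the external individuals.  With ``evaluate=True`` the external group
    labels are scored against the predictions.
    """
    config = result.config
    if reference_samples is not None:
        reference = pool_reference(list(reference_samples), statistic=config.pooling_statistic)
    else:
        reference = result.reference
    tracks = {
        s.sample_id: divergence.divergence_track(
            s, reference, prior_mode=config.prior_mode, min_coverage=config.min_coverage
        )
        for s in external_samples
    }
    groups = {s.sample_id: s.group for s in external_samples}
    critical_values = _fit_sample_models(tracks, config.families, config.alpha)
    pdmps = signal_detect.select_potential_dmps(
        tracks, groups, critical_values, result.tv_cut, tailp_per_site=config.tailp_per_site
    )
    dmps = signal_detect.call_dmps(pdmps, result.cutpoint)
    n_track_sites = int(sum(len(t) for t in tracks.values()))
    if len(dmps) == 0:
        return ExternalPrediction(
            tracks=tracks,
            critical_values=critical_values,
            pdmps=pdmps,
            dmps=dmps,
            features=pdmps,
            predicted=np.array([], dtype=object),
            posterior=np.array([]),
            report=None,
            n_track_sites=n_track_sites,
            empty=True,
        )
    features = clf.build_feature_frame(dmps.members, config.chrom_lengths)
    predicted, posterior = clf.predict(result.model, features)
    report = clf.confusion_metrics(features["label"].to_numpy(), predicted) if evaluate else None
    return ExternalPrediction(
        tracks=tracks,
        critical_values=critical_values,
        pdmps=pdmps,
        dmps=dmps,
        features=features,
        predicted=predicted,
        posterior=posterior,
        report=report,
        n_track_sites=n_track_sites,
    )


def load_manifest(manifest_path: str | Path) -> tuple[list[MethSample], list[MethSample]]:
    """Read a sample manifest TSV (path, sample_id, group) into samples.

    Group ``reference`` rows become the reference-builder list.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", names=["path", "sample_id", "group"],
                           comment="#", header=None)
    base = Path(manifest_path).parent
    samples, reference = [], []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        s = read_cov(p, sample_id=row.sample_id, group=row.group)
        (reference if row.group == "reference" else samples).append(s)
    return samples, reference


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    """Write stage outputs (tracks, fit report, cutpoint, DMPs, CV report)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    tracks_dir = out_dir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for sid, track in result.tracks.items():
        divergence.write_track(track, tracks_dir / f"{sid}.divergence.tsv")
    manifest["stages"]["divergence"] = sorted(result.tracks)
    dist_fit.write_model_report(result.critical_values, out_dir / "fitted_models.txt")
    manifest["stages"]["fit"] = "fitted_models.txt"
    with open(out_dir / "cutpoint.txt", "w") as fh:
        fh.write(f"method = {result.cutpoint.method}\n")
        fh.write(f"h_cutoff = {result.cutpoint.h_cutoff:.10g}\n")
        fh.write(f"tv_cut = {result.tv_cut:.10g}\n")
        for k, v in result.cutpoint.diagnostics.items():
            if isinstance(v, (int, float, str, bool, list)):
                fh.write(f"{k} = {v}\n")
    manifest["stages"]["detect"] = "cutpoint.txt"
    result.pdmps.to_csv(out_dir / "pdmps.tsv", sep="\t", index=False, float_format="%.10g")
    signal_detect.write_dmps_bed(result.dmps, out_dir / "dmps.bed")
    manifest["stages"]["dmps"] = ["pdmps.tsv", "dmps.bed"]
    clf.save_classifier(result.model, out_dir / "classifier.json")
    result.report.to_frame().to_csv(out_dir / "cv_report.tsv", sep="\t", float_format="%.6f")
    with open(out_dir / "cv_report.txt", "w") as fh:
        fh.write(str(result.report) + "\n")
    manifest["stages"]["classify"] = ["classifier.json", "cv_report.tsv"]
    manifest["seed"] = result.config.seed
    manifest["tv_cut"] = result.tv_cut
    manifest["h_cutoff"] = result.cutpoint.h_cutoff
    manifest["n_dmps"] = len(result.dmps)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
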