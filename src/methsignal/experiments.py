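"""Canonical simulation-study protocols.

These functions reproduce the package's benchmark experiments: train the
full signal-detection + classification pipeline on simulated
control/treatment datasets at a given genome-wide mean absolute
methylation-level difference, cross-validate it, validate it on external
individuals drawn from the same populations, and measure the false
positive rate on control-only external data.

All experiments use the classifier-posterior optimal cutoff and a PCA+QDA
model (the configuration that keeps both DMP classes in the final set),
999-resample 60/40 Monte Carlo cross-validation, and the simulator
defaults (30x negative-binomial coverage, beta(0.09, 0.5) background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierSpec
from .pipeline import PipelineConfig, PipelineResult, predict_external, run_pipeline
from .signal_detect import tv_quantile_cutoff
from .simulator import SimConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "TrainedExperiment",
    "train_scenario",
    "external_validation",
    "control_fpr",
    "pooled_tv95",
]


@dataclass
class TrainedExperiment:
    dataset: SimulatedDataset
    result: PipelineResult


def _seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) % (2**31 - 1)]


def train_scenario(
    target_mean_tv: float,
    n_sites: int = 100_000,
    n_samples: int = 3,
    n_reference: int = 4,
    cv_resamples: int = 999,
    seed: int = 1,
) -> TrainedExperiment:
    """Simulate a scenario and run the full pipeline with Monte Carlo CV."""
    sim_seed, pop_seed, pipe_seed = _seeds(seed, 3)
    dataset = simulate_dataset(
        SimConfig(
            n_sites=n_sites,
            n_control=n_samples,
            n_treatment=n_samples,
            n_reference=n_reference,
            target_mean_tv=target_mean_tv,
            seed=sim_seed,
            population_seed=pop_seed,
        )
    )
    config = PipelineConfig(
        samples=dataset.control + dataset.treatment,
        reference_samples=dataset.reference,
        chrom_lengths=dataset.chrom_lengths,
        cutoff_method="classifier_posterior",
        classifier_spec=ClassifierSpec(family="pca_qda"),
        cv_resamples=cv_resamples,
        seed=pipe_seed,
    )
    return TrainedExperiment(dataset=dataset, result=run_pipeline(config))


def external_validation(
    experiment: TrainedExperiment,
    n_samples: int = 10,
    n_sites: int | None = None,
    seed: int = 2,
) -> dict[str, float]:
    """Score the trained pipeline on an independent same-population dataset."""
    cfg = experiment.dataset.config
    ext = simulate_dataset(
        SimConfig(
            n_sites=n_sites or cfg.n_sites,
            n_control=n_samples,
            n_treatment=n_samples,
            n_reference=0,
            treatment_beta=cfg.treatment_beta,
            seed=_seeds(seed, 1)[0],
            population_seed=cfg.population_seed,
        )
    )
    pred = predict_external(experiment.result, ext.control + ext.treatment)
    if pred.report is None:
        raise RuntimeError("external evaluation was empty")
    return pred.report


def control_fpr(
    experiment: TrainedExperiment,
    n_seeds: int = 10,
    n_samples: int = 3,
    n_sites: int | None = None,
    seed: int = 3,
) -> float:
    """Fraction of external control-process sites called DMPs and labelled
    treatment, averaged over independently drawn external cohorts."""
    cfg = experiment.dataset.config
    rates = []
    for s in _seeds(seed, n_seeds):
        ext = simulate_dataset(
            SimConfig(
                n_sites=n_sites or cfg.n_sites,
                n_control=n_samples,
                n_treatment=0,
                n_reference=0,
                treatment_beta=cfg.treatment_beta,
                seed=s,
                population_seed=cfg.population_seed,
            )
        )
        pred = predict_external(experiment.result, ext.control, evaluate=False)
        false_tt = 0 if pred.empty else int((pred.predicted == "TT").sum())
        rates.append(false_tt / pred.n_track_sites)
    return float(np.mean(rates))


def pooled_tv95(
    target_mean_tv: float = 0.0356,
    n_sites: int = 100_000,
    n_samples: int = 3,
    n_seeds: int = 5,
    seed: int = 4,
) -> float:
    """95% quantile of |TV| pooled over all sample-vs-reference tracks,
    averaged over seeds."""
    from .divergence import divergence_track
    from .meth_io import pool_reference

    values = []
    for s in _seeds(seed, n_seeds):
        ds = simulate_dataset(
            SimConfig(
                n_sites=n_sites,
                n_control=n_samples,
                n_treatment=n_samples,
                target_mean_tv=target_mean_tv,
                seed=s,
            )
        )
        ref = pool_reference(ds.reference)
        tracks = [divergence_track(smp, ref) for smp in ds.control + ds.treatment]
        values.append(tv_quantile_cutoff(tracks, q=0.95))
    return float(np.mean(values))
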