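"""Simulated control/treatment/reference methylome count datasets.

The generator emulates whole-genome bisulfite count data at single-cytosine
resolution:

* per-site read coverage from a negative-binomial distribution, floored at
  a minimum (default 10) by rejection resampling;
* a latent *population* methylation level per site, drawn from a beta
  distribution and shared by every individual of a group (between-sample
  variation enters through coverage and binomial count noise);
* observed counts through a Bayes chain: binomial pseudo-counts at the
  latent level, conjugate beta posterior mean, and methylated reads =
  round(coverage x posterior level).

The treatment methylome is a *quantile-preserved perturbation* of the
control methylome: at each site the treatment latent level is the same
quantile of a mean-shifted beta distribution (concentration held fixed).
Under this coupling the genome-wide mean absolute methylation-level
difference E|p_t - p_c| equals the shift of the beta mean, so the
effect-size scenarios are calibrated exactly; reference individuals are
drawn from the control population (sharing its latent levels) and pooled
into the virtual reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meth_io import COLUMNS, MethSample

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_coverage",
    "simulate_site_levels",
    "simulate_counts",
    "calibrate_treatment_beta",
    "simulate_dataset",
]

# Paper-scenario effect sizes: genome-wide mean |methylation level difference|
SCENARIO_MEAN_TV = {"mild": 0.0356, "medium": 0.1332, "large": 0.1845}


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for one simulated dataset.

    Defaults describe a 30x bisulfite experiment over a mostly
    unmethylated, strongly bimodal background (beta(0.09, 0.5) levels)
    with three individuals per group and four reference-builders.
    """

    n_sites: int = 50_000
    n_control: int = 3
    n_treatment: int = 3
    n_reference: int = 4
    coverage_mean: float = 30.0
    coverage_dispersion: float = 4.5
    min_coverage: int = 10
    control_beta: tuple[float, float] = (0.09, 0.5)
    treatment_beta: tuple[float, float] | None = None
    target_mean_tv: float | None = None
    chrom: str = "chr1"
    chrom_length: int | None = None  # default: n_sites * site_spacing
    site_spacing: int = 100
    seed: int = 1
    # The latent site-level profile defines the *population*; give two
    # datasets the same population_seed (with different seeds) to draw
    # independent individuals from the same populations, e.g. for external
    # validation.  None derives the profile from `seed`.
    population_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if any(v <= 0 for v in self.control_beta):
            raise ValueError("beta parameters must be positive")
        if self.treatment_beta is not None and any(v <= 0 for v in self.treatment_beta):
            raise ValueError("beta parameters must be positive")
        if self.target_mean_tv is not None and not 0 <= self.target_mean_tv < 1:
            raise ValueError("target_mean_tv must be in [0, 1)")

    @property
    def effective_chrom_length(self) -> int:
        return self.chrom_length or self.n_sites * self.site_spacing


@dataclass
class SimulatedDataset:
    """Simulated samples plus the latent truth used to generate them."""

    config: SimConfig
    control: list[MethSample]
    treatment: list[MethSample]
    reference: list[MethSample]
    truth: pd.DataFrame  # chrom, pos, p_control, p_treatment
    realized_mean_tv: float

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {self.config.chrom: self.config.effective_chrom_length}


def simulate_coverage(
    n: int,
    mean: float,
    dispersion: float,
    min_coverage: int = 10,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Negative-binomial coverages floored at ``min_coverage`` by rejection.

    The NB is parameterized by mean mu and dispersion theta
    (variance = mu + mu^2/theta).  Values below the floor are redrawn,
    preserving the conditional distribution above it.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=n)
    while True:
        bad = cov < min_coverage
        if not bad.any():
            break
        cov[bad] = rng.negative_binomial(dispersion, p, size=int(bad.sum()))
    return cov.astype(np.int64)


def simulate_site_levels(
    n_sites: int,
    beta_params: tuple[float, float],
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Latent per-site methylation levels drawn from a beta distribution."""
    a, b = beta_params
    if a <= 0 or b <= 0:
        raise ValueError("beta parameters must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.beta(a, b, size=n_sites)


def simulate_counts(
    latent_levels: np.ndarray,
    coverage: np.ndarray,
    prior: tuple[float, float],
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts via binomial pseudo-counts and the conjugate posterior mean.

    k ~ Binomial(coverage, p0); p* = (a + k)/(a + b + coverage);
    n_mc = round(coverage * p*), n_uc = coverage - n_mc.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b = prior
    coverage = np.asarray(coverage)
    k = rng.binomial(coverage, latent_levels)
    post = (a + k) / (a + b + coverage)
    n_mc = np.floor(coverage * post + 0.5).astype(np.int64)
    return n_mc, (coverage - n_mc).astype(np.int64)


def _shifted_beta(control_beta: tuple[float, float], shift: float) -> tuple[float, float]:
    a, b = control_beta
    conc = a + b
    m = a / conc + shift
    if not 0 < m < 1:
        raise ValueError("mean shift leaves the unit interval")
    return (m * conc, (1.0 - m) * conc)


def calibrate_treatment_beta(
    control_beta: tuple[float, float],
    target_mean_tv: float,
    n_draws: int = 100_000,
    tol: float = 0.02,
    seed: int = 0,
) -> tuple[float, float]:
    """Treatment beta whose quantile-coupled draws differ from the control
    draws by ``target_mean_tv`` on average.

    Searches the one-parameter family of beta-mean shifts at fixed
    concentration for E|p_t - p_c| = target, where (p_c, p_t) are
    quantile-coupled (comonotone) pairs; the realized mean is verified by
    Monte Carlo within ``tol`` relative error.  The family minimum is 0
    (no shift); targets >= 1 - control mean are unreachable and raise.
    """
    a, b = control_beta
    m0 = a / (a + b)
    if not 0 <= target_mean_tv < 1 - m0:
        raise ValueError(
            f"target {target_mean_tv} unreachable: the mean-shift family covers "
            f"[0, {1 - m0:.4f}) for control beta {control_beta}"
        )
    if target_mean_tv == 0:
        return control_beta
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_draws)
    p_c = stats.beta.ppf(u, a, b)

    def realized(shift: float) -> float:
        a_t, b_t = _shifted_beta(control_beta, shift)
        p_t = stats.beta.ppf(u, a_t, b_t)
        return float(np.mean(np.abs(p_t - p_c)))

    # comonotone mean-shift: E|p_t - p_c| = shift, so the search is a
    # one-step verification with a bracketing fallback
    shift = target_mean_tv
    value = realized(shift)
    if abs(value - target_mean_tv) > tol * target_mean_tv:
        hi = min((1 - m0) * 0.999, 2 * target_mean_tv)
        shift = float(
            optimize.brentq(
                lambda s: realized(s) - target_mean_tv, 1e-9, hi, xtol=1e-10
            )
        )
        value = realized(shift)
        if abs(value - target_mean_tv) > tol * target_mean_tv:
            raise RuntimeError(
                f"calibration failed: realized {value:.5f} vs target {target_mean_tv}"
            )
    return _shifted_beta(control_beta, shift)


def _sample_frame(chrom: str, pos: np.ndarray, n_mc: np.ndarray, n_uc: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": [chrom] * len(pos), "pos": pos, "n_mc": n_mc, "n_uc": n_uc}
    )[COLUMNS]


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate control, treatment and reference samples under one config.

    Reference individuals are drawn from the control generating process
    (same latent site levels, independent coverages and counts).  If
    ``out_dir`` is given, COV files, a latent truth table and a config echo
    are written there.  Fully reproducible from the config (and its seed).
    """
    if config.treatment_beta is not None:
        treatment_beta = config.treatment_beta
    elif config.target_mean_tv is not None:
        treatment_beta = calibrate_treatment_beta(
            config.control_beta, config.target_mean_tv, seed=config.seed
        )
    else:
        treatment_beta = config.control_beta

    ss = np.random.SeedSequence(config.seed)
    s_levels, s_counts = ss.spawn(2)
    if config.population_seed is not None:
        rng_levels = np.random.default_rng(config.population_seed)
    else:
        rng_levels = np.random.default_rng(s_levels)
    rng_counts = np.random.default_rng(s_counts)

    pos = (np.arange(config.n_sites, dtype=np.int64) * config.site_spacing) + 1
    p_control = simulate_site_levels(config.n_sites, config.control_beta, rng_levels)
    # quantile-preserved perturbation of the same methylome
    a, b = config.control_beta
    if treatment_beta == config.control_beta:
        p_treatment = p_control.copy()
    else:
        u = stats.beta.cdf(p_control, a, b)
        p_treatment = stats.beta.ppf(u, *treatment_beta)
    realized_mean_tv = float(np.mean(np.abs(p_treatment - p_control)))

    def draw_group(n_samples, latent, prior, prefix, group):
        samples = []
        for i in range(n_samples):
            cov = simulate_coverage(
                config.n_sites,
                config.coverage_mean,
                config.coverage_dispersion,
                config.min_coverage,
                rng_counts,
            )
            n_mc, n_uc = simulate_counts(latent, cov, prior, rng_counts)
            samples.append(
                MethSample(
                    sample_id=f"{prefix}{i + 1}",
                    group=group,
                    data=_sample_frame(config.chrom, pos, n_mc, n_uc),
                )
            )
        return samples

    reference = draw_group(config.n_reference, p_control, config.control_beta, "R", "reference")
    control = draw_group(config.n_control, p_control, config.control_beta, "C", "control")
    treatment = draw_group(config.n_treatment, p_treatment, treatment_beta, "T", "treatment")

    truth = pd.DataFrame(
        {
            "chrom": [config.chrom] * config.n_sites,
            "pos": pos,
            "p_control": p_control,
            "p_treatment": p_treatment,
        }
    )
    dataset = SimulatedDataset(
        config=replace(config, treatment_beta=treatment_beta),
        control=control,
        treatment=treatment,
        reference=reference,
        truth=truth,
        realized_mean_tv=realized_mean_tv,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: SimulatedDataset, out_dir: Path) -> None:
    from .meth_io import write_cov

    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in dataset.control + dataset.treatment + dataset.reference:
        write_cov(sample, out_dir / f"{sample.sample_id}.cov")
    dataset.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    cfg = dataset.config
    with open(out_dir / "config.yaml", "w") as fh:
        for key in (
            "n_sites", "n_control", "n_treatment", "n_reference", "coverage_mean",
            "coverage_dispersion", "min_coverage", "control_beta", "treatment_beta",
            "target_mean_tv", "chrom", "site_spacing", "seed", "population_seed",
        ):
            fh.write(f"{key}: {getattr(cfg, key)}\n")
        fh.write(f"realized_mean_tv: {dataset.realized_mean_tv:.6f}\n")
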