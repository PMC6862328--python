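"""Methylation-level estimation and per-site information divergences.

Methylation levels are posterior means under a beta prior.  With a uniform
prior the level at a site with counts (n_mc, n_uc) is
``(n_mc + 1) / (n_mc + n_uc + 2)``; alternatively a beta prior fitted to the
sample's own crude level distribution can be used (its shape parameters act
as pseudo-counts).

Two divergences of a sample against the reference individual are computed
at every shared site:

* the (signed) total-variation distance on the two-point space (p, 1-p),
  ``tv = p_sample - p_ref`` with ``tv_abs = |tv|``; and
* the coverage-weighted Hellinger divergence

  .. math::

     H = w \\left[(\\sqrt{p_c} - \\sqrt{p_t})^2
              + (\\sqrt{1-p_c} - \\sqrt{1-p_t})^2\\right],
     \\qquad w = \\frac{2 m_c m_t}{m_c + m_t},

  with ``m = coverage + 1`` for each party.  Under the no-difference null,
  H is asymptotically chi-square with one degree of freedom, the basis of
  the Hellinger chi-square test (HCT).

The two divergences satisfy ``tv_abs <= 2*sqrt(H/w)`` (total variation is
bounded by twice the unweighted Hellinger distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meth_io import MethSample

__all__ = [
    "BetaPrior",
    "uniform_prior_level",
    "fit_beta_prior",
    "posterior_level",
    "tv_distance",
    "hellinger_divergence",
    "hct_pvalue",
    "divergence_track",
    "write_track",
    "read_track",
]

TRACK_COLUMNS = [
    "chrom",
    "pos",
    "cov_ref",
    "cov_sample",
    "p_ref",
    "p_sample",
    "tv",
    "tv_abs",
    "hdiv",
    "weight",
    "hct_pvalue",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior for methylation levels; shapes act as pseudo-counts."""

    a_shape: float
    b_shape: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_shape > 0 and self.b_shape > 0):
            raise ValueError("beta prior shapes must be positive")


UNIFORM_PRIOR = BetaPrior(1.0, 1.0)


def uniform_prior_level(n_mc, n_uc):
    """Posterior-mean methylation level under a uniform prior.

    Defined for zero coverage (returns the prior mean 1/2) and always
    strictly inside (0, 1).
    """
    n_mc = np.asarray(n_mc, dtype=float)
    n_uc = np.asarray(n_uc, dtype=float)
    return (n_mc + 1.0) / (n_mc + n_uc + 2.0)


def posterior_level(n_mc, n_uc, prior: BetaPrior):
    """Posterior-mean methylation level under an arbitrary beta prior."""
    n_mc = np.asarray(n_mc, dtype=float)
    n_uc = np.asarray(n_uc, dtype=float)
    return (prior.a_shape + n_mc) / (prior.a_shape + prior.b_shape + n_mc + n_uc)


def fit_beta_prior(levels, min_n: int = 50) -> BetaPrior:
    """Fit beta shape parameters by least squares on the ECDF.

    Minimizes the sum of squared differences between the beta CDF and the
    empirical CDF evaluated at the sorted levels, starting from
    method-of-moments estimates.
    """
    x = np.sort(np.asarray(levels, dtype=float))
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} levels to fit a beta prior, got {x.size}")
    if np.var(x) == 0:
        raise ValueError("degenerate level distribution (zero variance)")
    if x.min() <= 0 or x.max() >= 1:
        raise ValueError("levels must lie strictly inside (0, 1)")
    m, v = x.mean(), x.var()
    # method-of-moments start; guard against v >= m(1-m)
    common = max(m * (1 - m) / v - 1.0, 1e-3)
    theta0 = np.log([max(m * common, 1e-3), max((1 - m) * common, 1e-3)])
    ecdf = np.arange(1, x.size + 1) / x.size

    def objective(theta):
        a, b = np.exp(theta)
        return np.sum((stats.beta.cdf(x, a, b) - ecdf) ** 2)

    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"beta prior fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return BetaPrior(float(a), float(b), fit_residual=float(res.fun))


def tv_distance(p_ref, p_sample):
    """Signed and absolute total-variation distance of methylation levels."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_sample = np.asarray(p_sample, dtype=float)
    tv = p_sample - p_ref
    return tv, np.abs(tv)


def hellinger_divergence(p_ref, p_sample, cov_ref, cov_sample):
    """Coverage-weighted Hellinger divergence and its weight.

    ``cov`` is the total read count (n_mc + n_uc) of each party; the
    effective counts are m = cov + 1.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_sample = np.asarray(p_sample, dtype=float)
    m_ref = np.asarray(cov_ref, dtype=float) + 1.0
    m_sample = np.asarray(cov_sample, dtype=float) + 1.0
    weight = 2.0 * m_ref * m_sample / (m_ref + m_sample)
    hdiv = weight * (
        (np.sqrt(p_ref) - np.sqrt(p_sample)) ** 2
        + (np.sqrt(1.0 - p_ref) - np.sqrt(1.0 - p_sample)) ** 2
    )
    return hdiv, weight


def hct_pvalue(hdiv):
    """Hellinger chi-square test (HCT) p-value.

    Under the null of equal level distributions, twice the weighted
    divergence is asymptotically chi-square with one degree of freedom
    (for two-point distributions the bracketed Hellinger term approaches
    (p_c - p_t)^2 / (4 p (1-p)) + ... = half the chi-square kernel, so the
    factor 2 restores the nominal type-I error).
    """
    return stats.chi2.sf(2.0 * np.asarray(hdiv, dtype=float), df=1)


def divergence_track(
    sample: MethSample,
    reference: MethSample,
    prior_mode: Literal["uniform", "fitted"] = "uniform",
    min_coverage: int = 10,
    with_hct: bool = True,
) -> pd.DataFrame:
    """Per-site divergence record of a sample against the reference.

    Only sites covered at >= min_coverage in *both* the sample and the
    reference are scored (no imputation).  In ``fitted`` mode a beta prior
    is fitted separately to the sample's and the reference's own crude
    level distributions.
    """
    s = sample.data.set_index(["chrom", "pos"])
    r = reference.data.set_index(["chrom", "pos"])
    merged = s.join(r, how="inner", lsuffix="_s", rsuffix="_r")
    cov_s = (merged["n_mc_s"] + merged["n_uc_s"]).to_numpy()
    cov_r = (merged["n_mc_r"] + merged["n_uc_r"]).to_numpy()
    keep = (cov_s >= min_coverage) & (cov_r >= min_coverage)
    merged = merged.loc[keep]
    if len(merged) == 0:
        raise ValueError(
            f"no shared sites between {sample.sample_id} and {reference.sample_id} "
            f"at coverage >= {min_coverage}"
        )
    cov_s, cov_r = cov_s[keep], cov_r[keep]
    if prior_mode == "uniform":
        p_s = uniform_prior_level(merged["n_mc_s"], merged["n_uc_s"])
        p_r = uniform_prior_level(merged["n_mc_r"], merged["n_uc_r"])
    elif prior_mode == "fitted":
        prior_s = fit_beta_prior(uniform_prior_level(merged["n_mc_s"], merged["n_uc_s"]))
        prior_r = fit_beta_prior(uniform_prior_level(merged["n_mc_r"], merged["n_uc_r"]))
        p_s = posterior_level(merged["n_mc_s"], merged["n_uc_s"], prior_s)
        p_r = posterior_level(merged["n_mc_r"], merged["n_uc_r"], prior_r)
    else:
        raise ValueError(f"unknown prior mode {prior_mode!r}")
    tv, tv_abs = tv_distance(p_r, p_s)
    hdiv, weight = hellinger_divergence(p_r, p_s, cov_r, cov_s)
    out = pd.DataFrame(
        {
            "chrom": merged.index.get_level_values("chrom"),
            "pos": merged.index.get_level_values("pos"),
            "cov_ref": cov_r.astype(np.int64),
            "cov_sample": cov_s.astype(np.int64),
            "p_ref": np.asarray(p_r),
            "p_sample": np.asarray(p_s),
            "tv": tv,
            "tv_abs": tv_abs,
            "hdiv": hdiv,
            "weight": weight,
        }
    )
    out["hct_pvalue"] = hct_pvalue(hdiv) if with_hct else np.nan
    return out.reset_index(drop=True)


def write_track(track: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a divergence track as a TSV (full float precision)."""
    path = Path(path)
    track.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_track(path: str | Path) -> pd.DataFrame:
    """Read back a divergence track written by :func:`write_track`."""
    track = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    track["chrom"] = track["chrom"].astype(object)
    return track
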