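"""Nonlinear CDF models for the per-sample Hellinger divergence distribution.

The genome-wide distribution of the Hellinger divergence H within one
sample is summarized by its empirical CDF and approximated by a Weibull or
gamma model fitted by nonlinear least squares on the (H, ECDF) pairs:

* Weibull:  F(H) = 1 - exp(-((H - mu)/lambda)^alpha)
* gamma:    F(H) = gammainc(alpha, beta*(H - mu))   (regularized)

each in a 2-parameter (location mu fixed at 0) and a 3-parameter variant.
The best model (lowest AIC computed from the Gaussian RSS over the ECDF
points, ties to fewer parameters then higher R^2) provides the per-sample
critical value H(alpha) — the (1 - alpha) quantile separating background
noise from potential signal — and per-site tail probabilities used as a
classifier predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "EcdfCurve",
    "FittedModel",
    "CriticalValue",
    "FAMILIES",
    "empirical_cdf",
    "fit_cdf_model",
    "select_best_model",
    "critical_value",
    "tail_log2p",
    "write_model_report",
]

FAMILIES = ("weibull2", "weibull3", "gamma2", "gamma3")

LOG2P_FLOOR = np.log2(1e-300)


class FitError(RuntimeError):
    """Nonlinear CDF fit failure, carrying per-family diagnostics."""


@dataclass(frozen=True)
class EcdfCurve:
    """Sorted divergence values with their empirical CDF probabilities."""

    values: np.ndarray
    probs: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FittedModel:
    """A Weibull or gamma CDF fitted to a divergence ECDF.

    ``scale`` is the Weibull scale lambda, or 1/rate for the gamma family;
    ``location`` is 0 for the 2-parameter variants.
    """

    family: str
    shape: float
    scale: float
    location: float
    r_squared: float
    rss: float
    aic: float
    n_points: int

    @property
    def n_parameters(self) -> int:
        return 2 if self.family.endswith("2") else 3

    def cdf(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        z = np.maximum(h - self.location, 0.0)
        if self.family.startswith("weibull"):
            return 1.0 - np.exp(-((z / self.scale) ** self.shape))
        return special.gammainc(self.shape, z / self.scale)

    def sf(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        z = np.maximum(h - self.location, 0.0)
        if self.family.startswith("weibull"):
            return np.exp(-((z / self.scale) ** self.shape))
        return special.gammaincc(self.shape, z / self.scale)

    def quantile(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.family.startswith("weibull"):
            return self.location + self.scale * (-np.log1p(-q)) ** (1.0 / self.shape)
        return self.location + self.scale * special.gammaincinv(self.shape, q)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))


@dataclass(frozen=True)
class CriticalValue:
    """Per-sample critical divergence H(alpha) from the best fitted model."""

    sample_id: str
    alpha: float
    h_crit: float
    model: FittedModel


def empirical_cdf(values) -> EcdfCurve:
    """ECDF F(H0) = #{H_k <= H0}/n evaluated at each sorted value.

    Ties all receive the full right-continuous step value.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empirical_cdf requires at least one value")
    # right-continuous: at tied values the ECDF equals the count of <= x
    probs = np.searchsorted(x, x, side="right") / x.size
    return EcdfCurve(values=x, probs=probs)


def _weibull_init(x: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    """Shape/scale start values via the log-log linearization of the CDF."""
    mask = (probs > 0) & (probs < 1) & (x > 0)
    lx = np.log(x[mask])
    ly = np.log(-np.log1p(-probs[mask]))
    slope, intercept = np.polyfit(lx, ly, 1)
    shape = max(slope, 1e-3)
    scale = float(np.exp(-intercept / shape))
    return shape, max(scale, 1e-12)


def _gamma_init(x: np.ndarray) -> tuple[float, float]:
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    shape = max(m * m / v, 1e-3)
    scale = max(v / m, 1e-12)
    return shape, scale


def fit_cdf_model(ecdf: EcdfCurve, family: str, min_n: int = 100) -> FittedModel:
    """Least-squares fit of a theoretical CDF to the ECDF points.

    Deterministic given the input (bounded trust-region least squares from
    a fixed initialization rule).  Raises :class:`FitError` on failure.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x, probs = ecdf.values, ecdf.probs
    if x.size < min_n:
        raise FitError(f"{family}: need >= {min_n} ECDF points, got {x.size}")
    if x.min() <= 0:
        raise FitError(f"{family}: divergence values must be strictly positive")

    three_param = family.endswith("3")
    if family.startswith("weibull"):
        shape0, scale0 = _weibull_init(x, probs)
    else:
        shape0, scale0 = _gamma_init(x)
    xmin = float(x.min())
    p0 = [shape0, scale0] + ([min(1e-6, 0.5 * xmin)] if three_param else [])
    lower = [1e-6, 1e-12] + ([0.0] if three_param else [])
    upper = [np.inf, np.inf] + ([np.nextafter(xmin, 0.0)] if three_param else [])

    if family.startswith("weibull"):
        def model(h, shape, scale, loc=0.0):
            z = np.maximum(h - loc, 0.0)
            return 1.0 - np.exp(-((z / scale) ** shape))
    else:
        def model(h, shape, scale, loc=0.0):
            z = np.maximum(h - loc, 0.0)
            return special.gammainc(shape, z / scale)

    try:
        popt, _ = optimize.curve_fit(
            model, x, probs, p0=p0, bounds=(lower, upper), method="trf",
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{family}: nonlinear fit failed ({exc})") from None
    resid = model(x, *popt) - probs
    rss = float(np.sum(resid**2))
    tss = float(np.sum((probs - probs.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 0.0
    k = len(popt)
    n = x.size
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * k
    shape, scale = float(popt[0]), float(popt[1])
    location = float(popt[2]) if three_param else 0.0
    return FittedModel(
        family=family,
        shape=shape,
        scale=scale,
        location=location,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        rss=rss,
        aic=float(aic),
        n_points=n,
    )


def subsample_ecdf(ecdf: EcdfCurve, max_points: int = 100_000) -> EcdfCurve:
    """Deterministic every-k-th subsample of a large ECDF (shape-preserving)."""
    n = len(ecdf)
    if n <= max_points:
        return ecdf
    step = int(np.ceil(n / max_points))
    idx = np.arange(0, n, step)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)  # keep the F=1 endpoint
    return EcdfCurve(values=ecdf.values[idx], probs=ecdf.probs[idx])


def select_best_model(
    ecdf: EcdfCurve,
    families: Sequence[str] = FAMILIES,
    min_n: int = 100,
) -> FittedModel:
    """Fit all candidate families and return the lowest-AIC convergent fit.

    Ties (within 1e-9 of AIC) are broken by fewer parameters, then higher
    R^2.  Invariant to the order of the candidate list.
    """
    if len(families) == 0:
        raise ValueError("no candidate families")
    fits: list[FittedModel] = []
    failures: list[str] = []
    for family in families:
        try:
            fits.append(fit_cdf_model(ecdf, family, min_n=min_n))
        except FitError as exc:
            failures.append(str(exc))
    if not fits:
        raise FitError("all families failed: " + "; ".join(failures))
    return min(fits, key=lambda m: (round(m.aic, 9), m.n_parameters, -m.r_squared, m.family))


def critical_value(model: FittedModel, alpha: float = 0.05) -> float:
    """Inverse model CDF at 1 - alpha (closed form for both families)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(model.quantile(1.0 - alpha))


def tail_log2p(model: FittedModel, h, per_site: bool = True, h_crit: float | None = None):
    """log2 of the model tail probability, floored to stay finite.

    ``per_site=True`` evaluates the tail at each site's own divergence;
    with ``per_site=False`` the tail is evaluated at the constant critical
    value ``h_crit`` instead (one value per sample).
    """
    if not per_site:
        if h_crit is None:
            raise ValueError("constant-mode tail_log2p requires h_crit")
        h = np.full_like(np.asarray(h, dtype=float), h_crit)
    h = np.asarray(h, dtype=float)
    z = np.maximum(h - model.location, 0.0)
    if model.family.startswith("weibull"):
        # exact log tail avoids underflow: log2 sf = -(z/scale)^shape / ln 2
        log2p = -((z / model.scale) ** model.shape) / np.log(2.0)
    else:
        with np.errstate(divide="ignore"):
            log2p = np.log2(special.gammaincc(model.shape, z / model.scale))
    return np.maximum(log2p, LOG2P_FLOOR)


def save_critical_values(models: dict[str, CriticalValue], path: str | Path) -> Path:
    """Machine-readable JSON dump of per-sample fitted models."""
    import json

    payload = {
        sid: {
            "alpha": cv.alpha,
            "h_crit": cv.h_crit,
            "family": cv.model.family,
            "shape": cv.model.shape,
            "scale": cv.model.scale,
            "location": cv.model.location,
            "r_squared": cv.model.r_squared,
            "rss": cv.model.rss,
            "aic": cv.model.aic,
            "n_points": cv.model.n_points,
        }
        for sid, cv in models.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return Path(path)


def load_critical_values(path: str | Path) -> dict[str, CriticalValue]:
    """Inverse of :func:`save_critical_values`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for sid, d in payload.items():
        model = FittedModel(
            family=d["family"],
            shape=d["shape"],
            scale=d["scale"],
            location=d["location"],
            r_squared=d["r_squared"],
            rss=d["rss"],
            aic=d["aic"],
            n_points=d["n_points"],
        )
        out[sid] = CriticalValue(
            sample_id=sid, alpha=d["alpha"], h_crit=d["h_crit"], model=model
        )
    return out


def write_model_report(models: dict[str, CriticalValue], path: str | Path) -> Path:
    """Plain-text key-value report of per-sample fitted models."""
    path = Path(path)
    with open(path, "w") as fh:
        for sample_id, cv in sorted(models.items()):
            m = cv.model
            fh.write(f"[{sample_id}]\n")
            fh.write(f"family = {m.family}\n")
            fh.write(f"shape = {m.shape:.10g}\n")
            fh.write(f"scale = {m.scale:.10g}\n")
            fh.write(f"location = {m.location:.10g}\n")
            fh.write(f"r_squared = {m.r_squared:.6f}\n")
            fh.write(f"rss = {m.rss:.10g}\n")
            fh.write(f"aic = {m.aic:.10g}\n")
            fh.write(f"n_points = {m.n_points}\n")
            fh.write(f"alpha = {cv.alpha}\n")
            fh.write(f"h_crit = {cv.h_crit:.10g}\n\n")
    return path
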