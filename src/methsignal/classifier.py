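"""DMP origin classification (control vs treatment) with Monte Carlo CV.

Each DMP contributes four predictors: the absolute methylation-level
difference |TV|, the Hellinger divergence H, the relative chromosome
position of the site, and the log2 tail probability of H under the DMP's
own sample model.  The label is the group of origin: ``CT`` (control) or
``TT`` (treatment), with TT as the positive class throughout.

Four model families are available: plain logistic regression (no scaling,
no PCA) and scaled-PCA variants feeding logistic, linear-discriminant or
quadratic-discriminant models.  Performance is estimated by Monte Carlo
cross-validation: repeated stratified random splits (default 999 resamples
of 60% training / 40% testing) with an indicator panel (accuracy, kappa,
sensitivity, specificity, PPV, NPV, detection rate, FDR) reported as means
with percentile bootstrap confidence intervals across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .dist_fit import CriticalValue
from .signal_detect import DMPSet

__all__ = [
    "FEATURES",
    "INDICATORS",
    "ClassifierSpec",
    "TrainedClassifier",
    "PerformanceReport",
    "build_features",
    "build_feature_frame",
    "train_classifier",
    "predict",
    "monte_carlo_cv",
    "confusion_metrics",
]

FEATURES = ["tv_abs", "hdiv", "rel_pos", "log2_tailp"]
INDICATORS = [
    "accuracy",
    "kappa",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "detection_rate",
    "fdr",
]

FAMILY_CHOICES = ("logistic", "pca_logistic", "pca_lda", "pca_qda")


@dataclass(frozen=True)
class ClassifierSpec:
    """Model family and preprocessing choices.

    ``scale`` standardizes predictors before PCA; it is ignored (per the
    model definition) for the plain logistic family.
    """

    family: str = "pca_qda"
    n_components: int = 4
    scale: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILY_CHOICES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILY_CHOICES}")
        if not 1 <= self.n_components <= len(FEATURES):
            raise ValueError("n_components must be between 1 and 4")


@dataclass
class TrainedClassifier:
    """A fitted classification pipeline plus its training metadata."""

    spec: ClassifierSpec
    pipeline: Pipeline
    classes_: np.ndarray

    @property
    def rotation(self) -> np.ndarray | None:
        """PCA rotation matrix (components in rows), if PCA is used."""
        if "pca" in self.pipeline.named_steps:
            return self.pipeline.named_steps["pca"].components_
        return None


@dataclass(frozen=True)
class PerformanceReport:
    """Indicator means with percentile bootstrap CIs over MC-CV resamples."""

    means: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    confusion: np.ndarray  # pooled [[TN, FP], [FN, TP]]
    n_resamples: int
    train_fraction: float
    seed: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": pd.Series(self.means),
                "ci_2.5%": pd.Series(self.ci_lower),
                "ci_97.5%": pd.Series(self.ci_upper),
            }
        )

    def __str__(self) -> str:  # human-readable text report
        lines = [
            f"Monte Carlo cross-validation: {self.n_resamples} resamples, "
            f"{self.train_fraction:.0%} training fraction, seed {self.seed}",
            f"pooled confusion [[TN FP] [FN TP]]: {self.confusion.tolist()}",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def build_feature_frame(
    pdmps: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Attach rel_pos and the CT/TT label to a pDMP/DMP table.

    ``log2_tailp`` is expected to be present already (it is computed when
    potential DMPs are selected, under each DMP's own sample model).
    """
    missing = set(pdmps["chrom"].unique()) - set(chrom_lengths)
    if missing:
        raise KeyError(f"no chromosome length for: {sorted(missing)}")
    lengths = pdmps["chrom"].map(chrom_lengths).to_numpy(dtype=float)
    out = pdmps.copy()
    out["rel_pos"] = out["pos"].to_numpy(dtype=float) / lengths
    if (out["rel_pos"] > 1).any():
        raise ValueError("position beyond chromosome length")
    out["label"] = np.where(out["group"].to_numpy() == "control", "CT", "TT")
    return out


def build_features(
    dmps: DMPSet,
    chrom_lengths: Mapping[str, int],
    critical_values: Mapping[str, CriticalValue] | None = None,
) -> pd.DataFrame:
    """Feature table for a DMP set (recomputing log2_tailp if models given)."""
    from .dist_fit import tail_log2p

    table = dmps.members
    if critical_values is not None:
        table = table.copy()
        tail = np.empty(len(table))
        for sample_id, idx in table.groupby("sample_id").groups.items():
            cv = critical_values[sample_id]
            tail[table.index.get_indexer(idx)] = tail_log2p(
                cv.model, table.loc[idx, "hdiv"].to_numpy()
            )
        table["log2_tailp"] = tail
    return build_feature_frame(table, chrom_lengths)


def _make_pipeline(spec: ClassifierSpec, seed: int | None = None) -> Pipeline:
    steps = []
    if spec.family == "logistic":
        steps.append(("model", LogisticRegression(max_iter=1000)))
        return Pipeline(steps)
    if spec.scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("pca", PCA(n_components=spec.n_components, svd_solver="full")))
    if spec.family == "pca_logistic":
        model = LogisticRegression(max_iter=1000)
    elif spec.family == "pca_lda":
        model = LinearDiscriminantAnalysis()
    else:
        # mild shrinkage keeps near-collinear predictor sets (|TV|, H and
        # the tail probability are strongly dependent) numerically sane
        model = QuadraticDiscriminantAnalysis(reg_param=1e-3)
    steps.append(("model", model))
    return Pipeline(steps)


def train_classifier(
    features: pd.DataFrame, spec: ClassifierSpec, seed: int = 0
) -> TrainedClassifier:
    """Fit the specified model on a labelled feature table."""
    labels = features["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes (CT, TT) must be present for training")
    if len(features) < 10:
        raise ValueError("need at least 10 labelled rows to train")
    X = features[FEATURES].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    pipe = _make_pipeline(spec, seed)
    try:
        pipe.fit(X, labels)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            f"singular covariance during {spec.family} fit; "
            "try fewer principal components"
        ) from exc
    return TrainedClassifier(spec=spec, pipeline=pipe, classes_=pipe.classes_)


def predict(model: TrainedClassifier, features: pd.DataFrame):
    """Posterior P(TT|x) per row and hard labels at threshold 0.5."""
    X = features[FEATURES].to_numpy(dtype=float)
    proba = model.pipeline.predict_proba(X)
    tt_col = int(np.nonzero(model.classes_ == "TT")[0][0])
    posterior = proba[:, tt_col]
    labels = np.where(posterior >= 0.5, "TT", "CT")
    return labels, posterior


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Indicator panel from true/predicted CT/TT labels (TT positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("labels must be nonempty and aligned")
    tp = float(np.sum((y_true == "TT") & (y_pred == "TT")))
    tn = float(np.sum((y_true == "CT") & (y_pred == "CT")))
    fp = float(np.sum((y_true == "CT") & (y_pred == "TT")))
    fn = float(np.sum((y_true == "TT") & (y_pred == "CT")))
    n = tp + tn + fp + fn

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    po = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    pe = p_yes + p_no
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return {
        "accuracy": po,
        "kappa": kappa,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "detection_rate": tp / n,
        "fdr": ratio(fp, tp + fp),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def monte_carlo_cv(
    features: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    n_resamples: int = 999,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> PerformanceReport:
    """Monte Carlo cross-validation of the DMP origin classifier.

    Each resample draws a stratified random train/test split, fits the
    model on the training part and scores the indicator panel on the
    held-out part.  Resamples whose test part lacks a class are redrawn
    (and counted).  Deterministic given the seed.
    """
    if spec is None:
        spec = ClassifierSpec()
    labels = features["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 5:
        raise ValueError("each class needs >= 5 rows for Monte Carlo CV")
    X = features[FEATURES].to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(
        n_splits=n_resamples, train_size=train_fraction, random_state=seed % (2**31 - 1)
    )
    per_resample = {k: np.empty(n_resamples) for k in INDICATORS}
    pooled = np.zeros((2, 2))
    n_redrawn = 0
    n_failed = 0
    pipe = _make_pipeline(spec, seed)
    for i, (train_idx, test_idx) in enumerate(splitter.split(X, labels)):
        # stratified splits keep both classes; guard stays for tiny inputs
        if len(np.unique(labels[test_idx])) < 2 or len(np.unique(labels[train_idx])) < 2:
            n_redrawn += 1
            rng = np.random.default_rng((seed + 7919 * (i + 1)) % (2**31 - 1))
            while True:
                perm = rng.permutation(len(labels))
                cut = int(round(train_fraction * len(labels)))
                train_idx, test_idx = perm[:cut], perm[cut:]
                if (
                    len(np.unique(labels[train_idx])) == 2
                    and len(np.unique(labels[test_idx])) == 2
                ):
                    break
        try:
            pipe.fit(X[train_idx], labels[train_idx])
        except np.linalg.LinAlgError:
            for k in INDICATORS:
                per_resample[k][i] = np.nan
            n_failed += 1
            continue
        pred = pipe.predict(X[test_idx])
        m = confusion_metrics(labels[test_idx], pred)
        for k in INDICATORS:
            per_resample[k][i] = m[k]
        pooled += np.array([[m["tn"], m["fp"]], [m["fn"], m["tp"]]])
    if n_failed == n_resamples:
        raise RuntimeError(
            f"{spec.family} fit failed on every resample (singular class covariance); "
            "try fewer principal components or a linear model"
        )
    means = {k: float(np.nanmean(v)) for k, v in per_resample.items()}
    ci_lo = {k: float(np.nanpercentile(v, 2.5)) for k, v in per_resample.items()}
    ci_hi = {k: float(np.nanpercentile(v, 97.5)) for k, v in per_resample.items()}
    return PerformanceReport(
        means=means,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        confusion=pooled,
        n_resamples=n_resamples,
        train_fraction=train_fraction,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def save_classifier(model: TrainedClassifier, path: str | Path) -> Path:
    """Serialize a trained classifier to a portable plain-text JSON file.

    All coefficients are stored as plain numbers; :func:`load_classifier`
    reconstructs an equivalent pipeline.
    """
    import json

    path = Path(path)
    payload: dict = {
        "family": model.spec.family,
        "n_components": model.spec.n_components,
        "scale": model.spec.scale,
        "classes": model.classes_.tolist(),
    }
    steps = model.pipeline.named_steps
    if "scale" in steps:
        payload["center"] = steps["scale"].mean_.tolist()
        payload["scale_vector"] = steps["scale"].scale_.tolist()
    if "pca" in steps:
        payload["rotation"] = steps["pca"].components_.tolist()
        payload["pca_mean"] = steps["pca"].mean_.tolist()
    est = steps["model"]
    if isinstance(est, LogisticRegression) or isinstance(est, LinearDiscriminantAnalysis):
        payload["coef"] = np.asarray(est.coef_).tolist()
        payload["intercept"] = np.asarray(est.intercept_).tolist()
    if isinstance(est, QuadraticDiscriminantAnalysis):
        payload["qda_means"] = np.asarray(est.means_).tolist()
        payload["qda_priors"] = np.asarray(est.priors_).tolist()
        payload["qda_rotations"] = [np.asarray(r).tolist() for r in est.rotations_]
        payload["qda_scalings"] = [np.asarray(s).tolist() for s in est.scalings_]
        payload["qda_reg"] = est.reg_param
    if isinstance(est, LinearDiscriminantAnalysis):
        payload["lda_xbar"] = np.asarray(est.xbar_).tolist() if hasattr(est, "xbar_") else None
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def load_classifier(path: str | Path) -> TrainedClassifier:
    """Reconstruct a trained classifier saved by :func:`save_classifier`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    spec = ClassifierSpec(
        family=payload["family"],
        n_components=payload["n_components"],
        scale=payload["scale"],
    )
    classes = np.asarray(payload["classes"], dtype=object)
    steps = []
    if "center" in payload:
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["center"])
        scaler.scale_ = np.asarray(payload["scale_vector"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        steps.append(("scale", scaler))
    if "rotation" in payload:
        pca = PCA(n_components=spec.n_components, svd_solver="full")
        pca.components_ = np.asarray(payload["rotation"])
        pca.mean_ = np.asarray(payload["pca_mean"])
        pca.n_components_ = pca.components_.shape[0]
        pca.n_features_in_ = pca.mean_.size
        pca.explained_variance_ = np.ones(pca.n_components_)
        pca.whiten = False
        steps.append(("pca", pca))
    if spec.family in ("logistic", "pca_logistic"):
        est = LogisticRegression(max_iter=1000)
        est.coef_ = np.asarray(payload["coef"])
        est.intercept_ = np.asarray(payload["intercept"])
        est.classes_ = classes
    elif spec.family == "pca_lda":
        est = LinearDiscriminantAnalysis()
        est.coef_ = np.asarray(payload["coef"])
        est.intercept_ = np.asarray(payload["intercept"])
        est.classes_ = classes
    else:
        est = QuadraticDiscriminantAnalysis(reg_param=payload.get("qda_reg", 0.0))
        est.means_ = np.asarray(payload["qda_means"])
        est.priors_ = np.asarray(payload["qda_priors"])
        est.rotations_ = [np.asarray(r) for r in payload["qda_rotations"]]
        est.scalings_ = [np.asarray(s) for s in payload["qda_scalings"]]
        est.classes_ = classes
    steps.append(("model", est))
    return TrainedClassifier(spec=spec, pipeline=Pipeline(steps), classes_=classes)
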