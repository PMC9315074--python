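"""Scoring of binarized masks against gold-standard masks.

Pixel-location agreement is summarized per image by a confusion matrix
(TP = flow in both masks, FP = flow in the prediction only, FN = flow
in the gold standard only, TN = background in both), from which
sensitivity, specificity and accuracy follow.  Method-level summaries
average the per-image metrics; the "AUC" of this comparison is defined
as the arithmetic mean of sensitivity and specificity (not a
swept-threshold ROC area).

Vessel-density agreement between a method and the gold standard is
measured by the intraclass correlation coefficient in its two-way
random-effects, absolute-agreement, single-measure form (ICC(A,1) of
McGraw & Wong), with an F-based 95% confidence interval; methods pass
the reliability gate when ICC >= 0.750.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methods import MethodSpec, corner_roi_means, run_method, vessel_density
from .raster_io import BinaryMask, GrayImage

__all__ = [
    "ConfusionCounts",
    "ImageMetrics",
    "PerformanceSummary",
    "ReliabilityResult",
    "BlandAltman",
    "confusion_counts",
    "image_metrics",
    "auc_from_sens_spec",
    "aggregate_performance",
    "icc_absolute_agreement",
    "bland_altman",
    "regression_r2",
    "compare_methods",
]

ICC_GATE = 0.750


@dataclass
class ConfusionCounts:
    """Pixel counts of a prediction against its gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class ImageMetrics(NamedTuple):
    sensitivity: float  # percent; NaN if the image has no flow pixels
    specificity: float  # percent; NaN if it has no background pixels
    accuracy: float  # percent


@dataclass
class PerformanceSummary:
    """Per-method pixel-location performance, averaged over images."""

    auc: float
    sensitivity: float
    specificity: float
    mean_accuracy: float
    accuracy_sd: float
    ci_low: float
    ci_high: float
    n_images: int


@dataclass
class ReliabilityResult:
    """ICC(A,1) point estimate, 95% CI and the reliability gate."""

    icc: float
    ci_low: float
    ci_high: float
    passes_gate: bool
    degenerate: bool = False


@dataclass
class BlandAltman:
    """Mean difference and 1.96-SD limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float


def confusion_counts(
    pred: BinaryMask, gold: BinaryMask, valid: np.ndarray | None = None
) -> ConfusionCounts:
    """Pixel-location confusion over the valid region.

    TP: flow in both masks; FP: flow in the prediction only; FN: flow
    in the gold standard only; TN: background in both.
    """
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gold.shape}")
    if valid is None:
        valid = np.ones(pred.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != pred.shape:
            raise ValueError("valid-region shape mismatch")
    p = pred.flow[valid]
    g = gold.flow[valid]
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def image_metrics(c: ConfusionCounts) -> ImageMetrics:
    """Sensitivity, specificity and accuracy (percent) of one image.

    An image with an empty flow (or background) class has undefined
    sensitivity (or specificity); the value is NaN and a warning is
    issued so aggregation can exclude it.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    if c.tp + c.fn > 0:
        sens = 100.0 * c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no gold flow pixels: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    if c.tn + c.fp > 0:
        spec = 100.0 * c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no gold background pixels: specificity undefined", stacklevel=2)
        spec = float("nan")
    acc = 100.0 * (c.tp + c.tn) / c.total
    return ImageMetrics(sens, spec, acc)


def auc_from_sens_spec(sensitivity: float, specificity: float) -> float:
    """Average of sensitivity and specificity as a proportion.

    Inputs are percentages; the result is (sens + spec) / 200 rounded
    half-up to 3 decimals.
    """
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100):
        raise ValueError("sensitivity/specificity must lie in [0, 100]")
    auc = (sensitivity + specificity) / 200.0
    return floor(auc * 1000 + 0.5) / 1000


def aggregate_performance(
    per_image: Sequence[ImageMetrics | tuple[float, float, float]],
    confidence: float = 0.95,
) -> PerformanceSummary:
    """Average per-image metrics into a method-level summary.

    Images with an undefined metric are dropped with a warning.  The
    CI on mean accuracy is t-based with n-1 degrees of freedom.
    """
    rows = np.asarray([tuple(m) for m in per_image], dtype=np.float64)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need at least two images")
    defined = ~np.isnan(rows).any(axis=1)
    if not defined.all():
        warnings.warn(
            f"dropping {int((~defined).sum())} image(s) with undefined metrics",
            stacklevel=2,
        )
    rows = rows[defined]
    n = rows.shape[0]
    if n < 2:
        raise ValueError("fewer than two images with defined metrics")
    sens, spec, acc = rows.mean(axis=0)
    acc_sd = float(rows[:, 2].std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * acc_sd / np.sqrt(n)
    return PerformanceSummary(
        auc=auc_from_sens_spec(float(sens), float(spec)),
        sensitivity=float(sens),
        specificity=float(spec),
        mean_accuracy=float(acc),
        accuracy_sd=acc_sd,
        ci_low=float(acc - half),
        ci_high=float(acc + half),
        n_images=n,
    )


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, error) of an n x k table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_absolute_agreement(ratings: np.ndarray, confidence: float = 0.95) -> ReliabilityResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n_targets x k_raters matrix with no missing
    cells.  The estimate and its F-based confidence interval follow
    the McGraw & Wong formulation; the reliability gate is inclusive
    at 0.750.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    if (x == x[:, :1]).all():
        # raters agree exactly on every target
        if (x == x.flat[0]).all():
            return ReliabilityResult(float("nan"), float("nan"), float("nan"), False, True)
        return ReliabilityResult(1.0, 1.0, 1.0, True, False)
    msr, msc, mse = _anova_mean_squares(x)
    mse = max(mse, 0.0)
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if abs(denom) < 1e-30:
        # no variance anywhere: agreement is undefined
        return ReliabilityResult(float("nan"), float("nan"), float("nan"), False, True)
    icc = (msr - mse) / denom
    degenerate = msr <= 1e-30  # no variance across targets

    alpha = 1 - confidence
    if mse <= 1e-30 and msc <= 1e-30:
        # raters agree exactly on every target
        return ReliabilityResult(icc, icc, icc, icc >= ICC_GATE, degenerate)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        lo = hi = icc
    lo, hi = min(lo, icc), max(hi, icc)
    return ReliabilityResult(float(icc), float(lo), float(hi), icc >= ICC_GATE, degenerate)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltman:
    """Bias and 1.96-SD limits of agreement of paired measurements."""
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)


def regression_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares fit of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def compare_methods(
    images: Sequence[GrayImage],
    golds: Sequence[BinaryMask],
    registry: Iterable[MethodSpec],
    seed: int = 0,
    denominator: str = "valid_only",
) -> pd.DataFrame:
    """Run every method over an image battery and tabulate the study report.

    For each method: per-image VD, its ICC(A,1) against the
    gold-standard VD with 95% CI and the 0.750 reliability gate; for
    gated methods additionally the pixel-location performance (AUC,
    sensitivity, specificity, mean accuracy with 95% CI).  One row per
    method, mirroring the reliability and performance tables of the
    comparison study.
    """
    images = list(images)
    golds = list(golds)
    if len(images) != len(golds) or len(images) < 2:
        raise ValueError("need >= 2 images with matching gold masks")
    gold_vd = np.array(
        [vessel_density(g, img.valid, denominator).vd for g, img in zip(golds, images)]
    )
    rows = []
    for spec in registry:
        vds = []
        metrics = []
        for img, gold in zip(images, golds):
            mask = run_method(spec, img, seed=seed, cornea_means=corner_roi_means(img))
            vds.append(vessel_density(mask, img.valid, denominator).vd)
            metrics.append(image_metrics(confusion_counts(mask, gold, img.valid)))
        vds = np.array(vds)
        rel = icc_absolute_agreement(np.column_stack([vds, gold_vd]))
        row = {
            "method": spec.name,
            "step_count": spec.step_count,
            "mean_vd": float(vds.mean()),
            "sd_vd": float(vds.std(ddof=1)),
            "icc": rel.icc,
            "icc_ci_low": rel.ci_low,
            "icc_ci_high": rel.ci_high,
            "reliable": rel.passes_gate,
        }
        if rel.passes_gate:
            perf = aggregate_performance(metrics)
            row.update(
                auc=perf.auc,
                sensitivity=perf.sensitivity,
                specificity=perf.specificity,
                accuracy=perf.mean_accuracy,
                accuracy_sd=perf.accuracy_sd,
                acc_ci_low=perf.ci_low,
                acc_ci_high=perf.ci_high,
            )
        else:
            row.update(
                auc=np.nan, sensitivity=np.nan, specificity=np.nan,
                accuracy=np.nan, accuracy_sd=np.nan, acc_ci_low=np.nan, acc_ci_high=np.nan,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["gold_vd_mean"] = float(gold_vd.mean())
    df.attrs["gold_vd_sd"] = float(gold_vd.std(ddof=1))
    return df
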