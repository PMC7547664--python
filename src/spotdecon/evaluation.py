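"""Benchmark metrics: per-spot RMSE, paired Wilcoxon comparison, the
uniform-Dirichlet RMSE null distribution, pairwise co-localization, and
max-scaling of proportions for display."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .data_io import ProportionMatrix, ValidationError


@dataclass
class RMSEReport:
    per_spot_rmse: np.ndarray
    method: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_spot_rmse))

    @property
    def median(self) -> float:
        return float(np.median(self.per_spot_rmse))


@dataclass
class ColocalizationMatrix:
    type_labels: list[str]
    r: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha_level: float


def _aligned(w: ProportionMatrix, truth: ProportionMatrix) -> tuple[np.ndarray, np.ndarray]:
    if w.spot_ids != truth.spot_ids:
        raise ValidationError("spot ids differ between the two proportion sets")
    if set(w.type_labels) != set(truth.type_labels):
        raise ValidationError("type label sets differ")
    order = [truth.type_labels.index(t) for t in w.type_labels]
    return w.w, truth.w[:, order]


def rmse(w: ProportionMatrix, truth: ProportionMatrix, method: str = "") -> RMSEReport:
    """Per-spot root-mean-square error over types:
    sqrt(mean_z (w_sz - what_sz)^2)."""
    a, b = _aligned(w, truth)
    per_spot = np.sqrt(np.mean((a - b) ** 2, axis=1))
    return RMSEReport(per_spot, method)


def paired_wilcoxon(rmse_a: np.ndarray, rmse_b: np.ndarray) -> tuple[float, float]:
    """One-sided paired Wilcoxon signed-rank test of a < b.

    Tests whether the per-spot differences a - b are asymmetrically
    distributed below zero; zero differences are dropped (the convention of
    the standard R routine). Raises on a fully degenerate comparison.
    """
    rmse_a = np.asarray(rmse_a, dtype=float)
    rmse_b = np.asarray(rmse_b, dtype=float)
    if rmse_a.shape != rmse_b.shape:
        raise ValidationError("paired vectors must have equal length")
    if np.all(rmse_a == rmse_b):
        raise ValidationError("all paired differences are zero; test degenerate")
    stat, p = scipy.stats.wilcoxon(
        rmse_a, rmse_b, alternative="less", zero_method="wilcox"
    )
    return float(stat), float(p)


def dirichlet_null(
    truth: ProportionMatrix, reps: int = 1000, seed: int = 0, against_truth: bool = True
) -> np.ndarray:
    """Null distribution of mean per-spot RMSE under uninformed estimates.

    Each repetition replaces the estimates by flat-Dirichlet draws (all
    concentrations 1) over the |Z| types for every spot and scores them
    against the ground truth (or, optionally, against an independent draw).
    Returns ``reps`` mean per-spot RMSE values.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    Z = len(truth.type_labels)
    if Z < 2:
        raise ValidationError("need at least 2 types for a Dirichlet null")
    S = len(truth.spot_ids)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for i in range(reps):
        draw = rng.dirichlet(np.ones(Z), size=S)
        ref = truth.w if against_truth else rng.dirichlet(np.ones(Z), size=S)
        out[i] = float(np.mean(np.sqrt(np.mean((draw - ref) ** 2, axis=1))))
    return out


def null_per_spot_rmse(truth: ProportionMatrix, seed: int = 0) -> np.ndarray:
    """Per-spot RMSE of a single flat-Dirichlet draw against the truth,
    for paired per-location comparisons."""
    Z = len(truth.type_labels)
    if Z < 2:
        raise ValidationError("need at least 2 types for a Dirichlet null")
    rng = np.random.default_rng(seed)
    draw = rng.dirichlet(np.ones(Z), size=len(truth.spot_ids))
    return np.sqrt(np.mean((draw - truth.w) ** 2, axis=1))


def colocalization(w: ProportionMatrix, alpha_level: float = 0.01) -> ColocalizationMatrix:
    """Pairwise Pearson correlation of type proportions across locations.

    Each capture location is one data point; p-values are two-sided and not
    multiple-testing corrected. Zero-variance columns yield NaN entries,
    excluded from the significance mask.
    """
    if len(w.spot_ids) < 3:
        raise ValidationError("need at least 3 spots for correlation")
    Z = len(w.type_labels)
    if Z < 2:
        raise ValidationError("need at least 2 types for correlation")
    r = np.eye(Z)
    p = np.zeros((Z, Z))
    for i in range(Z):
        for j in range(i + 1, Z):
            xi, xj = w.w[:, i], w.w[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = scipy.stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    with np.errstate(invalid="ignore"):
        sig = p <= alpha_level
    sig &= ~np.isnan(p)
    np.fill_diagonal(sig, False)
    return ColocalizationMatrix(list(w.type_labels), r, p, sig, alpha_level)


def scale_proportions(w: ProportionMatrix) -> np.ndarray:
    """Max-scale each type's proportions for display: divide every column by
    its largest element. No thresholding or further adjustment."""
    out = np.array(w.w, dtype=float)
    maxima = out.max(axis=0)
    for j, m in enumerate(maxima):
        if m > 0:
            out[:, j] /= m
        else:
            warnings.warn(
                f"type {w.type_labels[j]!r} is zero everywhere; left unscaled",
                stacklevel=2,
            )
    return out
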