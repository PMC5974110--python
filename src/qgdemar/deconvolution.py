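"""Empirical Gaussian null estimation and tail-based detection.

The central idea: for a per-probe discrimination variable (a log-ratio,
super-ratio, difference or log2-quotient), the bulk of probes fluctuate
only stochastically and form an approximately Gaussian central region,
while differentially expressed probes sit in the tails.  Fitting the
Gaussian null on the *central quantile window* of the distribution
("deconvolution") instead of on all values keeps contaminated tails from
inflating the scale estimate, which yields narrower confidence limits
and a more sensitive, lower-FDR detection.

Detection is per tail: a candidate threshold t in the upper tail is
assigned an estimated false discovery rate

    FDR% = 100 * N * P(X > t | mu_hat, sigma_hat) / #{x_i > t}

(the expected number of null probes beyond t over the number actually
observed beyond t), and symmetrically for the lower tail.  The least
extreme threshold whose estimated FDR does not exceed the target is
selected, maximizing detections subject to the FDR bound.  If no
threshold qualifies, the tail is reported as NDAS ("not detectable as
significant").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("qgdemar")

Tail = Literal["upper", "lower"]

#: Default central quantile window used to fit the Gaussian null.
DEFAULT_WINDOW = (0.25, 0.75)

#: Default detection target: estimated FDR must not exceed this percentage.
DEFAULT_FDR_TARGET = 5.0

#: Minimum number of finite values required to attempt a fit.
MIN_FINITE_VALUES = 50

#: Minimum number of order statistics inside the quantile window.
MIN_WINDOW_POINTS = 10


class DeconvolutionError(ValueError):
    """Base class for errors raised by the null-fitting machinery."""


class DegenerateNullError(DeconvolutionError):
    """The data admit no positive-scale Gaussian null (e.g. constant input)."""


class InsufficientDataError(DeconvolutionError):
    """Too few finite values, or too few points inside the quantile window."""


class ThresholdSideError(DeconvolutionError):
    """A threshold lies on the wrong side of the null mean for the tail."""


@dataclass(frozen=True)
class GaussianNull:
    """Gaussian null ``N(mu_hat, sigma_hat**2)`` of a discrimination variable.

    Attributes
    ----------
    mu_hat, sigma_hat
        Location and scale in the units of the variable; ``sigma_hat > 0``.
    window
        Quantile window ``(q_lo, q_hi)`` the fit used; ``(0.0, 1.0)`` marks
        a whole-sample (control-chart) fit.
    n_points_fit
        Number of order statistics entering the regression.
    fit_r2
        R² of the probit-plot regression; a diagnostic of how Gaussian the
        fitted region is.
    """

    mu_hat: float
    sigma_hat: float
    window: tuple[float, float]
    n_points_fit: int
    fit_r2: float

    def __post_init__(self) -> None:
        if not self.sigma_hat > 0:
            raise DegenerateNullError(f"sigma_hat must be > 0, got {self.sigma_hat}")
        if not self.window[0] < self.window[1]:
            raise ValueError(f"window must satisfy q_lo < q_hi, got {self.window}")

    def tail_probability(self, threshold: float, tail: Tail) -> float:
        """Null probability of exceeding ``threshold`` in the given tail."""
        z = (threshold - self.mu_hat) / self.sigma_hat
        return float(stats.norm.sf(z)) if tail == "upper" else float(stats.norm.cdf(z))


NDAS = "NDAS"
DETECTED = "detected"


@dataclass(frozen=True)
class TailDetection:
    """Outcome of threshold selection in one tail."""

    status: str  # DETECTED or NDAS
    threshold: float | None
    probes: frozenset
    fdr_percent: float | None

    def __post_init__(self) -> None:
        if self.status == NDAS and (self.probes or self.threshold is not None):
            raise ValueError("NDAS tail must carry no threshold and no probes")

    @property
    def n_detected(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class DetectionResult:
    """Per-tail detection outcome for one discrimination variable.

    ``upper`` holds probes whose value significantly exceeds the null
    (numerator up-regulated, for ratio-type variables); ``lower`` holds the
    symmetric down-regulated tail.
    """

    variable_id: str
    null: GaussianNull
    upper: TailDetection
    lower: TailDetection
    n_total: int
    probe_ids: frozenset = field(repr=False)

    def tail(self, which: Tail) -> TailDetection:
        return self.upper if which == "upper" else self.lower

    @property
    def detected(self) -> frozenset:
        return self.upper.probes | self.lower.probes


def _finite(values) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (finite float array, index labels or None), logging exclusions."""
    if isinstance(values, pd.Series):
        arr = values.to_numpy(dtype=float)
        labels = values.index.to_numpy()
    else:
        arr = np.asarray(values, dtype=float)
        labels = None
    mask = np.isfinite(arr)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.info("excluding %d non-finite values from null fit/detection", n_bad)
    return arr[mask], (labels[mask] if labels is not None else None)


def fit_gaussian_null(
    values,
    q_lo: float = DEFAULT_WINDOW[0],
    q_hi: float = DEFAULT_WINDOW[1],
) -> GaussianNull:
    """Fit a Gaussian null to the central region of ``values``.

    Order statistics with plotting positions ``(k - 0.5)/n`` inside
    ``[q_lo, q_hi]`` are regressed by ordinary least squares on the
    corresponding standard-normal quantiles (a probit plot restricted to
    the central window).  The intercept estimates ``mu_hat`` and the
    slope ``sigma_hat``; contaminated tails never enter the regression.

    Raises
    ------
    InsufficientDataError
        Fewer than 50 finite values, or fewer than 10 points in the window.
    DegenerateNullError
        The regression slope is not positive (constant or degenerate data).
    """
    if not 0 < q_lo < q_hi < 1:
        raise ValueError(f"require 0 < q_lo < q_hi < 1, got ({q_lo}, {q_hi})")
    finite, _ = _finite(values)
    n = finite.size
    if n < MIN_FINITE_VALUES:
        raise InsufficientDataError(f"need >= {MIN_FINITE_VALUES} finite values, got {n}")
    order = np.sort(finite)
    pp = (np.arange(1, n + 1) - 0.5) / n
    inside = (pp >= q_lo) & (pp <= q_hi)
    if int(inside.sum()) < MIN_WINDOW_POINTS:
        raise InsufficientDataError(
            f"only {int(inside.sum())} order statistics inside window ({q_lo}, {q_hi})"
        )
    z = stats.norm.ppf(pp[inside])
    fit = stats.linregress(z, order[inside])
    if not fit.slope > 0:
        raise DegenerateNullError(
            f"probit regression slope {fit.slope} is not positive; data may be constant"
        )
    return GaussianNull(
        mu_hat=float(fit.intercept),
        sigma_hat=float(fit.slope),
        window=(q_lo, q_hi),
        n_points_fit=int(inside.sum()),
        fit_r2=float(fit.rvalue**2),
    )


def fit_full_sample_null(values) -> GaussianNull:
    """Fit the comparator null on the *whole* sample (no central trimming).

    Uses the sample mean and standard deviation of all finite values —
    the classical control-chart limits.  Contaminated tails inflate
    ``sigma_hat``, which is exactly what the deconvolved fit avoids.
    """
    finite, _ = _finite(values)
    n = finite.size
    if n < MIN_FINITE_VALUES:
        raise InsufficientDataError(f"need >= {MIN_FINITE_VALUES} finite values, got {n}")
    sigma = float(np.std(finite, ddof=1))
    if not sigma > 0:
        raise DegenerateNullError("sample standard deviation is zero; data are constant")
    # probit R2 over the full range, as a normality diagnostic only
    pp = (np.arange(1, n + 1) - 0.5) / n
    r = stats.linregress(stats.norm.ppf(pp), np.sort(finite)).rvalue
    return GaussianNull(
        mu_hat=float(np.mean(finite)),
        sigma_hat=sigma,
        window=(0.0, 1.0),
        n_points_fit=n,
        fit_r2=float(r**2),
    )


def tail_fdr(null: GaussianNull, values, threshold: float, tail: Tail) -> float | None:
    """Estimated FDR% of calling everything strictly beyond ``threshold``.

    ``FDR% = 100 * N * p_tail(threshold) / n_detected`` capped at 100,
    where ``N`` counts all finite values and ``n_detected`` the values
    strictly beyond the threshold.  Returns ``None`` (undefined; NDAS
    upstream) when nothing lies beyond the threshold.
    """
    _check_tail(tail)
    if tail == "upper" and threshold < null.mu_hat:
        raise ThresholdSideError(
            f"upper-tail threshold {threshold} lies below mu_hat {null.mu_hat}"
        )
    if tail == "lower" and threshold > null.mu_hat:
        raise ThresholdSideError(
            f"lower-tail threshold {threshold} lies above mu_hat {null.mu_hat}"
        )
    finite, _ = _finite(values)
    n_detected = int((finite > threshold).sum() if tail == "upper" else (finite < threshold).sum())
    if n_detected == 0:
        return None
    expected_false = finite.size * null.tail_probability(threshold, tail)
    return float(min(100.0, 100.0 * expected_false / n_detected))


def _check_tail(tail: str) -> None:
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def select_threshold(
    null: GaussianNull,
    values,
    fdr_target: float = DEFAULT_FDR_TARGET,
    tail: Tail = "upper",
) -> tuple[float | None, float | None]:
    """Least extreme threshold whose estimated FDR meets the target.

    Candidate thresholds are placed at every observed value beyond
    ``mu_hat`` in the requested tail, scanned moving outward; detections
    are strict (a value equal to the threshold is not detected).  Returns
    ``(threshold, fdr_percent)``, or ``(None, None)`` for NDAS.
    """
    _check_tail(tail)
    if not 0 < fdr_target <= 100:
        raise ValueError(f"fdr_target must be in (0, 100], got {fdr_target}")
    finite, _ = _finite(values)
    order = np.sort(finite)
    n = order.size
    if tail == "upper":
        cand = np.unique(order[order > null.mu_hat])  # ascending = moving outward
        n_det = n - np.searchsorted(order, cand, side="right")
    else:
        cand = np.unique(order[order < null.mu_hat])[::-1]  # descending = outward
        n_det = np.searchsorted(order, cand, side="left")
    if cand.size == 0:
        return None, None
    z = (cand - null.mu_hat) / null.sigma_hat
    p = stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_det > 0, np.minimum(100.0, 100.0 * n * p / np.maximum(n_det, 1)), np.inf)
    ok = np.flatnonzero((n_det > 0) & (fdr <= fdr_target))
    if ok.size == 0:
        return None, None
    i = int(ok[0])
    return float(cand[i]), float(fdr[i])


def _detect_with_null(variable, null: GaussianNull, fdr_target: float) -> DetectionResult:
    from .design import DiscriminationVariable  # local import; no cycle at module load

    if isinstance(variable, DiscriminationVariable):
        values = variable.values
        variable_id = variable.variable_id
    else:
        values = pd.Series(np.asarray(variable, dtype=float))
        variable_id = "values"
    finite, labels = _finite(values)
    if labels is None:
        labels = np.arange(finite.size)
    tails = {}
    for tail in ("upper", "lower"):
        thr, fdr = select_threshold(null, finite, fdr_target, tail)
        if thr is None:
            tails[tail] = TailDetection(NDAS, None, frozenset(), None)
            logger.info("%s: %s tail NDAS at FDR target %.3g%%", variable_id, tail, fdr_target)
        else:
            mask = finite > thr if tail == "upper" else finite < thr
            tails[tail] = TailDetection(DETECTED, thr, frozenset(labels[mask]), fdr)
            logger.info(
                "%s: %s tail threshold %.4g, %d probes, estimated FDR %.3g%%",
                variable_id, tail, thr, int(mask.sum()), fdr,
            )
    return DetectionResult(
        variable_id=variable_id,
        null=null,
        upper=tails["upper"],
        lower=tails["lower"],
        n_total=finite.size,
        probe_ids=frozenset(labels),
    )


def detect(
    variable,
    q_lo: float = DEFAULT_WINDOW[0],
    q_hi: float = DEFAULT_WINDOW[1],
    fdr_target: float = DEFAULT_FDR_TARGET,
) -> DetectionResult:
    """Full quantile-deconvolution detection on one discrimination variable.

    Fits one Gaussian null on the central window, then selects a threshold
    independently in each tail at the FDR target.  Accepts a
    :class:`~qgdemar.design.DiscriminationVariable` or a plain array/Series
    of per-probe values.
    """
    from .design import DiscriminationVariable

    values = variable.values if isinstance(variable, DiscriminationVariable) else variable
    null = fit_gaussian_null(values, q_lo, q_hi)
    return _detect_with_null(variable, null, fdr_target)


def control_chart_detect(variable, fdr_target: float = DEFAULT_FDR_TARGET) -> DetectionResult:
    """Non-deconvolved comparator: control-chart limits from the full sample.

    Identical detection machinery, but the null is the sample mean and
    standard deviation of all values.  On contaminated data this inflates
    the scale and detects fewer true outliers than :func:`detect`.
    """
    from .design import DiscriminationVariable

    values = variable.values if isinstance(variable, DiscriminationVariable) else variable
    null = fit_full_sample_null(values)
    return _detect_with_null(variable, null, fdr_target)
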