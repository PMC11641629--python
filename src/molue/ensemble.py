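"""Ensemble aggregation, spread features, error thresholds, and
error-distribution diagnostics.

The ensemble prediction is the (optionally weighted) mean of the member
predictions.  Three spread statistics quantify member disagreement:

* ``M_s1`` — mean absolute deviation of member predictions from the
  ensemble prediction,
* ``M_s2`` — root-mean-square deviation,
* ``M_m``  — range (largest minus smallest member prediction).

A prediction is *unsatisfactory* when its absolute error exceeds the
threshold ``D_t``, chosen as the empirical quantile of the absolute
errors so that a target fraction (85% by default, i.e. 15%
unsatisfactory) of the data set is satisfactory.  Absolute errors of
the tasks this framework targets are far better described by an
exponential than a normal distribution, which is why the framework
predicts threshold-exceedance probabilities rather than standard
deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

DEFAULT_SATISFIED_FRACTIONS = (0.80, 0.85, 0.90, 0.95)


def ensemble_prediction(
    model_preds: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted mean of the member predictions (equal weights default)."""
    p = np.asarray(model_preds, float)
    if p.size < 1:
        raise ValueError("at least one model prediction required")
    if weights is None:
        return float(p.mean())
    w = np.asarray(weights, float)
    if w.shape != p.shape:
        raise ValueError("weights length does not match predictions")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return float(w @ p)


def spread_features(
    model_preds: Sequence[float], y_ens: float
) -> tuple[float, float, float]:
    """Return ``(M_s1, M_s2, M_m)`` for one ensemble.

    ``M_s1 = mean|p_i - y_ens|``, ``M_s2 = sqrt(mean (p_i - y_ens)^2)``,
    ``M_m = max(p) - min(p)``.  Jensen's inequality gives
    ``M_s1 <= M_s2`` for every input.
    """
    p = np.asarray(model_preds, float)
    if p.size < 2:
        raise ValueError("spread features require at least 2 models")
    dev = p - y_ens
    m_s1 = float(np.mean(np.abs(dev)))
    m_s2 = float(np.sqrt(np.mean(dev**2)))
    m_m = float(p.max() - p.min())
    return m_s1, m_s2, m_m


@dataclass(frozen=True)
class ErrorThresholds:
    """Map from the satisfied fraction f to the error threshold D_t."""

    thresholds: dict[float, float]

    def __post_init__(self) -> None:
        fs = sorted(self.thresholds)
        dts = [self.thresholds[f] for f in fs]
        if any(b <= a for a, b in zip(dts, dts[1:])):
            raise ValueError("D_t must be strictly increasing in f")

    def __getitem__(self, f: float) -> float:
        return self.thresholds[f]


def compute_threshold(abs_errors: Sequence[float], satisfied_fraction: float) -> float:
    """Empirical f-quantile of the absolute errors.

    Linear-interpolation (type-7) quantile; downstream labeling uses a
    strict ``>`` comparison, so for continuous errors the unsatisfactory
    fraction is ``1 - f`` up to 1/n.
    """
    e = np.asarray(abs_errors, float)
    if e.size == 0:
        raise ValueError("abs_errors must be non-empty")
    if not (0.0 < satisfied_fraction < 1.0):
        raise ValueError("satisfied_fraction must lie in (0, 1)")
    return float(np.quantile(e, satisfied_fraction))


def compute_thresholds(
    abs_errors: Sequence[float],
    fractions: Sequence[float] = DEFAULT_SATISFIED_FRACTIONS,
) -> ErrorThresholds:
    """D_t for each satisfied fraction (default 80/85/90/95%)."""
    return ErrorThresholds(
        {f: compute_threshold(abs_errors, f) for f in fractions}
    )


def label_predictions(
    abs_errors: Sequence[float], d_t: float
) -> np.ndarray:
    """Binary labels: 1 = unsatisfactory, i.e. ``|error| > D_t`` strictly."""
    e = np.asarray(abs_errors, float)
    return (e > d_t).astype(int)


Family = Literal["normal", "exponential", "cauchy"]


@dataclass(frozen=True)
class ErrorDistributionFit:
    """Maximum-likelihood fit of an error-distribution family.

    For the exponential family the fit is on absolute errors and
    ``params`` is ``(lambda,)``; normal and Cauchy are fit on signed
    errors with ``params = (loc, scale)``.
    """

    family: Family
    params: tuple[float, ...]
    log_likelihood: float

    @property
    def rate(self) -> float:
        if self.family != "exponential":
            raise ValueError("rate is defined for the exponential family only")
        return self.params[0]


def fit_error_distribution(
    errors: Sequence[float], family: Family
) -> ErrorDistributionFit:
    """Fit one error-distribution family by maximum likelihood.

    ``exponential`` expects absolute errors and uses the closed-form
    MLE ``lambda = 1 / mean``; ``normal`` and ``cauchy`` accept signed
    errors (Cauchy via numeric MLE).
    """
    x = np.asarray(errors, float)
    if x.size < 10:
        raise ValueError("at least 10 samples required")
    if family == "exponential":
        ax = np.abs(x)
        mean = ax.mean()
        if mean <= 0:
            raise ValueError("mean absolute error must be positive")
        lam = 1.0 / mean
        ll = float(x.size * np.log(lam) - lam * ax.sum())
        return ErrorDistributionFit("exponential", (lam,), ll)
    if family == "normal":
        loc, scale = float(x.mean()), float(x.std())
        if scale <= 0:
            raise ValueError("degenerate sample: zero variance")
        ll = float(stats.norm.logpdf(x, loc, scale).sum())
        return ErrorDistributionFit("normal", (loc, scale), ll)
    if family == "cauchy":
        loc, scale = stats.cauchy.fit(x)
        ll = float(stats.cauchy.logpdf(x, loc, scale).sum())
        return ErrorDistributionFit("cauchy", (float(loc), float(scale)), ll)
    raise ValueError(f"unknown family {family!r}")


def tail_probability(fit: ErrorDistributionFit, t: float) -> float:
    """P(|error| > t) under the fitted distribution."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    if fit.family == "exponential":
        return float(np.exp(-fit.rate * t))
    if fit.family == "normal":
        loc, scale = fit.params
        return float(stats.norm.sf(t, loc, scale) + stats.norm.cdf(-t, loc, scale))
    loc, scale = fit.params
    return float(stats.cauchy.sf(t, loc, scale) + stats.cauchy.cdf(-t, loc, scale))
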