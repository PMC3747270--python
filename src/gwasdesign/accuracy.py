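"""Expected genomic prediction accuracy from marker-by-marker regression.

Effects of ``M`` markers jointly explaining a fraction ``h2`` of phenotypic
variance are estimated by least squares on ``N`` training records; each
estimate carries a prediction error variance of roughly ``sigma^2 / N``.
The expected squared correlation between true and estimated genetic values
is the ratio of true to estimated genetic variance,

    r^2 = N*h2 / (N*h2 + M)  =  tau*h2 / (tau*h2 + 1),     tau = N/M,

with ``h2`` expressed on the scale of the analysed response:

* quantitative traits — the trait-scale ``h2`` directly (residual variance
  approximated by the phenotypic variance, 1);
* disease, population sample — ``h2`` transformed to the 0/1 observed
  scale at prevalence ``K`` (residual variance ``K*(1-K)``);
* disease, ascertained case-control sample — ``h2`` transformed with the
  case-control variant at case fraction ``P`` (residual variance
  ``P*(1-P)``); the per-marker ascertainment inflation factor is taken as
  1, which holds once the signal is spread over enough markers (roughly
  ``M > 20``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

from .liability import h2_obs_cc, h2_obs_population

__all__ = [
    "AccuracySpec",
    "AccuracyResult",
    "accuracy_quantitative",
    "accuracy_disease_population",
    "accuracy_disease_cc",
]

# Below this marker count the per-marker inflation factor f is no longer
# close to 1 and the case-control formula leaves its validity regime.
_MIN_MARKERS_CC = 20


@dataclass(frozen=True)
class AccuracySpec:
    """Inputs for an expected-accuracy calculation."""

    N: int
    M: int
    h2: float
    K: float = 0.5
    P: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError(
                f"N and M must be >= 1; got N={self.N!r}, M={self.M!r}"
            )
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must lie in [0, 1]; got h2={self.h2!r}")

    @property
    def tau(self) -> float:
        """Records per marker, ``N/M``."""
        return self.N / self.M


@dataclass(frozen=True)
class AccuracyResult:
    """Expected correlation ``r`` between true and estimated genetic values.

    ``h2_working`` is the observed-scale variance proportion that entered
    the accuracy formula.
    """

    r: float
    r2: float
    h2_working: float


def _accuracy(N: int, M: int, h2_working: float) -> AccuracyResult:
    r2 = N * h2_working / (N * h2_working + M)
    return AccuracyResult(r=sqrt(r2), r2=r2, h2_working=h2_working)


def accuracy_quantitative(N: int, M: int, h2: float) -> AccuracyResult:
    """Expected accuracy for a quantitative trait: ``r^2 = N*h2/(N*h2 + M)``."""
    spec = AccuracySpec(N=N, M=M, h2=h2)
    return _accuracy(spec.N, spec.M, spec.h2)


def accuracy_disease_population(
    N: int, M: int, h2: float, K: float
) -> AccuracyResult:
    """Expected accuracy for disease risk trained on a population sample.

    The liability-scale ``h2`` is first moved to the 0/1 observed scale at
    prevalence ``K``.
    """
    spec = AccuracySpec(N=N, M=M, h2=h2, K=K)
    return _accuracy(spec.N, spec.M, h2_obs_population(spec.h2, spec.K))


def accuracy_disease_cc(
    N: int, M: int, h2: float, K: float, P: float
) -> AccuracyResult:
    """Expected accuracy for disease risk trained on an ascertained sample.

    Uses the case-control observed-scale transformation at prevalence
    ``K`` and case fraction ``P``; coincides with
    :func:`accuracy_disease_population` when ``P = K``.  Warns when
    ``M < 20``, outside the regime in which the per-marker inflation
    factor is close to 1.
    """
    spec = AccuracySpec(N=N, M=M, h2=h2, K=K, P=P)
    if spec.M < _MIN_MARKERS_CC:
        warnings.warn(
            f"case-control accuracy formula assumes the signal is spread "
            f"over at least ~{_MIN_MARKERS_CC} markers; M={spec.M} is below "
            f"that, so the unit inflation-factor approximation may fail",
            UserWarning,
            stacklevel=2,
        )
    return _accuracy(spec.N, spec.M, h2_obs_cc(spec.h2, spec.K, spec.P))
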