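"""Non-centrality parameters and power for five GWAS designs.

The 1-df chi-square association test has power determined entirely by its
non-centrality parameter (NCP, lambda).  Five designs are supported:

* ``QT_POP`` — quantitative response, population sample;
* ``BT_POP`` — binary (0/1 disease) response, population sample;
* ``BT_CC``  — binary response, ascertained case-control sample;
* ``QT_CC``  — quantitative (liability) response, ascertained
  case-control sample;
* ``QB_CC``  — quantitative response recorded in cases only (controls
  scored zero), ascertained case-control sample; e.g. a severity score
  measured only in affected individuals.

``q2`` is the proportion of liability (or trait) variance explained by the
tested marker or marker set; the single parameter accommodates multi-locus
tests.  The default NCPs are the small-``q2`` forms, accurate in the
single-marker regime; ``exact_inflation=True`` substitutes the
ascertainment-inflated marker variance for multi-locus ``q2``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from scipy import stats

from .liability import (
    genetic_variance_cc,
    h2_obs_cc,
    h2_obs_population,
    make_design,
)

__all__ = [
    "Design",
    "PowerSpec",
    "PowerResult",
    "ncp_qt_pop",
    "ncp_bt_pop",
    "ncp_bt_cc",
    "ncp_qt_cc",
    "ncp_qb_cc",
    "power_from_ncp",
    "calculate_power",
]


class Design(str, enum.Enum):
    """Association study design (response coding x sampling scheme)."""

    QT_POP = "QT_POP"
    BT_POP = "BT_POP"
    BT_CC = "BT_CC"
    QT_CC = "QT_CC"
    QB_CC = "QB_CC"

    def __str__(self) -> str:  # plain value in tables / CLI output
        return self.value


def _check_common(N: float, q2: float) -> None:
    if N < 1 or int(N) != N:
        raise ValueError(f"N must be a positive integer; got N={N!r}")
    if not (0.0 <= q2 < 1.0):
        raise ValueError(f"q2 must lie in [0, 1); got q2={q2!r}")


def ncp_qt_pop(N: int, q2: float) -> float:
    """NCP for a quantitative response in a population sample: ``N * q2``."""
    _check_common(N, q2)
    return N * q2


def ncp_bt_pop(N: int, q2: float, K: float) -> float:
    """NCP for a binary trait in a population sample.

    ``q2`` is transformed from the liability scale to the 0/1 observed
    scale at prevalence ``K``: ``lambda = N * q2 * z**2 / (K*(1-K))``.
    """
    _check_common(N, q2)
    return N * h2_obs_population(q2, K)


def ncp_bt_cc(
    N: int, q2: float, K: float, P: float, exact_inflation: bool = False
) -> float:
    """NCP for a binary response in an ascertained case-control sample.

    Default (small ``q2``): ``lambda = N * q2 * z**2 * P*(1-P) /
    (K**2 * (1-K)**2)``, which reduces to :func:`ncp_bt_pop` when
    ``P = K``.  With ``exact_inflation`` the marker variance entering the
    transformation is the ascertainment-inflated
    :func:`~gwasdesign.liability.genetic_variance_cc` of the tested set
    rather than its population value ``q2``.
    """
    _check_common(N, q2)
    q2_eff = genetic_variance_cc(q2, K, P) if exact_inflation else q2
    d = make_design(K, P)
    return N * q2_eff * d.z**2 * P * (1.0 - P) / (K**2 * (1.0 - K) ** 2)


def ncp_qt_cc(
    N: int, q2: float, K: float, P: float, exact_inflation: bool = False
) -> float:
    """NCP for a quantitative (liability) response in an ascertained sample.

    The covariance between the liability response and a marker explaining
    ``q2`` of liability variance is ``q2 * var_lcc`` in the ascertained
    mixture (within-group covariances shrink with the group liability
    variances, the between-group term restores the rest), so to first
    order ``lambda = N * q2 * var_lcc``.  With ``exact_inflation`` the
    marker's own inflated variance enters the denominator:
    ``lambda = N * q2**2 * var_lcc / var_g_cc(q2)``.
    """
    _check_common(N, q2)
    d = make_design(K, P)
    if exact_inflation:
        if q2 == 0.0:
            return 0.0
        var_g = genetic_variance_cc(q2, K, P)
        return N * q2**2 * d.var_lcc / var_g
    return N * q2 * d.var_lcc


def ncp_qb_cc(N: int, q2: float, K: float, P: float) -> float:
    """NCP for a quantitative response available in cases only.

    The recorded response is a mixture: the (truncated-normal) liability
    for cases, zero for controls.  Its variance is
    ``var(y*) = P*v_case + P*(1-P)*i_case**2`` and its covariance with a
    marker explaining ``q2`` of liability variance is
    ``q2 * [P*v_case + P*(1-P)*i_case*(i_case - i_ctrl)]``, giving

    ``lambda = N * q2 * cov_factor**2 / var(y*)``

    with ``cov_factor`` the bracketed term.  Power is very close to the
    binary-response ``BT_CC`` design throughout the ascertained regime.
    """
    _check_common(N, q2)
    d = make_design(K, P)
    cov_factor = P * d.v_case + P * (1.0 - P) * d.i_case * d.mean_diff
    var_mix = P * d.v_case + P * (1.0 - P) * d.i_case**2
    return N * q2 * cov_factor**2 / var_mix


def power_from_ncp(ncp: float, alpha: float, df: int = 1) -> float:
    """Power of the chi-square test with non-centrality ``ncp``.

    The survival function of the noncentral chi-square(``df``, ``ncp``)
    evaluated at the ``1 - alpha`` quantile of the central
    chi-square(``df``); a two-sided test on 1 df by default.  At
    ``ncp = 0`` this returns ``alpha`` exactly.
    """
    if ncp < 0:
        raise ValueError(f"ncp must be non-negative; got {ncp!r}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha!r}")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, ncp)) if ncp > 0 else alpha


_NCP_DISPATCH = {
    Design.QT_POP: lambda s: ncp_qt_pop(s.N, s.q2),
    Design.BT_POP: lambda s: ncp_bt_pop(s.N, s.q2, s.K),
    Design.BT_CC: lambda s: ncp_bt_cc(s.N, s.q2, s.K, s.P, s.exact_inflation),
    Design.QT_CC: lambda s: ncp_qt_cc(s.N, s.q2, s.K, s.P, s.exact_inflation),
    Design.QB_CC: lambda s: ncp_qb_cc(s.N, s.q2, s.K, s.P),
}


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a power calculation.

    ``K`` is ignored for ``QT_POP``; ``P`` only matters for the
    case-control designs.
    """

    N: int
    q2: float
    design: Design
    K: float = 0.5
    P: float = 0.5
    alpha: float = 0.05
    exact_inflation: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", Design(self.design))
        _check_common(self.N, self.q2)
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha!r}")


@dataclass(frozen=True)
class PowerResult:
    """NCP and power of a 1-df chi-square association test."""

    ncp: float
    power: float
    df: int = 1
    spec: PowerSpec | None = field(default=None, repr=False)


def calculate_power(spec: PowerSpec) -> PowerResult:
    """Dispatch the NCP formula for ``spec.design`` and evaluate power."""
    ncp = _NCP_DISPATCH[Design(spec.design)](spec)
    return PowerResult(
        ncp=ncp, power=power_from_ncp(ncp, spec.alpha), spec=spec
    )
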