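"""Truncated-normal geometry of the liability threshold model.

A binary disease phenotype is modelled through an unobserved continuous
liability, standard normal in the population.  Individuals whose liability
exceeds the threshold ``t = Phi^{-1}(1 - K)`` are affected, where ``K`` is
the population prevalence.  Ascertained case-control samples over-represent
cases (case fraction ``P > K``), which inflates the liability, genetic and
marker variances relative to the population.  Every downstream power and
prediction-accuracy formula is built on the quantities collected here:

* ``t`` — liability threshold (standard-deviation units);
* ``z`` — standard normal density at ``t``;
* ``i_case = z/K`` — mean liability of cases (selection intensity);
* ``i_ctrl = -z/(1-K)`` — mean liability of controls;
* ``v_case``, ``v_ctrl`` — within-group liability variances under
  truncation;
* ``var_lcc`` — liability variance in the ``P:(1-P)`` case-control mixture.

Scale transformations between the liability scale and the 0/1 observed
scale (population and ascertained case-control variants) and the
ascertainment-inflated genetic/residual variances live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "LiabilityDesign",
    "make_design",
    "h2_obs_population",
    "h2_obs_cc",
    "genetic_variance_cc",
    "residual_variance_cc",
]

# K (or P) closer than this to 0 or 1 loses all precision in z/K.
_PROB_EPS = 1e-8


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not (_PROB_EPS < value < 1.0 - _PROB_EPS):
        raise ValueError(
            f"{name} must lie strictly inside (0, 1) "
            f"(at least {_PROB_EPS} from either end); got {name}={value!r}"
        )
    return value


def _check_h2(h2: float) -> float:
    h2 = float(h2)
    if not (0.0 <= h2 <= 1.0):
        raise ValueError(f"h2 must lie in [0, 1]; got h2={h2!r}")
    return h2


@dataclass(frozen=True)
class LiabilityDesign:
    """Prevalence/ascertainment geometry of a liability-threshold design.

    Attributes
    ----------
    K : float
        Population disease prevalence.
    P : float
        Proportion of cases in the analysed sample.
    t : float
        Liability threshold, ``Phi^{-1}(1-K)``.
    z : float
        Standard normal density at ``t``.
    i_case, i_ctrl : float
        Mean liability of cases (``z/K``) and controls (``-z/(1-K)``).
    v_case, v_ctrl : float
        Liability variance within cases / controls (upper / lower
        truncation of the standard normal at ``t``).
    var_lcc : float
        Liability variance in the ``P:(1-P)`` case-control mixture;
        exceeds 1 whenever cases are over-sampled (``P > K``).
    """

    K: float
    P: float
    t: float
    z: float
    i_case: float
    i_ctrl: float
    v_case: float
    v_ctrl: float
    var_lcc: float

    @property
    def mean_diff(self) -> float:
        """Difference in mean liability between cases and controls."""
        return self.i_case - self.i_ctrl


def make_design(K: float, P: float) -> LiabilityDesign:
    """Build the liability geometry for prevalence ``K`` and case fraction ``P``.

    The within-group variances follow the standard truncated-normal
    results: for cases (upper truncation, mean ``i``)
    ``v_case = 1 - i*(i - t)``; for controls (lower truncation, mean
    ``m = i_ctrl``) ``v_ctrl = 1 + t*m - m**2``.  The mixture variance adds
    the between-group term ``P*(1-P)*(i_case - i_ctrl)**2``.

    Raises
    ------
    ValueError
        If ``K`` or ``P`` is outside the open interval (0, 1).
    """
    K = _check_prob(K, "K")
    P = _check_prob(P, "P")
    t = float(stats.norm.isf(K))
    z = float(stats.norm.pdf(t))
    i_case = z / K
    i_ctrl = -z / (1.0 - K)
    v_case = 1.0 - i_case * (i_case - t)
    v_ctrl = 1.0 + t * i_ctrl - i_ctrl**2
    var_lcc = (
        P * v_case
        + (1.0 - P) * v_ctrl
        + P * (1.0 - P) * (i_case - i_ctrl) ** 2
    )
    return LiabilityDesign(
        K=K, P=P, t=t, z=z,
        i_case=i_case, i_ctrl=i_ctrl,
        v_case=v_case, v_ctrl=v_ctrl,
        var_lcc=var_lcc,
    )


def h2_obs_population(h2: float, K: float) -> float:
    """Liability-scale variance proportion on the 0/1 observed scale.

    In a population sample the classical transformation is
    ``h2_obs = h2 * z**2 / (K * (1 - K))``.

    Parameters
    ----------
    h2 : float
        Variance proportion on the liability scale, in [0, 1].
    K : float
        Population prevalence.
    """
    h2 = _check_h2(h2)
    d = make_design(K, 0.5)  # P unused
    return h2 * d.z**2 / (K * (1.0 - K))


def h2_obs_cc(h2: float, K: float, P: float) -> float:
    """Observed-scale variance proportion in an ascertained case-control sample.

    ``h2_obs_cc = h2 * z**2 * P*(1-P) / (K**2 * (1-K)**2)``; reduces to the
    population transformation when ``P = K``.
    """
    h2 = _check_h2(h2)
    d = make_design(K, P)
    return h2 * d.z**2 * P * (1.0 - P) / (K**2 * (1.0 - K) ** 2)


def genetic_variance_cc(h2: float, K: float, P: float) -> float:
    """Liability-scale genetic variance in an ascertained case-control sample.

    Selecting on liability shrinks the genetic variance within each of the
    case and control groups and separates the group genetic means
    (``h2*i_case`` vs ``h2*i_ctrl``); mixing the groups at ``P:(1-P)`` then
    yields

    ``h2*[P*(1 - h2*(1 - v_case)) + (1-P)*(1 - h2*(1 - v_ctrl))]
    + P*(1-P)*h2**2*(i_case - i_ctrl)**2``.

    For an infinitesimal variance fraction the inflation vanishes
    (``value/h2 -> 1`` as ``h2 -> 0``); for appreciable ``h2`` with
    ``P > K`` the variance is inflated relative to ``h2``.
    """
    h2 = _check_h2(h2)
    d = make_design(K, P)
    within = P * (1.0 - h2 * (1.0 - d.v_case)) + (1.0 - P) * (
        1.0 - h2 * (1.0 - d.v_ctrl)
    )
    between = P * (1.0 - P) * h2**2 * d.mean_diff**2
    return h2 * within + between


def residual_variance_cc(h2: float, K: float, P: float) -> float:
    """Liability-scale residual (non-genetic) variance in the ascertained sample.

    Mirror image of :func:`genetic_variance_cc` with the roles of the
    genetic fraction ``h2`` and the residual fraction ``1 - h2`` swapped.
    """
    h2 = _check_h2(h2)
    return genetic_variance_cc(1.0 - h2, K, P)
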