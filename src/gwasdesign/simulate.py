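"""Liability-threshold cohort simulator for validating power and accuracy.

Cohorts follow an additive multilocus model: ``M`` independent biallelic
markers with allele frequency ``p`` (0.5 by default), per-marker allele
substitution effects scaled so the markers jointly explain ``h2`` of the
unit liability variance, Gaussian residuals making up the remainder, and
disease status assigned by thresholding the liability at
``t = Phi^{-1}(1-K)``.  Ascertained case-control cohorts are produced by
batched rejection sampling from the population model until the case and
control quotas ``N*P`` and ``N*(1-P)`` are filled.

Three response codings are available:

* ``BT`` — 0/1 disease status;
* ``QT`` — the liability itself (an ideal quantitative endophenotype);
* ``QB`` — liability for cases, zero for controls (e.g. a severity score
  recorded only in affected individuals).

:func:`empirical_power` runs per-marker marginal regressions across
replicates and reports the rejection fraction; :func:`empirical_accuracy`
trains per-marker regressions on the 0/1 response and correlates predicted
with true genetic values in an independent population validation cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .liability import make_design

__all__ = [
    "SimConfig",
    "CohortData",
    "SimSummary",
    "simulate_cohort",
    "association_scan",
    "empirical_power",
    "empirical_accuracy",
    "write_cohort_tsv",
]

# Rejection-sampling batches are capped so a batch never exceeds ~2e7
# genotype entries (about 20 MB at int8).
_MAX_BATCH_ELEMENTS = 20_000_000

_RESPONSES = ("BT", "QT", "QB")
_EFFECT_DISTRIBUTIONS = ("equal", "normal", "exponential")


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    Parameters
    ----------
    M, N : int
        Marker count and analysed sample size.
    h2 : float
        Liability variance jointly explained by the ``M`` markers, in
        [0, 1); each marker explains ``h2/M``.
    K, P : float
        Population prevalence and case fraction of the analysed sample
        (``P`` only applies when ``ascertained``).
    design : str
        Response coding, one of ``BT``, ``QT``, ``QB``.
    ascertained : bool
        Fill case/control quotas ``N*P`` / ``N*(1-P)`` by rejection
        sampling instead of taking ``N`` population draws.
    allele_freq : float
        Per-marker allele frequency.
    effect_distribution : str
        ``equal`` (identical positive effects), ``normal`` or
        ``exponential``; the latter two are rescaled so the expected
        genetic variance is exactly ``h2``.
    n_replicates, alpha, seed : simulation bookkeeping.
    N_validation : int
        Size of the population validation cohort in accuracy runs.
    max_draws : int
        Rejection-sampling budget (population draws per replicate).
    """

    M: int
    N: int
    h2: float
    K: float = 0.1
    P: float = 0.5
    design: str = "BT"
    ascertained: bool = False
    allele_freq: float = 0.5
    effect_distribution: str = "equal"
    n_replicates: int = 100
    alpha: float = 0.05
    seed: int | None = None
    N_validation: int = 2000
    max_draws: int = 10_000_000

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError(f"M and N must be >= 1; got M={self.M}, N={self.N}")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError(f"h2 must lie in [0, 1); got {self.h2!r}")
        if self.design not in _RESPONSES:
            raise ValueError(
                f"design must be one of {_RESPONSES}; got {self.design!r}"
            )
        if self.effect_distribution not in _EFFECT_DISTRIBUTIONS:
            raise ValueError(
                f"effect_distribution must be one of {_EFFECT_DISTRIBUTIONS}; "
                f"got {self.effect_distribution!r}"
            )
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError(f"allele_freq must lie in (0,1); got {self.allele_freq!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        make_design(self.K, self.P)  # validates K, P


@dataclass
class CohortData:
    """A simulated cohort with its generating quantities.

    ``genotypes`` holds allele counts in {0, 1, 2} as ``int8``;
    ``g``, ``e`` and ``liability`` are the genetic value, residual and
    their sum; ``status`` is the thresholded disease indicator;
    ``response`` is the configured coding; ``beta`` the true per-marker
    effects; ``n_draws`` the population draws consumed (equals ``N`` for
    population cohorts).
    """

    genotypes: np.ndarray
    g: np.ndarray
    e: np.ndarray
    liability: np.ndarray
    status: np.ndarray
    response: np.ndarray
    beta: np.ndarray
    n_draws: int


@dataclass(frozen=True)
class SimSummary:
    """Replicate-averaged simulation estimate with empirical uncertainty.

    ``se`` is the primary empirical standard error (binomial across all
    marker tests for power; across replicates for accuracy);
    ``se_replicate`` is always the between-replicate standard error of the
    mean, reported separately because for power the two conventions
    differ.
    """

    estimate: float
    se: float
    se_replicate: float
    n_replicates: int
    n_tests: int
    seed: int | None
    scenario: dict = field(repr=False, default_factory=dict)


def _draw_effects(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-marker substitution effects with expected var(g) exactly h2."""
    p = config.allele_freq
    marker_var = 2.0 * p * (1.0 - p)
    if config.effect_distribution == "equal":
        return np.full(config.M, np.sqrt(config.h2 / (config.M * marker_var)))
    if config.effect_distribution == "normal":
        beta = rng.standard_normal(config.M)
    else:  # exponential
        beta = rng.standard_exponential(config.M)
    ss = float(np.sum(beta**2)) * marker_var
    if ss == 0.0:  # pathological draw; fall back to equal effects
        return np.full(config.M, np.sqrt(config.h2 / (config.M * marker_var)))
    return beta * np.sqrt(config.h2 / ss)


def _population_batch(
    n: int, config: SimConfig, beta: np.ndarray, rng: np.random.Generator
):
    """Draw ``n`` individuals from the population model."""
    p = config.allele_freq
    x = rng.binomial(2, p, size=(n, config.M)).astype(np.int8)
    g = (x - 2.0 * p) @ beta  # centred so liability is ~N(0,1)
    e = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=n)
    y = g + e
    return x, g, e, y


def simulate_cohort(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    beta: np.ndarray | None = None,
) -> CohortData:
    """Simulate one cohort under ``config``.

    Population mode draws exactly ``N`` individuals; ascertained mode
    rejection-samples the population until ``round(N*P)`` cases and the
    complementary number of controls are collected (cases are the
    individuals whose liability exceeds the threshold).

    Parameters
    ----------
    rng :
        A :class:`numpy.random.Generator`, a seed, or None (fresh
        entropy).
    beta :
        True effects to reuse (e.g. for a matched validation cohort);
        drawn according to ``config.effect_distribution`` if omitted.

    Raises
    ------
    RuntimeError
        If the case/control quotas are not filled within
        ``config.max_draws`` population draws.
    """
    rng = np.random.default_rng(rng)
    if beta is None:
        beta = _draw_effects(config, rng)
    t = make_design(config.K, config.P).t

    if not config.ascertained:
        x, g, e, y = _population_batch(config.N, config, beta, rng)
        status = y > t
        n_draws = config.N
    else:
        n_cases = int(round(config.N * config.P))
        n_ctrls = config.N - n_cases
        max_batch = max(1, _MAX_BATCH_ELEMENTS // config.M)
        parts: list[tuple] = []
        have_cases = have_ctrls = 0
        n_draws = 0
        while have_cases < n_cases or have_ctrls < n_ctrls:
            if n_draws >= config.max_draws:
                raise RuntimeError(
                    f"ascertainment quota not reached within max_draws="
                    f"{config.max_draws}: K={config.K}, P={config.P}, "
                    f"N={config.N}; collected {have_cases}/{n_cases} cases "
                    f"and {have_ctrls}/{n_ctrls} controls after {n_draws} draws"
                )
            # expected draws to finish, padded 10%, clipped to budget/batch cap
            need_c = n_cases - have_cases
            need_u = n_ctrls - have_ctrls
            guess = max(
                int(1.1 * need_c / config.K) if need_c > 0 else 0,
                int(1.1 * need_u / (1.0 - config.K)) if need_u > 0 else 0,
                256,
            )
            n_batch = min(guess, max_batch, config.max_draws - n_draws)
            x, g, e, y = _population_batch(n_batch, config, beta, rng)
            n_draws += n_batch
            is_case = y > t
            take_c = np.flatnonzero(is_case)[: n_cases - have_cases]
            take_u = np.flatnonzero(~is_case)[: n_ctrls - have_ctrls]
            take = np.concatenate([take_c, take_u])
            if take.size:
                parts.append((x[take], g[take], e[take], y[take]))
            have_cases += take_c.size
            have_ctrls += take_u.size
        x = np.concatenate([p[0] for p in parts])
        g = np.concatenate([p[1] for p in parts])
        e = np.concatenate([p[2] for p in parts])
        y = np.concatenate([p[3] for p in parts])
        status = y > t
        # interleave cases and controls deterministically
        order = rng.permutation(config.N)
        x, g, e, y, status = x[order], g[order], e[order], y[order], status[order]

    if config.design == "BT":
        response = status.astype(float)
    elif config.design == "QT":
        response = y.copy()
    else:  # QB: liability for cases, zero for controls
        response = np.where(status, y, 0.0)

    return CohortData(
        genotypes=x, g=g, e=e, liability=y, status=status,
        response=response, beta=beta, n_draws=n_draws,
    )


def association_scan(
    genotypes: np.ndarray, response: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker marginal association tests.

    Each marker is tested by simple linear regression of the response on
    the allele count; the test statistic is the score form
    ``N * r**2`` (``r`` the sample correlation) referred to chi-square on
    1 df, asymptotically equivalent to the Wald ``t**2``.  Monomorphic
    markers get statistic 0 and p-value 1.

    Returns
    -------
    (statistics, p_values) : per-marker arrays of length ``M``.

    Raises
    ------
    ValueError
        If the response has zero variance.
    """
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(response, dtype=float)
    n = x.shape[0]
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ValueError("response has zero variance; nothing to test")
    xc = x - x.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    cross = yc @ xc
    poly = ss_x > 0
    r2 = np.zeros(x.shape[1])
    np.divide(cross**2, ss_x * ss_y, out=r2, where=poly)
    stat = n * r2
    pvals = np.where(poly, stats.chi2.sf(stat, 1), 1.0)
    return stat, pvals


def _replicate_rngs(config: SimConfig) -> Iterable[np.random.Generator]:
    """Independent per-replicate streams from the master seed.

    Spawned from a single :class:`~numpy.random.SeedSequence`, so earlier
    replicates are unchanged when ``n_replicates`` grows.
    """
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(c) for c in ss.spawn(config.n_replicates)]


def _scenario(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def empirical_power(config: SimConfig) -> SimSummary:
    """Empirical power: rejection fraction over all marker tests.

    Each replicate simulates a cohort and tests all ``M`` markers at
    ``config.alpha``; the estimate pools the ``n_replicates * M`` tests.
    ``se`` is the binomial standard error over pooled tests,
    ``se_replicate`` the between-replicate standard error of the mean.
    """
    rejections = np.empty(config.n_replicates)
    for idx, rng in enumerate(_replicate_rngs(config)):
        cohort = simulate_cohort(config, rng)
        if np.ptp(cohort.response) == 0:
            # e.g. zero cases in a rare-disease population cohort: no
            # test can reject on a constant response
            rejections[idx] = 0.0
            continue
        _, pvals = association_scan(cohort.genotypes, cohort.response)
        rejections[idx] = np.mean(pvals < config.alpha)
    n_tests = config.n_replicates * config.M
    power = float(rejections.mean())
    se_binom = float(np.sqrt(max(power * (1.0 - power), 0.0) / n_tests))
    se_rep = (
        float(rejections.std(ddof=1) / np.sqrt(config.n_replicates))
        if config.n_replicates > 1
        else 0.0
    )
    return SimSummary(
        estimate=power, se=se_binom, se_replicate=se_rep,
        n_replicates=config.n_replicates, n_tests=n_tests,
        seed=config.seed, scenario=_scenario(config),
    )


def marginal_effect_estimates(
    genotypes: np.ndarray, response: np.ndarray
) -> np.ndarray:
    """Per-marker least-squares slopes of the response on allele count."""
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(response, dtype=float)
    xc = x - x.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    cross = (y - y.mean()) @ xc
    beta_hat = np.zeros(x.shape[1])
    np.divide(cross, ss_x, out=beta_hat, where=ss_x > 0)
    return beta_hat


def empirical_accuracy(config: SimConfig) -> SimSummary:
    """Empirical genomic prediction accuracy over replicates.

    Per replicate: train per-marker marginal regressions of the 0/1
    disease status on allele counts in the (possibly ascertained)
    training cohort; predict genetic values in an independent population
    validation cohort of ``config.N_validation`` individuals sharing the
    true effects; record ``corr(g, g_hat)``.  The accuracy theory is
    derived on the observed scale, so the training response is always the
    0/1 status regardless of ``config.design``.
    """
    train_cfg = dataclasses.replace(config, design="BT")
    valid_cfg = dataclasses.replace(
        config, design="BT", ascertained=False, N=config.N_validation
    )
    corrs = np.empty(config.n_replicates)
    for idx, rng in enumerate(_replicate_rngs(config)):
        train = simulate_cohort(train_cfg, rng)
        beta_hat = marginal_effect_estimates(train.genotypes, train.response)
        valid = simulate_cohort(valid_cfg, rng, beta=train.beta)
        xc = valid.genotypes - valid.genotypes.mean(axis=0, dtype=float)
        g_hat = xc @ beta_hat
        if g_hat.std() == 0 or valid.g.std() == 0:
            # degenerate predictor (e.g. a zero-case training cohort
            # yields all-zero slopes): no predictive ability
            corrs[idx] = 0.0
        else:
            corrs[idx] = np.corrcoef(valid.g, g_hat)[0, 1]
    acc = float(corrs.mean())
    se_rep = (
        float(corrs.std(ddof=1) / np.sqrt(config.n_replicates))
        if config.n_replicates > 1
        else 0.0
    )
    return SimSummary(
        estimate=acc, se=se_rep, se_replicate=se_rep,
        n_replicates=config.n_replicates, n_tests=config.n_replicates,
        seed=config.seed, scenario=_scenario(config),
    )


def write_cohort_tsv(
    cohort: CohortData, genotype_path, phenotype_path
) -> None:
    """Export a cohort as two TSV files.

    ``genotype_path``: individuals x markers allele counts with a header
    row of marker IDs (``snp1..snpM``).  ``phenotype_path``: columns
    ``id``, ``g``, ``liability``, ``status``, ``response``.
    """
    import pandas as pd

    n, m = cohort.genotypes.shape
    geno = pd.DataFrame(
        cohort.genotypes, columns=[f"snp{j + 1}" for j in range(m)]
    )
    geno.to_csv(genotype_path, sep="\t", index=False)
    pheno = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "g": cohort.g,
            "liability": cohort.liability,
            "status": cohort.status.astype(int),
            "response": cohort.response,
        }
    )
    pheno.to_csv(phenotype_path, sep="\t", index=False)
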