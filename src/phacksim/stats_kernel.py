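"""Closed-form statistics and single-experiment stochastic machinery.

This module is the purely computational core of the simulator: the
effort-to-productivity curve, the exponential effect-size model and its
prior-probability-of-the-null parameterisation, noncentral-*t* test
simulation, critical values, the Šidák family-wise correction used for
truth bookkeeping, outcome classification, and the closed-form
literature false-positive-rate calculator.

Everything here is deterministic given an explicit :class:`numpy.random.Generator`.

The statistical model
---------------------
Each simulated experiment is an independent two-sample *t*-test with
per-group sample size ``E`` (the researcher's effort), so the test
statistic under a true standardised effect ``d`` (Cohen's *d*) follows a
noncentral *t* distribution with ``2E - 2`` degrees of freedom and
noncentrality ``lambda = d * sqrt(E / 2)``.  True effect sizes are drawn
from an exponential distribution with scale ``d0``; effects at or below
the minimally relevant size ``d_min`` count as true nulls, which ties the
prior probability of the null to the scale via
``P[H0] = 1 - exp(-d_min / d0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "TestConfig",
    "ExperimentOutcome",
    "experiment_probability",
    "scale_from_prior",
    "prior_from_scale",
    "sample_effect_sizes",
    "noncentrality",
    "sample_t_statistics",
    "critical_t",
    "sidak_alpha",
    "classify_outcome",
    "analytic_fpr",
]


def _as_scalar_or_array(x: np.ndarray):
    """Return a Python scalar for 0-d results, the array otherwise."""
    return x.item() if x.ndim == 0 else x


# ---------------------------------------------------------------------------
# effort -> productivity
# ---------------------------------------------------------------------------

def experiment_probability(effort, effort_min, eta):
    """Per-step probability that a researcher completes an experiment.

    ``p = exp(-eta * (effort - effort_min))`` — a convex, decreasing
    function of effort: careful work is slower.  Equals 1 at the effort
    floor and for ``eta == 0``.

    Parameters
    ----------
    effort : float or array_like
        Effort level(s) ``E >= effort_min``.
    effort_min : float
        Lower bound on effort.
    eta : float
        Decay rate (``>= 0``) controlling how strongly effort slows output.
    """
    e = np.asarray(effort, dtype=float)
    if eta < 0:
        raise ParameterError(f"eta must be >= 0, got {eta}")
    if np.any(e < effort_min):
        raise ParameterError("effort must be >= effort_min")
    return _as_scalar_or_array(np.exp(-eta * (e - effort_min)))


# ---------------------------------------------------------------------------
# effect-size model
# ---------------------------------------------------------------------------

def scale_from_prior(d_min: float, prior_null: float) -> float:
    """Exponential effect-size scale ``d0`` implied by ``P[H0]`` and ``d_min``.

    Inverts ``P[H0] = 1 - exp(-d_min/d0)``, giving
    ``d0 = -d_min / ln(1 - P[H0])``.  For ``d_min = 0.2`` and
    ``P[H0] = 0.8`` this is 0.1243.
    """
    if not 0.0 < prior_null < 1.0:
        raise ParameterError(f"prior_null must be in (0, 1), got {prior_null}")
    if d_min <= 0:
        raise ParameterError(f"d_min must be > 0, got {d_min}")
    return -d_min / math.log1p(-prior_null)


def prior_from_scale(d_min: float, d0: float) -> float:
    """Prior probability of a true null: mass of ``Exp(d0)`` at or below ``d_min``."""
    if d0 <= 0:
        raise ParameterError(f"d0 must be > 0, got {d0}")
    if d_min < 0:
        raise ParameterError(f"d_min must be >= 0, got {d_min}")
    return -math.expm1(-d_min / d0)


def sample_effect_sizes(scale, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` true effect sizes from the exponential distribution with mean ``scale``."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if np.any(np.asarray(scale) <= 0):
        raise ParameterError("scale must be > 0")
    return rng.exponential(scale, size=k)


# ---------------------------------------------------------------------------
# noncentral-t test machinery
# ---------------------------------------------------------------------------

def noncentrality(d, effort):
    """Noncentrality ``lambda = d * sqrt(E/2)`` of the two-sample *t* statistic.

    ``effort`` plays the role of the per-group sample size; it must
    exceed 1 so that ``df = 2E - 2`` stays positive.  Effort is allowed
    to be real-valued (the noncentral *t* is defined for non-integer df).
    """
    d_arr = np.asarray(d, dtype=float)
    e_arr = np.asarray(effort, dtype=float)
    if np.any(e_arr <= 1):
        raise ParameterError("effort must be > 1 (df = 2E - 2 must be positive)")
    if np.any(d_arr < 0):
        raise ParameterError("effect size d must be >= 0")
    return _as_scalar_or_array(d_arr * np.sqrt(e_arr / 2.0))


def sample_t_statistics(lambdas, df, rng: np.random.Generator) -> np.ndarray:
    """One noncentral-*t* draw per noncentrality parameter.

    Uses the defining construction ``T = (Z + lambda) / sqrt(V / df)``
    with ``Z ~ N(0,1)`` and ``V ~ chi2(df)`` independent, which is exact
    for real-valued ``df`` and reduces to the central *t* at
    ``lambda = 0``.  ``df`` may be a scalar or an array broadcast
    against ``lambdas``.
    """
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), lam.shape)
    if np.any(df_arr <= 0):
        raise ParameterError("df must be > 0")
    if not np.all(np.isfinite(lam)) or np.any(lam < 0):
        raise ParameterError("noncentrality parameters must be finite and >= 0")
    z = rng.standard_normal(lam.shape)
    v = rng.chisquare(df_arr)
    return (z + lam) / np.sqrt(v / df_arr)


def critical_t(alpha, df, two_sided: bool = True):
    """Critical value ``t*`` of the central *t* distribution at level ``alpha``.

    Two-sided: ``P(|T| > t*) = alpha``; one-sided: ``P(T > t*) = alpha``.
    Accepts ``alpha`` in ``(0, 1]`` (``alpha = 1`` is the degenerate
    always-reject threshold) and scalar or array ``alpha``/``df``.
    """
    a = np.asarray(alpha, dtype=float)
    d = np.asarray(df, dtype=float)
    if np.any((a <= 0) | (a > 1)):
        raise ParameterError("alpha must be in (0, 1]")
    if np.any(d <= 0):
        raise ParameterError("df must be > 0")
    q = 1.0 - a / 2.0 if two_sided else 1.0 - a
    return _as_scalar_or_array(np.asarray(_st.t.ppf(q, d)))


def sidak_alpha(alpha, k):
    """Šidák-corrected per-test threshold ``1 - (1-alpha)^(1/k)``.

    Controls the family-wise error of ``k`` independent tests at
    ``alpha``; the identity at ``k = 1`` and strictly decreasing in ``k``.
    """
    a = np.asarray(alpha, dtype=float)
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or not np.issubdtype(k_arr.dtype, np.integer):
        raise ParameterError("k must be an integer >= 1")
    if np.any((a <= 0) | (a > 1)):
        raise ParameterError("alpha must be in (0, 1]")
    # -expm1(log1p(-a)/k) is 1-(1-a)^(1/k) evaluated stably for small a
    with np.errstate(divide="ignore"):
        out = -np.expm1(np.log1p(-a) / k_arr)
    out = np.where(a == 1.0, 1.0, out)
    return _as_scalar_or_array(out)


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

@dataclass
class TestConfig:
    """Configuration of a single researcher's hypothesis test.

    ``d0`` and ``prior_null`` are two parameterisations of the same
    exponential effect-size model; either may be given and the other is
    derived.  If both are given they must agree to relative tolerance
    1e-12.
    """

    __test__ = False  # not a test class, despite the Test* name

    alpha: float = 0.05
    two_sided: bool = True
    dmin: float = 0.2
    prior_null: float | None = None
    d0: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.dmin < 0:
            raise ParameterError(f"dmin must be >= 0, got {self.dmin}")
        if self.prior_null is None and self.d0 is None:
            return
        if self.d0 is None:
            self.d0 = scale_from_prior(self.dmin, self.prior_null)
        elif self.prior_null is None:
            self.prior_null = prior_from_scale(self.dmin, self.d0)
        else:
            implied = scale_from_prior(self.dmin, self.prior_null)
            if not math.isclose(implied, self.d0, rel_tol=1e-12):
                raise ParameterError(
                    f"inconsistent (dmin={self.dmin}, prior_null={self.prior_null}) "
                    f"vs d0={self.d0}: implied d0={implied}"
                )


@dataclass
class ExperimentOutcome:
    """Classification of one experiment (one researcher, one time step)."""

    published: bool
    true_positive: bool
    n_tests: int
    effect_sizes: np.ndarray = field(repr=False)
    t_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        self.t_values = np.asarray(self.t_values, dtype=float)
        if len(self.effect_sizes) != self.n_tests or len(self.t_values) != self.n_tests:
            raise InvalidInputError("effect_sizes and t_values must have length n_tests")
        if self.true_positive and not self.published:
            raise InvalidInputError("a true positive must be published")


def classify_outcome(t_values, effect_sizes, cfg: TestConfig, df, k: int | None = None) -> ExperimentOutcome:
    """Classify one experiment's batch of tests as published / true positive.

    Publication follows the P-hacker's rule: the experiment is published
    if *any* of the ``k`` statistics exceeds the **uncorrected** critical
    value at ``cfg.alpha`` (the researcher applies no multiplicity
    correction).  Truth is the simulator's private bookkeeping: the
    outcome is a true positive if at least one test simultaneously has a
    true effect ``>= cfg.dmin`` and a statistic exceeding the
    Šidák-corrected critical value at ``sidak_alpha(cfg.alpha, k)``.
    Since the corrected critical value is never smaller, a true positive
    is always published; a published outcome that is not a true positive
    is a false positive.
    """
    t = np.atleast_1d(np.asarray(t_values, dtype=float))
    d = np.atleast_1d(np.asarray(effect_sizes, dtype=float))
    if t.shape != d.shape or t.ndim != 1:
        raise InvalidInputError(
            f"t_values and effect_sizes must be equal-length 1-d sequences, "
            f"got shapes {t.shape} and {d.shape}"
        )
    n_tests = t.size
    if n_tests < 1:
        raise InvalidInputError("at least one test is required")
    if k is not None and k != n_tests:
        raise InvalidInputError(f"k={k} does not match {n_tests} supplied tests")

    t_crit = critical_t(cfg.alpha, df, cfg.two_sided)
    t_crit_corr = critical_t(sidak_alpha(cfg.alpha, n_tests), df, cfg.two_sided)
    evidence = np.abs(t) if cfg.two_sided else t
    published = bool(np.any(evidence > t_crit))
    true_positive = bool(np.any((evidence > t_crit_corr) & (d >= cfg.dmin)))
    return ExperimentOutcome(published, true_positive, n_tests, d, t)


# ---------------------------------------------------------------------------
# analytic literature false-positive rate
# ---------------------------------------------------------------------------

def analytic_fpr(alpha: float, power: float, prior_odds_alt: float) -> float:
    """Expected fraction of significant results that are false positives.

    With prior odds ``prior_odds_alt`` of the alternative versus the
    null, a fraction ``alpha`` of true nulls and ``power`` of true
    alternatives reach significance, so the literature-wide
    false-positive rate is ``alpha / (alpha + power * prior_odds_alt)``.
    At ``alpha = 0.05``, power 1.0 and odds 1:10 this is 1/3; lowering
    the threshold to 0.005 brings it down to about 5%.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if not 0.0 < power <= 1.0:
        raise ParameterError(f"power must be in (0, 1], got {power}")
    if prior_odds_alt <= 0:
        raise ParameterError(f"prior odds must be > 0, got {prior_odds_alt}")
    return alpha / (alpha + power * prior_odds_alt)
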