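"""Finite-sample theory for min-p screening of union hypotheses.

Model
-----
Each of m hypothesis pairs carries two independent p-values.  Null p-values
are standard uniform; non-null p-values arise from a one-sided test of a
Gaussian statistic with unit variance and mean shift ``snr`` (the
signal-to-noise ratio), so their CDF is ``F(u) = Φ(snr − Φ⁻¹(1 − u))``.
Pairs come in three types — (0,0) both components true, (0,1)/(1,0) exactly
one false, (1,1) both false — with counts (m0, m1, m2).

Screening retains pair i when its minimum p-value is ≤ c; the familywise
error rate (FWER) of the second-stage Bonferroni test at level α/|S| can
then exceed α in finite samples, because conditional on selection the
maximum p-value of a true union hypothesis is no longer stochastically
larger than uniform.  This module provides the exact conditional CDFs after
screening, the exact law of the selected-set size |S(c)|, the resulting
FWER expression (exact when all pairs are of (0,1) type, an upper bound
otherwise), the power of the two-stage test, and the threshold solvers:
the oracle threshold (smallest c whose approximate FWER is ≤ α) and its
large-m approximation, the root of c·E|S(c)| = α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GaussianShift",
    "MixtureModel",
    "SelectionSizePMF",
    "gaussian_p_cdf",
    "cond_cdf_mixed",
    "cond_cdf_doublenull",
    "selection_prob",
    "selection_size_pmf",
    "expected_selection_size",
    "fwer_bound",
    "conditional_power",
    "power_exact",
    "approx_fwer",
    "approx_power",
    "oracle_threshold",
    "approx_oracle_threshold",
    "ThresholdInfeasibleError",
]


class ThresholdInfeasibleError(ValueError):
    """No threshold in (0, α] satisfies the FWER constraint."""


def gaussian_p_cdf(u, snr: float):
    """CDF of a one-sided p-value from a N(snr, 1) test statistic.

    ``F(u) = Φ(snr − z_{1−u})`` with ``z_q`` the standard normal quantile;
    reduces to the uniform CDF when ``snr = 0``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("p-value argument u must lie in [0, 1]")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    # isf(u) = z_{1-u}; handles u -> 0/1 limits gracefully (+-inf)
    with np.errstate(invalid="ignore"):
        out = stats.norm.cdf(snr - stats.norm.isf(u))
    return out if out.ndim else float(out)


class GaussianShift:
    """Non-null p-value distribution for a unit-variance Gaussian mean shift.

    Callable: ``F(u)`` returns P(p ≤ u) for the one-sided p-value of a
    N(snr, 1) statistic.  The density is strictly decreasing on (0, 1) for
    ``snr > 0``, and F(u) ≥ u with equality everywhere iff ``snr = 0``.
    """

    def __init__(self, snr: float):
        if snr < 0:
            raise ValueError("snr must be nonnegative")
        self.snr = float(snr)

    def __call__(self, u):
        return gaussian_p_cdf(u, self.snr)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GaussianShift(snr={self.snr})"


def _as_cdf(F) -> Callable:
    if callable(F):
        return F
    return GaussianShift(float(F))


@dataclass(frozen=True)
class MixtureModel:
    """Counts of (0,0), one-false and (1,1) pairs, plus the non-null CDF.

    Counts are stored as integers (never proportions) so there is no
    rounding ambiguity; ``pi0``, ``pi1``, ``pi2`` are derived.
    """

    m0: int
    m1: int
    m2: int
    nonnull: GaussianShift

    def __post_init__(self):
        for name in ("m0", "m1", "m2"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.m < 1:
            raise ValueError("mixture must contain at least one pair")
        if not callable(self.nonnull):
            object.__setattr__(self, "nonnull", GaussianShift(float(self.nonnull)))

    @property
    def m(self) -> int:
        return self.m0 + self.m1 + self.m2

    @property
    def pi0(self) -> float:
        return self.m0 / self.m

    @property
    def pi1(self) -> float:
        return self.m1 / self.m

    @property
    def pi2(self) -> float:
        return self.m2 / self.m


def cond_cdf_mixed(u, c: float, F) -> float:
    """Conditional CDF of the max p-value of a one-false pair, given selection.

    For a pair with exactly one false component, P(p̄ ≤ u | p̲ ≤ c) equals
    ``u·F(u)/D`` for u ≤ c and ``(c·F(u) + u·F(c) − c·F(c))/D`` for u ≥ c,
    where ``D = F(c) + c − c·F(c)`` is the selection probability.  Evaluated
    at the testing threshold this quantity is the post-selection null
    p-value level, written P0(u, c).
    """
    F = _as_cdf(F)
    if not 0 < c < 1:
        raise ValueError("screening threshold c must lie in (0, 1)")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    Fc = F(c)
    D = Fc + c - c * Fc
    if D <= 0:
        raise ValueError("degenerate selection probability at this threshold")
    Fu = F(u)
    out = np.where(u <= c, u * Fu / D, (c * Fu + u * Fc - c * Fc) / D)
    return out if out.ndim else float(out)


def cond_cdf_doublenull(u, c: float) -> float:
    """Conditional CDF of the max p-value of a both-null pair, given selection.

    ``u² / (c(2−c))`` for u ≤ c and ``(2u − c)/(2 − c)`` for u ≥ c.
    """
    if not 0 < c < 1:
        raise ValueError("screening threshold c must lie in (0, 1)")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    out = np.where(u <= c, u**2 / (c * (2.0 - c)), (2.0 * u - c) / (2.0 - c))
    return out if out.ndim else float(out)


def selection_prob(pair_type: str, c: float, F=None) -> float:
    """Probability that a pair of the given type passes the min-p screen.

    Under independence this is 1 − P(both component p-values > c):
    ``2c − c²`` for type "00", ``F(c) + c − c·F(c)`` for type "01" and
    ``1 − (1 − F(c))²`` for type "11".
    """
    if not 0 < c < 1:
        raise ValueError("screening threshold c must lie in (0, 1)")
    pair_type = str(pair_type)
    if pair_type == "00":
        return 2.0 * c - c * c
    F = _as_cdf(F)
    Fc = float(F(c))
    if pair_type in ("01", "10"):
        return Fc + c - c * Fc
    if pair_type == "11":
        return 1.0 - (1.0 - Fc) ** 2
    raise ValueError(f"unknown pair type {pair_type!r}; expected '00', '01' or '11'")


@dataclass(frozen=True)
class SelectionSizePMF:
    """Exact distribution of the selected-set size |S(c)| under a mixture model."""

    threshold: float
    probs: np.ndarray  # probs[s] = P(|S| = s), s = 0..m

    @property
    def m(self) -> int:
        return self.probs.size - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)


def selection_size_pmf(model: MixtureModel, c: float) -> SelectionSizePMF:
    """Exact PMF of |S(c)|: the convolution of three independent binomials.

    Each pair type is selected independently with its own probability, so
    |S| is a sum of Binomial(m0, ·), Binomial(m1, ·) and Binomial(m2, ·)
    counts.  With a single nonzero component this reduces to the plain
    binomial law.
    """
    F = model.nonnull
    parts = []
    for count, ptype in ((model.m0, "00"), (model.m1, "01"), (model.m2, "11")):
        p = selection_prob(ptype, c, F)
        parts.append(stats.binom.pmf(np.arange(count + 1), count, p))
    probs = parts[0]
    for part in parts[1:]:
        probs = np.convolve(probs, part)
    return SelectionSizePMF(threshold=c, probs=probs)


def expected_selection_size(model: MixtureModel, c: float) -> float:
    """E|S(c)| = m0·Psel(00) + m1·Psel(01) + m2·Psel(11)."""
    F = model.nonnull
    return (
        model.m0 * selection_prob("00", c, F)
        + model.m1 * selection_prob("01", c, F)
        + model.m2 * selection_prob("11", c, F)
    )


def _one_minus_pow(p, s):
    """1 − (1 − p)^s, stable for small p and real-valued s."""
    return -np.expm1(np.asarray(s, float) * np.log1p(-np.asarray(p, float)))


def fwer_bound(model: MixtureModel, c: float, alpha: float) -> float:
    """Finite-sample FWER of the two-stage procedure (exact when π1 = 1).

    Evaluates ``E[(1 − (1 − P0(α/|S|, c))^|S|)·1{|S| > 0}]`` exactly over
    the law of |S(c)|, with P0 the post-selection conditional CDF of a
    one-false pair.  This is the exact familywise error rate when every
    pair has exactly one false component, and an upper bound otherwise.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pmf = selection_size_pmf(model, c)
    s = np.arange(1, pmf.m + 1)
    P0 = cond_cdf_mixed(alpha / s, c, model.nonnull)
    return float(pmf.probs[1:] @ _one_minus_pow(P0, s))


def conditional_power(s, c: float, alpha: float, F) -> float:
    """P(reject a false union hypothesis | |S| = s) for the two-stage test.

    The joint probability that a (1,1) pair passes the screen and its max
    p-value clears the testing threshold α/s:

    * ``2F(c)F(α/s) − F(c)²``  when c·s ≤ α (testing threshold above c);
    * ``F(α/s)²``              when c·s > α;
    * 0                        when s = 0.

    ``s`` may be real-valued (used by the expected-|S| approximation).
    """
    if not 0 < c < 1:
        raise ValueError("screening threshold c must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    F = _as_cdf(F)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("selected-set size s must be nonnegative")
    Fc = F(c)
    with np.errstate(divide="ignore"):
        thr = np.where(s > 0, np.minimum(alpha / np.maximum(s, 1e-300), 1.0), 1.0)
    Fthr = F(thr)
    out = np.where(
        c * s <= alpha,
        2.0 * Fc * Fthr - Fc**2,
        Fthr**2,
    )
    out = np.where(s == 0, 0.0, out)
    return out if out.ndim else float(out)


def power_exact(
    model: MixtureModel, c: float, alpha: float, focal: str = "shifted"
) -> float:
    """Unconditional power to reject a false union hypothesis.

    Averages :func:`conditional_power` over the law of |S(c)|.  Two
    conventions for the pair under test ("focal" pair) are available:

    * ``"shifted"`` (default): the focal (1,1) pair is set aside and |S| is
      decomposed as 1 + (selections among the other m − 1 pairs), since the
      rejection event already contains the focal pair's own selection.
      Requires ``m2 ≥ 1``.  This is exact under independence and matches
      brute-force simulation.
    * ``"marginal"``: the expectation is taken over the law of |S| for the
      full m-pair table, reading the conditional power formula at each s
      directly; it double-counts the focal selection slightly and
      overestimates power at small m.

    The two agree as m grows; see the package methods note.
    """
    F = model.nonnull
    if focal == "marginal":
        pmf = selection_size_pmf(model, c)
        s = np.arange(1, pmf.m + 1)
        return float(pmf.probs[1:] @ conditional_power(s, c, alpha, F))
    if focal == "shifted":
        if model.m2 < 1:
            raise ValueError("shifted convention needs at least one (1,1) pair")
        if model.m == 1:  # no other pairs: |S| = 1 on the rejection event
            return float(conditional_power(1, c, alpha, F))
        rest = MixtureModel(model.m0, model.m1, model.m2 - 1, F)
        pmf = selection_size_pmf(rest, c)
        s = 1 + np.arange(pmf.m + 1)
        # the joint event in conditional_power already contains focal selection,
        # so |S| = 1 + S_rest on that event and no renormalisation is needed
        return float(pmf.probs @ conditional_power(s, c, alpha, F))
    raise ValueError("focal must be 'marginal' or 'shifted'")


def approx_fwer(model: MixtureModel, c: float, alpha: float) -> float:
    """Plug-in FWER approximation 1 − (1 − P0(α/E|S|, c))^{E|S|}.

    Replaces the expectation over |S(c)| by evaluation at E|S(c)|; the
    non-integer exponent is computed via expm1/log1p for stability.
    Returns 0 when E|S(c)| = 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    E = expected_selection_size(model, c)
    if E <= 0:
        return 0.0
    P0 = cond_cdf_mixed(min(alpha / E, 1.0), c, model.nonnull)
    return float(_one_minus_pow(P0, E))


def approx_power(model: MixtureModel, c: float, alpha: float) -> float:
    """Power approximation: conditional power evaluated at s = E|S(c)|."""
    E = expected_selection_size(model, c)
    if E <= 0:
        return 0.0
    return float(conditional_power(E, c, alpha, model.nonnull))


class OracleResult(NamedTuple):
    threshold: float
    constraint_value: float  # approx FWER at the returned threshold
    constraint_binding: bool  # False if the constraint held at the scan floor
    power_maximal_on_grid: bool  # approx power at c* >= power at feasible grid pts


def oracle_threshold(
    model: MixtureModel,
    alpha: float,
    grid_size: int = 400,
    tol: float = 1e-10,
    full_output: bool = False,
):
    """Power-maximizing screening threshold under the FWER constraint.

    Returns the smallest c in (0, α] whose approximate FWER (see
    :func:`approx_fwer`) is ≤ α, restricted to the principal feasibility
    branch: the candidate is the smallest feasible c above the *largest*
    infeasible scan point.  (At extremely small c, where the expected
    selected set is nearly empty, the approximate FWER can dip below α
    again; that sliver carries negligible power and is not a meaningful
    solution of the constrained power-maximization, so it is ignored, and
    choosing it would be flagged by the power diagnostic anyway.)  The
    feasibility boundary is bracketed on ``grid_size`` log-spaced points in
    [α/(10m), α] and then bisected to absolute tolerance ``tol``.

    With ``full_output=True`` an :class:`OracleResult` is returned whose
    diagnostics report whether the constraint actually binds at the
    returned threshold and whether the approximate power is indeed maximal
    there over the feasible scan points.

    Raises :class:`ThresholdInfeasibleError` when no scanned c is feasible.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    grid = np.geomspace(alpha / (10.0 * model.m), alpha, grid_size)
    fw = np.array([approx_fwer(model, c, alpha) for c in grid])
    feasible = fw <= alpha
    if not feasible.any() or not feasible[-1]:
        raise ThresholdInfeasibleError(
            f"no threshold in (0, {alpha}] satisfies the FWER constraint"
        )
    if feasible.all():
        c_star = float(grid[0])
        binding = False
    else:
        last_infeasible = int(np.flatnonzero(~feasible)[-1])
        lo, hi = float(grid[last_infeasible]), float(grid[last_infeasible + 1])
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if approx_fwer(model, mid, alpha) <= alpha:
                hi = mid
            else:
                lo = mid
        c_star = hi
        binding = True
    if not full_output:
        return c_star
    pw_star = approx_power(model, c_star, alpha)
    pw_grid = np.array([approx_power(model, c, alpha) for c in grid[feasible]])
    return OracleResult(
        threshold=c_star,
        constraint_value=approx_fwer(model, c_star, alpha),
        constraint_binding=binding,
        power_maximal_on_grid=bool(pw_star >= pw_grid.max() - 1e-12),
    )


def approx_oracle_threshold(
    model: MixtureModel, alpha: float, tol: float = 1e-14, full_output: bool = False
):
    """Large-m oracle threshold: the root of c·E|S(c)| = α on (0, α].

    ``g(c) = c·E|S(c)| − α`` is strictly increasing, so the root is unique.
    If g(α) < 0 (the root would exceed the testing level) the threshold is
    capped at α and a warning is issued; ``full_output=True`` additionally
    returns the capped flag.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    def g(c):
        return c * expected_selection_size(model, c) - alpha

    if g(alpha) < 0:
        warnings.warn(
            "c·E|S(c)| < alpha on all of (0, alpha]; returning the cap c = alpha",
            RuntimeWarning,
            stacklevel=2,
        )
        return (alpha, True) if full_output else alpha
    lo = min(1e-12, alpha / model.m * 1e-3)
    root = float(optimize.brentq(g, lo, alpha, xtol=tol))
    return (root, False) if full_output else root
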