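"""Escalation/de-escalation boundaries: fixed gBOIN and adaptive gBOINS.

The fixed design compares the observed mean toxicity at the current dose
with a pair of boundaries (lambda_e, lambda_d) chosen to minimize the
probability of an incorrect dose-transition decision under three point
hypotheses mu = phi0 (target), mu = phi1 (subtherapeutic) and mu = phi2
(overly toxic), each with prior weight 1/3.  The minimizer has the closed
form

    lambda_e = (A(phi1) - A(phi0)) / (eta(phi1) - eta(phi0)),
    lambda_d = (A(phi2) - A(phi0)) / (eta(phi2) - eta(phi0)),

which for the (quasi-)binomial family reduces to the familiar BOIN
log-ratio boundaries and for the normal family to midpoints
(phi0 + phik) / 2 (sigma cancels).

The shrinkage design replaces the fixed alternatives phi1, phi2 with
sample-size-dependent alternatives phi1*(n) < phi0 < phi2*(n) derived from
the uniformly most powerful Bayesian test: phik* optimizes

    g_gamma(mu, phi0) = (log(gamma) + n {A(mu) - A(phi0)}) / (eta(mu) - eta(phi0))

with Bayes-factor evidence thresholds gamma_k = exp(c_k * n^eps_k) that
grow with n, so both boundaries contract toward phi0 at rate
O(sqrt(log gamma_k / n)).  During an initial per-dose lead-in of N0
patients the fixed boundaries are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .endpoint_models import EndpointFamily, FamilyKind, natural_terms

# Named (c1, c2) presets.  The schedule constants must be calibrated per
# endpoint type and target; these sets cover the tabulated boundary tables
# ("table1", keyed by family/target) and the simulation studies.
PRESETS = {
    ("table1", "binomial", 0.2): (math.log(1.05), math.log(1.05) / 3),
    ("table1", "binomial", 0.3): (math.log(1.1), math.log(1.1) / 3),
    ("table1", "normal", 0.2): (math.log(1.1), math.log(1.1) / 3),
    ("table1", "normal", 0.3): (math.log(1.1), math.log(1.1) / 3),
    ("sim-binary", "binomial", 0.2): (math.log(1.05) / 3, math.log(1.05) / 3),
    ("sim-binary", "binomial", 0.3): (math.log(1.1) / 3, math.log(1.1) / 3),
    # simulation-study presets: c1 > c2 = c1/3, the ordering under which the
    # escalation threshold gamma1 exceeds gamma2 (harder escalation, easier
    # de-escalation -- the safety-oriented asymmetry)
    ("sim-quasibinary", None, None): (math.log(1.2), math.log(1.2) / 3),
    ("sim-continuous", None, None): (math.log(1.1), math.log(1.1) / 3),
}


def preset_constants(
    name: str, family_kind: str | FamilyKind | None = None, phi0: float | None = None
) -> tuple[float, float]:
    """Resolve a named (c1, c2) preset.

    ``table1`` and ``sim-binary`` depend on the family/target; the
    quasi-binary and continuous simulation presets do not.
    """
    kind = None
    if family_kind is not None:
        kind = FamilyKind(family_kind)
        if kind is FamilyKind.QUASI_BINOMIAL:
            kind = FamilyKind.BINOMIAL
    for (pname, pkind, ptarget), value in PRESETS.items():
        if pname != name:
            continue
        if pkind is None:
            return value
        if kind is not None and pkind == kind.value and ptarget == phi0:
            return value
    raise KeyError(
        f"no preset {name!r} for family={family_kind!r}, target={phi0!r}"
    )


class BoundaryRegime(str, Enum):
    FIXED_GBOIN = "fixed_gboin"
    SHRINKAGE = "shrinkage"


def _score_scale(family: EndpointFamily) -> float:
    """Normalizing constant for the quasi-Bernoulli likelihood.

    Toxicity-grade scores are fractions-of-a-DLT up to ``max_score``
    (1.5 with the default weights); the quasi-Bernoulli model applies to
    score / max_score, which lies in [0, 1].  Targets and boundaries are
    kept on the raw score scale at the API surface and normalized here.
    """
    return family.max_score if family.kind is FamilyKind.QUASI_BINOMIAL else 1.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used for the display tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BoundaryParams:
    """Design hypothesis and schedule parameters.

    phi0 is the target mean toxicity; phi1 < phi0 < phi2 are the fixed
    subtherapeutic / overly-toxic alternatives (defaults 0.6*phi0 and
    1.4*phi0).  c1, c2 and eps1, eps2 drive the evidence-threshold schedule
    gamma_k = exp(c_k n^eps_k); N0 is the per-dose lead-in sample size;
    sigma is the plug-in score SD for the normal family (default 1.1*phi0).
    """

    phi0: float
    phi1: float | None = None
    phi2: float | None = None
    c1: float = math.log(1.1) / 3
    c2: float = math.log(1.1)
    eps1: float = 0.5
    eps2: float = 0.5
    n0: int = 6
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.phi1 is None:
            object.__setattr__(self, "phi1", 0.6 * self.phi0)
        if self.phi2 is None:
            object.__setattr__(self, "phi2", 1.4 * self.phi0)
        if self.sigma is None:
            object.__setattr__(self, "sigma", 1.1 * self.phi0)
        if not self.phi1 < self.phi0 < self.phi2:
            raise ValueError(
                f"need phi1 < phi0 < phi2; got {self.phi1}, {self.phi0}, {self.phi2}"
            )
        if self.phi0 <= 0:
            raise ValueError("phi0 must be positive")
        if not (0.0 < self.eps2 <= self.eps1 < 1.0):
            raise ValueError("exponents must satisfy 1 > eps1 >= eps2 > 0")
        if self.n0 < 0 or int(self.n0) != self.n0:
            raise ValueError("N0 must be a non-negative integer")

    def validate_for(self, family: EndpointFamily) -> None:
        if family.kind is not FamilyKind.NORMAL:
            if not self.phi2 / _score_scale(family) < 1.0:
                raise ValueError(
                    "(quasi-)binomial scale requires phi1 < phi0 < phi2 < 1 "
                    "after normalization by the maximal score"
                )


@dataclass(frozen=True)
class BoundaryPair:
    """An (escalation, de-escalation) boundary pair active at sample size n."""

    lambda_e: float
    lambda_d: float
    n_at: int | None = None
    regime: BoundaryRegime = BoundaryRegime.FIXED_GBOIN

    def __post_init__(self) -> None:
        if not self.lambda_e < self.lambda_d:
            raise ValueError("lambda_e must be below lambda_d")


def gboin_boundaries(
    family: EndpointFamily, params: BoundaryParams
) -> BoundaryPair:
    """Optimal fixed boundaries for the three-point-hypothesis test.

    Evaluates lambda = (A(phik) - A(phi0)) / (eta(phik) - eta(phi0)) through
    the family's natural parametrization; for the normal family sigma
    cancels, leaving the midpoints (phi0 + phik) / 2.
    """
    params.validate_for(family)
    if params.phi1 == params.phi0 or params.phi2 == params.phi0:
        raise ValueError("degenerate hypotheses: phik must differ from phi0")
    sigma = 1.0 if family.kind is FamilyKind.NORMAL else None
    scale = _score_scale(family)
    eta0, a0 = natural_terms(family, params.phi0 / scale, sigma)
    eta1, a1 = natural_terms(family, params.phi1 / scale, sigma)
    eta2, a2 = natural_terms(family, params.phi2 / scale, sigma)
    lam_e = scale * (a1 - a0) / (eta1 - eta0)
    lam_d = scale * (a2 - a0) / (eta2 - eta0)
    return BoundaryPair(lam_e, lam_d, n_at=None, regime=BoundaryRegime.FIXED_GBOIN)


def gamma_schedule(c: float, eps: float, n: int) -> float:
    """Evidence threshold gamma = exp(c * n^eps); strictly increasing in n."""
    if c <= 0:
        raise ValueError("schedule constant c must be positive")
    if not 0.0 < eps < 1.0:
        raise ValueError("schedule exponent must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be at least 1")
    return math.exp(c * n**eps)


def validate_schedule(
    params: BoundaryParams, family: EndpointFamily, n: int
) -> list[str]:
    """Check the schedule-constant constraints; returns warnings, never raises.

    The constraints are 0 < c1 < n^(1-eps1) log(1/(1-phi0)) and
    c1 < c2 < n^(1-eps2) log(1/phi0).  Violations are reported as warnings
    because the tabulated boundary constants themselves violate c1 < c2.
    """
    warnings: list[str] = []
    phi0 = params.phi0 / _score_scale(family)
    if family.kind is FamilyKind.NORMAL:
        return warnings  # the bounds are stated on the probability scale
    if params.c1 <= 0:
        warnings.append("c1 must be positive")
    else:
        hi1 = n ** (1.0 - params.eps1) * math.log(1.0 / (1.0 - phi0))
        if params.c1 >= hi1:
            warnings.append(
                f"c1 = {params.c1:.4g} exceeds its upper bound "
                f"n^(1-eps1) log(1/(1-phi0)) = {hi1:.4g} at n = {n}"
            )
    if params.c2 <= params.c1:
        warnings.append(
            f"c1 < c2 violated (c1 = {params.c1:.4g}, c2 = {params.c2:.4g})"
        )
    hi2 = n ** (1.0 - params.eps2) * math.log(1.0 / phi0)
    if params.c2 >= hi2:
        warnings.append(
            f"c2 = {params.c2:.4g} exceeds its upper bound "
            f"n^(1-eps2) log(1/phi0) = {hi2:.4g} at n = {n}"
        )
    return warnings


def g_gamma(
    family: EndpointFamily,
    mu: float,
    phi0: float,
    n: int,
    gamma: float,
    sigma: float | None = None,
) -> float:
    """UMPBT objective (log gamma + n {A(mu)-A(phi0)}) / (eta(mu)-eta(phi0)).

    For the quasi-binomial family ``mu`` and ``phi0`` are given on the raw
    score scale and evaluated on the normalized [0, 1] scale.
    """
    if mu == phi0:
        raise ValueError("g_gamma undefined at mu = phi0 (zero denominator)")
    scale = _score_scale(family)
    eta0, a0 = natural_terms(family, phi0 / scale, sigma)
    eta, a = natural_terms(family, mu / scale, sigma)
    return (math.log(gamma) + n * (a - a0)) / (eta - eta0)


_EDGE = 1e-6  # open-interval floor/ceiling for the binomial mean search


def _optimize_phi(
    family: EndpointFamily,
    phi0: float,
    n: int,
    gamma: float,
    sigma: float | None,
    side: str,
) -> float:
    """Shared numerical argmax/argmin of g_gamma on one side of phi0."""
    if gamma < 1.0:
        raise ValueError("gamma must be at least 1")
    if n < 1:
        raise ValueError("n must be at least 1")
    if family.kind is FamilyKind.NORMAL:
        offset = sigma * math.sqrt(2.0 * math.log(gamma) / n)
        return phi0 - offset if side == "lower" else phi0 + offset
    if gamma == 1.0:
        return phi0
    scale = _score_scale(family)
    phi0n = phi0 / scale
    log_gamma = math.log(gamma)
    eta0, a0 = natural_terms(family, phi0n)
    if side == "lower":
        lo, hi, sign = _EDGE, phi0n - _EDGE, -1.0  # maximize g
    else:
        lo, hi, sign = phi0n + _EDGE, 1.0 - _EDGE, 1.0  # minimize g
    if lo >= hi:
        raise ValueError(f"empty search interval ({lo}, {hi})")

    def objective(mu: float) -> float:
        eta, a = natural_terms(family, mu)
        return sign * (log_gamma + n * (a - a0)) / (eta - eta0)

    # Coarse grid seed keeps the bounded scalar minimizer on the single
    # interior optimum; the objective is smooth and unimodal on each side.
    grid = np.linspace(lo, hi, 1001)
    values = np.array([objective(m) for m in grid])
    k = int(np.argmin(values))
    b_lo = grid[max(k - 1, 0)]
    b_hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"phi* optimization failed on ({b_lo:.6g}, {b_hi:.6g}): {res.message}"
        )
    return float(res.x) * scale


def optimal_phi1(
    family: EndpointFamily,
    phi0: float,
    n: int,
    gamma1: float,
    sigma: float | None = None,
) -> float:
    """UMPBT subtherapeutic alternative phi1*(n) = argmax_{mu<phi0} g_gamma1.

    Normal family: closed form phi0 - sigma * sqrt(2 log gamma1 / n).
    (Quasi-)binomial: numerical maximizer over (0, phi0).
    """
    return _optimize_phi(family, phi0, n, gamma1, sigma, side="lower")


def optimal_phi2(
    family: EndpointFamily,
    phi0: float,
    n: int,
    gamma2: float,
    sigma: float | None = None,
) -> float:
    """UMPBT overly-toxic alternative phi2*(n) = argmin_{mu>phi0} g_gamma2.

    Normal family: closed form phi0 + sigma * sqrt(2 log gamma2 / n).
    (Quasi-)binomial: numerical minimizer over (phi0, 1).
    """
    return _optimize_phi(family, phi0, n, gamma2, sigma, side="upper")


def shrinkage_boundaries(
    family: EndpointFamily,
    params: BoundaryParams,
    n: int,
    sigma: float | None = None,
) -> BoundaryPair:
    """Active boundary pair at per-dose sample size n under the adaptive design.

    During the lead-in (n <= N0) the fixed gBOIN pair applies; afterwards
    the fixed alternatives are replaced by the shrinking UMPBT alternatives
    phi1*(n), phi2*(n) before evaluating the boundary formulas.  ``sigma``
    overrides ``params.sigma`` (used for the sample/posterior SD policies).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n <= params.n0:
        fixed = gboin_boundaries(family, params)
        return replace(fixed, n_at=n)
    sig = sigma if sigma is not None else params.sigma
    gamma1 = gamma_schedule(params.c1, params.eps1, n)
    gamma2 = gamma_schedule(params.c2, params.eps2, n)
    phi1s = optimal_phi1(family, params.phi0, n, gamma1, sig)
    phi2s = optimal_phi2(family, params.phi0, n, gamma2, sig)
    shrunk = replace(params, phi1=phi1s, phi2=phi2s, sigma=sig)
    pair = gboin_boundaries(family, shrunk)
    return BoundaryPair(
        pair.lambda_e, pair.lambda_d, n_at=n, regime=BoundaryRegime.SHRINKAGE
    )


def boundary_table(
    family: EndpointFamily,
    params: BoundaryParams,
    n_grid: Sequence[int],
) -> pd.DataFrame:
    """Pre-tabulated boundaries over a grid of per-dose sample sizes.

    Returns one row per n with 2-dp half-up display values (``lambda_e``,
    ``lambda_d``) alongside their full-precision twins; trial decisions
    always use full precision.
    """
    if len(n_grid) == 0:
        raise ValueError("n_grid must be non-empty")
    if any(b <= a for a, b in zip(n_grid, list(n_grid)[1:])):
        raise ValueError("n_grid must be strictly ascending")
    rows = []
    for n in n_grid:
        pair = shrinkage_boundaries(family, params, n)
        rows.append(
            {
                "n": n,
                "lambda_e": round_half_up(pair.lambda_e),
                "lambda_d": round_half_up(pair.lambda_d),
                "lambda_e_raw": pair.lambda_e,
                "lambda_d_raw": pair.lambda_d,
                "regime": pair.regime.value,
            }
        )
    return pd.DataFrame(rows)


def decision_error_rate(
    family: EndpointFamily,
    lambda_e: float,
    lambda_d: float,
    phi0: float,
    phi1: float,
    phi2: float,
    n: int,
    sigma: float | None = None,
) -> float:
    """Probability of an incorrect transition decision at a candidate pair.

    Averages, with equal 1/3 weights, P(escalate or de-escalate | mu=phi0),
    P(no escalation | mu=phi1) and P(no de-escalation | mu=phi2), using the
    design's inclusive conventions (escalate iff mu-hat <= lambda_e,
    de-escalate iff mu-hat >= lambda_d).  Binomial: exact enumeration of
    counts; normal: Gaussian CDF of the sample mean.  Serves as the
    brute-force verification oracle for the optimality of the fixed pair.
    """
    if not lambda_e < lambda_d:
        raise ValueError("lambda_e must be below lambda_d")
    if n < 1:
        raise ValueError("n must be at least 1")
    if family.kind is FamilyKind.QUASI_BINOMIAL:
        raise ValueError(
            "exact error enumeration is defined for the binary and normal "
            "endpoints only"
        )
    if family.kind is FamilyKind.NORMAL:
        se = sigma / math.sqrt(n)
        z = stats.norm.cdf
        wrong_h0 = z((lambda_e - phi0) / se) + 1.0 - z((lambda_d - phi0) / se)
        wrong_h1 = 1.0 - z((lambda_e - phi1) / se)
        wrong_h2 = z((lambda_d - phi2) / se)
        return (wrong_h0 + wrong_h1 + wrong_h2) / 3.0
    counts = np.arange(n + 1)
    means = counts / n
    esc = means <= lambda_e
    deesc = means >= lambda_d
    pmf0 = stats.binom.pmf(counts, n, phi0)
    pmf1 = stats.binom.pmf(counts, n, phi1)
    pmf2 = stats.binom.pmf(counts, n, phi2)
    wrong_h0 = pmf0[esc | deesc].sum()
    wrong_h1 = pmf1[~esc].sum()
    wrong_h2 = pmf2[~deesc].sum()
    return float((wrong_h0 + wrong_h1 + wrong_h2) / 3.0)
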