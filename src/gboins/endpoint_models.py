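"""Exponential-family toxicity endpoint models.

The interval designs implemented by this package treat the per-patient
toxicity outcome ``y`` as a draw from a one-parameter exponential family

    f(y | d_j) = h(y) exp{ eta(theta_j) y - A(theta_j) },

with three concrete members:

* **binomial** — the classical dose-limiting-toxicity (DLT) indicator,
  ``eta(mu) = logit(mu)``, ``A(mu) = -log(1 - mu)``;
* **quasi_binomial** — toxicity grades mapped to fractional DLT
  "equivalent toxicity scores" (ETS); the score mean is treated through the
  same logit/log forms as the binomial mean (quasi-Bernoulli likelihood);
* **normal** — a continuous composite toxicity score (TTB/TBS/TTP/AUC style)
  with ``eta(mu) = mu / sigma^2``, ``A(mu) = mu^2 / (2 sigma^2)``.

All escalation/de-escalation decisions downstream depend only on
differences of ``eta`` and ``A``, so the carrier ``h(y)`` is never evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class FamilyKind(str, Enum):
    """The three supported endpoint distributions."""

    BINOMIAL = "binomial"
    QUASI_BINOMIAL = "quasi_binomial"
    NORMAL = "normal"


class SigmaPolicy(str, Enum):
    """How the score SD enters normal-family boundary computation.

    ``plugin`` uses a fixed dimensionless value (recommended 1.1 * phi0),
    ``sample`` uses the divisor-n sample SD of the current dose's data, and
    ``posterior_mean`` uses the posterior mean of sigma^2 under an
    inverse-gamma(alpha0, beta0) prior.
    """

    PLUGIN = "plugin"
    SAMPLE = "sample"
    POSTERIOR_MEAN = "posterior_mean"


#: Grade categories in severity order; grades 0 and 1 are merged because
#: neither contributes toward a DLT equivalent.
GRADE_CATEGORIES = ("0/1", "2", "3", "4")

#: Default equivalent-toxicity-score weights: grade 2 counts as half a DLT,
#: grade 3 as one DLT, grade 4 as one and a half.
DEFAULT_GRADE_WEIGHTS: Mapping[str, float] = {
    "0/1": 0.0,
    "2": 0.5,
    "3": 1.0,
    "4": 1.5,
}


@dataclass(frozen=True)
class EndpointFamily:
    """An endpoint distribution plus the bookkeeping it needs.

    Parameters
    ----------
    kind
        Which exponential-family member the outcome follows.
    grade_weights
        Grade-category -> score map (quasi-binomial only).
    sigma_policy
        SD handling for the normal family; ignored otherwise.
    plugin_value
        Fixed SD used when ``sigma_policy`` is ``plugin``.
    alpha0, beta0
        Inverse-gamma prior shape/rate for the ``posterior_mean`` policy.
        No canonical defaults exist, so they must be supplied by the user.
    """

    kind: FamilyKind
    grade_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_WEIGHTS)
    )
    sigma_policy: SigmaPolicy = SigmaPolicy.PLUGIN
    plugin_value: float | None = None
    alpha0: float | None = None
    beta0: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.kind, FamilyKind):
            object.__setattr__(self, "kind", FamilyKind(self.kind))
        if not isinstance(self.sigma_policy, SigmaPolicy):
            object.__setattr__(self, "sigma_policy", SigmaPolicy(self.sigma_policy))
        if self.kind is FamilyKind.QUASI_BINOMIAL:
            weights = [self.grade_weights[c] for c in GRADE_CATEGORIES]
            if any(w < 0 for w in weights):
                raise ValueError("grade weights must be non-negative")
            if any(b < a for a, b in zip(weights, weights[1:])):
                raise ValueError(
                    "grade weights must be non-decreasing in severity"
                )
        if self.kind is FamilyKind.NORMAL and self.sigma_policy is SigmaPolicy.PLUGIN:
            if self.plugin_value is not None and self.plugin_value <= 0:
                raise ValueError("plugin sigma must be positive")
        if self.sigma_policy is SigmaPolicy.POSTERIOR_MEAN:
            if self.alpha0 is None or self.beta0 is None:
                raise ValueError(
                    "posterior_mean sigma policy requires alpha0 and beta0"
                )

    @property
    def max_score(self) -> float:
        """Largest attainable per-patient score (quasi-binomial)."""
        return max(self.grade_weights[c] for c in GRADE_CATEGORIES)


#: Convenience instances for the two parameter-free families.
BINOMIAL = EndpointFamily(FamilyKind.BINOMIAL)
QUASI_BINOMIAL = EndpointFamily(FamilyKind.QUASI_BINOMIAL)


def normal_family(
    sigma_policy: SigmaPolicy | str = SigmaPolicy.PLUGIN,
    plugin_value: float | None = None,
    alpha0: float | None = None,
    beta0: float | None = None,
) -> EndpointFamily:
    """Build a normal (continuous-score) endpoint family."""
    return EndpointFamily(
        FamilyKind.NORMAL,
        sigma_policy=SigmaPolicy(sigma_policy),
        plugin_value=plugin_value,
        alpha0=alpha0,
        beta0=beta0,
    )


@dataclass
class DoseData:
    """Sufficient statistics for one dose level.

    ``sum_y`` is on the probability scale for binary/quasi-binary endpoints
    and in score units for the normal endpoint; ``sum_y2`` is only needed to
    recover the sample variance of a continuous score.
    """

    n: int = 0
    sum_y: float = 0.0
    sum_y2: float = 0.0

    def add(self, y: float) -> None:
        self.n += 1
        self.sum_y += y
        self.sum_y2 += y * y

    @property
    def mean(self) -> float:
        """Sample mean toxicity mu-hat; requires at least one patient."""
        if self.n < 1:
            raise ValueError("sample mean undefined for an empty dose")
        return self.sum_y / self.n

    def sample_sd(self) -> float:
        """Divisor-n sample SD of the scores (0.0 when n < 2)."""
        if self.n < 2:
            return 0.0
        var = self.sum_y2 / self.n - self.mean**2
        return math.sqrt(max(var, 0.0))


def _grade_category(grade: int | str) -> str:
    if grade in (0, 1, "0", "1", "0/1"):
        return "0/1"
    key = str(grade)
    if key in GRADE_CATEGORIES:
        return key
    raise ValueError(f"unknown toxicity grade: {grade!r}")


def ets_score(grade: int | str, family: EndpointFamily = QUASI_BINOMIAL) -> float:
    """Map a toxicity grade to its equivalent toxicity score.

    With the default weights: grades 0/1 -> 0 (no DLT), grade 2 -> 0.5,
    grade 3 -> 1.0, grade 4 -> 1.5 DLT equivalents.
    """
    if family.kind is not FamilyKind.QUASI_BINOMIAL:
        raise ValueError("ets_score applies to the quasi-binomial family only")
    return float(family.grade_weights[_grade_category(grade)])


def target_from_profile(
    profile, family: EndpointFamily = QUASI_BINOMIAL
) -> float:
    """Expected ETS of a grade-probability profile.

    ``profile`` gives probabilities over the categories (0/1, 2, 3, 4) in
    that order and must sum to 1.  E.g. the target profile
    (0.49, 0.18, 0.23, 0.10) yields the ETS target 0.47.
    """
    profile = list(profile)
    if len(profile) != len(GRADE_CATEGORIES):
        raise ValueError(
            f"profile must have {len(GRADE_CATEGORIES)} entries "
            f"(categories {GRADE_CATEGORIES})"
        )
    total = sum(profile)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"grade profile must sum to 1 (got {total!r})")
    weights = [family.grade_weights[c] for c in GRADE_CATEGORIES]
    return float(sum(p * w for p, w in zip(profile, weights)))


def natural_terms(
    family: EndpointFamily, mu: float, sigma: float | None = None
) -> tuple[float, float]:
    """Natural parameter eta and log-partition A at mean ``mu``.

    Returns ``(logit(mu), -log(1 - mu))`` for the (quasi-)binomial families
    and ``(mu / sigma^2, mu^2 / (2 sigma^2))`` for the normal family.
    """
    if family.kind in (FamilyKind.BINOMIAL, FamilyKind.QUASI_BINOMIAL):
        if not 0.0 < mu < 1.0:
            raise ValueError(
                f"(quasi-)binomial mean must lie in (0, 1); got {mu}"
            )
        return math.log(mu / (1.0 - mu)), -math.log(1.0 - mu)
    if sigma is None or sigma <= 0:
        raise ValueError(f"normal family requires sigma > 0; got {sigma}")
    s2 = sigma * sigma
    return mu / s2, mu * mu / (2.0 * s2)
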