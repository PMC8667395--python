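"""Sequential dose-assignment engine.

One simulated (or real) trial enrolls patients in cohorts, starting at a
prespecified dose.  After each cohort the observed mean toxicity at the
current dose is compared with the active boundary pair — fixed for the
gBOIN design, sample-size dependent for the adaptive gBOINS design — and
the dose for the next cohort is escalated, retained or de-escalated.  A
safety overdose-control rule eliminates the current dose and everything
above it when the posterior probability that its mean toxicity exceeds the
target is above a cutoff (default 0.95, requiring at least 3 patients);
elimination of the lowest dose terminates the trial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import special

from .boundaries import BoundaryPair, BoundaryParams, gboin_boundaries, shrinkage_boundaries
from .endpoint_models import DoseData, EndpointFamily, FamilyKind, SigmaPolicy

logger = logging.getLogger(__name__)


class Decision(str, Enum):
    ESCALATE = "escalate"
    RETAIN = "retain"
    DEESCALATE = "deescalate"


class Design(str, Enum):
    GBOIN = "gboin"
    GBOINS = "gboins"


class TScale(str, Enum):
    """Scale convention for the normal-endpoint posterior t distribution.

    ``mle`` uses the divisor-n variance directly as the squared scale;
    ``standard`` uses the conventional noninformative-posterior scale
    s^2 / n with the divisor-(n-1) variance.
    """

    MLE = "mle"
    STANDARD = "standard"


@dataclass(frozen=True)
class DesignConfig:
    """Everything needed to conduct one trial."""

    family: EndpointFamily
    boundary_params: BoundaryParams
    design: Design = Design.GBOINS
    n_doses: int = 5
    n_max: int = 30
    cohort_size: int = 3
    start_dose: int = 0
    elim_threshold: float = 0.95
    elim_min_n: int = 3
    use_elimination: bool = True
    t_scale: TScale = TScale.MLE

    def __post_init__(self) -> None:
        if not isinstance(self.design, Design):
            object.__setattr__(self, "design", Design(self.design))
        if not isinstance(self.t_scale, TScale):
            object.__setattr__(self, "t_scale", TScale(self.t_scale))
        if self.n_max <= 0 or self.n_max % self.cohort_size != 0:
            raise ValueError("n_max must be a positive multiple of cohort_size")
        if not 0 <= self.start_dose < self.n_doses:
            raise ValueError("start_dose outside the dose range")
        if not 0.5 < self.elim_threshold < 1.0:
            raise ValueError("elim_threshold must lie in (0.5, 1)")
        if self.elim_min_n < 1:
            raise ValueError("elim_min_n must be at least 1")


@dataclass
class TrialState:
    """Mutable per-trial bookkeeping."""

    doses: list[DoseData]
    current_dose: int
    admissible: list[bool]
    terminated: bool = False
    termination_reason: str | None = None
    history: list[tuple] = field(default_factory=list)

    @classmethod
    def fresh(cls, config: DesignConfig) -> "TrialState":
        return cls(
            doses=[DoseData() for _ in range(config.n_doses)],
            current_dose=config.start_dose,
            admissible=[True] * config.n_doses,
        )

    @property
    def total_n(self) -> int:
        return sum(d.n for d in self.doses)


class BoundaryCache:
    """Memoizes the active boundary pair per sample size for one config.

    Valid whenever the boundaries depend on n only (always for binary and
    quasi-binary endpoints; for the normal endpoint under the plug-in sigma
    policy).  With the data-dependent sigma policies the pair is computed
    fresh each call.
    """

    def __init__(self, config: DesignConfig):
        self.config = config
        self._fixed = gboin_boundaries(config.family, config.boundary_params)
        self._cacheable = (
            config.family.kind is not FamilyKind.NORMAL
            or config.family.sigma_policy is SigmaPolicy.PLUGIN
        )
        self._pairs: dict[int, BoundaryPair] = {}

    def pair_at(self, n: int, data: DoseData | None = None) -> BoundaryPair:
        if self.config.design is Design.GBOIN:
            return self._fixed
        if self._cacheable:
            pair = self._pairs.get(n)
            if pair is None:
                pair = shrinkage_boundaries(
                    self.config.family, self.config.boundary_params, n
                )
                self._pairs[n] = pair
            return pair
        sigma = _effective_sigma(self.config, data)
        return shrinkage_boundaries(
            self.config.family, self.config.boundary_params, n, sigma=sigma
        )


def _effective_sigma(config: DesignConfig, data: DoseData | None) -> float:
    """Score SD used for normal-family boundary computation."""
    params = config.boundary_params
    policy = config.family.sigma_policy
    plugin = (
        config.family.plugin_value
        if config.family.plugin_value is not None
        else params.sigma
    )
    if policy is SigmaPolicy.PLUGIN or data is None:
        return plugin
    if policy is SigmaPolicy.SAMPLE:
        sd = data.sample_sd()
        return sd if sd > 0 else plugin
    # posterior mean of sigma^2 under inverse-gamma(alpha0, beta0)
    if data.n < 1:
        return plugin
    ss = data.sum_y2 - data.n * data.mean**2
    var = (2.0 * config.family.beta0 + ss) / (data.n + config.family.alpha0)
    return math.sqrt(max(var, 0.0)) if var > 0 else plugin


def decide(
    state: TrialState,
    config: DesignConfig,
    cache: BoundaryCache | None = None,
) -> Decision:
    """Escalate/retain/de-escalate at the current dose.

    Escalate iff mu-hat <= lambda_e; de-escalate iff mu-hat >= lambda_d;
    otherwise retain.  The comparisons are inclusive, so floating-point
    ties resolve deterministically.
    """
    data = state.doses[state.current_dose]
    if data.n < 1:
        raise ValueError("no data at the current dose")
    if cache is None:
        cache = BoundaryCache(config)
    pair = cache.pair_at(data.n, data)
    mu_hat = data.mean
    if mu_hat <= pair.lambda_e:
        return Decision.ESCALATE
    if mu_hat >= pair.lambda_d:
        return Decision.DEESCALATE
    return Decision.RETAIN


def apply_decision(
    state: TrialState, decision: Decision, config: DesignConfig
) -> int:
    """Resolve a decision to the next dose, respecting admissibility.

    Escalation targets the lowest admissible dose above the current one,
    de-escalation the highest admissible dose below; when no such dose
    exists the trial stays at the current dose (if still admissible) or
    falls back to the highest admissible dose below it.
    """
    if state.terminated:
        raise ValueError("trial already terminated")
    cur = state.current_dose
    if decision is Decision.ESCALATE:
        for j in range(cur + 1, config.n_doses):
            if state.admissible[j]:
                return j
    elif decision is Decision.DEESCALATE:
        for j in range(cur - 1, -1, -1):
            if state.admissible[j]:
                return j
    if state.admissible[cur]:
        return cur
    for j in range(cur - 1, -1, -1):
        if state.admissible[j]:
            return j
    # elimination is always a contiguous suffix, so reaching here means the
    # lowest dose was eliminated — which already terminates the trial
    state.terminated = True
    state.termination_reason = "all-doses-eliminated"
    raise RuntimeError("no admissible dose at or below the current dose")


def overdose_posterior(
    family: EndpointFamily,
    data: DoseData,
    phi0: float,
    t_scale: TScale = TScale.MLE,
) -> float:
    """Posterior probability P(mu_j > phi0 | data) at one dose.

    (Quasi-)binomial: beta-binomial with a uniform beta(1, 1) prior;
    quasi-binary scores enter as fractional pseudo-counts on the
    normalized (score / max score) scale, with the target normalized the
    same way, so the posterior is a proper beta.  Normal:
    posterior t with n-1 degrees of freedom centered at the sample mean;
    the default scale is the divisor-n sample SD (``mle``), the
    ``standard`` switch uses s / sqrt(n) with the divisor-(n-1) SD.
    """
    if family.kind is not FamilyKind.NORMAL:
        if data.n < 1:
            raise ValueError("posterior requires at least one patient")
        scale = family.max_score if family.kind is FamilyKind.QUASI_BINOMIAL else 1.0
        pseudo = data.sum_y / scale
        a = 1.0 + pseudo
        b = 1.0 + data.n - pseudo
        return float(1.0 - special.betainc(a, b, phi0 / scale))
    if data.n < 2:
        return 0.0  # a 0- or 1-observation t posterior cannot be evaluated
    mu_hat = data.mean
    ss = max(data.sum_y2 - data.n * mu_hat**2, 0.0)
    if ss == 0.0:
        return 1.0 if mu_hat > phi0 else 0.0
    df = data.n - 1
    if t_scale is TScale.MLE:
        scale = math.sqrt(ss / data.n)
    else:
        scale = math.sqrt(ss / df) / math.sqrt(data.n)
    t_stat = (phi0 - mu_hat) / scale
    return float(1.0 - special.stdtr(df, t_stat))


def eliminate_check(state: TrialState, config: DesignConfig) -> TrialState:
    """Apply the overdose-control rule at the current dose.

    If P(mu_j > phi0 | data) exceeds the threshold with at least
    ``elim_min_n`` patients, the current dose and all higher doses become
    inadmissible; eliminating the lowest dose terminates the trial.
    A no-op when the configuration disables the rule.
    """
    if not config.use_elimination:
        return state
    j = state.current_dose
    data = state.doses[j]
    if data.n < config.elim_min_n:
        return state
    prob = overdose_posterior(
        config.family, data, config.boundary_params.phi0, config.t_scale
    )
    if prob > config.elim_threshold:
        for k in range(j, config.n_doses):
            state.admissible[k] = False
        if j == 0:
            state.terminated = True
            state.termination_reason = "lowest-dose-eliminated"
    return state


@dataclass
class TrialRecord:
    """Outcome of one completed trial."""

    state: TrialState
    mtd: int | None
    n_cohorts: int


def run_trial(
    scenario,
    config: DesignConfig,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    cache: BoundaryCache | None = None,
) -> TrialRecord:
    """Simulate one trial under a true-toxicity scenario.

    Outcomes are sampled from the scenario's per-dose law; cohorts are
    assigned by decide/eliminate/apply until the patient budget ``n_max``
    is exhausted or the trial terminates for excessive toxicity.  The MTD
    is then chosen by isotonic-regression selection (terminated trials
    select none).  Fully reproducible given the seed.
    """
    from .mtd_selection import select_mtd
    from .simulator import sample_cohort

    if scenario.n_doses != config.n_doses:
        raise ValueError(
            f"scenario has {scenario.n_doses} doses, config expects {config.n_doses}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if cache is None:
        cache = BoundaryCache(config)
    state = TrialState.fresh(config)
    cohort_idx = 0
    while state.total_n < config.n_max and not state.terminated:
        j = state.current_dose
        outcomes = sample_cohort(scenario, j, config.cohort_size, rng)
        data = state.doses[j]
        for y in outcomes:
            data.add(float(y))
        decision = decide(state, config, cache)
        eliminate_check(state, config)
        state.history.append((cohort_idx, j, tuple(outcomes), decision.value))
        if logger.isEnabledFor(logging.INFO):
            pair = cache.pair_at(data.n, data)
            logger.info(
                "cohort %d: dose %d n=%d mean=%.4f boundaries=(%.4f, %.4f) "
                "decision=%s%s",
                cohort_idx, j + 1, data.n, data.mean,
                pair.lambda_e, pair.lambda_d, decision.value,
                " [terminated]" if state.terminated else "",
            )
        cohort_idx += 1
        if state.terminated:
            break
        state.current_dose = apply_decision(state, decision, config)
    mtd = None if state.terminated else select_mtd(state, config.boundary_params.phi0)
    return TrialRecord(state=state, mtd=mtd, n_cohorts=cohort_idx)
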