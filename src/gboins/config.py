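"""Flat key-value run configuration with validated defaults.

A run configuration collects the design parameters (endpoint family,
target, schedule constants, sample size, cohorting, safety rule), the
scenario selection and the replication settings in one flat YAML mapping.
Unknown keys are rejected — a protocol file with a typo should fail loudly
rather than silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .boundaries import BoundaryParams, preset_constants, validate_schedule
from .endpoint_models import (
    BINOMIAL,
    QUASI_BINOMIAL,
    EndpointFamily,
    FamilyKind,
    normal_family,
)
from .trial_engine import DesignConfig

#: User-facing family names.
FAMILY_NAMES = {
    "binary": FamilyKind.BINOMIAL,
    "quasibinary": FamilyKind.QUASI_BINOMIAL,
    "continuous": FamilyKind.NORMAL,
}

_DEFAULT_PRESET = {
    FamilyKind.BINOMIAL: "table1",
    FamilyKind.QUASI_BINOMIAL: "sim-quasibinary",
    FamilyKind.NORMAL: "sim-continuous",
}


@dataclass
class RunConfig:
    """Resolved run configuration; round-trips losslessly through YAML."""

    family: str
    target: float
    design: str = "gboins"
    phi1: float | None = None
    phi2: float | None = None
    preset: str | None = None
    c1: float | None = None
    c2: float | None = None
    eps1: float = 0.5
    eps2: float = 0.5
    n0: int = 6
    sigma: float | None = None
    sigma_policy: str = "plugin"
    alpha0: float | None = None
    beta0: float | None = None
    n_doses: int = 5
    n_max: int = 30
    cohort_size: int = 3
    start_dose: int = 1  # 1-based in configuration files
    elim_threshold: float = 0.95
    elim_min_n: int = 3
    use_elimination: bool = True
    t_scale: str = "mle"
    scenario_set: str | None = None
    scenario: int | None = None
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_NAMES:
            raise ValueError(
                f"family must be one of {sorted(FAMILY_NAMES)}; got {self.family!r}"
            )
        kind = FAMILY_NAMES[self.family]
        if kind is not FamilyKind.NORMAL and not 0.0 < self.target < 1.0:
            raise ValueError(
                f"target must lie in (0, 1) for family {self.family!r}"
            )
        if kind is FamilyKind.NORMAL and self.target <= 0:
            raise ValueError("target must be positive")
        if self.design not in ("gboin", "gboins"):
            raise ValueError(f"design must be gboin or gboins; got {self.design!r}")
        # fill defaults
        if self.phi1 is None:
            self.phi1 = 0.6 * self.target
        if self.phi2 is None:
            self.phi2 = 1.4 * self.target
        if self.sigma is None:
            self.sigma = 1.1 * self.target
        if self.c1 is None or self.c2 is None:
            preset = self.preset or _DEFAULT_PRESET[kind]
            try:
                self.c1, self.c2 = preset_constants(preset, kind, self.target)
                self.preset = preset
            except KeyError as exc:
                raise ValueError(
                    f"no schedule constants: give c1/c2 or a valid preset ({exc})"
                ) from exc
        if not 1 <= self.start_dose <= self.n_doses:
            raise ValueError("start_dose must be a 1-based dose index")

    # -- conversions -------------------------------------------------------
    @property
    def kind(self) -> FamilyKind:
        return FAMILY_NAMES[self.family]

    def endpoint_family(self) -> EndpointFamily:
        if self.kind is FamilyKind.BINOMIAL:
            return BINOMIAL
        if self.kind is FamilyKind.QUASI_BINOMIAL:
            return QUASI_BINOMIAL
        return normal_family(
            sigma_policy=self.sigma_policy,
            plugin_value=self.sigma,
            alpha0=self.alpha0,
            beta0=self.beta0,
        )

    def boundary_params(self) -> BoundaryParams:
        return BoundaryParams(
            phi0=self.target,
            phi1=self.phi1,
            phi2=self.phi2,
            c1=self.c1,
            c2=self.c2,
            eps1=self.eps1,
            eps2=self.eps2,
            n0=self.n0,
            sigma=self.sigma,
        )

    def design_config(self) -> DesignConfig:
        return DesignConfig(
            family=self.endpoint_family(),
            boundary_params=self.boundary_params(),
            design=self.design,
            n_doses=self.n_doses,
            n_max=self.n_max,
            cohort_size=self.cohort_size,
            start_dose=self.start_dose - 1,
            elim_threshold=self.elim_threshold,
            elim_min_n=self.elim_min_n,
            use_elimination=self.use_elimination,
            t_scale=self.t_scale,
        )

    def schedule_warnings(self) -> list[str]:
        return validate_schedule(
            self.boundary_params(), self.endpoint_family(), max(self.n_max, 1)
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Missing keys take their documented defaults; unknown keys are errors.
    Schedule-constant constraint violations are advisory (fetch them with
    ``RunConfig.schedule_warnings``), matching the published constants that
    themselves violate the asymptotic ordering.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved configuration; load_config round-trips it."""
    data = {k: v for k, v in asdict(config).items() if v is not None}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
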