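"""Monte-Carlo power for the 1-df interaction test.

Power is estimated by direct simulation: generate a single-study
case-control dataset from an explicit design (arm sizes, risk-allele
frequency, factor distribution, main-effect ORs), run the interaction test,
and count rejections at the chosen significance level.  The minimum
detectable interaction OR at a target power is read off a power curve
evaluated on an ascending OR grid.

Designs must state the factor distribution explicitly — power depends
strongly on the exposure's variance, and there is no universally sensible
hidden default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import SnpCatalog, SnpDef
from .errors import ConfigError
from .factors import get_factor
from .scan import interaction_test
from .simulate import SimConfig, StudyArm, sample_case_control


@dataclass(frozen=True)
class PowerDesign:
    """Single-study design for an interaction power run.

    ``factor_params`` follows the simulator's parameter vocabulary (e.g.
    ``parous_p``, ``births_lambda_*``, ``menarche_*``, ``bmi_log_*``) and is
    mandatory: it defines the exposure distribution the power estimate is
    conditional on.
    """

    n_cases: int
    n_controls: int
    risk_allele_freq: float
    factor: str
    factor_params: dict[str, float]
    snp_or: float = 1.0
    factor_or: float = 1.0
    prevalence_target: float = 0.125

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ConfigError(
                f"risk_allele_freq {self.risk_allele_freq} is degenerate; "
                "must be strictly inside (0, 1)"
            )
        get_factor(self.factor)

    def sim_config(self, or_int: float) -> SimConfig:
        snp = SnpDef("locus-rs0", ("A", "B"), "B", self.risk_allele_freq,
                     per_allele_or=self.snp_or)
        return SimConfig(
            studies=(StudyArm("S1", self.n_cases, self.n_controls),),
            catalog=SnpCatalog([snp]),
            factor_params=dict(self.factor_params),
            main_effect_ors={self.factor: self.factor_or},
            interaction_ors={(snp.name, self.factor): float(or_int)},
            prevalence_target=self.prevalence_target,
        )


@dataclass(frozen=True)
class PowerResult:
    or_int: float
    alpha: float
    power: float
    se: float
    n_sims: int
    n_flagged: int
    seed: int


def estimate_power(design: PowerDesign, or_int: float, alpha: float,
                   n_sims: int, seed: int) -> PowerResult:
    """Fraction of simulated datasets whose interaction LRT p < alpha.

    The Monte-Carlo standard error is ``sqrt(power (1-power) / n_sims)``.
    Flagged (degenerate/separated) simulated tests count as non-rejections
    and are tallied in ``n_flagged``.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    if n_sims < 100:
        raise ConfigError("n_sims must be >= 100 for a usable estimate")
    config = design.sim_config(or_int)
    snp = config.catalog[0]
    factor = get_factor(design.factor)
    master = np.random.default_rng(seed)
    sim_seeds = master.integers(0, 2**31 - 1, size=n_sims)
    hits = 0
    flagged = 0
    for s in sim_seeds:
        cohort = sample_case_control(config, seed=int(s))
        res = interaction_test(cohort, snp, factor)
        if not res.ok:
            flagged += 1
        elif res.p < alpha:
            hits += 1
    power = hits / n_sims
    se = float(np.sqrt(power * (1.0 - power) / n_sims))
    return PowerResult(float(or_int), float(alpha), power, se, n_sims,
                       flagged, int(seed))


@dataclass(frozen=True)
class PowerCurve:
    """Power evaluated along an ascending interaction-OR grid."""

    design: PowerDesign
    alpha: float
    target_power: float
    results: tuple[PowerResult, ...] = field(default_factory=tuple)
    met: bool = False
    min_detectable_or: float | None = None


def min_detectable_or(design: PowerDesign, alpha: float,
                      grid, target_power: float = 0.90,
                      n_sims: int = 1000, seed: int = 0) -> PowerCurve:
    """Smallest grid OR whose estimated power reaches the target.

    Evaluates the whole grid (so the returned curve is complete) and
    reports the first value meeting ``target_power``; if none does, the
    curve comes back with ``met=False`` and no minimum.
    """
    grid = [float(g) for g in grid]
    if len(grid) < 1:
        raise ConfigError("OR grid must be non-empty")
    if grid != sorted(grid):
        raise ConfigError("OR grid must be ascending")
    results = tuple(
        estimate_power(design, or_int, alpha, n_sims, seed=seed + i)
        for i, or_int in enumerate(grid)
    )
    for r in results:
        if r.power >= target_power:
            return PowerCurve(design, alpha, target_power, results, True, r.or_int)
    return PowerCurve(design, alpha, target_power, results, False, None)
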