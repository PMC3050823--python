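"""Environmental effect schedules and ecological feedback.

Every live cell receives, once per day, an independent Gaussian draw of
the net environmental growth signal alpha (hormones, growth factors,
spatial constraints), in doublings/day.  An :class:`AlphaSchedule` is an
ordered list of stages, each with its own (mu, sigma); schedules may be
cyclic (e.g. a 21-day-on / 7-day-off contraceptive cycle) or end in an
open-ended stage.

When ecological feedback is enabled, the tissue pushes back against
growth: each cell disturbs its basic tissue in proportion to its growth
rate (cellular impact), and the tissue reacts on every cell with a
stochastic counter-signal (ecological balance) whose mean opposes the
summed impact.  A homeostatic tissue (zero net growth) exerts no net
reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stage",
    "AlphaSchedule",
    "EcologyState",
    "sample_alpha",
    "cellular_impact",
    "tissue_reaction",
    "make_metastasis_schedule",
    "ALPHA_PRESETS",
    "get_preset",
]

LN2 = math.log(2.0)
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class Stage:
    """One schedule stage: ``duration`` days of N(mu, sigma) draws.

    ``duration=None`` marks an open-ended terminal stage.
    """

    duration: float | None
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.duration is not None and self.duration <= 0:
            raise ValueError("stage duration must be positive")
        if self.sigma < 0:
            raise ValueError("stage sigma must be >= 0")


@dataclass(frozen=True)
class AlphaSchedule:
    stages: tuple[Stage, ...]
    cyclic: bool = False

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        open_ended = [s for s in self.stages if s.duration is None]
        if len(open_ended) > 1 or (open_ended and self.stages[-1].duration is not None):
            raise ValueError("at most one open-ended stage, and only terminal")
        if self.cyclic and open_ended:
            raise ValueError("cyclic schedules cannot have open-ended stages")

    @classmethod
    def constant(cls, mu: float, sigma: float) -> "AlphaSchedule":
        return cls(stages=(Stage(None, mu, sigma),))

    @property
    def cycle_length(self) -> float | None:
        if not self.cyclic:
            return None
        return sum(s.duration for s in self.stages)

    def stage_at(self, t: float) -> Stage:
        """Resolve the active stage at time t (days). Pure function of (self, t)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.cyclic:
            t = t % self.cycle_length
        for stage in self.stages:
            if stage.duration is None or t < stage.duration:
                return stage
            t -= stage.duration
        raise ValueError(f"time {t} days beyond the end of a finite schedule")


@dataclass(frozen=True)
class EcologyState:
    """Basic-tissue feedback parameters.

    ``q`` converts a cell's growth rate into its impact on the tissue,
    ``beta`` scales the tissue's counter-reaction, ``n_basic`` is the
    stable cell number of one basic tissue.  The reaction applied to each
    cell is Gaussian with mean ``-beta * total_impact / n_basic`` and a
    spread that is ``sigma_frac`` of |mean| (floored at ``sigma_floor``).
    """

    enabled: bool = False
    q: float = 1.0
    beta: float = 1.0
    n_basic: float = 18_800.0
    sigma_frac: float = 0.3
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_basic <= 0:
            raise ValueError("n_basic must be positive")
        if self.q < 0 or self.beta < 0 or self.sigma_frac < 0 or self.sigma_floor < 0:
            raise ValueError("q, beta, sigma_frac, sigma_floor must be >= 0")


def sample_alpha(schedule: AlphaSchedule, t: float, rng, size=None):
    """Draw the day's environmental effect(s) at time ``t``.

    Draws are independent across cells and days; ``size=None`` returns a
    scalar, otherwise an array of per-cell draws.
    """
    stage = schedule.stage_at(t)
    if stage.sigma == 0 and size is None:
        # keep the degenerate constant case draw-free and exact
        return stage.mu
    return rng.normal(stage.mu, stage.sigma, size=size)


def cellular_impact(P, ecology: EcologyState):
    """Instantaneous impact of a cell on its basic tissue: q * ln2 * P.

    The ln2 factor converts doublings/day into the exponential growth
    rate of cell number; the impact is proportional to that growth rate.
    """
    out = ecology.q * LN2 * np.asarray(P, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def tissue_reaction(total_impact: float, ecology: EcologyState) -> tuple[float, float]:
    """Mean and spread of the ecological-balance reaction per cell.

    mu_EB = -beta * total_impact / n_basic; sigma_EB = max(sigma_floor,
    sigma_frac * |mu_EB|).  Each live cell then receives an independent
    Normal(mu_EB, sigma_EB) draw added to its alpha that day.
    """
    if not ecology.enabled:
        raise ValueError("tissue_reaction requires ecology.enabled")
    mu_eb = -ecology.beta * total_impact / ecology.n_basic
    sigma_eb = max(ecology.sigma_floor, ecology.sigma_frac * abs(mu_eb))
    return mu_eb, sigma_eb


#: cascade step durations in days: dissemination, intravasation,
#: circulation, extravasation, ectopic survival
CASCADE_DURATIONS = (3.0, 2.0, 1.0, 2.0, 3.0)

#: default per-step alpha means (doublings/day); monotone harshness into
#: circulation and out, calibrated so survival over the 11-day cascade is
#: high for well-differentiated cells and low for k=0 cells (see
#: docs/methods.md)
DEFAULT_CASCADE_MEANS = (-0.035, -0.05, -0.085, -0.05, -0.035)
DEFAULT_CASCADE_SIGMAS = (0.05, 0.05, 0.05, 0.05, 0.05)


def make_metastasis_schedule(
    step_alphas=DEFAULT_CASCADE_MEANS,
    step_sigmas=DEFAULT_CASCADE_SIGMAS,
    follow_mu: float = 0.0,
    follow_sigma: float = 0.02,
    follow_years: float = 5.0,
) -> AlphaSchedule:
    """Build the five-step metastatic cascade schedule.

    Five hostile stages of durations (3, 2, 1, 2, 3) days — 11 days in
    total — followed by an ectopic-site stage of ``follow_years`` years.
    All step means must be negative (every cascade step opposes growth).
    """
    step_alphas = tuple(float(a) for a in step_alphas)
    step_sigmas = tuple(float(s) for s in step_sigmas)
    if len(step_alphas) != 5 or len(step_sigmas) != 5:
        raise ValueError("the cascade has exactly 5 steps")
    if any(a >= 0 for a in step_alphas):
        raise ValueError("cascade step means must all be negative")
    stages = tuple(
        Stage(d, a, s)
        for d, a, s in zip(CASCADE_DURATIONS, step_alphas, step_sigmas)
    ) + (Stage(follow_years * DAYS_PER_YEAR, follow_mu, follow_sigma),)
    return AlphaSchedule(stages=stages)


# Named presets for the scenario experiments.  The underlying study only
# reports these settings qualitatively (zero / neutral / weak positive /
# strong contraceptive doses), so the numbers here are this package's
# documented calibration, not literature values.
ALPHA_PRESETS: dict[str, AlphaSchedule] = {
    "zero": AlphaSchedule.constant(0.0, 0.0),
    "neutral-slight": AlphaSchedule.constant(0.0, 0.02),
    "neutral-lo": AlphaSchedule.constant(0.0, 0.05),
    "neutral-hi": AlphaSchedule.constant(0.0, 0.1),
    # "effectively neutral": a drift an order of magnitude below the daily
    # noise; mature masses need it because the senescent schedule gives
    # every differentiated cell a slightly negative programmed potential
    "weak-faint": AlphaSchedule.constant(0.005, 0.05),
    "weak-lo": AlphaSchedule.constant(0.01, 0.1),
    "weak-hi": AlphaSchedule.constant(0.02, 0.1),
    "strong": AlphaSchedule.constant(0.05, 0.1),
    # weak chronic stimulation with a tight spread; used where the tissue
    # reaction, not the signal noise, should drive cell death
    "weak-tight": AlphaSchedule.constant(0.02, 0.002),
    # monophasic contraceptive: 21 days of strong stimulation, then off.
    # Doses are kept below ~0.15 doublings/day so that with the daily step
    # a cell's potential stays under one doubling/day and the generation
    # clock tracks actual divisions.
    "contraceptive-lo": AlphaSchedule(
        stages=(Stage(21.0, 0.05, 0.1), Stage(None, 0.0, 0.1))
    ),
    "contraceptive-mid": AlphaSchedule(
        stages=(Stage(21.0, 0.1, 0.1), Stage(None, 0.0, 0.1))
    ),
    "contraceptive-hi": AlphaSchedule(
        stages=(Stage(21.0, 0.15, 0.1), Stage(None, 0.0, 0.1))
    ),
    "metastasis-default": make_metastasis_schedule(),
}


def get_preset(name: str) -> AlphaSchedule:
    try:
        return ALPHA_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown alpha preset {name!r}; known: {sorted(ALPHA_PRESETS)}"
        ) from None
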