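"""Single-cell state and update rules for epithelial clone dynamics.

The model tracks, per cell, a proliferation potential ``P`` (doublings/day),
a fate accumulator ``F`` (net doublings since birth, log2 scale), and a
continuous generation clock ``g``.  A cell divides when ``F`` reaches +1
(one accumulated doubling) and dies when ``F`` reaches -1.  Programmed
schedules tie proliferation and differentiation to the generation clock:
the programmed potential ``Pg(g) = c1*g*(T-g)`` rises, peaks at mid-life
and turns negative past the maximal programmed generation ``T``
(senescence), while the programmed differentiation coefficient
``kg(g) = k_max*(1-exp(-c_k*g))`` saturates at ``k_max``.  A cell's
resistance potential restores ``P`` toward ``Pg`` with a strength
proportional to its differentiation coefficient, so de-differentiated
(low-k) cells lose growth control.

All schedule functions accept scalars or numpy arrays; the population
engine reuses them on whole-population arrays.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Cell",
    "programmed_proliferation",
    "programmed_differentiation",
    "effective_k",
    "resistance_potential",
    "advance_cell",
    "divide_cell",
    "apply_mutations",
    "round_half_away",
]

#: days per month used when config values are given per month
DAYS_PER_MONTH = 30.0

_cell_ids = itertools.count()


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (the convention used for printed k tables).

    numpy/python round() is banker's rounding; printed clinical tables
    conventionally round 0.005 up.
    """
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ModelParams:
    """Tissue-level constants of the single-cell model.

    Parameters
    ----------
    T : float
        Maximal programmed generation before senescence (generations).
    c1 : float
        Proliferation-schedule coefficient (doublings/day/generation^2).
        The default is calibrated so the schedule peaks at 0.1 doublings/day
        at ``g = T/2``.
    k_max, c_k : float
        Plateau and rate constant of the programmed differentiation
        schedule; defaults fitted to the printed generation/kg table.
    lambda_rp : float
        Restoration rate of the resistance potential (1/day).
    dt : float
        Time step (days).
    division_threshold, death_threshold : float
        Fate-accumulator levels triggering division (+1 doubling) and
        death (-1 doubling).
    mu_v, sigma_v : float
        Gaussian mutation-effect distribution on the differentiation
        coefficient (differentiation units per alteration).
    mutations_per_generation : int
        Alterations gained per integer generation crossing.
    senescent_Pg : float
        Programmed potential used for cells seeded in the senescent stage
        (doublings/day); default -2/month.
    """

    T: float = 11.0
    c1: float = 0.1 / (5.5 * 5.5)
    k_max: float = 3.79
    c_k: float = 0.4
    lambda_rp: float = 1.0
    dt: float = 1.0
    division_threshold: float = 1.0
    death_threshold: float = -1.0
    mu_v: float = 0.0
    sigma_v: float = 0.2
    mutations_per_generation: int = 1
    senescent_Pg: float = -2.0 / DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if self.T <= 0 or self.k_max <= 0 or self.c_k <= 0 or self.dt <= 0:
            raise ValueError("T, k_max, c_k and dt must be positive")
        if not (self.division_threshold > 0 > self.death_threshold):
            raise ValueError(
                "need division_threshold > 0 > death_threshold, got "
                f"{self.division_threshold}, {self.death_threshold}"
            )
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be >= 0")
        if self.mutations_per_generation < 0:
            raise ValueError("mutations_per_generation must be >= 0")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class Cell:
    """One simulated epithelial cell.

    ``k_mode`` is ``"programmed_plus_mutations"`` (differentiation follows
    the generation schedule plus the accumulated mutation effects) or
    ``"fixed"`` (``k_fixed`` regardless of history; mutations are ignored).
    ``senescent_seed`` marks cells seeded in the senescent stage whose
    programmed potential is pinned at ``params.senescent_Pg``.
    """

    P: float
    birth_time: float = 0.0
    F: float = 0.0
    g: float = 0.0
    k_mode: str = "programmed_plus_mutations"
    k_fixed: float = float("nan")
    mutation_sum: float = 0.0
    n_mutations: int = 0
    last_integer_g: int = 0
    senescent_seed: bool = False
    alive: bool = True
    id: int = field(default_factory=lambda: next(_cell_ids))
    parent_id: int | None = None


def programmed_proliferation(g, params: ModelParams):
    """Programmed proliferation potential Pg(g) = c1*g*(T-g), doublings/day.

    Zero at g=0 and g=T, maximal at T/2, negative past T (senescence).
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("generation g must be >= 0")
    out = params.c1 * g * (params.T - g)
    if out.ndim == 0:
        return float(out)
    return out


def programmed_differentiation(g, params: ModelParams):
    """Programmed differentiation coefficient kg(g) = k_max*(1-exp(-c_k*g)).

    Strictly increasing in g, bounded above by ``k_max``.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("generation g must be >= 0")
    out = params.k_max * -np.expm1(-params.c_k * g)
    if out.ndim == 0:
        return float(out)
    return out


def effective_k(cell: Cell, params: ModelParams) -> float:
    """Current differentiation coefficient of a cell, clamped at zero.

    Fixed mode returns ``k_fixed``; programmed mode returns
    ``max(0, kg(g) + mutation_sum)``.  Negative differentiation has no
    meaning in the model, hence the clamp.
    """
    if cell.k_mode == "fixed":
        return float(cell.k_fixed)
    k = programmed_differentiation(cell.g, params) + cell.mutation_sum
    return max(0.0, k)


def resistance_potential(P, g, k, params: ModelParams, senescent=False):
    """Restoring force pulling P back to its programmed level (per day).

    RP = lambda_rp * (Pg(g) - P) * min(k, k_max) / k_max.  A fully
    differentiated cell (k = k_max) is restored at rate ``lambda_rp``;
    a fully de-differentiated cell (k = 0) feels no restoring force at
    all, which is what lets transformed cells grow unchecked.

    ``senescent`` (scalar or boolean array) selects ``params.senescent_Pg``
    instead of the parabolic schedule for senescent-seeded cells.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be pre-clamped to >= 0")
    pg = programmed_proliferation(g, params)
    pg = np.where(senescent, params.senescent_Pg, pg)
    out = params.lambda_rp * (pg - np.asarray(P, dtype=float)) * (
        np.minimum(k, params.k_max) / params.k_max
    )
    if out.ndim == 0:
        return float(out)
    return out


def advance_cell(
    cell: Cell, alpha_eff: float, params: ModelParams
) -> tuple[Cell, str, int]:
    """Advance one cell by one explicit-Euler step of length ``dt``.

    ``alpha_eff`` is the combined environmental effect for the day
    (signal alpha plus any ecological reaction), in doublings/day.

    Update order: P first (resistance potential + environment), then the
    fate accumulator F with the updated P, then the generation clock,
    which only runs forward (dg/dt = max(P, 0)).

    Returns the updated cell, the fate (``"none"``, ``"divide"`` or
    ``"die"``; division wins a same-step tie), and the number of integer
    generations crossed, each of which owes
    ``params.mutations_per_generation`` alterations (applied by the
    caller via :func:`apply_mutations`).
    """
    if not cell.alive:
        raise ValueError("cannot advance a dead cell")
    if not (math.isfinite(cell.P) and math.isfinite(alpha_eff)):
        raise ValueError("non-finite state or environmental effect")
    k = effective_k(cell, params)
    rp = resistance_potential(
        cell.P, cell.g, k, params, senescent=cell.senescent_seed
    )
    new_P = cell.P + (rp + alpha_eff) * params.dt
    new_F = cell.F + new_P * params.dt
    new_g = cell.g + max(new_P, 0.0) * params.dt
    crossings = int(math.floor(new_g) - math.floor(cell.g))
    cell = replace(cell, P=new_P, F=new_F, g=new_g)
    if new_F >= params.division_threshold:
        fate = "divide"
    elif new_F <= params.death_threshold:
        fate = "die"
    else:
        fate = "none"
    return cell, fate, crossings


def divide_cell(cell: Cell, t: float) -> tuple[Cell, Cell]:
    """Split a cell into two daughters at time ``t``.

    Daughters inherit P, g, the mutation ledger and the k mode; the fate
    accumulator resets to zero at birth.  The parent is retired (marked
    dead) and should be removed from its population by the caller.
    """
    if not cell.alive:
        raise ValueError("cannot divide a dead cell")
    daughters = tuple(
        Cell(
            P=cell.P,
            birth_time=t,
            F=0.0,
            g=cell.g,
            k_mode=cell.k_mode,
            k_fixed=cell.k_fixed,
            mutation_sum=cell.mutation_sum,
            n_mutations=cell.n_mutations,
            last_integer_g=int(math.floor(cell.g)),
            senescent_seed=cell.senescent_seed,
            parent_id=cell.id,
        )
        for _ in range(2)
    )
    cell.alive = False
    return daughters


def apply_mutations(cell: Cell, count: int, params: ModelParams, rng) -> Cell:
    """Draw ``count`` i.i.d. Gaussian mutation effects and accrue them.

    Cells in fixed-k mode ignore mutations (their differentiation
    coefficient is pinned); the draw is still not consumed for them so
    fixed-mode streams stay independent of the mutation distribution.
    """
    if count < 0:
        raise ValueError("mutation count must be >= 0")
    if count == 0 or cell.k_mode == "fixed":
        return cell
    v = rng.normal(params.mu_v, params.sigma_v, size=count)
    return replace(
        cell,
        mutation_sum=cell.mutation_sum + float(v.sum()),
        n_mutations=cell.n_mutations + count,
        last_integer_g=int(math.floor(cell.g)),
    )
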