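"""Daily-stepped population simulation.

Populations (clones, tumor masses, basic-tissue pools) are stored as
flat numpy arrays, one entry per live cell, kept sorted by cell id.
Each day every cell receives an independent environmental draw (and,
with ecology enabled, an independent tissue-reaction draw computed from
the previous day's total impact), is advanced by one Euler step, gains
mutations for every integer generation it crossed, and then divides or
dies if its fate accumulator crossed a threshold.

Draw order is fixed and documented so runs are bit-reproducible under a
seed: per step, the alpha vector is drawn for all cells in ascending id
order, then the ecological-balance vector (if enabled), then the
mutation effects (cells in ascending id order, each cell's draws
consecutive).  Daughters receive fresh ids in birth order; a dividing
parent's id is retired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams, programmed_differentiation, programmed_proliferation
from .environment import AlphaSchedule, EcologyState, cellular_impact, tissue_reaction

__all__ = [
    "Population",
    "RunRecord",
    "ReplicateSummary",
    "seed_clone",
    "seed_mass",
    "step_population",
    "simulate",
    "summarize_replicates",
]

DEFAULT_SIZE_CAP = 1_000_000

_SERIES = ("n_live", "n_dead_cum", "median_k", "mean_P")


@dataclass
class Population:
    """Array-of-columns container for the live cells of one simulation."""

    ids: np.ndarray
    birth_time: np.ndarray
    P: np.ndarray
    F: np.ndarray
    g: np.ndarray
    mutation_sum: np.ndarray
    n_mutations: np.ndarray
    k_fixed: np.ndarray  # NaN entries follow the programmed schedule
    senescent: np.ndarray
    t: float = 0.0
    cumulative_deaths: int = 0
    cumulative_divisions: int = 0
    n_seeded: int = 0
    next_id: int = 0

    def __len__(self) -> int:
        return self.ids.size

    @property
    def cumulative_births(self) -> int:
        """Daughter cells created so far (two per division)."""
        return 2 * self.cumulative_divisions

    def effective_k(self, params: ModelParams) -> np.ndarray:
        """Per-cell differentiation coefficient, clamped at zero."""
        programmed = np.maximum(
            0.0, programmed_differentiation(self.g, params) + self.mutation_sum
        )
        return np.where(np.isnan(self.k_fixed), programmed, self.k_fixed)

    def check_bookkeeping(self) -> None:
        # each division retires the parent and adds two daughters: net +1
        expected = self.n_seeded + self.cumulative_divisions - self.cumulative_deaths
        if expected != len(self):
            raise AssertionError(
                f"bookkeeping broken: {self.n_seeded} seeded "
                f"+ {self.cumulative_divisions} divisions "
                f"- {self.cumulative_deaths} deaths != {len(self)} live"
            )


def _empty_like(n: int) -> dict[str, np.ndarray]:
    return {
        "ids": np.zeros(n, dtype=np.int64),
        "birth_time": np.zeros(n),
        "P": np.zeros(n),
        "F": np.zeros(n),
        "g": np.zeros(n),
        "mutation_sum": np.zeros(n),
        "n_mutations": np.zeros(n, dtype=np.int64),
        "k_fixed": np.full(n, np.nan),
        "senescent": np.zeros(n, dtype=bool),
    }


def seed_clone(P0: float, t0: float, params: ModelParams) -> Population:
    """One progenitor cell at generation 0, programmed-k mode."""
    cols = _empty_like(1)
    cols["P"][0] = P0
    cols["birth_time"][0] = t0
    return Population(**cols, t=t0, n_seeded=1, next_id=1)


def _resolve_assignment(spec, n: int, rng, clamp_at_zero: bool) -> np.ndarray:
    """A scalar value, or ("normal", mu, sigma) drawn per cell."""
    if np.isscalar(spec):
        values = np.full(n, float(spec))
    else:
        kind, *ps = spec
        if kind != "normal" or len(ps) != 2:
            raise ValueError(f"unsupported assignment spec {spec!r}")
        mu, sigma = map(float, ps)
        if sigma < 0:
            raise ValueError("assignment sigma must be >= 0")
        values = rng.normal(mu, sigma, size=n)
    if clamp_at_zero:
        values = np.maximum(values, 0.0)
    return values


def seed_mass(
    n: int,
    k_assignment,
    P0_assignment,
    params: ModelParams,
    rng,
    g0: float | None = None,
    t0: float = 0.0,
    mode: str = "fixed",
    senescent: bool = False,
) -> Population:
    """Seed a mass of ``n`` mature cells.

    ``k_assignment`` is a fixed value or ``("normal", mu, sigma)``;
    Gaussian draws are clamped at zero (negative differentiation has no
    meaning).  In ``mode="fixed"`` each cell keeps its assigned k forever.
    In ``mode="programmed"`` the assigned k is realised as an initial
    mutation load ``k - kg(g0)`` on top of the programmed schedule, so
    subsequent mutations keep moving the coefficient.  ``senescent=True``
    pins the cells' programmed potential at ``params.senescent_Pg``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("fixed", "programmed"):
        raise ValueError("mode must be 'fixed' or 'programmed'")
    g0 = params.T if g0 is None else g0
    cols = _empty_like(n)
    cols["ids"][:] = np.arange(n)
    cols["P"][:] = _resolve_assignment(P0_assignment, n, rng, clamp_at_zero=False)
    cols["g"][:] = g0
    cols["birth_time"][:] = t0
    k0 = _resolve_assignment(k_assignment, n, rng, clamp_at_zero=True)
    if mode == "fixed":
        cols["k_fixed"][:] = k0
    else:
        cols["mutation_sum"][:] = k0 - programmed_differentiation(g0, params)
    cols["senescent"][:] = senescent
    return Population(**cols, t=t0, n_seeded=n, next_id=n)


def step_population(
    pop: Population,
    schedule: AlphaSchedule,
    ecology: EcologyState,
    params: ModelParams,
    rng,
) -> Population:
    """Advance the population by one time step (in place).

    Order within the step: (1) ecological balance from the pre-step
    population, (2) per-cell draws and the Euler update, (3) mutations
    for generation crossings, (4) divisions and deaths.  An empty
    population is a valid fixed point.
    """
    n = len(pop)
    stage = schedule.stage_at(pop.t)
    if n == 0:
        pop.t += params.dt
        return pop

    if ecology.enabled:
        total_impact = float(np.sum(cellular_impact(pop.P, ecology)))
        mu_eb, sigma_eb = tissue_reaction(total_impact, ecology)

    alpha = rng.normal(stage.mu, stage.sigma, size=n)
    if ecology.enabled:
        alpha = alpha + rng.normal(mu_eb, sigma_eb, size=n)

    k = pop.effective_k(params)
    pg = np.where(
        pop.senescent, params.senescent_Pg, programmed_proliferation(pop.g, params)
    )
    rp = params.lambda_rp * (pg - pop.P) * (np.minimum(k, params.k_max) / params.k_max)

    pop.P += (rp + alpha) * params.dt
    pop.F += pop.P * params.dt
    g_floor_old = np.floor(pop.g)
    pop.g += np.maximum(pop.P, 0.0) * params.dt

    # mutations: only programmed-mode cells accrue them
    crossings = (np.floor(pop.g) - g_floor_old).astype(np.int64)
    crossings[~np.isnan(pop.k_fixed)] = 0
    counts = crossings * params.mutations_per_generation
    total = int(counts.sum())
    if total > 0:
        draws = rng.normal(params.mu_v, params.sigma_v, size=total)
        owner = np.repeat(np.arange(n), counts)
        pop.mutation_sum += np.bincount(owner, weights=draws, minlength=n)
        pop.n_mutations += counts

    divide = pop.F >= params.division_threshold  # division wins a tie
    die = (pop.F <= params.death_threshold) & ~divide
    keep = ~(divide | die)
    n_div = int(np.count_nonzero(divide))
    pop.cumulative_deaths += int(np.count_nonzero(die))
    pop.cumulative_divisions += n_div
    pop.t += params.dt

    if n_div or not keep.all():
        cols = {
            name: getattr(pop, name)
            for name in (
                "ids", "birth_time", "P", "F", "g",
                "mutation_sum", "n_mutations", "k_fixed", "senescent",
            )
        }
        new_cols = {}
        for name, arr in cols.items():
            daughters = np.repeat(arr[divide], 2)
            new_cols[name] = np.concatenate([arr[keep], daughters])
        n_daughters = 2 * n_div
        if n_daughters:
            new_cols["ids"][-n_daughters:] = pop.next_id + np.arange(n_daughters)
            new_cols["F"][-n_daughters:] = 0.0
            new_cols["birth_time"][-n_daughters:] = pop.t
            pop.next_id += n_daughters
        for name, arr in new_cols.items():
            setattr(pop, name, arr)
    return pop


@dataclass
class RunRecord:
    """Per-day time series of one simulation plus its stop reason."""

    day: np.ndarray
    n_live: np.ndarray
    n_dead_cum: np.ndarray
    median_k: np.ndarray
    mean_P: np.ndarray
    stop_reason: str = ""

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, s)) for s in ("day",) + _SERIES}
        if len(lengths) != 1:
            raise ValueError("all recorded series must have equal length")

    @property
    def peak_size(self) -> int:
        return int(self.n_live.max())

    def time_to_size(self, size: int) -> float:
        """First recorded day the live count reached ``size`` (inf if never)."""
        hit = np.nonzero(self.n_live >= size)[0]
        return float(self.day[hit[0]]) if hit.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "n_live": self.n_live,
                "n_dead_cum": self.n_dead_cum,
                "median_k": self.median_k,
                "mean_P": self.mean_P,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(
            path, index=False, float_format="%.10g", lineterminator="\n"
        )


class _Recorder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def snap(self, pop: Population, params: ModelParams) -> None:
        n = len(pop)
        if n:
            k = pop.effective_k(params)
            med_k, mean_p = float(np.median(k)), float(pop.P.mean())
        else:
            med_k = mean_p = float("nan")
        self.rows.append((pop.t, n, pop.cumulative_deaths, med_k, mean_p))

    def build(self, stop_reason: str) -> RunRecord:
        cols = list(zip(*self.rows))
        return RunRecord(
            day=np.asarray(cols[0], dtype=float),
            n_live=np.asarray(cols[1], dtype=np.int64),
            n_dead_cum=np.asarray(cols[2], dtype=np.int64),
            median_k=np.asarray(cols[3], dtype=float),
            mean_P=np.asarray(cols[4], dtype=float),
            stop_reason=stop_reason,
        )


def simulate(
    pop: Population,
    schedule: AlphaSchedule,
    ecology: EcologyState,
    params: ModelParams,
    stop: dict,
    rng,
    check_bookkeeping: bool = False,
) -> RunRecord:
    """Iterate daily steps until t_max, the size cap, or extinction.

    ``stop`` must provide at least one of ``t_max`` (days from the start
    of the run) and ``size_cap`` (live-cell count).
    """
    t_max = stop.get("t_max")
    size_cap = stop.get("size_cap", DEFAULT_SIZE_CAP)
    if t_max is None and size_cap is None:
        raise ValueError("stop needs at least one of t_max / size_cap")
    t0 = pop.t
    rec = _Recorder()
    rec.snap(pop, params)
    stop_reason = "t_max"
    while True:
        if len(pop) == 0:
            stop_reason = "extinct"
            break
        if size_cap is not None and len(pop) >= size_cap:
            stop_reason = "size_cap"
            break
        if t_max is not None and pop.t - t0 >= t_max:
            stop_reason = "t_max"
            break
        step_population(pop, schedule, ecology, params, rng)
        if check_bookkeeping:
            pop.check_bookkeeping()
        rec.snap(pop, params)
    return rec.build(stop_reason)


@dataclass
class ReplicateSummary:
    """Pointwise order statistics of recorded series across replicates."""

    day: np.ndarray
    quantiles: tuple[float, ...]
    series: dict[str, np.ndarray] = field(default_factory=dict)
    n_replicates: int = 0

    def frame(self, name: str) -> pd.DataFrame:
        arr = self.series[name]
        df = pd.DataFrame(
            arr, columns=[f"q{int(round(q * 100))}" for q in self.quantiles]
        )
        df.insert(0, "day", self.day)
        return df

    def to_csv(self, path, name: str = "n_live") -> None:
        self.frame(name).to_csv(
            path, index=False, float_format="%.10g", lineterminator="\n"
        )


def _padded(values: np.ndarray, length: int, pad_value: float) -> np.ndarray:
    if values.size >= length:
        return values[:length]
    return np.concatenate([values, np.full(length - values.size, pad_value)])


def summarize_replicates(
    records: list[RunRecord],
    quantiles: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> ReplicateSummary:
    """Align replicate runs on a common day grid and take quantiles.

    Shorter runs are padded with their terminal values; extinct runs
    carry a live count of zero forward.  The k and P series are padded
    with NaN and summarised with NaN-aware quantiles.
    """
    if not records:
        raise ValueError("need at least one record")
    length = max(r.day.size for r in records)
    longest = max(records, key=lambda r: r.day.size)
    day = longest.day
    summary = ReplicateSummary(
        day=day, quantiles=tuple(quantiles), n_replicates=len(records)
    )
    for name in _SERIES:
        stacked = []
        for r in records:
            values = np.asarray(getattr(r, name), dtype=float)
            if name == "n_live":
                pad = 0.0 if r.stop_reason == "extinct" else values[-1]
            elif name == "n_dead_cum":
                pad = values[-1]
            else:
                # an extinct population has no k/P to carry forward
                pad = np.nan if r.stop_reason == "extinct" else values[-1]
            stacked.append(_padded(values, length, pad))
        data = np.vstack(stacked)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanquantile(data, quantiles, axis=0).T
        summary.series[name] = q
    return summary
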