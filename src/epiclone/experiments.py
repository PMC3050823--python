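"""Configuration-driven scenario runners.

Five in-silico experiments built on the population engine:

``clone``       clone lifetime of normal epithelium under menopausal /
                contraceptive hormone schedules,
``incidence``   escape from senescence of fully de-differentiated cells
                and the resulting tumor-size incidence table,
``evolution``   growth and subclone selection in heterogeneous masses,
``ecology``     cell death during tumor progression with basic-tissue
                feedback (the proposed metastasis-initiation mechanism),
``metastasis``  survival through the five-step metastatic cascade and
                regrowth at the ectopic site.

Each runner is a plain function with documented defaults; a YAML config
file (strict schema, unknown keys rejected) can override them through
:func:`load_config` / :func:`run_config`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelParams
from .engine import (
    ReplicateSummary,
    RunRecord,
    seed_clone,
    seed_mass,
    simulate,
    summarize_replicates,
)
from .environment import (
    AlphaSchedule,
    EcologyState,
    Stage,
    get_preset,
    make_metastasis_schedule,
)
from .transformation import build_table1

__all__ = [
    "exp_clone_lifetime",
    "exp_incidence",
    "exp_tumor_evolution",
    "exp_death_metastasis",
    "exp_metastatic_cascade",
    "generate_fixtures",
    "load_config",
    "run_config",
    "EXPERIMENTS",
]

SCHEMA_VERSION = 1
DAYS_PER_YEAR = 365.0

#: default initial k distributions of the four heterogeneous masses
EVOLUTION_K_DISTRIBUTIONS = (
    ("normal", 3.5, 0.78),
    ("normal", 2.0, 0.5),
    ("normal", 1.5, 0.5),
    ("normal", 1.0, 0.5),
)

INCIDENCE_THRESHOLDS = (10, 100, 1_000, 10_000, 100_000, 1_000_000)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _replicate_records(
    make_pop,
    schedule: AlphaSchedule,
    ecology: EcologyState,
    params: ModelParams,
    stop: dict,
    replicates: int,
    seed: int,
) -> list[RunRecord]:
    records = []
    for rng in _streams(seed, replicates):
        pop = make_pop(rng)
        records.append(simulate(pop, schedule, ecology, params, stop, rng))
    return records


def exp_clone_lifetime(
    presets=("zero", "neutral-lo", "neutral-hi", "weak-lo", "weak-hi"),
    replicates: int = 101,
    t_max: float = 5 * DAYS_PER_YEAR,
    size_cap: int = 1_000_000,
    P0: float = 0.0,
    params: ModelParams | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Clone lifetimes of a single progenitor under each alpha preset.

    Clones start as one progenitor at generation 0 with the programmed
    potential Pg(0)=0; mutations are off (the scenario isolates the
    environmental effect).  Returns, per preset, the replicate records
    and their five-curve summary.
    """
    params = (params or ModelParams()).with_overrides(mutations_per_generation=0)
    out = {}
    for i, name in enumerate(presets):
        schedule = get_preset(name) if isinstance(name, str) else name
        records = _replicate_records(
            lambda rng: seed_clone(P0=P0, t0=0.0, params=params),
            schedule,
            EcologyState(enabled=False),
            params,
            {"t_max": t_max, "size_cap": size_cap},
            replicates,
            seed + 10_000 * i,
        )
        out[name] = {
            "records": records,
            "summary": summarize_replicates(records),
            "peak_sizes": np.array([r.peak_size for r in records]),
        }
    return out


def _incidence_schedule(exposure_months: float, mu: float, sigma: float) -> AlphaSchedule:
    if exposure_months >= 12:
        return AlphaSchedule.constant(mu, sigma)
    return AlphaSchedule(
        stages=(Stage(exposure_months * 30.0, mu, sigma), Stage(None, 0.0, 0.0))
    )


def exp_incidence(
    n_seeds: int = 600,
    exposure_months: float = 12.0,
    mutations_per_generation: int = 1,
    alpha_mu: float = 0.0005,
    alpha_sigma: float = 0.005,
    P0: float = 0.005,
    t_max: float = DAYS_PER_YEAR,
    per_seed_cap: int = 100_000,
    params: ModelParams | None = None,
    seed: int = 0,
    rngs: list[np.random.Generator] | None = None,
) -> dict:
    """Tumor incidence among senescent cells that lost all differentiation.

    Each seed is one fully de-differentiated cell (effective k = 0 via its
    mutation load) at the senescent stage, whose programmed potential is
    pinned at -2/month; each evolves for a year in its own basic tissue
    under the given hormonal exposure.  Returns the final mass size per
    seed and the counts of masses exceeding decade thresholds, alongside
    the factor that extrapolates the scaled seed count to the 60,000-cell
    lifetime incidence.

    ``rngs`` may supply one generator per seed so that different exposure
    settings can be compared with common random numbers.
    """
    params = (params or ModelParams()).with_overrides(
        mutations_per_generation=mutations_per_generation
    )
    schedule = _incidence_schedule(exposure_months, alpha_mu, alpha_sigma)
    ecology = EcologyState(enabled=False)
    stop = {"t_max": t_max, "size_cap": per_seed_cap}
    if rngs is None:
        rngs = _streams(seed, n_seeds)
    elif len(rngs) != n_seeds:
        raise ValueError("need one rng per seed")
    final_sizes = np.zeros(n_seeds, dtype=np.int64)
    for i, rng in enumerate(rngs):
        pop = seed_mass(
            1, 0.0, P0, params, rng, g0=params.T, mode="programmed", senescent=True
        )
        record = simulate(pop, schedule, ecology, params, stop, rng)
        final_sizes[i] = record.n_live[-1]
    counts = {th: int(np.count_nonzero(final_sizes > th)) for th in INCIDENCE_THRESHOLDS}
    return {
        "final_sizes": final_sizes,
        "counts": counts,
        "scale_factor": 60_000 / n_seeds,
        "table": pd.DataFrame(
            {"threshold": list(counts), "n_masses": list(counts.values())}
        ),
    }


def exp_tumor_evolution(
    k_distributions=EVOLUTION_K_DISTRIBUTIONS,
    n_cells: int = 1000,
    replicates: int = 101,
    alpha_preset: str = "weak-faint",
    P0=("normal", 0.01, 0.005),
    t_max: float = 2 * DAYS_PER_YEAR,
    size_cap: int = 1_000_000,
    params: ModelParams | None = None,
    seed: int = 0,
) -> dict:
    """Growth and subclone selection in heterogeneous fixed-k masses.

    Each mass starts with ``n_cells`` mature cells whose differentiation
    coefficients are drawn from its distribution (clamped at zero) and
    frozen (no mutations), under a neutral environment.  Low-k cells feel
    a weaker resistance potential, so selection drives the population
    median k down toward the minimal seeded value.
    """
    params = (params or ModelParams()).with_overrides(mutations_per_generation=0)
    schedule = get_preset(alpha_preset)
    out = {}
    for i, k_spec in enumerate(k_distributions):
        records = _replicate_records(
            lambda rng: seed_mass(n_cells, k_spec, P0, params, rng, g0=params.T),
            schedule,
            EcologyState(enabled=False),
            params,
            {"t_max": t_max, "size_cap": size_cap},
            replicates,
            seed + 10_000 * i,
        )
        out[k_spec] = {
            "records": records,
            "summary": summarize_replicates(records),
            "time_to_cap": np.array([r.time_to_size(size_cap) for r in records]),
        }
    return out


def exp_death_metastasis(
    k_values=(0.0, 0.2, 1.9, 3.5),
    replicates: int = 101,
    alpha_preset: str = "weak-tight",
    P0: float = 0.01,
    t_max: float = DAYS_PER_YEAR,
    size_cap: int = 1_000_000,
    ecology: EcologyState | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
) -> dict:
    """Cell death during tumor progression with basic-tissue feedback.

    Four single founder cells with fixed differentiation coefficients
    grow under an identical weak stimulation; the basic tissue reacts
    stochastically to the mass's total impact.  The k=0 founder outgrows
    the tissue's carrying pressure and suffers massive recurrent death —
    the proposed trigger of metastasis — while well-differentiated
    founders stay dormant with no death at all.
    """
    params = (params or ModelParams()).with_overrides(mutations_per_generation=0)
    ecology = ecology if ecology is not None else EcologyState(enabled=True)
    schedule = get_preset(alpha_preset)
    out = {}
    for i, k in enumerate(k_values):
        records = _replicate_records(
            lambda rng: seed_mass(1, float(k), P0, params, rng, g0=params.T),
            schedule,
            ecology,
            params,
            {"t_max": t_max, "size_cap": size_cap},
            replicates,
            seed + 10_000 * i,
        )
        out[k] = {
            "records": records,
            "summary": summarize_replicates(records),
            "final_deaths": np.array([r.n_dead_cum[-1] for r in records]),
            "final_sizes": np.array([r.n_live[-1] for r in records]),
        }
    return out


def exp_metastatic_cascade(
    k_values=(0.0, 2.0, 3.5),
    n_cells: int = 10_000,
    replicates: int = 101,
    schedule: AlphaSchedule | None = None,
    P0=("normal", 0.1, 0.02),
    follow_years: float = 5.0,
    size_cap: int = 1_000_000,
    params: ModelParams | None = None,
    seed: int = 0,
) -> dict:
    """Survival through the metastatic cascade and ectopic regrowth.

    Masses of ``n_cells`` cells with a fixed k attempt the five-step
    cascade (11 days of negative stimulation) and are then followed at
    the ectopic site.  Reported per k: surviving cells at day 11 and
    day 30 and the full size trajectory.
    """
    params = (params or ModelParams()).with_overrides(mutations_per_generation=0)
    if schedule is None:
        schedule = make_metastasis_schedule(follow_years=follow_years)
    if all(s.duration is not None for s in schedule.stages):
        t_max = sum(s.duration for s in schedule.stages)
    else:
        t_max = 11.0 + follow_years * DAYS_PER_YEAR
    out = {}
    for i, k in enumerate(k_values):
        records = _replicate_records(
            lambda rng: seed_mass(n_cells, float(k), P0, params, rng, g0=params.T),
            schedule,
            EcologyState(enabled=False),
            params,
            {"t_max": t_max, "size_cap": size_cap},
            replicates,
            seed + 10_000 * i,
        )

        def _at_day(r: RunRecord, d: float) -> int:
            idx = np.searchsorted(r.day, d)
            idx = min(idx, r.day.size - 1)
            if r.day[idx] < d and r.stop_reason == "extinct":
                return 0
            return int(r.n_live[min(idx, r.n_live.size - 1)])

        out[k] = {
            "records": records,
            "summary": summarize_replicates(records),
            "survivors_day11": np.array([_at_day(r, 11.0) for r in records]),
            "survivors_day30": np.array([_at_day(r, 30.0) for r in records]),
            "final_sizes": np.array([r.n_live[-1] for r in records]),
        }
    return out


# ---------------------------------------------------------------- config I/O

_ALLOWED_KEYS = {
    "schema_version", "experiment", "seed", "replicates", "alpha_preset",
    "alpha_stages", "alpha_cyclic", "params", "ecology", "stop", "seeding",
}

EXPERIMENTS = ("clone", "incidence", "evolution", "ecology", "metastasis")


def load_config(path) -> dict:
    """Read and validate a YAML experiment config (strict schema)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if cfg.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"config schema_version must be {SCHEMA_VERSION}, "
            f"got {cfg.get('schema_version')!r}"
        )
    if cfg.get("experiment") not in EXPERIMENTS:
        raise ValueError(
            f"experiment must be one of {EXPERIMENTS}, got {cfg.get('experiment')!r}"
        )
    replicates = cfg.get("replicates", 101)
    if not isinstance(replicates, int) or replicates < 1:
        raise ValueError("replicates must be a positive integer")
    return cfg


def _schedule_from_config(cfg: dict) -> AlphaSchedule | None:
    if "alpha_stages" in cfg:
        stages = tuple(
            Stage(None if d is None else float(d), float(mu), float(sigma))
            for d, mu, sigma in cfg["alpha_stages"]
        )
        return AlphaSchedule(stages=stages, cyclic=bool(cfg.get("alpha_cyclic", False)))
    if "alpha_preset" in cfg:
        return get_preset(cfg["alpha_preset"])
    return None


def run_config(cfg: dict, out_dir, seed: int | None = None,
               replicates: int | None = None) -> dict:
    """Run the configured experiment and write CSV/JSON outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = cfg["experiment"]
    seed = cfg.get("seed", 0) if seed is None else seed
    replicates = cfg.get("replicates", 101) if replicates is None else replicates
    params = ModelParams().with_overrides(**cfg.get("params", {}))
    ecology = EcologyState(**cfg.get("ecology", {})) if "ecology" in cfg else None
    stop = cfg.get("stop", {})
    seeding = cfg.get("seeding", {})
    schedule = _schedule_from_config(cfg)

    if name == "clone":
        presets = [schedule] if schedule is not None else None
        kwargs = dict(replicates=replicates, params=params, seed=seed, **seeding)
        if presets is not None:
            kwargs["presets"] = presets
        kwargs.update({k: v for k, v in stop.items() if k in ("t_max", "size_cap")})
        result = exp_clone_lifetime(**kwargs)
        arms = {("clone" if not isinstance(k, str) else k): v for k, v in result.items()}
    elif name == "incidence":
        result = exp_incidence(
            params=params, seed=seed,
            **{k: v for k, v in stop.items() if k in ("t_max", "per_seed_cap")},
            **seeding,
        )
        result["table"].to_csv(
            out_dir / "incidence.csv", index=False, lineterminator="\n"
        )
        arms = {}
    elif name == "evolution":
        kwargs = dict(replicates=replicates, params=params, seed=seed, **seeding)
        kwargs.update({k: v for k, v in stop.items() if k in ("t_max", "size_cap")})
        result = exp_tumor_evolution(**kwargs)
        arms = {f"k_{i}": v for i, v in enumerate(result.values())}
    elif name == "ecology":
        kwargs = dict(replicates=replicates, params=params, seed=seed,
                      ecology=ecology, **seeding)
        kwargs.update({k: v for k, v in stop.items() if k in ("t_max", "size_cap")})
        result = exp_death_metastasis(**kwargs)
        arms = {f"k_{k}": v for k, v in result.items()}
    elif name == "metastasis":
        kwargs = dict(replicates=replicates, params=params, seed=seed, **seeding)
        if schedule is not None:
            kwargs["schedule"] = schedule
        kwargs.update({k: v for k, v in stop.items() if k in ("size_cap",)})
        result = exp_metastatic_cascade(**kwargs)
        arms = {f"k_{k}": v for k, v in result.items()}
    else:  # pragma: no cover - load_config already validated
        raise ValueError(name)

    for arm, data in arms.items():
        data["summary"].to_csv(out_dir / f"{arm}_size_summary.csv", name="n_live")
    meta = {
        "experiment": name,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "replicates": replicates,
        "arms": sorted(str(a) for a in arms),
    }
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return result


# ----------------------------------------------------------------- fixtures

CLONE_SMALL_CONFIG = {
    "schema_version": SCHEMA_VERSION,
    "experiment": "clone",
    "replicates": 3,
    "alpha_preset": "neutral-hi",
    "params": {"mutations_per_generation": 0},
    "stop": {"t_max": 60, "size_cap": 200},
    "seeding": {"P0": 0.0},
}


def generate_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Emit tiny deterministic configs and reference outputs for tests.

    The bundle is byte-identical for identical seeds: a 15-row
    generation/kg table, a 3-replicate 60-day clone config, and the
    reference size-summary CSV that re-running the config must reproduce.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = build_table1(ModelParams(), n_max=15)
    paths["table1"] = out_dir / "table1_kg.csv"
    table.to_csv(paths["table1"], index=False, float_format="%.10g",
                 lineterminator="\n")

    cfg = dict(CLONE_SMALL_CONFIG, seed=seed)
    paths["config"] = out_dir / "clone_small.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))

    result = exp_clone_lifetime(
        presets=("neutral-hi",),
        replicates=cfg["replicates"],
        t_max=cfg["stop"]["t_max"],
        size_cap=cfg["stop"]["size_cap"],
        P0=0.0,
        seed=seed,
    )
    paths["reference"] = out_dir / "clone_small_reference.csv"
    result["neutral-hi"]["summary"].to_csv(paths["reference"], name="n_live")
    return paths
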