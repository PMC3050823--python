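"""Closed-form probabilities of malignant transformation by mutation.

After ``n`` generations with ``m`` alterations per generation a cell
carries ``M = n*m`` independent Gaussian mutation effects, so its
differentiation coefficient is ``kg(n) + S`` with
``S ~ Normal(M*mu_v, sigma_v*sqrt(M))``.  The probability that the
coefficient has dropped below a threshold theta (0 = complete
de-differentiation / full malignant transformation; 2 = substantial
de-differentiation) is therefore a Gaussian tail probability, evaluated
here in closed form and cross-checkable by brute-force Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ModelParams, programmed_differentiation, round_half_away

__all__ = [
    "TransformationQuery",
    "TABLE1_KG",
    "transformation_probability",
    "mc_transformation_probability",
    "build_table1",
    "expected_transformed_cells",
    "fit_differentiation_schedule",
]

#: printed generation -> kg reference column (generations 1..15) used as
#: the regression fixture for the differentiation schedule
TABLE1_KG = {
    1: 1.25, 2: 2.09, 3: 2.65, 4: 3.02, 5: 3.28,
    6: 3.45, 7: 3.56, 8: 3.64, 9: 3.69, 10: 3.72,
    11: 3.75, 12: 3.76, 13: 3.77, 14: 3.78, 15: 3.78,
}


@dataclass(frozen=True)
class TransformationQuery:
    """A 'probability that k has fallen below threshold' question."""

    n_generations: int
    threshold: float
    mutations_per_generation: int = 1
    mu_v: float = 0.0
    sigma_v: float = 0.2

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be >= 0")

    @property
    def n_mutations(self) -> int:
        return self.n_generations * self.mutations_per_generation


def transformation_probability(
    query: TransformationQuery, params: ModelParams
) -> float:
    """P[k < threshold] after ``n_generations`` under the Gaussian-sum model.

    Returns Phi((threshold - kg(n) - M*mu_v) / (sigma_v*sqrt(M))).  With a
    degenerate distribution (sigma_v = 0 or M = 0) the probability is the
    0/1 indicator of the strict inequality kg(n) + M*mu_v < threshold.
    """
    kg = programmed_differentiation(query.n_generations, params)
    m = query.n_mutations
    loc = kg + m * query.mu_v
    scale = query.sigma_v * np.sqrt(m)
    if scale == 0.0:
        return 1.0 if loc < query.threshold else 0.0
    return float(stats.norm.cdf((query.threshold - loc) / scale))


def mc_transformation_probability(
    query: TransformationQuery,
    params: ModelParams,
    reps: int,
    rng,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo estimate of the same probability.

    Draws the M individual mutation effects per replicate and counts how
    often ``kg(n) + sum(v)`` falls strictly below the threshold.  Returns
    (estimate, binomial standard error).  Kept deliberately independent of
    the closed form: it never collapses the sum into a single Gaussian.
    """
    if reps < 1_000:
        raise ValueError("reps must be >= 1000 for a meaningful estimate")
    kg = programmed_differentiation(query.n_generations, params)
    m = query.n_mutations
    hits = 0
    done = 0
    while done < reps:
        block = min(chunk, reps - done)
        if m == 0:
            sums = np.zeros(block)
        else:
            v = rng.normal(query.mu_v, query.sigma_v, size=(block, m))
            sums = v.sum(axis=1)
        hits += int(np.count_nonzero(kg + sums < query.threshold))
        done += block
    p_hat = hits / reps
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1.0 / reps) / reps))
    return p_hat, se


def build_table1(
    params: ModelParams,
    n_max: int = 15,
    mutations_per_generation: int = 1,
    mu_v: float | None = None,
    sigma_v: float | None = None,
) -> pd.DataFrame:
    """Generation table of kg and transformation probabilities.

    One row per generation 1..n_max with the programmed differentiation
    coefficient (reported to 2 decimals, half away from zero) and the
    probabilities of the coefficient having fallen below 0 and below 2.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    mu_v = params.mu_v if mu_v is None else mu_v
    sigma_v = params.sigma_v if sigma_v is None else sigma_v
    rows = []
    for n in range(1, n_max + 1):
        kg = programmed_differentiation(n, params)
        probs = {
            f"p_below_{int(th)}": transformation_probability(
                TransformationQuery(
                    n_generations=n,
                    threshold=th,
                    mutations_per_generation=mutations_per_generation,
                    mu_v=mu_v,
                    sigma_v=sigma_v,
                ),
                params,
            )
            for th in (0.0, 2.0)
        }
        rows.append({"generation": n, "kg": round_half_away(kg, 2), **probs})
    return pd.DataFrame(rows)


def expected_transformed_cells(
    p: float,
    cells_at_any_time: float,
    cell_lifespan_years: float,
    human_lifetime_years: float,
) -> float:
    """Expected lifetime number of transformed cells in a tissue.

    With ``cells_at_any_time`` cells present at any moment, each living
    ``cell_lifespan_years``, a lifetime of ``human_lifetime_years`` sees
    ``cells * lifetime / lifespan`` cell-lifetimes in total, each
    transformed with probability ``p``.
    """
    if cells_at_any_time <= 0 or cell_lifespan_years <= 0 or human_lifetime_years <= 0:
        raise ValueError("cell numbers and times must be positive")
    return p * cells_at_any_time * (human_lifetime_years / cell_lifespan_years)


def fit_differentiation_schedule(
    table: dict[int, float] | None = None,
) -> tuple[float, float, float]:
    """Least-squares fit of k_max*(1-exp(-c*g)) to a printed kg column.

    Returns (k_max, c, max_abs_residual).  With the default reference
    column this recovers the package defaults k_max=3.79, c_k=0.4.
    """
    table = TABLE1_KG if table is None else table
    g = np.array(sorted(table), dtype=float)
    y = np.array([table[int(n)] for n in g], dtype=float)

    def model(g, k_max, c):
        return k_max * -np.expm1(-c * g)

    (k_max, c), _ = optimize.curve_fit(model, g, y, p0=(3.5, 0.5))
    resid = np.max(np.abs(model(g, k_max, c) - y))
    return float(k_max), float(c), float(resid)
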