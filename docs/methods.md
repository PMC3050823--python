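# Methods

## The single-cell model

`epiclone` simulates epithelial tissue turnover and tumorigenesis one cell
at a time. Each cell carries three continuous state variables:

- **P** — proliferation potential (doublings/day). Positive P drives the
  cell toward division, negative P toward death.
- **F** — fate accumulator: net doublings accumulated since birth
  (log2 scale). F = 0 at birth; the cell divides when F ≥ +1 and dies when
  F ≤ −1. One accumulated doubling is one division, which ties the fate
  rule directly to the exponential-growth reading of P. If one step ever
  crossed both thresholds, division would win; with a single-signed P
  inside a step this cannot happen, but the tie-break is fixed and tested.
- **g** — generation clock (continuous generations), a cellular reading of
  lineage progression. It advances as dg/dt = max(P, 0): the clock never
  runs backward, and under pure growth each division advances g by exactly
  one generation. Every integer crossing of g triggers a configurable
  number of mutations.

Two programmed schedules tie cell behaviour to the clock:

- **Programmed proliferation** Pg(g) = c1·g·(T−g): zero at birth, maximal
  at mid-development (g = T/2), negative past the maximal programmed
  generation T (senescence). Defaults: T = 11 generations, c1 calibrated
  so the peak is 0.1 doublings/day — the order of magnitude appropriate for
  weakly stimulated epithelium rather than cultured cells.
- **Programmed differentiation** kg(g) = k_max·(1 − e^(−c_k·g)), rising to
  a plateau as cells mature. Defaults k_max = 3.79, c_k = 0.4 are the
  least-squares fit to the package's 15-row generation/kg reference table
  (`fit_differentiation_schedule` recovers them; max |residual| 0.006, with
  the generation-11 row off by one rounding unit — treated as a printing
  artifact of the reference).

A cell's **effective differentiation coefficient** is
k = max(0, kg(g) + Σvᵢ), where the vᵢ ~ N(μ_v, σ_v) are the effects of the
mutations it has accrued (negative k has no meaning; the clamp is part of
the model). Cells can instead run in *fixed-k* mode — the coefficient
frozen, mutations ignored — which is how mature tumor masses with known
composition are seeded.

The **resistance potential** restores P to its programmed level with a
strength proportional to differentiation:

    RP = λ · (Pg(g) − P) · min(k, k_max)/k_max,    λ = 1/day.

A fully differentiated cell is pulled back at rate λ; a fully
de-differentiated cell (k = 0) feels no restoring force at all — this is
the mechanistic core of the package: transformation is loss of growth
control, expressed as loss of the restoring force. The linear restoring
form scaled by normalised k is the minimal law with these properties.

Each day every cell receives an independent Gaussian **environmental
effect** α (hormones, growth factors, spatial constraints) and, when
ecological feedback is on, an independent tissue reaction EB. The update
is explicit Euler with dt = 1 day (α is defined as a net effect over one
day, so one draw per cell per day):

    P ← P + (RP + α + EB)·dt;   F ← F + P·dt;   g ← g + max(P, 0)·dt.

With λ·dt = 1 the relaxation is exact in one step (the discrete map is an
AR(1) with coefficient 1 − λ·dt·k/k_max); λ·dt ≤ 1 is required for
monotone relaxation and is asserted in tests.

Daughters inherit P, g, the mutation ledger and the k mode; F resets to
zero at birth. Mutations accumulate independently in each daughter.

### Mutation statistics and the transformation probabilities

After n generations with m mutations per generation the coefficient is
kg(n) + S with S ~ N(M·μ_v, σ_v√M), M = n·m, so

    P[k < θ] = Φ((θ − kg(n) − M·μ_v) / (σ_v·√M)).

Defaults μ_v = 0, σ_v = 0.2 make full de-differentiation by mutation alone
essentially impossible within a programmed lifetime (≈8×10⁻⁹ by the
senescence limit) — which, extrapolated over ~10¹³ cell-lifetimes in a
century, still yields tens of thousands of transformed cells, the seed
pool for the incidence experiment. M counts one mutation per completed
generation; the generation/probability table quotes k to two decimals
using round-half-away-from-zero (the convention of printed clinical
tables). The closed form is cross-checked against a brute-force Monte
Carlo that draws every individual mutation effect.

## Environment schedules and ecological feedback

α schedules are ordered stage lists (duration, μ, σ), optionally cyclic or
ending in an open-ended stage. Stage resolution is a pure function of
(schedule, t); draws are independent across cells and days, made in
ascending cell-id order (α vector first, then the EB vector, then mutation
draws) so that runs are bit-reproducible under a seed.

With ecology enabled, each cell disturbs its **basic tissue** — the
smallest tissue unit maintaining a stable cell count, default
n_basic = 18,800 cells — in proportion to its growth rate
(CI = q·ln2·P), and the tissue reacts on every cell with an independent
draw from N(μ_EB, σ_EB), where μ_EB = −β·ΣCI/n_basic and
σ_EB = max(σ_floor, 0.3·|μ_EB|). The reaction uses the *previous* day's
population (an explicit one-day lag), avoiding within-day circularity.
A homeostatic tissue (ΣCI = 0) exerts no net reaction. The reaction
spread fraction 0.3 is a package choice; the feedback enters the P-update
additively with α and can be disabled.

### Preset calibration

The scenario studies are stated qualitatively in the source material
(neutral vs weak vs strong stimulation); the numeric presets below are
this package's calibration, chosen from the AR(1) variance analysis of
the update rule and pilot runs, and then frozen:

| preset | μ_α, σ_α (/day) | emulates |
|---|---|---|
| zero | 0, 0 | hormone-free menopause (dormant progenitors) |
| neutral-slight | 0, 0.02 | barely varying environment |
| neutral-lo / neutral-hi | 0, 0.05 / 0, 0.1 | menopausal noise; median clone dies young |
| weak-faint | 0.005, 0.05 | "no deliberate stimulation" for mature masses |
| weak-lo / weak-hi | 0.01, 0.1 / 0.02, 0.1 | chronic weak estrogen |
| weak-tight | 0.02, 0.002 | weak stimulation, tissue-reaction-dominated noise |
| strong | 0.05, 0.1 | strong chronic stimulation |
| contraceptive-lo/mid/hi | 0.05/0.1/0.15 (σ 0.1), 21 days then off | monophasic oral contraceptive |

Two calibration constraints are worth recording. First, contraceptive
doses are kept below ~0.15 doublings/day: with the daily step a cell can
divide at most once per step, so at P·dt > 1 the generation clock outruns
division and clones paradoxically shrink with dose. Second, a mature
(g = T) cell with any k > 0 has slightly negative programmed potential,
so under an exactly-zero-mean α every differentiated mass decays; the
evolution experiment therefore uses a drift (0.005) an order of magnitude
below its noise (0.05) as its operational "neutral".

The five-step metastatic cascade (dissemination, intravasation,
circulation, extravasation, ectopic survival) lasts (3, 2, 1, 2, 3) days
with step means (−0.035, −0.05, −0.085, −0.05, −0.035) and σ = 0.05 —
monotone harshness into circulation and out — followed by an ectopic
stage of N(0, 0.02) draws. This calibration puts 30-day survival between
~5% (k = 0) and ~97% (k = 3.5), strictly ordered in k, with ectopic
regrowth possible only for k = 0 cells.

## The five experiments and their scaled defaults

All experiments run 101 replicates by default and summarise them as
pointwise (min, 25%, median, 75%, max) curves; tests and the acceptance
checks use 25 replicates with size caps of 10⁴–10⁵ cells and horizons of
1–5 years — the problem sizes this package documents for its own checks.
Extinct replicates carry a live count of zero forward in summaries;
capped replicates carry terminal values.

1. **Clone lifetime** — one progenitor (g = 0, P = Pg(0) = 0, programmed
   k, no mutations) per replicate under each preset. Zero environment:
   permanent dormancy. Neutral: every clone returns to zero cells, peak
   below 2^(T+1). Stimulation: median peak size increases with μ_α;
   contraceptive clones are 10–1000× the pooled menopausal median.
2. **Incidence** — fully de-differentiated senescent seeds (g = T,
   effective k = 0 via an initial mutation load of −kg(T), programmed
   potential pinned at −2/month, P₀ = 0.005/day), each in its own basic
   tissue, under α(0.0005, 0.005) exposure for 6 or 12 months of the
   year. Reported: counts of masses exceeding 10¹…10⁶ cells, with the
   60,000-cell lifetime extrapolation factor. Seeds default to 600 (1%
   scale). P₀ is set so an unstimulated, unmutated seed cannot form a
   10-cell mass within a year (the all-zero control column).
3. **Tumor evolution** — 1000-cell masses with frozen per-cell k drawn
   from Gaussians of decreasing mean, under weak-faint α. Low-k cells
   amplify and retain environmental noise (weak restoring force), so
   selection drives the population median k down toward the minimal
   seeded value; the lowest-k̄ masses reach the size cap first.
4. **Death and the initiation of metastasis** — single founders with
   k ∈ {0, 0.2, 1.9, 3.5} under weak-tight α with ecology on. The k = 0
   founder outgrows the tissue's carrying pressure and suffers recurrent
   mass death (cumulative deaths exceed the live size at 12 months); the
   k = 0.2 founder shows late-onset death; the two differentiated
   founders record exactly zero deaths.
5. **Metastatic cascade** — 10,000-cell masses (scaled: 1000) with
   k ∈ {0, 2.0, 3.5} through the 11-day cascade plus follow-up.
   Day-30 survival is strictly increasing in k; only k = 0 survivors
   regrow into a detectable (≥10⁴-cell) lesion.

## What the generator emulates — and what it does not

The synthetic scenarios emulate: generation-programmed proliferation and
differentiation; mutation effects as i.i.d. Gaussian increments on a
scalar differentiation coefficient; the environment as a daily i.i.d.
Gaussian signal; tissue feedback as a lagged mean-field reaction. They do
not emulate: spatial structure, stem-cell dynamics, cell-cycle phases,
pharmacokinetics, or any sequence-level mutation process. Passing tests
therefore show internal consistency of the model and the direction of its
predicted contrasts, not agreement with any particular clinical dataset.

Known limitations of the reconstruction, found during calibration:

- Cascade day-11 survival is 20–100% depending on k rather than uniformly
  >90%: with this update rule no single calibration yields near-total
  11-day survival for k = 0 cells *and* low 30-day survival that is not
  masked by regrowth. The strict k-ordering of 30-day survival was
  prioritised.
- The incidence experiment does not reproduce a positive effect of the
  mutation rate on mass counts: for seeds already at k = 0, further
  mutations can only raise k back toward enforced senescence.
- At the 1000-cell scale the k ~ N(2, 0.5) heterogeneous mass usually
  declines to extinction within a year (its selectable low-k tail is
  ~1 cell); its median-k decline — the property under test — is unaffected.
- The full-scale printed magnitudes (10⁵–10⁷ cells, 60,000 seeds) are out
  of desk-scale reach and are covered by directional tests only.

## Numerical and bookkeeping conventions

- Explicit Euler, dt = 1 day; per-month config values divide by 30.
- Division wins a same-step threshold tie; daughters get fresh ids in
  birth order; a dividing parent's id is retired; populations stay sorted
  by id, which fixes the random-draw order.
- Conservation is checked after every step in tests:
  live = seeded + divisions − deaths.
- k is reported to two decimals, rounded half away from zero.
- An empty population is a valid fixed point; extinction, the size cap
  and the time horizon are the three stop reasons.
- RNG streams: one root `SeedSequence` per experiment, spawned per
  replicate (and per seed cell for the incidence experiment, enabling
  common-random-number comparisons across exposure settings).
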