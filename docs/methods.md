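# Methods

This note documents the models behind `graftsim`, the defaults and their
units, the numerical choices, and what the synthetic scenarios do and do
not represent.

## Demand scenarios

A scenario is a vector of weekly tray demands over a contiguous, 1-based
horizon — weeks are the only time granularity anywhere in the package,
because nursery planning and all reported outputs are weekly. Three
stylized peak patterns are generated: a single-week peak, a multi-week
plateau, and a peak descending linearly to the baseline over a
configurable window (default 12 weeks for the descending study
scenario). The descending ramp interpolates linearly and rounds to whole
trays. Multiplicative demand noise exists but is **off by default**:
scenarios are fixed planning inputs; stochasticity belongs to the
production simulator.

The six study scenarios in `analysis/03_labor_scenarios.py` use a
24-week horizon, a 60 tray/week baseline and a 600-tray peak. These
magnitudes are stand-ins chosen once as representative of a large
North-American grafting nursery (a 600-tray tomato week is ≈ 120,000
grafted plants); there is no standard demand profile for such
operations, so absolute worker counts and costs from the simulation are
scenario-specific, while the *relative* with/without storage comparisons
are the meaningful outputs.

## Schedule optimization

Demand is decomposed into blocks of `block_size` trays (default 10; a
week's non-divisible remainder forms one smaller block). A block shipped
in week `s` may be grafted in weeks `max(1, s − S) … s` — grafting only
moves *earlier*, never later — where `S` is the crop's maximum storage
duration in whole weeks; a block shifted `k` weeks spends exactly `k`
weeks in storage. The objective is lexicographic: minimize the peak
weekly grafting load, then the population variance of weekly loads over
the full horizon (zero weeks included), with a seeded random tie-break.

Solver. Moving `s` trays from week `a` to week `b` lowers the sum of
squared loads iff `L_b + s < L_a`, and such a move can never create a
new maximum — so descending on the sum of squares is a valid descent on
the lexicographic objective (variance and sum of squares are equivalent
at fixed totals). The greedy solver combines:

* single-block relocations;
* chain relocations of equal-size blocks (A→B enabled by B→C, …): these
  telescope so only the endpoint loads change, and BFS finds improving
  chains of any length;
* a bounded walk search (depth 6 for ≤ 12 blocks, else 3–4) for
  mixed-size exchanges such as swaps, whose intermediate states do not
  improve.

When all blocks share one size, the feasible load vectors are the base
set of a polymatroid (each block picks one week from an interval
window), where exchange-local optima of a separable convex objective are
global — the test suite certifies this against an exhaustive oracle.
With mixed sizes the optimal exchange can be a long plateau walk that a
bounded search misses, so `optimize_schedule` defaults to `method="auto"`:
exact enumeration of per-week shift multisets whenever the instance
admits ≤ 20,000 placements, greedy descent otherwise. Mixed-size *large*
instances are therefore best-effort; in the studies here demands are
multiples of the block size, where the greedy is exact.

The enumerator (`enumerate_optimal`) exploits that blocks from the same
demand week are interchangeable, enumerating shift multisets rather than
labelled placements, and refuses instances above a configurable bound
(500,000 placements).

## Production simulation

The nursery flow is seeding → germination/growth → sorting →
pre-grafting growth → grafting → healing (1 week) → optional storage →
finishing (2 weeks) → shipment. The ledger's week axis is
shipment-aligned: the constant seeding-to-graft (tomato 3 weeks,
watermelon 2) and finishing leads are normalized out, so with zero noise
every tray ships exactly in its demand week, and the simulator's storage
occupancy equals the schedule module's event table. Seeding weeks are
back-computed from graft weeks, so growth-duration noise does not move
the planned graft week.

Stochastic draws are per weekly batch (one batch per schedule
assignment), from a symmetric truncated normal at ± 3 sd:

| quantity | mean | sd | note |
|---|---|---|---|
| stage durations | nominal weeks | 22 % of nominal | rounded to whole weeks, min 1 |
| survival fraction | 1 − mean loss (default loss 0) | 0.05 | not capped at 1, keeping shipping unbiased; lost trays are not re-sown |
| grafting speed multiplier | 1.00 | 0.10 | applied per week to all workers |

The published variability range for durations is 21–23 %; 0.22 is the
midpoint and is exposed per crop. Each noise source draws from its own
`SeedSequence` substream, so toggling one source leaves the others'
draws unchanged and a fixed seed reproduces ledgers bit for bit.
Replication defaults to 5 runs with t-based margins of error
(`t₀.₉₇₅,₄ · sd/√5`); tests raise the replicate count where tighter
Monte-Carlo bounds are needed.

## Labor model

Learning curve `T(P) = X + N·Pᶜ`, `P ≥ 1` in practice days. `X` is the
expert time (tomato 12 s/plant, watermelon 24), `N = initial − X`
(initial 36 s / 64 s), and `c = log 0.05 / log 21 ≈ −0.984` so that
after the 3-week (21-day) learning period only 5 % of the learnable
amplitude remains. This calibration reproduces both printed endpoints
exactly; note `T(21) = X + 0.05·N`, which for tomato is 13.2 s — the
curve approaches the asymptote in amplitude fraction, not within 5 % of
`X` itself.

Workforce sizing per week: the skilled crew is constant, sized as
`ceil(min weekly plants × X / (40 h × 3600))` from the *planned*
schedule minimum (the base load always present). The residual is covered
by unskilled workers, retained most-experienced-first; capacity is
accumulated day by day along the learning curve (5 workdays/week, 8
h/day). Up to 50 unskilled per week are seasonal hires (minimum wage
$7.80/h + 25 % fringe); any further workers are migrants ($7.80/h, 7
billed expense days × $17.50, and $500 transport charged once per
migrant on arrival). Practice accrues only on employed workdays and a
released worker restarts the curve if rehired — skill is retained only
through continuous employment, which is the mechanism by which a
flattened schedule lowers cost per plant. Shift length (40 h/week,
5 workdays) is a config default.

## Chamber cost model

Design base: 7.6 × 7.6 × 3.7 m insulated walk-in room (213.7 ≈ 214 m³)
inside a warehouse at 15 °C, two shelving units × 5 layers of 7.6 × 3.4
m, 960 trays of 0.23 m², lit 24 h/day. Luminaire count per layer is the
lumen method: `ceil(PPF · area / (37 µmol s⁻¹ · CU · MF))` with
coefficient of utilization 0.6 and maintenance factor 0.9 — a single
configurable utilization factor stands in for full photometric cavity
tables; with these defaults the 5 vs 12 µmol set-points need 70 vs 160
lamps, whose cost ratio matches the published luminaire capital ratio
exactly. Electricity is a sensible-load model: lamps draw 32 W each;
the chiller removes lighting heat plus envelope conduction
(`U = 0.25 W m⁻² K⁻¹`, default rate $0.11/kWh) at COP 2.93. Latent
(humidity) load is recorded in the design but not modelled. Unit capital
costs (structure $533.47/m², shelving $84.61/m², chiller $24.53/m²,
luminaire $23.57 each) are config defaults back-solved from the
published itemized table; plant capacities per m² of footprint (tomato
3,307, watermelon 2,116) are taken as direct parameters because their
derivation from tray counts and densities does not close exactly.
Money is computed at full precision and rounded to cents for display.

The absolute reference electricity costs ($0.79 and $2.21 per m²
per week) are not reproduced by this sensible-load model at any single
electricity rate — their ratio cannot come from lighting and conduction
alone, pointing to additional inputs (latent load, equipment overheads)
behind them. They enter only through the packaged reference table, from
which the per-plant identities ($0.00024 and $0.00104 per plant-week)
are computed.

## Storability analysis

Scores are the printed per-day means (1–5 scale; ≥ 3.0 marketable) on
days 1, 7, 14, 21, 28 (in storage) and 31, 42 (post-storage). The
"6-week mean" is the unweighted mean of the seven printed values,
rounded half-up to one decimal; one reference row (Sweet Harmony, 3.0)
recomputes to 3.1 from the tabulated values — presumably averaged from
unrounded raw scores — and is left as a documented discrepancy.
Clustering is Ward linkage on the Euclidean distance between the
7-dimensional score vectors (`scipy.cluster.hierarchy`), cut to k
groups, labelled A, B, … by descending cluster mean; trajectories are
sorted by cultivar first so the partition is input-order invariant.
Exact reproduction of every published cluster letter is not promised
(the original preprocessing is unstated); the strong separations are
asserted instead. Storability: the largest `k ∈ {0..4}` with all scores
through day `7k` marketable, plus recovered day-42 quality when the full
4-week stay is claimed — reproducing 4 weeks for tomato at 10 °C and 2
weeks for the most sensitive watermelon scion at 12 °C.

## Comparison statistics

Per-metric comparisons between arms use a two-sided Welch
(unequal-variance) t-test over replicate runs; the source material says
only "T-test", and Welch is the safe default when arm variances differ
(the without-storage arm is systematically more variable). Zero-variance
metrics are reported as *not testable* rather than as a NaN p-value.
Percentage reductions are `(without − with)/without × 100`, rounded to
whole percent. The published per-week pooled tests (with varying n per
scenario) are under-specified; the pipeline writes both per-week means ±
ME and the per-metric replicate tests.

## What the synthetic scenarios do not show

Passing tests demonstrate internal consistency (conservation,
optimality, unbiasedness, reproducibility) and reproduction of the
desk-computable published quantities. They do not validate the absolute
worker counts or costs for any real nursery: those depend on the true
demand magnitudes, shift lengths, and wage details of the operation.
Germination-chamber microclimate, greenhouse spatial layout, multi-crop
concurrent production, overtime/payroll rules beyond the stated fringe,
and storage-capacity-constrained optimization (capacity is an output,
not a constraint) are out of scope.
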