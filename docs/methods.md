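# Methods

## Model

The simulator implements a surface-bound, metabolically coupled replicator
community as a stochastic cellular automaton. Sites of a toroidal square
lattice are empty or hold one replicator; a replicator's heritable state is
its activity vector `E ∈ R^A_{≥0}`, its replicability `k`, and (not
heritable) the index of the single activity its current fold expresses.

One *generation* consists of `n_grid²` site visits at independently uniform
random positions, so per-site visit counts are Poisson with mean 1. A visit
to an occupied site kills the occupant with probability `P_death` and
otherwise does nothing. A visit to an empty site runs a replication
contest: every occupant of the 3×3 replication neighbourhood claims the
vacancy with weight `W = k·M`, against the constant empty claim `C_empty`;
`M` is the geometric mean over activities of the activity sums in the
*candidate's own* metabolic neighbourhood (the candidate is a property of
the replicator, not of the vacancy). The winner places a copy, which is a
mutant with probability `P_mutation`. After every demographic update,
`⌊D⌋` random 2×2 block rotations are applied, plus one more with
probability `frac(D)`; a generation closes with one fold-switch sweep over
all occupants in row-major order.

Assumptions inherited from the model family: metabolism is implicit (only
the presence of all `A` activities within `N_met` cells matters);
metabolites crossing the neighbourhood boundary are lost, which is what
makes `N_met` a proxy for metabolite diffusion; all replicators are equally
mobile; degradation is state-independent.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `k_min`, `k_max` | replicability range (copies per unit fitness scale) | 2.0, 4.0 | `k_max ∈ {2.0, 2.5, 4.0}` in scans |
| `A` | activities required by metabolism | 3 | 3 or 5 in scans |
| `E_max` | cap on any single activity | 10.0 | |
| `D` | diffusion steps per demographic update | 0.0 | 0 or 5 in scans; fractional part = Bernoulli extra step |
| `N_met` | metabolic neighbourhood (cells) | 5 | catalogue {5, 9, 13, 25, 29, 49}; 0 = whole grid (mean field) |
| `N_repl` | replication neighbourhood (cells) | 9 | Moore 3×3 |
| `b` | catalytic trade-off exponent | 1.0 | < 1 strong, > 1 weak |
| `g` | activity/replicability trade-off exponent | 1.0 | |
| `P_death` | per-visit decay probability | 0.1 | |
| `P_mutation` | per-replication mutation probability | 0.01 | |
| `C_empty` | empty-site claim | 20.0 | |
| `n_grid` | lattice side | 300 | 90,000 sites |
| `init_occupancy` | initial occupied fraction | 0.80 | exact count, not Bernoulli |
| `m_significant` | significance threshold for classification | 0.01 | |
| `parasite_threshold` | all-activities-below ⇒ parasite | 0.1 | |

The scanned defaults (`k_max=4`, `A=3`, `D=0`, `N_met=5`, `b=g=1`) are the
centre of the studied grid; every test and the acceptance script set them
explicitly.

The two classification thresholds deliberately coexist: the parasite rule
(`E_a ≤ 0.1` for all `a`) is applied first, then significant activities of
non-parasites are counted at `m = 0.01`. A replicator with every activity
in (0.01, 0.1] is therefore a parasite, not a low-grade generalist.

## Neighbourhood masks

Sizes 5 and 13 are von Neumann of radius 1 and 2. Size 29 is the Euclidean
disk of radius 3 (`dx² + dy² ≤ 9`): the radius-3 von Neumann diamond has
only 25 cells, so the disk is the only standard 29-cell member of that
family. Sizes 9/25/49 are Moore squares. All masks include the focal cell
(a replicator's own expressed activity counts toward its metabolic
neighbourhood) and are point-symmetric.

## Phenotype space and sampling

Feasibility means `Σ E_a^b ≤ E_max^b` and `k ≤ bound(Ê)`; both are checked
with a relative boundary slack of 1e-12 so exact surface points (bump
points) remain feasible.

Initial phenotypes are uniform on the catalytically feasible region. The
sampler substitutes `v_a = (E_a/E_max)^b`, under which the region becomes
the simplex `Σ v ≤ 1` and the uniform law on `E` becomes
Dirichlet(1/b, …, 1/b, 1) on `(v, slack)`; drawing `v` that way and mapping
back is an exact uniform sample with no rejection step. (Plain box
rejection has acceptance ≈ 1.3·10⁻⁶ at `b = 0.2`, `A = 3`, and is kept only
as a cross-check oracle in the tests, where a KS test compares the two
samplers at `b = 1`.) Replicability is then uniform on
`[k_min, bound(Ê)]`.

Mutation (default, `mutation_mode = "global"`): the parent's activity
vector is projected radially onto the catalytic surface (its *bump point*
`B`), and each mutant activity is drawn uniformly on `[0, B_a]`; any such
point is feasible, so no rejection is needed. An all-zero parent has no
bump direction and its mutants are drawn uniformly from the whole feasible
region — this is the route by which parasites re-acquire function. The
mutant's `k` is uniform on `[k_min, bound(Ê_mutant)]`; `k` has no separate
bump coordinate because the replicability surface is its only stated
constraint. A local-Gaussian alternative (`mutation_mode = "local"`,
scale `local_sigma`) is available for sensitivity checks but is not the
default: global resampling is what lets parasites arise at the modelled
rate.

Two structural consequences are worth noting. First, an exact specialist
`(E_max, 0, …, 0)` is absorbing: its bump box has zero width off-axis, so
promiscuity cannot evolve from exact single-activity ancestors — which is
why the initial community is sampled from the full feasible region rather
than from the axes. Second, mutants' minor activities shrink by a uniform
factor per mutation event on average, so crossing a fixed significance
threshold takes several mutation events along a lineage; community-level
classification statistics therefore move on a timescale of thousands of
generations at the default turnover (`P_death·P_mutation ≈ 10⁻³`
mutations per lineage per generation).

## Expression and fold switching

The steric assumption is that a folded ribozyme catalyses one reaction per
time step. Neighbourhood activity sums therefore count only each
occupant's currently expressed activity (`metabolic_semantics =
"expressed"`; the whole-vector variant is retained behind the flag for
sensitivity analysis). Between generations a replicator with ≥ 2 positive
activities refolds with probability `geomean(E⁺)/max(E⁺)` — balanced
activities switch freely, a dominant activity locks its fold in.

Which structure the molecule folds *into* — at birth and when a refold
fires — is drawn with probability proportional to the activity value
(`expression_weighting = "activity"`). This is a deliberate design choice
at a point the model definition leaves open, and it is load-bearing.
Because continuous mutation never produces exact zeros, every replicator
permanently has `A` positive activities; under a uniform fold choice a
near-specialist `(9, ε, ε)` would express `ε` two-thirds of the time, its
effective catalytic output would be `≈ Σ E/A` — *below* that of a balanced
generalist — and balanced promiscuity would be the global attractor for
every `b`, erasing the specialist regimes entirely. Weighting fold choice
by activity (fold stability tracks catalytic efficiency, which is also the
physical reading of the lock-in formula above) restores the intended
competition between specialists and generalists. The uniform variant is
kept as a config option.

Refolding runs once per generation as a sweep, reading "between time
steps" against the definition of a generation as the unit time step; a
per-visit variant sits behind `refold_per_update`.

## Diffusion

An elementary step rotates the 2×2 block at a uniformly random anchor
(torus-wrapped) by 90° clockwise or anticlockwise with equal chance —
random anchors, not the alternating even/odd block partition of the
textbook algorithm, following the model's own wording. Rotations move
whole cell contents, so any sequence of them conserves the replicator
multiset exactly; this is asserted over 10⁴ rotations in the tests, and a
frozen-dynamics mixing check (12.5M rotations ≈ 1,000 generations at
`D = 5` on 50×50) drives the lag-1 occupancy autocorrelation of a
half-plane pattern from > 0.9 to < 0.1.

## Numerical choices

- Claim selection draws one uniform number against the cumulative fitness
  walk (candidates in mask order, empty claim as the remainder); the
  normalisation `p_e + Σ p_i = 1` is exact by construction.
- All randomness flows from one `numpy.random.Generator` seeded from
  `(params, seed)`, shared by the Python layer and the numba kernels, so
  runs are bit-reproducible; replicate seeds are 31-bit integers derived
  from the base seed via `SeedSequence`.
- In mean-field mode (`N_met = 0`) whole-grid activity sums are maintained
  incrementally across births/deaths/refolds and recomputed from scratch at
  each generation start to cap float drift.
- Degenerate inputs: an empty candidate set or all-zero claims leave the
  site empty with probability 1; the generalism index of an empty community
  is NaN (`"no population"`); an all-zero activity vector expresses index 0
  by convention and contributes nothing.
- Extinction is checked once per generation (indistinguishable from
  per-update checking at `P_death = 0.1`, and much cheaper).

## What the tests and the acceptance script do (and do not) show

The synthetic initial community — exact 80% occupancy, uniform-feasible
phenotypes, activity-weighted folds — defines the study conditions; there
are no external data. Scaled-down runs used by the tests and
`scripts/acceptance.py`: equation-level checks are exact; the death-only
closed form and Poisson visit statistics run on the full 300×300 lattice
for one generation; the evolved-regime checks use a 100×100 lattice for
2,000 generations with 5 replicates per setting, and the mean-field check a
50×50 lattice. At these sizes the weak-trade-off/immobile regime
(`b = 1.6`, `D = 0`) reproducibly fixes full promiscuity (`G ≈ 1`). The
neutral-trade-off/mixing regime (`b = 1.1`, `D = 5`) shows the specialist
sweep in progress (`G` falling from ~1.0 through ~0.83 at generation 2,000,
reaching `G ≈ 0.44` with all three specialist classes abundant by
generation ~6,000–8,000): the direction is robust, but the endpoint lies
beyond the 2,000-generation window because threshold crossings are
mutation-limited (see above). Likewise the mean-field run reproduces the
runaway selection for replicability (mean `k` 2.24 → 3.7, activities
eroding toward zero) that degrades the community toward parasitism, but
the strict parasite classification or extinction is not reached within
2,000 generations under continuous phenotypes. Both are reported as
measured; the corresponding assertions in `tests/test_acceptance.py` state
the short-horizon endpoints and fail honestly at these scales.

Passing tests show the update rules, constraints and estimators behave as
specified under the modelled conditions; they do not calibrate the model
against laboratory kinetics, real ribozyme trade-off measurements, or
sequence-level evolution (phenotypes, not sequences, are the state).

## Known limitations

- Full-scale scans (300×300, 50,000 generations, ≥ 5 replicates per cell
  of the parameter grid) are supported by the sweep runner but are
  cluster-scale work; desk-scale runs shown here use reduced lattices and
  horizons.
- Stationarity is not detected formally; runs stop at the generation limit
  or extinction.
- The census classifies by phenotype (significant activities), not by the
  currently expressed fold; per-grid-site variants of the promiscuity index
  are not implemented.
- No cluster-geometry statistics beyond the lag-1 mixing diagnostic.
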