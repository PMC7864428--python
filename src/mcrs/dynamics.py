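"""Demographic update rules and the generation/simulation loop.

The demographic model: a replicator at site *i* has fitness ``W_i = k_i M_i``
where ``k_i`` is its replicability and ``M_i`` its metabolic efficiency, the
geometric mean of the per-activity sums over its metabolic neighbourhood — a
single missing activity means no monomer supply and ``M_i = 0``.  An empty
site is claimed by neighbour *i* with probability
``p_i = W_i / (C_e + sum_r W_r)`` and stays empty with the complementary
``p_e = C_e / (C_e + sum_r W_r)``.  Occupied sites decay with probability
``P_death`` per visit.  One generation performs ``side**2`` such visits on
uniformly random sites (visit counts per site are Poisson with mean 1),
interleaved with diffusion steps, and closes with a fold-switch sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .lattice import Lattice, init_lattice, mask_for_size
from .params import FULL_GRID, Params

__all__ = [
    "ClaimSet",
    "SiteEvent",
    "RunResult",
    "metabolic_efficiency",
    "fitness",
    "claim_probabilities",
    "transition_probability",
    "refold_sweep",
    "site_update",
    "run_generation",
    "run_simulation",
]


@dataclass(frozen=True)
class ClaimSet:
    """Normalized claims on an empty site: candidates' p_i plus the empty p_e."""

    p: np.ndarray
    p_empty: float


@dataclass(frozen=True)
class SiteEvent:
    """Outcome of one site visit."""

    kind: str  # "survived" | "death" | "empty" | "birth"
    parent: tuple[int, int] | None = None
    mutated: bool = False


@dataclass
class RunResult:
    """Outcome of :func:`run_simulation`."""

    records: list  # CensusRecords at the census cadence
    lattice: Lattice
    stop_reason: str  # "completed" | "extinction"
    params: Params
    seed: int

    def to_frame(self):
        from .metrics import records_to_frame

        return records_to_frame(self.records, self.params.A)


def metabolic_efficiency(S, A: int | None = None) -> float:
    """Geometric mean of the activity sums: ``M = (prod_a S_a)**(1/A)``.

    Zero whenever any activity sum is zero (incomplete local metabolism).
    """
    S = np.asarray(S, dtype=float)
    if A is None:
        A = S.shape[0]
    elif S.shape[0] != A:
        raise ValueError(f"S has length {S.shape[0]}, expected A={A}")
    if np.any(S <= 0.0):
        return 0.0
    return float(np.prod(S) ** (1.0 / A))


def fitness(k: float, M: float) -> float:
    """Replication fitness ``W = k * M``."""
    if k < 0 or M < 0:
        raise ValueError("k and M must be non-negative")
    return k * M


def claim_probabilities(W, C_e: float) -> ClaimSet:
    """Claims of candidates with fitnesses ``W`` on an empty site.

    ``p_i = W_i / (C_e + sum W)``; the site stays empty with the remaining
    ``p_e = C_e / (C_e + sum W)``.  If every claim (including ``C_e``) is
    zero the site stays empty with probability one.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0) or C_e < 0:
        raise ValueError("fitnesses and C_e must be non-negative")
    total = C_e + float(W.sum())
    if total == 0.0:
        return ClaimSet(p=np.zeros_like(W), p_empty=1.0)
    p = W / total
    return ClaimSet(p=p, p_empty=1.0 - float(p.sum()))


def transition_probability(E_positive) -> float:
    """Fold-switch probability of a promiscuous ribozyme.

    ``P = geomean(E) / max(E)`` over its strictly positive activities: equal
    activities switch every time, a dominant activity locks the fold in.
    """
    E = np.asarray(E_positive, dtype=float)
    if E.size < 1 or np.any(E <= 0.0):
        raise ValueError("transition_probability needs >= 1 strictly positive values")
    B = E.size
    return float(np.prod(E) ** (1.0 / B) / np.max(E))


def _flags(params: Params):
    return (
        params.metabolic_semantics == "expressed",
        params.N_met == FULL_GRID,
        params.mutation_mode == "local",
        params.expression_weighting == "activity",
    )


def global_activity_sums(lattice: Lattice, semantics: str = "expressed") -> np.ndarray:
    """Whole-grid per-activity sums (the mean-field neighbourhood sums)."""
    gs = np.zeros(lattice.A, dtype=np.float64)
    occ = lattice.occ
    if semantics == "expressed":
        xs, ys = np.nonzero(occ)
        es = lattice.expressed[xs, ys]
        np.add.at(gs, es, lattice.E[xs, ys, es])
    else:
        gs[:] = lattice.E[occ].sum(axis=0)
    return gs


def _masks(params: Params):
    rep_off = mask_for_size(params.N_repl).offsets
    if params.N_met == FULL_GRID:
        met_off = np.zeros((1, 2), dtype=np.int64)  # unused in mean-field mode
    else:
        met_off = mask_for_size(params.N_met).offsets
    return met_off, rep_off


def refold_sweep(lattice: Lattice, rng: np.random.Generator,
                 params: Params) -> int:
    """Fold-switch attempt for every occupant (row-major); returns #switches.

    Promiscuous replicators refold with :func:`transition_probability`; the
    new expressed activity is drawn among the other positive ones, weighted
    by their values by default.  Phenotypes and positions never change.
    """
    expressed_sem, full_met, _, expr_weighted = _flags(params)
    gs = global_activity_sums(lattice, params.metabolic_semantics) if full_met \
        else np.zeros(lattice.A)
    return int(K.refold_sweep_kernel(rng, lattice.occ, lattice.E,
                                     lattice.expressed, full_met, gs,
                                     expressed_sem, expr_weighted))


_EVENT_NAMES = {
    K.EV_SURVIVED: "survived",
    K.EV_DEATH: "death",
    K.EV_EMPTY_STAYS: "empty",
    K.EV_BIRTH_COPY: "birth",
    K.EV_BIRTH_MUTANT: "birth",
}


def site_update(lattice: Lattice, pos: tuple[int, int], rng: np.random.Generator,
                params: Params) -> SiteEvent:
    """Visit one site: death test if occupied, replication contest if empty."""
    expressed_sem, full_met, mut_local, expr_weighted = _flags(params)
    met_off, rep_off = _masks(params)
    gs = global_activity_sums(lattice, params.metabolic_semantics) if full_met \
        else np.zeros(lattice.A)
    x, y = lattice.wrap(*pos)
    A = lattice.A
    code, px, py = K.site_update_kernel(
        rng, lattice.occ, lattice.E, lattice.k, lattice.expressed, x, y,
        met_off, rep_off,
        params.b, params.g, params.E_max, params.k_min, params.k_max,
        params.P_death, params.P_mutation, params.C_empty,
        expressed_sem, full_met, mut_local, params.local_sigma,
        params.refold_per_update, expr_weighted,
        gs, np.zeros(A), np.zeros(rep_off.shape[0]), np.zeros(A))
    return SiteEvent(
        kind=_EVENT_NAMES[int(code)],
        parent=(int(px), int(py)) if code in (K.EV_BIRTH_COPY, K.EV_BIRTH_MUTANT) else None,
        mutated=code == K.EV_BIRTH_MUTANT,
    )


def run_generation(lattice: Lattice, rng: np.random.Generator,
                   params: Params) -> np.ndarray:
    """Advance the lattice by one generation in place; returns visit counts.

    ``side**2`` site updates on independently uniform random sites, each
    followed by the diffusion steps implied by mobility ``D`` (integer part
    always, fractional part as a Bernoulli extra), then one fold-switch
    sweep.
    """
    expressed_sem, full_met, mut_local, expr_weighted = _flags(params)
    met_off, rep_off = _masks(params)
    gs = global_activity_sums(lattice, params.metabolic_semantics) if full_met \
        else np.zeros(lattice.A)
    visits = np.zeros((lattice.side, lattice.side), dtype=np.int64)
    d_int = int(np.floor(params.D))
    d_frac = float(params.D - d_int)
    K.generation_kernel(
        rng, lattice.occ, lattice.E, lattice.k, lattice.expressed, visits,
        met_off, rep_off,
        params.b, params.g, params.E_max, params.k_min, params.k_max,
        params.P_death, params.P_mutation, params.C_empty,
        d_int, d_frac,
        expressed_sem, full_met, mut_local, params.local_sigma,
        params.refold_per_update, expr_weighted, gs)
    return visits


def run_simulation(params: Params, seed: int | None = None,
                   progress: bool = False) -> RunResult:
    """Full run: random initial community, generation loop, periodic census.

    Stops after ``n_generations`` or at the extinction of the last replicator
    (checked once per generation), whichever comes first.  Fully reproducible
    from ``(params, seed)``; ``seed`` defaults to ``params.seed``.
    """
    from .metrics import census

    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    lattice = init_lattice(params, rng)
    records = [census(lattice, 0, params)]
    stop_reason = "completed"
    for gen in range(1, params.n_generations + 1):
        run_generation(lattice, rng, params)
        extinct = lattice.occupancy() == 0
        if gen % params.census_every == 0 or extinct or gen == params.n_generations:
            records.append(census(lattice, gen, params))
        if progress and gen % 100 == 0:
            print(f"generation {gen}: occupancy {lattice.occupancy()}")
        if extinct:
            stop_reason = "extinction"
            break
    return RunResult(records=records, lattice=lattice, stop_reason=stop_reason,
                     params=params, seed=seed)
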