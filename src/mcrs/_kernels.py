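"""Numba-jitted update engine.

All stochastic state transitions (death, replication claims, mutation,
fold switching, block-rotation diffusion) are implemented here once, as
nopython kernels operating on the raw lattice arrays, and are driven by a
single ``numpy.random.Generator`` so that a run is fully reproducible from
``(params, seed)``.  The public wrappers in :mod:`mcrs.dynamics` and
:mod:`mcrs.diffusion` call these same kernels, whether updating one site in a
unit test or sweeping whole generations.

Conventions: lattices are ``(side, side)`` toroidal arrays indexed
``(row, col)`` with Python modulo wrapping; ``expr`` holds the expressed
activity index or ``-1`` when empty; ``gs`` carries whole-grid activity sums
and is only consulted when ``full_met`` is set (mean-field metabolite
mixing).
"""

import numpy as np
from numba import njit

NO_ACT = -1

# Event codes returned by site_update_kernel.
EV_SURVIVED = 0
EV_DEATH = 1
EV_EMPTY_STAYS = 2
EV_BIRTH_COPY = 3
EV_BIRTH_MUTANT = 4


@njit(cache=True)
def _gs_add(gs, E, expr, x, y, expressed_sem, sign):
    if expressed_sem:
        e = expr[x, y]
        if e >= 0:
            gs[e] += sign * E[x, y, e]
    else:
        for a in range(E.shape[2]):
            gs[a] += sign * E[x, y, a]


@njit(cache=True)
def met_efficiency_kernel(occ, E, expr, met_off, x, y,
                          expressed_sem, full_met, gs, S):
    """Metabolic efficiency M of the replicator at (x, y).

    Geometric mean over activities of the neighbourhood activity sums; zero
    as soon as any activity is absent from the neighbourhood (incomplete
    metabolism means no monomer supply).
    """
    side = occ.shape[0]
    A = E.shape[2]
    if full_met:
        prod = 1.0
        for a in range(A):
            if gs[a] <= 0.0:
                return 0.0
            prod *= gs[a]
        return prod ** (1.0 / A)
    for a in range(A):
        S[a] = 0.0
    for i in range(met_off.shape[0]):
        xx = (x + met_off[i, 0]) % side
        yy = (y + met_off[i, 1]) % side
        if occ[xx, yy]:
            if expressed_sem:
                e = expr[xx, yy]
                if e >= 0:
                    S[e] += E[xx, yy, e]
            else:
                for a in range(A):
                    S[a] += E[xx, yy, a]
    prod = 1.0
    for a in range(A):
        if S[a] <= 0.0:
            return 0.0
        prod *= S[a]
    return prod ** (1.0 / A)


@njit(cache=True)
def mutate_kernel(rng, Ep, kp, Ec,
                  b, g, E_max, k_min, k_max, mut_local, local_sigma):
    """Draw a mutant phenotype of parent (Ep, kp); writes activities into Ec,
    returns the mutant replicability.

    Global mode: activities uniform in the parent's bump box (radial
    projection onto the catalytic trade-off surface); an all-zero parent has
    no bump direction, so the mutant is uniform over the whole feasible
    region (sampled exactly via the Dirichlet(1/b, ..., 1/b, 1) transform).
    Replicability is uniform between k_min and its trade-off bound at the
    mutant's effective activity.

    Local mode: Gaussian proposals around the parent, re-drawn until the
    catalytic constraint holds; k perturbed and clipped to its bound.
    """
    A = Ep.shape[0]
    budget = E_max**b
    if mut_local:
        while True:
            tot = 0.0
            for a in range(A):
                v = Ep[a] + rng.standard_normal() * local_sigma
                if v < 0.0:
                    v = 0.0
                Ec[a] = v
                tot += v**b
            if tot <= budget * (1.0 + 1e-12):
                break
        e_hat = tot ** (1.0 / b)
        if e_hat > E_max:
            e_hat = E_max
        hi = (E_max**g - e_hat**g) ** (1.0 / g) * (k_max - k_min) / E_max + k_min
        k_sigma = local_sigma * (k_max - k_min) / E_max
        kc = kp + rng.standard_normal() * k_sigma
        if kc < k_min:
            kc = k_min
        if kc > hi:
            kc = hi
        return kc
    tot = 0.0
    for a in range(A):
        tot += Ep[a] ** b
    if tot == 0.0:
        ssum = rng.gamma(1.0)
        for a in range(A):
            Ec[a] = rng.gamma(1.0 / b)
            ssum += Ec[a]
        for a in range(A):
            Ec[a] = E_max * (Ec[a] / ssum) ** (1.0 / b)
    else:
        s = (budget / tot) ** (1.0 / b)
        for a in range(A):
            Ec[a] = rng.random() * s * Ep[a]
    tot = 0.0
    for a in range(A):
        tot += Ec[a] ** b
    e_hat = tot ** (1.0 / b)
    if e_hat > E_max:
        e_hat = E_max
    hi = (E_max**g - e_hat**g) ** (1.0 / g) * (k_max - k_min) / E_max + k_min
    return k_min + rng.random() * (hi - k_min)


@njit(cache=True)
def _draw_expressed(rng, E, x, y, weighted):
    """Folded structure of the occupant at (x, y): index among its strictly
    positive activities, chosen with probability proportional to the activity
    value (``weighted``) or uniformly; 0 if all activities are zero."""
    A = E.shape[2]
    npos = 0
    tot = 0.0
    for a in range(A):
        if E[x, y, a] > 0.0:
            npos += 1
            tot += E[x, y, a]
    if npos == 0:
        return 0
    if weighted:
        u = rng.random() * tot
        acc = 0.0
        for a in range(A):
            if E[x, y, a] > 0.0:
                acc += E[x, y, a]
                if u < acc:
                    return a
        return A - 1  # guard against round-off
    j = rng.integers(0, npos)
    cnt = 0
    for a in range(A):
        if E[x, y, a] > 0.0:
            if cnt == j:
                return a
            cnt += 1
    return 0  # unreachable


@njit(cache=True)
def refold_site_kernel(rng, occ, E, expr, x, y, full_met, gs, expressed_sem,
                       expr_weighted):
    """One fold-switch attempt for the occupant at (x, y).

    A replicator with B >= 2 strictly positive activities refolds with
    probability geomean(E_positive) / max(E_positive); the new expressed
    index is drawn over its *other* positive activities, weighted by their
    values (default) or uniformly.  Returns 1 if the expressed activity
    changed.
    """
    A = E.shape[2]
    npos = 0
    maxv = 0.0
    prod = 1.0
    for a in range(A):
        v = E[x, y, a]
        if v > 0.0:
            npos += 1
            prod *= v
            if v > maxv:
                maxv = v
    if npos < 2:
        return 0
    p = prod ** (1.0 / npos) / maxv
    if rng.random() >= p:
        return 0
    cur = expr[x, y]
    n_others = npos
    tot_others = 0.0
    for a in range(A):
        if E[x, y, a] > 0.0 and a != cur:
            tot_others += E[x, y, a]
    if cur >= 0 and E[x, y, cur] > 0.0:
        n_others -= 1
    if n_others == 0:
        return 0
    new = cur
    if expr_weighted:
        u = rng.random() * tot_others
        acc = 0.0
        for a in range(A):
            if E[x, y, a] > 0.0 and a != cur:
                acc += E[x, y, a]
                if u < acc:
                    new = a
                    break
        if new == cur:  # round-off guard: take the last eligible index
            for a in range(A - 1, -1, -1):
                if E[x, y, a] > 0.0 and a != cur:
                    new = a
                    break
    else:
        j = rng.integers(0, n_others)
        cnt = 0
        for a in range(A):
            if E[x, y, a] > 0.0 and a != cur:
                if cnt == j:
                    new = a
                    break
                cnt += 1
    if new == cur:
        return 0
    if full_met and expressed_sem:
        gs[cur] -= E[x, y, cur]
        gs[new] += E[x, y, new]
    expr[x, y] = new
    return 1


@njit(cache=True)
def refold_sweep_kernel(rng, occ, E, expr, full_met, gs, expressed_sem,
                        expr_weighted):
    """Row-major fold-switch attempt for every occupant; returns #switches."""
    side = occ.shape[0]
    n = 0
    for x in range(side):
        for y in range(side):
            if occ[x, y]:
                n += refold_site_kernel(rng, occ, E, expr, x, y,
                                        full_met, gs, expressed_sem,
                                        expr_weighted)
    return n


@njit(cache=True)
def site_update_kernel(rng, occ, E, k, expr, x, y, met_off, rep_off,
                       b, g, E_max, k_min, k_max,
                       P_death, P_mut, C_e,
                       expressed_sem, full_met, mut_local, local_sigma,
                       refold_per_update, expr_weighted, gs, S, W, Ec):
    """One visit to site (x, y); returns (event, parent_x, parent_y).

    Occupied site: the occupant dies with probability P_death, otherwise
    nothing happens (optionally a per-visit refold attempt).  Empty site: the
    occupants of the replication neighbourhood claim it in proportion to
    their fitnesses W = k * M (each M over the candidate's own metabolic
    neighbourhood), against the empty claim C_e; the winning parent places a
    copy, mutated with probability P_mut, whose expressed activity is uniform
    over its positive activities.
    """
    side = occ.shape[0]
    A = E.shape[2]
    if occ[x, y]:
        if rng.random() < P_death:
            if full_met:
                _gs_add(gs, E, expr, x, y, expressed_sem, -1.0)
            occ[x, y] = False
            expr[x, y] = NO_ACT
            k[x, y] = 0.0
            for a in range(A):
                E[x, y, a] = 0.0
            return EV_DEATH, -1, -1
        if refold_per_update:
            refold_site_kernel(rng, occ, E, expr, x, y,
                               full_met, gs, expressed_sem, expr_weighted)
        return EV_SURVIVED, -1, -1
    # Empty site: competition for the vacancy.
    n_rep = rep_off.shape[0]
    total = C_e
    for i in range(n_rep):
        xx = (x + rep_off[i, 0]) % side
        yy = (y + rep_off[i, 1]) % side
        w = 0.0
        if occ[xx, yy]:
            m = met_efficiency_kernel(occ, E, expr, met_off, xx, yy,
                                      expressed_sem, full_met, gs, S)
            w = k[xx, yy] * m
        W[i] = w
        total += w
    if total <= 0.0:
        return EV_EMPTY_STAYS, -1, -1
    u = rng.random() * total
    chosen = -1
    acc = 0.0
    for i in range(n_rep):
        acc += W[i]
        if u < acc:
            chosen = i
            break
    if chosen < 0:
        return EV_EMPTY_STAYS, -1, -1
    px = (x + rep_off[chosen, 0]) % side
    py = (y + rep_off[chosen, 1]) % side
    mutated = P_mut > 0.0 and rng.random() < P_mut
    if mutated:
        kc = mutate_kernel(rng, E[px, py], k[px, py], Ec,
                           b, g, E_max, k_min, k_max, mut_local, local_sigma)
        for a in range(A):
            E[x, y, a] = Ec[a]
        k[x, y] = kc
    else:
        for a in range(A):
            E[x, y, a] = E[px, py, a]
        k[x, y] = k[px, py]
    occ[x, y] = True
    expr[x, y] = _draw_expressed(rng, E, x, y, expr_weighted)
    if full_met:
        _gs_add(gs, E, expr, x, y, expressed_sem, 1.0)
    return (EV_BIRTH_MUTANT if mutated else EV_BIRTH_COPY), px, py


@njit(cache=True)
def rotate_block_kernel(occ, E, k, expr, r, c, clockwise):
    """Rotate the 2x2 block anchored at (r, c) by 90 degrees.

    With the block written (a b / c d), clockwise yields (c a / d b) and
    anticlockwise (b d / a c); the torus wraps the block across edges.
    Replicators move with their cells; nothing is created or destroyed.
    """
    side = occ.shape[0]
    A = E.shape[2]
    r2 = (r + 1) % side
    c2 = (c + 1) % side
    if clockwise:
        # cycle: 00 <- 10 <- 11 <- 01 <- 00
        t_o = occ[r, c]
        occ[r, c] = occ[r2, c]
        occ[r2, c] = occ[r2, c2]
        occ[r2, c2] = occ[r, c2]
        occ[r, c2] = t_o
        t_k = k[r, c]
        k[r, c] = k[r2, c]
        k[r2, c] = k[r2, c2]
        k[r2, c2] = k[r, c2]
        k[r, c2] = t_k
        t_e = expr[r, c]
        expr[r, c] = expr[r2, c]
        expr[r2, c] = expr[r2, c2]
        expr[r2, c2] = expr[r, c2]
        expr[r, c2] = t_e
        for a in range(A):
            t = E[r, c, a]
            E[r, c, a] = E[r2, c, a]
            E[r2, c, a] = E[r2, c2, a]
            E[r2, c2, a] = E[r, c2, a]
            E[r, c2, a] = t
    else:
        # cycle: 00 <- 01 <- 11 <- 10 <- 00
        t_o = occ[r, c]
        occ[r, c] = occ[r, c2]
        occ[r, c2] = occ[r2, c2]
        occ[r2, c2] = occ[r2, c]
        occ[r2, c] = t_o
        t_k = k[r, c]
        k[r, c] = k[r, c2]
        k[r, c2] = k[r2, c2]
        k[r2, c2] = k[r2, c]
        k[r2, c] = t_k
        t_e = expr[r, c]
        expr[r, c] = expr[r, c2]
        expr[r, c2] = expr[r2, c2]
        expr[r2, c2] = expr[r2, c]
        expr[r2, c] = t_e
        for a in range(A):
            t = E[r, c, a]
            E[r, c, a] = E[r, c2, a]
            E[r, c2, a] = E[r2, c2, a]
            E[r2, c2, a] = E[r2, c, a]
            E[r2, c, a] = t


@njit(cache=True)
def random_rotation_kernel(rng, occ, E, k, expr):
    """One elementary mixing step: uniform random anchor, fair coin direction."""
    side = occ.shape[0]
    r = rng.integers(0, side)
    c = rng.integers(0, side)
    cw = rng.integers(0, 2) == 0
    rotate_block_kernel(occ, E, k, expr, r, c, cw)


@njit(cache=True)
def diffusion_kernel(rng, occ, E, k, expr, d_int, d_frac):
    """floor(D) rotations plus one more with probability frac(D); returns count."""
    for _ in range(d_int):
        random_rotation_kernel(rng, occ, E, k, expr)
    if d_frac > 0.0 and rng.random() < d_frac:
        random_rotation_kernel(rng, occ, E, k, expr)
        return d_int + 1
    return d_int


@njit(cache=True)
def rotations_kernel(rng, occ, E, k, expr, n):
    """n independent random rotations (used for mixing diagnostics)."""
    for _ in range(n):
        random_rotation_kernel(rng, occ, E, k, expr)


@njit(cache=True)
def generation_kernel(rng, occ, E, k, expr, visits, met_off, rep_off,
                      b, g, E_max, k_min, k_max,
                      P_death, P_mut, C_e,
                      d_int, d_frac,
                      expressed_sem, full_met, mut_local, local_sigma,
                      refold_per_update, expr_weighted, gs):
    """One generation: side**2 visits to uniformly random sites.

    Every demographic update is followed by the diffusion steps implied by
    D = d_int + d_frac; the generation closes with one fold-switch sweep
    (unless refolding is per-update).  Visit counts accumulate into
    ``visits``.
    """
    side = occ.shape[0]
    A = E.shape[2]
    S = np.zeros(A, dtype=np.float64)
    W = np.zeros(rep_off.shape[0], dtype=np.float64)
    Ec = np.zeros(A, dtype=np.float64)
    do_diff = d_int > 0 or d_frac > 0.0
    for _ in range(side * side):
        x = rng.integers(0, side)
        y = rng.integers(0, side)
        visits[x, y] += 1
        site_update_kernel(rng, occ, E, k, expr, x, y, met_off, rep_off,
                           b, g, E_max, k_min, k_max,
                           P_death, P_mut, C_e,
                           expressed_sem, full_met, mut_local, local_sigma,
                           refold_per_update, expr_weighted, gs, S, W, Ec)
        if do_diff:
            diffusion_kernel(rng, occ, E, k, expr, d_int, d_frac)
    if not refold_per_update:
        refold_sweep_kernel(rng, occ, E, expr, full_met, gs, expressed_sem,
                            expr_weighted)
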