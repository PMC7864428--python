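"""Constrained phenotype geometry: trade-off surfaces, projection, sampling.

A replicator's phenotype is a vector of ``A`` catalytic activities
``E = (E_1, ..., E_A)`` together with a replicability ``k``.  Two trade-offs
bound the feasible region:

* the catalytic trade-off  ``sum_a E_a**b <= E_max**b``  (one activity can
  grow only at the expense of the others on the same sequence), and
* the activity/replicability trade-off
  ``k <= (E_max**g - Ehat**g)**(1/g) * (k_max - k_min)/E_max + k_min``
  with the effective total activity ``Ehat = (sum_a E_a**b)**(1/b)``.

``b`` (resp. ``g``) below 1 is a strong, above 1 a weak trade-off.  Mutation
is confined to the axis-aligned box spanned by the *bump point*: the radial
projection of the parent's activity vector onto the catalytic trade-off
surface.  Any point of that box is feasible, so bump-box mutants need no
rejection step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Phenotype",
    "catalytic_feasible",
    "effective_activity",
    "replicability_bound",
    "bump_point",
    "sample_activities",
    "sample_phenotype",
    "mutate_phenotype",
]

#: Relative slack applied at the trade-off boundary so that points *on* the
#: surface (e.g. bump points) always test feasible.
BOUNDARY_RTOL = 1e-12


@dataclass(frozen=True)
class Phenotype:
    """Activity vector plus replicability of one replicator."""

    E: np.ndarray
    k: float

    def __post_init__(self):
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))

    @property
    def A(self) -> int:
        return self.E.shape[0]


def _check_nonnegative(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError(f"activities must be non-negative, got {E}")
    return E


def catalytic_feasible(E, b: float, E_max: float) -> bool:
    """Whether ``E`` satisfies the catalytic trade-off ``sum E_a**b <= E_max**b``.

    The boundary is included, with a relative tolerance of ``1e-12`` so that
    exact surface points survive floating-point round-off.
    """
    E = _check_nonnegative(E)
    if not b > 0:
        raise ValueError(f"b must be > 0, got {b}")
    budget = E_max**b
    return bool(np.sum(E**b) <= budget * (1.0 + BOUNDARY_RTOL))


def effective_activity(E, b: float) -> float:
    """Effective total activity ``Ehat = (sum_a E_a**b)**(1/b)``.

    This is the b-norm of the activity vector: the single-activity level that
    would exhaust the same share of the catalytic budget.  For feasible ``E``
    it lies in ``[max(E), E_max]``.
    """
    E = _check_nonnegative(E)
    return float(np.sum(E**b) ** (1.0 / b))


def replicability_bound(
    E_hat: float, *, E_max: float, g: float, k_min: float, k_max: float
) -> float:
    """Upper bound on replicability ``k`` at effective activity ``E_hat``.

    ``(E_max**g - E_hat**g)**(1/g) * (k_max - k_min)/E_max + k_min``:
    the trade-off surface scaled so that a fully inactive replicator may reach
    ``k_max`` while a maximally active one is pinned at ``k_min``.
    Strictly decreasing in ``E_hat`` whenever ``k_max > k_min``.
    """
    if E_hat < 0:
        raise ValueError(f"E_hat must be >= 0, got {E_hat}")
    if E_hat > E_max * (1.0 + BOUNDARY_RTOL):
        raise ValueError(f"E_hat={E_hat} exceeds E_max={E_max}")
    E_hat = min(E_hat, E_max)
    return float(
        (E_max**g - E_hat**g) ** (1.0 / g) * (k_max - k_min) / E_max + k_min
    )


def bump_point(E, b: float, E_max: float) -> np.ndarray | None:
    """Radial projection of ``E`` onto the catalytic trade-off surface.

    Returns ``s * E`` with the unique ``s > 0`` such that
    ``sum (s*E_a)**b = E_max**b``; the direction of ``E`` is preserved.
    For the all-zero vector no direction exists and ``None`` is returned —
    the caller should then treat the whole feasible region as the mutation
    box.
    """
    E = _check_nonnegative(E)
    total = float(np.sum(E**b))
    if total == 0.0:
        return None
    s = (E_max**b / total) ** (1.0 / b)
    return s * E


def _dirichlet_activities(rng: np.random.Generator, A: int, b: float, E_max: float) -> np.ndarray:
    """Draw E uniformly from ``{E >= 0 : sum E_a**b <= E_max**b}``.

    Substituting ``v_a = (E_a/E_max)**b`` maps the region onto the simplex
    ``sum v <= 1`` and the uniform density on ``E`` onto a
    Dirichlet(1/b, ..., 1/b, 1) law for ``(v, slack)``; drawing ``v`` that way
    and mapping back is therefore an exact uniform sample, with no rejection
    step (plain box rejection is astronomically inefficient for small ``b``).
    """
    v = rng.dirichlet(np.concatenate([np.full(A, 1.0 / b), [1.0]]))[:A]
    return E_max * v ** (1.0 / b)


def sample_activities(rng: np.random.Generator, A: int, b: float, E_max: float,
                      size: int | None = None) -> np.ndarray:
    """Uniform sample(s) from the feasible activity region (see above)."""
    if size is None:
        return _dirichlet_activities(rng, A, b, E_max)
    alpha = np.concatenate([np.full(A, 1.0 / b), [1.0]])
    v = rng.dirichlet(alpha, size=size)[:, :A]
    return E_max * v ** (1.0 / b)


def _draw_k(rng: np.random.Generator, E: np.ndarray, params) -> float:
    e_hat = effective_activity(E, params.b)
    hi = replicability_bound(
        e_hat, E_max=params.E_max, g=params.g, k_min=params.k_min, k_max=params.k_max
    )
    return float(rng.uniform(params.k_min, hi)) if hi > params.k_min else params.k_min


def sample_phenotype(rng: np.random.Generator, params) -> Phenotype:
    """Random phenotype for initialisation.

    Activities are uniform over the catalytically feasible region;
    replicability is then uniform on ``[k_min, replicability_bound(Ehat)]``.
    """
    E = _dirichlet_activities(rng, params.A, params.b, params.E_max)
    return Phenotype(E=E, k=_draw_k(rng, E, params))


def mutate_phenotype(parent: Phenotype, rng: np.random.Generator, params) -> Phenotype:
    """Mutant copy of ``parent``, confined below the trade-off surfaces.

    Default (``mutation_mode="global"``): each activity is redrawn uniformly
    on ``[0, B_a]`` where ``B`` is the parent's bump point (for an all-zero
    parent, the whole feasible region); replicability is redrawn uniformly on
    ``[k_min, replicability_bound(Ehat_mutant)]``.  The result is always
    feasible by construction.

    ``mutation_mode="local"``: Gaussian perturbation of the parent's
    activities (scale ``local_sigma``), re-proposed until feasible, with a
    matching perturbation of ``k`` clipped to its bound.
    """
    if params.mutation_mode == "local":
        return _mutate_local(parent, rng, params)
    B = bump_point(parent.E, params.b, params.E_max)
    if B is None:
        E = _dirichlet_activities(rng, params.A, params.b, params.E_max)
    else:
        E = rng.uniform(0.0, 1.0, size=params.A) * B
    return Phenotype(E=E, k=_draw_k(rng, E, params))


def _mutate_local(parent: Phenotype, rng: np.random.Generator, params) -> Phenotype:
    sigma = params.local_sigma
    while True:
        E = np.clip(parent.E + rng.normal(0.0, sigma, size=params.A), 0.0, None)
        if catalytic_feasible(E, params.b, params.E_max):
            break
    e_hat = effective_activity(E, params.b)
    hi = replicability_bound(
        e_hat, E_max=params.E_max, g=params.g, k_min=params.k_min, k_max=params.k_max
    )
    k_sigma = sigma * (params.k_max - params.k_min) / params.E_max
    k = float(np.clip(parent.k + rng.normal(0.0, k_sigma), params.k_min, hi))
    return Phenotype(E=E, k=k)
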