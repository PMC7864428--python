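"""Model parameters and run controls.

All tunables of the surface-bound metabolically coupled replicator system
(MCRS) live in a single flat :class:`Params` record: the trade-off exponents,
neighbourhood sizes, demographic rates and lattice geometry, plus run controls
(generations, census cadence, RNG seed).  Configurations are plain TOML with
keys named exactly after the model symbols, e.g.::

    k_min = 2.0
    k_max = 4.0
    A = 3
    b = 1.0
    N_met = 5

Validation is total: every violated constraint raises
:class:`ParamsError` naming the offending field; nothing is silently clamped.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "Params",
    "ParamsError",
    "MASK_CATALOGUE",
    "FULL_GRID",
    "load_params",
    "loads_params",
    "serialize_params",
    "replicate_seeds",
]

#: Neighbourhood sizes with a defined cell mask (see :mod:`mcrs.lattice`).
MASK_CATALOGUE = frozenset({5, 9, 13, 25, 29, 49})

#: Sentinel for ``N_met`` meaning the metabolic neighbourhood is the whole
#: grid (the mean-field limit of metabolite diffusion).
FULL_GRID = 0


class ParamsError(ValueError):
    """A configuration key is unknown, unparsable, or violates an invariant."""


@dataclass(frozen=True)
class Params:
    """Full parameter set of the replicator model.

    Attributes
    ----------
    k_min, k_max : float
        Minimum and maximum replicability (template copying rate).
    A : int
        System size: the number of catalytic activity types the implicit
        metabolism requires.
    E_max : float
        Upper bound on any single catalytic activity.
    D : float
        Replicator mobility: block-rotation diffusion steps per demographic
        update.  The integer part is performed always; the fractional part is
        a Bernoulli probability of one extra step.
    N_met, N_repl : int
        Metabolic and replication neighbourhood sizes (cells).  ``N_met = 0``
        selects the whole grid (mean-field metabolite mixing).
    b : float
        Catalytic trade-off exponent; ``b < 1`` strong, ``b > 1`` weak.
    g : float
        Activity/replicability trade-off exponent.
    P_death : float
        Per-visit decay probability of an occupied site.
    P_mutation : float
        Per-replication probability of a phenotypic mutation.
    C_empty : float
        Claim of an empty site to remain empty (competes with fitnesses).
    n_grid : int
        Side length of the toroidal square lattice.
    n_generations : int
        Run length; one generation is ``n_grid**2`` site updates.
    init_occupancy : float
        Fraction of sites occupied (exactly) at initialisation.
    m_significant : float
        Activity level above which an activity counts as significant when
        classifying replicators.
    parasite_threshold : float
        A replicator with every activity at or below this level is a parasite.
    seed : int
        Base RNG seed; replicate seeds are derived from it.
    census_every : int
        Census cadence in generations.
    metabolic_semantics : str
        ``"expressed"``: a replicator contributes only its currently folded
        activity to neighbourhood sums (one reaction per ribozyme per step);
        ``"all"``: contributes its whole activity vector.
    expression_weighting : str
        How a molecule picks the structure it folds into, at birth and when
        a refold fires: ``"activity"`` (default) folds into activity ``a``
        with probability proportional to ``E_a`` (fold stability tracks
        catalytic strength), ``"uniform"`` picks uniformly among strictly
        positive activities.
    mutation_mode : str
        ``"global"``: mutant traits resampled uniformly inside the bump box;
        ``"local"``: Gaussian perturbation of the parent (non-default).
    local_sigma : float
        Scale of the Gaussian used by ``mutation_mode="local"``.
    refold_per_update : bool
        If true, a visited replicator may refold at each demographic update
        instead of once per generation sweep.
    """

    k_min: float = 2.0
    k_max: float = 4.0
    A: int = 3
    E_max: float = 10.0
    D: float = 0.0
    N_met: int = 5
    N_repl: int = 9
    b: float = 1.0
    g: float = 1.0
    P_death: float = 0.1
    P_mutation: float = 0.01
    C_empty: float = 20.0
    n_grid: int = 300
    n_generations: int = 50_000
    init_occupancy: float = 0.80
    m_significant: float = 0.01
    parasite_threshold: float = 0.1
    seed: int = 0
    census_every: int = 1
    metabolic_semantics: str = "expressed"
    expression_weighting: str = "activity"
    mutation_mode: str = "global"
    local_sigma: float = 0.5
    refold_per_update: bool = False

    def __post_init__(self) -> None:
        if not self.k_min > 0:
            raise ParamsError(f"k_min must be > 0, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ParamsError(
                f"k_max must be >= k_min, got k_max={self.k_max} < k_min={self.k_min}"
            )
        if self.A < 1:
            raise ParamsError(f"A must be >= 1, got {self.A}")
        if not self.E_max > 0:
            raise ParamsError(f"E_max must be > 0, got {self.E_max}")
        if self.D < 0:
            raise ParamsError(f"D must be >= 0, got {self.D}")
        if self.N_met != FULL_GRID and self.N_met not in MASK_CATALOGUE:
            raise ParamsError(
                f"N_met={self.N_met} is not a supported neighbourhood size; "
                f"choose one of {sorted(MASK_CATALOGUE)} (or 0 for the whole grid)"
            )
        if self.N_repl not in MASK_CATALOGUE:
            raise ParamsError(
                f"N_repl={self.N_repl} is not a supported neighbourhood size; "
                f"choose one of {sorted(MASK_CATALOGUE)}"
            )
        if not self.b > 0:
            raise ParamsError(f"b must be > 0, got {self.b}")
        if not self.g > 0:
            raise ParamsError(f"g must be > 0, got {self.g}")
        for name in ("P_death", "P_mutation", "init_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamsError(f"{name} must lie in [0, 1], got {v}")
        if self.C_empty < 0:
            raise ParamsError(f"C_empty must be >= 0, got {self.C_empty}")
        if self.n_grid < 2:
            raise ParamsError(f"n_grid must be >= 2, got {self.n_grid}")
        if self.n_generations < 0:
            raise ParamsError(f"n_generations must be >= 0, got {self.n_generations}")
        if self.m_significant < 0:
            raise ParamsError(f"m_significant must be >= 0, got {self.m_significant}")
        if self.parasite_threshold < 0:
            raise ParamsError(
                f"parasite_threshold must be >= 0, got {self.parasite_threshold}"
            )
        if self.census_every < 1:
            raise ParamsError(f"census_every must be >= 1, got {self.census_every}")
        if self.metabolic_semantics not in ("expressed", "all"):
            raise ParamsError(
                "metabolic_semantics must be 'expressed' or 'all', "
                f"got {self.metabolic_semantics!r}"
            )
        if self.expression_weighting not in ("activity", "uniform"):
            raise ParamsError(
                "expression_weighting must be 'activity' or 'uniform', "
                f"got {self.expression_weighting!r}"
            )
        if self.mutation_mode not in ("global", "local"):
            raise ParamsError(
                f"mutation_mode must be 'global' or 'local', got {self.mutation_mode!r}"
            )
        if not self.local_sigma > 0:
            raise ParamsError(f"local_sigma must be > 0, got {self.local_sigma}")

    def replace(self, **overrides) -> "Params":
        """Return a copy with the given fields replaced (and revalidated)."""
        return dataclasses.replace(self, **overrides)


_FIELD_TYPES = {f.name: f.type for f in fields(Params)}


def _coerce(name: str, value):
    """Coerce a TOML value onto the declared field type, strictly."""
    typ = _FIELD_TYPES[name]
    if typ in ("int", int):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ParamsError(f"{name} must be an integer, got {value!r}")
        return int(value)
    if typ in ("float", float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParamsError(f"{name} must be a number, got {value!r}")
        return float(value)
    if typ in ("bool", bool):
        if not isinstance(value, bool):
            raise ParamsError(f"{name} must be a boolean, got {value!r}")
        return value
    if typ in ("str", str):
        if not isinstance(value, str):
            raise ParamsError(f"{name} must be a string, got {value!r}")
        return value
    raise AssertionError(name)


def loads_params(config_text: str) -> Params:
    """Parse a TOML configuration string into a validated :class:`Params`.

    Unknown keys are rejected (typos must not pass silently); missing keys
    take their documented defaults.
    """
    try:
        raw = tomllib.loads(config_text)
    except tomllib.TOMLDecodeError as exc:
        raise ParamsError(f"configuration does not parse as TOML: {exc}") from exc
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ParamsError(f"unknown configuration keys: {sorted(unknown)}")
    return Params(**{k: _coerce(k, v) for k, v in raw.items()})


def load_params(path) -> Params:
    """Read and validate a TOML configuration file."""
    with open(path, "rb") as fh:
        text = fh.read().decode("utf-8")
    return loads_params(text)


def serialize_params(params: Params) -> str:
    """Render ``params`` as TOML text; ``loads_params`` round-trips it."""
    lines = []
    for f in fields(Params):
        v = getattr(params, f.name)
        if isinstance(v, bool):
            lines.append(f"{f.name} = {'true' if v else 'false'}")
        elif isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, float):
            lines.append(f"{f.name} = {v!r}")
        else:
            lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def replicate_seeds(params: Params, n_replicates: int) -> list[int]:
    """Derive ``n_replicates`` distinct integer seeds from the base seed.

    Replicate runs of one parameter setting use different seeds; the
    derivation is deterministic, so the same base seed always yields the
    same replicate seeds.  Seeds are 31-bit non-negative integers.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    ss = np.random.SeedSequence(params.seed)
    seeds: list[int] = []
    seen: set[int] = set()
    n_words = 2 * n_replicates
    while len(seeds) < n_replicates:
        for word in ss.generate_state(n_words, dtype=np.uint32):
            s = int(word) & 0x7FFFFFFF
            if s not in seen:
                seen.add(s)
                seeds.append(s)
                if len(seeds) == n_replicates:
                    break
        n_words *= 2
    return seeds
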