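"""Toroidal lattice storage, neighbourhood masks, and test fixtures.

The habitat is a square toroidal lattice; each site is empty or holds one
replicator.  State is kept in flat numpy arrays (occupancy, activity vectors,
replicability, expressed-activity index) so the update engine can run jitted;
:class:`Lattice` wraps them with a site-level API.

Neighbourhoods come in a fixed catalogue of sizes:

====  =======================================
size  mask
====  =======================================
5     von Neumann, radius 1
13    von Neumann, radius 2 (``|dx|+|dy| <= 2``)
29    Euclidean disk of radius 3 (``dx**2+dy**2 <= 9``)
9     Moore 3x3
25    Moore 5x5
49    Moore 7x7
====  =======================================

All masks include the focal cell and are point-symmetric about it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .geometry import Phenotype, sample_activities
from .params import FULL_GRID, MASK_CATALOGUE

__all__ = [
    "Replicator",
    "NeighbourhoodMask",
    "Lattice",
    "mask_for_size",
    "init_lattice",
    "activity_sums",
    "make_fixture_lattice",
    "parse_fixture",
    "format_fixture",
]

#: Expressed-activity index stored at empty sites.
NO_ACTIVITY = -1


@dataclass(frozen=True)
class Replicator:
    """One surface-bound replicator: phenotype plus its current fold.

    ``expressed`` is the 0-based index of the single activity the folded
    ribozyme currently catalyses; promiscuous sequences switch folds between
    generations (see :func:`mcrs.dynamics.refold_sweep`).
    """

    phenotype: Phenotype
    expressed: int


@dataclass(frozen=True)
class NeighbourhoodMask:
    """Explicit set of toroidal offsets defining a neighbourhood."""

    offsets: np.ndarray  # (size, 2) int64, rows (dx, dy)
    size: int

    def offset_set(self) -> set[tuple[int, int]]:
        return {(int(dx), int(dy)) for dx, dy in self.offsets}


def _sorted_offsets(pairs) -> np.ndarray:
    return np.array(sorted(pairs), dtype=np.int64)


def mask_for_size(size: int) -> NeighbourhoodMask:
    """Return the mask of the catalogue with the given cell count.

    Sizes 5/13 are von Neumann radius 1/2; 29 is the Euclidean radius-3 disk
    (the only standard 29-cell extension of the von Neumann family); 9/25/49
    are Moore squares.
    """
    if size == 5:
        pairs = [(dx, dy) for dx in range(-1, 2) for dy in range(-1, 2)
                 if abs(dx) + abs(dy) <= 1]
    elif size == 13:
        pairs = [(dx, dy) for dx in range(-2, 3) for dy in range(-2, 3)
                 if abs(dx) + abs(dy) <= 2]
    elif size == 29:
        pairs = [(dx, dy) for dx in range(-3, 4) for dy in range(-3, 4)
                 if dx * dx + dy * dy <= 9]
    elif size in (9, 25, 49):
        r = {9: 1, 25: 2, 49: 3}[size]
        pairs = [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]
    else:
        raise ValueError(
            f"unsupported neighbourhood size {size}; supported: {sorted(MASK_CATALOGUE)}"
        )
    offsets = _sorted_offsets(pairs)
    assert offsets.shape[0] == size
    return NeighbourhoodMask(offsets=offsets, size=size)


def full_grid_mask(side: int) -> NeighbourhoodMask:
    """Mask covering every site of a ``side`` x ``side`` torus (mean field)."""
    half = side // 2
    pairs = [(dx, dy) for dx in range(-half, side - half)
             for dy in range(-half, side - half)]
    return NeighbourhoodMask(offsets=_sorted_offsets(pairs), size=side * side)


def metabolic_mask(params) -> NeighbourhoodMask:
    """The metabolic neighbourhood mask implied by ``params`` (honours mean field)."""
    if params.N_met == FULL_GRID:
        return full_grid_mask(params.n_grid)
    return mask_for_size(params.N_met)


class Lattice:
    """Toroidal grid of optional replicators backed by numpy arrays.

    Attributes
    ----------
    side : int
        Lattice side length.
    A : int
        Number of activity types per replicator.
    occ : (side, side) bool array
        Occupancy.
    E : (side, side, A) float array
        Activity vectors (zeros at empty sites).
    k : (side, side) float array
        Replicabilities (zero at empty sites).
    expressed : (side, side) int8 array
        Expressed-activity index, ``-1`` at empty sites.

    Coordinates are 0-based ``(x, y) = (row, column)`` and wrap modulo
    ``side`` in both directions.
    """

    def __init__(self, side: int, A: int):
        if side < 2:
            raise ValueError(f"side must be >= 2, got {side}")
        self.side = int(side)
        self.A = int(A)
        self.occ = np.zeros((side, side), dtype=bool)
        self.E = np.zeros((side, side, A), dtype=np.float64)
        self.k = np.zeros((side, side), dtype=np.float64)
        self.expressed = np.full((side, side), NO_ACTIVITY, dtype=np.int8)

    # -- site access -----------------------------------------------------
    def wrap(self, x: int, y: int) -> tuple[int, int]:
        return x % self.side, y % self.side

    def occupancy(self) -> int:
        return int(np.count_nonzero(self.occ))

    def get(self, x: int, y: int) -> Replicator | None:
        x, y = self.wrap(x, y)
        if not self.occ[x, y]:
            return None
        return Replicator(
            phenotype=Phenotype(E=self.E[x, y].copy(), k=float(self.k[x, y])),
            expressed=int(self.expressed[x, y]),
        )

    def place(self, x: int, y: int, phenotype: Phenotype, expressed: int) -> None:
        x, y = self.wrap(x, y)
        E = np.asarray(phenotype.E, dtype=float)
        if E.shape != (self.A,):
            raise ValueError(f"activity vector must have length {self.A}, got {E.shape}")
        if not 0 <= expressed < self.A:
            raise ValueError(f"expressed index {expressed} outside 0..{self.A - 1}")
        self.occ[x, y] = True
        self.E[x, y] = E
        self.k[x, y] = phenotype.k
        self.expressed[x, y] = expressed

    def remove(self, x: int, y: int) -> None:
        x, y = self.wrap(x, y)
        self.occ[x, y] = False
        self.E[x, y] = 0.0
        self.k[x, y] = 0.0
        self.expressed[x, y] = NO_ACTIVITY

    def copy(self) -> "Lattice":
        out = Lattice(self.side, self.A)
        out.occ[:] = self.occ
        out.E[:] = self.E
        out.k[:] = self.k
        out.expressed[:] = self.expressed
        return out

    def iter_occupied(self):
        """Yield ``(x, y, Replicator)`` in row-major order."""
        for x, y in zip(*np.nonzero(self.occ)):
            yield int(x), int(y), self.get(int(x), int(y))

    def phenotype_multiset(self) -> list[tuple]:
        """Sorted hashable view of all occupants, for conservation checks."""
        items = [
            (tuple(np.round(r.phenotype.E, 12)), round(r.phenotype.k, 12), r.expressed)
            for _, _, r in self.iter_occupied()
        ]
        return sorted(items)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Lattice):
            return NotImplemented
        return (
            self.side == other.side
            and self.A == other.A
            and np.array_equal(self.occ, other.occ)
            and np.array_equal(self.E, other.E)
            and np.array_equal(self.k, other.k)
            and np.array_equal(self.expressed, other.expressed)
        )


def draw_expressed(rng: np.random.Generator, E: np.ndarray,
                   weighted: bool = True) -> int:
    """Fold choice among strictly positive activities (index 0 if none).

    By default the molecule folds into activity ``a`` with probability
    proportional to ``E_a``; ``weighted=False`` picks uniformly instead.
    """
    pos = np.nonzero(E > 0.0)[0]
    if pos.size == 0:
        return 0
    if weighted:
        w = E[pos] / E[pos].sum()
        return int(rng.choice(pos, p=w))
    return int(pos[rng.integers(0, pos.size)])


def init_lattice(params, rng: np.random.Generator) -> Lattice:
    """Random initial community.

    Exactly ``round(init_occupancy * side**2)`` sites are occupied, chosen
    uniformly without replacement; each occupant gets an independent random
    phenotype from the feasible region and folds into one of its strictly
    positive activities (activity-weighted by default, see
    :func:`draw_expressed`).
    """
    side, A = params.n_grid, params.A
    lat = Lattice(side, A)
    n_occ = int(round(params.init_occupancy * side * side))
    if n_occ == 0:
        return lat
    flat = rng.choice(side * side, size=n_occ, replace=False)
    xs, ys = np.divmod(flat, side)
    E = sample_activities(rng, A, params.b, params.E_max, size=n_occ)
    e_hat = np.sum(E**params.b, axis=1) ** (1.0 / params.b)
    e_hat = np.minimum(e_hat, params.E_max)
    hi = (params.E_max**params.g - e_hat**params.g) ** (1.0 / params.g) * (
        params.k_max - params.k_min
    ) / params.E_max + params.k_min
    k = params.k_min + rng.random(n_occ) * (hi - params.k_min)
    lat.occ[xs, ys] = True
    lat.E[xs, ys] = E
    lat.k[xs, ys] = k
    weighted = params.expression_weighting == "activity"
    for i in range(n_occ):
        lat.expressed[xs[i], ys[i]] = draw_expressed(rng, E[i], weighted)
    return lat


def activity_sums(
    lattice: Lattice,
    pos: tuple[int, int],
    mask: NeighbourhoodMask,
    semantics: str = "expressed",
) -> np.ndarray:
    """Per-activity sums over the neighbourhood of ``pos`` (torus-wrapped).

    Under ``semantics="expressed"`` each occupant contributes only its
    currently expressed activity value to that activity's sum; under
    ``"all"`` it contributes its whole activity vector.
    """
    if semantics not in ("expressed", "all"):
        raise ValueError(f"semantics must be 'expressed' or 'all', got {semantics!r}")
    x0, y0 = pos
    S = np.zeros(lattice.A, dtype=np.float64)
    for dx, dy in mask.offsets:
        x, y = (x0 + dx) % lattice.side, (y0 + dy) % lattice.side
        if not lattice.occ[x, y]:
            continue
        if semantics == "expressed":
            e = lattice.expressed[x, y]
            if e >= 0:
                S[e] += lattice.E[x, y, e]
        else:
            S += lattice.E[x, y]
    return S


def make_fixture_lattice(rows, side: int, A: int) -> Lattice:
    """Deterministic lattice from an explicit placement table.

    ``rows`` is an iterable of ``(x, y, E, k, expressed)`` with ``E`` a
    length-``A`` sequence.  Duplicate placements raise.
    """
    lat = Lattice(side, A)
    seen: set[tuple[int, int]] = set()
    for x, y, E, k, expressed in rows:
        key = lat.wrap(int(x), int(y))
        if key in seen:
            raise ValueError(f"duplicate placement at {key}")
        seen.add(key)
        lat.place(int(x), int(y), Phenotype(E=np.asarray(E, float), k=float(k)),
                  int(expressed))
    return lat


def parse_fixture(text: str) -> Lattice:
    """Parse the tabular fixture format written by :func:`format_fixture`.

    Header comment carries ``side`` and ``A``; the column line is
    ``x,y,expressed,E_1..E_A,k``; one row per replicator.
    """
    side = A = None
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].replace(",", " ").split():
                if tok.startswith("side="):
                    side = int(tok[5:])
                elif tok.startswith("A="):
                    A = int(tok[2:])
            continue
        if line.startswith("x,"):
            continue
        parts = line.split(",")
        rows.append(parts)
    if side is None or A is None:
        raise ValueError("fixture header must declare side= and A=")
    table = []
    for parts in rows:
        if len(parts) != 3 + A + 1:
            raise ValueError(f"fixture row has {len(parts)} fields, expected {4 + A}")
        x, y, expressed = int(parts[0]), int(parts[1]), int(parts[2])
        E = [float(v) for v in parts[3:3 + A]]
        k = float(parts[3 + A])
        table.append((x, y, E, k, expressed))
    return make_fixture_lattice(table, side, A)


def format_fixture(lattice: Lattice, extra_header: str = "") -> str:
    """Serialise ``lattice`` to the tabular fixture format (lossless)."""
    lines = [f"# side={lattice.side} A={lattice.A} indexing=0-based (row,col)"
             + (f" {extra_header}" if extra_header else "")]
    cols = ["x", "y", "expressed"] + [f"E_{a + 1}" for a in range(lattice.A)] + ["k"]
    lines.append(",".join(cols))
    for x, y, r in lattice.iter_occupied():
        vals = [str(x), str(y), str(r.expressed)]
        vals += [repr(float(v)) for v in r.phenotype.E]
        vals.append(repr(float(r.phenotype.k)))
        lines.append(",".join(vals))
    return "\n".join(lines) + "\n"
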