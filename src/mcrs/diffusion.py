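"""Surface diffusion by random 2x2 block rotation (Toffoli–Margolus style).

An elementary mixing step rotates a uniformly random 2x2 block of sites by 90
degrees, clockwise or anticlockwise with equal chance; the block may wrap
across the torus edges.  Replicators move with their cells, so any sequence
of rotations conserves the multiset of replicators exactly.  The mobility
parameter ``D`` is the number of such steps per demographic update: its
integer part is always performed, its fractional part is the probability of
one extra step.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .lattice import Lattice

__all__ = ["rotate_block", "diffusion_after_update", "apply_rotations"]


def rotate_block(lattice: Lattice, anchor: tuple[int, int], direction: str) -> None:
    """Rotate the 2x2 block whose top-left cell is ``anchor``, in place.

    ``direction`` is ``"clockwise"`` or ``"anticlockwise"``; writing the
    block (a b / c d), clockwise gives (c a / d b) and anticlockwise
    (b d / a c).
    """
    if direction not in ("clockwise", "anticlockwise"):
        raise ValueError(f"direction must be 'clockwise' or 'anticlockwise', got {direction!r}")
    r, c = lattice.wrap(*anchor)
    K.rotate_block_kernel(lattice.occ, lattice.E, lattice.k, lattice.expressed,
                          r, c, direction == "clockwise")


def diffusion_after_update(lattice: Lattice, rng: np.random.Generator,
                           D: float) -> int:
    """Perform the diffusion steps that follow one demographic update.

    ``floor(D)`` random rotations, plus one more with probability
    ``frac(D)``.  Returns the number of rotations performed.
    """
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    d_int = int(np.floor(D))
    d_frac = float(D - d_int)
    return int(K.diffusion_kernel(rng, lattice.occ, lattice.E, lattice.k,
                                  lattice.expressed, d_int, d_frac))


def apply_rotations(lattice: Lattice, rng: np.random.Generator, n: int) -> None:
    """Apply ``n`` elementary random rotations (mixing diagnostics)."""
    K.rotations_kernel(rng, lattice.occ, lattice.E, lattice.k,
                       lattice.expressed, int(n))
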