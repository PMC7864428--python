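"""Minimal plotting helpers: G-vs-generation curves and lattice rasters."""

from __future__ import annotations

import numpy as np

from .lattice import Lattice

__all__ = ["plot_timeseries", "plot_lattice"]


def plot_timeseries(records, A: int, ax=None):
    """Plot G and parasite fraction against generation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    gens = [r.generation for r in records]
    ax.plot(gens, [r.G for r in records], label="G (generalism index)")
    ax.plot(gens, [r.parasite_fraction for r in records], label="parasite fraction")
    ax.set_xlabel("generation")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_lattice(lattice: Lattice, ax=None):
    """Raster of the lattice coloured by expressed activity (empty = white)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = np.where(lattice.occ, lattice.expressed.astype(float), np.nan)
    ax.imshow(img, interpolation="nearest", cmap="tab10",
              vmin=0, vmax=max(lattice.A - 1, 1))
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
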