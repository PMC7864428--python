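"""Replicator classification, the generalism index G, and the census.

Classification uses two thresholds, both of which appear in the model's
definition: a replicator is a *parasite* if every activity is at or below
``parasite_threshold`` (default 0.1); otherwise its *significant* activities
are those above ``m_significant`` (default 0.01), and it is a *specialist*
with exactly one of them or a *generalist* with two or more.

The community-level index of overall generalism is

    G = sum_{a=1..A} a * n_a / (A * sum_{a=0..A} n_a)

with ``n_a`` the number of replicators carrying ``a`` significant activities
(parasites count at a = 0); G is 0 for a pure-parasite community and 1 when
every replicator carries all A activities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import Lattice, Replicator

__all__ = [
    "ClassLabel",
    "CensusRecord",
    "classify",
    "g_index",
    "census",
    "pattern_labels",
    "records_to_frame",
]

#: Sentinel returned by :func:`g_index` when the community is empty.
NO_POPULATION = float("nan")


@dataclass(frozen=True)
class ClassLabel:
    """Classification of one replicator."""

    kind: str  # "parasite" | "specialist" | "generalist"
    active_set: frozenset  # 0-based indices of significant activities


@dataclass(frozen=True)
class CensusRecord:
    """Community summary at one generation.

    ``n_by_activities[a]`` counts replicators with ``a`` significant
    activities (index 0 = parasites); ``pattern_counts[m]`` counts
    replicators whose significant-activity bitmask is ``m`` (bit ``a`` set
    iff activity ``a+1`` is significant; parasites sit at mask 0).
    """

    generation: int
    occupancy: int
    n_by_activities: tuple
    pattern_counts: tuple
    G: float
    parasite_fraction: float
    mean_k: float
    mean_E: tuple

    @property
    def A(self) -> int:
        return len(self.n_by_activities) - 1


def classify(replicator: Replicator, params) -> ClassLabel:
    """Classify one replicator by its activity vector (not its current fold)."""
    E = np.asarray(replicator.phenotype.E, dtype=float)
    if np.all(E <= params.parasite_threshold):
        return ClassLabel(kind="parasite", active_set=frozenset())
    active = frozenset(int(a) for a in np.nonzero(E > params.m_significant)[0])
    kind = "specialist" if len(active) == 1 else "generalist"
    return ClassLabel(kind=kind, active_set=active)


def g_index(n, A: int) -> float:
    """Index of overall generalism from activity-count histogram ``n_0..n_A``.

    Returns NaN (no population) when all counts are zero.
    """
    n = np.asarray(n, dtype=float)
    if n.shape[0] != A + 1:
        raise ValueError(f"need counts n_0..n_{A}, got length {n.shape[0]}")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    total = n.sum()
    if total == 0:
        return NO_POPULATION
    a = np.arange(A + 1)
    return float((a * n).sum() / (A * total))


def census(lattice: Lattice, generation: int, params) -> CensusRecord:
    """Single-pass community summary of the lattice."""
    A = lattice.A
    occ = lattice.occ
    n_occ = int(np.count_nonzero(occ))
    if n_occ == 0:
        return CensusRecord(
            generation=generation, occupancy=0,
            n_by_activities=tuple([0] * (A + 1)),
            pattern_counts=tuple([0] * (2**A)),
            G=NO_POPULATION, parasite_fraction=NO_POPULATION,
            mean_k=NO_POPULATION, mean_E=tuple([NO_POPULATION] * A),
        )
    Eo = lattice.E[occ]
    ko = lattice.k[occ]
    parasite = np.all(Eo <= params.parasite_threshold, axis=1)
    sig = Eo > params.m_significant
    sig[parasite] = False
    n_active = sig.sum(axis=1)
    n_by = np.bincount(n_active, minlength=A + 1)
    masks = sig.astype(np.int64) @ (1 << np.arange(A))
    patterns = np.bincount(masks, minlength=2**A)
    return CensusRecord(
        generation=generation,
        occupancy=n_occ,
        n_by_activities=tuple(int(v) for v in n_by),
        pattern_counts=tuple(int(v) for v in patterns),
        G=g_index(n_by, A),
        parasite_fraction=float(parasite.mean()),
        mean_k=float(ko.mean()),
        mean_E=tuple(float(v) for v in Eo.mean(axis=0)),
    )


def pattern_labels(A: int) -> list[str]:
    """Column labels for the 2**A significant-activity patterns.

    Mask ``m`` is labelled by its bit string, lowest activity first, e.g.
    for A = 3 mask 0b011 -> ``"110"`` meaning activities 1 and 2 significant.
    """
    return ["".join("1" if m >> a & 1 else "0" for a in range(A))
            for m in range(2**A)]


def record_columns(A: int) -> list[str]:
    cols = ["generation", "occupancy"]
    cols += [f"n_{a}" for a in range(A + 1)]
    cols += ["G", "parasite_fraction", "mean_k"]
    cols += [f"mean_E_{a + 1}" for a in range(A)]
    cols += [f"p_{lbl}" for lbl in pattern_labels(A)]
    return cols


def record_to_row(rec: CensusRecord) -> list:
    row: list = [rec.generation, rec.occupancy]
    row += list(rec.n_by_activities)
    row += [rec.G, rec.parasite_fraction, rec.mean_k]
    row += list(rec.mean_E)
    row += list(rec.pattern_counts)
    return row


def records_to_frame(records, A: int) -> pd.DataFrame:
    """Census records as a tidy DataFrame, one row per census."""
    return pd.DataFrame([record_to_row(r) for r in records],
                        columns=record_columns(A))


def record_from_row(row, A: int) -> CensusRecord:
    """Inverse of :func:`record_to_row` (used by the CSV reader)."""
    row = list(row)
    n_by = tuple(int(v) for v in row[2:2 + A + 1])
    base = 2 + A + 1
    G, pf, mk = (float(row[base]), float(row[base + 1]), float(row[base + 2]))
    mean_E = tuple(float(v) for v in row[base + 3:base + 3 + A])
    patterns = tuple(int(v) for v in row[base + 3 + A:base + 3 + A + 2**A])
    return CensusRecord(
        generation=int(row[0]), occupancy=int(row[1]), n_by_activities=n_by,
        pattern_counts=patterns, G=G, parasite_fraction=pf, mean_k=mk,
        mean_E=mean_E,
    )
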