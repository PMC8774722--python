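"""Square-lattice geometry, concentric shell partition, and removal-probability schedules.

The lattice is an L x L grid of sites with 4-nearest-neighbor connectivity and
open (non-periodic) boundaries.  It is partitioned into ``n_shells`` concentric
square annuli ("shells"): shell 0 is the outermost ring (the tumor periphery,
where oxygen is replenished by diffusion and radiative cell-kill is most
effective), shell ``n_shells - 1`` is the innermost block (the hypoxic core).
Each shell carries its own site-removal probability, decreasing geometrically
toward the center with reduction rate ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LatticeSpec",
    "ShellMap",
    "RemovalSchedule",
    "assign_shells",
    "removal_probabilities",
    "site_weights",
    "per_shell_occupancy",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the shelled square lattice.

    Parameters
    ----------
    side_length : int
        Sites per edge, ``L >= 2``.
    n_shells : int
        Number of concentric square shells, ``1 <= n_shells <= ceil(L/2)``.

    Connectivity is fixed at 4 nearest neighbors with open boundaries.
    """

    side_length: int
    n_shells: int = 5

    def __post_init__(self) -> None:
        L, n = self.side_length, self.n_shells
        if int(L) != L or L < 2:
            raise ValueError(f"side_length must be an integer >= 2, got {L!r}")
        if int(n) != n or not 1 <= n <= math.ceil(L / 2):
            raise ValueError(
                f"n_shells must satisfy 1 <= n_shells <= ceil(L/2) = "
                f"{math.ceil(L / 2)}, got {n!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.side_length * self.side_length

    @property
    def shell_width(self) -> int:
        """Nominal width of the outer shells, ``floor(L / (2 n_shells))``.

        Remainder sites (when L is not divisible by ``2 * n_shells``) are
        absorbed by the innermost shell, keeping the outermost, highest-removal
        shell at exact nominal width.
        """
        return max(1, self.side_length // (2 * self.n_shells))


@dataclass(frozen=True)
class ShellMap:
    """Per-site shell index on the lattice.

    ``shell_index`` is an (L, L) integer array, 0 = outermost shell,
    ``n_shells - 1`` = innermost.  Shells partition the lattice into
    concentric square annuli; the index is a non-increasing function of the
    Chebyshev distance from the lattice center.
    """

    spec: LatticeSpec
    shell_index: np.ndarray

    @property
    def n_shells(self) -> int:
        return self.spec.n_shells

    def shell_sizes(self) -> np.ndarray:
        """Site count per shell, outermost first."""
        return np.bincount(self.shell_index.ravel(), minlength=self.n_shells)


@dataclass(frozen=True)
class RemovalSchedule:
    """Per-shell removal probabilities for reduction rate ``r``.

    ``probabilities[k] = (1 - r)**k`` for shell index k (0 = outermost, whose
    removal probability is exactly 1).  Unrounded values are used in
    simulation.
    """

    r: float
    probabilities: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.probabilities)


def assign_shells(spec: LatticeSpec) -> ShellMap:
    """Partition the lattice into concentric square shells.

    Sites are banded by their Chebyshev distance from the lattice center
    ``((L-1)/2, (L-1)/2)`` — equivalently by their distance
    ``m = min(i, j, L-1-i, L-1-j)`` to the nearest boundary — into bands of
    width ``floor(L / (2 n_shells))``; the innermost shell absorbs any
    remainder.  Deterministic and idempotent.
    """
    L, n = spec.side_length, spec.n_shells
    idx = np.arange(L)
    edge_dist = np.minimum(idx, L - 1 - idx)
    depth = np.minimum(edge_dist[:, None], edge_dist[None, :])
    shell = np.minimum(depth // spec.shell_width, n - 1).astype(np.int32)
    shell.setflags(write=False)
    return ShellMap(spec=spec, shell_index=shell)


def removal_probabilities(r: float, n_shells: int) -> RemovalSchedule:
    """Geometric removal-probability schedule for reduction rate ``r``.

    The removal probability of the outermost shell is 1 and decreases by the
    factor ``1 - r`` from each shell to its neighbor toward the center:
    ``probabilities[k] = (1 - r)**k``.  For ``r = 0`` the model reduces to
    homogeneous inverse percolation.

    Raises
    ------
    ValueError
        If ``r`` is outside ``[0, 1)`` or ``n_shells < 1``.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"reduction rate r must lie in [0, 1), got {r!r}")
    if int(n_shells) != n_shells or n_shells < 1:
        raise ValueError(f"n_shells must be a positive integer, got {n_shells!r}")
    probs = (1.0 - float(r)) ** np.arange(n_shells, dtype=np.float64)
    probs.setflags(write=False)
    return RemovalSchedule(r=float(r), probabilities=probs)


def site_weights(shells: ShellMap, schedule: RemovalSchedule) -> np.ndarray:
    """Flat (length L*L) per-site removal probabilities.

    Raises
    ------
    ValueError
        If the shell map and schedule disagree on the shell count.
    """
    if shells.n_shells != schedule.n_shells:
        raise ValueError(
            f"shell map has {shells.n_shells} shells but schedule has "
            f"{schedule.n_shells}"
        )
    return schedule.probabilities[shells.shell_index].ravel()


def per_shell_occupancy(shells: ShellMap, occupancy: np.ndarray) -> np.ndarray:
    """Occupied-site fraction of each shell, outermost first."""
    occ = np.asarray(occupancy, dtype=bool).ravel()
    counts = np.bincount(
        shells.shell_index.ravel(), weights=occ, minlength=shells.n_shells
    )
    return counts / shells.shell_sizes()
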