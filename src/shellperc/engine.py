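"""One inverse-percolation realization: stochastic site removal under the shell
schedule, exact detection of the spanning-loss step, and cluster labeling.

The simulated process starts from a fully occupied lattice and removes sites
one by one.  A candidate site is drawn uniformly among the occupied sites and
removed with its shell's probability; on rejection a new candidate is drawn.
The critical density ``p_c`` of a realization is the occupied-site fraction
immediately after the removal that first destroys the spanning cluster.

Deletion is turned into insertion: the full removal order is pregenerated and
replayed in reverse with an incremental union-find (path compression, union by
size, boundary-contact flags merged on union).  Spanning first appears during
reverse addition at occupied count ``n + 1``, so the forward break leaves
``n`` sites and ``p_c = n / L**2`` — bit-identical to the forward one-by-one
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _kernels
from .lattice import LatticeSpec, RemovalSchedule, ShellMap, site_weights

__all__ = [
    "RemovalOrder",
    "ClusterState",
    "ThresholdSample",
    "GridSnapshot",
    "sample_removal_order",
    "find_critical_density",
    "find_critical_density_forward",
    "label_clusters",
    "spans",
    "snapshot_at_density",
    "snapshot_at_threshold",
    "largest_cluster",
]


@dataclass(frozen=True)
class RemovalOrder:
    """A complete removal sequence: a permutation of all ``L*L`` flat site
    indices in the order they are removed, plus the seed that produced it."""

    sequence: np.ndarray
    seed: int
    spec: LatticeSpec

    def __post_init__(self) -> None:
        seq = np.asarray(self.sequence, dtype=np.int64)
        N = self.spec.n_sites
        if seq.shape != (N,) or not np.array_equal(np.sort(seq), np.arange(N)):
            raise ValueError(
                f"sequence must be a permutation of 0..{N - 1}"
            )
        seq.setflags(write=False)
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ClusterState:
    """Labeled occupancy grid.

    ``labels`` is 0 on empty sites; occupied sites carry labels 1..n_clusters
    partitioning them into maximal 4-connected components.  ``sizes[c]`` is
    the site count of cluster c (``sizes[0]`` is the empty-site count) and
    ``touches[c]`` holds the four boundary-contact flags
    (top, bottom, left, right).
    """

    labels: np.ndarray
    n_clusters: int
    sizes: np.ndarray
    touches: np.ndarray

    @property
    def n_occupied(self) -> int:
        return int(self.sizes[1:].sum())


@dataclass(frozen=True)
class ThresholdSample:
    """Critical density of one Monte Carlo realization.

    ``n_remaining`` is the occupied-site count immediately after the removal
    that first destroys spanning; ``p_c = n_remaining / L**2``.
    """

    p_c: float
    n_remaining: int
    seed: int


@dataclass(frozen=True)
class GridSnapshot:
    """Boolean occupancy grid at a chosen process point, with an optional
    largest-cluster mask (a single maximal connected component)."""

    occupancy: np.ndarray
    largest_cluster: Optional[np.ndarray] = None


GridLike = Union[np.ndarray, GridSnapshot]


def _as_grid(grid: GridLike) -> np.ndarray:
    occ = grid.occupancy if isinstance(grid, GridSnapshot) else grid
    return np.ascontiguousarray(occ, dtype=np.uint8)


def sample_removal_order(
    shells: ShellMap,
    schedule: RemovalSchedule,
    seed: int,
    method: str = "race",
) -> RemovalOrder:
    """Draw the full removal sequence of one realization.

    ``method="rejection"`` runs the literal rejection loop: draw a uniformly
    random occupied site, remove it with its shell's probability, otherwise
    redraw.  ``method="race"`` (default) draws an independent exponential
    clock ``E_s / w_s`` per site, where ``w_s`` is the site's shell
    probability, and removes sites in order of firing times — the
    Efraimidis–Spirakis construction of successive sampling without
    replacement with probability proportional to weight, which is exactly the
    acceptance distribution of the rejection loop at every step.  For r = 0
    both reduce to a uniform random permutation.
    """
    weights = site_weights(shells, schedule)  # validates shell counts
    rng = np.random.default_rng(seed)
    N = weights.size
    if method == "race":
        keys = rng.exponential(size=N) / weights
        seq = np.argsort(keys, kind="stable")
    elif method == "rejection":
        seq = np.empty(N, dtype=np.int64)
        alive = np.arange(N, dtype=np.int64)
        n_alive = N
        k = 0
        while n_alive > 0:
            t = int(rng.integers(n_alive))
            s = alive[t]
            if rng.random() < weights[s]:
                n_alive -= 1
                alive[t] = alive[n_alive]
                seq[k] = s
                k += 1
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return RemovalOrder(sequence=seq, seed=int(seed), spec=shells.spec)


def find_critical_density(order: RemovalOrder, spec: LatticeSpec | None = None) -> ThresholdSample:
    """Locate the spanning-loss step of a removal order exactly.

    Replays the order in reverse as additions with incremental union-find;
    spanning first appears at occupied count ``n + 1``, and the sample
    reports ``n_remaining = n`` and ``p_c = n / L**2``.
    """
    spec = spec or order.spec
    L = spec.side_length
    count = _kernels.reverse_break_count(order.sequence, L)
    n_remaining = int(count) - 1
    return ThresholdSample(
        p_c=n_remaining / spec.n_sites, n_remaining=n_remaining, seed=order.seed
    )


def find_critical_density_forward(
    order: RemovalOrder, spec: LatticeSpec | None = None
) -> ThresholdSample:
    """Naive forward oracle: remove sites one by one, relabel the whole grid
    after each removal, and stop when spanning is first lost.

    Quadratic in the site count — intended for small lattices and for
    verifying :func:`find_critical_density`, with which it agrees exactly.
    """
    spec = spec or order.spec
    L = spec.side_length
    occ = np.ones((L, L), dtype=np.uint8)
    for t, s in enumerate(order.sequence):
        occ[s // L, s % L] = 0
        if not spans(label_clusters(occ)):
            n_remaining = spec.n_sites - (t + 1)
            return ThresholdSample(
                p_c=n_remaining / spec.n_sites,
                n_remaining=n_remaining,
                seed=order.seed,
            )
    raise AssertionError("spanning never lost; invalid removal order")


def label_clusters(grid: GridLike) -> ClusterState:
    """Label maximal 4-connected components of occupied sites.

    Single raster pass with label-equivalence merging (Hoshen–Kopelman /
    cluster multiple labeling technique); labels are 1..k in raster order.
    """
    occ = _as_grid(grid)
    labels, k = _kernels.hoshen_kopelman(occ)
    sizes = np.bincount(labels.ravel(), minlength=k + 1)  # sizes[0] = empty sites
    touches = np.zeros((k + 1, 4), dtype=bool)
    for axis, line in enumerate(
        (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1])
    ):
        touches[np.unique(line), axis] = True
    touches[0] = False
    return ClusterState(labels=labels, n_clusters=k, sizes=sizes, touches=touches)


def spans(state: ClusterState) -> bool:
    """True iff some cluster touches both top and bottom rows, or both left
    and right columns (either-axis spanning)."""
    t = state.touches
    return bool(np.any((t[:, 0] & t[:, 1]) | (t[:, 2] & t[:, 3])))


def snapshot_at_density(
    order: RemovalOrder, spec: LatticeSpec | None = None, p: float = 1.0
) -> GridSnapshot:
    """Occupancy grid after removals have reduced the occupied count to
    ``round(p * L**2)``, following the given order."""
    spec = spec or order.spec
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"density p must lie in [0, 1], got {p!r}")
    N = spec.n_sites
    n_keep = int(round(p * N))
    occ = np.ones(N, dtype=bool)
    occ[order.sequence[: N - n_keep]] = False
    return GridSnapshot(occupancy=occ.reshape(spec.side_length, spec.side_length))


def snapshot_at_threshold(
    order: RemovalOrder, spec: LatticeSpec | None = None
) -> GridSnapshot:
    """The last spanning configuration of a removal order (the state just
    before the removal that destroys spanning), with its largest-cluster
    mask attached."""
    spec = spec or order.spec
    sample = find_critical_density(order, spec)
    snap = snapshot_at_density(order, spec, (sample.n_remaining + 1) / spec.n_sites)
    return largest_cluster(label_clusters(snap.occupancy))


def largest_cluster(state: ClusterState) -> GridSnapshot:
    """Mask of the maximal-size cluster; ties broken by smallest label.

    Raises
    ------
    ValueError
        If the grid has no occupied site.
    """
    if state.n_clusters == 0:
        raise ValueError("cannot extract the largest cluster of an empty grid")
    lab = int(np.argmax(state.sizes[1:])) + 1  # argmax → smallest label on ties
    return GridSnapshot(
        occupancy=state.labels > 0, largest_cluster=state.labels == lab
    )
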