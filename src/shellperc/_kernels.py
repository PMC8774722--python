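"""Compiled inner loops: union-find reverse addition and Hoshen-Kopelman labeling.

Boundary-contact flags are a 4-bit mask per cluster root:
bit 0 = touches top row, bit 1 = bottom row, bit 2 = left column,
bit 3 = right column.  A cluster spans when it holds bits 0&1 or bits 2&3.
"""

import numpy as np
from numba import njit

SPAN_TOP = np.uint8(1)
SPAN_BOTTOM = np.uint8(2)
SPAN_LEFT = np.uint8(4)
SPAN_RIGHT = np.uint8(8)


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


@njit(cache=True)
def _boundary_flags(i, j, L):
    f = np.uint8(0)
    if i == 0:
        f |= SPAN_TOP
    if i == L - 1:
        f |= SPAN_BOTTOM
    if j == 0:
        f |= SPAN_LEFT
    if j == L - 1:
        f |= SPAN_RIGHT
    return f


@njit(cache=True)
def _add_site(s, L, parent, size, flags, occupied):
    """Occupy site s and union it with its occupied 4-neighbors.

    Returns the root of the cluster containing s after all unions.
    """
    i = s // L
    j = s % L
    parent[s] = s
    size[s] = 1
    flags[s] = _boundary_flags(i, j, L)
    occupied[s] = 1
    root = s
    for d in range(4):
        if d == 0:
            ok = i > 0
            nb = s - L
        elif d == 1:
            ok = i < L - 1
            nb = s + L
        elif d == 2:
            ok = j > 0
            nb = s - 1
        else:
            ok = j < L - 1
            nb = s + 1
        if ok and occupied[nb]:
            rn = _find(parent, nb)
            root = _find(parent, root)
            if rn != root:
                # union by size
                if size[rn] > size[root]:
                    rn, root = root, rn
                parent[rn] = root
                size[root] += size[rn]
                flags[root] |= flags[rn]
    return _find(parent, root)


@njit(cache=True)
def _spans_flag(f):
    updown = (f & SPAN_TOP) != 0 and (f & SPAN_BOTTOM) != 0
    leftright = (f & SPAN_LEFT) != 0 and (f & SPAN_RIGHT) != 0
    return updown or leftright


@njit(cache=True)
def reverse_break_count(sequence, L):
    """Replay a removal order in reverse as additions; return the occupied
    count at which a spanning cluster first appears.

    The forward break step (the removal that first destroys spanning) leaves
    this count minus one occupied sites.
    """
    N = L * L
    parent = np.empty(N, np.int64)
    size = np.zeros(N, np.int64)
    flags = np.zeros(N, np.uint8)
    occupied = np.zeros(N, np.uint8)
    count = 0
    for t in range(N - 1, -1, -1):
        root = _add_site(sequence[t], L, parent, size, flags, occupied)
        count += 1
        if _spans_flag(flags[root]):
            return count
    return count  # unreachable for L >= 2: the full lattice always spans


@njit(cache=True)
def reverse_addition_trace(sequence, L):
    """Full reverse-addition replay for oracle tests (no early exit).

    Returns
    -------
    roots : (N, N) int64
        ``roots[k, s]`` is the union-find root of site ``s`` after the
        (k+1)-th addition, or -1 if s is still unoccupied.
    spanning : (N,) uint8
        1 where some cluster spans after the (k+1)-th addition.
    """
    N = L * L
    parent = np.empty(N, np.int64)
    size = np.zeros(N, np.int64)
    flags = np.zeros(N, np.uint8)
    occupied = np.zeros(N, np.uint8)
    roots = np.full((N, N), -1, np.int64)
    spanning = np.zeros(N, np.uint8)
    span = False
    for k in range(N):
        s = sequence[N - 1 - k]
        root = _add_site(s, L, parent, size, flags, occupied)
        if _spans_flag(flags[root]):
            span = True
        spanning[k] = 1 if span else 0
        for x in range(N):
            if occupied[x]:
                roots[k, x] = _find(parent, x)
    return roots, spanning


@njit(cache=True)
def hoshen_kopelman(occ):
    """Single-pass raster cluster labeling with label-equivalence merging.

    Parameters
    ----------
    occ : (n1, n2) uint8 occupancy grid.

    Returns
    -------
    labels : (n1, n2) int32 — 0 for empty sites, clusters numbered 1..k in
        raster order of first appearance.
    k : int — number of clusters.
    """
    n1, n2 = occ.shape
    labels = np.zeros((n1, n2), np.int32)
    # at most ceil(N/2) provisional labels (checkerboard worst case)
    parent = np.zeros(n1 * n2 // 2 + 2, np.int32)
    nxt = np.int32(1)
    for i in range(n1):
        for j in range(n2):
            if occ[i, j] == 0:
                continue
            up = labels[i - 1, j] if i > 0 else 0
            left = labels[i, j - 1] if j > 0 else 0
            if up == 0 and left == 0:
                parent[nxt] = nxt
                labels[i, j] = nxt
                nxt += 1
            elif up != 0 and left != 0:
                ru = _find(parent, up)
                rl = _find(parent, left)
                if ru < rl:
                    parent[rl] = ru
                    labels[i, j] = ru
                else:
                    parent[ru] = rl
                    labels[i, j] = rl
            else:
                labels[i, j] = _find(parent, up + left)
    # relabel to consecutive 1..k in raster order of cluster roots
    remap = np.zeros(nxt, np.int32)
    k = np.int32(0)
    for i in range(n1):
        for j in range(n2):
            lab = labels[i, j]
            if lab != 0:
                r = _find(parent, lab)
                if remap[r] == 0:
                    k += 1
                    remap[r] = k
                labels[i, j] = remap[r]
    return labels, int(k)
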