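# Methods

## Model

The tumor/TME network is abstracted as an L × L square lattice of sites with
4-nearest-neighbor connectivity and open (non-periodic) boundaries.  All sites
start occupied (live tissue).  Radiotherapy is modeled as *inverse site
percolation*: sites are removed one at a time until the lattice no longer
*spans*, i.e. until no 4-connected cluster of occupied sites touches both the
top and bottom rows or both the left and right columns.  The critical density
p_c of one realization is the occupied fraction immediately after the removal
that first destroys spanning; ensembles of independent realizations give the
Monte Carlo estimate of the threshold.

Hypoxia heterogeneity enters through a spatial gradient of the removal
probability.  The lattice is partitioned into `n_shells` concentric square
annuli by banding the Chebyshev distance from the lattice center
((L−1)/2, (L−1)/2) — equivalently the distance m = min(i, j, L−1−i, L−1−j) to
the nearest boundary — into bands of width ⌊L / (2 n_shells)⌋.  Shell 0 is the
outermost ring; when L is not divisible by 2·n_shells the remainder is
absorbed by the innermost shell, so the outermost (highest-removal) shell
keeps its exact nominal width.  Square rather than circular shells keep the
partition exact on the lattice; the even-L case has no center site, and the
half-integral center keeps the banding well defined.

A site in shell k is removed, when selected, with probability

  p_k = (1 − r)^k ,  0 ≤ r < 1,

so the outermost shell removes with probability exactly 1 and the rate of
reduction from one shell to the next toward the center is multiplicative.
For r = 0.1 and five shells this gives [1, 0.9, 0.81, 0.729, 0.6561]
(outermost → innermost); unrounded values are always used internally.  With
r = 0 or a single shell the model reduces exactly to homogeneous inverse
percolation.

## Removal process and its exact reformulation

The defining process is a rejection loop: draw a uniformly random occupied
site, remove it with its shell's probability, otherwise draw again.
Conditional on a removal happening, the removed site is distributed over the
remaining sites with probability proportional to its shell probability w_s.
The whole process therefore defines a random total order on the sites —
successive sampling without replacement with probability ∝ w_s — and nothing
else about it matters for any quantity computed here.

Two samplers of that order are implemented:

- `rejection` — the literal loop, useful as a reference at small L;
- `race` (default) — each site draws an independent exponential clock
  E_s / w_s and sites are removed in order of firing times
  (Efraimidis–Spirakis).  By the memorylessness of the exponential this
  reproduces the acceptance distribution of the rejection loop at every step,
  and it vectorizes to one `argsort` per realization.

The two are equivalence-tested against the closed-form first-removal law and
against each other.

Given the order, deletion is turned into insertion: the order is replayed in
reverse as site additions into an incremental union-find (path compression,
union by size) whose roots carry 4-bit boundary-contact flags merged on
union.  Spanning appears during reverse addition exactly where it disappears
during forward removal — site removal can only disconnect, so the break step
is unique — and if spanning first appears at occupied count n + 1, the
forward break leaves n sites and p_c = n / L².  The off-by-one convention
follows the "density of still-remaining sites" definition; the alternative
convention differs by 1/L², negligible at L = 1000 but fixed for determinism.
A naive forward simulation (full relabeling after every removal) is kept as
an oracle and agrees with the reverse engine exactly on shared orders.

Cluster labeling for snapshots uses a single-pass raster Hoshen–Kopelman
(cluster multiple labeling) kernel; tests cross-check it against
`scipy.ndimage.label` with 4-connectivity.

## Spanning criterion

"Spanning" is read as *some* cluster connecting either opposite pair of
boundaries (up/down or right/left).  Near the break step the spanning cluster
is the largest cluster with probability approaching one, so checking any
cluster via union-find extent flags is equivalent in practice to checking the
largest specifically, and a one-axis criterion is used rather than both axes.
Both choices shift p_c only by boundary-case events of vanishing measure at
the sizes studied.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `side_length` L | 1000 | lattice edge, sites (study scale) |
| `n_shells` | 5 | concentric shells; the five-zone worked example fixes the default |
| `r` | grid 0 … 0.6 step 0.1 | reduction rate of removal probability per shell inward (dimensionless) |
| `n_realizations` | 100 | Monte Carlo realizations per r |
| `base_seed` | 0 | root of all randomness |

Realization seeds are hashed from (base_seed, r-index, realization-index)
through numpy `SeedSequence`, giving independent, individually re-runnable
31-bit streams; every threshold sample records its seed, so any realization
can be reproduced bit for bit.

The p_c(r) relation is summarized by an *unweighted* ordinary-least-squares
line through the ensemble means over the configured r grid (no weighting is
applied because the standard errors are nearly uniform across the grid);
standard errors of the means are reported alongside even though the fit does
not use them.

## Problem sizes and finite-size behavior

Default ensembles run at the study scale L = 1000 with 100 realizations per
r; the compiled union-find kernel completes a realization in well under a
second, a seven-point curve in a few minutes on one CPU.  Smaller lattices
carry a systematic finite-size shift of the mean threshold that grows with r:
at L = 256 the mid-grid means sit ≈ 0.03 below their L = 1000 values (e.g.
0.614 vs 0.642 at r = 0.2), at L = 512 ≈ 0.013 below.  Scaled-down runs are
therefore fine for smoke tests and qualitative work but not for comparing
against study-scale threshold values; the test suite runs its threshold
checks at full scale for this reason.

## What the simulations do and do not represent

The lattice is a deliberately minimal abstraction.  It captures the
qualitative consequences of a radial cell-kill gradient: the threshold rises
roughly linearly with r (slope ≈ 0.3 over the seven-point grid), and at a
fixed occupied fraction below the homogeneous threshold the periphery is
rarefied while the core remains dense — in every one of 100 realizations at
p = 0.59, r = 0.4 the innermost shell's occupied fraction exceeds the
outermost's.  It does not represent real tumor geometry: shells are square
and concentric, the lattice is two-dimensional, boundaries are open, and
connectivity is strictly 4-neighbor.  Three-dimensional lattices,
patient-specific geometries, bond percolation, periodic boundaries, and
finite-size-scaling extrapolation are out of scope.  Passing tests show the
model's internal consistency and its agreement with the homogeneous
percolation threshold, not the clinical validity of the hypoxia
interpretation.

## Numerical choices and degenerate inputs

- Thresholds are exact integers n_remaining divided by L²; no floating-point
  accumulation enters the break-step location.
- Largest-cluster ties are broken by the smallest raster label
  (deterministic).
- `n_realizations = 1` yields NaN standard deviation / error (flagged, not
  zero).
- A linear fit requires at least two distinct r values; duplicated r values
  are permitted and handled by ordinary least squares.
- Shell geometry requires 1 ≤ n_shells ≤ ⌈L/2⌉; the subnormal range of r is
  excluded only by floating point itself (1 − r must be < 1 representably for
  the schedule to decrease strictly).
- CSV output is comma-separated with LF line endings and '.' decimals; PNG
  rendering maps the grid pixel-exactly (occupied dark, empty white), so
  identical seeds reproduce byte-identical CSVs and images.
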