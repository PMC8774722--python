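# shellperc

Monte Carlo simulations of radiotherapy-induced tumor-network break-up as
**inverse site percolation on a shelled square lattice**.

Radiation kills tumor cells most effectively where oxygen is plentiful.
Because oxygen diffuses in from the surrounding tissue, a tumor is usually
least hypoxic at its periphery and most hypoxic at its center, so the
radiative cell-kill probability decreases from the rim inward.  `shellperc`
models this as inverse percolation: an L × L square lattice (4-nearest-neighbor
connectivity, open boundaries) starts fully occupied and sites are removed one
by one, but the removal probability depends on which of `n_shells` concentric
square shells the site lies in.  Shell 0 (the periphery) removes with
probability 1; each shell inward removes with probability reduced by the
factor 1 − r,

```
p_k = (1 − r)^k ,    k = 0 (outermost) … n_shells − 1 (innermost),
```

where r ∈ [0, 1) is the *reduction rate* encoding the hypoxia gradient.  For
r = 0.1 and five shells the schedule is [1, 0.9, 0.81, 0.729, 0.6561].  A
realization's **critical density p_c** is the occupied-site fraction
immediately after the removal that first disconnects the lattice — the step at
which no cluster any longer touches both the top and bottom rows or both the
left and right columns.  For r = 0 the model is homogeneous inverse
percolation with the known threshold p_c ≈ 0.5927; for r > 0 the break-up
requires removing fewer sites overall (p_c rises roughly linearly with r,
slope ≈ 0.3), because removals concentrate at the periphery while the hypoxic
core stays connected — the mathematical face of radio-resistance under
hypoxia heterogeneity.

The engine pregenerates the full removal order (the rejection rule "pick a
uniformly random occupied site, remove it with its shell's probability,
otherwise redraw" is sampled exactly via exponential racing) and replays it in
reverse with an incremental union-find, so the break step is located exactly
and a 1000 × 1000 realization takes well under a second.

Intended for researchers in mathematical oncology and statistical physics who
want reproducible threshold curves, cluster snapshots, and a compact testbed
for gradient-percolation ideas.

## Worked example (library)

```python
import numpy as np
import shellperc as sp

spec = sp.LatticeSpec(side_length=200, n_shells=5)
shells = sp.assign_shells(spec)                      # concentric square annuli
schedule = sp.removal_probabilities(r=0.4, n_shells=5)

order = sp.sample_removal_order(shells, schedule, seed=7)
ts = sp.find_critical_density(order)
print("p_c =", round(ts.p_c, 4), "n_remaining =", ts.n_remaining)

snap = sp.snapshot_at_density(order, p=0.59)         # just below threshold
print("per-shell occupancy:",
      np.round(sp.per_shell_occupancy(shells, snap.occupancy), 3))
```

prints

```
p_c = 0.6724 n_remaining = 26896
per-shell occupancy: [0.402 0.589 0.726 0.829 0.894]
```

With the gradient (r = 0.4) this 200 × 200 realization stays connected down to
67.2 % occupancy — far above the homogeneous 59.3 % — and at the fixed density
0.59 the innermost shell is still 89 % occupied while the periphery has
thinned to 40 %: radiation has "poked holes" in the rim but the hypoxic core
resists break-up.

## Worked example (CLI)

```bash
shellperc threshold --size 256 --shells 5 --r 0.4 --realizations 10 --seed 1 --out-dir demo
# mean p_c = 0.6744 (n=10) -> demo
```

which writes `samples.csv` (one row per realization: L, n_shells, r, seed,
n_remaining, p_c), `summary.json` (mean 0.6744, sd 0.0100, se 0.0032), and a
`manifest.json` with SHA-256 digests sufficient to re-create every file from
the echoed parameters.  Other subcommands:

```bash
shellperc curve --config curve.yaml --out-dir out    # p_c vs r, OLS fit, figure
shellperc snapshot --mode at-density --r 0.4 --density 0.59 --out-dir snap
```

`curve.yaml` is a flat YAML map (`size`, `shells`, `r_values`,
`realizations`, `seed`); CLI flags override config keys.  Snapshots are
written as plain 0/1 array dumps plus pixel-exact two-color PNGs, with a
per-shell occupancy CSV.

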