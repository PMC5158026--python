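# tubemech

Biomechanics of growing pollen tubes from micro-indentation, built around a
Lab-on-a-Chip + Cellular Force Microscope (CFM) workflow: lily pollen tubes
are guided through parallel microchannels onto a glass slide, where a
sub-micron tip (Φ = 800 nm) indents the tube to a 5 µN maximum load at
2 µm/s.  The slope of the force–indentation curve in the region of maximum
load — the *apparent stiffness* (N/m) — conflates cell-wall elasticity,
turgor pressure, wall thickness, tube diameter and contact geometry, so a
single stiffness value never pins down a wall modulus.  This package
quantifies both sides of that statement: it recovers the cohort stiffness
statistics from raw force curves, and it inverts them through a mechanical
model into the *range* of compatible wall moduli.

The package provides, as importable modules with a thin `tubemech` CLI on
top:

* **`synth`** — a synthetic-cohort generator (the study's raw CFM
  recordings are not public).  Virtual tubes carry known truth stiffness,
  drawn either from lognormal distributions matched to the published group
  statistics (growing shank: mean/median loading 2.20/1.73 N/m, unloading
  3.28/2.98 N/m over n = 19 tubes, m = 135 indentations; non-growing:
  loading mean 0.69 N/m, unloading 1.67 N/m, n = 11, m = 71), or from the
  shell model at a prescribed modulus.  Raw curves embed the series sensor
  spring, a capillary background slope, loading/unloading hysteresis, mild
  nonlinearity and Gaussian force noise.
* **`curves`** — contact detection, sensor-compliance cancellation
  (`δ = (z − z0) − F/k_sensor`), windowed least-squares apparent stiffness
  per phase, pooled cohort statistics, a permutation test for the
  growing/non-growing comparison, and the stiffness-vs-distance apex
  profile.
* **`shell`** — the forward model: a turgid, linear-elastic thin cylinder
  (Donnell shallow-shell equations with membrane pretension N<sub>θ</sub> = pR,
  N<sub>x</sub> = pR/2) under a circular patch load, solved by a double Fourier
  series, with an independent finite-difference oracle used in the tests.
* **`invert`** — bisection of the strictly monotone stiffness–modulus map
  and the *compatible set*: every (E, t, p, d) combination on a
  physiological grid reproducing a target stiffness within tolerance.
* **`layout`** — chip-design arithmetic (9 × 44 = 396 channel capacity,
  9 × 12 = 108 guided lily tubes, 6 × 40 = 240 Arabidopsis tubes) and
  grain/tube/channel compatibility checks.
* **`io` / `pipeline` / `config`** — plain-text TSV/CSV/JSON formats, a
  deterministic end-to-end runner, validated YAML configuration.

## Worked example

Simulate the growing-tube cohort at the published size, process it, and ask
what wall moduli are compatible with the measured mean:

```sh
$ tubemech simulate --species lily --group growing --seed 7 -o demo/growing
wrote 135 curves + manifest to demo/growing
$ tubemech run -i demo/growing -o demo/out
{"compare": "skipped: single group", "invert": "ok: 44 compatible combinations",
 "load": "ok: 135 curves", "process": "ok: 135 records", "stats": "ok: groups ['growing']"}
```

`demo/out/stats.csv` then holds the pooled per-indentation statistics of
this cohort (one 19-tube cohort fluctuates around the population values by
a few tenths of N/m):

```
group,n_tubes,m_indentations,load_mean_N_per_m,load_median_N_per_m,...
growing,19,135,2.08956906,1.32648746,...
```

A single forward-model evaluation — a lily-sized tube (d = 17.4 µm) with a
0.2 µm wall at 0.2 MPa turgor and a 90 MPa wall modulus:

```sh
$ tubemech forward --e 90 --t 0.2 --d 17.4 --p 0.2
{"converged": true, "k_model_N_per_m": 3.0189068725619825, ...}
```

i.e. about 3 N/m of apparent stiffness, in the measured range.  Running the
inversion at the published mean loading stiffness over the physiological
box (wall 0.1–0.3 µm, turgor 0.1–0.4 MPa, diameter 12.4–22.4 µm) shows why
a point estimate of the modulus is unsupported: the compatible moduli span
far more than an order of magnitude, consistent with the published
20–400 MPa spread.

```sh
$ tubemech invert --k-target 2.20 --grid 10
{"E_max_MPa": 658.8, "E_min_MPa": 1.0, "E_spread_ratio": 658.8,
 "diagnostics": {"n_above_range": 0, "n_below_range": 333, "n_grid": 1000},
 "k_target_N_per_m": 2.2, "n_compatible": 771, "tolerance": 0.1}
```

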