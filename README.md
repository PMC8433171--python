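# striderswarm

An individual-based model of a water-strider (*Gerris*) group on a bounded
patch of water surface, together with the measurement pipeline needed to
compare the model with field video of a natural population.

Water striders of all sizes share one habitat and one niche: they compete
for insect prey falling onto the surface, defend private space, aggregate
loosely, and flee shoreline disturbances in synchronized "waves of fear".
`striderswarm` models the group as N(t) size-heterogeneous agents obeying

    m_j dv_j/dt = Σ_k (f_jk^rep + f_jk^att) + Σ_n f_jn^food + f_j^bound + f_j^wave − η_j v_j

with Gaussian pair forces f_jk = B_jk (r_j − r_k) exp(−|r_j − r_k|²/R_jk²):
strong short-range repulsion (radius R^rep, the private territory) plus weak
long-range attraction (R^att > R^rep, B^att < B^rep), whose balance sets an
equilibrium spacing R_min = sqrt(ln(B^rep/B^att)/(1/R_rep² − 1/R_att²)).
Strength scales with size as m^(2/3) and body length and drag as m^(1/3).
Discrete food portions appear at random (probability ζ per step); animals
within the contact range feed at rate dm/dt = μ m, everyone pays a metabolic
drain λ m, small recruits enter at rate ς per step, and any animal reaching
m_min (starved) or m_max (full grown) leaves the population.  Periodic
"wave of fear" forcing from one wall and the resulting spatial
redistribution of animals and food are included.

The field pipeline maps detected animals from camera pixels to ground
coordinates through a perspective transform, estimates body volumes as
two-axis ellipsoids V = (π/6) L W², and compares model and field histograms
of nearest-neighbor distance and body volume with a two-sample
Kolmogorov–Smirnov test.  A synthetic camera-scene generator makes the whole
pipeline testable without video.

## Worked example

```python
import numpy as np
import striderswarm as sw

p = sw.SimulationParams()                      # baseline: 100 animals, 30x30 arena
print("R_min =", round(sw.equilibrium_distance(1.0, p), 3))

rec = sw.run(p, n_steps=20_000, record_every=100)   # 400 time units
ct = rec.counters_table()
print(ct[["t", "N", "N_c1", "N_c2", "N_c3", "n_born", "n_died"]].iloc[-1])

acc = sw.HistogramAccumulator(sw.default_nnd_edges(p))
for s in rec.snapshots[len(rec.snapshots) // 2:]:
    acc.fold(sw.nearest_neighbor_distances(s.r))
print("NND histogram mode =", round(acc.mode_center(), 2))
```

prints (seed 12345):

```
R_min = 2.218
t         400.0
N         176.0
N_c1      167.0
N_c2        8.0
N_c3        1.0
n_born    426.0
n_died    350.0
Name: 200, dtype: float64
NND histogram mode = 1.66
```

The population has settled near N ≈ 180 with the small size class prevailing
(N_c1 ≫ N_c2, N_c3) and continuous turnover (426 born, 350 died or left in
400 time units).  The nearest-neighbor-distance mode of 1.66 lies below the
unit-mass equilibrium spacing R_min = 2.218 because the stationary
population is dominated by small animals (a pair's R_min scales with body
length, m^(1/3)) and feeding aggregations compress spacing further.  With
foraging and demography switched off and uniform masses, packed groups sit
at the pair balance distance: that experiment's long-run NND histogram peaks
within one bin (R_min/10) of the analytic R_min, as the test suite checks.

The same runs are available from a shell:

```bash
striderswarm run --scenario baseline --steps 20000 --out-dir out/
striderswarm scenario fear_wave --out wave.cfg
striderswarm run --config wave.cfg --seed 7 --out-dir wave_out/
```

writing `snapshots.csv`, `counters.csv`, NND/mass histogram CSVs, a
time–volume map, density profiles (for wave runs) and a JSON run log.

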