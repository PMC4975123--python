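# relief-districts

Tools for analysing the part/whole structure of **pictorial relief** — the
depth impression a viewer forms when looking into a picture.  The package
reconstructs depth orders from exhaustive 2-point "which is nearer?"
comparisons, segments the picture region by a confusion-augmented distance
metric, integrates gauge-figure attitude samples into a depth relief, and
extracts the relief's hill/dale geography (peaks, pits, passes, ridges,
water courses and the two natural district parcellations).  It is aimed at
visual psychophysicists studying depth from pictures, and ships a
simulated-observer module so every stage can be exercised and validated
without human data.

## The core quantities

* **Consensus depth order.** With all V(V−1)/2 vertex pairs judged once,
  vertices are ranked by how often each was called nearer (win counts,
  dense ranks, ties allowed).  Consistency is summarised by a *number of
  merit* defined like Kendall's tau: (C − D)/N over judged pairs, where C
  agree and D disagree with the consensus, consensus-tied pairs counting in
  N only.  Judgements that contradict the consensus are the *confusions*.
* **Confusion metric.** d(A,B) = |AB| for unconfused pairs and
  |AB| + diameter of the triangulation for confused ones.  Average-linkage
  clustering of this dissimilarity segments the region into districts
  within which depth comparison is reliable; partitions are compared by the
  Rand index and summarised by the inter/intra confusion-probability ratio.
* **Gauge-figure integration.** Attitude samples (slant/tilt → gradient
  (p,q) = tan σ·(cos τ, sin τ)) at face barycenters are integrated into a
  vertex depth field by area-weighted least squares; the normalised
  residual measures non-integrability (0 = a surface exists, ≈1 = pure
  curl).
* **Hill/dale geography.** Steepest ascent/descent along mesh edges assigns
  every vertex to the basin of a peak (hill district) and of a pit (dale
  district); ridges and water courses run through the saddles.  Negating
  the relief swaps the two parcellations exactly — the formal reason
  depth-inverted reliefs have different parts.

## Worked example

```python
from relief_districts import (
    four_bump_spec, make_grid_mesh, bump_relief, districts,
    ObserverSpec, simulate_judgements, DepthOrderModel, ConfusionClusterModel,
    rand_index,
)

spec = four_bump_spec()                  # four Gaussian bumps, 8x8 grid
mesh = make_grid_mesh(spec)              # 64 vertices, 161 edges, 98 faces
field = bump_relief(mesh, spec)          # zero-mean depth relief
dm = districts(mesh, field)              # 4 hill districts (the bulges)

obs = ObserverSpec(eps_within=0.05, eps_between=0.25, seed=1)
js = simulate_judgements(field, dm, obs)           # all 2,016 pairs
order = DepthOrderModel(js, mesh.n_vertices).fit()
print(order.summary())

seg = ConfusionClusterModel(mesh, order.confusions).fit()
print(seg.summary())
print("Rand vs planted districts:", rand_index(seg.partition, dm.hill_label))
```

prints

```
Consensus depth order (win-count reconstruction)
  observer/session : sim/s1
  vertices         : 64
  judged pairs     : 2016
  resolved levels  : 35
  number of merit  : 0.525
  discordant pairs : 456
Confusion-metric segmentation (average linkage)
  vertices          : 64
  confusions        : 456
  chosen k          : 4
  inter/intra ratio : 2.82
  connected clusters: 3/4
Rand vs planted districts: 0.9424603174603174
```

The simulated observer errs five times more often across bulges than within
one; the consensus order still resolves 35 of 64 depth levels, and the 456
confusions suffice for the clustering to pick k = 4 and recover the four
planted hill districts almost perfectly (Rand 0.94), with inter-cluster
confusions ≈2.8× as probable as intra-cluster ones.

The same stages are available from the shell:

```sh
relief-districts simulate --grid 8x8 --eps-within 0.05 --eps-between 0.25 \
    --sessions 3 --seed 17 --out data/
relief-districts order     --judgements data/judgements.csv --mesh data/mesh.off --out out/
relief-districts cluster   --judgements data/judgements.csv --mesh data/mesh.off --out out/
relief-districts integrate --attitudes data/attitudes.csv   --mesh data/mesh.off --out out/
relief-districts geography --mesh data/mesh.off --depths out/reconstructed_depths.csv --out out/
relief-districts run       --config run.yaml      # full pipeline + report.json
```

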