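# mdsegclust

Segment-based clustering of molecular-dynamics time series.

Point-based clustering of MD observables (dihedral angles, tICs,
interatomic distances) ignores the temporal structure of a trajectory:
two metastable states whose sample distributions overlap are smeared
into one, and slow transitions masquerade as states.  `mdsegclust`
clusters *segments* instead of frames:

1. **Change-point detection.**  A set of change points S maximizes the
   penalized Laplace log-likelihood
   `L(data | S) − λ Σᵢ |Sᵢ|^α`,
   where |Sᵢ| is the number of dimensions changing at time i,
   λ > 0 weighs the penalty and α ∈ [0, 1] discounts simultaneous
   changes (penalty λ·k^α for k co-changing dimensions), reflecting
   that conformational changes usually move several observables at
   once.  Small instances are solved to the global optimum.
2. **Earth mover's distances.**  Each segment becomes a unit-mass
   signature in observable space; the distance between two segments is
   the exact 1-Wasserstein transport cost
   `EMD(P, Q) = min_f Σᵢⱼ fᵢⱼ dᵢⱼ` with Euclidean ground distance —
   continuous even for non-overlapping supports (a signature shifted by
   θ is exactly |θ| away).
3. **Density-peak clustering.**  Segments get a Gaussian-kernel local
   density ρ (each neighbor weighted by its length in frames) and a
   separation δ to the nearest higher-density segment; elements with
   large ρ·δ are centroids, everything else follows its
   higher-density neighbor in one pass.  The kernel cutoff is the mean
   distance to the round(ln N)-th nearest neighbor.  A point-based
   control mode (every frame an element of weight 1, distances
   generated blockwise on the fly) is included.
4. **Slope analysis.**  Segments whose OLS slope exceeds
   1.96·σ_slope, with `σ_slope = σ_resid / √Σ(i−ī)²`, are flagged as
   transition segments (p < 0.05 against the flat null) and can be
   dropped before re-clustering.

A built-in two-state synthetic benchmark (25,000-point trajectories,
50 alternating segments, major-state mean 100, σ = 20, configurable
intensity ratio and minor-state population) provides ground truth and a
*minor-state accuracy* score for end-to-end validation.

## Worked example

```python
import numpy as np
from mdsegclust import (SyntheticSpec, generate_dataset, PipelineConfig,
                        run_pipeline, minor_state_accuracy)

spec = SyntheticSpec(ratio=2.0, pop2=0.5)          # easy corner: I2=200, 50/50
series, truth = generate_dataset(spec, seed=7)
cfg = PipelineConfig(lam=10.0, max_support=128, output_dir="example_out")
res = run_pipeline(cfg, series=series)
print(f"frames={series.n_frames}  segments={len(res.segments)}  clusters={res.state.n_clusters}")
for c in range(res.state.n_clusters):
    v = series.values[res.frame_labels == c, 0]
    print(f"cluster {c}: {v.size:>6} frames  mean={v.mean():7.2f}  sem={v.std()/np.sqrt(v.size):.3f}")
print(f"minor-state accuracy = {minor_state_accuracy(res.frame_labels, truth):.1f}%")
```

Output:

```
frames=25000  segments=57  clusters=2
cluster 0:  12501 frames  mean= 199.84  sem=0.177
cluster 1:  12499 frames  mean=  99.89  sem=0.178
minor-state accuracy = 100.0%
```

The detector over-segments slightly (57 segments for 50 true ones —
benign, since clustering reabsorbs false splits), the density-peak step
finds exactly the two generating states, and the recovered cluster
means match the configured intensities of 100 and 200 to within two
standard errors.  The run directory contains every intermediate as a
TSV (change points, segments, decision graph, per-frame assignments,
slope report) plus a JSON manifest of all effective parameters.

The same protocol is available from the shell:

```sh
mdsegclust simulate --ratio 2.0 --pop2 0.5 --seed 7 --out traj.csv
mdsegclust run --input traj.csv --lam 10 --output-dir example_out
mdsegclust evaluate --ratios 1.02,1.5,2.0 --pops 0.05,0.25,0.5 --out grid.tsv
```

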