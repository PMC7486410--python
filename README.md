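# cahub

Surrogate-based analysis of population calcium-imaging rasters: network
bursts and single-cell stimulation tests in developing hippocampal
slices, and locomotion/SCE/assembly modulation, directed
functional-connectivity graphs and hub classification in adult in vivo
recordings — with a synthetic-session generator providing ground truth
for every stage.

## The scientific problem

A small population of early-born GABAergic neurons is thought to act as
"hub cells" that orchestrate hippocampal network dynamics.  Testing that
idea from calcium imaging requires a chain of nonstandard statistics on
binary onset rasters (cells × frames):

* **GDP detection and stimulation tests (slices).**  Giant depolarizing
  potentials (GDPs) are frames whose population onset count exceeds the
  99th percentile of pooled circular-shift surrogates.  Whether
  stimulating one cell changes the rhythm is tested three ways:
  windowed inter-GDP-interval (IGI) distributions compared across
  pre/stim/post epochs with Kolmogorov–Smirnov tests; the per-burst
  phase Φᵢ = (t_Gⁱ − i·Δt)/Δt against a harmonic oscillator with the
  control period Δt; and a locking test comparing the highest peak of
  the trial-aligned onset histogram (normalised by the GDP count during
  stimulation) with 100 pseudo-stimulation surrogates built from
  concatenated control + post frames.

* **State modulation (in vivo).**  Locomotion and rest epochs come from
  the treadmill signal (rest = movement-free runs > 200 ms).  A cell is
  locomotion-ON if its onset-aligned Z-PSTH,
  Z = (PSTH − μ_B)/σ_B, holds two consecutive bins above Z = 2, or its
  locomotion/rest spike-count ratio exceeds the per-cell 95th percentile
  under circular shifts.  Synchronous calcium events (SCEs) are rest
  bins (200 ms) above a pooled surrogate threshold; a cell is SCE-ON if
  its zero-lag Z exceeds 3.

* **Cell assemblies.**  Co-activation patterns are extracted by
  PCA/ICA from the smoothed, z-scored rest-binned count matrix; the
  number of patterns is the count of principal-component variances above
  the maximum eigenvalue of circularly shifted matrices.  Assembly
  activity is the quadratic projection R_k(t) = z(t)ᵀ P_k z(t) with
  P_k = w_k w_kᵀ, diag(P_k) = 0.

* **Directed connectivity and hubs.**  For each cell pair, the lag
  distribution of B's spikes around A's onsets (±1 s) is kept only if it
  is neither sparse, nor uniform (unrelated firing), nor zero-centred
  (synchrony without direction); the sign of the mean lag orients the
  edge.  Hub cells jointly project to ≥5% of their field of view, sit in
  the top 5% of the pooled out-connection distribution, and have
  betweenness centrality at or above the pooled 80th percentile.

* **Group statistics.**  Small tagged populations are compared to
  matched random subsamples (per-field-of-view matched counts, 1000
  bootstrap draws, upper-tail 95th-percentile rule) and contingency
  tables to exact two-sided Fisher tests.

## Worked example

```python
import numpy as np
from cahub import (SliceSimSpec, HubEffect, gen_slice_session, detect_gdps,
                   test_gdp_locking, fisher_exact_test)

spec = SliceSimSpec(
    seed=7,
    gdp_jitter_frames=1.5,
    baseline_event_rate_hz=0.03,
    hub_effect=HubEffect.locking(latency_s=2.2, lock_prob=0.9),
)
raster, protocol, truth = gen_slice_session(spec)
print(f"simulated {len(truth['gdp_frames'])} true GDPs "
      f"({len(truth['locked_gdp_frames'])} stimulation-locked)")
catalog = detect_gdps(raster, rng=0)
print(f"detected {catalog.n_gdps} GDPs ({catalog.rate_hz:.3f} Hz)")
lock = test_gdp_locking(raster, protocol, catalog, rng=1)
print(f"locking: p = {lock.p:.2f}, latency = {lock.latency_s:.1f} s")

res = fisher_exact_test(np.array([[5, 18], [12, 10]]))
print(f"Fisher exact: p = {res.p:.4f}, OR = {res.odds_ratio:.3f}")
```

prints

```
simulated 41 true GDPs (15 stimulation-locked)
detected 43 GDPs (0.029 Hz)
locking: p = 0.00, latency = 2.3 s
Fisher exact: p = 0.0331, OR = 0.231
```

The simulated slice carries GDPs at ~0.02 Hz plus a hub cell whose
stimulation entrains extra bursts 2.2 s after each pulse; the detector
recovers the bursts, and the locking test finds the effect (no surrogate
peak reaches the observed one) with the latency recovered to within one
frame.  The Fisher example reproduces a responsive-cell-proportion
comparison between two groups of recorded neurons.

The same pipeline is available from the shell:

```bash
cahub simulate slice --seed 7 --out session/
cahub gdp --raster session/raster.tsv --protocol session/protocol.json \
      --seed 0 --out gdp.json
```

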