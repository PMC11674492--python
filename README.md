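# cyclicity

Lead–lag analysis of multichannel time series by **cyclicity analysis**:
reparametrization-invariant quantification of which channels lead and which
follow, spectral recovery of the order in which a traveling "ripple" of
activity sweeps through the channels, and persistence-based detection of
lead–lag *reversals* and *burstiness* in task-driven recordings.

The package is aimed at researchers working with slow, aperiodic
multichannel recordings — the motivating case is parcellated resting-state
and task fMRI (e.g., 68 cortical regions sampled at TR = 0.72 s), but
nothing in the method assumes a base frequency, stationarity, or even a
uniform clock: every statistic is built from iterated path integrals that
are invariant under monotone reparametrizations of the timeline.

## The method

For channels *x_k*(*t*), *x_l*(*t*) the **oriented area**

    a_kl = 1/2 ∮ (x_k dx_l − x_l dx_k)

is the signed area encircled by their parametric plot (a level-2 iterated
integral, computed exactly for the linearly interpolated samples by a
shoelace sum). *a_kl* > 0 means *x_k* leads; proportional signals and
signals with disjoint temporal supports give exactly zero. The
skew-symmetric **lead matrix** *A* = (*a_kl*) has purely imaginary
eigenvalue pairs ±*iλ*₁, ±*iλ*₂, …; the components of the eigenvector of the
largest pair — the **constellation** — line up along an ellipse in the
complex plane, in the cyclic order in which a chain-of-offsets wave
*x_k*(*t*) = *a_k* φ(*ωt* − *α_k*) excites the channels. Channels are ranked
by the elliptic norm of the fitted **constellation ellipse**
*q*(*z*) = *ax*² + 2*bxy* + *cy*² (rank 1 = most exposed to the ripple), and
the kept channels are ordered by phase after rotating the constellation's
centroid onto the positive real axis.

Treating the oriented area as a function of time, *a_kl*(*t*) =
½∫₀ᵗ(x_k dx_l − x_l dx_k), turns lead–lag into a dynamic quantity. Its
persistent direction changes — extracted by 0-dimensional sublevel-set
persistence with the elder rule, keeping the longest-lived features of the
trajectory and of its negation — mark **reversals** of the leader–follower
role; the summed length of the 10 longest bars is the trajectory's
**burstiness**. A seeded chain-of-offsets simulator (periodic waves,
solitary ripple trains, traveling-wave fields, and two-channel task-block
designs with alternating leader) provides ground truth for every stage,
including a closed-form lead matrix for Fourier seeds.

## Worked example

Five channels carrying the same 50-s waveform with increasing phase offsets
(0.0, 0.4, 0.9, 1.5, 2.2 rad), amplitudes 0.8–1.2, additive noise, sampled
for 1,200 frames at dt = 0.72 s:

```python
import numpy as np
from cyclicity import (CoomSpec, FourierSeed, coom_series, normalize,
                       lead_matrix, leading_constellation, fit_ellipse,
                       elliptic_rank, phase_order, dominance_ratio,
                       eigendecompose)

spec = CoomSpec(n=5, amplitudes=[1.0, 0.8, 1.2, 0.9, 1.1],
                offsets=[0.0, 0.4, 0.9, 1.5, 2.2],
                seed_function=FourierSeed([0.5]),      # phi = cos
                omega=2*np.pi/50, duration=864.0, dt=0.72,
                noise_sd=0.25, seed=7)
rec = coom_series(spec)
A = lead_matrix(normalize(rec))
print("a_12 =", round(A.entry("ch01", "ch02"), 4))
dec = eigendecompose(A)
print("dominance |l1|/|l3| =", round(dominance_ratio(dec), 2))
con = leading_constellation(A)
q = fit_ellipse(con.points)
print("phase order:", " -> ".join(phase_order(con).channels))
```

prints

```
a_12 = 0.1312
dominance |l1|/|l3| = 31.71
phase order: ch01 -> ch02 -> ch03 -> ch04 -> ch05
```

`a_12 > 0` says channel 1 leads channel 2 (it has the smaller offset); the
eigenvalue ratio ≫ 1 says one ripple dominates the dynamics (the lead
matrix is nearly rank 2); and the phase ordering recovers the planted
excitation order exactly despite the noise.

The same pipeline is available from the shell:

```sh
cyclicity simulate --preset social-hcp --seed 1 --out rec.csv
cyclicity lead --in rec.csv --dt 0.72 --out lead.csv
cyclicity reversals --in rec.csv --p 5 --out events.csv
cyclicity burstiness --in rec.csv --out burst.csv
cyclicity run --preset rest --seed 1 --out results/
```

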