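# halfcenter

A reduced model of the bilateral spinal locomotor central pattern
generator (CPG), with the analysis tooling needed to map its coordination
regimes. The package is for computational neuroscientists studying
interlimb coordination — in particular how a pair of flexor–extensor
rhythm generators (RGs), coupled by inhibitory commissural pathways,
reproduces the phase-duration structure of tied-belt (symmetric) and
split-belt (asymmetric) locomotion in cats.

## The model

Each of the four units (left/right flexor and extensor half-centers) is an
activity-based population model whose membrane potential $V_i$ obeys

$$C\,\dot V_i = -I_L - I_{NaP} - I_{syn,i},$$

with leak current $I_L = g_L (V - E_L)$ and a slowly inactivating
persistent sodium current

$$I_{NaP} = g_{NaP}\, m_\infty(V)\, h\, (V - E_{Na}),$$

whose inactivation gate $h$ relaxes toward a falling sigmoid
$h_\infty(V)$ with a sech-shaped voltage-dependent time constant
($\tau_{max} = 1500$ ms). This current makes each half-center a
*conditional burster*: quiescent at low excitatory drive, intrinsically
rhythmic in an intermediate window, tonically active above it. Synaptic
input is conductance-based,

$$I_{syn,i} = d_i (V_i - E_{ex}) + \sum_j b_{ji}\, f(V_j)\,(V_i - E_{inh}),$$

where $f(V)$ is a piecewise-linear normalized firing rate and $d_i$ the
excitatory drive conductance. Within each RG the flexor and extensor
inhibit each other; between RGs there is mutual flexor–flexor (F–F)
inhibition and crossed extensor–flexor (E–F) inhibition.

The model's distinctive ingredient is **drive coupling**: the drive that
excites a flexor half-center simultaneously withdraws excitation from the
ipsilateral extensor, $d_E = D_{E0} - d_F$. As the drive (a proxy for
locomotor speed) grows, the rhythmogenic mechanism shifts from
*flexor-driven* bursting (short flexion, long extension) toward the
*classical half-center* regime (quasi-balanced phases) — which is what
lets the model reproduce speed-dependent phase-duration changes and
split-belt coordination patterns (1:1 locking, and 1:2 … 1:4 "extreme"
regimes when the slow side is driven weakly).

## Worked example

```python
from halfcenter import (DriveConfig, NetworkConfig,
                        integrate, detect_bursts, cycle_metrics)

net = NetworkConfig.single_rg()          # one RG in isolation
drv = DriveConfig.symmetric(0.4)         # flexor drive 0.4 -> extensor 1.0
trace = integrate(net, drv).after(10_000)    # 40 s run, drop 10 s transient
cm = cycle_metrics(detect_bursts(trace, unit=0))
print(f"{cm.frequency:.2f} Hz, flexion {cm.flexion_duration:.0f} ms, "
      f"extension {cm.extension_duration:.0f} ms")
```

prints

```
1.10 Hz, flexion 325 ms, extension 580 ms
```

— a flexor-driven rhythm: at this moderate drive the extension phase
(580 ms) is still much longer than the near-constant flexion phase
(325 ms); raising the drive shortens extension while flexion barely
moves, so the oscillation accelerates. The bilateral experiments are one
call each, e.g.

```python
from halfcenter import split_belt_sweep
sw = split_belt_sweep(slow_drive=0.5)     # fast drive 0.5 -> 0.8
print(sw.data[["fast_drive", "ratio", "fast_flexion_ms", "slow_period_ms"]])
```

which shows 1:1 coordination at every point with fast-side flexion
growing from ~344 ms to ~508 ms while the cycle period stays near 850 ms.

A CLI mirrors the main experiments
(`halfcenter simulate | sweep-single | freq-map | regime-map | ratio-map |
split-belt-sweep`, each with `--config`, `--out`, `--coarse`).

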