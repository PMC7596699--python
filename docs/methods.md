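# Methods

## Model

The network has four activity-based units — left/right flexor and
extensor half-centers — each representing a neuronal population by its
average membrane potential `V` (mV) and a normalized firing rate
`f(V)`, piecewise-linear between threshold `Vmin = -50 mV` and
saturation `Vmax = 0 mV`. The current balance per unit is

    C dV/dt = -I_L - I_NaP - I_syn

with `C = 20 pF`, leak `I_L = gL (V - EL)` (`gL = 2.8 nS`,
`EL = -65 mV`), and a persistent sodium current
`I_NaP = gNaP m_inf(V) h (V - ENa)` (`gNaP = 5 nS`, `ENa = 50 mV`).
Activation `m_inf` is instantaneous (half-voltage −40 mV, slope −6 mV);
inactivation `h` relaxes toward `h_inf` (half-voltage −50 mV, slope
10 mV) with time constant `tau(V) = tau_max / cosh((V + 100)/40)`.
`tau_max` is 1500 ms; a negative relaxation time would make the gate
equation divergent (cosh > 0, and `h` must relax *toward* `h_inf`), so
the config loader takes the magnitude, with a warning, if handed a
negative value.

Synaptic input is conductance-based:

    I_syn_i = d_i (V_i - Eex) + sum_j b_ji f(V_j) (V_i - Einh)

with `Eex = -10 mV`, `Einh = -90 mV`. All connections are inhibitory.
Within each RG the extensor inhibits its flexor with weight 0.5 and the
flexor its extensor with weight 1. Between RGs: flexor–flexor (F–F)
inhibition `b12 = b21` and crossed extensor–flexor (E–F) inhibition
`b41 = b32`, both varied in the experiments; flexor→contralateral
extensor and extensor→extensor connections are structurally absent.

**Drive coupling.** Flexor drives `d_F` are control parameters (the
locomotor speed command). The net extensor drive is `d_E = DE0 - d_F`,
clamped at zero with a warning: the same command that excites a flexor
withdraws excitation from its extensor. The gross constant `DE0` is not
independently constrained; the default `DE0 = 1.4` is chosen so that
flexor and net extensor drives are equal at `d_F = 0.7`, the drive
around which the flexor–extensor duration reversal is expected. A
decoupled mode (`coupled=False`) fixes `d_E` explicitly (default 0.7)
and serves as the control experiment.

Units are mV, ms, nS, pF, pA throughout, so the current balance is
dimensionally consistent without hidden scale factors.

## Numerics

The production integrator is fixed-step classical RK4 at `dt = 0.05 ms`
(numba-compiled; the fastest membrane time scale `C/g ≈ 5 ms` is
resolved by two orders of magnitude). Traces are stored on a 1 ms grid
regardless of solver internals. An adaptive LSODA path exists purely as
an independent cross-check; the suite verifies RK4-vs-LSODA and
step-halving agreement on period and flexion duration to <0.5%.

Default runs simulate 40 s and discard the first 10 s as transient
(≥ 12 cycles at the slowest rhythm of interest, ≈ 0.4 Hz). Burst-ratio
experiments use a 60 s horizon so that ≥ 10 slow cycles survive
transient removal. These horizons are the package's accuracy/cost
choice; halving or doubling them does not change any reported label.

Initial conditions are deterministic seeds: *anti-phase* (left flexor at
−30 mV, everything else at −65 mV) and *in-phase* (both flexors
depolarized, the right one at −32 mV rather than −30 mV). The 2 mV
asymmetry in the in-phase seed is deliberate: the exactly left–right
symmetric subspace is invariant under the flow, so a perfectly symmetric
seed would track the synchronous solution even where it is unstable and
every point of the plane would misclassify as bistable. Gates start at
`h_inf(V)`.

## Measurement conventions

Bursts are detected on the normalized rate `f` with hysteresis: onset at
an upward crossing of 0.10, offset at a downward crossing of 0.05
(dimensionless because `f` is normalized; the hysteresis avoids chatter
near threshold). Partial bursts at trace edges are discarded. The
thresholds are a declared convention of this package. Measured
durations shift by a few
percent as the thresholds move, which is well below the regime-level
distinctions the maps report, but matters when comparing exact duration
values.

Cycle metrics: period = mean onset-to-onset interval of the flexor;
flexion = mean burst duration; extension = period − flexion;
regularity = coefficient of variation of the period, with CV < 2% as
the steady-rhythm criterion. The left–right phase difference is the
fractional position of the nearest following right-flexor onset inside
each left-flexor cycle, summarized circularly. Classification bins:
in-phase if the lag is < 0.05 (either side of zero), anti-phase if
|φ − 0.5| < 0.05, small-phase-lag if the lag is in [0.05, 0.2),
asymmetric alternation otherwise; irregular or unsettled runs are
intermittent. A point is *bistable* when the two seeds settle into
distinct classes. Burst-count ratios over ≥ 10 slow cycles must agree on
the same integer n in ≥ 90% of cycles to be labeled 1:n, else
intermittent.

An isolated unit's activity mode (quiescent / bursting / tonic /
indeterminate) is classified from a 40 s single-unit run by the same
thresholds. With default parameters the unit bursts for drives ≈ 0.1–0.5,
is quiescent below and tonic above — the conditional-burster window that
underlies the flexor-driven → half-center transition.

## Experiments and their settings

* **Single-RG drive sweep** — commissural weights zero, coupled drives,
  drive 0.2→0.8, step 0.01 (0.05 in coarse/test mode). The
  flexion–extension crossover is located by linear interpolation of the
  sign change of (flexion − extension). Boundary-type quantities are
  stated to two decimals, hence the default step.
* **Two-parameter frequency map** — independent flexor / net extensor
  drives (coupling off), frequency per cell, plus the flexor's intrinsic
  rhythmicity window along the drive axis.
* **Symmetric regime map** — equal drives; F–F × E–F inhibition plane
  probed from both seeds. Default grid step 0.02, coarse 0.05.
* **Asymmetric ratio map / ladders** — reference commissural point
  F–F = 0.4, E–F = 0.2, chosen because the asymmetric experiments
  require a point lying in the monostable anti-phase region at all
  drives, which `validate_reference_point()` checks (swapping the two
  values fails it).
  Fast-drive sweeps run until the fast flexor saturates (tonic) or the
  drive reaches 1.3.
* **Split-belt sweeps** — slow drive fixed (default 0.5), fast drive
  0.5→0.8, with drive coupling on, or off (extensor drives pinned at
  0.7) as the control.

## What the model produces, and known departures

With the reference parameter set the model produces: the
conditional-burster window; the flexor-driven regime (short flexion,
long extension) at low drive and its progressive balancing; single-RG
frequencies ≈ 0.47 Hz at drive 0.2 and ≈ 1.45 Hz at 0.8; the structure
of the symmetric coordination plane (anti-phase at high F–F, in-phase at
low F–F / high E–F, an asymmetric-alternation region only at low drive
and low E–F, a bistable band between in-phase and anti-phase that
shrinks as drive grows, and growth of the in-phase region with drive);
the full asymmetric-drive phenomenology (1:1 with growing fast-side
flexion and near-constant period on the split-belt sweep; 1:2 maximum at
slow drive 0.4; the 1:1→1:2→1:3→1:4 ladder at slow drive 0.25;
multi-step regimes only below slow drive ≈ 0.45; intermittent bands
between locked regions; loss of these features in the drive-decoupled
control).

Known quantitative departures from the idealized expectation that phase
durations equalize exactly where the two drives equalize, all traceable
to one property of the reference parameter set: the intra-RG inhibition
is asymmetric (0.5 extensor→flexor vs 1 flexor→extensor), so the
flexor and extensor half-centers are not interchangeable even at equal
drives. Consequently the flexion–extension crossover falls at drive
≈ 0.57 rather than at the drive-equality point 0.7, the single-RG
frequency peaks near drive 0.67 instead of rising monotonically to 0.8,
and the bistable→anti-phase boundary of the symmetric plane drifts
upward with drive rather than staying fixed. Solver refinement,
threshold conventions, and alternative readings of the ambiguous
constants were tested systematically and do not remove these
departures; equalizing the intra-RG weights would, but that is a
different model, so the reference weights are kept.

## Limitations

Population-rate units with a single inactivation gate: no spiking, no
noise, no heterogeneity, no sensory feedback or supraspinal control.
The synthetic-trace generator used by the test suite plants rectangular
rate bursts with optional Gaussian noise; it validates the measurement
layer, not the dynamics. Regime maps are brute-force grids — boundaries
are resolved only to the grid step, and no continuation of unstable
branches is attempted. Bistability detection uses exactly two seeds;
attractors reachable from neither seed would be missed.
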