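# Methods

## The model

The package simulates pyramidal-interneuron network gamma (PING): networks
of excitatory cells (E) and inhibitory cells (I) coupled by AMPA-like and
GABA_A-like synapses, in which tonically driven E-cells fire, their volleys
recruit the I-cells, and the returning inhibition gates and synchronizes
the E-cells at gamma frequency (25–100 Hz). The scientific focus is the
*breakdown* of this rhythm: as E→I synapses weaken, as I→E synapses weaken
in the presence of heterogeneity, as the tonically driven ensemble shrinks,
or as connectivity becomes too spatially local.

### Cells

* E-cells are reduced Traub-Miles pyramidal neurons: single-compartment
  Hodgkin-Huxley dynamics with C = 1 µF/cm², ḡ_Na = 100, ḡ_K = 80,
  ḡ_L = 0.1 mS/cm², E_Na = 50, E_K = −100, E_L = −67 mV, and the sodium
  activation m slaved to m∞(v). Rheobase is near 0.1 µA/cm²; at drive
  1.4–1.8 µA/cm² the intrinsic rate is ≈54–64 Hz, which is what places the
  locked network rhythms in the gamma band.
* I-cells are Wang-Buzsáki fast-spiking interneurons (ḡ_Na = 35, ḡ_K = 9,
  ḡ_L = 0.1 mS/cm², E_Na = 55, E_K = −90, E_L = −65 mV, temperature factor
  φ = 5 on h and n; m instantaneous). Rheobase ≈ 0.16 µA/cm²; all analyses
  drive I-cells at or below threshold so that they fire only when recruited
  by excitation.

### Synapses

Each cell owns one output gating variable obeying
ds/dt = ρ(v)(1−s)/τ_r − s/τ_d with ρ(v) = (1 + tanh(v/10))/2, so s jumps
toward 1 during the presynaptic action potential and decays exponentially
afterwards. Kinetics: τ_r = 0.1 ms, τ_d = 3 ms, E_rev = 0 mV for excitation;
τ_r = 0.3 ms, τ_d = 9 ms, E_rev = −75 mV for inhibition (GABA_A decay of
roughly 9–10 ms, the hyperpolarizing regime). Conductance notation follows
the field's convention: g for a single synapse's maximal conductance
density, G for its sum over presynaptic cells (per target), Ḡ for the mean
of G over targets. E→E synapses are omitted throughout.

### Drives and the synthetic-data layer

All inputs are generated internally by `network_builder`:

* "h % heterogeneity" in tonic drives: values evenly spaced on
  [Ī(1−h/100), Ī(1+h/100)], randomly assigned to cells. The sample mean is
  exactly Ī and the spread is 2·(h/100)·Ī.
* Sparse random connectivity with compensation: each potential synapse is
  kept independently with probability p and survivors are scaled by 1/p, so
  Ḡ is preserved in expectation (at 50 % connectivity the survivors are
  doubled in strength). Self-connections are excluded.
* Poisson background (the kainate-bath analogue): independent event trains
  per E-cell; each event adds a fixed conductance to an input gate decaying
  with τ = 3 ms.
* Spatial networks: cells placed uniformly at random in the unit disk;
  each directed connection drawn with probability exp(−d/ℓ); synaptic
  *strengths* uniform, so locality acts through connectivity only.

## Numerical integration

Classical RK4 with fixed step dt = 0.02 ms (network) / 0.01 ms
(single-cell analyses). Synaptic coupling is a matrix-vector product per
stage; Poisson events are applied between steps. A spike is an upward
crossing of −20 mV, timed by linear interpolation, with a 1 ms refractory
guard. Intrinsic and synaptic gating variables are clipped to [0, 1] after
each step (the clip engages only at the 1e-16 level). The hot loops are
numba-compiled with a pure-Python fallback of identical semantics.
Halving dt moves strong-PING spike times by < 0.1 ms over hundreds of
milliseconds, provided the trajectory does not pass a grazing event (an
I-cell double spike appearing or disappearing); near such structural
boundaries individual spike times are genuinely dt-sensitive.

Asynchronous initialization pre-integrates every cell in isolation under
its tonic drive and starts it at a uniformly random phase of its limit
cycle; subthreshold cells start at their settled (resting) state.

## Rhythmicity, volleys, synchrony

* γ (gamma rhythmicity) is the fraction of the spectral energy of the
  population-mean E-output gating trace s̄(t) that lies in the gamma band
  (default 25–100 Hz; 25–50 Hz for the kainate-background analyses),
  computed from a Hann-window periodogram after discarding a 100 ms
  transient. The denominator is the total signal energy *including* the
  mean (DC) component. This makes γ amplitude-sensitive in the right way:
  an asynchronous population, whose s̄ is a near-constant with small
  finite-size fluctuations concentrated near the single-cell rate, scores
  γ ≈ 0, while a strongly modulated rhythm scores high. A DC-excluded
  ratio would be invariant under amplitude and score asynchronous states
  as "rhythmic"; the breakdown curves (γ → 0 as synapses weaken) require
  the DC-included convention. γ is invariant under amplitude scaling but
  not under adding a constant, which is intended.
* Volleys: contiguous above-threshold regions of the 1 ms-binned,
  Gaussian-smoothed (σ = 1 ms, zero-padded) population spike histogram;
  threshold 3× the mean rate, a level a rate-matched Poisson surrogate
  essentially never reaches. The narrow smoothing kernel matters: σ = 2 ms
  pushes a 20-cell synchronous volley peak below 3× mean and merges near
  doublets.
* Entrainment ratio: each E-volley is attributed to the first I-volley at
  or after it; the ratio is the modal E-count per I-volley. 1:1 is intact
  PING; 2:1 means two excitatory volleys are needed to recruit the
  I-cells.
* Synchrony σ: mean resultant length of spike phases, with the population
  cycle defined by detected volley times. 1 for perfect synchrony, ≈ 0
  (within 1/√N) for uniform phases.
* Cycles-to-synchrony (homogeneous networks): the number of I-volley
  cycles before the within-cycle standard deviation of E-spike times stays
  ≤ 2 ms. "Rapid" locking is ≤ 5 cycles.

## Single-cell analyses

* I-cell delay δ: the Wang-Buzsáki cell rests at its (subthreshold) drive;
  an instantaneous-rise, exponentially decaying excitatory conductance
  pulse (τ = 3 ms) arrives at t = 0; δ is the delay to the spike. From
  rest at drive 0 the response threshold is g* ≈ 0.043 mS/cm² — between
  the 0.04 and 0.08 mS/cm² volley strengths at which the network switches
  entrainment. The sensitivity of δ to a 30 % pulse reduction falls from
  ~7 ms near threshold to < 0.5 ms at strong pulses: heterogeneity in
  inputs to I-cells only matters for marginal E→I coupling.
* E-cell inhibition response t_E(s): the cell sits on its limit cycle with
  a spike at 0; an inhibitory pulse (τ = 9 ms) arrives at s ∈ (0, T); t_E
  is the time from pulse to next spike. Strong inhibition makes t_E nearly
  flat (phase history erased — the synchronizing mechanism), except for a
  sharp drop near s ≈ T, where an imminent spike cannot be delayed. Zero
  inhibition gives t_E = T − s exactly (a closed-form check on the whole
  pipeline). The s-grid has 200 points by default.
* Integrate-and-fire oracle: τ_m·dv/dt = −v + τ_m(I + A·𝟙_{t≥0}) from the
  subthreshold equilibrium, giving the elementary delay
  δ = τ_m ln((v∞ − v₀)/(v∞ − v_th)). The pulse is a step (the slow-decay
  limit) precisely so the delay has a closed form with the right
  qualitative structure: δ → ∞ at the reach-threshold boundary and
  |dδ/dA| strictly decreasing above it — the same sensitivity collapse as
  the conductance-based I-cell.

## Locking theory for the reduced 20E + 1I network

Drives increase linearly with index (1.4 → 1.8 µA/cm²); coupling is
all-to-all; the single I-cell carries the whole inhibitory population. A
once-per-cycle phase-locked rhythm with period P must satisfy
s_i + t_E(s_i, I_i) = P for every cell, where s_i is the delay from E-cell
i's spike to the I-spike. The solver builds the twenty curves
f_i(s) = s + t_E(s, I_i) (one vectorized batch), intersects them with a
horizontal line at P, and takes the *smaller* root of each curve (the
inhibitory volley follows the excitatory one closely). Existence fails
exactly when the lowest curve's maximum drops below the line — inhibition
too weak for its ascending branch to reach P.

P is closed self-consistently: given a trial solution, the E-spikes fall
at −s_i relative to the putative I-spike; integrating the I-cell against
that staggered volley yields its actual firing time, a new delay for the
least-driven (last-firing) cell, and a new P = f_least(s); iteration stops
when P changes < 0.01 ms. This closure reproduces simulated per-cell
delays to ~1 ms and the period to ~2 ms in the locked regime; the residual
bias comes from idealizing the within-network inhibitory conductance as a
clean exponential pulse launched at the I-spike's threshold crossing.

Two modeling choices differ deliberately from the full networks:

* The I-cell is hyperpolarized (drive −1.5 µA/cm²) so it acts as a
  coincidence detector. With 20 E-cells each contributing 1/20 of
  Ḡ_EI = 0.25, an asynchronous population delivers a sustained conductance
  dribble around the single-pulse threshold; an undriven I-cell then fires
  tonically and no once-per-cycle rhythm can be probed at all.
* Reduced-network simulations start from rest (a near-coherent first
  volley) rather than asynchronously: the locked state coexists with
  multi-cluster attractors in which the I-cell answers each sub-volley
  separately, and a fully asynchronous start is often captured by those.

The theory-vs-simulation sweep declares the simulation "locked" when ≥ 90 %
of cycles have every E-cell firing exactly once; across the inhibition
sweep 0.3 → 0.05 mS/cm² the solver's existence flag and the simulated
locking flip within one sweep step of each other.

## Reference conditions per study family

Text values are population means Ḡ in mS/cm², drives in µA/cm².

| family | N_E/N_I | Ḡ_EI | Ḡ_IE | Ḡ_II | drive_E | notes |
|---|---|---|---|---|---|---|
| E→I weakening | 80/20 | 0.25 / 0.08 / 0.04 | 0.2 | 0.05 | 1.6 | rows: homogeneous; sparse E→I (p = 0.5); + 15 % drive heterogeneity |
| I→E weakening | 80/20 | 0.25 | 0.2 / 0.05 / 0.02 | 0.2 | 1.6 | heterogeneous variant: 10 % drives, sparse E→I |
| assembly size | 320/80 | 0.4 (×3 in the rescue panel) | 0.3 | 0.15 | 1.5 (driven subset) | Poisson background 20 Hz, 0.05 mS/cm² to all E |
| spatial | 320/80 (×2 in the doubled variant) | 0.4 | 0.3 | 0.15 | 1.5 (patch) | per-synapse strengths from Ḡ at ℓ = 0.25 via mean connection probability 0.085 |
| reduced | 20/1 | 0.25 total | sweep | — | 1.4–1.8 | I-cell drive −1.5 |

Within one family a single parameter is varied and everything else held
fixed; Ḡ_II differs across families because the strong-excitation panels
need enough I-to-I inhibition to prevent interneuron double-firing, while
the entrainment-bifurcation panels need the I-cells to recover within two
excitatory cycles. The Poisson background (rate 20 Hz, 0.05 mS/cm² per
event ≈ 2× the E-cell's single-EPSP threshold) is calibrated so that the
undriven 320E/80I network produces a weak-PING rhythm in the 25–50 Hz
band: events are individually suprathreshold from rest but vetoable by
inhibition, which is the weak-PING participation mechanism.

Under these conditions the assembly-size study yields I-population rates
of ≈58, ≈46 and ≈27 Hz for 200, 100 and 50 driven E-cells (5-seed means),
with the rhythm intact at 200 and 100, largely abolished at 50, restored
at 50 when E→I strengths are tripled, and background weak PING at 0.

## What the generators do and do not emulate

The synthetic networks reproduce the statistical structure the breakdown
mechanisms rely on: binomial in-degree fluctuations (Law-of-Large-Numbers
scaling CV ∝ 1/√n of excitatory input per I-cell), exact mean-preserving
compensation, drive heterogeneity with controlled spread, independent
Poisson streams, and the geometric edge effect of driven patches (cells
near the patch edge receive less input from the driven population). They
do not emulate conduction delays, synaptic depression or facilitation,
NMDA-mediated recurrent excitation, cell-intrinsic parameter variability,
or non-uniform spatial densities — so passing tests show that the
breakdown mechanisms operate as described in this idealized setting, not
that their quantitative thresholds transfer to any particular tissue.

## Numerical/edge-case conventions

* γ of an all-constant (or shorter-than-8-sample) trace is 0.
* Entrainment requires ≥ 3 I-volleys; fewer raises an error so "no
  I-rhythm" is never read as 1:1.
* Synchrony requires ≥ 2 detected cycles; degenerate single-volley input
  raises.
* Locking roots are bracketed on the 200-point grid and refined by linear
  interpolation; a NaN root certifies non-existence for that cell.
* Simulation blow-up (non-finite state) raises immediately, naming the
  first offending cell and time.
* All randomness flows from user-passed integer seeds through
  `numpy.random.default_rng`; replay of any run is bit-identical.

## Problem sizes

Default study sizes are the reference conditions above (networks up to 640
cells, 400–600 ms). The test suite runs the same studies at these sizes
with a handful of seeds (2–5 per stochastic claim); seed-averaged
quantities in the assembly-size family have a between-seed standard
deviation of ≈1 Hz, so 5 seeds pin the means to well under the comparison
tolerances.
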