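# ping-assembly

Simulation and analysis of **PING gamma rhythms** — and of how they break
down — in conductance-based networks of excitatory pyramidal cells and
fast-spiking interneurons.

In a PING (pyramidal-interneuron network gamma) rhythm, tonically driven
E-cells fire a volley, the volley recruits the I-cells, and the returning
inhibition gates and synchronizes the E-cells, producing a 25–100 Hz
population oscillation. This package is built for the questions on the
other side of that mechanism: *when does the rhythm fail?* It provides

* reduced Traub-Miles E-cells and Wang-Buzsáki I-cells with first-order
  synaptic gating, integrated with fixed-step RK4 (numba-accelerated);
* a synthetic-network layer: homogeneous all-to-all, sparse random with
  1/p strength compensation, heterogeneous tonic drives ("h %
  heterogeneity"), Poisson background input (kainate-bath analogue), and
  spatial networks on the unit disk with connection probability
  exp(−d/ℓ);
* rhythmicity and synchrony measures: the gamma-band energy fraction γ of
  the population-mean E-gating trace s̄(t), spike-volley detection, E:I
  entrainment ratios, and a circular-statistics synchrony index σ;
* single-cell response analyses: the I-cell's spike delay δ to excitatory
  pulses and its sensitivity collapse above threshold, and the E-cell's
  inhibition-response map t_E(s);
* the phase-locking fixed-point theory of a reduced 20E+1I network: a
  locked rhythm with period P must satisfy s_i + t_E(s_i, I_i) = P for
  every cell, and the solver certifies when no such solution exists;
* a config-driven experiments layer (with the `ping-assembly` CLI) that
  reproduces each figure-level study: entrainment bifurcation, the
  rapid-or-never synchronization law, assembly-size breakdown, and
  spatial-patch/locality breakdown.

The headline findings the package reproduces: weakening E→I synapses
switches 1:1 entrainment to 2:1 at the strength where one excitatory
volley stops recruiting the I-cells; in a realistically heterogeneous
network a PING rhythm forms within a few cycles or not at all; and for
given synaptic strengths there is a soft lower bound on the number of
driven cells that can sustain a gamma-coordinated assembly.

## Worked example

Breakdown of the assembly as the tonically driven ensemble shrinks
(`examples/assembly_size.py`): all 320 E-cells of an 80 I / 320 E sparse
network receive stochastic background input, and a subset receives strong
tonic drive.

```
$ python examples/assembly_size.py
panel driven  I-rate (Hz)   gamma
    A    200         58.7    0.26
    B    100         46.0    0.40
    C     50         27.5    0.02
    D      0         20.4    0.29
    E     50         56.1    0.25 (tripled E→I)
```

With 200 or 100 driven cells the I-population fires at gamma rates
(≈54–58 and ≈46 Hz) and the rhythmicity γ of s̄ is high; with 50 driven
cells the excitatory input per I-cell is too weak and too heterogeneous —
the I-rate drops to ≈27 Hz and γ collapses to 0.02 even though the cells
keep spiking. With no driven cells the slower background weak-PING rhythm
reappears (γ = 0.29), and tripling the E→I synapses at 50 driven cells
restores the rhythm (γ = 0.25): the bound is synaptic, not a head count.

Other short examples in `examples/`: `entrainment_breakdown.py` (1:1 → 2:1
switch), `single_cell_responses.py` (δ and t_E(s) maps),
`locking_analysis.py` (fixed-point existence vs simulation),
`spatial_patch.py` (patch-radius and locality breakdown).

The same studies run from the shell:

```bash
ping-assembly run --experiment fig13 --seed 7 --out out/
ping-assembly sweep --experiment fig10 --parameter gie_panels/A \
    --values 0.3,0.15,0.05 --out sweep.csv
```

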