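"""Breakdown of strong PING as E-to-I synapses weaken.

Simulates the homogeneous all-to-all network (80 E-cells, 20 I-cells) at
three mean excitatory conductance densities per I-cell and reports the
E:I volley entrainment ratio, population rates, and the gamma rhythmicity
of the mean E-synaptic gating trace. At 0.08 mS/cm² each excitatory volley
still triggers an inhibitory volley (1:1); at 0.04 a single volley is no
longer enough and 2:1 entrainment appears, with a sharp drop in the
inhibitory population frequency.
"""

import numpy as np

from ping_assembly import metrics as met
from ping_assembly import network_builder as nb
from ping_assembly.simulator import run_simulation

for gbar_ei in (0.25, 0.08, 0.04):
    net = nb.build_all_to_all(80, 20, gbar_ei, gbar_ie=0.2, gbar_ii=0.05)
    drives = nb.DriveSpec(drive_e=np.full(80, 1.6), drive_i=np.zeros(20))
    res = run_simulation(net, drives, duration=400.0, seed=3)

    post = lambda s: s[s[:, 1] >= 100.0]
    ev = met.detect_volleys(post(res.population_spikes("E")), res.duration)
    iv = met.detect_volleys(post(res.population_spikes("I")), res.duration)
    ratio = met.entrainment_ratio(ev, iv)
    f_i = met.mean_population_frequency(post(res.population_spikes("I")), 20, (100, 400))
    gamma = met.rhythmicity_gamma(res.s_bar, res.dt).gamma
    print(f"Ḡ_EI = {gbar_ei:5.2f} mS/cm²:  E:I entrainment {ratio}:1, "
          f"I-rate {f_i:5.1f} Hz, γ = {gamma:.2f}")

print("\nThe 1:1 → 2:1 switch between 0.08 and 0.04 marks the E-to-I strength"
      "\nbelow which one excitatory volley can no longer recruit the I-cells.")
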