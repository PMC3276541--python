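"""Single-cell pulse responses that underlie PING synchronization.

Part 1 — I-cell delay δ: a subthreshold Wang-Buzsáki interneuron receives
an excitatory conductance pulse; the spike delay δ and its sensitivity to a
30 % pulse reduction are printed across pulse strengths. Sensitivity is
large only near the response threshold: heterogeneity in inputs to I-cells
matters only when E-to-I synapses are marginal.

Part 2 — E-cell inhibition response t_E(s): a tonically driven pyramidal
cell spikes at t = 0 and an inhibitory pulse arrives s ms later. For strong
inhibition t_E is nearly independent of s (one pulse erases phase history
and synchronizes a population); for zero inhibition t_E = T − s exactly.
"""

import numpy as np

from ping_assembly import single_cell as sc

print("I-cell: delay δ and Δδ from reducing the pulse by 30 %")
g = np.array([0.05, 0.07, 0.1, 0.15, 0.25, 0.4])
d_full = sc.icell_pulse_delay(g, drive=0.0)
d_red = sc.icell_pulse_delay(0.7 * g, drive=0.0)
for gi, df, dr in zip(g, d_full, d_red):
    dd = "reduced pulse fails" if np.isnan(dr) else f"Δδ = {dr - df:6.2f} ms"
    print(f"  g = {gi:4.2f} mS/cm²: δ = {df:6.2f} ms, {dd}")

print("\nE-cell: inhibition-response map t_E(s) at drive 1.6 µA/cm²")
for g_inh in (0.24, 0.06, 0.0):
    r = sc.ecell_inhibition_response(1.6, g_inh, n_s=40)
    body = r.t_e[(r.s > 0.1 * r.period) & (r.s < 0.8 * r.period)]
    print(f"  g_inh = {g_inh:4.2f}: T = {r.period:5.2f} ms, "
          f"t_E over mid-range = {body.mean():5.2f} ± {body.std():4.2f} ms")

print("\nΔδ collapses above threshold; t_E flattens as inhibition strengthens —"
      "\nboth effects set where heterogeneity can or cannot break the rhythm.")
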