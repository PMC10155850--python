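"""Select optimal laser doses under the 50 degC temperature threshold.

Sweeps the full factorial treatment grid (energy density x pulse width
x spot diameter, 27 candidates) on the scar preset, then picks the
candidate that maximizes the final scar damage among those whose peak
center temperature stays at or below 50 degC — the temperature at which
tissue protein denatures and coagulation necrosis begins.

A reduced grid resolution keeps this demo to roughly a minute; the
acceptance script runs the same study at the working resolution.
"""

from scartherm import GridSpec, SolverSpec, run_sweep, select_optimal, summarize

resolution = GridSpec(dr_mm=0.25, nz=60, dz0_mm=0.01)
solver = SolverSpec(pulse_steps=120)

results = run_sweep(("hps",), mode="factorial", resolution=resolution, spec=solver)
table = summarize(results)
print(table[["q", "tau_ms", "spot_mm", "peak_T_C", "final_damage_extent",
             "threshold_pass"]].to_string(index=False))

verdict = select_optimal(results, threshold_C=50.0)
q, tau, spot = verdict.chosen
print(f"\nselected dose: q = {q} (printed unit J/cm^3), tau = {tau} ms, "
      f"spot = {spot} mm")
print(f"objective ({verdict.objective}): {verdict.objective_value:.3e}")
print("Candidates above 50 degC are inadmissible however much damage they "
      "would cause; among the admissible ones the largest spot at the "
      "highest safe energy density treats the most scar volume.")
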