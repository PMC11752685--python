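"""QIVIVE reverse dosimetry: from an in vitro IC50 to an in vivo dose.

Converts a transporter inhibition IC50 (µM) to the oral dose (mg/kg/day)
whose steady-state plasma concentration equals it, then verifies the
extrapolation by simulating that dose and reading the plasma level back.
"""

from cholmech import decision, descriptors, pbtk

smiles = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"  # ibuprofen-like probe
mw = descriptors.molecular_weight(smiles)
params = pbtk.build_parameters(fub=0.05, clint=25.0)

ic50 = 8.0  # µM, hypothetical BSEP inhibition potency
dose = decision.qivive_dose(ic50, mw, params)
print(f"MW = {mw:.2f} g/mol, IC50 = {ic50} µM = {ic50 * mw / 1000:.4f} mg/L")
print(f"equivalent oral dose: {dose:.3f} mg/kg/day")

# close the loop: dosing at that rate reproduces the IC50 in plasma
days = pbtk.days_to_steady_state(params)
sim = pbtk.simulate_regimen(params, pbtk.DosingRegimen(dose, 1, days))
print(f"simulated Css at that dose: {sim.css:.4f} mg/L "
      f"(target {ic50 * mw / 1000:.4f} mg/L)")

# the decision rule compares this dose with the therapeutic dose T_D:
td = 400.0 / params.body_weight  # 400 mg/day for a 70 kg adult
verdict = decision.classify(td, {"BSEP": dose}, decision.RuleConfig(selected=("BSEP",)))
print(f"T_D = {td:.2f} mg/kg/day -> {'cholestatic' if verdict else 'non-cholestatic'}"
      " (flagged when T_D exceeds the extrapolated dose)")
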