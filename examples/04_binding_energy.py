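"""Binding free-energy bookkeeping and table auditing.

Combines published-style MM-PBSA component terms into gas-phase, solvation
and total binding energies, and audits a component table for internal
additivity — the kind of check that catches typesetting slips in published
energy tables.
"""

import prspath as pp

# peptide-inhibitor complex, energies in kJ/mol
components = pp.BindingEnergyComponents.from_solvation_total(
    e_ele=-198.46, e_vdw=-30.81, g_solv=215.38
)
out = pp.combine_components(components)
print(f"dG_gas   = {out.g_gas:8.2f} kJ/mol  (electrostatics + van der Waals)")
print(f"dG_solv  = {out.g_solv:8.2f} kJ/mol  (polar + nonpolar solvation)")
print(f"dG_total = {out.g_total:8.2f} kJ/mol  (negative = favorable binding)")

# audit a second column whose printed gas-phase sum does not match its addends
flags = pp.audit_consistency(
    {"e_vdw": -40.52, "e_ele": -302.56, "g_gas": -338.11,
     "g_solv": 302.56, "g_total": -35.54}
)
print("\naudit of the second table column:")
for f in flags:
    print(" *", f)

# nonpolar solvation from a buried-surface estimate
params = pp.NonpolarParams(gamma_surface=0.0227, beta_offset=3.85)
print(f"\nnonpolar term for dSASA = -100 A^2: {pp.nonpolar_term(-100.0, params):.2f} kJ/mol")
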