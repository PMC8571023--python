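"""Entropy-enthalpy compensation audit and hot-residue calls.

The MM-PBSA/GBSA summary obeys dG = dH - TdS per solvation model; a
synthetic per-residue decomposition shows the hot-spot call at the
-3.0 kcal/mol threshold.
"""

from scaffold_screen import (SimulationConfig, check_compensation, datasets,
                             hot_residues, simulate_decomposition)

print("compensation audit (dG = dH - TdS, tol 0.01 kcal/mol):")
for record in datasets.load_thermo_table():
    violations = check_compensation(record)
    print(f"  compound {record.compound_id}: "
          f"{'ok' if not violations else violations}")

sim = simulate_decomposition(SimulationConfig(seed=3, n_residues=42, n_hot=3))
hot = hot_residues(sim.entries)
print(f"\nplanted hot residues: {sorted(sim.hot_labels)}")
print(f"recovered at <= -3.0 kcal/mol: {sorted(e.label for e in hot)}")
# An empty violation list means the tabulated free energies, enthalpies and
# entropy are mutually consistent; the hot-residue call recovers exactly the
# residues planted below the threshold.
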