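"""Fingerprint similarity and hierarchical clustering of the hit set.

E-state atom-type fingerprints (79 features, binarized) are compared by
Tanimoto index; average-linkage clustering on 1 - T groups the compounds
into four structural families.
"""

from scaffold_screen import (MoleculeRecord, datasets, hierarchical_cluster,
                             similarity_matrix, similarity_to_reference)
from scaffold_screen.library_io import PROPANESULFONIC_ACID_SMILES

records = datasets.load_hit_structures().records
scaffold = MoleculeRecord.from_smiles(PROPANESULFONIC_ACID_SMILES, id="scaffold")

print("Tanimoto similarity to the bare propanesulfonic scaffold:")
for cid, t in similarity_to_reference(records, scaffold):
    print(f"  compound {cid:>2}: T = {t:.2f}")

matrix = similarity_matrix(records)
tree = hierarchical_cluster(matrix)
groups = tree.cut(4)
print("\ncluster membership at k = 4:")
for group in sorted(set(groups.values())):
    members = [cid for cid, g in groups.items() if g == group]
    print(f"  group {group}: compounds {', '.join(members)}")
# The two lead candidates (4: menadione bisulfite, 6: camphotamide) fall in
# the same structural family; a higher T marks a closer match to the
# scaffold that seeded the screen.
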