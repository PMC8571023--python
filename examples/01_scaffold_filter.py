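"""Filter a drug library for molecules containing the tramiprosate scaffold.

The query is the propane-1-sulfonic acid core (SMARTS
``CCCS(=O)(=O)[OX1,OX2]``), matched after salt stripping. The packaged
library holds curated structures of the screened compounds.
"""

from scaffold_screen import ScaffoldQuery, datasets, scaffold_filter

library = datasets.load_hit_structures()
query = ScaffoldQuery()
hits = scaffold_filter(library.records, query)

print(f"library: {len(library.records)} molecules (skipped {library.n_skipped})")
print(f"scaffold hits with pattern {query.pattern!r}:")
for hit in hits:
    print(f"  {hit.id:>2}  {hit.name}")
# Each listed molecule embeds the 3-carbon sulfonate chain at least once;
# entries with only adduct/ester sulfonates (looser 'scaffold-like' matches)
# are excluded by this strict pattern.
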