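# scaffold-screen

A toolkit for scaffold-based drug-repurposing screens, built around the
tramiprosate (3-aminopropanesulfonic acid) screen against amyloid-beta
aggregation. Starting from a library of approved drugs, the pipeline

1. **filters** the library for molecules containing a query scaffold
   (default: the propane-1-sulfonic acid core, SMARTS
   `CCCS(=O)(=O)[OX1,OX2]`, matched after salt stripping);
2. **profiles** the hits: 2D descriptors (MW, AlogP, HBA, HBD, PSA, QED),
   E-state fingerprint Tanimoto similarity, average-linkage hierarchical
   clustering on 1 − T;
3. **post-processes docking summaries** into inhibition constants and
   ligand efficiencies,

   K<sub>i</sub> = exp(ΔG<sub>bind</sub>/RT), R = 1.98×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K;  LE = ΔG<sub>bind</sub>/N<sub>atm</sub>

   and calls **leads**: compounds with ΔG<sub>bind</sub> strictly below the
   reference compound's;
4. **scores CNS access** with two published linear logBB models,

   logBB<sub>cl</sub> = 0.152·AlogP − 0.0148·PSA + 0.139  and  logBB<sub>ri</sub> = 0.155·AlogP − 0.01·PSA + 0.164,

   flagging logBB > 0 and PSA < 70 Å² as favourable;
5. **audits MM-PBSA/GBSA outputs**: the compensation identity
   ΔG = ΔH − TΔS, hot-residue calls from per-residue/pairwise energy
   decomposition (thresholds −3.0 / −6.0 kcal/mol), and buried surface
   area BSA = (ASA<sub>pep</sub> + ASA<sub>lig</sub> − ASA<sub>comp</sub>)/2;
6. reports Pearson/OLS **regressions** (with the t-test on r) for
   flexibility–conformational-spread and similarity–efficiency analyses.

It is aimed at computational chemists who have docking / end-state
free-energy summaries in hand and want the downstream screening analytics
reproducible and tested. Docking engines, MD and surface-area programs are
deliberately out of scope: their tabulated outputs are this package's
inputs. A synthetic-data module generates libraries, regression data and
energy decompositions with planted ground truth so every stage is testable
without external databases or engines.

## Worked example

```python
from scaffold_screen import datasets, run_screen

report = run_screen(datasets.load_hit_structures(),
                    datasets.load_docking_table(),
                    datasets.load_descriptor_frame())
print(report.table[["compound_id", "name", "dg_bind", "ki_value", "ki_unit",
                    "le", "status"]].head(5).to_string(index=False))
print("leads:", report.leads)
```

```
compound_id                name  dg_bind  ki_value ki_unit        le    status
          4 menadione bisulfite    -7.11      5.88      uM -0.395000      lead
          6        camphotamide    -6.82      9.61      uM -0.454667      lead
         14        tramiprosate    -6.19     27.94      uM -0.562727 reference
          8            ecamsule    -6.17     28.90      uM -0.154250       hit
         13   indocyanine green    -5.71     63.00      uM -0.103818       hit
leads: ['4', '6']
```

The table is ranked by ascending binding energy. Menadione bisulfite and
camphotamide out-bind the tramiprosate reference (−7.11 and −6.82 vs
−6.19 kcal/mol), putting their predicted inhibition constants in the
single-digit micromolar range, and are therefore called leads; the
remaining scaffold hits bind no better than the reference. The packaged
docking, descriptor and thermodynamic tables ship with the package
(`scaffold_screen.datasets`), as do curated structures of the screened
compounds.

The `examples/` directory contains one short script per capability
(filtering, similarity/clustering, docking metrics, logBB, thermodynamic
post-analysis, regressions, the full screen, and a synthetic benchmark).
A thin CLI mirrors the library: `scaffold-screen filter-scaffold|descriptors|
similarity|cluster|dock-metrics|bbb|thermo|regress|simulate|screen|
reproduce-tables`.

`reproduce_reference_tables()` (CLI: `reproduce-tables`) recomputes every
derived cell of the packaged tables — 14 K<sub>i</sub>, 14 LE, 8 logBB and
6 compensation values, the two regressions and the lead call — and reports
per-cell agreement at two levels: strict (the printed value is the
correctly rounded recomputation) and printed-precision (within one unit of
the last printed digit).

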