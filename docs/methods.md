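# Methods

## Scope and model of the screen

The package implements the analytics around a scaffold-based repurposing
screen: substructure filtering of a drug library, hit profiling, and
post-processing of externally produced docking and end-state free-energy
tables. It does not run docking, molecular dynamics, pocket detection or
surface-area programs; their summary tables are inputs. That boundary makes
every quantity in the package a deterministic, desk-scale function of
small tabular or structural inputs, which is what allows the whole screen
to be regression-tested.

## Scaffold filtering

The scaffold query is a SMARTS pattern; the default,
`CCCS(=O)(=O)[OX1,OX2]`, encodes the propane-1-sulfonic acid core of
tramiprosate: a three-carbon aliphatic chain bonded to a sulfonic
acid/sulfonate group, with the terminal-oxygen primitive accepting both
the protonated and the anionic form. Each library entry is salt-stripped
(largest covalently connected component; ties keep the first) before
matching, because approved drugs are frequently registered as sodium or
ammonium salts whose counter-components are irrelevant to the scaffold.
The filter preserves library order and never invents records, so its
output is a verifiable subset of its input. A `ScaffoldQuery` refuses to
construct unless the pattern compiles *and* matches its own reference
structure — a cheap guard against typo'd SMARTS.

The original screen's hit list was produced by a commercial
similarity-search tool whose matching semantics are not public; a few of
its hits carry only adduct or one-carbon sulfonates that a strict
substructure query rightly rejects. The hit *count* of such a screen is
therefore tool-dependent and is not asserted anywhere; the packaged
curated structures (two of which — sulfamazone and cefpimizole — are
approximations, and dermatan sulfate is represented by one disaccharide
repeat unit) exist to exercise the pipeline, not to re-litigate the
original hit list.

## Descriptors, fingerprints and clustering

Descriptors are the standard RDKit implementations: molecular weight with
implicit hydrogens, Crippen atom-contribution AlogP, Lipinski N/O
acceptor/donor counts, topological PSA, and QED with its published
desirability weights. Descriptor software lineages differ in atom typing,
so cross-toolkit agreement is approximate by nature; tests assert
invariants (non-negativity, atom-order invariance, QED ∈ [0,1]) and
generous windows, never third-party-exact values.

Similarity uses 79-feature E-state atom-type fingerprints binarized at
count > 0 (a path-based 2048-bit fingerprint is available as an option),
compared by Tanimoto index. Fingerprints are computed on the **full
registered substance, salt components included**: the counter-component of
a salt-form drug is part of the registered entity and contributes atom
types of its own, and for salt-form entries like camphotamide (an
N-methylnicotinamide camphorsulfonate) discarding the cation would
misrepresent the substance being clustered. Salt stripping is applied only
to substructure matching. Two all-zero fingerprints have undefined
overlap; their similarity is reported as 0 with a warning.

Clustering is agglomerative with average linkage on the distance 1 − T,
via SciPy; for a fixed input ordering the merge sequence is deterministic
(ties resolve to the lowest index pair). Average linkage is the common
default for chemical-similarity trees and is the package default; the cut
at k groups relabels clusters in order of first appearance so outputs are
stable across runs. Trees export to Newick.

## Docking post-processing

K<sub>i</sub> = exp(ΔG/RT) uses R = 1.98×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K. Display formatting auto-scales the unit (M ≥ 0.1 M,
mM ≥ 10⁻⁴ M, else µM) and rounds half-up to two decimals; all comparisons
and downstream computation use the unrounded molar value. LE = ΔG/N_atm
preserves sign. Lead selection is a strict inequality against the
reference compound's ΔG with no statistical test — the screen's inputs
carry no replicate information that would support one — and returns leads
sorted by ascending ΔG.

The packaged docking summary regenerates its printed K<sub>i</sub>/LE
columns from the printed two-decimal binding energies at one unit of the
last printed digit for every row, and at half a unit (i.e. exact rounded
agreement) for all but five cells (K<sub>i</sub> of compounds 2, 4, 13; LE
of compounds 3, 6). Those five are consistent with the original columns
having been derived from unrounded upstream energies: e.g. ΔG = −7.11
gives 5.88 µM while the table prints 5.87 µM, which corresponds to an
unrounded ΔG in [−7.1117, −7.110]. `reproduce_reference_tables()` reports
both agreement levels per cell rather than hiding the discrepancy.

## Blood–brain-barrier models

The two logBB estimators are fixed published linear models, implemented
exactly and never refitted:
logBB = 0.152·AlogP − 0.0148·PSA + 0.139 (Clark) and
logBB = 0.155·AlogP − 0.01·PSA + 0.164 (Rishton). A compound is flagged
`optimal` only when **both** models are strictly positive — the
literature criterion cites a single logBB > 0 rule without choosing a
model, and requiring both is the conservative reading. The CNS
surface-area window is quoted as 60–70 Å²; the package fixes the
permissive upper bound (PSA < 70 Å², configurable). Experimental logBB
values are carried as annotations only.

## Thermodynamic post-analysis

The compensation identity ΔG = ΔH − TΔS is applied per solvation model
(PB and GB) and audited with a default tolerance of 0.01 kcal/mol,
matching two-decimal reporting; records with missing components are
skipped rather than failed. Hot-residue calls use ≤ thresholds
(−3.0 kcal/mol per-residue, −6.0 pairwise) and "either model" semantics: a
residue qualifies when its PB **or** GB contribution reaches the
threshold. The decomposition plots this mirrors show both models per
residue without designating a primary one, so the inclusive reading is
used and is explicit in the API. BSA applies the half-interface
convention, dividing the whole ASA difference by two; a negative buried
area beyond round-off is rejected as an invalid ASA triple. Published BSA
values are not recomputed because their ASA inputs are not published;
BSA is validated on constructed triples and monotonicity properties.

## Regression

`pearson_regression` is ordinary least squares with Pearson r and the
classical two-tailed t-test on r (t = r·√((n−2)/(1−r²)), n−2 df), via
`scipy.stats.linregress`; a label-permutation test serves as an
independent oracle in the test suite. Missing values are dropped pairwise
(the docking summary has cluster-RMS values for only 6 of 14 rows), and
fewer than 3 complete pairs or zero variance in either variable is an
error, not a NaN. The similarity–efficiency regression includes the
reference compound (n = 14): its printed p = 0.008 reproduces only with
the reference included. The flexibility regression over the 6 complete
rows reproduces r² = 0.78, p = 0.02. The published r² = 0.63 for the
companion clRMSa statistic is *not* recoverable from the printed columns
(they give r² ≈ 0.95); that fit is computable but not asserted.

## Synthetic data

The generators emulate input structure, not physics. Defaults are the
study conditions of the screen this package reproduces: a 4,642-molecule
library with a scaffold fraction of 13/4642; a 6-point regression with
slope 0.106, intercept 0.095 and residual sd 0.35 (the scale of the
flexibility fit) over torsion counts 1–30; a 126-row decomposition (3
chains × the 42-residue amyloid peptide, residues named from its
sequence) with 2 hot residues planted 1.0 kcal/mol below the −3.0
threshold. Scaffold molecules are built by grafting the propanesulfonic
chain onto one of ~30 fixed small organic cores; decoys are bare or
one-carbon-sulfonate-decorated cores, and every molecule is re-verified
against the query at generation so planted truth is exact by
construction. Each generator draws from `numpy.random.default_rng` seeded
with `(seed, operation-offset)`, making outputs byte-identical for a fixed
config and independent across generators. What passing synthetic tests
shows is that the *machinery* (filtering, fitting, thresholding) is
correct under controlled conditions; it says nothing about docking
accuracy, force-field quality or the realism of any particular library.

## Problem sizes and determinism

All packaged-table computations are O(10¹)–O(10²) element operations and
run in milliseconds. Test simulations use 20–500-element problems (500
null regressions for the type-I-error calibration at α = 0.05, n = 200
each); these sizes give binomial/Monte-Carlo error bands comfortably
tighter than the asserted tolerances while keeping the suite fast.
Re-running the screen on identical inputs yields byte-identical reports;
run metadata records versions and parameters, never timestamps.

## Known limitations

- Substructure semantics of the original commercial screen are not
  reproducible; hit counts on real databases are therefore out of scope.
- Descriptor values are RDKit-lineage; cross-toolkit deltas of a few
  percent (and occasionally more for PSA on exotic functional groups) are
  expected.
- The E-state fingerprint is coarse (79 features); it is the screen's
  documented choice, not a recommendation for general-purpose similarity.
- Five of the 28 packaged K<sub>i</sub>/LE cells regenerate only to one
  unit in the last printed digit (see above); this is a property of the
  published table, not a tunable of the implementation.
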