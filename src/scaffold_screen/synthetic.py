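"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the *shape* of the real inputs — a drug library with
a known fraction of scaffold-bearing molecules, a linear x-y relationship
with Gaussian noise, a per-residue energy decomposition with a known hot
set — not docking physics or force-field energetics. Defaults mirror the
study conditions of the screen this package reproduces: a 4,642-compound
library with 13 scaffold hits, a 6-point torsion/RMS regression, and a
three-chain 42-residue amyloid receptor with a couple of sub-threshold
residues.

Every generator draws from ``numpy.random.default_rng`` seeded with
``(config.seed, operation_offset)``, so a fixed config reproduces its
outputs exactly while the generators stay independent of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .library_io import MoleculeRecord, ScaffoldQuery
from .thermo import PER_RESIDUE_THRESHOLD, ResidueEnergy

# Per-operation PRNG stream offsets.
_OFFSET_LIBRARY = 1
_OFFSET_REGRESSION = 2
_OFFSET_DECOMPOSITION = 3

#: Propane-1-sulfonic acid written head-first so that appending a core
#: SMILES bonds the chain's terminal carbon to the core's first atom.
_SCAFFOLD_PREFIX = "OS(=O)(=O)CCC"
#: One-carbon (methanesulfonic) decoration used for harder decoys.
_DECOY_PREFIX = "OS(=O)(=O)C"

#: Small valid organic cores; each parses standalone and when prefixed.
_CORES: tuple[str, ...] = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccc2ccccc2c1", "c1ccsc1",
    "c1cc[nH]c1", "c1ccoc1", "c1ccc(Cl)cc1", "c1ccc(F)cc1", "c1ccc(O)cc1",
    "c1ccc(N)cc1", "c1ccc(C#N)cc1", "C1CCCCC1", "C1CCNCC1", "C1CCOC1",
    "C1CCCC1", "N1CCOCC1", "N1CCNCC1", "N1CCCC1", "OCCO", "OCC(O)CO",
    "NC(=O)C1CC1", "CC(C)O", "CC(C)C", "CC(N)=O", "CC(=O)OC", "CCOCC",
    "CS(C)=O", "CS(C)(=O)=O", "CC(C)N",
)

#: Amyloid-beta 1-42 sequence, used to name simulated receptor residues.
_ABETA42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
_THREE_LETTER = {
    "A": "Ala", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly", "H": "His",
    "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn", "Q": "Gln",
    "R": "Arg", "S": "Ser", "V": "Val", "Y": "Tyr",
}
_CHAINS = ("A", "B", "C")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for all generators.

    seed           master seed; each generator derives its own stream
    n_molecules    library size (default: the 4,642-compound screen)
    frac_scaffold  fraction of scaffold-bearing molecules (13/4642)
    dg_range       binding-energy span, kcal/mol
    slope, intercept, noise_sd, n_points, x_range
                   linear-relationship generator (torsions vs cluster RMS)
    n_residues     decomposition rows (3 chains x 42 residues)
    n_hot          planted sub-threshold residues
    hot_effect     depth below the -3.0 kcal/mol threshold, kcal/mol
    """

    seed: int = 0
    n_molecules: int = 4642
    frac_scaffold: float = 13 / 4642
    dg_range: tuple[float, float] = (-7.11, 0.66)
    slope: float = 0.106
    intercept: float = 0.095
    noise_sd: float = 0.35
    n_points: int = 6
    x_range: tuple[int, int] = (1, 30)
    n_residues: int = 126
    n_hot: int = 2
    hot_effect: float = 1.0


@dataclass
class SimulatedLibrary:
    records: list[MoleculeRecord]
    scaffold_ids: set[str] = field(default_factory=set)


@dataclass
class SimulatedDecomposition:
    entries: list[ResidueEnergy]
    hot_labels: set[str] = field(default_factory=set)


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


def _matches(smiles: str, query: ScaffoldQuery) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.HasSubstructMatch(query.query_mol)


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Library with exactly round(n * frac_scaffold) scaffold-bearing entries.

    Scaffold molecules graft a propane-1-sulfonic acid chain onto a random
    core; decoys are bare cores or cores with a one-carbon sulfonate
    decoration (too short to match). Every molecule is verified against the
    default query at generation, so the planted truth is exact by
    construction.
    """
    if config.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not 0.0 <= config.frac_scaffold <= 1.0:
        raise ValueError("frac_scaffold must lie in [0, 1]")
    query = ScaffoldQuery()
    rng = _rng(config, _OFFSET_LIBRARY)
    n = config.n_molecules
    n_scaffold = round(n * config.frac_scaffold)
    scaffold_positions = set(rng.choice(n, size=n_scaffold, replace=False).tolist())

    # Decoy decoration is only safe on cores that do not open with an
    # aliphatic-carbon chain (which could complete the 3-carbon motif).
    decorable = [c for c in _CORES if not _matches(_DECOY_PREFIX + c, query)]

    records, scaffold_ids = [], set()
    for i in range(n):
        rec_id = f"SYN{i + 1:05d}"
        if i in scaffold_positions:
            smiles = _SCAFFOLD_PREFIX + _CORES[rng.integers(len(_CORES))]
            if not _matches(smiles, query):  # pragma: no cover - guard
                raise RuntimeError(f"planted molecule fails to match: {smiles}")
            scaffold_ids.add(rec_id)
        else:
            if rng.random() < 0.3 and decorable:
                smiles = _DECOY_PREFIX + decorable[rng.integers(len(decorable))]
            else:
                smiles = _CORES[rng.integers(len(_CORES))]
            if _matches(smiles, query):  # pragma: no cover - guard
                raise RuntimeError(f"decoy accidentally matches: {smiles}")
        records.append(MoleculeRecord.from_smiles(smiles, id=rec_id,
                                                  source="synthetic"))
    return SimulatedLibrary(records=records, scaffold_ids=scaffold_ids)


def simulate_regression_data(config: SimulationConfig) -> tuple[list[float], list[float]]:
    """(x, y) with y = slope*x + intercept + N(0, noise_sd), seed-reproducible.

    x values are integer counts drawn uniformly from x_range (redrawn, up
    to a bound, if all collapse onto a single value).
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(config, _OFFSET_REGRESSION)
    lo, hi = config.x_range
    for _ in range(100):
        x = rng.integers(lo, hi + 1, size=config.n_points).astype(float)
        if config.n_points < 2 or np.ptp(x) > 0:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw non-degenerate x values")
    noise = rng.normal(0.0, config.noise_sd, size=config.n_points)
    y = config.slope * x + config.intercept + noise
    return x.tolist(), y.tolist()


def simulate_decomposition(config: SimulationConfig,
                           threshold: float = PER_RESIDUE_THRESHOLD) -> SimulatedDecomposition:
    """Per-residue decomposition with n_hot residues planted at or below
    ``threshold - hot_effect`` and the rest strictly above the threshold.

    With hot_effect = 0 the hot residues sit exactly on the threshold
    (which the <= hot-spot semantics still admits).
    """
    if config.n_hot > config.n_residues:
        raise ValueError("n_hot cannot exceed n_residues")
    grid = [(pos, chain) for chain in _CHAINS
            for pos in range(1, len(_ABETA42) + 1)]
    if config.n_residues > len(grid):
        raise ValueError(f"n_residues cannot exceed {len(grid)} "
                         "(3 chains x 42 residues)")
    rng = _rng(config, _OFFSET_DECOMPOSITION)
    chosen = rng.permutation(len(grid))[:config.n_residues]

    entries, hot_labels = [], set()
    for rank, idx in enumerate(chosen):
        pos, chain = grid[idx]
        name = f"{_THREE_LETTER[_ABETA42[pos - 1]]}{pos}"
        if rank < config.n_hot:
            base = threshold - config.hot_effect * (1.0 + rng.random())
            gb = base - rng.uniform(0.0, 0.3)
            entry = ResidueEnergy(residue=name, chain=chain,
                                  dg_pb_contrib=base, dg_gb_contrib=gb)
            hot_labels.add(entry.label)
        else:
            base = rng.uniform(threshold + 0.3, -0.2)
            gb = float(np.clip(base + rng.uniform(-0.2, 0.2),
                               threshold + 0.1, -0.05))
            entry = ResidueEnergy(residue=name, chain=chain,
                                  dg_pb_contrib=base, dg_gb_contrib=gb)
        entries.append(entry)
    return SimulatedDecomposition(entries=entries, hot_labels=hot_labels)
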