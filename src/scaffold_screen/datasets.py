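"""Packaged reference tables for the tramiprosate-scaffold screen.

Three small CSVs ship with the package:

* ``docking_summary.csv`` — the AutoDock summary for the 13 hits plus the
  tramiprosate reference (compound 14): binding energy, conformational
  cluster RMS statistics, heavy-atom and torsion counts, and the published
  Ki/LE/Tanimoto columns used for validation.
* ``descriptor_panel.csv`` — the descriptor/logBB panel for the two lead
  candidates, tramiprosate, and donepezil (the CNS-drug control).
* ``thermo_summary.csv`` — MM-PBSA/GBSA free energies, normal-mode entropy,
  enthalpies and buried surface areas for the leads and the reference.
* ``hit_structures.csv`` — curated SMILES for the 14 compounds. Structures
  were assembled from public structure records; dermatan sulfate is
  represented by a single disaccharide repeat unit and the sulfamazone and
  cefpimizole entries are approximations of the full registered substances
  (marked in their names).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .docking import DockResult, read_docking_table
from .library_io import LibraryLoad, read_library
from .thermo import ThermoRecord, read_thermo_table

#: Compound id of the reference molecule (tramiprosate) in the docking table.
REFERENCE_COMPOUND_ID = "14"


def _data_path(filename: str) -> Path:
    return Path(resources.files("scaffold_screen").joinpath("data", filename))


def load_docking_table() -> list[DockResult]:
    """Docking summary rows for the 14 screened compounds."""
    return read_docking_table(_data_path("docking_summary.csv"))


def load_docking_frame() -> pd.DataFrame:
    """Raw docking CSV including the published Ki/LE/T reference columns."""
    return pd.read_csv(_data_path("docking_summary.csv"),
                       dtype={"compound_id": str})


def load_descriptor_frame() -> pd.DataFrame:
    """Descriptor/logBB panel (leads, reference, donepezil control)."""
    return pd.read_csv(_data_path("descriptor_panel.csv"),
                       dtype={"compound_id": str})


def load_thermo_table() -> list[ThermoRecord]:
    """MM-PBSA/GBSA summaries for the leads and the reference."""
    return read_thermo_table(_data_path("thermo_summary.csv"))


def load_thermo_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("thermo_summary.csv"),
                       dtype={"compound_id": str})


def load_hit_structures() -> LibraryLoad:
    """Curated structures of the 13 hits plus tramiprosate (compound 14)."""
    return read_library(_data_path("hit_structures.csv"), format="csv")
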