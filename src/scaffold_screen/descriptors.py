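"""Molecular descriptors, fingerprints, Tanimoto similarity and clustering.

Descriptors (MW, AlogP, HBA, HBD, topological PSA, QED) are the standard
2D set used to profile screening hits. Similarity uses electrotopological-
state (E-state) atom-type fingerprints binarized to presence/absence, with
a path-based alternative; compounds are grouped by agglomerative clustering
on the Tanimoto distance 1 - T.

Fingerprints are computed on the full registered substance, salt components
included: for salt-form drugs the counter-component is part of the
registered entity and contributes atom types of its own. Salt stripping is
applied only for substructure matching (see :mod:`~scaffold_screen.library_io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .library_io import MoleculeRecord

#: Number of E-state atom types in the fingerprint.
N_ESTATE_FEATURES = 79
#: Bit length of the path-based (RDKit topological) fingerprint.
N_PATH_BITS = 2048


@dataclass(frozen=True)
class DescriptorSet:
    """2D descriptor panel for one molecule.

    mw      molecular weight, g/mol (implicit hydrogens included)
    alogp   atom-contribution octanol/water logP (Crippen), unitless
    hba     Lipinski H-bond acceptor count (N + O)
    hbd     Lipinski H-bond donor count (NH + OH)
    psa     topological polar surface area, A^2
    qed     quantitative estimate of drug-likeness in [0, 1]
    """

    mw: float
    alogp: float
    hba: int
    hbd: int
    psa: float
    qed: float


def compute_descriptors(record: MoleculeRecord) -> DescriptorSet:
    """Compute the descriptor panel for one record.

    Values follow the RDKit implementations of each descriptor; other
    cheminformatics toolkits implement slightly different atom typings, so
    agreement with published tables is approximate by nature.
    """
    mol = record.mol
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        alogp=Crippen.MolLogP(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        qed=QED.qed(mol),
    )


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length non-negative feature vector under a named scheme."""

    scheme: str  # "estate" or "path"
    values: np.ndarray

    def __post_init__(self):
        if self.scheme not in {"estate", "path"}:
            raise ValueError(f"unknown fingerprint scheme: {self.scheme!r}")
        if np.any(self.values < 0):
            raise ValueError("fingerprint entries must be >= 0")


def estate_fingerprint(mol: Chem.Mol) -> Fingerprint:
    """79-feature E-state atom-type fingerprint, binarized at count > 0."""
    counts, _sums = EStateFingerprinter.FingerprintMol(mol)
    return Fingerprint("estate", (np.asarray(counts) > 0).astype(np.uint8))


def path_fingerprint(mol: Chem.Mol, n_bits: int = N_PATH_BITS) -> Fingerprint:
    """Daylight-style path-based binary fingerprint (RDKit topological)."""
    bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return Fingerprint("path", np.frombuffer(bytes(bv.ToBitString(), "ascii"),
                                             dtype=np.uint8) - ord("0"))


def fingerprint(record: MoleculeRecord, scheme: str = "estate") -> Fingerprint:
    if scheme == "estate":
        return estate_fingerprint(record.mol)
    if scheme == "path":
        return path_fingerprint(record.mol)
    raise ValueError(f"unknown fingerprint scheme: {scheme!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a & b| / |a | b| on binarized vectors.

    Two all-zero fingerprints have no defined overlap; the similarity is
    reported as 0.0 with a warning.
    """
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    if a.values.shape != b.values.shape:
        raise ValueError("fingerprint length mismatch")
    av = a.values > 0
    bv = b.values > 0
    union = int(np.sum(av | bv))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; defined as 0.0")
        return 0.0
    return int(np.sum(av & bv)) / union


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise Tanimoto indexes with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v

    def to_long(self):
        """Long-format rows (id_a, id_b, tanimoto) for a >= b ordering."""
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if j <= i:
                    yield a, b, float(self.values[i, j])


def similarity_matrix(records: Sequence[MoleculeRecord],
                      scheme: str = "estate") -> SimilarityMatrix:
    fps = [fingerprint(r, scheme) for r in records]
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids=[r.id for r in records], values=values)


def similarity_to_reference(library: Sequence[MoleculeRecord],
                            reference: MoleculeRecord,
                            scheme: str = "estate") -> list[tuple[str, float]]:
    """Tanimoto index of every library entry against one reference structure."""
    ref_fp = fingerprint(reference, scheme)
    return [(rec.id, tanimoto(fingerprint(rec, scheme), ref_fp))
            for rec in library]


@dataclass
class ClusterTree:
    """Agglomerative merge history over the compounds of a similarity matrix."""

    ids: list[str]
    linkage_matrix: np.ndarray  # scipy linkage encoding: n-1 merges
    linkage_method: str

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of exactly k groups (labels 1..k).

        Labels are renumbered deterministically in order of first appearance
        along the leaf list.
        """
        n = len(self.ids)
        if not 1 <= k <= n:
            raise ValueError(f"k={k} outside [1, {n}]")
        raw = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        relabel: dict[int, int] = {}
        out: dict[str, int] = {}
        for leaf_id, label in zip(self.ids, raw):
            if label not in relabel:
                relabel[label] = len(relabel) + 1
            out[leaf_id] = relabel[label]
        if len(set(out.values())) != k:
            raise ValueError(f"cut produced {len(set(out.values()))} groups, not {k}")
        return out

    def to_newick(self) -> str:
        """Newick string with leaf ids and merge-height branch lengths."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_cluster(matrix: SimilarityMatrix,
                         linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering on the Tanimoto distance 1 - T.

    scipy's linkage on a condensed distance matrix is deterministic for a
    fixed input ordering (ties resolve to the lowest index pair).
    """
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(ids=list(matrix.ids), linkage_matrix=Z,
                       linkage_method=linkage)
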