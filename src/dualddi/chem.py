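"""SMILES parsing into molecular graphs and drug-library I/O.

A molecule is represented as a heavy-atom graph: nodes are non-hydrogen atoms
with a fixed-width feature vector, edges are covalent bonds, hydrogens stay
implicit.  The adjacency matrix is binary, symmetric with zero diagonal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import DEFAULT_SCHEME, get_scheme

__all__ = [
    "MolecularGraph",
    "DrugRecord",
    "SmilesParseError",
    "parse_smiles",
    "load_drug_library",
    "write_drug_library",
]


class SmilesParseError(ValueError):
    pass


@dataclass
class MolecularGraph:
    smiles: str
    num_nodes: int
    node_features: np.ndarray  # (N, d0)
    adjacency: np.ndarray      # (N, N) binary, symmetric, zero diagonal

    def __post_init__(self):
        n = self.num_nodes
        if n < 1:
            raise ValueError("molecular graph must have at least one atom")
        if self.node_features.shape[0] != n or self.adjacency.shape != (n, n):
            raise ValueError("node_features/adjacency shapes inconsistent with N")
        if not np.all(np.isfinite(self.node_features)):
            raise ValueError("non-finite node features")
        if np.any(self.adjacency != self.adjacency.T) or np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    graph: MolecularGraph = field(repr=False)


def parse_smiles(smiles: str, scheme: str = DEFAULT_SCHEME) -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Featurization is deterministic: the same string always yields identical
    matrices.  Raises :class:`SmilesParseError` for unparsable strings and for
    molecules with no heavy atoms.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    feat = get_scheme(scheme)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"RDKit could not parse SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"SMILES {smiles!r} has no heavy atoms")
    x = np.zeros((n, feat.n_features))
    for atom in mol.GetAtoms():
        x[atom.GetIdx()] = feat.atom_features(atom)
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolecularGraph(smiles=smiles, num_nodes=n, node_features=x, adjacency=adj)


def _read_table(path, required: set[str]) -> pd.DataFrame:
    """Read a UTF-8 CSV/TSV with a mandatory header; delimiter inferred from it."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def load_drug_library(path, scheme: str = DEFAULT_SCHEME) -> list[DrugRecord]:
    """Load a (drug_id, smiles) table into parsed drug records, preserving order."""
    df = _read_table(path, {"drug_id", "smiles"})
    dupes = df["drug_id"][df["drug_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate drug_id values: {', '.join(dupes)}")
    records, bad_rows = [], []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            graph = parse_smiles(row.smiles, scheme)
        except SmilesParseError:
            bad_rows.append((row_number, row.smiles))
            continue
        records.append(DrugRecord(drug_id=row.drug_id, smiles=row.smiles, graph=graph))
    if bad_rows:
        listing = "; ".join(f"row {r}: {s!r}" for r, s in bad_rows)
        raise SmilesParseError(f"{path}: unparsable SMILES at {listing}")
    return records


def write_drug_library(records: list[DrugRecord], path) -> None:
    pd.DataFrame(
        {"drug_id": [r.drug_id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, index=False)
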