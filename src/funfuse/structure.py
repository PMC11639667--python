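"""Protein structures and residue contact graphs.

A protein chain is reduced to its residue sequence and one representative
coordinate per residue (Cα by default, Cβ optionally).  The contact graph
connects residue pairs whose representative atoms lie closer than a distance
threshold θ (default 10 Å); its edge index feeds the graph branch of the
predictor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_THETA = 10.0  # Å, contact threshold

__all__ = [
    "ProteinStructure",
    "ContactGraph",
    "parse_structure",
    "build_contact_graph",
    "extract_sequence_fasta",
    "write_ca_pdb",
    "save_contact_graph",
    "load_contact_graph",
    "DEFAULT_THETA",
]


@dataclass
class ProteinStructure:
    """One chain: identifier, one-letter sequence, per-residue coordinates (Å)."""

    id: str
    sequence: str
    coords: np.ndarray  # (L, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if len(self.sequence) == 0:
            raise ValueError(f"{self.id}: empty sequence")
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} does not match "
                f"coordinate shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactGraph:
    """Undirected residue contact graph.

    ``edges`` stores each undirected contact once, canonically as ``(u, v)``
    with ``u < v``, in a ``(2, E)`` integer array.  :meth:`directed_index`
    materializes both directions for message passing (self-loops are added
    later by the graph-convolution normalization, not here).
    """

    n_nodes: int
    edges: np.ndarray  # (2, E), u < v
    theta: float
    id: str = ""

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(2, -1)
        if self.edges.size:
            u, v = self.edges
            if np.any(u == v):
                raise ValueError("self-edges are not allowed")
            if np.any(u >= v):
                raise ValueError("edges must be stored canonically with u < v")
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge index out of range")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def directed_index(self) -> np.ndarray:
        """Return the 2×2E edge index with both directions of every contact."""
        if self.edges.size == 0:
            return np.zeros((2, 0), dtype=np.int64)
        return np.concatenate([self.edges, self.edges[::-1]], axis=1)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency matrix (no self-loops)."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        if self.edges.size:
            u, v = self.edges
            A[u, v] = 1.0
            A[v, u] = 1.0
        return A


def parse_structure(path: str | Path, chain: str | None = None, atom: str = "CA") -> ProteinStructure:
    """Parse a single chain from a PDB file into a :class:`ProteinStructure`.

    One residue is emitted per representative atom, in file order.  Residues
    lacking the representative atom are skipped with a warning (keeps sequence
    and coordinates aligned).  Non-standard residues (e.g. MSE) become ``'X'``.

    Parameters
    ----------
    chain:
        Chain identifier.  ``None`` is accepted only for single-chain files.
    atom:
        ``"CA"`` (default) or ``"CB"``; glycine falls back to Cα under ``"CB"``.
    """
    if atom not in ("CA", "CB"):
        raise ValueError("atom must be 'CA' or 'CB'")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure(path.stem, str(path))[0]

    chain_ids = [c.id for c in model]
    if chain is None:
        if len(chain_ids) != 1:
            raise ValueError(f"{path.name}: multiple chains {chain_ids}; specify one")
        chain = chain_ids[0]
    if chain not in chain_ids:
        raise KeyError(f"{path.name}: chain {chain!r} not found (has {chain_ids})")

    seq_chars: list[str] = []
    coords: list[np.ndarray] = []
    for residue in model[chain]:
        if residue.id[0] == "W":  # waters
            continue
        name = atom
        if atom == "CB" and residue.get_resname().strip() == "GLY":
            name = "CA"
        if name not in residue:
            logger.warning("%s chain %s: residue %s lacks %s atom; skipped",
                           path.name, chain, residue.get_resname(), name)
            continue
        seq_chars.append(seq1(residue.get_resname().strip().capitalize(), undef_code="X"))
        coords.append(residue[name].get_coord().astype(np.float64))

    if not seq_chars:
        raise ValueError(f"{path.name}: chain {chain} has no usable residues")
    return ProteinStructure(id=f"{path.stem}_{chain}", sequence="".join(seq_chars),
                            coords=np.vstack(coords))


def build_contact_graph(structure: ProteinStructure, theta: float = DEFAULT_THETA) -> ContactGraph:
    """Contacts between residues whose representative atoms are closer than θ Å."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    L = len(structure)
    if L == 1:
        return ContactGraph(n_nodes=1, edges=np.zeros((2, 0), dtype=np.int64),
                            theta=theta, id=structure.id)
    dist = squareform(pdist(structure.coords))
    iu, iv = np.triu_indices(L, k=1)
    mask = dist[iu, iv] < theta
    edges = np.vstack([iu[mask], iv[mask]])
    return ContactGraph(n_nodes=L, edges=edges, theta=theta, id=structure.id)


def extract_sequence_fasta(structure: ProteinStructure) -> str:
    """FASTA record (header = structure id, body = sequence)."""
    return f">{structure.id}\n{structure.sequence}\n"


_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}


def write_ca_pdb(structure: ProteinStructure, path: str | Path, chain: str = "A") -> None:
    """Write a Cα-trace PDB file (one ATOM record per residue).

    Coordinates are stored at PDB field precision (1e-3 Å), so a write/parse
    round trip reproduces them to that tolerance.
    """
    lines = []
    for i, (aa, xyz) in enumerate(zip(structure.sequence, structure.coords), start=1):
        resname = _THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} {chain}{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def save_contact_graph(graph: ContactGraph, tsv_path: str | Path) -> None:
    """Serialize the edge list as two-column TSV plus a JSON sidecar."""
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("node_u\tnode_v\n")
        for u, v in graph.edges.T:
            fh.write(f"{u}\t{v}\n")
    sidecar = tsv_path.with_suffix(tsv_path.suffix + ".json")
    sidecar.write_text(json.dumps({"id": graph.id, "L": graph.n_nodes, "theta": graph.theta}))


def load_contact_graph(tsv_path: str | Path) -> ContactGraph:
    tsv_path = Path(tsv_path)
    meta = json.loads(tsv_path.with_suffix(tsv_path.suffix + ".json").read_text())
    rows = np.loadtxt(tsv_path, skiprows=1, dtype=np.int64, ndmin=2)
    edges = rows.T if rows.size else np.zeros((2, 0), dtype=np.int64)
    return ContactGraph(n_nodes=int(meta["L"]), edges=edges, theta=float(meta["theta"]),
                        id=meta.get("id", ""))
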