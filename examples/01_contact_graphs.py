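"""Build a residue contact graph from a protein structure.

Generates an ideal α-helix Cα trace, writes it as a PDB file, parses it back
and builds the θ = 10 Å contact graph — the graph input of the GCN branch.
"""

import tempfile
from pathlib import Path

import numpy as np

from funfuse import build_contact_graph, make_helix_structure, parse_structure
from funfuse.structure import save_contact_graph, write_ca_pdb

helix = make_helix_structure(L=40, seed=0)
print(f"structure {helix.id}: {len(helix)} residues")
print(f"sequence: {helix.sequence}")

with tempfile.TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "helix.pdb"
    write_ca_pdb(helix, pdb)
    parsed = parse_structure(pdb)
    graph = build_contact_graph(parsed, theta=10.0)
    save_contact_graph(graph, Path(tmp) / "edges.tsv")

    print(f"contact graph: {graph.n_nodes} nodes, {graph.n_edges} undirected contacts "
          f"at θ = {graph.theta} Å")
    d1 = np.linalg.norm(parsed.coords[1] - parsed.coords[0])
    d7 = np.linalg.norm(parsed.coords[7] - parsed.coords[0])
    print(f"|i−j| = 1 distance: {d1:.2f} Å (always a contact: < 10 Å)")
    print(f"|i−j| = 7 distance: {d7:.2f} Å (never a contact: ≥ 10 Å)")
    # The sequence-neighbour band plus the i±3/i±4 helical turn contacts give
    # each interior residue about 11 neighbours in an ideal helix.
    degrees = np.bincount(graph.directed_index()[0], minlength=graph.n_nodes)
    print(f"mean node degree: {degrees.mean():.1f}")
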