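"""Deterministic synthetic fixtures: structures, ontologies, labeled datasets.

Everything the real pipeline consumes can be generated here with no
downloads: ideal α-helix Cα traces (rise 1.5 Å/residue, radius 2.3 Å, 100°
turn/residue), random rooted DAGs of ontology terms, and annotation matrices
produced by a planted sequence-motif → leaf-term mechanism and closed under
the ancestor relation.  The per-residue embedding channel comes from the
deterministic synthetic provider keyed to the same seed.

The motif mechanism makes the labels learnable from sequence content by both
branches; the contact topology of the helices is label-independent by
construction, which is a stated limitation of the fixture, not of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encodings import AMINO_ACIDS, SyntheticEmbeddingProvider, tokenize_sequence
from .go_metrics import GoDag, propagate_ancestors, write_annotations_tsv, write_parent_child_tsv
from .structure import ProteinStructure, build_contact_graph, extract_sequence_fasta, write_ca_pdb
from .training import Sample

HELIX_RISE = 1.5     # Å per residue along the axis
HELIX_RADIUS = 2.3   # Å
HELIX_TURN = 100.0   # degrees per residue

DEFAULT_MOTIFS = ("WWW", "CCC", "HHH", "MMM", "YYY", "FFF", "PPP", "KKK")

__all__ = [
    "SyntheticConfig", "SyntheticDataset", "make_helix_structure", "make_go_dag",
    "make_annotated_dataset", "DEFAULT_MOTIFS", "HELIX_RISE", "HELIX_RADIUS", "HELIX_TURN",
]


def make_helix_structure(L: int, seed: int, id: str | None = None) -> ProteinStructure:
    """Ideal α-helix Cα trace with a uniformly random sequence.

    Consecutive residues are ~3.8 Å apart (always in contact at θ = 10 Å);
    residues seven apart are separated axially by 10.5 Å and hence never in
    contact at that threshold.
    """
    if L < 1:
        raise ValueError("L must be ≥ 1")
    rng = np.random.default_rng(seed)
    i = np.arange(L)
    phi = np.deg2rad(HELIX_TURN * i)
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * i,
    ])
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    return ProteinStructure(id=id or f"helix{L}_s{seed}", sequence=seq, coords=coords)


def make_go_dag(C: int, branching: int = 2, seed: int = 0,
                reserved_leaves: int = 0) -> GoDag:
    """Random rooted DAG: term 0 is the root; term i ≥ 1 draws 1..branching
    parents among lower-index terms.

    ``reserved_leaves`` keeps the last k terms out of every parent pool so
    they are guaranteed childless (used to attach motifs to leaves).
    """
    if C < 1:
        raise ValueError("C must be ≥ 1")
    if reserved_leaves >= C:
        raise ValueError("cannot reserve all terms as leaves")
    rng = np.random.default_rng(seed)
    terms = [f"SYN:{i:04d}" for i in range(C)]
    edges: list[tuple[str, str]] = []
    cutoff = C - reserved_leaves
    for i in range(1, C):
        pool = np.arange(min(i, cutoff)) if min(i, cutoff) > 0 else np.array([0])
        k = int(rng.integers(1, branching + 1))
        parents = rng.choice(pool, size=min(k, pool.size), replace=False)
        edges.extend((terms[i], terms[int(p)]) for p in parents)
    return GoDag(terms=terms, parent_edges=edges)


@dataclass
class SyntheticConfig:
    """The stated synthetic world: sizes, ontology shape, motif signal, noise."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (30, 60)
    n_terms: int = 16
    branching: int = 2
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    implant_prob: float = 0.5
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proteins, self.n_terms, self.branching) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must lie in [0, 1]")
        if self.length_range[0] < min(len(m) for m in self.motifs):
            raise ValueError("motif longer than the minimum protein length")
        if len(self.motifs) >= self.n_terms:
            raise ValueError("need more terms than motifs (root + leaves)")


@dataclass
class SyntheticDataset:
    """Structures + ontology + closed annotations + 8:1:1 split, one seed."""

    config: SyntheticConfig
    structures: list[ProteinStructure]
    dag: GoDag
    annotations: np.ndarray          # (N, C) bool, ancestor-closed
    motif_terms: dict[str, str]      # leaf term id -> motif
    splits: dict[str, np.ndarray]    # 'train'/'valid'/'test' -> protein indices
    provider: SyntheticEmbeddingProvider = field(repr=False, default=None)

    @property
    def protein_ids(self) -> list[str]:
        return [s.id for s in self.structures]

    def samples(self, split: str, theta: float = 10.0) -> list[Sample]:
        """Materialize featurized samples (tokens, embeddings, graph, labels)."""
        out = []
        for i in self.splits[split]:
            s = self.structures[i]
            out.append(Sample(
                id=s.id,
                tokens=tokenize_sequence(s.sequence),
                lm=self.provider(s.sequence),
                graph=build_contact_graph(s, theta=theta),
                labels=self.annotations[i].astype(np.float64),
            ))
        return out

    def emit_to_dir(self, out_dir: str | Path) -> None:
        """Write the on-disk formats the real pipeline reads: per-protein PDB,
        a joint FASTA, parent-child TSV for the DAG, annotation TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "structures").mkdir(exist_ok=True)
        fasta = []
        for s in self.structures:
            write_ca_pdb(s, out_dir / "structures" / f"{s.id}.pdb")
            fasta.append(extract_sequence_fasta(s))
        (out_dir / "sequences.fasta").write_text("".join(fasta))
        write_parent_child_tsv(self.dag, out_dir / "ontology.tsv")
        write_annotations_tsv(self.annotations, self.protein_ids, self.dag,
                              out_dir / "annotations.tsv")
        for name, idx in self.splits.items():
            (out_dir / f"split_{name}.txt").write_text(
                "\n".join(self.structures[i].id for i in idx) + "\n")


def make_annotated_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full labeled world of a :class:`SyntheticConfig`.

    Each motif maps to one guaranteed-childless leaf term.  Per protein and
    motif, the motif is implanted at a random position with probability
    ``implant_prob``; the protein's leaf label is then *containment* of the
    motif in the final sequence (so noise 0 is perfectly consistent), flipped
    with probability ``noise``; annotations are closed over ancestors.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    dag = make_go_dag(cfg.n_terms, cfg.branching, seed=cfg.seed,
                      reserved_leaves=len(cfg.motifs))
    leaf_terms = dag.terms[cfg.n_terms - len(cfg.motifs):]
    motif_terms = dict(zip(leaf_terms, cfg.motifs))

    lo, hi = cfg.length_range
    structures: list[ProteinStructure] = []
    N, C = cfg.n_proteins, cfg.n_terms
    ann = np.zeros((N, C), dtype=bool)

    for i in range(N):
        L = int(rng.integers(lo, hi + 1))
        s = make_helix_structure(L, seed=int(rng.integers(2**31)), id=f"prot{i:04d}")
        seq = list(s.sequence)
        for motif in cfg.motifs:
            if rng.random() < cfg.implant_prob:
                start = int(rng.integers(0, L - len(motif) + 1))
                seq[start:start + len(motif)] = list(motif)
        seq = "".join(seq)
        structures.append(ProteinStructure(id=s.id, sequence=seq, coords=s.coords))
        for term, motif in motif_terms.items():
            label = motif in seq
            if cfg.noise > 0 and rng.random() < cfg.noise:
                label = not label
            ann[i, dag.index[term]] = label

    ann = propagate_ancestors(ann, dag)

    order = rng.permutation(N)
    n_train = int(round(0.8 * N))
    n_valid = int(round(0.1 * N))
    splits = {
        "train": np.sort(order[:n_train]),
        "valid": np.sort(order[n_train:n_train + n_valid]),
        "test": np.sort(order[n_train + n_valid:]),
    }
    return SyntheticDataset(config=cfg, structures=structures, dag=dag,
                            annotations=ann, motif_terms=motif_terms, splits=splits,
                            provider=SyntheticEmbeddingProvider(seed=cfg.seed))
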