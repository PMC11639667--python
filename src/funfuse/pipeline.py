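"""End-to-end workflow: prepare → train → predict → evaluate.

These functions are the package's operational surface (there is no shell
command-line tool; the examples/ scripts show typical drive-throughs):

* :func:`prepare` parses a directory of PDB files into per-protein feature
  bundles (tokens, embeddings, contact edges) with a manifest, idempotently;
* :func:`train_model` runs the three-phase protocol and returns a
  :class:`FusedModel`;
* :func:`predict_to_tsv` writes CAFA-style (protein, term, score) records;
* :func:`evaluate_predictions` scores a prediction TSV against ground-truth
  annotations with Fmax, Smin and AUPR.

Every function takes an explicit seed where randomness exists; checkpoints
carry a JSON manifest of hyperparameters so architecture mismatches are
detected on load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .agcn import AGCNBranch
from .encodings import SyntheticEmbeddingProvider, provide_embeddings, tokenize_sequence
from .go_metrics import (EvalPair, GoDag, evaluate_all, propagate_ancestors,
                         read_annotations_tsv, read_predictions_tsv, write_predictions_tsv)
from .mcnn import MCNNBranch
from .structure import ContactGraph, build_contact_graph, parse_structure
from .training import (FusionParams, Sample, TrainConfig, adaptive_fuse, branch_scores,
                       train_branch, train_fusion)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "FusedModel", "prepare", "load_bundles", "train_model",
    "predict_to_tsv", "evaluate_predictions",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the chosen configuration:
    three GCN layers, four MCNN attention heads, θ = 10 Å upstream)."""

    n_terms: int
    hidden: int = 512
    agcn_heads: int = 4
    m0: int = 32
    n_gcn_layers: int = 3
    mcnn_channels: tuple[int, int, int] = (512, 256, 128)
    mcnn_kernels: tuple[int, int, int] = (7, 5, 3)
    cam_kernels: tuple[int, ...] = (3, 5, 7, 9)
    dropout: float = 0.2
    pool: str = "max"
    fusion_mode: str = "per_sample"
    context_width: int | None = None  # None = width-preserving recurrent stage
    seed: int = 0

    def __post_init__(self):
        if self.hidden % self.agcn_heads:
            raise ValueError("hidden width must be divisible by agcn_heads")
        if self.fusion_mode not in ("per_sample", "global"):
            raise ValueError("fusion_mode must be 'per_sample' or 'global'")

    @classmethod
    def desk_scale(cls, n_terms: int, seed: int = 0, **overrides) -> "ModelConfig":
        """Reduced-width configuration for CPU-budget runs and tests.

        Keeps the chosen structure (3 GCN layers, 4 channel-attention heads)
        but narrows hidden widths and the recurrent context stage.
        """
        kwargs = dict(n_terms=n_terms, hidden=32, agcn_heads=2, m0=4,
                      mcnn_channels=(64, 32, 16), context_width=64,
                      dropout=0.0, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class FusedModel:
    """Both trained branches plus the fitted fusion parameters."""

    config: ModelConfig
    agcn: AGCNBranch
    mcnn: MCNNBranch
    fusion: FusionParams

    @classmethod
    def initialize(cls, config: ModelConfig) -> "FusedModel":
        agcn = AGCNBranch(
            n_terms=config.n_terms, hidden=config.hidden, n_heads=config.agcn_heads,
            m0=config.m0, dropout=config.dropout, seed=config.seed,
            n_gcn_layers=config.n_gcn_layers, context_width=config.context_width,
        )
        mcnn = MCNNBranch(
            n_terms=config.n_terms, channels=config.mcnn_channels,
            kernels=config.mcnn_kernels, cam_kernels=config.cam_kernels,
            dropout=config.dropout, pool=config.pool, seed=config.seed + 1,
        )
        fusion = FusionParams(config.n_terms, mode=config.fusion_mode, seed=config.seed)
        return cls(config=config, agcn=agcn, mcnn=mcnn, fusion=fusion)

    def predict(self, samples: Sequence[Sample], branch: str = "fused") -> np.ndarray:
        """Inference-mode N×C score matrix from one branch or the fusion."""
        if branch not in ("agcn", "mcnn", "fused"):
            raise ValueError("branch must be 'agcn', 'mcnn' or 'fused'")
        if branch == "agcn":
            return branch_scores(self.agcn, samples)
        if branch == "mcnn":
            return branch_scores(self.mcnn, samples)
        s_gcn = branch_scores(self.agcn, samples)
        s_cnn = branch_scores(self.mcnn, samples)
        return np.stack([
            adaptive_fuse(s_gcn[i], s_cnn[i], self.fusion).data
            for i in range(len(samples))
        ])

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single .npz of all parameter arrays + JSON manifest sidecar."""
        path = Path(path)
        arrays = (self.agcn.state_arrays() + self.mcnn.state_arrays()
                  + self.fusion.state_arrays())
        np.savez(path, *arrays)
        manifest = {"model_config": asdict(self.config),
                    "n_arrays": len(arrays), "format": "funfuse-checkpoint-v1"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FusedModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg_dict = manifest["model_config"]
        for key in ("mcnn_channels", "mcnn_kernels", "cam_kernels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        model = cls.initialize(cfg)
        with np.load(path) as data:
            arrays = [data[f"arr_{i}"] for i in range(manifest["n_arrays"])]
        n_a = len(model.agcn.parameters())
        n_m = len(model.mcnn.parameters())
        try:
            model.agcn.load_state_arrays(arrays[:n_a])
            model.mcnn.load_state_arrays(arrays[n_a:n_a + n_m])
            model.fusion.load_state_arrays(arrays[n_a + n_m:])
        except ValueError as exc:
            raise ValueError(
                f"checkpoint/architecture mismatch for {path.name}: {exc}; "
                f"manifest = {manifest['model_config']}") from exc
        return model


# ---------------------------------------------------------------------------
# prepare
# ---------------------------------------------------------------------------


def prepare(structures_dir: str | Path, out_dir: str | Path, theta: float = 10.0,
            provider=None, seed: int = 0, chain: str | None = None) -> dict:
    """Parse every ``*.pdb`` under `structures_dir` into per-protein bundles.

    Each bundle (.npz) holds tokens, the L×1280 embedding matrix and the
    contact edge index; a ``manifest.json`` lists finished proteins so
    re-runs skip them.  Unparseable files are logged and skipped; if *all*
    fail, an error is raised.
    """
    structures_dir, out_dir = Path(structures_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provider = provider or SyntheticEmbeddingProvider(seed=seed)
    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "theta": theta, "seed": seed, "provider": getattr(provider, "name", "custom"),
        "entries": {}}

    pdb_files = sorted(structures_dir.glob("*.pdb"))
    if not pdb_files:
        raise FileNotFoundError(f"no .pdb files under {structures_dir}")
    n_ok, n_fail = 0, 0
    for pdb in pdb_files:
        pid = pdb.stem
        bundle = out_dir / f"{pid}.npz"
        if pid in manifest["entries"] and bundle.exists():
            continue  # idempotent re-run
        try:
            structure = parse_structure(pdb, chain=chain)
            graph = build_contact_graph(structure, theta=theta)
            tokens = tokenize_sequence(structure.sequence)
            lm = provide_embeddings(structure.sequence, provider).values
        except Exception as exc:
            logger.warning("skipping %s: %s", pdb.name, exc)
            n_fail += 1
            continue
        np.savez(bundle, tokens=tokens, lm=lm, edges=graph.edges,
                 L=np.int64(graph.n_nodes), theta=np.float64(theta),
                 sequence=np.array(structure.sequence))
        manifest["entries"][pid] = {"L": graph.n_nodes, "n_edges": graph.n_edges}
        n_ok += 1
    if n_ok == 0 and not manifest["entries"]:
        raise RuntimeError(f"all {n_fail} structure files failed to parse")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def load_bundles(out_dir: str | Path, labels: np.ndarray | None = None,
                 protein_ids: Sequence[str] | None = None) -> list[Sample]:
    """Load prepared bundles back into :class:`Sample` objects.

    `protein_ids` selects and orders the proteins (default: manifest order);
    `labels` is the aligned N×C matrix (zeros if absent, e.g. for inference).
    """
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    ids = list(protein_ids) if protein_ids is not None else sorted(manifest["entries"])
    samples = []
    for i, pid in enumerate(ids):
        with np.load(out_dir / f"{pid}.npz") as data:
            graph = ContactGraph(n_nodes=int(data["L"]), edges=data["edges"],
                                 theta=float(data["theta"]), id=pid)
            lab = labels[i].astype(np.float64) if labels is not None else np.zeros(0)
            samples.append(Sample(id=pid, tokens=data["tokens"], lm=data["lm"],
                                  graph=graph, labels=lab))
    return samples


# ---------------------------------------------------------------------------
# train / predict / evaluate
# ---------------------------------------------------------------------------


def train_model(train: Sequence[Sample], valid: Sequence[Sample],
                model_cfg: ModelConfig, train_cfg: TrainConfig) -> tuple[FusedModel, dict]:
    """Three-phase protocol: AGCN, then MCNN, then frozen-branch fusion."""
    model = FusedModel.initialize(model_cfg)
    hist_a = train_branch(model.agcn, train, valid, train_cfg, kind="agcn")
    hist_m = train_branch(model.mcnn, train, valid, train_cfg, kind="mcnn")
    model.fusion, hist_f = train_fusion(model.agcn, model.mcnn, train, valid,
                                        train_cfg, mode=model_cfg.fusion_mode)
    return model, {"agcn": hist_a, "mcnn": hist_m, "fusion": hist_f}


def predict_to_tsv(model: FusedModel, samples: Sequence[Sample], dag: GoDag,
                   path: str | Path, branch: str = "fused") -> np.ndarray:
    """Write CAFA-style 3-column predictions (3-decimal scores); returns scores."""
    scores = model.predict(samples, branch=branch)
    write_predictions_tsv(scores, [s.id for s in samples], dag, path)
    return scores


def evaluate_predictions(pred_tsv: str | Path, annotations_tsv: str | Path,
                         dag: GoDag, protein_ids: Sequence[str],
                         out_json: str | Path | None = None) -> dict:
    """Score a prediction TSV against ground truth: Fmax, Smin, AUPR.

    Ground-truth annotations are ancestor-closed before evaluation; the
    information content for Smin is estimated from that closed truth set.
    """
    truth = read_annotations_tsv(annotations_tsv, list(protein_ids), dag)
    truth = propagate_ancestors(truth, dag)
    scores = read_predictions_tsv(pred_tsv, list(protein_ids), dag)
    record = evaluate_all(EvalPair(truth=truth, scores=scores))
    record["n_proteins"] = len(protein_ids)
    record["n_terms"] = dag.n_terms
    if out_json is not None:
        Path(out_json).write_text(json.dumps(record, indent=2))
    return record
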