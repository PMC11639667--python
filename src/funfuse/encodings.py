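"""Residue feature channels for the two network branches.

Two per-residue channels are produced from a sequence:

* ``onehot96`` — integer tokens (20 standard residues → 0..19 alphabetically,
  anything else → 21st "missing" token 20) looked up in a learnable 21×96
  embedding table;
* ``lm1280`` — an L×1280 per-residue embedding matrix from a protein language
  model.  A deterministic synthetic provider is built in so the pipeline runs
  with no downloads; a real pretrained provider can be plugged in behind the
  same one-call interface.

Their row-wise concatenation (``concat1376``, language-model block first) is
the joint input channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # token 0..19 in alphabetical order
MISSING_TOKEN = 20
N_TOKENS = 21
ONEHOT_DIM = 96
LM_DIM = 1280
CONCAT_DIM = LM_DIM + ONEHOT_DIM

_AA_TO_TOKEN = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CHANNEL_DIMS = {"onehot96": ONEHOT_DIM, "lm1280": LM_DIM, "concat1376": CONCAT_DIM}

__all__ = [
    "AMINO_ACIDS", "MISSING_TOKEN", "N_TOKENS", "ONEHOT_DIM", "LM_DIM", "CONCAT_DIM",
    "FeatureMatrix", "tokenize_sequence", "detokenize", "make_embedding_table",
    "embed_tokens", "SyntheticEmbeddingProvider", "provide_embeddings",
    "concat_features", "save_features", "load_features",
]


@dataclass
class FeatureMatrix:
    """An L×D real-valued residue feature matrix tagged with its channel."""

    values: np.ndarray
    channel: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.channel not in _CHANNEL_DIMS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.values.ndim != 2 or self.values.shape[1] != _CHANNEL_DIMS[self.channel]:
            raise ValueError(
                f"channel {self.channel} requires width {_CHANNEL_DIMS[self.channel]}, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def tokenize_sequence(sequence: str) -> np.ndarray:
    """Map a one-letter sequence to integer tokens in [0, 20].

    The 20 standard residues map to 0..19 in alphabetical order of their
    one-letter codes; every other character (``X``, ambiguity codes, ...)
    maps to the missing-position token 20.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return np.array([_AA_TO_TOKEN.get(c, MISSING_TOKEN) for c in sequence.upper()],
                    dtype=np.int64)


def detokenize(tokens: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[t] if t < MISSING_TOKEN else "X" for t in tokens)


def make_embedding_table(seed: int = 0) -> np.ndarray:
    """Seeded initial 21×96 embedding table (standard normal / √96)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((N_TOKENS, ONEHOT_DIM)) / np.sqrt(ONEHOT_DIM)


def embed_tokens(tokens: np.ndarray, table: np.ndarray) -> FeatureMatrix:
    """Look tokens up in a 21×96 table → ``onehot96`` channel."""
    tokens = np.asarray(tokens)
    table = np.asarray(table, dtype=np.float64)
    if table.shape[0] != N_TOKENS:
        raise ValueError(f"table must have {N_TOKENS} rows, got {table.shape[0]}")
    if tokens.size and (tokens.min() < 0 or tokens.max() >= N_TOKENS):
        raise ValueError("token out of range")
    return FeatureMatrix(table[tokens], "onehot96")


class EmbeddingProvider(Protocol):
    """Adapter interface for per-residue embedding sources (width 1280)."""

    name: str

    def __call__(self, sequence: str) -> np.ndarray: ...


class SyntheticEmbeddingProvider:
    """Deterministic stand-in for a protein language model.

    Row ``i`` is a pseudo-random but fixed function of (residue identity at
    position i, position i, seed).  Like a real language-model embedding it
    is dominated by residue identity, with a positional component:

        row = √ρ · r(residue) + √(1−ρ) · p(residue, position)

    where r and p are unit-normal vectors drawn from generators keyed on
    (seed, residue) and (seed, residue, position) respectively, and ρ is the
    fraction of variance carried by residue identity (default 0.9, mirroring
    how strongly real language-model embeddings encode residue identity).  Rows
    have configurable mean (default 0) and unit scale.  Identical
    (sequence, seed) pairs give bitwise-identical matrices, and positions
    sharing residue and index share rows across sequences.
    """

    name = "synthetic"

    def __init__(self, seed: int = 0, mean: float = 0.0, scale: float = 1.0,
                 residue_fraction: float = 0.9):
        if not 0.0 <= residue_fraction <= 1.0:
            raise ValueError("residue_fraction must lie in [0, 1]")
        self.seed = int(seed)
        self.mean = float(mean)
        self.scale = float(scale)
        self.residue_fraction = float(residue_fraction)

    def __call__(self, sequence: str) -> np.ndarray:
        tokens = tokenize_sequence(sequence)
        w_res = np.sqrt(self.residue_fraction)
        w_pos = np.sqrt(1.0 - self.residue_fraction)
        res_vecs = {}
        out = np.empty((len(tokens), LM_DIM))
        for pos, tok in enumerate(tokens):
            tok = int(tok)
            if tok not in res_vecs:
                rng_r = np.random.default_rng(np.random.SeedSequence([self.seed, tok]))
                res_vecs[tok] = rng_r.standard_normal(LM_DIM)
            rng_p = np.random.default_rng(np.random.SeedSequence([self.seed, tok, pos]))
            row = w_res * res_vecs[tok] + w_pos * rng_p.standard_normal(LM_DIM)
            out[pos] = self.mean + self.scale * row
        return out


def provide_embeddings(sequence: str, provider: EmbeddingProvider) -> FeatureMatrix:
    """Run a provider on a sequence → ``lm1280`` channel, with error context."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        values = provider(sequence)
    except Exception as exc:  # surface provider identity with the failure
        raise RuntimeError(
            f"embedding provider {getattr(provider, 'name', provider)!r} failed "
            f"on sequence of length {len(sequence)}: {exc}"
        ) from exc
    return FeatureMatrix(values, "lm1280")


def concat_features(lm: FeatureMatrix, oh: FeatureMatrix) -> FeatureMatrix:
    """Row-wise [lm | onehot] concatenation → ``concat1376`` channel."""
    if lm.channel != "lm1280" or oh.channel != "onehot96":
        raise ValueError("expected (lm1280, onehot96) inputs")
    if lm.length != oh.length:
        raise ValueError(f"length mismatch: {lm.length} vs {oh.length}")
    return FeatureMatrix(np.concatenate([lm.values, oh.values], axis=1), "concat1376")


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """One-protein binary container (shape/dtype header via .npz)."""
    np.savez(path, values=fm.values, channel=np.array(fm.channel))


def load_features(path: str | Path) -> FeatureMatrix:
    with np.load(path) as data:
        return FeatureMatrix(data["values"], str(data["channel"]))
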