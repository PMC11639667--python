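"""Objective, adaptive fusion of branch predictions, and the training protocol.

Training is three-phase: each branch is optimized separately with Adam under
its own learning rate and batch size (multi-label binary cross-entropy
objective, early stopping on validation loss with a patience window, best
parameters restored), then both branches are frozen and the fusion weight
α of

    f̂ = α · ŷ_gcn + (1 − α) · ŷ_cnn

is fitted on the same objective.  α is a logistic-squashed learnable: either
a single global scalar, or per-sample — an affine map from the concatenated
branch score vectors (length 2C) to one logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tensor import Tensor, as_tensor, concat
from .agcn import AGCNBranch
from .mcnn import MCNNBranch
from .nn import Adam, Linear, Module
from .structure import ContactGraph

EPS = 1e-7  # probability clamp keeping the loss finite

__all__ = [
    "Sample", "TrainConfig", "FusionParams", "EarlyStopper",
    "bce_loss", "adaptive_fuse", "train_branch", "train_fusion",
    "branch_scores", "EPS",
]


@dataclass
class Sample:
    """One protein ready for either branch: features, graph, closed labels."""

    id: str
    tokens: np.ndarray        # (L,) ints in [0, 20]
    lm: np.ndarray            # (L, 1280)
    graph: ContactGraph
    labels: np.ndarray        # (C,) binary, ancestor-closed


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, per-branch learning rates and batch sizes,
    early stopping on validation loss."""

    lr_agcn: float = 1e-4
    lr_mcnn: float = 5e-4
    batch_agcn: int = 48
    batch_mcnn: int = 64
    max_epochs: int = 100
    patience: int = 5
    lr_fusion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_agcn, self.lr_mcnn, self.lr_fusion) <= 0:
            raise ValueError("learning rates must be positive")
        if min(self.batch_agcn, self.batch_mcnn, self.max_epochs, self.patience) < 1:
            raise ValueError("counts must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Protocol scaled to a ~40-protein training split: the standard batch
        sizes exceed such a split (one optimizer step per epoch), so batches
        shrink to 1/2 and the epoch cap rises to 200; learning rates and the
        patience window keep their standard values."""
        kwargs = dict(batch_agcn=1, batch_mcnn=2, max_epochs=200, patience=5, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)


def bce_loss(y_hat, y, reduction: str = "sum"):
    """Multi-label binary cross-entropy, summed (as printed) or averaged.

    Predictions are clamped to [EPS, 1−EPS].  Accepts Tensors (differentiable)
    or arrays; returns a scalar of the same kind.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    y_hat_t = as_tensor(y_hat)
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    if y_hat_t.shape != y_arr.shape:
        raise ValueError(f"shape mismatch {y_hat_t.shape} vs {y_arr.shape}")
    p = y_hat_t.clip(EPS, 1.0 - EPS)
    y_t = Tensor(y_arr)
    ll = y_t * p.log() + (1.0 - y_t) * (1.0 - p).log()
    total = -ll.sum()
    if reduction == "mean":
        total = total * (1.0 / y_arr.size)
    return total if isinstance(y_hat, Tensor) else float(total.data)


class FusionParams(Module):
    """Learnable α of the branch-score fusion.

    mode="per_sample": logit = affine([ŷ_gcn ; ŷ_cnn]); mode="global": a
    single scalar logit.  Either way α = logistic(logit) ∈ (0, 1).
    """

    def __init__(self, n_terms: int, mode: str = "per_sample", seed: int = 0):
        super().__init__()
        if mode not in ("per_sample", "global"):
            raise ValueError("mode must be 'per_sample' or 'global'")
        self.mode = mode
        self.n_terms = n_terms
        if mode == "per_sample":
            # zero-init weights → α starts at 0.5 for every sample
            self.linear = Linear(2 * n_terms, 1, np.random.default_rng(seed))
            self.linear.weight.data[:] = 0.0
        else:
            self.logit = Tensor(0.0, requires_grad=True)

    def alpha(self, y_gcn, y_cnn) -> Tensor:
        if self.mode == "global":
            return self.logit.sigmoid()
        both = concat([as_tensor(y_gcn), as_tensor(y_cnn)], axis=0).reshape(1, -1)
        return self.linear(both).sigmoid().reshape(())


def adaptive_fuse(y_gcn, y_cnn, params: FusionParams) -> Tensor:
    """Elementwise convex combination of the two branch score vectors."""
    y_gcn, y_cnn = as_tensor(y_gcn), as_tensor(y_cnn)
    if y_gcn.shape != y_cnn.shape:
        raise ValueError("branch score shapes differ")
    alpha = params.alpha(y_gcn, y_cnn)
    return alpha * y_gcn + (1.0 - alpha) * y_cnn


class EarlyStopper:
    """Stop when validation loss has not improved for `patience` epochs.

    Epochs are 1-based; `best_epoch` is the epoch whose parameters should be
    restored at the stop.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be ≥ 1")
        self.patience = patience
        self.best = float("inf")
        self.best_epoch = 0
        self._since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True if it improved."""
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self._since_best = 0
            return True
        self._since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self._since_best >= self.patience


def _forward(branch: Module, sample: Sample) -> Tensor:
    if isinstance(branch, AGCNBranch):
        return branch(sample.lm, sample.tokens, sample.graph)
    if isinstance(branch, MCNNBranch):
        return branch(sample.lm, sample.tokens)
    return branch(sample)  # duck-typed branch (used by toy tests)


def _dataset_loss(branch: Module, samples: Sequence[Sample]) -> float:
    branch.eval()
    total = 0.0
    for s in samples:
        total += bce_loss(_forward(branch, s).data, s.labels, reduction="mean")
    return total / len(samples)


def branch_scores(branch: Module, samples: Sequence[Sample]) -> np.ndarray:
    """Inference-mode score matrix (N×C) for a trained branch."""
    branch.eval()
    return np.stack([_forward(branch, s).data for s in samples])


def train_branch(branch: Module, train: Sequence[Sample], valid: Sequence[Sample],
                 config: TrainConfig, kind: str) -> dict:
    """Optimize one branch; returns a history record, best parameters restored.

    kind selects the learning rate / batch size pair ("agcn" or "mcnn").
    """
    if not train or not valid:
        raise ValueError("empty dataset")
    if kind not in ("agcn", "mcnn"):
        raise ValueError("kind must be 'agcn' or 'mcnn'")
    lr = config.lr_agcn if kind == "agcn" else config.lr_mcnn
    batch = min(config.batch_agcn if kind == "agcn" else config.batch_mcnn, len(train))

    rng = np.random.default_rng(config.seed)
    opt = Adam(branch.parameters(), lr=lr)
    stopper = EarlyStopper(config.patience)
    best_state = [a.copy() for a in branch.state_arrays()]
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        branch.train()
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            opt.zero_grad()
            loss = None
            for j in idx:
                term = bce_loss(_forward(branch, train[j]), Tensor(train[j].labels),
                                reduction="mean")
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(idx))
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        train_loss = epoch_loss / len(order)
        val_loss = _dataset_loss(branch, valid)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if stopper.update(val_loss):
            best_state = [a.copy() for a in branch.state_arrays()]
        if stopper.should_stop:
            break

    branch.load_state_arrays(best_state)
    return {"history": history, "best_epoch": stopper.best_epoch,
            "best_val_loss": stopper.best, "stopped_epoch": stopper.epoch}


def train_fusion(agcn: Module, mcnn: Module, train: Sequence[Sample],
                 valid: Sequence[Sample], config: TrainConfig,
                 mode: str = "per_sample") -> tuple[FusionParams, dict]:
    """Phase three: freeze both branches, fit the fusion parameters.

    The fusion weight is fitted on the *validation* split (stacking-style
    held-out weighting): the branches were already selected by validation
    loss, and fitting α on training data would let a branch that overfits
    the training split dominate the blend.  Fitting on the held-out split
    makes the fused validation loss at most that of the better branch (the
    objective is convex in α, and α = 0/1 recover the single branches).
    Branch scores are precomputed once (the branches are frozen), so each
    epoch is one full-batch Adam step; early stopping uses the same
    validation objective.
    """
    s_gcn_tr = branch_scores(agcn, train)
    s_cnn_tr = branch_scores(mcnn, train)
    s_gcn_va = branch_scores(agcn, valid)
    s_cnn_va = branch_scores(mcnn, valid)
    y_tr = np.stack([s.labels for s in train]).astype(np.float64)
    y_va = np.stack([s.labels for s in valid]).astype(np.float64)

    params = FusionParams(train[0].labels.size, mode=mode, seed=config.seed)
    opt = Adam(params.parameters(), lr=config.lr_fusion)
    stopper = EarlyStopper(config.patience)
    best_state = [a.copy() for a in params.state_arrays()]
    history: list[dict] = []

    def fused_matrix(sg: np.ndarray, sc: np.ndarray) -> Tensor:
        rows = [adaptive_fuse(Tensor(sg[i]), Tensor(sc[i]), params).reshape(1, -1)
                for i in range(sg.shape[0])]
        return concat(rows, axis=0)

    for epoch in range(1, config.max_epochs + 1):
        opt.zero_grad()
        loss = bce_loss(fused_matrix(s_gcn_va, s_cnn_va), Tensor(y_va), reduction="mean")
        loss.backward()
        opt.step()
        val_loss = float(bce_loss(fused_matrix(s_gcn_va, s_cnn_va), Tensor(y_va),
                                  reduction="mean").data)
        train_loss = float(bce_loss(fused_matrix(s_gcn_tr, s_cnn_tr), Tensor(y_tr),
                                    reduction="mean").data)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if stopper.update(val_loss):
            best_state = [a.copy() for a in params.state_arrays()]
        if stopper.should_stop:
            break

    params.load_state_arrays(best_state)
    return params, {"history": history, "best_epoch": stopper.best_epoch,
                    "best_val_loss": stopper.best, "stopped_epoch": stopper.epoch}
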