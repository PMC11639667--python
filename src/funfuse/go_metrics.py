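"""Gene Ontology handling and protein-centric CAFA-style evaluation.

The ontology is a rooted DAG with child→parent ``is_a`` edges.  Ground-truth
annotation matrices are made consistent by ancestor closure (annotating a term
implies all of its ancestors), and predictions are scored with the three
standard protein-centric metrics:

* ``Fmax`` — maximum over score thresholds of the protein-averaged F1;
* ``Smin`` — minimum over thresholds of √(ru² + mi²), where remaining
  uncertainty ru and misinformation mi weight missed / spurious terms by
  their information content;
* ``AUPR`` — trapezoidal area under the micro-averaged precision–recall
  curve over all protein–term pairs.

Thresholds run over the grid 0.01, 0.02, …, 1.00 and a term counts as
predicted at threshold t when its score is ≥ t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

THRESHOLD_GRID = np.round(np.arange(1, 101) * 0.01, 2)

__all__ = [
    "GoDag", "EvalPair", "read_obo", "read_parent_child_tsv",
    "read_annotations_tsv", "write_annotations_tsv",
    "read_predictions_tsv", "write_predictions_tsv",
    "propagate_ancestors", "propagate_scores_max", "information_content",
    "fmax", "smin", "aupr", "evaluate_all", "THRESHOLD_GRID",
]


@dataclass
class GoDag:
    """Rooted DAG of ontology terms with child→parent edges.

    Invariants checked at construction: acyclic; exactly one root (a term
    with no parents); every term reaches the root.
    """

    terms: list[str]
    parent_edges: list[tuple[str, str]]
    graph: nx.DiGraph = field(init=False, repr=False)
    root: str = field(init=False)

    def __post_init__(self):
        if not self.terms:
            raise ValueError("empty ontology")
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.terms)
        for child, parent in self.parent_edges:
            if child not in self.graph or parent not in self.graph:
                raise ValueError(f"edge ({child}, {parent}) references unknown term")
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph has a cycle")
        roots = [t for t in self.terms if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        for t in self.terms:
            if t != self.root and self.root not in nx.descendants(self.graph, t):
                raise ValueError(f"term {t} does not reach the root")
        self.index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def ancestors(self, term: str) -> set[str]:
        """Proper ancestors of a term (term itself excluded)."""
        return set(nx.descendants(self.graph, term))

    def leaves(self) -> list[str]:
        """Terms with no children, in term order."""
        return [t for t in self.terms if self.graph.in_degree(t) == 0]

    def closure_matrix(self) -> np.ndarray:
        """C×C boolean matrix: entry (j, k) true iff k is j or an ancestor of j."""
        C = self.n_terms
        M = np.eye(C, dtype=bool)
        for t in self.terms:
            j = self.index[t]
            for a in self.ancestors(t):
                M[j, self.index[a]] = True
        return M


@dataclass
class EvalPair:
    """Aligned ground truth (N×C binary, ancestor-closed) and scores (N×C in [0,1])."""

    truth: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.truth.shape != self.scores.shape or self.truth.ndim != 2:
            raise ValueError("truth and scores must be equal-shape N×C matrices")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_obo(path: str | Path) -> GoDag:
    """Minimal OBO reader: ``[Term]`` stanzas, ``id:`` and ``is_a:`` lines only.

    Obsolete terms are dropped.  ``part_of``/``regulates`` relationships are
    out of scope.
    """
    terms: list[str] = []
    edges: list[tuple[str, str]] = []
    cur_id: str | None = None
    cur_parents: list[str] = []
    obsolete = False
    in_term = False

    def flush():
        nonlocal cur_id, cur_parents, obsolete
        if cur_id is not None and not obsolete:
            terms.append(cur_id)
            edges.extend((cur_id, p) for p in cur_parents)
        cur_id, cur_parents, obsolete = None, [], False

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term or not line:
            continue
        if line.startswith("id:"):
            cur_id = line[3:].strip()
        elif line.startswith("is_a:"):
            edges_part = line[5:].split("!")[0].strip()
            cur_parents.append(edges_part)
        elif line.startswith("is_obsolete:") and "true" in line:
            obsolete = True
    flush()
    known = set(terms)
    edges = [(c, p) for c, p in edges if p in known]
    return GoDag(terms=terms, parent_edges=edges)


def read_parent_child_tsv(path: str | Path) -> GoDag:
    """Two-column child<TAB>parent fallback format (header optional)."""
    edges: list[tuple[str, str]] = []
    terms: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lower().startswith(("child", "#")):
            continue
        child, parent = line.split("\t")[:2]
        for t in (child.strip(), parent.strip()):
            if t not in seen:
                seen.add(t)
                terms.append(t)
        edges.append((child.strip(), parent.strip()))
    return GoDag(terms=terms, parent_edges=edges)


def write_parent_child_tsv(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for c, p in dag.parent_edges:
            fh.write(f"{c}\t{p}\n")


def read_annotations_tsv(path: str | Path, protein_ids: list[str], dag: GoDag) -> np.ndarray:
    """2-column (protein_id, term_id) TSV → N×C binary matrix (not auto-closed)."""
    rows = {p: i for i, p in enumerate(protein_ids)}
    ann = np.zeros((len(protein_ids), dag.n_terms), dtype=bool)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lower().startswith(("protein", "#")):
            continue
        pid, term = line.split("\t")[:2]
        pid, term = pid.strip(), term.strip()
        if term not in dag.index:
            raise KeyError(f"unknown term {term!r} in {path}")
        if pid in rows:
            ann[rows[pid], dag.index[term]] = True
    return ann


def write_annotations_tsv(ann: np.ndarray, protein_ids: list[str], dag: GoDag,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\n")
        for i, pid in enumerate(protein_ids):
            for j in np.flatnonzero(ann[i]):
                fh.write(f"{pid}\t{dag.terms[j]}\n")


def write_predictions_tsv(scores: np.ndarray, protein_ids: list[str], dag: GoDag,
                          path: str | Path, decimals: int = 3) -> None:
    """CAFA-style 3-column (protein_id, term_id, score) TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\tscore\n")
        for i, pid in enumerate(protein_ids):
            for j, term in enumerate(dag.terms):
                fh.write(f"{pid}\t{term}\t{scores[i, j]:.{decimals}f}\n")


def read_predictions_tsv(path: str | Path, protein_ids: list[str], dag: GoDag) -> np.ndarray:
    rows = {p: i for i, p in enumerate(protein_ids)}
    scores = np.zeros((len(protein_ids), dag.n_terms))
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lower().startswith(("protein", "#")):
            continue
        pid, term, val = line.split("\t")[:3]
        if pid in rows:
            scores[rows[pid], dag.index[term.strip()]] = float(val)
    return scores


# ---------------------------------------------------------------------------
# Annotation closure and information content
# ---------------------------------------------------------------------------


def propagate_ancestors(annotations: np.ndarray, dag: GoDag) -> np.ndarray:
    """Close an N×C binary annotation matrix under the ancestor relation.

    Idempotent: applying it to an already-closed matrix is a no-op.
    """
    ann = np.asarray(annotations, dtype=bool)
    if ann.shape[1] != dag.n_terms:
        raise ValueError(f"annotation matrix has {ann.shape[1]} columns, DAG has {dag.n_terms} terms")
    return (ann.astype(np.int64) @ dag.closure_matrix().astype(np.int64)) > 0


def propagate_scores_max(scores: np.ndarray, dag: GoDag) -> np.ndarray:
    """Optional prediction-time propagation: ancestor score = max over descendants.

    Not applied by default anywhere; provided for hierarchically consistent
    score post-processing.
    """
    out = np.array(scores, dtype=np.float64)
    for t in nx.topological_sort(dag.graph):  # children before parents
        j = dag.index[t]
        for p in dag.graph.successors(t):
            k = dag.index[p]
            out[:, k] = np.maximum(out[:, k], out[:, j])
    return out


def information_content(annotations: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Per-term IC in bits from a closed N×C annotation matrix.

    IC(t) = −log₂((count(t)+pseudo)/(N+pseudo)); with zero pseudocount an
    unannotated term is capped at −log₂(1/(N+1)).
    """
    ann = np.asarray(annotations, dtype=bool)
    N = ann.shape[0]
    if N < 1:
        raise ValueError("need at least one protein")
    counts = ann.sum(axis=0).astype(np.float64)
    if pseudocount > 0:
        return -np.log2((counts + pseudocount) / (N + pseudocount))
    ic = np.full(counts.shape, np.log2(N + 1.0))
    nz = counts > 0
    ic[nz] = -np.log2(counts[nz] / N)
    ic[ic == 0] = 0.0  # normalize -0.0 for ubiquitous terms
    return ic


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def fmax(pair: EvalPair) -> tuple[float, float]:
    """Protein-centric Fmax and its argmax threshold.

    At each threshold, precision is averaged over proteins with at least one
    predicted term and recall over proteins with at least one true term;
    thresholds where no protein has a prediction leave F undefined.  If no
    threshold yields any prediction, Fmax is 0 by convention.
    """
    truth, scores = pair.truth, pair.scores
    best_f, best_t = 0.0, float("nan")
    n_true = truth.sum(axis=1)
    has_truth = n_true > 0
    for t in THRESHOLD_GRID:
        pred = scores >= t
        n_pred = pred.sum(axis=1)
        covered = n_pred > 0
        if not covered.any() or not has_truth.any():
            continue
        tp = (pred & truth).sum(axis=1)
        pr = float(np.mean(tp[covered] / n_pred[covered]))
        rc = float(np.mean(tp[has_truth] / n_true[has_truth]))
        f = 0.0 if pr + rc == 0 else 2 * pr * rc / (pr + rc)
        if f > best_f:
            best_f, best_t = f, float(t)
    return best_f, best_t


def smin(pair: EvalPair, ic: np.ndarray) -> float:
    """Minimum over thresholds of √(ru² + mi²), averaged over all proteins."""
    truth, scores = pair.truth, pair.scores
    ic = np.asarray(ic, dtype=np.float64)
    N = truth.shape[0]
    best = float("inf")
    for t in THRESHOLD_GRID:
        pred = scores >= t
        ru = float(((truth & ~pred) * ic).sum() / N)
        mi = float(((pred & ~truth) * ic).sum() / N)
        best = min(best, float(np.sqrt(ru * ru + mi * mi)))
    return best


def aupr(pair: EvalPair) -> float:
    """Micro-averaged area under the precision–recall curve (trapezoidal).

    All N·C protein–term pairs are ranked together; a PR point is taken at
    every distinct score cutoff and the area integrated over recall starting
    from (recall 0, precision of the top cutoff).
    """
    y = pair.truth.ravel().astype(np.int64)
    s = pair.scores.ravel()
    P = int(y.sum())
    if P == 0:
        raise ValueError("AUPR undefined with zero positive protein–term pairs")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    k = np.arange(1, y.size + 1)
    # last index of each distinct-score block = a cutoff "score >= s_sorted[i]"
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate([boundary, [y.size - 1]])
    recall = tp[idx] / P
    precision = tp[idx] / k[idx]
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.sum(np.diff(r) * (p[1:] + p[:-1]) / 2.0))


def evaluate_all(pair: EvalPair, ic: np.ndarray | None = None) -> dict[str, float]:
    """Fmax, Smin and AUPR in one record (IC from the evaluation truth if absent)."""
    if ic is None:
        ic = information_content(pair.truth)
    f, t = fmax(pair)
    return {"fmax": f, "fmax_threshold": t, "smin": smin(pair, ic), "aupr": aupr(pair)}
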