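"""Ancestral motif inference: alignment, tree building and marginal
maximum-likelihood posteriors at the root.

The workflow mirrors classical ancestral sequence reconstruction of a small
family of tandem-repeat motifs: the motifs are multiply aligned, assembled
into a neighbour-joining tree on maximum-likelihood pairwise distances,
branch lengths are polished by per-branch likelihood optimisation, and the
per-column marginal posterior distribution over the 20 amino acids is
computed at the midpoint root with Felsenstein's pruning algorithm.  The
most probable ancestor (MPA) is the per-position argmax of that posterior.

Gapped leaves are treated as missing data (a vector of ones in the pruning
recursion), the convention used by marginal reconstruction tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .seqrep import _GLOBAL_ALIGNER, pairwise_identity
from .substmodel import (AA_INDEX, AMINO_ACIDS, SubstitutionModel, get_model)

__all__ = [
    "MotifAlignment", "AncestralPosterior", "align_motifs", "build_tree",
    "root_posteriors", "extract_mpa", "tree_log_likelihood",
    "read_alignment_fasta", "write_tree_newick", "posterior_to_tsv",
]


@dataclass
class MotifAlignment:
    """A gapped multiple alignment of repeat motifs."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment requires at least two rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def pairwise_column_identity(self, i: int, j: int) -> float:
        """Identity of two rows over columns where neither is gapped."""
        matches = columns = 0
        for a, b in zip(self.rows[i], self.rows[j]):
            if a != "-" and b != "-":
                columns += 1
                matches += a == b
        return matches / columns if columns else 0.0


@dataclass
class AncestralPosterior:
    """Per-position marginal posterior over amino acids at the tree root."""

    posterior: np.ndarray          # (n_positions, 20) in AMINO_ACIDS order
    mpa: str
    max_prob: np.ndarray
    columns: list[int]             # alignment columns retained as positions

    @property
    def n_positions(self) -> int:
        return self.posterior.shape[0]


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def align_motifs(motifs: list[str], labels: list[str] | None = None
                 ) -> MotifAlignment:
    """Progressive (center-star) global alignment of repeat motifs.

    The center is the motif with the highest summed pairwise identity to the
    others; every other motif is aligned to it and the pairwise gap patterns
    are merged.  Row order follows the input order.
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motifs to align")
    if labels is None:
        labels = [f"motif{i + 1}" for i in range(len(motifs))]
    k = len(motifs)
    if len(set(motifs)) == 1:
        return MotifAlignment(list(labels), list(motifs))
    sums = np.zeros(k)
    for i in range(k):
        for j in range(i + 1, k):
            ident = pairwise_identity(motifs[i], motifs[j])
            sums[i] += ident
            sums[j] += ident
    center = int(np.argmax(sums))
    c = motifs[center]
    lc = len(c)
    # per-motif: residues inserted before each center position, and the
    # residue (or gap) paired with each center position
    ins: list[list[list[str]]] = []
    paired: list[list[str]] = []
    for i in range(k):
        if i == center:
            ins.append([[] for _ in range(lc + 1)])
            paired.append(list(c))
            continue
        aln = _GLOBAL_ALIGNER.align(c, motifs[i])[0]
        row_c, row_m = _gapped_rows(aln)
        pre: list[list[str]] = [[] for _ in range(lc + 1)]
        par: list[str] = []
        j = 0
        for cc, mm in zip(row_c, row_m):
            if cc == "-":
                pre[j].append(mm)
            else:
                par.append(mm)
                j += 1
        ins.append(pre)
        paired.append(par)
    master = [max(len(ins[i][j]) for i in range(k)) for j in range(lc + 1)]
    rows = []
    for i in range(k):
        out = []
        for j in range(lc + 1):
            chunk = ins[i][j]
            out.append("-" * (master[j] - len(chunk)) + "".join(chunk))
            if j < lc:
                out.append(paired[i][j])
        rows.append("".join(out))
    return MotifAlignment(list(labels), rows)


def build_tree(alignment: MotifAlignment, model: str = "jtt") -> TreeNode:
    """Neighbour-joining on pairwise maximum-likelihood distances, rooted at
    the midpoint.  Deterministic given the input row order."""
    m = get_model(model)
    k = len(alignment.rows)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ident = alignment.pairwise_column_identity(i, j)
            d = m.ml_distance(ident)
            dist[i, j] = dist[j, i] = d
    dm = DistanceMatrix(dist, ids=alignment.labels)
    if k == 2:
        half = dist[0, 1] / 2.0
        tree = TreeNode.read(
            [f"({alignment.labels[0]}:{half},{alignment.labels[1]}:{half});"])
        return tree
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if dist.max() > 0:
        tree = tree.root_at_midpoint()
    else:
        tree = tree.copy()
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Pruning-algorithm likelihoods and root posteriors

def _leaf_conditionals(alignment: MotifAlignment) -> dict[str, np.ndarray]:
    cond = {}
    for label, row in zip(alignment.labels, alignment.rows):
        arr = np.ones((len(row), 20))
        for i, ch in enumerate(row):
            if ch in AA_INDEX:
                arr[i] = 0.0
                arr[i, AA_INDEX[ch]] = 1.0
        cond[label] = arr
    return cond


def _node_conditionals(node: TreeNode, leaf_cond: dict[str, np.ndarray],
                       model: SubstitutionModel) -> np.ndarray:
    """Conditional likelihoods L_v(a) for the subtree below ``node`` (before
    applying ``node``'s own branch)."""
    if node.is_tip():
        return leaf_cond[node.name]
    res = None
    for child in node.children:
        down = _node_conditionals(child, leaf_cond, model)
        p = model.transition_matrix(child.length or 0.0)
        contrib = down @ p.T
        res = contrib if res is None else res * contrib
    return res


def tree_log_likelihood(alignment: MotifAlignment, tree: TreeNode,
                        model: str | SubstitutionModel = "jtt") -> float:
    """Total log-likelihood of the alignment on the tree under the model,
    computed by the pruning algorithm with stationary root frequencies."""
    m = model if isinstance(model, SubstitutionModel) else get_model(model)
    leaf_cond = _leaf_conditionals(alignment)
    root_cond = _node_conditionals(tree, leaf_cond, m)
    site_lik = root_cond @ m.frequencies
    return float(np.sum(np.log(np.maximum(site_lik, 1e-300))))


def _polish_branch_lengths(alignment: MotifAlignment, tree: TreeNode,
                           m: SubstitutionModel) -> TreeNode:
    """One round of per-branch Brent optimisation of the total
    log-likelihood."""
    tree = tree.copy()
    branches = [n for n in tree.traverse() if not n.is_root()]
    for node in branches:
        def negll(t, node=node):
            node.length = float(t)
            return -tree_log_likelihood(alignment, tree, m)
        res = minimize_scalar(negll, bounds=(1e-8, 10.0), method="bounded",
                              options={"xatol": 1e-4})
        node.length = float(res.x)
    return tree


def root_posteriors(alignment: MotifAlignment, tree: TreeNode,
                    model: str = "jtt",
                    polish_branches: bool = True) -> AncestralPosterior:
    """Marginal posterior distributions at the root of ``tree``.

    For each alignment column, the posterior over ancestral amino acids a is
    proportional to pi_a times the product over the root's children of the
    pruned conditional likelihoods propagated across their branches.  Columns
    gapped in half or more of the rows are dropped from the reported
    positions (the ancestor is reconstructed as an ungapped motif).
    """
    m = get_model(model)
    leaves = {t.name for t in tree.tips()}
    if leaves != set(alignment.labels):
        raise ValueError("tree leaves do not match alignment labels")
    if polish_branches:
        tree = _polish_branch_lengths(alignment, tree, m)
    leaf_cond = _leaf_conditionals(alignment)
    root_cond = _node_conditionals(tree, leaf_cond, m)
    post = m.frequencies[np.newaxis, :] * root_cond
    post /= post.sum(axis=1, keepdims=True)
    n_rows = len(alignment.rows)
    keep = [j for j in range(alignment.n_columns)
            if sum(r[j] == "-" for r in alignment.rows) * 2 < n_rows]
    post = post[keep]
    mpa, max_prob = _argmax_alpha(post)
    return AncestralPosterior(posterior=post, mpa=mpa, max_prob=max_prob,
                              columns=keep)


def _argmax_alpha(post: np.ndarray, tol: float = 1e-12
                  ) -> tuple[str, np.ndarray]:
    """Per-position argmax with alphabetical tie-breaking."""
    out = []
    maxima = post.max(axis=1)
    for i in range(post.shape[0]):
        tied = [AMINO_ACIDS[k] for k in range(20)
                if post[i, k] >= maxima[i] - tol]
        out.append(min(tied))
    return "".join(out), maxima


def extract_mpa(posterior: AncestralPosterior) -> str:
    """The most probable ancestor: per-position argmax residues, ties broken
    alphabetically."""
    mpa, _ = _argmax_alpha(posterior.posterior)
    return mpa


# ---------------------------------------------------------------------------
# I/O

def read_alignment_fasta(path: str | Path) -> MotifAlignment:
    from Bio import SeqIO
    labels, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MotifAlignment(labels, rows)


def write_tree_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def posterior_to_tsv(posterior: AncestralPosterior,
                     path: str | Path | None = None) -> pd.DataFrame:
    """Posterior table: one row per position (1-based), 20 probability
    columns plus the MPA residue and its probability."""
    df = pd.DataFrame(posterior.posterior, columns=list(AMINO_ACIDS))
    df.insert(0, "position", np.arange(1, posterior.n_positions + 1))
    df["mpa"] = list(posterior.mpa)
    df["max_prob"] = posterior.max_prob
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
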